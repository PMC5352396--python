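"""Simple renderings of the pipeline's data exports.

These are convenience plots (distance ECDFs, correlation heatmap); the
authoritative outputs are the TSV exports they are drawn from.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .integration import EcdfCurve
from .peaks import CorrelationMatrix

__all__ = ["plot_distance_ecdf", "plot_correlation_heatmap"]


def _get_axes(ax=None):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    return ax


def plot_distance_ecdf(curves: Mapping[str, EcdfCurve], path: str | Path | None = None,
                       ax=None, max_distance: float | None = None):
    """Step plot of nearest-peak distance ECDFs, one line per group."""
    ax = _get_axes(ax)
    for label, curve in curves.items():
        x = np.concatenate([[0.0], curve.support])
        y = np.concatenate([[0.0], curve.fraction])
        ax.step(x, y, where="post", label=label)
    if max_distance is not None:
        ax.set_xlim(0, max_distance)
    ax.set_xlabel("distance to nearest binding site (bp)")
    ax.set_ylabel("cumulative fraction of transcripts")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_correlation_heatmap(corr: CorrelationMatrix, path: str | Path | None = None,
                             ax=None):
    """Heatmap of pairwise Spearman correlations between samples."""
    ax = _get_axes(ax)
    n = len(corr.sample_ids)
    im = ax.imshow(corr.rho, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(n), corr.sample_ids, rotation=90)
    ax.set_yticks(range(n), corr.sample_ids)
    ax.figure.colorbar(im, ax=ax, label="Spearman rho")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
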