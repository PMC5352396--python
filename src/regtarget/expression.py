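"""Differential-expression filtering and direction classification.

The contrast convention throughout is knockdown minus control on the log2
scale: a transcript that goes DOWN upon knockdown of the factor
(log2fc < 0) is classified as *activated* by the factor, one that goes UP
(log2fc > 0) as *repressed*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression_types import DOWN_UPON_KD, UP_UPON_KD
from .genomic_io import DERecord
from .peaks import Linkage, hierarchical_cluster

__all__ = ["FilteredDE", "filter_de", "expression_heatmap_order",
           "DOWN_UPON_KD", "UP_UPON_KD"]

_SEX_CHROMS = {"x", "y"}


def _is_sex_chrom(chrom: str) -> bool:
    c = chrom.lower()
    if c.startswith("chr"):
        c = c[3:]
    return c in _SEX_CHROMS


@dataclass
class FilteredDE:
    """DE records surviving the fold-change filter, with per-transcript direction."""

    retained: list[DERecord]
    direction: dict[str, str] = field(default_factory=dict)
    fold_threshold: float = 2.0
    n_boundary_excluded: int = 0

    @property
    def n_down(self) -> int:
        return sum(1 for d in self.direction.values() if d == DOWN_UPON_KD)

    @property
    def n_up(self) -> int:
        return sum(1 for d in self.direction.values() if d == UP_UPON_KD)

    def ids(self, direction: Optional[str] = None) -> set[str]:
        if direction is None:
            return set(self.direction)
        return {t for t, d in self.direction.items() if d == direction}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.transcript_id, r.chrom, r.log2fc,
             np.nan if r.padj is None else r.padj,
             self.direction[r.transcript_id])
            for r in self.retained
        ]
        return pd.DataFrame(
            rows, columns=["transcript_id", "chrom", "log2fc", "padj", "direction"]
        )


def filter_de(
    records: Sequence[DERecord],
    fold_threshold: float = 2.0,
    drop_sex_chromosomes: bool = True,
    padj_threshold: Optional[float] = None,
) -> FilteredDE:
    """Retain transcripts with a fold change strictly beyond the threshold.

    Records on chrX/chrY (any case, with or without "chr" prefix) are removed
    before filtering when ``drop_sex_chromosomes`` is set. The retention rule
    is strict: ``|log2fc| > log2(fold_threshold)``, so a transcript at exactly
    the threshold fold change is excluded (and counted in
    ``n_boundary_excluded``). No significance filter is applied unless
    ``padj_threshold`` is given.
    """
    if fold_threshold <= 1:
        raise ValueError(f"fold_threshold must be > 1, got {fold_threshold}")
    log2_cut = math.log2(fold_threshold)
    retained: list[DERecord] = []
    direction: dict[str, str] = {}
    n_boundary = 0
    for r in records:
        if drop_sex_chromosomes and _is_sex_chrom(r.chrom):
            continue
        if abs(r.log2fc) == log2_cut:
            n_boundary += 1
            continue
        if abs(r.log2fc) <= log2_cut:
            continue
        if padj_threshold is not None and (r.padj is None or r.padj > padj_threshold):
            continue
        retained.append(r)
        direction[r.transcript_id] = DOWN_UPON_KD if r.log2fc < 0 else UP_UPON_KD
    return FilteredDE(retained, direction, fold_threshold, n_boundary)


def expression_heatmap_order(matrix: pd.DataFrame) -> tuple[Linkage, list[str]]:
    """Ward/euclidean row clustering of a transcripts-by-samples matrix.

    Rows are standardized to mean 0, sd 1 first (constant rows are left at
    zero rather than erroring). Returns the linkage and the clustered row
    order as transcript labels.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 transcripts to cluster")
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    link = hierarchical_cluster(z, labels=[str(i) for i in matrix.index],
                                method="ward", metric="euclidean")
    order = [str(matrix.index[i]) for i in link.leaf_order]
    return link, order
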