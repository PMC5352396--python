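"""Overlap-based gene-set enrichment: hypergeometric upper tail with
Benjamini–Hochberg FDR control.

Enrichment is run separately for each regulation direction of a
direct-target set; BH adjustment is applied within each run across all
tested sets. The universe defaults to all autosomal genes in the annotation,
consistent with the sex-chromosome omission upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genomic_io import GeneSet

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich_gene_sets",
]


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N, K, n), via log-gamma."""
    k = np.asarray(k, dtype=float)

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logc(K, k) + logc(N - K, n - k) - logc(N, n)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    ``k`` = overlap, ``n`` = query size, ``K`` = set size in the universe,
    ``N`` = universe size.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(n, K, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    ks = np.arange(k, min(n, K) + 1)
    logs = _log_hypergeom_pmf(ks, N, K, n)
    m = logs.max()
    p = float(np.exp(m) * np.sum(np.exp(logs - m)))
    return min(max(p, float(np.nextafter(0, 1))), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, preserving input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), clamped to <= 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int       # overlap count
    n: int       # query size after universe restriction
    K: int       # set size in universe
    N: int       # universe size
    p_value: float
    q_value: float


def enrich_gene_sets(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    transcript_to_gene: Optional[Mapping[str, str]] = None,
) -> list[EnrichmentResult]:
    """Hypergeometric overlap enrichment of a query against gene sets.

    The query is intersected with the universe (ids outside it are dropped);
    an optional transcript-to-gene mapping is applied first and duplicates
    collapse, so a gene contributes at most once to any overlap. Sets with no
    members in the universe are skipped. Results are BH-adjusted across all
    tested sets and sorted ascending by (q, p).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    q_ids = set(query)
    if transcript_to_gene is not None:
        q_ids = {transcript_to_gene.get(t, t) for t in q_ids}
    query_in = q_ids & universe_set
    n = len(query_in)
    N = len(universe_set)
    rows = []
    for gs in sets:
        members_in = gs.members & universe_set
        K = len(members_in)
        if K == 0:
            continue
        k = len(query_in & members_in)
        rows.append((gs.set_name, k, K, hypergeom_upper_tail(k, n, K, N)))
    if not rows:
        return []
    qvals = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(name, k, n, K, N, p, float(qv))
        for (name, k, K, p), qv in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.set_name, r.k, r.K, r.n, r.N, r.p_value, r.q_value) for r in results],
        columns=["set_name", "k", "K", "n", "N", "p_value", "q_value"],
    )
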