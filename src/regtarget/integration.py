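"""Binding–expression integration: TSS-to-peak distances, empirical CDFs,
the two-sample Kolmogorov–Smirnov enrichment test, and direct-target calling.

The central inference: differentially expressed transcripts whose nearest
high-confidence binding site lies within a distance cutoff (default 50 kb)
of their TSS are called direct targets, split by regulation direction. The
KS test compares the DE transcripts' nearest-peak distance distribution with
that of the annotated background; transcripts with no same-chromosome peak
carry an infinite distance that counts in sample sizes and ECDF denominators
but contributes no finite support point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .expression import FilteredDE
from .expression_types import DOWN_UPON_KD, UP_UPON_KD
from .genomic_io import PeakSet, TranscriptRecord

__all__ = [
    "DistanceResult",
    "EcdfCurve",
    "KSResult",
    "DirectTargetSet",
    "nearest_peak_distance",
    "distance_ecdf",
    "ks_two_sample",
    "call_direct_targets",
    "fraction_within",
    "intersect_target_sets",
]


# ---------------------------------------------------------------------------
# nearest-peak distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceResult:
    transcript_id: str
    distance: float  # bp; math.inf when no peak shares the chromosome
    nearest_peak: Optional[str]

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if (self.nearest_peak is None) != math.isinf(self.distance):
            raise ValueError("nearest_peak must be None iff distance is infinite")


def nearest_peak_distance(
    tss_records: Sequence[TranscriptRecord],
    peaks: PeakSet,
    mode: Literal["summit", "edge"] = "summit",
) -> list[DistanceResult]:
    """Distance from each TSS to the nearest same-chromosome peak.

    Unstranded absolute distance. ``summit`` (default) measures to the peak
    summit; ``edge`` measures to the nearest covered base (0 when the TSS
    falls inside the peak). Transcripts on chromosomes with no peak get an
    infinite sentinel.
    """
    if mode == "summit":
        by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
        for chrom, plist in peaks.by_chrom().items():
            order = sorted(plist, key=lambda p: p.summit)
            by_chrom[chrom] = (
                np.array([p.summit for p in order]), [p.name for p in order]
            )
        out = []
        for t in tss_records:
            if t.chrom not in by_chrom:
                out.append(DistanceResult(t.transcript_id, math.inf, None))
                continue
            summits, names = by_chrom[t.chrom]
            i = int(np.searchsorted(summits, t.tss))
            best = None
            for j in (i - 1, i):
                if 0 <= j < len(summits):
                    d = abs(int(summits[j]) - t.tss)
                    if best is None or d < best[0]:
                        best = (d, names[j])
            assert best is not None
            out.append(DistanceResult(t.transcript_id, float(best[0]), best[1]))
        return out
    if mode == "edge":
        edge_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        for chrom, plist in peaks.by_chrom().items():
            edge_by_chrom[chrom] = (
                np.array([p.interval.start for p in plist]),
                np.array([p.interval.end for p in plist]),
                [p.name for p in plist],
            )
        out = []
        for t in tss_records:
            if t.chrom not in edge_by_chrom:
                out.append(DistanceResult(t.transcript_id, math.inf, None))
                continue
            starts, ends, names = edge_by_chrom[t.chrom]
            d = np.maximum.reduce([starts - t.tss, t.tss - (ends - 1),
                                   np.zeros(len(starts), dtype=np.int64)])
            j = int(np.argmin(d))
            out.append(DistanceResult(t.transcript_id, float(d[j]), names[j]))
        return out
    raise ValueError(f"unknown distance mode {mode!r}")


def distances_to_frame(results: Sequence[DistanceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.transcript_id, r.distance, r.nearest_peak or "") for r in results],
        columns=["transcript_id", "distance", "nearest_peak"],
    )


# ---------------------------------------------------------------------------
# ECDF
# ---------------------------------------------------------------------------


@dataclass
class EcdfCurve:
    """Right-continuous empirical CDF over nearest-peak distances.

    Infinite sentinels are counted in the denominator (they are evidence
    against proximity) but never appear as support points, so the last
    fraction is 1 only when every distance is finite.
    """

    support: np.ndarray
    fraction: np.ndarray
    n_total: int
    n_infinite: int

    def __call__(self, d: float) -> float:
        i = int(np.searchsorted(self.support, d, side="right"))
        return 0.0 if i == 0 else float(self.fraction[i - 1])


def distance_ecdf(distances) -> EcdfCurve:
    d = np.asarray([float(x) for x in distances])
    if len(d) == 0:
        raise ValueError("no distances given")
    finite = np.sort(d[np.isfinite(d)])
    if len(finite) == 0:
        raise ValueError("all distances are infinite; ECDF undefined")
    support, counts = np.unique(finite, return_counts=True)
    fraction = np.cumsum(counts) / len(d)
    return EcdfCurve(support, fraction, len(d), int(len(d) - len(finite)))


# ---------------------------------------------------------------------------
# two-sample KS test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KSResult:
    d_stat: float
    p_value: float
    n1: int
    n2: int
    method: str


def _ks_d(d1: np.ndarray, d2: np.ndarray) -> float:
    """Sup of |F1 - F2| evaluated at every finite observed value."""
    support = np.unique(np.concatenate([d1[np.isfinite(d1)], d2[np.isfinite(d2)]]))
    if len(support) == 0:
        raise ValueError("both samples entirely infinite; d undefined")
    f1 = np.searchsorted(np.sort(d1), support, side="right") / len(d1)
    f2 = np.searchsorted(np.sort(d2), support, side="right") / len(d2)
    return float(np.max(np.abs(f1 - f2)))


def _ks_asymptotic_p(d: float, n1: int, n2: int) -> float:
    """Asymptotic tail probability with small-sample correction.

    lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D with ne = n1*n2/(n1+n2);
    Q(lambda) = 2 * sum_{j>=1} (-1)^(j-1) exp(-2 j^2 lambda^2), truncated when
    terms drop below 1e-10, clamped to (0, 1].
    """
    if d <= 0:
        return 1.0
    ne = n1 * n2 / (n1 + n2)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
    total = 0.0
    for j in range(1, 100001):
        term = math.exp(-2.0 * j * j * lam * lam)
        total += term if j % 2 else -term
        if term < 1e-10:
            break
    p = 2.0 * total
    return min(max(p, float(np.nextafter(0, 1))), 1.0)


@lru_cache(maxsize=8)
def _combination_masks(n: int, n1: int) -> np.ndarray:
    """All C(n, n1) boolean assignment masks over n pooled positions."""
    combs = np.fromiter(
        (i for c in combinations(range(n), n1) for i in c), dtype=np.intp
    ).reshape(-1, n1)
    masks = np.zeros((combs.shape[0], n), dtype=bool)
    masks[np.arange(combs.shape[0])[:, None], combs] = True
    return masks


def _ks_exact_p(d1: np.ndarray, d2: np.ndarray, d_obs: float) -> float:
    """Exact permutation p: fraction of label assignments with D >= observed.

    Enumerates every split of the pooled values; ties (and infinite
    sentinels) are handled by evaluating ECDF differences only at the last
    position of each tie group of finite values.
    """
    n1, n2 = len(d1), len(d2)
    pooled = np.sort(np.concatenate([d1, d2]))
    n = n1 + n2
    # last index of each tie group, finite values only
    finite = np.isfinite(pooled)
    group_end = np.r_[pooled[1:] != pooled[:-1], True]
    eval_idx = np.nonzero(group_end & finite)[0]
    masks = _combination_masks(n, n1)
    c1 = np.cumsum(masks, axis=1)[:, eval_idx] / n1
    c2 = np.cumsum(~masks, axis=1)[:, eval_idx] / n2
    d_all = np.max(np.abs(c1 - c2), axis=1)
    return float(np.mean(d_all >= d_obs - 1e-12))


def _ks_montecarlo_p(
    d1: np.ndarray, d2: np.ndarray, d_obs: float, n_perm: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([d1, d2])
    n1 = len(d1)
    count = 0
    sorted_pool = np.sort(pooled)
    finite = np.isfinite(sorted_pool)
    group_end = np.r_[sorted_pool[1:] != sorted_pool[:-1], True]
    eval_idx = np.nonzero(group_end & finite)[0]
    labels = np.zeros(len(pooled), dtype=bool)
    labels[:n1] = True
    chunk = max(1, min(n_perm, 2_000_000 // max(1, len(pooled))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = np.argsort(rng.random((m, len(pooled))), axis=1)
        mask = labels[perm]
        # pooled is pre-sorted per permutation only in value space: permuting
        # labels over the sorted pool is equivalent to permuting the data.
        c1 = np.cumsum(mask, axis=1)[:, eval_idx] / n1
        c2 = np.cumsum(~mask, axis=1)[:, eval_idx] / (len(pooled) - n1)
        count += int(np.sum(np.max(np.abs(c1 - c2), axis=1) >= d_obs - 1e-12))
        done += m
    # add-one smoothing keeps the Monte-Carlo p in (0, 1]
    return (count + 1) / (n_perm + 1)


def ks_two_sample(
    d1,
    d2,
    method: Literal["auto", "asymptotic", "exact_permutation"] = "auto",
    seed: int = 0,
    max_enumeration: int = 200_000,
    n_montecarlo: int = 10_000,
) -> KSResult:
    """Two-sample KS test on (possibly infinite) distance samples.

    ``d_stat`` is the sup of |F1 - F2| over all finite observed values.
    ``exact_permutation`` enumerates all C(n1+n2, n1) label assignments when
    that count is at most ``max_enumeration``, otherwise falls back to a
    seeded Monte-Carlo permutation test; ``auto`` uses exact enumeration when
    feasible and the asymptotic series otherwise.
    """
    d1 = np.asarray([float(x) for x in d1])
    d2 = np.asarray([float(x) for x in d2])
    if len(d1) == 0 or len(d2) == 0:
        raise ValueError("both samples must be non-empty")
    d_obs = _ks_d(d1, d2)
    n1, n2 = len(d1), len(d2)
    n_splits = math.comb(n1 + n2, n1)
    if method == "auto":
        method_used = "exact_permutation" if n_splits <= max_enumeration else "asymptotic"
    else:
        method_used = method
    if method_used == "asymptotic":
        p = _ks_asymptotic_p(d_obs, n1, n2)
    elif method_used == "exact_permutation":
        if n_splits <= max_enumeration:
            p = _ks_exact_p(d1, d2, d_obs)
        else:
            p = _ks_montecarlo_p(d1, d2, d_obs, n_montecarlo, seed)
            method_used = "monte_carlo_permutation"
    else:
        raise ValueError(f"unknown method {method!r}")
    return KSResult(d_obs, min(max(p, float(np.nextafter(0, 1))), 1.0), n1, n2, method_used)


# ---------------------------------------------------------------------------
# direct targets
# ---------------------------------------------------------------------------


@dataclass
class DirectTargetSet:
    """DE transcripts with a high-confidence peak within the cutoff, by direction."""

    sample_id: str
    activated: set[str] = field(default_factory=set)   # down upon knockdown
    repressed: set[str] = field(default_factory=set)   # up upon knockdown
    cutoff: int = 50_000

    def __post_init__(self) -> None:
        if self.activated & self.repressed:
            raise ValueError("a transcript cannot be both activated and repressed")

    @property
    def all_targets(self) -> set[str]:
        return self.activated | self.repressed

    def __len__(self) -> int:
        return len(self.activated) + len(self.repressed)


def call_direct_targets(
    filtered: FilteredDE,
    distances: Sequence[DistanceResult],
    cutoff: int = 50_000,
    sample_id: str = "",
) -> DirectTargetSet:
    """Call direct targets: filtered DE transcripts with a peak within ``cutoff``.

    The boundary is inclusive ("within 50 kb"). Direction is carried over
    from the DE filter: down upon knockdown -> activated by the factor.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    dist_by_id = {r.transcript_id: r.distance for r in distances}
    targets = DirectTargetSet(sample_id, cutoff=cutoff)
    for tid, direction in filtered.direction.items():
        if tid not in dist_by_id:
            raise KeyError(f"no distance result for filtered transcript {tid!r}")
        if dist_by_id[tid] <= cutoff:
            (targets.activated if direction == DOWN_UPON_KD else targets.repressed).add(tid)
    return targets


def fraction_within(targets: DirectTargetSet, filtered: FilteredDE) -> float:
    """Fraction of retained DE transcripts that are direct targets."""
    if not filtered.retained:
        raise ValueError("empty filtered DE set")
    return len(targets) / len(filtered.retained)


def intersect_target_sets(a: DirectTargetSet, b: DirectTargetSet) -> pd.DataFrame:
    """Transcripts called targets in both samples, with per-set direction labels."""
    dir_a = {t: DOWN_UPON_KD for t in a.activated} | {t: UP_UPON_KD for t in a.repressed}
    dir_b = {t: DOWN_UPON_KD for t in b.activated} | {t: UP_UPON_KD for t in b.repressed}
    common = sorted(set(dir_a) & set(dir_b))
    return pd.DataFrame(
        [(t, dir_a[t], dir_b[t], dir_a[t] == dir_b[t]) for t in common],
        columns=["transcript_id", "direction_a", "direction_b", "direction_concordant"],
    )
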