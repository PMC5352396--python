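"""Replicate concordance, high-confidence peaks, summit-window signal,
cross-sample Spearman correlation, clustering and consensus-motif enrichment.

The replicate-combination logic implements the QC rule used for ChIP-seq
replicates: peaks reproducibly called in both replicates (any 1-bp overlap on
half-open intervals, one-to-one greedy pairing in genomic order) are merged
into a single set of high-confidence binding sites; concordance is reported
as shared pairs over the smaller replicate's peak count.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import binom, rankdata

from .genomic_io import GenomicInterval, Peak, PeakSet

__all__ = [
    "ConcordanceReport",
    "SignalMatrix",
    "CorrelationMatrix",
    "Linkage",
    "MotifEnrichmentResult",
    "replicate_concordance",
    "high_confidence_peaks",
    "summit_windows",
    "merge_intervals",
    "normalized_signal",
    "spearman_rho",
    "correlation_matrix",
    "hierarchical_cluster",
    "consensus_motif_enrichment",
]


# ---------------------------------------------------------------------------
# replicate concordance & high-confidence peaks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceReport:
    n_a: int
    n_b: int
    n_shared: int
    concordance: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_shared <= min(self.n_a, self.n_b)):
            raise ValueError("n_shared must be in [0, min(n_a, n_b)]")


def _overlap_pairs(a: PeakSet, b: PeakSet) -> list[tuple[Peak, Peak]]:
    """One-to-one pairs of overlapping peaks, greedy in genomic order.

    Both sets are swept in (chrom, start) order; when the current heads
    overlap they are paired and both consumed, otherwise the head that ends
    first is discarded. Each peak participates in at most one pair.
    """
    pa = a.sorted().peaks
    pb = b.sorted().peaks
    pairs: list[tuple[Peak, Peak]] = []
    i = j = 0
    while i < len(pa) and j < len(pb):
        x, y = pa[i], pb[j]
        if x.chrom != y.chrom:
            if x.chrom < y.chrom:
                i += 1
            else:
                j += 1
            continue
        if x.interval.start < y.interval.end and y.interval.start < x.interval.end:
            pairs.append((x, y))
            i += 1
            j += 1
        elif x.interval.end <= y.interval.start:
            i += 1
        else:
            j += 1
    return pairs


def replicate_concordance(
    a: PeakSet,
    b: PeakSet,
    denominator: Literal["min", "mean"] = "min",
) -> ConcordanceReport:
    """Fraction of peaks shared between two replicates.

    A pair counts as shared when the intervals overlap by >= 1 bp; pairing is
    one-to-one. ``denominator="min"`` (default) divides by the smaller
    replicate's peak count; ``"mean"`` averages the two per-replicate shared
    fractions.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("concordance is undefined for an empty peak set")
    n_shared = len(_overlap_pairs(a, b))
    if denominator == "min":
        conc = n_shared / min(len(a), len(b))
    elif denominator == "mean":
        conc = 0.5 * (n_shared / len(a) + n_shared / len(b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return ConcordanceReport(len(a), len(b), n_shared, conc)


def high_confidence_peaks(a: PeakSet, b: PeakSet, sample_id: str | None = None) -> PeakSet:
    """Merge replicate peaks into high-confidence binding sites.

    Each one-to-one overlapping pair yields one merged peak whose interval is
    the union of the two; summit and score come from the higher-scoring
    member (ties favour replicate ``a``). Peaks without a partner are dropped.
    """
    merged: list[Peak] = []
    for k, (x, y) in enumerate(_overlap_pairs(a, b)):
        winner = x if x.score >= y.score else y
        iv = GenomicInterval(
            x.chrom,
            min(x.interval.start, y.interval.start),
            max(x.interval.end, y.interval.end),
            x.interval.strand if x.interval.strand == y.interval.strand else ".",
        )
        merged.append(Peak(iv, winner.summit, winner.score, f"hc_{k + 1}"))
    return PeakSet(sample_id or f"{a.sample_id}+{b.sample_id}", merged)


# ---------------------------------------------------------------------------
# summit windows & normalized signal
# ---------------------------------------------------------------------------


def summit_windows(
    peak_set: PeakSet, chrom_sizes: Mapping[str, int], width: int = 100
) -> list[GenomicInterval]:
    """Fixed-width windows centred on each peak summit, clipped to the chromosome.

    Width must be even; each window is ``[summit - width/2, summit + width/2)``
    before clipping to ``[0, chrom length)``.
    """
    if width <= 0 or width % 2:
        raise ValueError(f"width must be even and > 0, got {width}")
    half = width // 2
    windows = []
    for p in peak_set.sorted():
        if p.chrom not in chrom_sizes:
            raise KeyError(f"chromosome {p.chrom!r} absent from chrom_sizes")
        length = chrom_sizes[p.chrom]
        if p.summit >= length:
            raise ValueError(f"summit {p.summit} beyond {p.chrom} length {length}")
        windows.append(
            GenomicInterval(p.chrom, max(0, p.summit - half), min(length, p.summit + half))
        )
    return windows


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping (>= 1 bp) intervals are merged."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            last = out.pop()
            iv = GenomicInterval(iv.chrom, last.start, max(last.end, iv.end))
        out.append(iv)
    return out


def normalized_signal(read_counts, library_size: float) -> np.ndarray:
    """Reads-per-million: ``count * 1e6 / library_size``."""
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    counts = np.asarray(read_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("read counts must be >= 0")
    return counts * 1e6 / library_size


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


@dataclass
class SignalMatrix:
    """Per-window, per-sample normalized signal (RPM)."""

    windows: list[GenomicInterval]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_windows, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.windows), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.windows)}, {len(self.sample_ids)})"
            )
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("signal values must be finite and >= 0")


@dataclass
class CorrelationMatrix:
    sample_ids: list[str]
    rho: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rho, index=self.sample_ids, columns=self.sample_ids)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (with a warning) when either vector has zero rank variance,
    where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("zero rank variance: Spearman rho undefined, returning NaN")
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def correlation_matrix(m: SignalMatrix) -> CorrelationMatrix:
    """All pairwise Spearman correlations over the shared window vector."""
    n = len(m.sample_ids)
    if n < 2:
        raise ValueError("need >= 2 samples")
    rho = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rho[i, j] = rho[j, i] = spearman_rho(m.values[:, i], m.values[:, j])
    return CorrelationMatrix(list(m.sample_ids), rho)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class Linkage:
    """An agglomerative merge sequence (scipy linkage encoding) with labels."""

    merges: np.ndarray  # (n-1, 4): cluster i, cluster j, height, size
    labels: list[str]

    @property
    def leaf_order(self) -> list[int]:
        return [int(i) for i in leaves_list(self.merges)]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Export the dendrogram as a Newick string with merge heights as branch lengths."""
        tree = to_tree(self.merges)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return rec(tree, tree.dist) + ";"


def hierarchical_cluster(
    vectors,
    labels: Sequence[str] | None = None,
    method: Literal["ward", "average"] = "ward",
    metric: Literal["euclidean", "one_minus_rho"] = "euclidean",
) -> Linkage:
    """Agglomerative clustering of item vectors.

    ``ward``/``euclidean`` is the expression-heatmap setting; ``average`` on
    ``one_minus_rho`` (1 - Spearman rho between item vectors) is the
    binding-pattern setting. Ward requires the euclidean metric.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D array with >= 2 items")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in clustering input")
    if labels is None:
        labels = [str(i) for i in range(x.shape[0])]
    if metric == "euclidean":
        z = linkage(x, method=method, metric="euclidean")
    elif metric == "one_minus_rho":
        if method == "ward":
            raise ValueError("ward linkage requires the euclidean metric")
        n = x.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = 1.0 - spearman_rho(x[i], x[j])
        z = linkage(squareform(d, checks=False), method=method)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return Linkage(z, list(labels))


# ---------------------------------------------------------------------------
# consensus motif enrichment
# ---------------------------------------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CANONICAL_STAT_MOTIF = "TTCNNNGAA"
"""The canonical 9-bp GAS-family binding consensus (TTCNNNGAA, fixed spacer)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _consensus_regex(consensus: str) -> re.Pattern:
    parts = []
    for ch in consensus.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in consensus")
        alts = IUPAC[ch]
        parts.append(alts if len(alts) == 1 else f"[{alts}]")
    return re.compile("".join(parts))


@dataclass(frozen=True)
class MotifEnrichmentResult:
    consensus: str
    n_sequences: int
    n_with_match: int
    background_rate: float
    p_value: float


def _matches(seq: str, fwd: re.Pattern, rev: re.Pattern) -> bool:
    return bool(fwd.search(seq) or rev.search(seq))


def consensus_motif_enrichment(
    sequences: Sequence[str],
    consensus: str = CANONICAL_STAT_MOTIF,
    n_shuffles: int = 100,
    seed: int = 0,
) -> MotifEnrichmentResult:
    """Binomial enrichment of an IUPAC consensus against a shuffled null.

    A sequence matches when the consensus occurs at any position on either
    strand. The background per-sequence match probability is estimated from
    ``n_shuffles`` seeded mononucleotide shuffles of every sequence; the
    p-value is the upper binomial tail at the observed match count.
    """
    if not sequences:
        raise ValueError("empty sequence collection")
    seqs = [s.upper() for s in sequences]
    for s in seqs:
        if set(s) - set("ACGTN"):
            raise ValueError("sequences must be over {A,C,G,T,N}")
    fwd = _consensus_regex(consensus)
    rev = _consensus_regex(reverse_complement(consensus.upper()))
    n_with_match = sum(_matches(s, fwd, rev) for s in seqs)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_shuffles):
        for s in seqs:
            arr = np.frombuffer(s.encode(), dtype="S1")
            shuffled = rng.permutation(arr).tobytes().decode()
            hits += _matches(shuffled, fwd, rev)
    background_rate = hits / (n_shuffles * len(seqs))
    if background_rate <= 0.0:
        p = 1.0 if n_with_match == 0 else float(np.nextafter(0, 1))
    else:
        p = float(binom.sf(n_with_match - 1, len(seqs), background_rate))
    p = min(max(p, float(np.nextafter(0, 1))), 1.0)
    return MotifEnrichmentResult(consensus.upper(), len(seqs), int(n_with_match), background_rate, p)
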