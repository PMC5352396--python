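"""Brute-force reference implementations used only to check the package.

Each oracle deliberately takes the most naive route (double loops, full
enumeration, lattice-path counting) and shares no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def spearman_oracle(x, y) -> float:
    """Rank-then-Pearson by hand: average ranks for ties, textbook Pearson."""

    def avg_ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1  # ranks are 1-based
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def ks_d_oracle(d1, d2) -> float:
    """Sup |F1 - F2| over all finite observed points, by double loop."""
    pts = sorted({v for v in list(d1) + list(d2) if math.isfinite(v)})
    best = 0.0
    for t in pts:
        f1 = sum(1 for v in d1 if v <= t) / len(d1)
        f2 = sum(1 for v in d2 if v <= t) / len(d2)
        best = max(best, abs(f1 - f2))
    return best


def ks_exact_p_enumeration(d1, d2) -> float:
    """Exact permutation p by explicit enumeration of every pooled split.

    Feasible only for tiny samples; handles ties and infinities because each
    split's D is recomputed from scratch with :func:`ks_d_oracle`.
    """
    pooled = list(d1) + list(d2)
    n1 = len(d1)
    d_obs = ks_d_oracle(d1, d2)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        s1 = [pooled[i] for i in idx]
        s2 = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        total += 1
        if ks_d_oracle(s1, s2) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def ks_exact_p_path_counting(n1: int, n2: int, d_obs: float) -> float:
    """Exact permutation p for continuous (tie-free) samples by lattice paths.

    Counts monotone paths from (0,0) to (n1,n2) whose every vertex satisfies
    |i/n1 - j/n2| < d_obs; the complement over C(n1+n2, n1) is P(D >= d_obs).
    Valid only when the pooled values are all distinct.
    """
    inside = np.zeros((n1 + 1, n2 + 1), dtype=object)
    inside[0, 0] = 1
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if i == 0 and j == 0:
                continue
            if abs(i / n1 - j / n2) >= d_obs - 1e-12:
                inside[i, j] = 0
                continue
            inside[i, j] = (inside[i - 1, j] if i else 0) + (inside[i, j - 1] if j else 0)
    total = math.comb(n1 + n2, n1)
    return (total - int(inside[n1, n2])) / total


def hypergeom_pmf_exact(k: int, N: int, K: int, n: int):
    """Exact rational hypergeometric pmf via integer binomials."""
    from fractions import Fraction

    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def hypergeom_upper_tail_exact(k: int, n: int, K: int, N: int) -> float:
    """Exact rational upper tail, summed over the feasible support."""
    lo = max(0, n - (N - K))
    hi = min(n, K)
    total = sum(hypergeom_pmf_exact(j, N, K, n) for j in range(max(k, lo), hi + 1))
    return float(total)


def bh_oracle(pvals):
    """Step-up BH executed literally from the definition."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q[i] = running
    return q


def max_overlap_matching(peaks_a, peaks_b) -> int:
    """Maximum one-to-one matching of overlapping peaks (bipartite, exact)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching

    rows, cols = [], []
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, p in enumerate(peaks_b):
        by_chrom.setdefault(p.chrom, []).append((p.interval.start, p.interval.end, j))
    for i, p in enumerate(peaks_a):
        for start, end, j in by_chrom.get(p.chrom, []):
            if p.interval.start < end and start < p.interval.end:
                rows.append(i)
                cols.append(j)
    if not rows:
        return 0
    graph = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(peaks_a), len(peaks_b))
    ).tocsr()
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match >= 0).sum())


def nearest_distance_oracle(tss_records, peaks):
    """All-pairs scan for the nearest same-chromosome summit."""
    out = {}
    for t in tss_records:
        best = math.inf
        for p in peaks:
            if p.chrom == t.chrom:
                best = min(best, abs(p.summit - t.tss))
        out[t.transcript_id] = best
    return out


def iupac_match_oracle(seq: str, consensus: str) -> bool:
    """Expand the IUPAC consensus to the explicit k-mer set, scan both strands."""
    from itertools import product

    table = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    kmers = {"".join(p) for p in product(*(table[c] for c in consensus.upper()))}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = {"".join(comp[c] for c in reversed(k)) for k in kmers}
    kmers |= rc
    k = len(consensus)
    return any(seq[i : i + k] in kmers for i in range(len(seq) - k + 1))
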