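"""Seeded synthetic-data generators with planted ground truth.

These generators emulate the statistical structure the integration analysis
assumes — replicated peak calls with a controllable concordance level,
planted direct-target transcripts whose nearest peak lies within the calling
cutoff of their TSS, decoy peaks far from every TSS, sample-group structure
in per-peak signal, a knockdown DE table with planted directions, and a
gene-set collection with one planted enriched set per direction. They do not
emulate reads, fragment-length or GC structure, or peak-calling artifacts.

Two ready-made scenarios:

``separated``
    Planted targets' peaks within ``max_target_distance`` (50 kb) of their
    TSS; every other peak at least ``min_decoy_distance`` (100 kb) from every
    TSS. Target recovery is exact by construction and the TSS-distance KS
    test is overwhelmingly significant.

``null``
    Peaks placed independently of transcripts and the DE set drawn uniformly,
    so the KS p-value is calibrated (approximately uniform across seeds).

The separated layout needs inter-TSS spacing larger than the separation
constraint, so its default genome uses large synthetic chromosomes with
jittered-grid TSS placement; the small toy genome is for unit-scale work
where no separation constraint applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .expression_types import DOWN_UPON_KD, UP_UPON_KD
from .genomic_io import (
    GeneSet,
    GenomicInterval,
    Peak,
    PeakSet,
    TranscriptRecord,
    write_gmt,
    write_narrowpeak,
    write_tss_table,
)

__all__ = [
    "SMALL_GENOME",
    "SEPARATED_GENOME",
    "NULL_GENOME",
    "ScenarioTruth",
    "SampleSim",
    "SyntheticScenario",
    "generate_annotation",
    "generate_peak_truth",
    "generate_null_peaks",
    "generate_replicates",
    "generate_signal",
    "generate_de_table",
    "generate_gmt",
    "build_scenario",
]

SMALL_GENOME: dict[str, int] = {"chr1": 10_000_000, "chr2": 10_000_000, "chrX": 5_000_000}
SEPARATED_GENOME: dict[str, int] = {"chr1": 160_000_000, "chr2": 140_000_000, "chrX": 30_000_000}
NULL_GENOME: dict[str, int] = {"chr1": 40_000_000, "chr2": 40_000_000, "chrX": 8_000_000}

_SEX = {"chrx", "chry", "x", "y"}


def _autosomal(t: TranscriptRecord) -> bool:
    return t.chrom.lower() not in _SEX


@dataclass
class ScenarioTruth:
    """Planted ground truth for one simulated sample."""

    planted_targets: dict[str, str] = field(default_factory=dict)  # transcript -> direction
    planted_distances: dict[str, int] = field(default_factory=dict)
    null_de_ids: set[str] = field(default_factory=set)
    replicate_concordance_target: float = 1.0
    sample_groups: dict[str, str] = field(default_factory=dict)
    planted_enriched_sets: dict[str, str] = field(default_factory=dict)  # direction -> set name

    def targets(self, direction: Optional[str] = None) -> set[str]:
        if direction is None:
            return set(self.planted_targets)
        return {t for t, d in self.planted_targets.items() if d == direction}


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _per_chrom_counts(
    n: int, chrom_sizes: Mapping[str, int], chrx_fraction: float
) -> dict[str, int]:
    """Deterministic per-chromosome transcript counts.

    The chrX count is fixed by rounding n * chrx_fraction; the remainder is
    split over the other chromosomes proportionally to length (largest
    remainder method).
    """
    counts: dict[str, int] = {}
    n_left = n
    if "chrX" in chrom_sizes and chrx_fraction > 0:
        counts["chrX"] = min(n, round(n * chrx_fraction))
        n_left = n - counts["chrX"]
    others = [c for c in sorted(chrom_sizes) if c not in counts]
    total = sum(chrom_sizes[c] for c in others)
    raw = {c: n_left * chrom_sizes[c] / total for c in others}
    base = {c: int(raw[c]) for c in others}
    rem = n_left - sum(base.values())
    for c in sorted(others, key=lambda c: raw[c] - base[c], reverse=True)[:rem]:
        base[c] += 1
    counts.update(base)
    return counts


def generate_annotation(
    n_transcripts: int,
    chrom_sizes: Mapping[str, int] = SMALL_GENOME,
    seed: int = 0,
    chrx_fraction: float = 0.0,
    min_spacing: Optional[int] = None,
) -> list[TranscriptRecord]:
    """Generate transcript records with TSSs over the synthetic genome.

    Default placement is uniform per chromosome, chromosomes weighted by
    length. With ``min_spacing`` set, TSSs are placed on a jittered grid that
    guarantees at least that many bp between adjacent TSSs (needed by the
    separated scenario's geometry). Deterministic given the seed.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if any(v <= 0 for v in chrom_sizes.values()):
        raise ValueError("chromosome sizes must be > 0")
    rng = np.random.default_rng(seed)
    counts = _per_chrom_counts(n_transcripts, chrom_sizes, chrx_fraction)
    records: list[TranscriptRecord] = []
    idx = 0
    for chrom in sorted(chrom_sizes):
        n_c = counts.get(chrom, 0)
        if n_c == 0:
            continue
        length = chrom_sizes[chrom]
        if min_spacing is not None:
            width = length // n_c
            if width < min_spacing:
                raise ValueError(
                    f"{chrom}: cannot place {n_c} TSSs with spacing {min_spacing} "
                    f"on {length} bp"
                )
            jitter = max(0, (width - min_spacing) // 2)
            offsets = rng.integers(-jitter, jitter + 1, size=n_c) if jitter else np.zeros(n_c, int)
            positions = np.arange(n_c) * width + width // 2 + offsets
        else:
            positions = np.sort(rng.integers(0, length, size=n_c))
        strands = rng.random(n_c) < 0.5
        for pos, plus in zip(positions, strands):
            idx += 1
            records.append(
                TranscriptRecord(
                    f"t{idx:05d}", f"g{idx:05d}", chrom, "+" if plus else "-", int(pos)
                )
            )
    return records


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


def _make_peak(chrom: str, summit: int, score: float, name: str, halfwidth: int,
               length: int) -> Peak:
    start = max(0, summit - halfwidth)
    end = min(length, summit + halfwidth)
    return Peak(GenomicInterval(chrom, start, end), summit, score, name)


def generate_peak_truth(
    annotation: Sequence[TranscriptRecord],
    chrom_sizes: Mapping[str, int],
    n_targets: int,
    n_background_peaks: int,
    max_target_distance: int = 50_000,
    min_decoy_distance: int = 100_000,
    seed: int = 0,
    peak_halfwidth: int = 150,
    max_tries: int = 1_000,
    sample_id: str = "truth",
) -> tuple[PeakSet, ScenarioTruth]:
    """Plant target peaks near chosen TSSs and decoy peaks far from every TSS.

    Each planted target (autosomal, directions alternating) gets one peak
    whose summit is ``tss +/- U(0, max_target_distance)``, rejected if within
    ``min_decoy_distance`` of any OTHER TSS so the recorded planted distance
    is exactly the transcript's nearest-peak distance. Background peaks are
    placed by rejection sampling at least ``min_decoy_distance`` from every
    TSS. Raises after ``max_tries`` rejections if the genome is too crowded.
    """
    autosomal = [t for t in annotation if _autosomal(t)]
    if n_targets > len(autosomal):
        raise ValueError("more targets requested than autosomal transcripts")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(autosomal), size=n_targets, replace=False)
    chosen = sorted((autosomal[i] for i in pick), key=lambda t: t.transcript_id)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom in chrom_sizes:
        tss_by_chrom[chrom] = np.sort(
            np.array([t.tss for t in annotation if t.chrom == chrom], dtype=np.int64)
        )

    def min_tss_dist(chrom: str, pos: int, exclude_tss: Optional[int] = None) -> int:
        arr = tss_by_chrom[chrom]
        if len(arr) == 0:
            return np.iinfo(np.int64).max
        i = int(np.searchsorted(arr, pos))
        best = np.iinfo(np.int64).max
        # window of 2 on each side: enough even when one entry is excluded
        for j in range(i - 2, i + 3):
            if 0 <= j < len(arr):
                if exclude_tss is not None and arr[j] == exclude_tss:
                    # skip one occurrence of the target's own TSS
                    exclude_tss = None
                    continue
                best = min(best, abs(int(arr[j]) - pos))
        return best

    truth = ScenarioTruth()
    peaks: list[Peak] = []
    for k, t in enumerate(chosen):
        direction = DOWN_UPON_KD if k % 2 == 0 else UP_UPON_KD
        length = chrom_sizes[t.chrom]
        for attempt in range(max_tries):
            dist = int(rng.integers(0, max_target_distance + 1))
            sign = -1 if rng.random() < 0.5 else 1
            summit = t.tss + sign * dist
            if not (peak_halfwidth <= summit <= length - peak_halfwidth - 1):
                summit = t.tss - sign * dist
            if not (peak_halfwidth <= summit <= length - peak_halfwidth - 1):
                continue
            if min_tss_dist(t.chrom, summit, exclude_tss=t.tss) < min_decoy_distance:
                continue
            score = float(10 ** rng.normal(1.0, 0.3))
            peaks.append(
                _make_peak(t.chrom, summit, score, f"tp_{t.transcript_id}",
                           peak_halfwidth, length)
            )
            truth.planted_targets[t.transcript_id] = direction
            truth.planted_distances[t.transcript_id] = abs(summit - t.tss)
            break
        else:
            raise RuntimeError(
                f"could not place a target peak near {t.transcript_id} after "
                f"{max_tries} tries; genome too crowded for the separation constraint"
            )
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for k in range(n_background_peaks):
        for attempt in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            length = chrom_sizes[chrom]
            pos = int(rng.integers(peak_halfwidth, length - peak_halfwidth))
            if min_tss_dist(chrom, pos) < min_decoy_distance:
                continue
            score = float(10 ** rng.normal(1.0, 0.3))
            peaks.append(_make_peak(chrom, pos, score, f"bg_{k + 1:05d}", peak_halfwidth, length))
            break
        else:
            raise RuntimeError(
                f"could not place background peak {k + 1} after {max_tries} tries"
            )
    return PeakSet(sample_id, peaks), truth


def generate_null_peaks(
    chrom_sizes: Mapping[str, int],
    n_peaks: int,
    seed: int = 0,
    peak_halfwidth: int = 150,
    sample_id: str = "null_truth",
) -> PeakSet:
    """Peaks placed uniformly, independent of any annotation (the null scenario)."""
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    peaks = []
    for k in range(n_peaks):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = chrom_sizes[chrom]
        pos = int(rng.integers(peak_halfwidth, length - peak_halfwidth))
        score = float(10 ** rng.normal(1.0, 0.3))
        peaks.append(_make_peak(chrom, pos, score, f"np_{k + 1:05d}", peak_halfwidth, length))
    return PeakSet(sample_id, peaks)


def generate_replicates(
    truth: PeakSet,
    concordance: float,
    jitter_sd: float = 5.0,
    seed: int = 0,
    always_keep: Optional[set[str]] = None,
) -> tuple[PeakSet, PeakSet]:
    """Two replicate peak sets from a truth set at a target concordance level.

    Each replicate keeps each truth peak independently with probability equal
    to ``concordance``: with the shared/min(n_a, n_b) definition the expected
    measured concordance is then the keep probability itself (shared ~= c^2 N,
    min ~= c N). Interval boundaries are jittered by a rounded Normal(0,
    jitter_sd), preserving interval validity and summit containment.

    Peaks named in ``always_keep`` survive in both replicates regardless of
    the concordance level; the separated scenario uses this for its planted
    target peaks so that the planted ground truth survives replicate
    combination and recovery stays exact by construction.
    """
    if not (0 < concordance <= 1):
        raise ValueError("concordance must be in (0, 1]")
    rng = np.random.default_rng(seed)
    always_keep = always_keep or set()

    def one_replicate(tag: str) -> PeakSet:
        kept = []
        for p in truth:
            if p.name not in always_keep and rng.random() > concordance:
                continue
            ds = int(round(rng.normal(0, jitter_sd))) if jitter_sd > 0 else 0
            de = int(round(rng.normal(0, jitter_sd))) if jitter_sd > 0 else 0
            start = max(0, min(p.interval.start + ds, p.summit))
            end = max(p.interval.end + de, p.summit + 1)
            kept.append(
                Peak(GenomicInterval(p.chrom, start, end, p.interval.strand),
                     p.summit, p.score, f"{p.name}_{tag}")
            )
        return PeakSet(f"{truth.sample_id}_{tag}", kept)

    return one_replicate("rep1"), one_replicate("rep2")


# ---------------------------------------------------------------------------
# signal counts
# ---------------------------------------------------------------------------


def generate_signal(
    peaks: PeakSet,
    samples: Mapping[str, str],
    library_sizes: Mapping[str, float],
    group_effect: float = 4.0,
    dispersion: float = 0.1,
    affected_fraction: float = 0.3,
    base_mean: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Overdispersed per-peak read counts with planted sample-group structure.

    Counts are Gamma–Poisson with mean ``base_p * fold * library/1e6`` where
    ``base_p`` is a shared per-peak baseline and ``fold = group_effect`` on a
    designated ``affected_fraction`` of peaks for every non-reference group
    (reference = alphabetically first group). At the defaults, within-group
    Spearman correlation exceeds between-group correlation by construction.
    Returns a long table (window_id, sample, count).
    """
    if any(v <= 0 for v in library_sizes.values()):
        raise ValueError("library sizes must be > 0")
    if set(samples) - set(library_sizes):
        raise ValueError("every sample needs a library size")
    rng = np.random.default_rng(seed)
    names = [p.name for p in peaks.sorted()]
    n = len(names)
    base = base_mean * np.exp(rng.normal(0, 0.5, size=n))
    groups = sorted(set(samples.values()))
    reference = groups[0]
    n_aff = int(round(affected_fraction * n))
    affected = np.zeros(n, dtype=bool)
    affected[rng.choice(n, size=n_aff, replace=False)] = True
    rows = []
    for sample in sorted(samples):
        group = samples[sample]
        fold = np.where(affected & (group != reference), group_effect, 1.0)
        mu = base * fold * (library_sizes[sample] / 1e6)
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
        else:
            lam = mu
        counts = rng.poisson(lam)
        rows.extend(zip(names, [sample] * n, counts.tolist()))
    return pd.DataFrame(rows, columns=["window_id", "sample", "count"])


# ---------------------------------------------------------------------------
# DE table and gene sets
# ---------------------------------------------------------------------------


def generate_de_table(
    annotation: Sequence[TranscriptRecord],
    truth: ScenarioTruth,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.2,
    n_null_de: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Knockdown-vs-control DE table with planted directions.

    Planted targets get ``log2fc = sign * (effect + Normal(0, noise_sd))``
    with the sign fixed by direction (down upon knockdown -> negative).
    ``n_null_de`` additional autosomal non-target transcripts get
    supra-threshold fold changes (DE-but-not-target decoys, recorded in
    ``truth.null_de_ids``); everything else gets Normal(0, noise_sd).
    """
    if effect_log2fc <= 1:
        raise ValueError("effect_log2fc must be > 1 to clear the 2-fold filter")
    rng = np.random.default_rng(seed)
    candidates = [
        t.transcript_id
        for t in annotation
        if _autosomal(t) and t.transcript_id not in truth.planted_targets
    ]
    if n_null_de > len(candidates):
        raise ValueError("n_null_de exceeds available non-target transcripts")
    null_ids = set(
        np.array(sorted(candidates))[rng.choice(len(candidates), n_null_de, replace=False)]
    )
    truth.null_de_ids = set(map(str, null_ids))
    rows = []
    for t in annotation:
        tid = t.transcript_id
        if tid in truth.planted_targets:
            sign = -1.0 if truth.planted_targets[tid] == DOWN_UPON_KD else 1.0
            fc = sign * (effect_log2fc + rng.normal(0, noise_sd) if noise_sd > 0 else effect_log2fc)
            padj = 10 ** (-rng.uniform(4, 10))
        elif tid in truth.null_de_ids:
            sign = -1.0 if rng.random() < 0.5 else 1.0
            fc = sign * (effect_log2fc + abs(rng.normal(0, noise_sd)) if noise_sd > 0 else effect_log2fc)
            padj = 10 ** (-rng.uniform(4, 10))
        else:
            fc = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
            padj = rng.uniform(0.05, 1.0)
        rows.append((tid, t.chrom, fc, padj))
    return pd.DataFrame(rows, columns=["transcript_id", "chrom", "log2fc", "padj"])


def generate_gmt(
    truth: ScenarioTruth,
    universe: Sequence[str],
    transcript_to_gene: Mapping[str, str],
    n_decoy_sets: int = 20,
    set_size: int = 50,
    seed: int = 0,
    target_fraction: float = 0.9,
) -> list[GeneSet]:
    """One planted enriched set per direction plus uniform decoy sets.

    Each planted set contains ``target_fraction`` (>= 80% at the default) of
    that direction's planted target genes, padded with filler genes drawn
    from the universe; decoy sets are uniform draws. Gene ids come from the
    supplied transcript-to-gene mapping.
    """
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe size")
    rng = np.random.default_rng(seed)
    universe_arr = np.array(sorted(set(universe)))
    sets: list[GeneSet] = []
    label = {DOWN_UPON_KD: "PLANTED_ACTIVATED", UP_UPON_KD: "PLANTED_REPRESSED"}
    for direction in (DOWN_UPON_KD, UP_UPON_KD):
        genes = sorted({transcript_to_gene[t] for t in truth.targets(direction)})
        if not genes:
            continue
        n_take = max(1, math.ceil(target_fraction * len(genes)))
        take = sorted(np.array(genes)[rng.choice(len(genes), n_take, replace=False)])
        filler_pool = np.array([g for g in universe_arr if g not in set(take)])
        n_fill = max(0, set_size - len(take))
        filler = filler_pool[rng.choice(len(filler_pool), min(n_fill, len(filler_pool)),
                                        replace=False)]
        members = frozenset(map(str, take)) | frozenset(map(str, filler))
        name = label[direction]
        sets.append(GeneSet(name, f"planted enriched set ({direction})", frozenset(members)))
        truth.planted_enriched_sets[direction] = name
    for k in range(n_decoy_sets):
        members = universe_arr[rng.choice(len(universe_arr), set_size, replace=False)]
        sets.append(
            GeneSet(f"DECOY_{k + 1:02d}", "uniform decoy set", frozenset(map(str, members)))
        )
    return sets


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass
class SampleSim:
    sample_id: str
    truth_peaks: PeakSet
    replicate_a: PeakSet
    replicate_b: PeakSet
    de_table: pd.DataFrame
    gene_sets: list[GeneSet]
    truth: ScenarioTruth


@dataclass
class SyntheticScenario:
    kind: str
    seed: int
    chrom_sizes: dict[str, int]
    annotation: list[TranscriptRecord]
    samples: list[SampleSim]
    counts: Optional[pd.DataFrame] = None
    library_sizes: Optional[dict[str, float]] = None
    parameters: dict = field(default_factory=dict)

    @property
    def transcript_to_gene(self) -> dict[str, str]:
        return {t.transcript_id: t.gene_id for t in self.annotation}

    def write(self, outdir: str | Path) -> Path:
        """Persist every input file plus a ready-to-run pipeline config.

        All paths inside the config are relative to the output directory so
        the run is relocatable.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tss_table(self.annotation, outdir / "annotation.tsv")
        with (outdir / "chrom_sizes.tsv").open("w") as fh:
            for c in sorted(self.chrom_sizes):
                fh.write(f"{c}\t{self.chrom_sizes[c]}\n")
        sample_cfgs = []
        for s in self.samples:
            write_narrowpeak(s.replicate_a, outdir / f"{s.sample_id}_rep1.narrowPeak")
            write_narrowpeak(s.replicate_b, outdir / f"{s.sample_id}_rep2.narrowPeak")
            s.de_table.to_csv(outdir / f"{s.sample_id}_de.tsv", sep="\t", index=False)
            write_gmt(s.gene_sets, outdir / f"{s.sample_id}.gmt")
            sample_cfgs.append(
                {
                    "id": s.sample_id,
                    "replicates": [f"{s.sample_id}_rep1.narrowPeak",
                                   f"{s.sample_id}_rep2.narrowPeak"],
                    "de_table": f"{s.sample_id}_de.tsv",
                    "gmt": f"{s.sample_id}.gmt",
                }
            )
        cfg = {
            "annotation": "annotation.tsv",
            "samples": sample_cfgs,
            "parameters": dict(self.parameters),
        }
        if self.counts is not None:
            self.counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
            with (outdir / "library_sizes.tsv").open("w") as fh:
                for sid in sorted(self.library_sizes or {}):
                    fh.write(f"{sid}\t{self.library_sizes[sid]:g}\n")
            cfg["counts"] = "counts.tsv"
            cfg["library_sizes"] = "library_sizes.tsv"
        with (outdir / "run.yaml").open("w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        return outdir / "run.yaml"


def build_scenario(kind: str, seed: int = 0, **overrides) -> SyntheticScenario:
    """Build a complete synthetic study ("separated" or "null").

    The separated scenario plants 50 direct targets per sample within 50 kb,
    keeps all other peaks at least 100 kb from every TSS, simulates two
    replicate peak sets per sample at 0.9 concordance, a noiseless planted DE
    table (50 DE-but-not-target decoys), per-sample gene sets with one
    planted enriched set per direction, and grouped per-peak signal counts.
    The null scenario places peaks independently of transcripts and draws the
    DE set uniformly.
    """
    if kind == "separated":
        return _separated_scenario(seed, **overrides)
    if kind == "null":
        return _null_scenario(seed, **overrides)
    raise ValueError(f"unknown scenario {kind!r}")


def _separated_scenario(
    seed: int,
    n_transcripts: int = 1_100,
    n_targets: int = 50,
    n_background_peaks: int = 300,
    n_null_de: int = 50,
    chrx_fraction: float = 0.09,
    concordance: float = 0.9,
    jitter_sd: float = 5.0,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.0,
    n_samples: int = 2,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> SyntheticScenario:
    sizes = dict(chrom_sizes or SEPARATED_GENOME)
    annotation = generate_annotation(
        n_transcripts, sizes, seed=seed, chrx_fraction=chrx_fraction, min_spacing=200_000
    )
    t2g = {t.transcript_id: t.gene_id for t in annotation}
    universe = [t.gene_id for t in annotation if _autosomal(t)]
    samples: list[SampleSim] = []
    union_peaks: list[Peak] = []
    groups: dict[str, str] = {}
    for i in range(n_samples):
        sid = f"sample{chr(ord('A') + i)}"
        truth_peaks, truth = generate_peak_truth(
            annotation, sizes, n_targets, n_background_peaks, seed=seed + 101 + i,
            sample_id=sid,
        )
        truth.replicate_concordance_target = concordance
        target_peak_names = {f"tp_{t}" for t in truth.planted_targets}
        rep_a, rep_b = generate_replicates(truth_peaks, concordance, jitter_sd,
                                           seed=seed + 201 + i,
                                           always_keep=target_peak_names)
        de = generate_de_table(annotation, truth, effect_log2fc, noise_sd,
                               n_null_de, seed=seed + 301 + i)
        gene_sets = generate_gmt(truth, universe, t2g, seed=seed + 401 + i)
        groups[f"{sid}_rep1"] = sid
        groups[f"{sid}_rep2"] = sid
        truth.sample_groups = dict(groups)
        union_peaks.extend(
            Peak(p.interval, p.summit, p.score, f"{sid}_{p.name}") for p in truth_peaks
        )
        samples.append(SampleSim(sid, truth_peaks, rep_a, rep_b, de, gene_sets, truth))
    library_sizes = {s: 1e6 * (1 + 0.1 * k) for k, s in enumerate(sorted(groups))}
    counts = generate_signal(
        PeakSet("union", union_peaks), groups, library_sizes, seed=seed + 501
    )
    return SyntheticScenario(
        "separated", seed, sizes, annotation, samples, counts, library_sizes,
        parameters={
            "fold_threshold": 2.0, "cutoff": 50_000, "min_concordance": 0.8,
            "background": "all", "seed": seed,
        },
    )


def _null_scenario(
    seed: int,
    n_transcripts: int = 2_000,
    n_peaks: int = 300,
    n_de: int = 40,
    chrx_fraction: float = 0.05,
    concordance: float = 0.9,
    jitter_sd: float = 5.0,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.2,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> SyntheticScenario:
    sizes = dict(chrom_sizes or NULL_GENOME)
    annotation = generate_annotation(
        n_transcripts, sizes, seed=seed, chrx_fraction=chrx_fraction
    )
    t2g = {t.transcript_id: t.gene_id for t in annotation}
    universe = [t.gene_id for t in annotation if _autosomal(t)]
    truth_peaks = generate_null_peaks(sizes, n_peaks, seed=seed + 101, sample_id="sampleA")
    truth = ScenarioTruth(replicate_concordance_target=concordance)
    rep_a, rep_b = generate_replicates(truth_peaks, concordance, jitter_sd, seed=seed + 201)
    de = generate_de_table(annotation, truth, effect_log2fc, noise_sd, n_de, seed=seed + 301)
    gene_sets = generate_gmt(truth, universe, t2g, seed=seed + 401)
    sample = SampleSim("sampleA", truth_peaks, rep_a, rep_b, de, gene_sets, truth)
    return SyntheticScenario(
        "null", seed, sizes, annotation, [sample],
        parameters={
            "fold_threshold": 2.0, "cutoff": 50_000, "min_concordance": 0.8,
            "background": "all", "seed": seed,
        },
    )
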