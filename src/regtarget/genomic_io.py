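"""Readers and writers for the genomic formats the pipeline touches.

Every coordinate in this package is 0-based, half-open ``[start, end)``.
Inputs that arrive in other conventions (e.g. 1-based fully-closed tables)
must be converted at the boundary; helpers for that conversion live here so
that no other module ever sees a 1-based coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "TranscriptRecord",
    "DERecord",
    "GeneSet",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_tss_table",
    "read_de_table",
    "read_gmt",
    "write_gmt",
    "write_bed",
    "read_bed",
    "read_chrom_sizes",
    "write_tss_table",
]

STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """A malformed line or table in an input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}; "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called binding site: interval, point of maximal signal, and score."""

    interval: GenomicInterval
    summit: int
    score: float
    name: str

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak {self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end}"
            )
        if self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class PeakSet:
    """An ordered collection of peaks from one sample/replicate."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.peaks]
        if len(names) != len(set(names)):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate peak name {dup!r} in sample {self.sample_id!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def sorted(self) -> "PeakSet":
        """Return a copy sorted by (chrom, start, end)."""
        return PeakSet(
            self.sample_id,
            sorted(self.peaks, key=lambda p: (p.chrom, p.interval.start, p.interval.end)),
        )

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.sorted():
            out.setdefault(p.chrom, []).append(p)
        return out


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript with its strand-aware transcription start site (0-based)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")


@dataclass(frozen=True)
class DERecord:
    """One transcript's knockdown-vs-control contrast (log2 scale)."""

    transcript_id: str
    chrom: str
    log2fc: float
    padj: Optional[float] = None

    def __post_init__(self) -> None:
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj must be in [0,1], got {self.padj}")


@dataclass(frozen=True)
class GeneSet:
    set_name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_name!r} has no members")


# ---------------------------------------------------------------------------
# narrowPeak / BED
# ---------------------------------------------------------------------------


def read_narrowpeak(path: str | Path, sample_id: str | None = None) -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file into a :class:`PeakSet`.

    The summit is ``start + offset`` (field 10) when the offset is >= 0; an
    offset of -1 (summit unknown) falls back to the interval midpoint with
    floor division, so every peak stays usable by summit-window operations.
    The score is taken from signalValue (field 7).
    """
    path = Path(path)
    peaks: list[Peak] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 10 tab-separated fields, got {len(fields)}"
                )
            chrom, name = fields[0], fields[3]
            try:
                start, end = int(fields[1]), int(fields[2])
                signal = float(fields[6])
                offset = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate field: {exc}") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            if offset >= end - start:
                raise ParseError(
                    f"{path}:{lineno}: summit offset {offset} >= peak length {end - start}"
                )
            summit = start + offset if offset >= 0 else (start + end) // 2
            try:
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end, fields[5] if fields[5] in STRANDS else "."),
                         summit, signal, name)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(sample_id or path.stem, peaks)


def write_narrowpeak(peak_set: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as narrowPeak, sorted by (chrom, start)."""
    with Path(path).open("w") as fh:
        for p in peak_set.sorted():
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}\t"
                f"{p.score:g}\t-1\t-1\t{p.summit - iv.start}\n"
            )


def write_bed(peak_set: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED6 plus a 7th thickStart column carrying the summit.

    Output is sorted by (chrom, start); the extra column lets
    :func:`read_bed` round-trip (chrom, start, end, summit) exactly.
    """
    with Path(path).open("w") as fh:
        for p in peak_set.sorted():
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:g}\t"
                f"{iv.strand}\t{p.summit}\n"
            )


def read_bed(path: str | Path, sample_id: str | None = None) -> PeakSet:
    """Read the BED6(+summit) files produced by :func:`write_bed`."""
    path = Path(path)
    peaks: list[Peak] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4])
                summit = int(fields[6]) if len(fields) > 6 else (start + end) // 2
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            strand = fields[5] if fields[5] in STRANDS else "."
            peaks.append(Peak(GenomicInterval(fields[0], start, end, strand), summit, score, fields[3]))
    return PeakSet(sample_id or path.stem, peaks)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

_TSS_COLUMNS = ["transcript_id", "gene_id", "chrom", "strand", "tx_start", "tx_end"]


def read_tss_table(path: str | Path) -> list[TranscriptRecord]:
    """Read a transcript table (TSV with header) and derive the TSS.

    The TSS is ``tx_start`` for "+" transcripts and ``tx_end - 1`` (the last
    covered base, 0-based) for "-" transcripts.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TSS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    dup = df["transcript_id"][df["transcript_id"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate transcript_id {dup.iloc[0]!r}")
    bad_strand = set(df["strand"]) - {"+", "-"}
    if bad_strand:
        raise ParseError(f"{path}: unknown strand value(s) {sorted(bad_strand)}")
    records = []
    for row in df.itertuples(index=False):
        tss = int(row.tx_start) if row.strand == "+" else int(row.tx_end) - 1
        records.append(
            TranscriptRecord(str(row.transcript_id), str(row.gene_id), str(row.chrom),
                             row.strand, tss)
        )
    return records


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a differential-expression table (TSV: transcript_id, chrom, log2fc, padj).

    The table is an upstream contract — the count model that produced it is
    outside this package. Rows whose log2fc is non-numeric are dropped with a
    warning; a missing/NA padj is kept as ``None``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "chrom": str})
    required = ["transcript_id", "chrom", "log2fc", "padj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    log2fc = pd.to_numeric(df["log2fc"], errors="coerce")
    n_bad = int(log2fc.isna().sum())
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} row(s) with non-numeric log2fc")
    padj = pd.to_numeric(df["padj"], errors="coerce")
    records = []
    for tid, chrom, fc, p in zip(df["transcript_id"], df["chrom"], log2fc, padj):
        if pd.isna(fc):
            continue
        records.append(DERecord(tid, chrom, float(fc), None if pd.isna(p) else float(p)))
    return records


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set file (name, description, then members)."""
    path = Path(path)
    sets: list[GeneSet] = []
    names: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            name = fields[0]
            if name in names:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            names.add(name)
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name, fields[1], members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_name, gs.description, *sorted(gs.members)]) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column (chrom, length) TSV without header."""
    sizes: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_tss_table(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    """Write TranscriptRecords in the TSV layout :func:`read_tss_table` reads.

    The stored tx_start/tx_end are a 1-bp stub interval at the TSS when only
    the TSS is known; round-tripping preserves the TSS exactly.
    """
    rows = []
    for r in records:
        # 1-bp stub: tss = tx_start for "+", tx_end - 1 for "-" — both hold.
        rows.append((r.transcript_id, r.gene_id, r.chrom, r.strand, r.tss, r.tss + 1))
    pd.DataFrame(rows, columns=_TSS_COLUMNS).to_csv(path, sep="\t", index=False)
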