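"""Shared fixtures: tiny in-memory genomic objects and file writers."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from regtarget.genomic_io import GenomicInterval, Peak, PeakSet


def make_peak(chrom, start, end, summit=None, score=1.0, name="p", strand="."):
    if summit is None:
        summit = (start + end) // 2
    return Peak(GenomicInterval(chrom, start, end, strand), summit, score, name)


@pytest.fixture
def peak_factory():
    return make_peak


@pytest.fixture
def small_peakset():
    peaks = [
        make_peak("chr1", 100, 200, 150, 8.5, "p1"),
        make_peak("chr1", 1000, 1300, 1100, 3.0, "p2"),
        make_peak("chr2", 500, 700, 600, 12.0, "p3"),
    ]
    return PeakSet("sampleX", peaks)


@pytest.fixture
def narrowpeak_file(tmp_path):
    """A well-formed 3-line narrowPeak file."""
    lines = [
        "chr1\t100\t200\tp1\t0\t.\t8.5\t-1\t-1\t50",
        "chr1\t1000\t1300\tp2\t0\t.\t3.0\t-1\t-1\t-1",
        "chr2\t500\t700\tp3\t0\t+\t12.0\t-1\t-1\t100",
    ]
    path = tmp_path / "sample.narrowPeak"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def tss_file(tmp_path):
    rows = [
        "transcript_id\tgene_id\tchrom\tstrand\ttx_start\ttx_end",
        "t1\tg1\tchr1\t+\t1000\t5000",
        "t2\tg1\tchr1\t-\t1000\t5000",
        "t3\tg2\tchr2\t+\t2000\t9000",
    ]
    path = tmp_path / "tss.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def de_file(tmp_path):
    rows = [
        "transcript_id\tchrom\tlog2fc\tpadj",
        "t1\tchr1\t2.0\t0.001",
        "t2\tchr1\t-1.5\tNA",
        "t3\tchr2\t0.2\t0.8",
        "t4\tchrX\t3.0\t0.0001",
    ]
    path = tmp_path / "de.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def gmt_file(tmp_path):
    lines = [
        "SETA\tfirst set\tg1\tg2\tg2",
        "SETB\tsecond set\tg3\tg4\tg5",
    ]
    path = tmp_path / "sets.gmt"
    path.write_text("\n".join(lines) + "\n")
    return path
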