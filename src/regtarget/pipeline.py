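"""End-to-end orchestration: peaks -> DE filter -> integration -> enrichment.

A run is a pure function of (input files, parameters, seeds): every stage
writes its intermediate table under the output directory and the summary
JSON is byte-identical across reruns with the same config. Replicate pairs
below the concordance threshold produce a warning, not a failure — the
threshold is a QC gate justifying replicate combination, not an automated
abort; ``strict=True`` upgrades the warning to an error.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import expression, integration, peaks as pk
from .expression_types import DOWN_UPON_KD, UP_UPON_KD
from .genomic_io import (
    read_chrom_sizes,
    read_de_table,
    read_gmt,
    read_narrowpeak,
    read_tss_table,
    write_bed,
)

logger = logging.getLogger("regtarget")

__all__ = ["SampleConfig", "RunConfig", "validate_config", "run_pipeline"]

SCHEMA_VERSION = 1


@dataclass
class SampleConfig:
    sample_id: str
    replicates: list[Path]
    de_table: Path
    gmt: Optional[Path] = None


@dataclass
class RunConfig:
    annotation: Path
    samples: list[SampleConfig]
    fold_threshold: float = 2.0
    cutoff: int = 50_000
    min_concordance: float = 0.8
    background: str = "all"  # "all" or "sample:<k>"
    seed: int = 0
    counts: Optional[Path] = None
    library_sizes: Optional[Path] = None
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        base = path.parent
        with path.open() as fh:
            raw = yaml.safe_load(fh)
        params = raw.get("parameters", {}) or {}
        samples = [
            SampleConfig(
                sample_id=str(s["id"]),
                replicates=[base / r for r in s["replicates"]],
                de_table=base / s["de_table"],
                gmt=(base / s["gmt"]) if s.get("gmt") else None,
            )
            for s in raw.get("samples", [])
        ]
        return cls(
            annotation=base / raw["annotation"],
            samples=samples,
            fold_threshold=float(params.get("fold_threshold", 2.0)),
            cutoff=int(params.get("cutoff", 50_000)),
            min_concordance=float(params.get("min_concordance", 0.8)),
            background=str(params.get("background", "all")),
            seed=int(params.get("seed", 0)),
            counts=(base / raw["counts"]) if raw.get("counts") else None,
            library_sizes=(base / raw["library_sizes"]) if raw.get("library_sizes") else None,
            strict=bool(params.get("strict", False)),
        )


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a human-readable list of config problems (empty when valid)."""
    errors: list[str] = []
    if not Path(cfg.annotation).exists():
        errors.append(f"annotation file not found: {cfg.annotation}")
    if not cfg.samples:
        errors.append("no samples defined")
    for s in cfg.samples:
        if len(s.replicates) != 2:
            errors.append(f"sample {s.sample_id}: expected exactly 2 replicate peak files")
        for r in s.replicates:
            if not Path(r).exists():
                errors.append(f"sample {s.sample_id}: replicate file not found: {r}")
        if not Path(s.de_table).exists():
            errors.append(f"sample {s.sample_id}: de_table file not found: {s.de_table}")
        if s.gmt is not None and not Path(s.gmt).exists():
            errors.append(f"sample {s.sample_id}: gmt file not found: {s.gmt}")
    if cfg.fold_threshold <= 1:
        errors.append(f"fold_threshold must be > 1, got {cfg.fold_threshold}")
    if cfg.cutoff < 0:
        errors.append(f"cutoff must be >= 0, got {cfg.cutoff}")
    if not (0 < cfg.min_concordance <= 1):
        errors.append(f"min_concordance must be in (0, 1], got {cfg.min_concordance}")
    if cfg.background != "all":
        parts = cfg.background.split(":")
        if len(parts) != 2 or parts[0] != "sample" or not parts[1].isdigit() or int(parts[1]) < 1:
            errors.append(f"background must be 'all' or 'sample:<k>', got {cfg.background!r}")
    if cfg.seed < 0:
        errors.append(f"seed must be >= 0, got {cfg.seed}")
    if (cfg.counts is None) != (cfg.library_sizes is None):
        errors.append("counts and library_sizes must be given together")
    for p in (cfg.counts, cfg.library_sizes):
        if p is not None and not Path(p).exists():
            errors.append(f"file not found: {p}")
    return errors


def _ks_to_dict(r: integration.KSResult) -> dict:
    return {"d_stat": r.d_stat, "p_value": r.p_value, "n1": r.n1, "n2": r.n2,
            "method": r.method}


def _run_sample(cfg: RunConfig, s: SampleConfig, annotation, background_distances,
                universe, t2g, outdir: Path) -> dict:
    logger.info("sample %s: reading replicates", s.sample_id)
    rep_a = read_narrowpeak(s.replicates[0], f"{s.sample_id}_rep1")
    rep_b = read_narrowpeak(s.replicates[1], f"{s.sample_id}_rep2")
    report = pk.replicate_concordance(rep_a, rep_b)
    if report.concordance < cfg.min_concordance:
        msg = (f"sample {s.sample_id}: replicate concordance "
               f"{report.concordance:.3f} below threshold {cfg.min_concordance}")
        if cfg.strict:
            raise RuntimeError(msg)
        warnings.warn(msg)
    highconf = pk.high_confidence_peaks(rep_a, rep_b, s.sample_id)
    write_bed(highconf, outdir / f"{s.sample_id}.highconf.bed")
    with (outdir / f"{s.sample_id}.concordance.json").open("w") as fh:
        json.dump({"n_a": report.n_a, "n_b": report.n_b, "n_shared": report.n_shared,
                   "concordance": report.concordance}, fh, sort_keys=True, indent=1)

    logger.info("sample %s: filtering DE table", s.sample_id)
    de_records = read_de_table(s.de_table)
    filtered = expression.filter_de(de_records, cfg.fold_threshold)
    filtered.to_frame().to_csv(outdir / f"{s.sample_id}.filtered_de.tsv",
                               sep="\t", index=False)

    logger.info("sample %s: computing TSS distances", s.sample_id)
    distances = integration.nearest_peak_distance(annotation, highconf)
    integration.distances_to_frame(distances).to_csv(
        outdir / f"{s.sample_id}.distances.tsv", sep="\t", index=False)
    sample_dist = {r.transcript_id: r.distance for r in distances}

    bg = background_distances(sample_dist)
    ks_results: dict[str, dict] = {}
    for direction in (DOWN_UPON_KD, UP_UPON_KD):
        ids = sorted(filtered.ids(direction))
        group = [sample_dist[t] for t in ids if t in sample_dist]
        if group:
            ecdf = integration.distance_ecdf(group)
            pd.DataFrame({"distance": ecdf.support, "fraction": ecdf.fraction}).to_csv(
                outdir / f"{s.sample_id}.ecdf_{direction}.tsv", sep="\t", index=False)
            ks = integration.ks_two_sample(group, bg, method="auto", seed=cfg.seed)
            ks_results[direction] = _ks_to_dict(ks)
    bg_ecdf = integration.distance_ecdf(bg)
    pd.DataFrame({"distance": bg_ecdf.support, "fraction": bg_ecdf.fraction}).to_csv(
        outdir / f"{s.sample_id}.ecdf_background.tsv", sep="\t", index=False)

    targets = integration.call_direct_targets(filtered, distances, cfg.cutoff, s.sample_id)
    rows = [(t, DOWN_UPON_KD) for t in sorted(targets.activated)]
    rows += [(t, UP_UPON_KD) for t in sorted(targets.repressed)]
    pd.DataFrame(rows, columns=["transcript_id", "direction"]).to_csv(
        outdir / f"{s.sample_id}.targets.tsv", sep="\t", index=False)
    frac = integration.fraction_within(targets, filtered) if filtered.retained else 0.0

    top_enrichment: dict[str, list] = {}
    if s.gmt is not None:
        gene_sets = read_gmt(s.gmt)
        for direction, ids in ((DOWN_UPON_KD, targets.activated),
                               (UP_UPON_KD, targets.repressed)):
            results = enr.enrich_gene_sets(ids, gene_sets, universe, t2g)
            enr.enrichment_to_frame(results).to_csv(
                outdir / f"{s.sample_id}.enrichment_{direction}.tsv",
                sep="\t", index=False)
            top_enrichment[direction] = [
                {"set_name": r.set_name, "k": r.k, "K": r.K,
                 "p_value": r.p_value, "q_value": r.q_value}
                for r in results[:10]
            ]
    return {
        "concordance": report.concordance,
        "n_rep_a": report.n_a,
        "n_rep_b": report.n_b,
        "n_shared": report.n_shared,
        "n_high_confidence_peaks": len(highconf),
        "n_filtered_de": len(filtered.retained),
        "n_down": filtered.n_down,
        "n_up": filtered.n_up,
        "n_targets_activated": len(targets.activated),
        "n_targets_repressed": len(targets.repressed),
        "n_targets": len(targets),
        "fraction_within": frac,
        "ks": ks_results,
        "top_enrichment": top_enrichment,
        "_targets": targets,
    }


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages and return (and persist) the run summary."""
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    annotation_all = read_tss_table(cfg.annotation)
    # universe and background are autosomal, consistent with the sex-chromosome filter
    annotation = [t for t in annotation_all
                  if t.chrom.lower().removeprefix("chr") not in {"x", "y"}]
    universe = sorted({t.gene_id for t in annotation})
    t2g = {t.transcript_id: t.gene_id for t in annotation}

    def background_distances(sample_dist: dict[str, float]) -> list[float]:
        ids = sorted(sample_dist)
        if cfg.background != "all":
            k = int(cfg.background.split(":")[1])
            rng = np.random.default_rng(cfg.seed)
            ids = sorted(np.array(ids)[rng.choice(len(ids), min(k, len(ids)),
                                                  replace=False)])
        return [sample_dist[t] for t in ids]

    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "parameters": {
            "fold_threshold": cfg.fold_threshold,
            "cutoff": cfg.cutoff,
            "min_concordance": cfg.min_concordance,
            "background": cfg.background,
            "seed": cfg.seed,
        },
        "samples": {},
        "cross_sample": {},
    }
    target_sets = {}
    for s in cfg.samples:
        try:
            result = _run_sample(cfg, s, annotation, background_distances,
                                 universe, t2g, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage failed for sample {s.sample_id}: {exc}") from exc
        target_sets[s.sample_id] = result.pop("_targets")
        summary["samples"][s.sample_id] = result

    sample_ids = sorted(target_sets)
    for i in range(len(sample_ids)):
        for j in range(i + 1, len(sample_ids)):
            a, b = sample_ids[i], sample_ids[j]
            common = integration.intersect_target_sets(target_sets[a], target_sets[b])
            common.to_csv(outdir / f"common_targets.{a}.{b}.tsv", sep="\t", index=False)
            summary["cross_sample"][f"{a}|{b}"] = {
                "n_common": int(len(common)),
                "n_direction_concordant": int(common["direction_concordant"].sum())
                if len(common) else 0,
            }

    if cfg.counts is not None:
        logger.info("computing cross-sample signal correlation")
        counts = pd.read_csv(cfg.counts, sep="\t")
        libs = {}
        with Path(cfg.library_sizes).open() as fh:
            for line in fh:
                if line.strip():
                    sid, size = line.split("\t")
                    libs[sid] = float(size)
        wide = counts.pivot_table(index="window_id", columns="sample",
                                  values="count", fill_value=0).sort_index()
        rpm = np.column_stack([
            pk.normalized_signal(wide[c].to_numpy(), libs[c]) for c in wide.columns
        ])
        from .genomic_io import GenomicInterval

        windows = [GenomicInterval("win", i, i + 1) for i in range(len(wide))]
        corr = pk.correlation_matrix(pk.SignalMatrix(windows, list(wide.columns), rpm))
        corr.to_frame().to_csv(outdir / "correlation.tsv", sep="\t")
        summary["correlation_samples"] = list(wide.columns)

    with (outdir / "summary.json").open("w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return summary
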