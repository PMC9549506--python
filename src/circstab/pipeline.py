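"""End-to-end pipeline: simulate/load -> filter -> DE -> dynamics ->
origin -> splicing -> report.

Driven by a :class:`PipelineConfig` (YAML-loadable). Every stage writes
its intermediate tables to the output directory and contributes counts
to the machine-readable :class:`RunSummary`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .diffexpr import DifferentialExpressionModel, classify_dynamics
from .model import ExpressionStudy
from .origin import classify_origin, correlate_fold_changes
from .repertoire import (
    composition_stats,
    filter_circ_biotype,
    filter_low_expression,
)
from .simulate import SimulationConfig, simulate_expression, simulate_junctions
from .splicing import ASEventTable, DeltaPsiModel

logger = logging.getLogger("circstab")

__all__ = ["PipelineConfig", "RunSummary", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds plus input paths or a simulation block."""

    outdir: str = "circstab_out"
    seed: int = 0
    # input paths (all four required when not simulating)
    counts_path: str | None = None
    tpm_path: str | None = None
    annotation_path: str | None = None
    design_path: str | None = None
    junctions_path: str | None = None
    # simulation block (used when input paths are absent)
    simulation: SimulationConfig | None = None
    # analysis thresholds (strict-inequality rules; see docs/methods.md)
    tpm_threshold: float = 1.0
    max_below: int = 4
    lfc_threshold: float = 0.5
    alpha: float = 0.05
    min_replicates: int = 2
    delta_psi_threshold: float = 0.05
    psi_alpha: float = 0.05
    min_total_reads: int = 10
    # flags
    gene_level_host_de: bool = True
    length_normalized_psi: bool = True
    bh_on_delta_psi: bool = False
    call_on_shrunken_lfc: bool = True
    origin_times_h: tuple = (24.0, 48.0)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the analytic configuration (paths excluded)."""
        d = self.to_dict()
        for key in ("outdir", "counts_path", "tpm_path", "annotation_path",
                    "design_path", "junctions_path"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunSummary:
    """Machine-readable per-stage record of one pipeline run."""

    config_hash: str = ""
    seed: int = 0
    stages: dict[str, Any] = field(default_factory=dict)
    wall_time_s: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True, default=str)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(summary: RunSummary, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("[%s] start", name)
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            summary.wall_time_s[name] = round(time.time() - self.t0, 3)
            if exc is not None:
                logger.error("[%s] failed: %s", name, exc)
                raise StageError(name, exc) from exc
            logger.info("[%s] done (%.2fs)", name, summary.wall_time_s[name])
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute the full analysis; returns the run summary.

    Stage failures abort with the stage name; outputs written before the
    failure are preserved in ``config.outdir``.
    """
    os.makedirs(config.outdir, exist_ok=True)
    summary = RunSummary(config_hash=config.config_hash(), seed=config.seed)
    have_paths = all(
        p is not None for p in (config.counts_path, config.tpm_path,
                                config.annotation_path, config.design_path)
    )
    if not have_paths and config.simulation is None:
        raise ValueError("no input source: provide input paths or a simulation block")

    truth = jx_truth = None
    with _stage(summary, "input"):
        if have_paths:
            study = cio.read_expression_study(
                config.counts_path, config.tpm_path,
                config.annotation_path, config.design_path,
            )
            junctions = None
            if config.junctions_path:
                junctions = ASEventTable.read(
                    config.junctions_path, study.samples
                )
        else:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            study, truth = simulate_expression(sim)
            junctions, jx_truth = simulate_junctions(sim)
            cio.write_expression_study(study, config.outdir)
            junctions.write(os.path.join(config.outdir, "junctions.tsv"))
            truth.transcripts.to_csv(
                os.path.join(config.outdir, "ground_truth_transcripts.tsv"),
                sep="\t", index=False,
            )
            jx_truth.events.to_csv(
                os.path.join(config.outdir, "ground_truth_events.tsv"),
                sep="\t", index=False,
            )
        summary.stages["input"] = {
            "n_transcripts": study.n_transcripts,
            "n_samples": study.n_samples,
            "simulated": not have_paths,
        }

    with _stage(summary, "filter"):
        n_in = study.n_transcripts
        kept_ann, excluded_ann, biotype_tally = filter_circ_biotype(
            study.transcripts
        )
        study = study.subset_transcripts(list(kept_ann.index))
        study, removed_low = filter_low_expression(
            study, tpm_threshold=config.tpm_threshold,
            max_below=config.max_below,
        )
        comp = composition_stats(study)
        comp.as_table().to_csv(
            os.path.join(config.outdir, "repertoire_summary.tsv"),
            sep="\t", index=False,
        )
        summary.stages["filter"] = {
            "input": n_in,
            "excluded_biotype": int(len(excluded_ann)),
            "biotype_tally": biotype_tally,
            "removed_low_expression": len(removed_low),
            "kept": study.n_transcripts,
            "class_counts": comp.class_counts,
            "class_fractions_pct": {
                k: round(100 * v, 1) for k, v in comp.class_fractions.items()
            },
            "tpm_share_pct": {
                k: round(100 * v, 1) for k, v in comp.tpm_shares.items()
            },
        }

    with _stage(summary, "de"):
        model = DifferentialExpressionModel(study)
        de = model.fit(
            lfc_threshold=config.lfc_threshold, alpha=config.alpha,
            call_on="shrunken" if config.call_on_shrunken_lfc else "raw",
        )
        cio.write_results_table(
            de.table, os.path.join(config.outdir, "de_results.tsv")
        )
        prop = de.proportions()
        cio.write_results_table(
            prop, os.path.join(config.outdir, "de_proportions.tsv")
        )
        summary.stages["de"] = {
            "n_fitted": int((de.table["status"] == "ok").sum()),
            "n_na": int((de.table["status"] != "ok").sum()),
            "dysregulated": {
                f"{cls}@{t}h": int(n) for cls, t, n in zip(
                    prop["rna_class"], prop["contrast_time_h"],
                    prop["n_dysregulated"],
                )
            },
            "proportions": {
                f"{cls}@{t}h": round(float(p), 4) for cls, t, p in zip(
                    prop["rna_class"], prop["contrast_time_h"],
                    prop["proportion"],
                )
            },
        }

    with _stage(summary, "dynamics"):
        dyn = classify_dynamics(
            study, tpm_threshold=config.tpm_threshold,
            min_replicates=config.min_replicates,
        )
        cio.write_results_table(
            dyn.proportions,
            os.path.join(config.outdir, "dynamics_proportions.tsv"),
        )
        cio.write_results_table(
            dyn.overlaps, os.path.join(config.outdir, "dynamics_overlaps.tsv"),
            allow_empty=True,
        )
        summary.stages["dynamics"] = {
            "newborn": {f"{t}h": len(s) for t, s in dyn.newborn.items()},
            "degraded": {f"{t}h": len(s) for t, s in dyn.degraded.items()},
        }

    with _stage(summary, "origin"):
        host_model = DifferentialExpressionModel(
            study, collapse_genes=config.gene_level_host_de
        )
        host_de = host_model.fit(
            times=list(config.origin_times_h),
            lfc_threshold=config.lfc_threshold, alpha=config.alpha,
        )
        host_table = host_de.table.rename(
            columns={host_de.table.columns[0]: "gene_id"}
        )
        circ_table = de.table[de.table["rna_class"] == "circRNA"]
        host_map = study.transcripts["gene_id"]
        origin_out = {}
        all_calls = []
        for t in config.origin_times_h:
            calls, tallies = classify_origin(
                circ_table, host_table, t, circ_host_map=host_map
            )
            all_calls.append(calls)
            entry: dict[str, Any] = {"tallies": tallies}
            try:
                r, p, n = correlate_fold_changes(
                    circ_table, host_table, t, circ_host_map=host_map
                )
                entry.update({"pearson_r": round(r, 4), "n_pairs": n})
            except ValueError:
                entry.update({"pearson_r": None, "n_pairs": 0})
            origin_out[f"{t}h"] = entry
        calls_frame = pd.concat(all_calls, ignore_index=True)
        cio.write_results_table(
            calls_frame, os.path.join(config.outdir, "origin_calls.tsv"),
            allow_empty=True,
        )
        summary.stages["origin"] = origin_out

    with _stage(summary, "splicing"):
        if junctions is not None:
            psi_model = DeltaPsiModel(
                junctions,
                length_normalized=config.length_normalized_psi,
                min_total_reads=config.min_total_reads,
            )
            dpsi = psi_model.fit(
                alpha=config.psi_alpha, min_delta=config.delta_psi_threshold,
                adjust=config.bh_on_delta_psi,
            )
            cio.write_results_table(
                dpsi.table, os.path.join(config.outdir, "delta_psi.tsv")
            )
            rates = dpsi.rates()
            cio.write_results_table(
                rates, os.path.join(config.outdir, "as_rates.tsv")
            )
            summary.stages["splicing"] = {
                "rates": {
                    f"{cls}@{t}h": None if pd.isna(r) else round(float(r), 4)
                    for cls, t, r in zip(
                        rates["rna_class"], rates["contrast_time_h"],
                        rates["rate"],
                    )
                },
            }
        else:
            summary.stages["splicing"] = {"skipped": "no junction table"}

    with _stage(summary, "report"):
        render_report(summary, config.outdir)

    return summary


def render_report(summary: RunSummary, outdir: str) -> list[str]:
    """Write the run summary JSON and flat TSV views of its tables."""
    os.makedirs(outdir, exist_ok=True)
    paths = [os.path.join(outdir, "run_summary.json")]
    summary.to_json(paths[0])
    de = summary.stages.get("de", {})
    if "proportions" in de:
        rows = []
        for key, val in de["proportions"].items():
            cls, t = key.split("@")
            rows.append({"rna_class": cls, "contrast_time_h": t.rstrip("h"),
                         "proportion": val})
        path = os.path.join(outdir, "report_de_proportions.tsv")
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths
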