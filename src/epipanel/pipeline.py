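"""End-to-end orchestration: simulate or load a cohort, derive subtype
signatures, transfer labels, run the silencing screen, call targetability
and assemble a covering gene panel.

Every run writes, in order: a cohort validation report, the signature TSV,
per-sample scores and assignments (samples with a known label keep it; the
classifier fills in the rest, mirroring the known-vs-inferred subtype
bookkeeping), silencing candidates, the targetability matrix, the coverage
report with the greedy panel trajectory, and a machine-readable summary
with sample counts per (known, inferred) subtype group. A run log records
the seed, a config hash and per-stage durations; outputs are a pure
function of config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cm
from . import screen as sc
from .scoring import knn_assign, score_matrix
from .signatures import derive_signatures, signatures_to_frame
from .simulate import CohortSimConfig, simulate_cohort

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


class ConfigError(ValueError):
    """Unknown or invalid configuration keys (fail-fast)."""


@dataclass
class PipelineConfig:
    """Flat, typed pipeline configuration with schema-checked keys.

    ``logfc_threshold`` defaults to 0.5 log2 units: the simulated study
    conditions plant a 1.0-sd expression shift, and a usable signature
    needs a threshold below the planted effect (see the methods note).
    """

    outdir: str = "epipanel_run"
    seed: int = 0
    # either simulate (default) or load from these paths
    expression_path: str | None = None
    methylation_path: str | None = None
    promoter_map_path: str | None = None
    cnv_path: str | None = None
    annotation_path: str | None = None
    # simulation block
    sim: CohortSimConfig | None = None
    # signature stage
    logfc_threshold: float = 0.5
    signature_alpha: float = 0.05
    # label transfer
    k_neighbors: int = 30
    # screen stage
    rho_max: float = -0.3
    screen_alpha: float = 0.05
    hyper_rule: str = "any-probe"
    # panel stage
    panel_max_size: int = 12
    # optional sub-pipelines (off-target / qPCR) carry their own defaults
    max_mismatches: int = 3
    window_bp: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            sim_known = {f.name for f in dataclasses.fields(CohortSimConfig)}
            bad = set(sim) - sim_known
            if bad:
                raise ConfigError(f"unknown sim keys: {sorted(bad)}")
            cfg.sim = CohortSimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _load_or_simulate(config: PipelineConfig):
    paths = (config.expression_path, config.methylation_path,
             config.promoter_map_path, config.cnv_path, config.annotation_path)
    if all(p is not None for p in paths):
        return cm.read_cohort(*paths), None
    if any(p is not None for p in paths):
        raise ConfigError("either all five cohort paths or none must be set")
    sim = config.sim or CohortSimConfig(seed=config.seed)
    sim.seed = config.seed
    return simulate_cohort(sim)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the cohort pipeline; returns the summary dict it also writes."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log = outdir / "run.log"
    handler = logging.FileHandler(run_log, mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s\t%(levelname)s\t%(message)s"))
    root = logging.getLogger("epipanel")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t_all = time.time()
    stage = "setup"
    try:
        log.info("seed=%d config_hash=%s", config.seed, config.config_hash())
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        stage = "cohort"
        t0 = time.time()
        bundle, truth = _load_or_simulate(config)
        report = cm.validate_cohort(bundle)
        (outdir / "validation_report.tsv").write_text(report.to_text())
        if not report.passed:
            raise PipelineError(
                f"cohort validation failed: {report.failures()[:3]}")
        log.info("stage cohort done in %.2fs (%d samples)",
                 time.time() - t0, len(bundle.samples))

        stage = "signatures"
        t0 = time.time()
        labels = bundle.labeled_tumors()
        signatures = derive_signatures(
            bundle.expression[labels.index], labels,
            logfc_threshold=config.logfc_threshold,
            alpha=config.signature_alpha)
        sig_frame = signatures_to_frame(signatures)
        sig_frame.to_csv(outdir / "signatures.tsv", sep="\t", index=False)
        log.info("stage signatures done in %.2fs (%d genes)",
                 time.time() - t0, len(sig_frame))

        stage = "label_transfer"
        t0 = time.time()
        tumors = bundle.tumors
        scores = score_matrix(bundle.expression[tumors], signatures)
        scores.to_csv(outdir / "scores.tsv", sep="\t",
                      index_label="sample_id", float_format="%.10g")
        unlabeled = tumors.difference(labels.index)
        assigned = pd.Series(index=tumors, dtype=object, name="subtype")
        assigned.loc[labels.index] = labels
        inferred = pd.Series(False, index=tumors, name="inferred")
        if len(unlabeled):
            assignments = knn_assign(scores.loc[labels.index], labels,
                                     scores.loc[unlabeled],
                                     k=config.k_neighbors)
            assigned.loc[unlabeled] = assignments["assigned"]
            inferred.loc[unlabeled] = True
            out_assign = assignments.copy()
        else:
            out_assign = pd.DataFrame(index=pd.Index([], name="sample_id"))
        out_assign.to_csv(outdir / "assignments.tsv", sep="\t",
                          index_label="sample_id", float_format="%.10g")
        group = assigned.astype(str) + np.where(inferred, "-inf", "")
        log.info("stage label_transfer done in %.2fs (%d assigned)",
                 time.time() - t0, int(inferred.sum()))

        stage = "screen"
        t0 = time.time()
        results = sc.screen_cohort(bundle, rho_max=config.rho_max,
                                   alpha=config.screen_alpha)
        results.to_csv(outdir / "candidates.tsv", sep="\t",
                       index_label="gene_id", float_format="%.10g")
        candidates = results.index[results["candidate"]].tolist()
        log.info("stage screen done in %.2fs (%d candidates)",
                 time.time() - t0, len(candidates))

        stage = "targetability"
        t0 = time.time()
        hyper = sc.call_hypermethylation(
            bundle.methylation, bundle.promoter_map,
            bundle.normals, tumors, rule=config.hyper_rule)
        tm = sc.targetable_matrix(hyper, bundle.cnv)
        panel_genes = [g for g in candidates if g in tm.targetable.index]
        tm.targetable.loc[panel_genes].astype(int).to_csv(
            outdir / "targetability.tsv", sep="\t", index_label="gene_id")
        log.info("stage targetability done in %.2fs", time.time() - t0)

        stage = "coverage"
        t0 = time.time()
        if panel_genes:
            target_sub = tm.targetable.loc[panel_genes]
            panel, trajectory = sc.greedy_panel(
                target_sub, group, max_size=config.panel_max_size)
            coverage = sc.panel_coverage(target_sub, group, panel)
        else:
            panel, trajectory = [], pd.DataFrame()
            coverage = sc.PanelCoverage(panel=[], overall_pct=0.0,
                                        group_pct={}, gene_pct={})
        trajectory.to_csv(outdir / "panel_trajectory.tsv", sep="\t",
                          index=False, float_format="%.10g")
        cov_rows = [{"group": "overall", "coverage_pct": coverage.overall_pct}]
        cov_rows += [{"group": g, "coverage_pct": v}
                     for g, v in sorted(coverage.group_pct.items())]
        pd.DataFrame(cov_rows).to_csv(outdir / "coverage.tsv", sep="\t",
                                      index=False, float_format="%.10g")
        log.info("stage coverage done in %.2fs", time.time() - t0)

        stage = "summary"
        group_counts = group.value_counts().sort_index()
        summary = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_samples": int(len(bundle.samples)),
            "n_tumors": int(len(tumors)),
            "n_normals": int(len(bundle.normals)),
            "groups": {str(k): int(v) for k, v in group_counts.items()},
            "n_signature_genes": {s: [len(sig.up), len(sig.down)]
                                  for s, sig in sorted(signatures.items())},
            "n_candidates": len(candidates),
            "panel": panel,
            "panel_coverage_pct": coverage.overall_pct,
            "elapsed_s": round(time.time() - t_all, 2),
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("pipeline complete in %.2fs", time.time() - t_all)
        return summary
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    finally:
        handler.close()
        root.removeHandler(handler)
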