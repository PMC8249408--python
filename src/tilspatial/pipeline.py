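"""End-to-end orchestration: simulate or load a cohort, compute per-patient
metrics, compare outcome groups, and write a run-artifact directory.

A run is fully determined by its configuration and seed: the per-patient
metrics table is byte-identical across re-runs.  Patients failing validation
are skipped with a logged reason; a run aborts if more than 20% of patients
are skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import metrics as sm
from .clusters import (ClusterParams, DEFAULT_CLUSTER_PARAMS,
                       DEFAULT_TLS_PARAMS, detect_clusters, detect_tls)
from .cohort import (DEFAULT_QUESTIONS, CohortComparison, SurvivalRecord,
                     compare_groups, km_estimate, metric_registry,
                     patient_summary, rfs_threshold)
from .grid import DEFAULT_L_LADDER
from .io import PointPattern, read_pattern_table, validate_pattern
from .synthetic import (DEFAULT_WINDOW, GOOD_PROFILE, POOR_PROFILE,
                        OutcomeProfile, Window, synthesize_cohort)

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]

logger = logging.getLogger("tilspatial")


@dataclass
class PipelineConfig:
    """One-stop configuration for a pipeline run.

    Defaults reproduce the standard constants: square sides spanning
    10–600 μm with fit windows 10–40 and 200–600 μm, clustering at
    eps = 20 μm / min_pts = 5, and the TLS criterion of 200 lymphocytes in a
    70 μm-radius circle.
    """

    mode: str = "synthetic"                  # "synthetic" | "files"
    inputs: list[str] = field(default_factory=list)  # pattern files (files mode)
    n_good: int = 24
    n_poor: int = 12
    window: Window = DEFAULT_WINDOW
    good_profile: OutcomeProfile = GOOD_PROFILE
    poor_profile: OutcomeProfile = POOR_PROFILE
    L_ladder: tuple[float, ...] = DEFAULT_L_LADDER
    cluster_params: ClusterParams = DEFAULT_CLUSTER_PARAMS
    tls_params: ClusterParams = DEFAULT_TLS_PARAMS
    question_names: tuple[str, ...] = tuple(DEFAULT_QUESTIONS)
    out_dir: str = "tilspatial_run"
    seed: int = 0
    max_skip_fraction: float = 0.2

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.inputs:
            raise ValueError("files mode requires input pattern paths")
        if not self.L_ladder:
            raise ValueError("L ladder must be non-empty")
        if any(L <= 0 for L in self.L_ladder):
            raise ValueError("L ladder entries must be positive")
        unknown = set(self.question_names) - set(DEFAULT_QUESTIONS)
        if unknown:
            raise ValueError(f"unknown question names {sorted(unknown)}")
        if self.n_good < 0 or self.n_poor < 0:
            raise ValueError("cohort sizes must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = {"width": self.window.width, "height": self.window.height}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML or JSON file.

        Nested keys ``window``, ``good_profile``, ``poor_profile``,
        ``cluster_params`` and ``tls_params`` are mapped onto their
        dataclasses; unknown keys are rejected.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        nested = {"window": Window, "good_profile": OutcomeProfile,
                  "poor_profile": OutcomeProfile,
                  "cluster_params": ClusterParams, "tls_params": ClusterParams}
        kwargs = {}
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in valid:
                raise ValueError(f"unknown config key {key!r}")
            if key in nested and isinstance(value, dict):
                value = nested[key](**value)
            elif key == "L_ladder":
                value = tuple(value)
            elif key == "question_names":
                value = tuple(value)
            kwargs[key] = value
        config = cls(**kwargs)
        config.validate()
        return config


def _load_patterns(config: PipelineConfig,
                   ) -> tuple[list[PointPattern], pd.DataFrame | None]:
    if config.mode == "synthetic":
        return synthesize_cohort(
            config.n_good, config.n_poor,
            profiles=(config.good_profile, config.poor_profile),
            window=config.window, seed=config.seed)
    patterns = [read_pattern_table(p) for p in config.inputs]
    return patterns, None


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run-artifact directory.

    Artifacts: ``patient_metrics.tsv`` (one row per patient),
    ``cohort_comparison.json`` (per-metric group means, t/Mann–Whitney p,
    ROC AUC), ``clusters.tsv``, ``rfs.tsv`` + ``km_<stratum>.tsv`` when
    survival data exist, and ``manifest.json`` (config, hash, versions,
    skip list).
    """
    config.validate()
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    questions = {q: DEFAULT_QUESTIONS[q] for q in config.question_names}

    patterns, rfs = _load_patterns(config)
    logger.info("loaded %d patterns (mode=%s)", len(patterns), config.mode)

    rows, cluster_rows, distance_rows, skipped = [], [], [], []
    for pattern in patterns:
        report = validate_pattern(pattern)
        if not report.ok:
            skipped.append({"patient_id": pattern.patient_id,
                            "reason": "; ".join(report.violations)})
            logger.warning("skipping %s: %s", pattern.patient_id,
                           report.violations)
            continue
        t_pat = time.perf_counter()
        clusters, isolated = detect_clusters(pattern, config.cluster_params)
        detect_tls(pattern, clusters, config.tls_params)
        pm = patient_summary(pattern, clusters, isolated,
                             questions=questions, Ls=config.L_ladder,
                             cluster_params=config.cluster_params,
                             tls_params=config.tls_params)
        rows.append(pm.as_row())
        dists = sm.cluster_island_distances(clusters, pattern)
        for cl, dist in zip(clusters, dists):
            distance_rows.append({
                "patient_id": pattern.patient_id,
                "cluster_id": cl.cluster_id, "lc_type": cl.lc_type,
                "size": cl.size_s,
                "distance_um": dist.distance_um if dist else np.nan})
        for cl in clusters:
            cluster_rows.append({
                "patient_id": pattern.patient_id,
                "cluster_id": cl.cluster_id, "size": cl.size_s,
                "lc_type": cl.lc_type, "is_tls": int(cl.is_tls),
                "centroid_x": cl.centroid[0], "centroid_y": cl.centroid[1],
                "n_B": cl.composition.get("B", 0),
                "n_T": cl.composition.get("T", 0),
                "n_CD8": cl.composition.get("T_CD8", 0),
                "n_Th": cl.composition.get("T_helper", 0),
                "n_Treg": cl.composition.get("Treg", 0)})
        logger.info("patient %s: %d cells, %d clusters (%.2fs)",
                    pattern.patient_id, pattern.n_cells, len(clusters),
                    time.perf_counter() - t_pat)

    if patterns and len(skipped) > config.max_skip_fraction * len(patterns):
        raise RuntimeError(
            f"{len(skipped)}/{len(patterns)} patients skipped "
            f"(> {config.max_skip_fraction:.0%}); aborting run")

    all_cols = ["patient_id", "outcome"] + metric_registry(questions)
    metrics_df = pd.DataFrame(rows).reindex(columns=all_cols)
    metrics_df.to_csv(out / "patient_metrics.tsv", sep="\t", index=False,
                      float_format="%.10g")
    pd.DataFrame(cluster_rows).to_csv(out / "clusters.tsv", sep="\t",
                                      index=False, float_format="%.10g")
    pd.DataFrame(distance_rows).to_csv(out / "distances.tsv", sep="\t",
                                       index=False, float_format="%.10g")

    comparisons: dict[str, dict] = {}
    if {"good", "poor"} <= set(metrics_df.get("outcome", pd.Series(dtype=str))):
        gdf = metrics_df[metrics_df["outcome"] == "good"]
        pdf = metrics_df[metrics_df["outcome"] == "poor"]
        for name in metric_registry(questions):
            g = gdf[name].to_numpy(dtype=float)
            p = pdf[name].to_numpy(dtype=float)
            if np.isnan(g).all() or np.isnan(p).all():
                continue
            try:
                comparisons[name] = compare_groups(g, p, metric=name).to_dict()
            except ValueError:
                continue
    (out / "cohort_comparison.json").write_text(
        json.dumps(comparisons, indent=2, sort_keys=True))

    if rfs is not None:
        rfs.to_csv(out / "rfs.tsv", sep="\t", index=False)
        # Stratify RFS by the flagship metric when it is defined everywhere.
        flag = "fd_delta_B_stroma"
        if flag in metrics_df and metrics_df[flag].notna().all() and len(metrics_df) >= 3:
            try:
                thr = rfs_threshold(metrics_df[flag].to_numpy(dtype=float))
                merged = metrics_df.merge(rfs, on="patient_id")
                records = [SurvivalRecord(r.patient_id, r.rfs_months,
                                          int(r.event),
                                          "above_threshold"
                                          if getattr(r, flag) > thr
                                          else "below_threshold")
                           for r in merged.itertuples(index=False)]
                for stratum, table in km_estimate(records).items():
                    table.to_csv(out / f"km_{stratum}.tsv", sep="\t",
                                 index=False)
            except ValueError as exc:
                logger.warning("RFS stratification skipped: %s", exc)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_patients": len(rows),
        "skipped": skipped,
        "runtime_s": round(time.perf_counter() - t0, 3),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    logger.info("run complete: %s (%.1fs)", out, manifest["runtime_s"])
    return out


def make_report(run_dir: str | Path) -> str:
    """Render a human-readable summary of a completed run."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"stage 'run_pipeline' artifacts missing: no manifest in {run_dir}")
    metrics_path = run_dir / "patient_metrics.tsv"
    if not metrics_path.exists():
        raise FileNotFoundError(
            f"stage 'patient_summary' artifacts missing: {metrics_path}")
    manifest = json.loads(manifest_path.read_text())
    metrics = pd.read_csv(metrics_path, sep="\t")
    lines = [
        "tilspatial run report",
        "=====================",
        f"run dir: {run_dir}",
        f"config hash: {manifest['config_hash']}  seed: {manifest['seed']}",
        f"patients analysed: {manifest['n_patients']}"
        f" (skipped: {len(manifest['skipped'])})",
        "",
    ]
    if manifest["skipped"]:
        lines.append("Skipped patients:")
        for s in manifest["skipped"]:
            lines.append(f"  {s['patient_id']}: {s['reason']}")
        lines.append("")
    comp_path = run_dir / "cohort_comparison.json"
    if comp_path.exists():
        comparisons = json.loads(comp_path.read_text())
        if comparisons:
            lines.append(f"{'metric':<42}{'good':>10}{'poor':>10}"
                         f"{'t p':>10}{'ROC AUC':>9}{'MW p':>10}")
            for name, c in sorted(comparisons.items()):
                lines.append(
                    f"{name:<42}{c['mean_good']:>10.4g}{c['mean_poor']:>10.4g}"
                    f"{c['t_p']:>10.3g}{c['roc_auc']:>9.3f}{c['mw_p']:>10.3g}")
        else:
            lines.append("No good-vs-poor comparison (single-group run).")
    lines.append("")
    lines.append(f"metrics table: {metrics.shape[0]} rows x "
                 f"{metrics.shape[1]} columns")
    return "\n".join(lines)
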