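"""End-to-end orchestration: input -> posture -> PMs -> stability -> stats.

Every stage is deterministic given the configuration seed, so rerunning a
config reproduces byte-identical tables; the manifest records a config
hash, per-stage row counts and a content hash of every output file.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .decomposition import (fit_basis, loo_robustness, participant_rvar,
                            principal_accelerations, project_pooled)
from .errors import PmgaitError, ValidationError
from .io import (read_cohort_csv, read_participant_metadata, write_table)
from .posture import pool, preprocess_trial
from .stability import EmbeddingParameters, stability_table
from .stats import (bonferroni_posthoc, mixed_rm_anova, shapiro_wilk_screen,
                    speed_stability_correlations)
from .synthetic import generate_cohort


class StageFailure(PmgaitError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def load_trials(config: RunConfig):
    if config.input.kind == "synthetic":
        return generate_cohort(config.synthetic_spec())
    metadata = (read_participant_metadata(config.input.metadata_csv)
                if config.input.metadata_csv else None)
    return read_cohort_csv(
        config.input.cohort_csv,
        fs_hz=config.input.fs_hz,
        marker_selection=list(config.layout) if config.layout else None,
        metadata=metadata,
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write result tables plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pmgait_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "files": {},
        "warnings": [],
    }

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageFailure(name, exc) from exc

    # -- input ---------------------------------------------------------
    trials = _stage("input", lambda: load_trials(config))
    if not trials:
        raise StageFailure("input", ValidationError("no trials loaded"))
    manifest["stages"]["input"] = {
        "n_trials": len(trials),
        "n_subjects": len({t.subject_id for t in trials}),
        "n_frames_total": sum(t.n_frames for t in trials),
    }

    # -- posture -------------------------------------------------------
    layout = config.layout or trials[0].marker_labels
    pooled = _stage("posture", lambda: pool(
        [preprocess_trial(t, layout) for t in trials]))
    manifest["stages"]["posture"] = {
        "rows": pooled.n_rows, "dims": pooled.dims,
        "n_blocks": len(pooled.block_index),
    }

    # -- decomposition -------------------------------------------------
    dec = config.decomposition

    def _decompose():
        basis = fit_basis(pooled, k_retained=dec.k_retained)
        scores = project_pooled(basis, pooled)
        scores = [principal_accelerations(s, cutoff_hz=dec.cutoff_hz,
                                          order=dec.filter_order)
                  for s in scores]
        rvar = participant_rvar(scores, k_retained=dec.k_retained,
                                scope=dec.rvar_scope)
        rvar_subject = participant_rvar(scores, k_retained=dec.k_retained,
                                        scope="subject")
        pa_rvar = participant_rvar(scores, k_retained=dec.k_retained,
                                   scope=dec.rvar_scope, use_pa=True)
        return basis, scores, pd.concat([rvar, rvar_subject, pa_rvar],
                                        ignore_index=True)

    basis, scores, rvar_table = _stage("decomposition", _decompose)
    write_table(rvar_table, out / "rvar_table.csv", "rvar_table")
    manifest["stages"]["decomposition"] = {
        "k_retained": basis.k_retained,
        "n_components": basis.n_components,
        "explained_variance_pct_first_k": [
            round(float(v), 4) for v in
            100 * basis.explained_variance_ratio[:basis.k_retained]
        ],
        "rvar_rows": len(rvar_table),
    }

    if dec.loo and len({t.subject_id for t in trials}) >= 3:
        report = _stage("robustness", lambda: loo_robustness(
            pooled, k_check=dec.k_retained, threshold=dec.loo_threshold))
        write_table(report.similarity, out / "robustness_table.csv",
                    "robustness_table")
        manifest["stages"]["robustness"] = {
            "min_similarity": {
                str(pm): round(float(v), 6)
                for pm, v in report.min_similarity().items()
            },
            "robust_pms": report.robust_pms(),
        }

    # -- stability -----------------------------------------------------
    st = config.stability
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        lye_table = _stage("stability", lambda: stability_table(
            scores, k_retained=dec.k_retained,
            params=EmbeddingParameters(tau=st.tau, m=st.m, source="fixed"),
            mode=st.mode, evolve_steps=st.evolve_steps, units=st.units,
            use_filtered=st.use_filtered, cutoff_hz=dec.cutoff_hz,
        ))
    manifest["warnings"].extend(str(w.message) for w in caught)
    write_table(lye_table, out / "lye_table.csv", "lye_table")
    n_failed = int((lye_table["status"] != "ok").sum())
    manifest["stages"]["stability"] = {
        "rows": len(lye_table), "failed_cells": n_failed,
    }

    # -- stats ---------------------------------------------------------
    long_rvar = rvar_table[(rvar_table["metric"] == "rvar")
                           & (rvar_table["condition"] != "pooled")]
    long_lye = lye_table.rename(columns={"lye": "value"}).assign(metric="lye")
    long_table = pd.concat([
        long_rvar[["subject", "age_group", "condition", "pm", "metric", "value"]],
        long_lye[["subject", "age_group", "condition", "pm", "metric", "value"]],
    ], ignore_index=True)

    sstats = config.stats
    anova_rows, posthoc_rows = [], []
    skipped = []
    for metric in ("rvar", "lye"):
        for pm in range(1, dec.k_retained + 1):
            try:
                anova_rows.append(mixed_rm_anova(long_table, metric, pm,
                                                 alpha=sstats.alpha))
                if sstats.run_posthoc:
                    posthoc_rows.append(bonferroni_posthoc(
                        long_table, metric, pm,
                        alpha_adj=sstats.alpha_posthoc))
            except PmgaitError as exc:
                skipped.append(f"{metric}/PM{pm}: {exc}")
    anova_table = (pd.concat(anova_rows, ignore_index=True)
                   if anova_rows else pd.DataFrame())
    write_table(anova_table, out / "anova_table.csv", "anova_table")
    if sstats.run_posthoc:
        posthoc = (pd.concat(posthoc_rows, ignore_index=True)
                   if posthoc_rows else pd.DataFrame())
        write_table(posthoc, out / "posthoc_table.csv", "posthoc_table")
    corr = _stage("stats", lambda: speed_stability_correlations(lye_table))
    write_table(corr, out / "correlation_table.csv", "correlation_table")
    if sstats.run_shapiro:
        shapiro = shapiro_wilk_screen(long_table)
        shapiro.to_csv(out / "shapiro_table.csv", index=False)
    manifest["stages"]["stats"] = {
        "anova_rows": len(anova_table),
        "correlation_rows": len(corr),
        "skipped": skipped,
    }

    for f in sorted(out.glob("*.csv")):
        manifest["files"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
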