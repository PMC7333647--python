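"""Pipeline orchestration: simulate -> genomics -> associations/survival ->
extract -> select -> evaluate -> exemplars, with a hashed artifact manifest.

Every stage writes plain-text artifacts into the output directory; the
manifest records the master seed, the full configuration, and a SHA-256
hash per artifact so that re-runs with the same seed can be verified to be
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import assoc_stats, evaluate, genomics, stability, synthcohort, texture
from .config import PipelineConfig, save_config

logger = logging.getLogger(__name__)

__all__ = ["StageError", "run_pipeline", "screen_cohort"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def screen_cohort(
    image_inventory: Mapping[str, Sequence[str]],
    genomic_inventory: Sequence[str],
    required_sequences: Sequence[str] = texture.SEQUENCES,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Include a patient iff all required MR sequences are present AND a
    genomic record exists; one logged reason per exclusion."""
    genomic = set(genomic_inventory)
    included: list[str] = []
    exclusions: list[tuple[str, str]] = []
    for pid in image_inventory:
        present = set(image_inventory[pid])
        missing = [s for s in required_sequences if s not in present]
        if missing:
            exclusions.append((pid, f"missing sequence(s): {','.join(missing)}"))
            continue
        if pid not in genomic:
            exclusions.append((pid, "missing genomic data"))
            continue
        included.append(pid)
    return included, exclusions


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on a synthetic cohort; returns the artifact directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    sim = config.simulation

    # --- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        cohort, variants, segments, truth = synthcohort.generate_genomic_cohort(sim)
        paths = synthcohort.write_cohort_tables(outdir, cohort, variants, segments, truth)
        artifacts.update(paths)
        volumes, masks = synthcohort.generate_image_cohort(sim, truth.cic_label)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- genomics -----------------------------------------------------------
    stage = "genomics"
    try:
        status = genomics.per_patient_status(
            variants,
            segments,
            truth.patient_ids,
            threshold=config.thresholds.segment_mean_deletion,
        )
        status_path = outdir / "genomic_status.csv"
        genomics.write_status_table(status, status_path)
        artifacts["genomic_status"] = status_path
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- associations and survival -----------------------------------------
    stage = "assoc"
    try:
        rows = []
        cic = cohort["cic_mutant"].to_numpy()
        for name, col, cut in (
            ("age_group", (cohort["age"] >= 50).astype(int), None),
            ("gender", (cohort["gender"] == "male").astype(int), None),
            ("grade", (cohort["grade"] == "G3").astype(int), None),
        ):
            tab = pd.crosstab(col, cic).to_numpy()
            if tab.shape == (2, 2) and (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
                stat, df_, p = assoc_stats.pearson_chi2(tab)
                rows.append({"test": f"chi2_{name}", "statistic": stat, "df": df_, "p": p})
        km_mut = assoc_stats.km_estimate(
            cohort.loc[cic == 1, "time"], cohort.loc[cic == 1, "event"]
        )
        km_wt = assoc_stats.km_estimate(
            cohort.loc[cic == 0, "time"], cohort.loc[cic == 0, "event"]
        )
        lr_stat, lr_df, lr_p = assoc_stats.logrank_test(
            cohort["time"], cohort["event"], cic
        )
        rows.append({"test": "logrank_cic", "statistic": lr_stat, "df": lr_df, "p": lr_p})
        cox_data = pd.DataFrame(
            {
                "time": cohort["time"],
                "event": cohort["event"],
                "cic": cic,
                "age": cohort["age"],
                "grade_g3": (cohort["grade"] == "G3").astype(int),
            }
        )
        cox = assoc_stats.cox_fit(cox_data)
        rows.append(
            {
                "test": "cox_cic",
                "statistic": float(cox.coefficients["cic"]),
                "df": np.nan,
                "p": float(cox.p_values["cic"]),
                "hr": float(cox.hazard_ratios["cic"]),
            }
        )
        assoc_df = pd.DataFrame(rows)
        assoc_df["median_os_mutant"] = km_mut.median
        assoc_df["median_os_wildtype"] = km_wt.median
        assoc_path = outdir / "associations.tsv"
        assoc_df.to_csv(assoc_path, sep="\t", index=False)
        artifacts["associations"] = assoc_path
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- feature extraction -------------------------------------------------
    stage = "extract"
    try:
        features = texture.extract_feature_table(
            volumes,
            masks,
            transforms=config.transforms,
            bin_width=config.thresholds.discretization_bin_width,
        )
        features_path = outdir / "features.csv"
        features.to_csv(features_path)
        artifacts["features"] = features_path
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- selection ----------------------------------------------------------
    stage = "select"
    try:
        y = truth.cic_label
        variable = features.loc[:, features.std(axis=0) > 0]
        dropped = features.shape[1] - variable.shape[1]
        if dropped:
            logger.info("dropped %d zero-variance feature columns", dropped)
        Xz = evaluate.zscore_columns(variable)
        selection = stability.repeat_selection(
            Xz.to_numpy(),
            y,
            repetitions=config.selection.repetitions,
            master_seed=config.master_seed,
            folds=config.selection.folds,
            n_alphas=config.selection.n_alphas,
            alpha_min_ratio=config.selection.alpha_min_ratio,
            feature_names=list(Xz.columns),
        )
        selected = stability.truncate_top_sqrt_n(selection, len(Xz))
        sel_path = outdir / "selection.csv"
        ranked = selection.ranked()
        ranked["retained"] = ranked["feature"].isin(selected)
        ranked.to_csv(sel_path, index=False)
        artifacts["selection"] = sel_path
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- evaluation ---------------------------------------------------------
    stage = "evaluate"
    try:
        Xsel = Xz[selected]
        result = evaluate.repeated_split_evaluate(
            Xsel,
            y,
            repetitions=config.evaluation.repetitions,
            test_fraction=config.evaluation.test_fraction,
            master_seed=config.master_seed,
            ridge_c=config.evaluation.ridge_c,
            grid_points=config.evaluation.curve_grid_points,
        )
        metrics_path = outdir / "evaluation_metrics.csv"
        result.metrics.to_csv(metrics_path, index=False)
        summary_path = outdir / "evaluation_summary.json"
        _write_json(
            summary_path,
            {
                "summary": result.summary,
                "roc_cutoff": {
                    "threshold": result.roc_cutoff[0],
                    "point": list(result.roc_cutoff[1]),
                },
                "pr_cutoff": {
                    "threshold": result.pr_cutoff[0],
                    "point": list(result.pr_cutoff[1]),
                },
                "repetitions": result.repetitions,
            },
        )
        curves_path = outdir / "curves.csv"
        pd.DataFrame(
            {
                "grid": result.roc_curve.x,
                "roc_tpr": result.roc_curve.y,
                "roc_threshold": result.roc_curve.thresholds,
                "pr_precision": result.pr_curve.y,
                "pr_threshold": result.pr_curve.thresholds,
            }
        ).to_csv(curves_path, index=False)
        importance_path = outdir / "importance.csv"
        result.importance.to_csv(importance_path)
        artifacts.update(
            {
                "evaluation_metrics": metrics_path,
                "evaluation_summary": summary_path,
                "curves": curves_path,
                "importance": importance_path,
            }
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- exemplars ----------------------------------------------------------
    stage = "exemplars"
    try:
        highlighted = evaluate.u_test_and_top_third(
            result.importance, Xsel, y, alpha=config.evaluation.alpha
        )
        exemplars = evaluate.select_exemplars(
            features, highlighted, result.mean_probability, masks
        )
        exemplars["highlighted_features"] = highlighted
        ex_path = outdir / "exemplars.json"
        _write_json(ex_path, exemplars)
        artifacts["exemplars"] = ex_path
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- manifest -----------------------------------------------------------
    config_path = outdir / "config.yaml"
    # normalize the run-specific path so manifests hash identically across
    # output locations
    portable = dataclasses.replace(config, output_dir=".")
    save_config(portable, config_path)
    artifacts["config"] = config_path
    manifest = {
        "master_seed": config.master_seed,
        "n_patients": sim.n_patients,
        "artifacts": {
            name: {"path": path.name, "sha256": _sha256(path)}
            for name, path in sorted(artifacts.items())
        },
    }
    _write_json(outdir / "manifest.json", manifest)
    return outdir
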