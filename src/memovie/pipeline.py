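"""End-to-end analysis pipeline.

Runs exclusions -> performance metrics -> consistency -> content
effects -> group regression -> classification -> upper bounds on a
dataset and writes every stage's CSV/JSON outputs plus a summary.
Fully deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import consistency as cons
from . import content_stats, metrics, predictors
from .io import Dataset

log = logging.getLogger("memovie")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_perm: int = 1_000
    n_null_iter: int = 1_000
    n_subsample_reps: int = 25
    cv_folds: int = 10
    run_classifier: bool = True
    run_shuffle_null: bool = False  # expensive; opt in
    max_consistency_pairs: int | None = 200
    properties: list[str] | None = None  # default: all binary features


def _stage(name: str):
    log.info("stage: %s", name)
    return time.time()


def run_pipeline(ds: Dataset, out_dir: str | Path, cfg: PipelineConfig | None = None) -> Path:
    """Execute every analysis stage and write reports to ``out_dir``.

    Raises with the failing stage's name; outputs written before the
    failure are preserved.
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    summary: dict = {"seed": cfg.seed, "stages": {}}

    stage = "exclusions"
    try:
        t0 = _stage(stage)
        retained, report = metrics.apply_exclusions(ds.trials)
        (out / "exclusions.json").write_text(json.dumps(report.to_dict(), indent=2))
        summary["stages"][stage] = {
            "n_trials": int(len(retained)),
            "n_excluded_subjects": len(report.excluded_subjects),
        }

        stage = "metrics"
        t0 = _stage(stage)
        perf, pooled = metrics.compute_performance(retained)
        perf.to_csv(out / "performance.csv", index=False)
        curves = []
        dur = metrics.duration_curve(retained, ds.shots)
        for b, pc, n in zip(dur.bin_labels, dur.pc_per_bin, dur.n_per_bin):
            curves.append({"curve": "duration", "bin": b, "pc": pc, "n": n,
                           "r": dur.r, "p": dur.p_value})
        for mode in ("full_shot", "single_frame"):
            ret = metrics.retention_curve(retained, mode=mode)
            for b, pc, n in zip(ret.bin_labels, ret.pc_per_bin, ret.n_per_bin):
                curves.append({"curve": f"retention_{mode}", "bin": b, "pc": pc,
                               "n": n, "r": ret.r, "p": ret.p_value})
        pd.DataFrame(curves).to_csv(out / "curves.csv", index=False)
        summary["stages"][stage] = {"pooled": pooled}

        stage = "consistency"
        t0 = _stage(stage)
        ctab = cons.consistency_table(retained, rng=rng,
                                      max_pairs=cfg.max_consistency_pairs)
        ctab.to_csv(out / "consistency.csv", index=False)
        summary["stages"][stage] = {"n_rows": int(len(ctab))}

        stage = "content"
        t0 = _stage(stage)
        props = cfg.properties
        if props is None:
            binary = [
                c for c in ds.feature_columns
                if set(pd.unique(ds.annotations[c])) <= {0, 1}
            ]
            props = binary
        etab = content_stats.effect_table(retained, ds.annotations, props,
                                          n_perm=cfg.n_perm, rng=rng)
        cont = [
            content_stats.continuous_effect(retained, ds.annotations, p,
                                            n_perm=cfg.n_perm, rng=rng)
            for p in ("n_characters_in_shot", "n_frames", "n_objects_in_shot")
            if p in ds.annotations.columns
        ]
        etab.to_csv(out / "content_effects.csv", index=False)
        pd.DataFrame(cont).to_csv(out / "continuous_effects.csv", index=False)
        summary["stages"][stage] = {"n_properties": int(len(etab))}

        stage = "regression"
        t0 = _stage(stage)
        full = retained[retained["presentation_mode"] == "full_shot"]
        group_pc = full.groupby("shot_id")["correct"].mean()
        model, _ = predictors.fit_group_regression(
            ds.annotations, group_pc, cv_folds=cfg.cv_folds, seed=cfg.seed
        )
        (out / "regression.json").write_text(json.dumps({
            "r_squared_cv": model.r_squared_cv,
            "cv_folds": model.cv_folds,
            "ridge_used": model.ridge_used,
            "intercept": model.intercept,
            "coefficients": model.coefficients,
        }, indent=2))
        summary["stages"][stage] = {"r_squared_cv": model.r_squared_cv}

        if cfg.run_classifier:
            stage = "classification"
            t0 = _stage(stage)
            labels = predictors.make_labels(retained, level="mode",
                                            condition="full_shot")
            reports = predictors.per_property_accuracy(
                ds.annotations, labels, props,
                cv_folds=cfg.cv_folds, n_subsample_reps=cfg.n_subsample_reps,
                rng=rng,
            )
            if cfg.run_shuffle_null:
                all_rep = next(r for r in reports if r.name == "ALL")
                null = predictors.shuffle_null(
                    ds.annotations, labels, None, n_iter=cfg.n_null_iter,
                    rng=rng, observed_accuracy=all_rep.accuracy_mean,
                    cv_folds=cfg.cv_folds,
                )
                all_rep.null_mean = null.null_mean
                all_rep.null_sd = null.null_sd
                all_rep.p_vs_null = null.p_value
            pd.DataFrame([
                {"feature_set": r.name, "accuracy_mean": r.accuracy_mean,
                 "accuracy_sd": r.accuracy_sd, "n_balanced": r.n_balanced,
                 "null_mean": r.null_mean, "null_sd": r.null_sd,
                 "p_vs_null": r.p_vs_null}
                for r in reports
            ]).to_csv(out / "classifier_reports.csv", index=False)
            summary["stages"][stage] = {
                "all_accuracy": next(r for r in reports if r.name == "ALL").accuracy_mean,
            }

        stage = "upper_bounds"
        t0 = _stage(stage)
        subjects = sorted(retained["subject_id"].unique())
        rows = [predictors.majority_predictor(retained, s).as_row() for s in subjects]
        rows += [predictors.self_predictor(retained, s).as_row() for s in subjects]
        pd.DataFrame(rows).to_csv(out / "upper_bounds.csv", index=False)
        summary["stages"][stage] = {"done": True}
    except Exception as exc:
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return out
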