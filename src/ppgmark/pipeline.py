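"""End-to-end experiment runner: generate/ingest -> screen -> preprocess ->
extract -> select -> optimize -> train -> evaluate.

A single global seed deterministically derives every stage seed, so one
integer reproduces a whole run.  A completed run directory contains the
resolved configuration, the segment-level feature table, the selection
report, the trained models' hyperparameters, and the evaluation report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, io, selection, synthetic
from .classifiers import PRESETS, make_model
from .markers import extract_segment_features
from .preprocess import preprocess_segment
from .selection import feature_table, select_features

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one experiment run."""

    seed: int = 0
    cohort: synthetic.CohortConfig | None = None  # None -> default preset
    savgol_order: int = 4
    savgol_frame: int = 21
    beat_length: int = 100
    selection_threshold: float = 0.6
    feature_mode: str = "significant"  # or "selected"
    optimize_family: str = "knn"
    optimize_iterations: int = 30
    cv_folds: int = 10
    #: fold-assignment repeats averaged per CV score; with ~3 subjects per
    #: fold a single assignment is too noisy to rank hyperparameters
    cv_repeats: int = 3
    comparison_presets: tuple[str, ...] = ("da_tuned", "svm_linear")
    quality: io.QualityRules = field(default_factory=io.QualityRules)

    def stage_seed(self, stage: str) -> int:
        """Derive a deterministic per-stage seed below 2**31."""
        key = zlib.crc32(stage.encode())  # stable across processes
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        return int(ss.generate_state(1)[0] % 2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("quality"), dict):
            d["quality"] = io.QualityRules(**d["quality"])
        if isinstance(d.get("cohort"), dict):
            c = dict(d["cohort"])
            for key in ("class0_shape", "class1_shape", "class1_shape_b"):
                if isinstance(c.get(key), dict):
                    c[key] = synthetic.PulseShapeParams(**c[key])
            if isinstance(c.get("noise"), dict):
                c["noise"] = synthetic.NoiseParams(**c["noise"])
            d["cohort"] = synthetic.CohortConfig(**c)
        if isinstance(d.get("comparison_presets"), list):
            d["comparison_presets"] = tuple(d["comparison_presets"])
        return cls(**d)


def extract_features(records: list[synthetic.RawRecord],
                     config: RunConfig) -> pd.DataFrame:
    """Segment, screen, preprocess and extract markers for a record list."""
    features = []
    n_rejected = 0
    for record in records:
        for seg in io.segment_record(record):
            seg = io.screen_quality(seg, config.quality)
            if not seg.quality_ok:
                n_rejected += 1
                continue
            beats = preprocess_segment(seg.samples, seg.fs,
                                       order=config.savgol_order,
                                       frame=config.savgol_frame,
                                       L=config.beat_length)
            seg = io.flag_too_few_beats(seg, len(beats), config.quality)
            if not seg.quality_ok:
                n_rejected += 1
                continue
            sf = extract_segment_features(seg, beats,
                                          min_beats=config.quality.min_beats)
            if sf is None:
                n_rejected += 1
                continue
            features.append(sf)
    logger.info("extracted %d segments (%d rejected)", len(features), n_rejected)
    if not features:
        raise RuntimeError("no usable segments survived quality screening")
    return feature_table(features)


@dataclass
class ExperimentResult:
    table: pd.DataFrame
    selection: selection.SelectionReport
    split: evaluation.SplitPlan
    best_params: dict
    best_cv_error: float
    trace: evaluation.SearchTrace
    reports: dict[str, evaluation.EvaluationReport]

    def summary(self) -> dict:
        return {
            "n_segments": int(len(self.table)),
            "selected_features": self.selection.selected,
            "classifier_features": self.selection.classifier_features,
            "best_params": {k: v for k, v in self.best_params.items()},
            "best_cv_error": self.best_cv_error,
            "reports": {name: r.to_dict() for name, r in self.reports.items()},
        }


def run_experiment(config: RunConfig,
                   records: list[synthetic.RawRecord] | None = None
                   ) -> ExperimentResult:
    """Run the full pipeline; generates the default cohort if no records."""
    if records is None:
        cohort_cfg = config.cohort or synthetic.CohortConfig(
            seed=config.stage_seed("cohort"))
        records = synthetic.generate_cohort(cohort_cfg)

    table = extract_features(records, config)
    report = select_features(table, threshold=config.selection_threshold,
                             mode=config.feature_mode)
    feats = report.classifier_features
    if not feats:
        raise RuntimeError(
            "feature selection is empty: no marker exceeds the correlation "
            "threshold; cannot train classifiers")

    plan = evaluation.subject_half_split(table, seed=config.stage_seed("split"))
    train, test = evaluation.split_rows(table, plan)
    logger.info("train half: %d segments / %d subjects; test half: %d / %d",
                len(train), len(plan.train_subjects),
                len(test), len(plan.test_subjects))

    best_params, best_err, trace = evaluation.optimize_hyperparams(
        train, config.optimize_family, feats,
        iterations=config.optimize_iterations, folds=config.cv_folds,
        cv_repeats=config.cv_repeats, seed=config.stage_seed("optimize"))

    Xtr = train[feats].to_numpy(dtype=float)
    ytr = train["label"].to_numpy(dtype=int)
    Xte = test[feats].to_numpy(dtype=float)
    yte = test["label"].to_numpy(dtype=int)

    reports: dict[str, evaluation.EvaluationReport] = {}

    tuned = make_model(config.optimize_family, **best_params).fit(Xtr, ytr)
    pred, scores = tuned.predict(Xte)
    reports[f"{config.optimize_family}_optimized"] = \
        evaluation.evaluate_predictions(yte, pred, scores)

    for preset in config.comparison_presets:
        params = dict(PRESETS[preset])
        family = ("knn" if preset.startswith("knn")
                  else "discriminant" if preset.startswith("da") else "svm")
        model = make_model(family, **params).fit(Xtr, ytr)
        pred, scores = model.predict(Xte)
        reports[preset] = evaluation.evaluate_predictions(yte, pred, scores)

    return ExperimentResult(table=table, selection=report, split=plan,
                            best_params=best_params, best_cv_error=best_err,
                            trace=trace, reports=reports)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run and persist an experiment; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        result = run_experiment(config)
    except Exception:
        (outdir / "FAILED").write_text("run aborted; see logs\n")
        raise
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(_yamlable(config.to_dict()), fh)
    result.table.to_csv(outdir / "features.csv", index=False)
    with open(outdir / "selection.json", "w") as fh:
        json.dump(result.selection.to_dict(), fh, indent=2)
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(_yamlable(result.summary()), fh, indent=2)
    pd.DataFrame({
        "iteration": np.arange(1, len(result.trace.errors) + 1),
        "cv_error": result.trace.errors,
        "incumbent_error": result.trace.incumbent_errors,
    }).to_csv(outdir / "optimization_trace.csv", index=False)
    return outdir


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
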