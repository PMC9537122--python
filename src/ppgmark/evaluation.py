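"""Subject-grouped evaluation: half splits, tenfold CV, hyperparameter
search, and confusion/ROC reporting.

All data splitting is by subject, never by segment: segments from one
subject are strongly correlated, so letting them straddle a train/test
boundary would leak identity information and inflate accuracy.  The
positive class is anesthesia throughout.

Hyperparameter search mirrors a 30-iteration Bayesian optimization: a
Gaussian-process surrogate with expected-improvement acquisition over the
family's search space, scored by subject-grouped tenfold CV error, with 5
random warm-up evaluations (a pure random-search mode is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.metrics import roc_curve

from .classifiers import make_model


@dataclass(frozen=True)
class SplitPlan:
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.test_subjects):
            raise ValueError("train and test subjects overlap")


def _subjects_by_class(table: pd.DataFrame) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    for cls, sub in table.groupby("label"):
        out[int(cls)] = sorted(sub["subject_id"].unique())
    return out


def subject_half_split(table: pd.DataFrame, seed: int) -> SplitPlan:
    """Split subjects 50/50 per class (odd counts favor training).

    Segment counts on each side then fall wherever subject membership puts
    them, so the two halves generally hold unequal numbers of segments.
    """
    by_class = _subjects_by_class(table)
    if len(by_class) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(by_class):
        subs = np.array(by_class[cls])
        if len(subs) < 2:
            raise ValueError("need at least 2 subjects per class to split")
        rng.shuffle(subs)
        n_train = (len(subs) + 1) // 2
        train.extend(subs[:n_train])
        test.extend(subs[n_train:])
    return SplitPlan(train_subjects=tuple(train), test_subjects=tuple(test))


def split_rows(table: pd.DataFrame, plan: SplitPlan
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    tr = table[table["subject_id"].isin(plan.train_subjects)]
    te = table[table["subject_id"].isin(plan.test_subjects)]
    return tr, te


def _fold_assignment(table: pd.DataFrame, folds: int, seed: int
                     ) -> dict[str, int]:
    """Deal subjects (shuffled within class) round-robin into folds."""
    by_class = _subjects_by_class(table)
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for cls in sorted(by_class):
        subs = np.array(by_class[cls])
        rng.shuffle(subs)
        for i, s in enumerate(subs):
            assignment[s] = (i + offset) % folds
        offset += len(subs)  # stagger so folds get both classes
    return assignment


def grouped_kfold_cv(table: pd.DataFrame, family: str, params: dict,
                     feature_names: list[str], folds: int = 10,
                     seed: int = 0, repeats: int = 1) -> float:
    """Mean test error of subject-grouped k-fold cross-validation.

    With ``repeats`` > 1 the error is additionally averaged over that many
    independent fold assignments; with few subjects per fold a single
    assignment is a noisy estimate.
    """
    if repeats > 1:
        return float(np.mean([
            grouped_kfold_cv(table, family, params, feature_names,
                             folds=folds, seed=seed + 7919 * rep)
            for rep in range(repeats)]))
    subjects = table["subject_id"].unique()
    if len(subjects) < folds:
        raise ValueError(
            f"{len(subjects)} subjects cannot fill {folds} folds; "
            "reduce the fold count")
    assignment = _fold_assignment(table, folds, seed)
    fold_ids = table["subject_id"].map(assignment).to_numpy()
    X = table[feature_names].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    errors = []
    for f in range(folds):
        tr, te = fold_ids != f, fold_ids == f
        if not te.any() or len(np.unique(y[tr])) < 2:
            continue
        model = make_model(family, **params).fit(X[tr], y[tr])
        pred, _ = model.predict(X[te])
        errors.append(float(np.mean(pred != y[te])))
    if not errors:
        raise ValueError("no usable folds")
    return float(np.mean(errors))


# ---------------------------------------------------------------------------
# hyperparameter search

#: default per-family search domains
def default_search_space(family: str) -> dict:
    if family == "knn":
        return {"k": (1, 30),
                "metric": ["euclidean", "cityblock", "chebychev", "minkowski",
                           "cosine", "mahalanobis"],
                "weighting": ["uniform", "inverse"]}
    if family == "discriminant":
        return {"kind": ["linear", "quadratic"]}
    if family == "svm":
        return {"logC": (-3.0, 3.0), "kernel": ["linear", "gaussian", "cubic"]}
    raise ValueError(f"unknown family {family!r}")


def _sample_config(family: str, space: dict, rng: np.random.Generator) -> dict:
    cfg: dict = {}
    for name, dom in space.items():
        if isinstance(dom, (list, tuple)) and dom and isinstance(dom[0], str):
            cfg[name] = dom[rng.integers(len(dom))]
        elif name == "k":
            cfg[name] = int(rng.integers(dom[0], dom[1] + 1))
        else:
            cfg[name] = float(rng.uniform(dom[0], dom[1]))
    return cfg


def _encode(family: str, space: dict, cfg: dict) -> np.ndarray:
    """Numeric embedding of a configuration for the GP surrogate."""
    vec: list[float] = []
    for name, dom in sorted(space.items()):
        if isinstance(dom, (list, tuple)) and dom and isinstance(dom[0], str):
            vec.extend(1.0 if cfg[name] == v else 0.0 for v in dom)
        elif name == "k":
            vec.append(np.log(cfg[name]))
        else:
            vec.append(float(cfg[name]))
    return np.asarray(vec)


def _to_params(family: str, cfg: dict) -> dict:
    params = dict(cfg)
    if "logC" in params:
        params["C"] = float(10.0 ** params.pop("logC"))
    if params.get("metric") == "minkowski":
        params.setdefault("p", 2.0)
    return params


@dataclass
class SearchTrace:
    configs: list[dict] = field(default_factory=list)
    errors: list[float] = field(default_factory=list)
    incumbent_errors: list[float] = field(default_factory=list)


def optimize_hyperparams(table: pd.DataFrame, family: str,
                         feature_names: list[str],
                         space: dict | None = None, iterations: int = 30,
                         folds: int = 10, seed: int = 0,
                         warmup: int = 5, cv_repeats: int = 1,
                         method: str = "gp") -> tuple[dict, float, SearchTrace]:
    """Sequential model-based hyperparameter search.

    Returns (best params, best CV error, trace).  ``method='gp'`` uses a
    Matern Gaussian-process surrogate and expected improvement evaluated on
    a pool of random candidates; ``method='random'`` is plain random
    search under the same budget.
    """
    if iterations < 1:
        raise ValueError("iteration budget must be >= 1")
    if space is None:
        space = default_search_space(family)
    rng = np.random.default_rng(seed)
    trace = SearchTrace()
    seen: set[tuple] = set()

    def evaluate(cfg: dict) -> float:
        params = _to_params(family, cfg)
        try:
            err = grouped_kfold_cv(table, family, params, feature_names,
                                   folds=folds, seed=seed, repeats=cv_repeats)
        except ValueError as e:
            if "exceeds" not in str(e):
                raise
            err = 1.0  # infeasible on these fold sizes (e.g. k > n_train)
        trace.configs.append(cfg)
        trace.errors.append(err)
        best = min(trace.errors)
        trace.incumbent_errors.append(best)
        seen.add(tuple(sorted(cfg.items())))
        return err

    # finite spaces smaller than the budget: exhaustive sweep
    all_categorical = all(isinstance(d, (list, tuple)) and d
                          and isinstance(d[0], str) for d in space.values())
    if all_categorical:
        from itertools import product
        combos = [dict(zip(sorted(space), vals))
                  for vals in product(*(space[k] for k in sorted(space)))]
        for cfg in combos[:iterations]:
            evaluate(cfg)
    else:
        n_warm = min(warmup, iterations)
        for _ in range(n_warm):
            evaluate(_sample_config(family, space, rng))
        for _ in range(iterations - n_warm):
            if method == "random":
                cfg = _sample_config(family, space, rng)
            else:
                cfg = _propose_gp(family, space, trace, rng, seen)
            evaluate(cfg)

    i_best = int(np.argmin(trace.errors))
    return (_to_params(family, trace.configs[i_best]),
            trace.errors[i_best], trace)


def _propose_gp(family: str, space: dict, trace: SearchTrace,
                rng: np.random.Generator, seen: set,
                n_candidates: int = 256) -> dict:
    X = np.array([_encode(family, space, c) for c in trace.configs])
    y = np.asarray(trace.errors)
    kernel = (ConstantKernel(1.0) * Matern(length_scale=np.ones(X.shape[1]),
                                           nu=2.5)
              + WhiteKernel(noise_level=1e-4))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                  random_state=int(rng.integers(2**31)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # GP hyperparameter bounds warnings
        gp.fit(X, y)
        cands = [_sample_config(family, space, rng) for _ in range(n_candidates)]
        fresh = [c for c in cands if tuple(sorted(c.items())) not in seen]
        if not fresh:
            return cands[0]
        Xc = np.array([_encode(family, space, c) for c in fresh])
        mu, sd = gp.predict(Xc, return_std=True)
    best = y.min()
    sd = np.maximum(sd, 1e-9)
    z = (best - mu) / sd
    ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
    return fresh[int(np.argmax(ei))]


# ---------------------------------------------------------------------------
# metrics

@dataclass
class EvaluationReport:
    tp: int
    fn: int
    fp: int
    tn: int
    error_rate: float
    accuracy: float
    sensitivity: float
    false_positive_rate: float
    specificity: float
    precision: float | None
    cohen_kappa: float
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fn": self.fn,
                          "fp": self.fp, "tn": self.tn},
            "error_rate": self.error_rate,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "false_positive_rate": self.false_positive_rate,
            "specificity": self.specificity,
            "precision": self.precision,
            "cohen_kappa": self.cohen_kappa,
            "auc": self.auc,
            "roc": (None if self.roc_fpr is None else
                    {"fpr": self.roc_fpr.tolist(),
                     "tpr": self.roc_tpr.tolist()}),
        }


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> EvaluationReport:
    """Confusion matrix and derived rates, anesthesia (1) positive.

    Precision is reported as None (not 0) when no positive predictions were
    made.  Cohen's kappa is (p_o - p_e) / (1 - p_e).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("inputs must be non-empty and the same length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    n = tp + fn + fp + tn
    p_o = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1 - p_e)
    return EvaluationReport(
        tp=tp, fn=fn, fp=fp, tn=tn,
        error_rate=(fp + fn) / n,
        accuracy=p_o,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        false_positive_rate=fp / (fp + tn) if fp + tn else float("nan"),
        specificity=tn / (fp + tn) if fp + tn else float("nan"),
        precision=tp / (tp + fp) if tp + fp else None,
        cohen_kappa=kappa,
    )


def roc_auc(scores: np.ndarray, y_true: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold-sweep ROC points and trapezoid AUC.

    Tied scores move along the curve simultaneously, so the trapezoid AUC
    equals the normalized Mann-Whitney U with 1/2 credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present for ROC")
    fpr, tpr, _ = roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def evaluate_predictions(y_true, y_pred, scores=None) -> EvaluationReport:
    """Full report; ROC/AUC included when ranking scores are given."""
    report = confusion_metrics(y_true, y_pred)
    if scores is not None:
        fpr, tpr, auc = roc_auc(scores, y_true)
        report.roc_fpr, report.roc_tpr, report.auc = fpr, tpr, auc
    return report
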