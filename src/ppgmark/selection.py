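"""Marker-vs-label association and feature selection.

Each of the 13 segment-level markers is scored against the binary
anesthesia label with the point-biserial correlation (identically the
Pearson correlation with the 0/1-coded label); markers with |r| above a
threshold (0.6 by default) are selected.  A Welch two-sample t-test (no
equal-variance assumption, Satterthwaite degrees of freedom) accompanies
each marker; in the default "4-feature" mode a selected marker that fails
the t-test at p < 0.05 is additionally excluded from the classifier set.
No multiple-testing correction is applied to the t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .markers import MARKER_NAMES, SegmentFeatures
from .synthetic import ANESTHESIA

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.6


def feature_table(features: list[SegmentFeatures]) -> pd.DataFrame:
    """Stack segment features into a rectangular table.

    Columns: subject_id, label (anesthesia coded 1), start_time, n_beats,
    then the 13 marker columns.
    """
    if not features:
        raise ValueError("no segment features to tabulate")
    rows = [{
        "subject_id": sf.subject_id,
        "label": int(sf.label == ANESTHESIA),
        "start_time": sf.start_time,
        "n_beats": sf.n_beats,
        **sf.values,
    } for sf in features]
    return pd.DataFrame(rows)


def point_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """Point-biserial correlation of a numeric vector with a binary one.

    r = (M1 - M0) / s_x * sqrt(n1 * n0 / n^2) with the population-sd
    convention, which equals the Pearson correlation of x with 0/1-coded y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = len(x)
    n1 = int(np.sum(y == 1))
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both groups must be non-empty")
    s_x = float(np.std(x))  # population convention (ddof=0)
    if s_x == 0:
        raise ValueError("x has zero variance; correlation undefined")
    m1 = float(np.mean(x[y == 1]))
    m0 = float(np.mean(x[y == 0]))
    return (m1 - m0) / s_x * np.sqrt(n1 * n0 / n**2)


def welch_t(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Satterthwaite df, two-sided p)."""
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(x0, x1, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class SelectionReport:
    r: dict[str, float]
    t: dict[str, float]
    df: dict[str, float]
    p: dict[str, float]
    threshold: float
    selected: list[str]
    classifier_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "per_feature": {
                name: {"r": self.r[name], "t": self.t[name],
                       "df": self.df[name], "p": self.p[name]}
                for name in self.r
            },
            "selected": self.selected,
            "classifier_features": self.classifier_features,
        }


def select_features(table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                    feature_names: tuple[str, ...] = MARKER_NAMES,
                    mode: str = "significant") -> SelectionReport:
    """Score all markers and pick the classifier feature set.

    ``mode='selected'`` trains on every |r| > threshold marker;
    ``mode='significant'`` (default) further drops selected markers whose
    Welch t-test p-value is >= 0.05, reflecting that a marker can clear the
    correlation screen while showing no significant group difference.
    """
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    r: dict[str, float] = {}
    t: dict[str, float] = {}
    df_: dict[str, float] = {}
    p: dict[str, float] = {}
    for name in feature_names:
        x = table[name].to_numpy(dtype=float)
        r[name] = point_biserial(x, y)
        t[name], df_[name], p[name] = welch_t(x[y == 0], x[y == 1])
    selected = [name for name in feature_names if abs(r[name]) > threshold]
    if not selected:
        logger.warning("no marker exceeds |r| > %.3g; selection is empty",
                       threshold)
    if mode == "significant":
        classifier_features = [name for name in selected if p[name] < 0.05]
    elif mode == "selected":
        classifier_features = list(selected)
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return SelectionReport(r=r, t=t, df=df_, p=p, threshold=threshold,
                           selected=selected,
                           classifier_features=classifier_features)
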