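"""Performance evaluation: confusion metrics, ROC/AUC, feature correlations
and pre-freeze detection latency.

All confusion-based metrics are reported in percent:

* sensitivity = TP / (TP + FN), specificity = TN / (TN + FP)
* PPV = TP / (TP + FP), NPV = TN / (TN + FN)
* accuracy = (TP + TN) / total
* F-score = harmonic mean of sensitivity and PPV
* Youden index = sensitivity + specificity - 100

A metric whose denominator is zero is *undefined* and propagated as NaN with
an explicit flag — never silently 0 or 100 — because small leave-one-subject-
out folds can lack a class entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "confusion_counts",
    "compute_metrics",
    "roc_curve",
    "spearman_feature_correlation",
    "detection_latency",
    "METRIC_NAMES",
]

METRIC_NAMES = [
    "sensitivity",
    "specificity",
    "accuracy",
    "ppv",
    "npv",
    "f_score",
    "youden",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class PerformanceReport:
    """Scalar metrics (percent; NaN = undefined) plus optional ROC data."""

    counts: ConfusionCounts
    metrics: dict[str, float]
    undefined: list[str] = field(default_factory=list)
    roc_points: np.ndarray | None = None  # (fpr, tpr) rows
    auc: float | None = None

    def __getattr__(self, name: str):
        try:
            return self.__dict__["metrics"][name]
        except KeyError:
            raise AttributeError(name) from None

    def as_dict(self) -> dict:
        out = {k: v for k, v in self.metrics.items()}
        out.update(
            tp=self.counts.tp, tn=self.counts.tn, fp=self.counts.fp, fn=self.counts.fn
        )
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise EvaluationError("label/prediction length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def compute_metrics(counts: ConfusionCounts) -> PerformanceReport:
    """Evaluate the seven confusion-based metrics exactly, in percent."""
    if counts.total == 0:
        raise EvaluationError("all-zero confusion counts")
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    npv = _ratio(counts.tn, counts.tn + counts.fn)
    acc = _ratio(counts.tp + counts.tn, counts.total)
    if math.isnan(sens) or math.isnan(ppv) or (sens + ppv) == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * sens * ppv / (sens + ppv)
    youden = sens + spec - 100.0  # nan-propagating
    metrics = {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "ppv": ppv,
        "npv": npv,
        "f_score": f1,
        "youden": youden,
    }
    undefined = [k for k, v in metrics.items() if math.isnan(v)]
    return PerformanceReport(counts=counts, metrics=metrics, undefined=undefined)


def roc_curve(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from continuous scores.

    Equal scores collapse onto one threshold. AUC equals the normalized
    Mann-Whitney U statistic on tie-free data.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("ROC requires both classes")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr]), float(_auc(fpr, tpr))


def spearman_feature_correlation(
    dataset: pd.DataFrame,
    selected_features: list[str],
    label_col: str = "label",
) -> pd.DataFrame:
    """Spearman rank correlation of each feature against the binary label.

    Negative rho means the feature *decreases* on steps approaching a freeze
    (label 1). Constant features give an undefined rho, flagged as NaN.
    P-values use the large-sample t approximation with average ranks for
    ties.
    """
    y = dataset[label_col].to_numpy()
    rows = []
    for name in selected_features:
        x = dataset[name].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rho, p = math.nan, math.nan
        else:
            rho, p = stats.spearmanr(x, y)
        rows.append({"feature": name, "rho": float(rho), "p_value": float(p)})
    return pd.DataFrame(rows)


def detection_latency(
    step_times_s: np.ndarray,
    predictions: np.ndarray,
    episode_onsets_s: list[float] | np.ndarray,
    strict_run: bool = True,
) -> pd.DataFrame:
    """Per-episode detection latency, in steps before the freeze onset.

    For each episode, the steps preceding its onset are taken in time order
    and the latency is the length of the *consecutive* run of pre-FOG
    predictions immediately before onset (counting backwards until the first
    gait prediction). With ``strict_run=False`` the looser convention — the
    number of pre-onset steps from the earliest positive prediction onwards —
    is used instead.

    Episodes with zero pre-onset steps are excluded from aggregation but
    reported with ``n_pre_steps = 0`` so coverage stays visible.
    """
    t = np.asarray(step_times_s, dtype=float)
    pred = np.asarray(predictions, dtype=int)
    order = np.argsort(t, kind="stable")
    t, pred = t[order], pred[order]
    rows = []
    for onset in episode_onsets_s:
        before = pred[t < onset]
        if before.size == 0:
            rows.append({"onset_s": float(onset), "latency_steps": math.nan,
                         "n_pre_steps": 0})
            continue
        if strict_run:
            run = 0
            for v in before[::-1]:
                if v == 1:
                    run += 1
                else:
                    break
        else:
            positive = np.nonzero(before == 1)[0]
            run = before.size - positive[0] if positive.size else 0
        rows.append(
            {
                "onset_s": float(onset),
                "latency_steps": int(run),
                "n_pre_steps": int(before.size),
            }
        )
    return pd.DataFrame(rows)


def latency_summary(per_episode: pd.DataFrame) -> dict[str, float]:
    """Mean +/- sd latency over episodes that had at least one pre-onset step."""
    valid = per_episode[per_episode["n_pre_steps"] > 0]["latency_steps"]
    return {
        "mean_steps": float(valid.mean()) if len(valid) else math.nan,
        "sd_steps": float(valid.std(ddof=1)) if len(valid) > 1 else math.nan,
        "n_episodes": int(len(valid)),
        "n_excluded": int((per_episode["n_pre_steps"] == 0).sum()),
    }
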