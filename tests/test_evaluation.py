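"""Metric identities, ROC equivalence, correlations and latency."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fogstep.evaluation import (
    ConfusionCounts,
    EvaluationError,
    compute_metrics,
    confusion_counts,
    detection_latency,
    latency_summary,
    roc_curve,
    spearman_feature_correlation,
)


class TestComputeMetrics:
    def test_worked_example_exact(self):
        rep = compute_metrics(ConfusionCounts(tp=8, fn=2, tn=9, fp=1))
        assert rep.sensitivity == pytest.approx(80.0)
        assert rep.specificity == pytest.approx(90.0)
        assert rep.accuracy == pytest.approx(85.0)
        assert rep.ppv == pytest.approx(88.89, abs=0.01)
        assert rep.npv == pytest.approx(81.82, abs=0.01)
        assert rep.f_score == pytest.approx(84.21, abs=0.01)
        assert rep.youden == pytest.approx(70.0)

    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionCounts(tp=5, fn=0, tn=7, fp=0))
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv", "f_score"):
            assert rep.metrics[name] == 100.0
        assert rep.youden == 100.0

    def test_undefined_metric_flagged_not_zero(self):
        rep = compute_metrics(ConfusionCounts(tp=0, fn=0, tn=9, fp=1))
        assert math.isnan(rep.sensitivity)
        assert "sensitivity" in rep.undefined
        assert rep.specificity == 90.0

    def test_youden_identity_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(1, 200, size=4)
            rep = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert rep.youden == pytest.approx(
                rep.sensitivity + rep.specificity - 100.0, abs=1e-9
            )

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 500)
        p = rng.integers(0, 2, 500)
        rep = compute_metrics(confusion_counts(y, p))
        assert rep.accuracy == pytest.approx(100.0 * np.mean(y == p))
        pos = y == 1
        assert rep.sensitivity == pytest.approx(100.0 * np.mean(p[pos] == 1))

    def test_counts_must_sum_to_n(self):
        counts = confusion_counts([0, 1, 1, 0], [1, 1, 0, 0])
        assert counts.total == 4


class TestROC:
    def test_perfect_separation_auc_one(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        _, auc = roc_curve(scores, labels)
        assert auc == 1.0

    def test_independent_scores_auc_half(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=10_000)
        labels = rng.integers(0, 2, 10_000)
        _, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_negated_scores_mirror_auc(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=300)
        labels = (scores + rng.normal(size=300) > 0).astype(int)
        _, auc = roc_curve(scores, labels)
        _, auc_neg = roc_curve(-scores, labels)
        assert auc_neg == pytest.approx(1.0 - auc, abs=1e-12)

    def test_auc_equals_mann_whitney_without_ties(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=400)  # continuous: ties a.s. absent
        labels = rng.integers(0, 2, 400)
        _, auc = roc_curve(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert auc == pytest.approx(u / (pos.size * neg.size), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_curve(np.array([0.2, 0.4]), np.array([1, 1]))


class TestSpearman:
    def test_feature_lower_in_positive_class_gives_negative_rho(self):
        df = pd.DataFrame(
            {"feat": [5, 6, 7, 1, 2, 3], "label": [0, 0, 0, 1, 1, 1]}
        )
        out = spearman_feature_correlation(df, ["feat"])
        assert out.loc[0, "rho"] < 0

    def test_independent_feature_small_rho(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(20):
            df = pd.DataFrame(
                {"feat": rng.normal(size=500), "label": rng.integers(0, 2, 500)}
            )
            out = spearman_feature_correlation(df, ["feat"])
            if abs(out.loc[0, "rho"]) < 0.1 and out.loc[0, "p_value"] > 0.05:
                hits += 1
        assert hits >= 18  # >= 90% of repetitions

    def test_constant_feature_flagged(self):
        df = pd.DataFrame({"feat": [1.0] * 10, "label": [0, 1] * 5})
        out = spearman_feature_correlation(df, ["feat"])
        assert math.isnan(out.loc[0, "rho"])


class TestLatency:
    def test_consecutive_run_definition(self):
        times = np.arange(6, dtype=float)
        preds = np.array([0, 0, 1, 1, 1, 1])
        out = detection_latency(times, preds, [6.0])
        assert out.loc[0, "latency_steps"] == 4

    def test_all_gait_gives_zero(self):
        out = detection_latency(np.arange(5.0), np.zeros(5, int), [5.0])
        assert out.loc[0, "latency_steps"] == 0

    def test_loose_convention_counts_from_first_positive(self):
        times = np.arange(6, dtype=float)
        preds = np.array([0, 1, 0, 1, 1, 1])
        strict = detection_latency(times, preds, [6.0], strict_run=True)
        loose = detection_latency(times, preds, [6.0], strict_run=False)
        assert strict.loc[0, "latency_steps"] == 3
        assert loose.loc[0, "latency_steps"] == 5

    def test_flipping_prediction_to_gait_never_increases_latency(self):
        rng = np.random.default_rng(11)
        times = np.arange(20, dtype=float)
        preds = rng.integers(0, 2, 20)
        base = detection_latency(times, preds, [20.0]).loc[0, "latency_steps"]
        for i in np.nonzero(preds == 1)[0]:
            flipped = preds.copy()
            flipped[i] = 0
            lat = detection_latency(times, flipped, [20.0]).loc[0, "latency_steps"]
            assert lat <= base

    def test_episode_without_pre_steps_excluded_from_aggregate(self):
        times = np.array([5.0, 6.0])
        preds = np.array([1, 1])
        out = detection_latency(times, preds, [3.0, 7.0])
        summary = latency_summary(out)
        assert summary["n_episodes"] == 1
        assert summary["n_excluded"] == 1

    def test_two_second_window_at_two_steps_per_second(self, study_cohort):
        """Predicting the ground-truth labels recovers ~4-step latencies."""
        trials, _, _ = study_cohort
        lat_all = []
        for trial in trials[:8]:
            times = np.sort(
                np.concatenate(
                    [trial.truth.step_times[leg] for leg in ("left", "right")]
                )
            )
            onsets = [e.onset_s for e in trial.truth.episodes]
            truth_pred = np.array(
                [
                    int(any(o - 2.0 <= t < o for o in onsets))
                    for t in times
                ]
            )
            out = detection_latency(times, truth_pred, onsets)
            lat_all.extend(out["latency_steps"].dropna().tolist())
        assert np.mean(lat_all) == pytest.approx(4.0, abs=1.0)
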