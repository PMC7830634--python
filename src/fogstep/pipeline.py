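"""End-to-end orchestration: cohort -> features -> labels -> models -> report.

This module glues the stages together for scripted use and for the command
line: it turns raw two-device recordings (synthetic or read from disk) into
synchronized trials, extracts the per-step feature matrix once, and then
runs the detection and prediction analyses with their validation protocols,
cost tuning, ensembling, transfer experiments, correlation table and latency
summary. A single top-level seed is expanded into per-stage seeds through a
:class:`numpy.random.SeedSequence` spawn tree, so stages are independently
reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, modeling, synthetic
from .features import FEATURE_COLUMNS, cohort_feature_table
from .labeling import LabeledDataset, LabelingConfig, label_steps
from .signal_io import (
    Episode,
    TrialRecording,
    gait_start_time,
    find_standup_peak,
    normalize_signal,
    read_trial_csv,
    read_manifest,
    synchronize_legs,
)

__all__ = [
    "recording_from_synthetic",
    "load_cohort",
    "episodes_by_trial",
    "build_feature_matrix",
    "labeled_dataset",
    "stage_seeds",
    "run_prediction_analysis",
    "run_detection_analysis",
    "run_full_analysis",
]


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Expand one top-level seed into per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def recording_from_synthetic(trial: synthetic.SyntheticTrial) -> TrialRecording:
    """Normalize and synchronize a simulated trial into a TrialRecording.

    This deliberately goes through the same normalization/synchronization
    code path as disk-read data — the generator's ground-truth offset is
    *not* consulted.
    """
    left = normalize_signal(trial.left_raw)
    right = normalize_signal(trial.right_raw)
    left_al, right_al, delay = synchronize_legs(left, right)
    fs = left_al.sample_rate_hz
    standup_s = left_al.t0 + find_standup_peak(left_al) / fs
    return TrialRecording(
        left=left_al,
        right=right_al,
        episodes=trial.annotations,
        subject_id=trial.subject_id,
        condition=trial.condition,
        trial_id=trial.trial_id,
        gait_start_s=gait_start_time(standup_s),
        sync_delay_s=delay,
    )


def load_cohort(cohort_dir: str | Path) -> list[TrialRecording]:
    """Read a cohort directory (manifest + per-leg CSVs + annotation JSONs)."""
    cohort_dir = Path(cohort_dir)
    manifest = read_manifest(cohort_dir / "manifest.csv")
    recordings = []
    for row in manifest.itertuples():
        rec, _ = read_trial_csv(
            cohort_dir / row.left_file,
            cohort_dir / row.right_file,
            cohort_dir / row.annotation_file,
            subject_id=str(row.subject_id),
            condition=str(row.condition),
            trial_id=str(row.trial_id),
        )
        recordings.append(rec)
    return recordings


def episodes_by_trial(recordings: list[TrialRecording]) -> dict[str, list[Episode]]:
    return {r.trial_id: r.episodes for r in recordings}


def build_feature_matrix(recordings: list[TrialRecording]) -> pd.DataFrame:
    return cohort_feature_table(recordings)


def labeled_dataset(
    features: pd.DataFrame,
    episodes: dict[str, list[Episode]],
    task: str,
    window_s: float = 2.0,
    condition: str | None = None,
) -> LabeledDataset:
    """Label the feature matrix for one task, optionally one therapy state."""
    ds = label_steps(
        features, episodes, LabelingConfig(prefog_window_s=window_s, task=task)
    )
    if condition is not None:
        ds = LabeledDataset(
            data=ds.data[ds.data["condition"] == condition].reset_index(drop=True),
            task=ds.task,
            positive_class=ds.positive_class,
            excluded_episodes=ds.excluded_episodes,
        )
    return ds


@dataclass
class AnalysisResult:
    """Machine-readable bundle of everything one full run computes."""

    detection: dict = field(default_factory=dict)
    prediction: dict = field(default_factory=dict)
    manifest: pd.DataFrame | None = None

    def summary(self) -> dict:
        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, pd.DataFrame):
                return json.loads(obj.to_json(orient="split"))
            if isinstance(obj, pd.Series):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, float)):
                v = float(obj)
                return None if math.isnan(v) else v
            if isinstance(obj, (np.integer, int)):
                return int(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, evaluation.PerformanceReport):
                return _clean(obj.as_dict())
            if isinstance(obj, modeling.ValidationReport):
                return {
                    "protocol": obj.protocol,
                    "aggregate": _clean(obj.aggregate),
                    "pooled": _clean(obj.pooled) if obj.pooled else None,
                    "leakage_audit": obj.leakage_audit,
                }
            if isinstance(obj, modeling.ModelSpec):
                return {
                    "family": obj.family,
                    "params": _clean(dict(obj.params)),
                    "features": list(obj.features),
                    "fn_cost": obj.fn_cost,
                }
            return obj

        return _clean({"detection": self.detection, "prediction": self.prediction})


def run_detection_analysis(
    features: pd.DataFrame,
    episodes: dict[str, list[Episode]],
    seed: int,
    protocols: tuple[str, ...] = ("kfold10", "split7030", "loso"),
    conditions: tuple[str, ...] = ("on", "off"),
    algorithm1_reps: int = 20,
) -> dict:
    """Gait-vs-FOG analysis per therapy state plus the transfer experiment."""
    seeds = stage_seeds(seed, 4)
    out: dict = {"per_condition": {}}
    for cond in conditions:
        ds = labeled_dataset(features, episodes, "detection", condition=cond)
        entry = {}
        if "kfold10" in protocols:
            entry["kfold10"] = modeling.kfold_validate(ds.data, seed=seeds[0])
        if "split7030" in protocols:
            entry["split7030"] = modeling.run_algorithm1(
                ds.data, k=algorithm1_reps, seed=seeds[1]
            )
        if "loso" in protocols:
            entry["loso"] = modeling.loso_validate(ds.data, seed=seeds[2])
        out["per_condition"][cond] = entry
    pooled = labeled_dataset(features, episodes, "detection")
    if len(conditions) == 2 and set(conditions) <= set(pooled.data["condition"]):
        out["cross_condition"] = {}
        for a, b in ((conditions[0], conditions[1]), (conditions[1], conditions[0])):
            rep, _ = modeling.cross_condition(pooled.data, a, b, seed=seeds[3])
            out["cross_condition"][f"train_{a}_test_{b}"] = rep
    return out


def run_prediction_analysis(
    features: pd.DataFrame,
    episodes: dict[str, list[Episode]],
    seed: int,
    windows: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0),
    final_window_s: float = 2.0,
    budget: int = 30,
    conditions: tuple[str, ...] = ("on", "off"),
    select_models: bool = True,
) -> dict:
    """Gait-vs-pre-FOG analysis: window/model selection, cost tuning,
    OR ensemble, LOSO, transfer, correlations and latency."""
    seeds = stage_seeds(seed, 8)
    out: dict = {}

    if select_models:
        builder = lambda w: labeled_dataset(features, episodes, "prediction", w).data
        best_w, best_fam, table, cell_params = modeling.select_window_and_model(
            builder, windows=windows, budget=budget, seed=seeds[0]
        )
        out["window_model_accuracy"] = table
        out["best_window_s"] = best_w
        out["best_family"] = best_fam

    ds = labeled_dataset(features, episodes, "prediction", final_window_s)
    data = ds.data
    out["final_window_s"] = final_window_s
    out["excluded_gait_initiation_episodes"] = ds.excluded_episodes

    # FN-cost tuning on the SVM spec tuned on the full prediction set
    svm_spec, _ = modeling._tuned_svm_spec(data, modeling.DEFAULT_C_RANGE, 10, seeds[1])
    curve, chosen_cost = modeling.tune_fn_cost(data, svm_spec, seed=seeds[2])
    out["fn_cost_curve"] = curve
    out["chosen_fn_cost"] = chosen_cost

    # OR combination of cost-tuned SVM and LDA on a stratified split
    from sklearn.model_selection import train_test_split

    train, test = train_test_split(
        data, test_size=0.3, stratify=data["label"], random_state=seeds[3] % (2**31)
    )
    svm_model = modeling.fit_model(
        train, replace(svm_spec, fn_cost=chosen_cost), seeds[3]
    )
    lda_spec = modeling.ModelSpec(
        family="lda", params=(("delta", 0.01), ("gamma", 0.1)),
        features=svm_spec.features, fn_cost=chosen_cost,
    )
    lda_model = modeling.fit_model(train, lda_spec, seeds[3])
    y_test = test["label"].to_numpy(int)
    or_pred = modeling.combine_or([svm_model, lda_model], test)
    out["or_ensemble"] = {
        "svm": evaluation.compute_metrics(
            evaluation.confusion_counts(y_test, svm_model.predict(test))
        ),
        "lda": evaluation.compute_metrics(
            evaluation.confusion_counts(y_test, lda_model.predict(test))
        ),
        "combined": evaluation.compute_metrics(
            evaluation.confusion_counts(y_test, or_pred)
        ),
    }

    # LOSO per condition + feature interpretability + latency
    out["per_condition"] = {}
    for cond in conditions:
        cds = labeled_dataset(
            features, episodes, "prediction", final_window_s, condition=cond
        )
        if cds.data["label"].nunique() < 2:
            continue
        try:
            loso = modeling.loso_validate(
                cds.data, seed=seeds[4], fn_cost=chosen_cost
            )
        except modeling.ModelingError as exc:
            # degenerate condition subset (e.g. a fold with a one-member
            # class); surface it instead of aborting the whole analysis
            out["per_condition"][cond] = {"error": str(exc)}
            continue
        freq = loso.extras["selection_frequency"]
        frequent = [f for f, v in freq.items() if v >= 0.8]
        corr = evaluation.spearman_feature_correlation(cds.data, frequent)
        lat = _latency_from_loso(cds.data, loso, episodes)
        out["per_condition"][cond] = {
            "loso": loso,
            "frequent_features": frequent,
            "spearman": corr,
            "latency": lat,
        }

    if len(conditions) == 2 and set(conditions) <= set(data["condition"]):
        out["cross_condition"] = {}
        for a, b in ((conditions[0], conditions[1]), (conditions[1], conditions[0])):
            rep, _ = modeling.cross_condition(
                data, a, b, fn_cost=chosen_cost, seed=seeds[5]
            )
            out["cross_condition"][f"train_{a}_test_{b}"] = rep
    return out


def _latency_from_loso(
    data: pd.DataFrame,
    loso: modeling.ValidationReport,
    episodes: dict[str, list[Episode]],
) -> dict:
    """Per-episode pre-freeze detection latency from LOSO fold predictions."""
    pred_frame = loso.extras["predictions"].set_index("row_index")
    per_ep = []
    for trial_id, grp in data.groupby("trial_id"):
        eps = [e for e in episodes.get(str(trial_id), []) if not e.at_gait_initiation]
        if not eps:
            continue
        preds = pred_frame.loc[grp.index, "prediction"].to_numpy()
        lat = evaluation.detection_latency(
            grp["peak_time_s"].to_numpy(), preds, [e.start_s for e in eps]
        )
        per_ep.append(lat)
    if not per_ep:
        return {"mean_steps": math.nan, "sd_steps": math.nan, "n_episodes": 0}
    table = pd.concat(per_ep, ignore_index=True)
    summary = evaluation.latency_summary(table)
    summary["per_episode"] = table
    return summary


def run_full_analysis(
    config: synthetic.CohortConfig,
    seed: int,
    out_dir: str | Path | None = None,
    detection_protocols: tuple[str, ...] = ("split7030", "loso"),
    windows: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0),
    budget: int = 30,
    algorithm1_reps: int = 20,
) -> AnalysisResult:
    """Simulate a cohort and run both analyses end to end.

    With ``out_dir`` set, writes the summary JSON, the feature matrix, the
    per-protocol metric tables and the correlation/latency tables under that
    directory.
    """
    seeds = stage_seeds(seed, 4)
    trials, manifest = synthetic.generate_cohort(replace(config, seed=seeds[0]))
    recordings = [recording_from_synthetic(t) for t in trials]
    features = build_feature_matrix(recordings)
    episodes = episodes_by_trial(recordings)
    result = AnalysisResult(manifest=manifest)
    result.detection = run_detection_analysis(
        features, episodes, seeds[1], protocols=detection_protocols,
        algorithm1_reps=algorithm1_reps,
    )
    result.prediction = run_prediction_analysis(
        features, episodes, seeds[2], windows=windows, budget=budget
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        features.to_csv(out_dir / "feature_matrix.csv", index=False)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        (out_dir / "summary.json").write_text(
            json.dumps(result.summary(), indent=1, default=str)
        )
    return result
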