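"""Step labeling: gait / pre-FOG / FOG classes from episode annotations.

A step belongs to a class by the position of its anchor peak (the mid-swing
instant), which gives every step exactly one unambiguous label:

* **FOG** — the peak lies inside an annotated episode ``[start, end]``;
* **pre-FOG** — the peak lies in ``[start - window, start)`` of some episode
  and not inside any other episode (so a pre-FOG window reaching back into a
  preceding episode is effectively truncated at that episode's end);
* **gait** — everything else.

Two binary tasks are derived from this three-way partition:

* **detection** (gait vs FOG): pre-FOG steps count as gait — the task has
  only two classes and all episodes are used;
* **prediction** (gait vs pre-FOG): FOG steps are dropped, and episodes that
  occurred during gait initiation (the stand-up-to-walking transition) are
  excluded from defining pre-FOG windows, since no steady-gait degradation
  can precede them.

The pre-FOG window length is the task's central free parameter; the analysis
sweeps 2–5 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import Episode

__all__ = [
    "LabelingConfig",
    "LabeledDataset",
    "classify_steps",
    "exclude_gait_initiation",
    "label_steps",
    "class_balance",
]

GAIT, PREFOG, FOG = "gait", "prefog", "fog"


@dataclass(frozen=True)
class LabelingConfig:
    """Task and pre-FOG window configuration.

    ``task`` is ``"detection"`` (gait=0 vs FOG=1) or ``"prediction"``
    (gait=0 vs pre-FOG=1). ``prefog_window_s`` is swept over {2, 3, 4, 5} s
    in the model/window selection stage but may take any positive value.
    """

    prefog_window_s: float = 2.0
    task: str = "prediction"
    exclude_gait_initiation: bool = True

    def __post_init__(self) -> None:
        if self.prefog_window_s <= 0:
            raise ValueError("prefog_window_s must be positive")
        if self.task not in ("detection", "prediction"):
            raise ValueError("task must be 'detection' or 'prediction'")


@dataclass
class LabeledDataset:
    """Feature matrix plus binary labels and bookkeeping for one task."""

    data: pd.DataFrame  # feature matrix + metadata + 'label' column
    task: str
    positive_class: str  # 'fog' or 'prefog'
    excluded_episodes: int = 0
    balance: pd.DataFrame | None = None


def exclude_gait_initiation(
    episodes: list[Episode],
) -> tuple[list[Episode], int]:
    """Drop episodes flagged as occurring during gait initiation.

    Used by the prediction task only; the detection task keeps all episodes.
    Returns the retained episodes and the exclusion count.
    """
    kept = [e for e in episodes if not e.at_gait_initiation]
    return kept, len(episodes) - len(kept)


def classify_steps(
    peak_times_s: np.ndarray,
    episodes: list[Episode],
    prefog_window_s: float,
    prefog_sources: list[Episode] | None = None,
) -> np.ndarray:
    """Three-way step classification by peak-time interval membership.

    ``prefog_sources`` restricts which episodes define pre-FOG windows (used
    to exclude gait-initiation episodes); FOG membership always considers
    every episode, so steps inside an excluded episode stay FOG rather than
    silently becoming gait.
    """
    t = np.asarray(peak_times_s, dtype=float)
    labels = np.full(t.shape, GAIT, dtype=object)
    sources = episodes if prefog_sources is None else prefog_sources
    for e in sources:
        in_window = (t >= e.start_s - prefog_window_s) & (t < e.start_s)
        labels[in_window] = PREFOG
    for e in episodes:
        labels[(t >= e.start_s) & (t <= e.end_s)] = FOG
    return labels


def label_steps(
    features: pd.DataFrame,
    episodes_by_trial: dict[str, list[Episode]],
    config: LabelingConfig,
) -> LabeledDataset:
    """Attach binary labels to a feature table and reduce it to one task.

    ``episodes_by_trial`` maps ``trial_id`` to its annotation list. For the
    prediction task an empty annotation set (hence zero pre-FOG steps) emits
    a warning but still returns the dataset, so callers can surface the
    degenerate case instead of crashing mid-cohort.
    """
    df = features.copy()
    excluded_total = 0
    labels = np.full(len(df), GAIT, dtype=object)
    for trial_id, grp in df.groupby("trial_id"):
        episodes = sorted(
            episodes_by_trial.get(str(trial_id), []), key=lambda e: e.start_s
        )
        sources = episodes
        if config.task == "prediction" and config.exclude_gait_initiation:
            sources, n_excl = exclude_gait_initiation(episodes)
            excluded_total += n_excl
        labels[grp.index.to_numpy()] = classify_steps(
            grp["peak_time_s"].to_numpy(), episodes, config.prefog_window_s, sources
        )
    df["step_class"] = labels
    if config.task == "detection":
        # two classes only: anything outside an episode is gait
        df["label"] = (df["step_class"] == FOG).astype(int)
        positive = FOG
    else:
        df = df[df["step_class"] != FOG].reset_index(drop=True)
        df["label"] = (df["step_class"] == PREFOG).astype(int)
        positive = PREFOG
        if df["label"].sum() == 0:
            warnings.warn(
                "prediction task produced zero pre-FOG steps", stacklevel=2
            )
    ds = LabeledDataset(
        data=df,
        task=config.task,
        positive_class=positive,
        excluded_episodes=excluded_total,
    )
    ds.balance = class_balance(df)
    return ds


def class_balance(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-condition class counts (for cost-tuning context)."""
    return (
        labeled.groupby(["subject_id", "condition", "label"])
        .size()
        .rename("n_steps")
        .reset_index()
    )
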