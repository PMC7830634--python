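"""Synthetic two-shin gait simulator with pre-freeze degradation and episodes.

Patient recordings of freezing of gait (FOG) are not publicly distributable,
so every downstream stage of this package is exercised against simulated
trials that reproduce the *statistical structure* the analysis relies on:

* a quiet sitting prefix, then a large biphasic sit-to-stand transient usable
  for two-device synchronization (each device starts recording at its own
  random offset);
* alternating-leg swing peaks at ~1 Hz per leg — each swing is a raised-cosine
  positive lobe (mid-swing peak) followed by a smaller negative trough;
* progressive pre-FOG degradation confined to a window before each episode
  onset: shrinking peak amplitude, shortening step/stride time, and a growing
  high-frequency component (the spectral shift away from the locomotor band);
* FOG episodes of two phenotypes — low-amplitude trembling at 4–7 Hz, or
  near-zero akinetic freezing;
* per-subject parameter variability and an on/off-therapy knob that scales
  the degradation depth (levodopa partially corrects the pre-FOG pattern, so
  the off state shows a deeper signature).

The generator records its own ground truth (placed swing times, episode
bounds, injected inter-device offset), which the tests use as the oracle for
peak recovery, labeling and parameter-recovery checks. Everything is driven
by a single seeded :class:`numpy.random.Generator`; identical seeds give
bit-identical trials.

The degradation effect sizes are free parameters of the simulator, not claims
about Parkinsonian physiology; the defaults are chosen to be plausible for a
moderate pre-freeze motor breakdown (amplitude roughly halved and step period
shortened by ~30% at onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_io import (
    DEFAULT_SAMPLE_RATE_HZ,
    SETTLE_AFTER_STANDUP_S,
    Episode,
    RawTrace,
    write_annotations,
    write_manifest,
    write_trace_csv,
)

__all__ = [
    "GaitProfile",
    "DegradationProfile",
    "FogEpisodeSpec",
    "CohortConfig",
    "TrialTruth",
    "SyntheticTrial",
    "generate_trial",
    "generate_cohort",
    "write_cohort",
    "scale_degradation",
]


class SyntheticError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class GaitProfile:
    """Morphology of one subject's steady gait.

    cadence_hz
        Step frequency per leg (a full stride cycle per leg), typically
        0.8–1.2 Hz.
    swing_amp
        Peak angular velocity at mid-swing, arbitrary units (the pipeline
        normalizes per trial, so only ratios matter).
    swing_duration_s
        Width of the positive raised-cosine swing lobe.
    trough_amp
        Amplitude of the negative inter-swing lobe (positive number).
    noise_sd
        Additive white-noise standard deviation, same units as swing_amp.
    phase_offset
        Contralateral phase lag as a fraction of the stride cycle (0.5 for
        perfectly alternating legs).
    """

    cadence_hz: float = 1.0
    swing_amp: float = 1.0
    swing_duration_s: float = 0.68
    trough_amp: float = 0.6
    noise_sd: float = 0.03
    phase_offset: float = 0.5

    def __post_init__(self) -> None:
        if self.cadence_hz <= 0:
            raise SyntheticError("cadence_hz must be positive")
        if self.swing_duration_s >= 1.0 / self.cadence_hz:
            raise SyntheticError("swing lobe must be shorter than the stride period")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be non-negative")


@dataclass(frozen=True)
class DegradationProfile:
    """Pre-FOG gait degradation ramped over a window before each onset.

    At a time ``t`` inside ``[onset - window_s, onset)`` the ramp progress is
    ``p = ramp((t - onset + window_s) / window_s)`` in [0, 1]; at onset the
    amplitude is multiplied by ``amp_decay``, the step period by
    ``steptime_shrink``, and a high-frequency component carrying a power
    fraction ``freq_shift`` of the (already decayed) swing is superimposed.
    ``ramp_shape`` is ``"linear"`` (minimal assumption) or ``"quadratic"``
    (degradation accelerating towards onset).
    """

    window_s: float = 2.0
    amp_decay: float = 0.5
    steptime_shrink: float = 0.7
    freq_shift: float = 0.3
    ramp_shape: str = "linear"
    shift_hz: float = 6.0

    def __post_init__(self) -> None:
        if not (0 < self.amp_decay <= 1):
            raise SyntheticError("amp_decay must be in (0, 1]")
        if not (0 < self.steptime_shrink <= 1):
            raise SyntheticError("steptime_shrink must be in (0, 1]")
        if self.window_s <= 0:
            raise SyntheticError("window_s must be positive")
        if self.ramp_shape not in ("linear", "quadratic"):
            raise SyntheticError("ramp_shape must be 'linear' or 'quadratic'")

    def ramp(self, p: float) -> float:
        p = min(max(p, 0.0), 1.0)
        return p * p if self.ramp_shape == "quadratic" else p


#: a degradation profile with no effect at all (clean gait)
NO_DEGRADATION = DegradationProfile(
    window_s=1e-9, amp_decay=1.0, steptime_shrink=1.0, freq_shift=0.0
)


def scale_degradation(base: DegradationProfile, depth: float) -> DegradationProfile:
    """Scale the *depth* of a degradation profile by ``depth``.

    Depth acts on the deviations from the identity: ``amp_decay`` of 0.5 at
    depth 1.5 becomes 0.25 (a deeper drop). Factors are clipped to stay in
    (0, 1]; the high-frequency power fraction is scaled directly.
    """
    clip = lambda v: float(min(1.0, max(0.05, v)))
    return replace(
        base,
        amp_decay=clip(1.0 - depth * (1.0 - base.amp_decay)),
        steptime_shrink=clip(1.0 - depth * (1.0 - base.steptime_shrink)),
        freq_shift=float(min(0.95, depth * base.freq_shift)),
    )


@dataclass(frozen=True)
class FogEpisodeSpec:
    """One simulated FOG episode.

    ``phenotype`` is ``"trembling"`` (leg oscillation at ``tremble_hz``,
    amplitude ``tremble_amp`` x swing amplitude) or ``"akinetic"``
    (near-zero signal, noise only).
    """

    onset_s: float
    duration_s: float
    phenotype: str = "trembling"
    tremble_hz: float = 5.0
    tremble_amp: float = 0.25
    at_gait_initiation: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise SyntheticError("episode duration must be positive")
        if self.phenotype not in ("trembling", "akinetic"):
            raise SyntheticError("phenotype must be 'trembling' or 'akinetic'")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class TrialTruth:
    """Generator-side ground truth for one trial (trial clock = left device)."""

    step_times: dict[str, np.ndarray]
    episodes: list[FogEpisodeSpec]
    sync_offset_s: float
    gait_start_s: float
    standup_time_s: float
    prefog_windows: list[tuple[float, float]]

    def n_steps(self, leg: str | None = None) -> int:
        if leg is not None:
            return int(self.step_times[leg].size)
        return sum(int(v.size) for v in self.step_times.values())


@dataclass
class SyntheticTrial:
    """Raw two-device recordings plus ground truth and metadata."""

    left_raw: RawTrace
    right_raw: RawTrace
    truth: TrialTruth
    subject_id: str = "s00"
    condition: str = "on"
    trial_id: str = "t0"

    @property
    def annotations(self) -> list[Episode]:
        return [
            Episode(e.onset_s, e.end_s, e.at_gait_initiation)
            for e in self.truth.episodes
        ]


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration for a simulated on/off-therapy cohort.

    Mirrors the acquisition protocol the pipeline targets: each subject
    performs TUG trials alternately on and off dopaminergic therapy, with the
    off state showing a deeper pre-freeze degradation
    (``condition_depth['off'] > condition_depth['on']``).
    """

    n_subjects: int = 10
    trials_per_subject: int = 2
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    trial_duration_s: float = 50.0
    episodes_per_trial: int = 3
    degradation: DegradationProfile = field(default_factory=DegradationProfile)
    condition_depth: tuple[tuple[str, float], ...] = (("on", 1.0), ("off", 1.5))
    sync_offset_range_s: tuple[float, float] = (0.1, 1.0)
    noise_sd: float = 0.03
    akinetic_prob: float = 0.3
    gait_initiation_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise SyntheticError("need at least 2 subjects (LOSO requires it)")
        if self.sample_rate_hz <= 0:
            raise SyntheticError("sample_rate_hz must be positive")


# ---------------------------------------------------------------------------
# Single-trial synthesis
# ---------------------------------------------------------------------------

#: quiet sitting time before the stand-up transient (s)
SIT_S = 2.0
#: duration of the biphasic stand-up pulse (s)
STANDUP_DURATION_S = 0.8


def _add_lobe(x: np.ndarray, fs: float, center_s: float, dur_s: float, amp: float) -> None:
    """Add a raised-cosine lobe ``amp * 0.5 * (1 + cos)`` in place."""
    lo = int(np.ceil((center_s - dur_s / 2) * fs))
    hi = int(np.floor((center_s + dur_s / 2) * fs))
    lo, hi = max(lo, 0), min(hi, x.size - 1)
    if hi < lo:
        return
    t = np.arange(lo, hi + 1) / fs
    x[lo : hi + 1] += amp * 0.5 * (1.0 + np.cos(2.0 * np.pi * (t - center_s) / dur_s))


def _degradation_progress(
    t: float, episodes: list[FogEpisodeSpec], deg: DegradationProfile
) -> float:
    """Ramp progress in [0, 1] at time ``t``; 0 outside every pre-onset window."""
    p = 0.0
    for e in episodes:
        if e.onset_s - deg.window_s <= t < e.onset_s:
            p = max(p, deg.ramp((t - (e.onset_s - deg.window_s)) / deg.window_s))
    return p


def generate_trial(
    profile: GaitProfile,
    episodes: list[FogEpisodeSpec] | None = None,
    degradation: DegradationProfile = NO_DEGRADATION,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    duration_s: float = 50.0,
    seed: int | np.random.Generator = 0,
    sync_offset_s: float = 0.0,
    subject_id: str = "s00",
    condition: str = "on",
    trial_id: str = "t0",
) -> SyntheticTrial:
    """Synthesize one two-shin trial.

    The left device defines the trial clock (offset 0); the right device
    starts ``sync_offset_s`` later, so its recording drops the first
    ``sync_offset_s`` seconds of the common timeline — recovering that offset
    is the synchronization module's job.

    Raises on overlapping episodes or an episode extending beyond the trial.
    """
    episodes = sorted(episodes or [], key=lambda e: e.onset_s)
    for a, b in zip(episodes, episodes[1:]):
        if b.onset_s < a.end_s:
            raise SyntheticError(
                f"episodes overlap: onset {b.onset_s} before end {a.end_s}"
            )
    for e in episodes:
        if e.end_s > duration_s:
            raise SyntheticError(f"episode ending at {e.end_s}s exceeds trial end")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    fs = sample_rate_hz
    n = int(round(duration_s * fs))
    standup_t = SIT_S + STANDUP_DURATION_S / 2
    walk_start = SIT_S + STANDUP_DURATION_S + SETTLE_AFTER_STANDUP_S
    if duration_s <= walk_start:
        raise SyntheticError("duration too short for sit + stand-up + settling")
    t_axis = np.arange(n) / fs
    period0 = 1.0 / profile.cadence_hz

    signals: dict[str, np.ndarray] = {}
    step_times: dict[str, np.ndarray] = {}
    for leg in ("left", "right"):
        x = np.zeros(n)
        # biphasic stand-up pulse, 2x the swing amplitude (same movement seen
        # by both devices at the same trial time)
        seg = (t_axis >= SIT_S) & (t_axis < SIT_S + STANDUP_DURATION_S)
        x[seg] += (
            2.0
            * profile.swing_amp
            * np.sin(2.0 * np.pi * (t_axis[seg] - SIT_S) / STANDUP_DURATION_S)
        )
        # alternating gait: place swings sequentially, skipping episodes and
        # applying the pre-onset degradation ramp
        lag = 0.0 if leg == "left" else profile.phase_offset * period0
        tp = walk_start + period0 / 2 + lag
        placed: list[float] = []
        margin = profile.swing_duration_s / 2 + 1.0 / fs
        while tp < duration_s - margin:
            inside = next((e for e in episodes if e.onset_s <= tp <= e.end_s), None)
            if inside is not None:
                # resume after the episode, preserving the contralateral lag
                tp = inside.end_s + period0 / 2 + lag
                continue
            p = _degradation_progress(tp, episodes, degradation)
            amp_mult = 1.0 + (degradation.amp_decay - 1.0) * p
            per_mult = 1.0 + (degradation.steptime_shrink - 1.0) * p
            amp = profile.swing_amp * amp_mult
            sdur = profile.swing_duration_s * per_mult
            period = period0 * per_mult
            _add_lobe(x, fs, tp, sdur, amp)
            # growing high-frequency component inside the swing lobe
            hf_frac = degradation.freq_shift * p
            if hf_frac > 0:
                lo = int(np.ceil((tp - sdur / 2) * fs))
                hi = int(np.floor((tp + sdur / 2) * fs))
                lo, hi = max(lo, 0), min(hi, n - 1)
                if hi > lo:
                    tt = t_axis[lo : hi + 1]
                    env = 0.5 * (1.0 + np.cos(2.0 * np.pi * (tt - tp) / sdur))
                    x[lo : hi + 1] += (
                        amp
                        * np.sqrt(hf_frac)
                        * env
                        * np.sin(2.0 * np.pi * degradation.shift_hz * (tt - tp))
                    )
            # inter-swing negative trough halfway to the next same-leg swing
            _add_lobe(x, fs, tp + period / 2, sdur, -profile.trough_amp * amp_mult)
            placed.append(tp)
            tp += period
        # FOG episodes: trembling oscillation or akinetic near-silence
        for e in episodes:
            if e.phenotype == "trembling":
                seg = (t_axis >= e.onset_s) & (t_axis <= e.end_s)
                tt = t_axis[seg]
                env = np.clip((tt - e.onset_s) / 0.2, 0, 1) * np.clip(
                    (e.end_s - tt) / 0.2, 0, 1
                )
                phase = 0.0 if leg == "left" else np.pi / 2
                x[seg] += (
                    e.tremble_amp
                    * profile.swing_amp
                    * env
                    * np.sin(2.0 * np.pi * e.tremble_hz * (tt - e.onset_s) + phase)
                )
        if profile.noise_sd > 0:
            x += rng.normal(0.0, profile.noise_sd, n)
        signals[leg] = x
        step_times[leg] = np.asarray(placed)

    # device recordings: the right device misses the first sync_offset_s
    if sync_offset_s >= standup_t:
        raise SyntheticError("sync offset must be smaller than the stand-up time")
    drop = int(round(sync_offset_s * fs))
    left_raw = RawTrace(signals["left"], fs, "left")
    right_raw = RawTrace(signals["right"][drop:], fs, "right")
    truth = TrialTruth(
        step_times=step_times,
        episodes=episodes,
        sync_offset_s=drop / fs,
        gait_start_s=walk_start,
        standup_time_s=standup_t,
        prefog_windows=[
            (e.onset_s - degradation.window_s, e.onset_s) for e in episodes
        ],
    )
    return SyntheticTrial(
        left_raw=left_raw,
        right_raw=right_raw,
        truth=truth,
        subject_id=subject_id,
        condition=condition,
        trial_id=trial_id,
    )


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------


def _draw_profile(rng: np.random.Generator, config: CohortConfig) -> GaitProfile:
    # swing lobe spans ~2/3 of the stride cycle: the shank rotation this
    # sensor records is smooth and nearly sinusoidal, which keeps the
    # locomotor power of steady gait below 2 Hz
    cadence = float(rng.uniform(0.85, 1.15))
    swing_amp = float(rng.uniform(0.8, 1.2))
    return GaitProfile(
        cadence_hz=cadence,
        swing_amp=swing_amp,
        swing_duration_s=float(rng.uniform(0.62, 0.72)) / cadence,
        trough_amp=float(rng.uniform(0.5, 0.7)) * swing_amp,
        noise_sd=config.noise_sd,
        phase_offset=float(rng.uniform(0.45, 0.55)),
    )


def _draw_episodes(
    rng: np.random.Generator, config: CohortConfig, walk_start: float
) -> list[FogEpisodeSpec]:
    """Place non-overlapping episodes in equal blocks of the walking span."""
    k = config.episodes_per_trial
    lo = walk_start + 4.0
    hi = config.trial_duration_s - 7.0
    if k == 0 or hi <= lo:
        return []
    block = (hi - lo) / k
    out: list[FogEpisodeSpec] = []
    prev_end = -np.inf
    for i in range(k):
        onset = lo + i * block + float(rng.uniform(0.2, 0.45)) * block
        onset = max(onset, prev_end + config.degradation.window_s + 1.5)
        dur = float(rng.uniform(3.0, 5.5))
        if onset + dur > config.trial_duration_s - 1.0:
            break
        phen = "akinetic" if rng.random() < config.akinetic_prob else "trembling"
        out.append(
            FogEpisodeSpec(
                onset_s=onset,
                duration_s=dur,
                phenotype=phen,
                tremble_hz=float(rng.uniform(4.0, 7.0)),
                tremble_amp=float(rng.uniform(0.22, 0.3)),
                at_gait_initiation=(
                    i == 0 and rng.random() < config.gait_initiation_prob
                ),
            )
        )
        prev_end = out[-1].end_s
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SyntheticTrial], pd.DataFrame]:
    """Simulate a full cohort; returns the trials and a manifest table.

    Each subject keeps one gait profile across their trials; trial *i* of a
    subject is recorded in condition ``on`` / ``off`` alternately (the
    within-subject on/off design). The manifest lists subject, condition,
    trial id and episode count and is identical across runs for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    depth = dict(config.condition_depth)
    trials: list[SyntheticTrial] = []
    rows = []
    conditions = list(depth)
    for s in range(config.n_subjects):
        subject = f"s{s:02d}"
        profile = _draw_profile(rng, config)
        for t in range(config.trials_per_subject):
            condition = conditions[t % len(conditions)]
            deg = scale_degradation(config.degradation, depth[condition])
            walk_start = SIT_S + STANDUP_DURATION_S + SETTLE_AFTER_STANDUP_S
            episodes = _draw_episodes(rng, config, walk_start)
            offset = float(rng.uniform(*config.sync_offset_range_s))
            trial = generate_trial(
                profile,
                episodes,
                deg,
                sample_rate_hz=config.sample_rate_hz,
                duration_s=config.trial_duration_s,
                seed=rng,
                sync_offset_s=offset,
                subject_id=subject,
                condition=condition,
                trial_id=f"{subject}_t{t}",
            )
            trials.append(trial)
            rows.append(
                {
                    "subject_id": subject,
                    "condition": condition,
                    "trial_id": trial.trial_id,
                    "n_episodes": len(episodes),
                    "n_steps_truth": trial.truth.n_steps(),
                    "sync_offset_s": trial.truth.sync_offset_s,
                }
            )
    return trials, pd.DataFrame(rows)


def write_cohort(
    trials: list[SyntheticTrial],
    manifest: pd.DataFrame,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write trials as per-leg CSVs + annotation JSONs and a manifest CSV.

    Returns the manifest augmented with file paths (as written to disk).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    lpaths, rpaths, apaths = [], [], []
    for trial in trials:
        stem = trial.trial_id
        lp, rp, ap = (
            out_dir / f"{stem}_left.csv",
            out_dir / f"{stem}_right.csv",
            out_dir / f"{stem}_annotations.json",
        )
        write_trace_csv(lp, trial.left_raw)
        write_trace_csv(rp, trial.right_raw)
        write_annotations(ap, trial.annotations)
        lpaths.append(lp.name)
        rpaths.append(rp.name)
        apaths.append(ap.name)
    manifest["left_file"] = lpaths
    manifest["right_file"] = rpaths
    manifest["annotation_file"] = apaths
    write_manifest(out_dir / "manifest.csv", manifest)
    return manifest
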