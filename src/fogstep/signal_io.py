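"""Trial recording I/O, amplitude normalization and two-device synchronization.

A trial is one timed-up-and-go (TUG) test recorded by two shank-mounted
gyroscopes, one per leg, sampled at a fixed rate (60 Hz by default). Only the
x-axis angular velocity ``omega_x`` is used: with the sensor strapped to the
shin its x axis lies in the frontal plane, so ``omega_x`` captures the
principal sagittal rotation of the leg during walking.

The two devices start recording independently while the subject is still
seated, so their clocks are offset by an unknown delay. The sit-to-stand
transition produces one large transient in both traces; superimposing those
stand-up peaks recovers the inter-device delay and puts both legs on a common
trial clock.

Normalization removes the per-trace mean and divides by the per-trace range::

    w' = (w - mean(w)) / (max(w) - min(w))

yielding zero-mean, unit-range signals so that downstream peak thresholds are
relative and subject-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: default sampling rate of the acquisition hardware (Hz)
DEFAULT_SAMPLE_RATE_HZ = 60.0

#: window (s) from the start of a recording searched for the stand-up peak
STANDUP_SEARCH_WINDOW_S = 10.0

#: the stand-up peak must exceed this multiple of the largest |amplitude|
#: found after the search window (the transient dwarfs any swing)
STANDUP_MIN_PROMINENCE = 1.3

#: settling time (s) after the stand-up peak excluded from step detection;
#: the subject is still arranging their posture and the data are not gait
SETTLE_AFTER_STANDUP_S = 3.5

#: a gap in the time column longer than this many sample periods is logged
GAP_FACTOR = 1.5

#: decimal format used when writing angular-velocity samples
CSV_FLOAT_FORMAT = "%.10g"


class SignalIOError(ValueError):
    """Raised for malformed trial files or signals violating preconditions."""


@dataclass(frozen=True)
class Episode:
    """One annotated freezing-of-gait episode, in trial-clock seconds."""

    start_s: float
    end_s: float
    at_gait_initiation: bool = False

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise SignalIOError(
                f"episode end {self.end_s} not after start {self.start_s}"
            )

    def contains(self, t: float) -> bool:
        return self.start_s <= t <= self.end_s


@dataclass
class RawTrace:
    """Angular velocity samples from one device, in its own clock.

    ``t0`` is the trial-clock time of sample 0; it is 0 for a freshly read
    device file and becomes meaningful after synchronization.
    """

    samples: np.ndarray
    sample_rate_hz: float
    leg: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise SignalIOError("trace must be a non-empty 1-D sequence")
        if self.sample_rate_hz <= 0:
            raise SignalIOError("sample_rate_hz must be positive")
        if self.leg not in ("left", "right"):
            raise SignalIOError(f"leg must be 'left' or 'right', got {self.leg!r}")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return (self.samples.size - 1) / self.sample_rate_hz


@dataclass
class NormalizedTrace(RawTrace):
    """A zero-mean, unit-range trace (dimensionless)."""


@dataclass
class TrialRecording:
    """Two synchronized, normalized leg traces plus annotations and metadata."""

    left: NormalizedTrace
    right: NormalizedTrace
    episodes: list[Episode] = field(default_factory=list)
    subject_id: str = ""
    condition: str = "on"
    trial_id: str = ""
    gait_start_s: float = 0.0
    sync_delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.left.sample_rate_hz != self.right.sample_rate_hz:
            raise SignalIOError("both legs must share one sample rate")
        eps = sorted(self.episodes, key=lambda e: e.start_s)
        for a, b in zip(eps, eps[1:]):
            if b.start_s < a.end_s:
                raise SignalIOError(
                    f"episodes overlap: [{a.start_s},{a.end_s}] and "
                    f"[{b.start_s},{b.end_s}]"
                )
        self.episodes = eps

    @property
    def sample_rate_hz(self) -> float:
        return self.left.sample_rate_hz

    def trace(self, leg: str) -> NormalizedTrace:
        return self.left if leg == "left" else self.right


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_signal(trace: RawTrace) -> NormalizedTrace:
    """Mean-remove and range-scale a trace to zero mean and unit range.

    Raises
    ------
    SignalIOError
        If the signal is constant (zero range), for which the map is
        undefined; this is never silently turned into NaN.
    """
    x = trace.samples
    rng = float(np.max(x) - np.min(x))
    if rng == 0.0:
        raise SignalIOError("cannot normalize a constant (zero-range) signal")
    y = (x - float(np.mean(x))) / rng
    return NormalizedTrace(
        samples=y, sample_rate_hz=trace.sample_rate_hz, leg=trace.leg, t0=trace.t0
    )


# ---------------------------------------------------------------------------
# Two-device synchronization
# ---------------------------------------------------------------------------


def find_standup_peak(
    trace: RawTrace,
    search_window_s: float = STANDUP_SEARCH_WINDOW_S,
    min_prominence: float = STANDUP_MIN_PROMINENCE,
) -> int:
    """Locate the sit-to-stand transient as the early-window |amplitude| maximum.

    The stand-up movement is by far the largest rotation in the first seconds
    of a recording, so the global maximum of ``|x|`` within the search window
    identifies it. To reject traces that contain no such transient, the peak
    must exceed ``min_prominence`` times the largest absolute amplitude seen
    *after* the search window: the transient is roughly twice any swing,
    whereas a recording that starts mid-walk (or pure noise) shows no such
    early dominance.
    """
    x = trace.samples
    n_win = min(x.size, int(round(search_window_s * trace.sample_rate_hz)))
    window = np.abs(x[:n_win])
    idx = int(np.argmax(window))
    rest = np.abs(x[n_win:])
    floor = float(rest.max()) if rest.size else 0.0
    if floor == 0.0:
        floor = float(np.median(window))
        if floor == 0.0:
            floor = np.finfo(float).tiny
    if window[idx] < min_prominence * floor:
        raise SignalIOError(
            "no detectable stand-up peak: early-window maximum "
            f"{window[idx]:.3g} does not dominate the rest of the trace"
        )
    return idx


def synchronize_legs(
    left: NormalizedTrace,
    right: NormalizedTrace,
    search_window_s: float = STANDUP_SEARCH_WINDOW_S,
    min_prominence: float = STANDUP_MIN_PROMINENCE,
) -> tuple[NormalizedTrace, NormalizedTrace, float]:
    """Align two leg traces by superimposing their stand-up peaks.

    Returns the aligned pair (trimmed to a common grid, with ``t0`` set to the
    trial-clock time of their first retained sample) and the estimated delay
    of the right device's start relative to the left's, in seconds. Calling
    with the arguments swapped negates the returned delay.
    """
    i_l = find_standup_peak(left, search_window_s, min_prominence)
    i_r = find_standup_peak(right, search_window_s, min_prominence)
    fs = left.sample_rate_hz
    d = i_l - i_r  # >0: right device started later by d samples
    delay_s = d / fs
    lx, rx = left.samples, right.samples
    if d >= 0:
        lx = lx[d:]
        t0 = d / fs
    else:
        rx = rx[-d:]
        t0 = 0.0
        # the left device started later: the left clock *is* the trial clock,
        # so its own samples already sit at t0 = 0
        lx = lx
    n = min(lx.size, rx.size)
    left_al = NormalizedTrace(lx[:n], fs, "left", t0=t0)
    right_al = NormalizedTrace(rx[:n], fs, "right", t0=t0)
    return left_al, right_al, delay_s


def gait_start_time(standup_peak_s: float, settle_s: float = SETTLE_AFTER_STANDUP_S) -> float:
    """Trial-clock time from which samples count as gait (peak + settling)."""
    return standup_peak_s + settle_s


# ---------------------------------------------------------------------------
# CSV / JSON round trip
# ---------------------------------------------------------------------------


def read_trace_csv(
    path: str | Path,
    leg: str,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> tuple[RawTrace, list[dict]]:
    """Read one device file with columns ``time_s, omega_x``.

    Single-file trials with ``omega_x_left`` / ``omega_x_right`` columns are
    also accepted; ``leg`` selects the column. Gaps in the time column wider
    than 1.5 sample periods are reported in the returned gap log (the trace is
    still loaded as-is).
    """
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"trial file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise SignalIOError(f"empty trial file: {path}")
    if "time_s" not in df.columns:
        raise SignalIOError(f"{path}: missing required column 'time_s'")
    col = "omega_x"
    if col not in df.columns:
        col = f"omega_x_{leg}"
        if col not in df.columns:
            raise SignalIOError(
                f"{path}: missing required column 'omega_x' (or '{col}')"
            )
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise SignalIOError(f"{path}: time column is not strictly increasing")
    period = 1.0 / sample_rate_hz
    gaps = []
    dt = np.diff(t)
    for i in np.nonzero(dt > GAP_FACTOR * period)[0]:
        gaps.append(
            {
                "after_time_s": float(t[i]),
                "gap_s": float(dt[i]),
                "missing_samples": int(round(dt[i] / period)) - 1,
            }
        )
    trace = RawTrace(df[col].to_numpy(dtype=float), sample_rate_hz, leg)
    return trace, gaps


def write_trace_csv(path: str | Path, trace: RawTrace) -> None:
    """Write one device file (columns ``time_s, omega_x``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(trace.samples.size) / trace.sample_rate_hz
    pd.DataFrame({"time_s": t, "omega_x": trace.samples}).to_csv(
        path, index=False, float_format=CSV_FLOAT_FORMAT
    )


def read_annotations(path: str | Path) -> list[Episode]:
    """Read the sidecar JSON episode annotation file."""
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Episode(
            start_s=float(e["start_s"]),
            end_s=float(e["end_s"]),
            at_gait_initiation=bool(e.get("at_gait_initiation", False)),
        )
        for e in payload.get("episodes", [])
    ]


def write_annotations(path: str | Path, episodes: list[Episode]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "episodes": [
            {
                "start_s": e.start_s,
                "end_s": e.end_s,
                "at_gait_initiation": e.at_gait_initiation,
            }
            for e in episodes
        ]
    }
    path.write_text(json.dumps(payload, indent=1))


def read_trial_csv(
    left_path: str | Path,
    right_path: str | Path,
    annotation_path: str | Path | None = None,
    subject_id: str = "",
    condition: str = "on",
    trial_id: str = "",
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    synchronize: bool = True,
) -> tuple[TrialRecording, list[dict]]:
    """Load, normalize and synchronize a two-device trial.

    Returns the assembled :class:`TrialRecording` and the merged gap log.
    Annotation times are interpreted in the left device's clock (the reference
    device; its recording defines the trial clock).
    """
    left_raw, gaps_l = read_trace_csv(left_path, "left", sample_rate_hz)
    right_raw, gaps_r = read_trace_csv(right_path, "right", sample_rate_hz)
    for g in gaps_l:
        g["leg"] = "left"
    for g in gaps_r:
        g["leg"] = "right"
    left_n = normalize_signal(left_raw)
    right_n = normalize_signal(right_raw)
    if synchronize:
        left_al, right_al, delay = synchronize_legs(left_n, right_n)
        standup_s = left_al.t0 + find_standup_peak(left_al) / sample_rate_hz
    else:
        left_al, right_al, delay = left_n, right_n, 0.0
        standup_s = 0.0
    episodes = read_annotations(annotation_path) if annotation_path else []
    rec = TrialRecording(
        left=left_al,
        right=right_al,
        episodes=episodes,
        subject_id=subject_id,
        condition=condition,
        trial_id=trial_id,
        gait_start_s=gait_start_time(standup_s) if synchronize else 0.0,
        sync_delay_s=delay,
    )
    return rec, gaps_l + gaps_r


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (subject, condition, trial and file paths)."""
    return pd.read_csv(path, dtype={"subject_id": str, "trial_id": str})


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)
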