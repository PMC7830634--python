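"""Step-to-step segmentation of normalized shank angular-velocity traces.

The instant of maximal shank angular velocity marks mid-swing, so signal
peaks anchor the step segmentation. Peaks are accepted when their amplitude
is at least 20% of the largest peak of the same leg in the same trial and
they are at least 350 ms apart (the amplitude threshold keeps anomalous
pre-freeze steps; the temporal one suppresses duplicate detections within a
single swing).

Each retained peak then yields two data frames:

* **Type I** — the samples between the previous peak (exclusive) and the
  current peak (inclusive); consecutive Type I slices tile the inter-peak
  region exactly. These carry the frequency-domain content of a stride.
* **Type II** — the positive lobe containing the current peak, found by
  walking outward from the peak to the nearest zero crossings. These carry
  range-of-motion and movement-intensity information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .signal_io import NormalizedTrace

__all__ = ["PeakSet", "StepSegment", "detect_peaks", "segment_steps"]

MIN_HEIGHT_FRAC = 0.2
MIN_SEPARATION_S = 0.35


class SegmentationError(ValueError):
    pass


@dataclass
class PeakSet:
    """Accepted mid-swing peaks of one leg, in trace sample indices."""

    peak_indices: np.ndarray
    peak_times_s: np.ndarray
    peak_heights: np.ndarray
    leg: str = ""

    def __len__(self) -> int:
        return int(self.peak_indices.size)


@dataclass
class StepSegment:
    """One detected step: the anchor peak plus its Type I / Type II slices.

    Only peaks with a same-leg predecessor yield a segment, so ``type1`` is
    always present. ``prev_contralateral_peak_time_s`` and ``prev_type1``
    (the previous stride's Type I slice, the DTW reference) are ``None`` when
    the corresponding earlier peak or slice does not exist; the feature stage
    applies the missing-data policy to those.
    """

    leg: str
    peak_index: int
    peak_time_s: float
    peak_height: float
    type1: np.ndarray
    type2: np.ndarray
    prev_peak_time_s: float
    prev_contralateral_peak_time_s: float | None = None
    prev_type1: np.ndarray | None = None


def _candidate_peaks(x: np.ndarray) -> np.ndarray:
    """Local maxima; a plateau contributes its first sample."""
    # plateau_size=(1, None) makes find_peaks report plateau edges; the left
    # edge is the first sample of the plateau
    _, props = find_peaks(x, plateau_size=(1, None))
    return props["left_edges"].astype(int)


def detect_peaks(
    trace: NormalizedTrace,
    min_height_frac: float = MIN_HEIGHT_FRAC,
    min_separation_s: float = MIN_SEPARATION_S,
    start_time_s: float | None = None,
) -> PeakSet:
    """Detect mid-swing peaks of one leg.

    Candidates before ``start_time_s`` (the non-gait sitting/stand-up prefix)
    are excluded before the relative amplitude threshold is applied, so the
    stand-up transient never inflates the reference maximum. When two
    candidates violate the separation constraint the higher one is kept
    (ties go to the earlier); enforcement is greedy by descending height,
    which is deterministic.
    """
    x = trace.samples
    if x.size == 0:
        raise SegmentationError("empty trace")
    cand = _candidate_peaks(x)
    if start_time_s is not None:
        first_idx = int(np.ceil((start_time_s - trace.t0) * trace.sample_rate_hz))
        cand = cand[cand >= first_idx]
    if cand.size == 0:
        return PeakSet(np.array([], int), np.array([]), np.array([]), trace.leg)
    heights = x[cand]
    ref = float(np.max(heights))
    keep = heights >= min_height_frac * ref
    cand, heights = cand[keep], heights[keep]
    # greedy separation: highest first, earlier index wins ties
    order = np.lexsort((cand, -heights))
    min_sep = min_separation_s * trace.sample_rate_hz
    selected: list[int] = []
    for i in order:
        idx = int(cand[i])
        if all(abs(idx - j) >= min_sep for j in selected):
            selected.append(idx)
    sel = np.sort(np.asarray(selected, dtype=int))
    return PeakSet(
        peak_indices=sel,
        peak_times_s=trace.t0 + sel / trace.sample_rate_hz,
        peak_heights=x[sel],
        leg=trace.leg,
    )


def _positive_lobe(x: np.ndarray, peak: int) -> np.ndarray:
    """Walk outward from ``peak`` to the nearest zero crossings (inclusive).

    Returns the contiguous slice of strictly positive samples containing the
    peak, extended by one boundary sample on each side (the crossing sample),
    clamped at the trace ends.
    """
    lo = peak
    while lo > 0 and x[lo - 1] > 0:
        lo -= 1
    hi = peak
    while hi < x.size - 1 and x[hi + 1] > 0:
        hi += 1
    lo = max(lo - 1, 0)
    hi = min(hi + 1, x.size - 1)
    return x[lo : hi + 1]


def segment_steps(
    trace: NormalizedTrace,
    peaks: PeakSet,
    contralateral_peaks: PeakSet | None = None,
) -> list[StepSegment]:
    """Cut one leg's trace into step segments.

    One segment per peak that has a same-leg predecessor (the first peak of
    a leg anchors no Type I slice and yields none); with ``n`` peaks the
    result has ``n - 1`` segments. Contralateral peak times must already be
    on the common (synchronized) trial clock.
    """
    idx = peaks.peak_indices
    if np.any(np.diff(idx) <= 0):
        raise SegmentationError("peak indices must be strictly increasing")
    if idx.size and (idx[0] < 0 or idx[-1] >= trace.samples.size):
        raise SegmentationError("peak index out of trace bounds")
    contra_times = (
        contralateral_peaks.peak_times_s
        if contralateral_peaks is not None
        else np.array([])
    )
    x = trace.samples
    segments: list[StepSegment] = []
    prev_type1: np.ndarray | None = None
    for k in range(1, idx.size):
        i = int(idx[k])
        type1 = x[idx[k - 1] + 1 : i + 1]
        earlier = contra_times[contra_times < peaks.peak_times_s[k]]
        segments.append(
            StepSegment(
                leg=trace.leg,
                peak_index=i,
                peak_time_s=float(peaks.peak_times_s[k]),
                peak_height=float(x[i]),
                type1=type1,
                type2=_positive_lobe(x, i),
                prev_peak_time_s=float(peaks.peak_times_s[k - 1]),
                prev_contralateral_peak_time_s=(
                    float(earlier[-1]) if earlier.size else None
                ),
                prev_type1=prev_type1,
            )
        )
        prev_type1 = type1
    return segments
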