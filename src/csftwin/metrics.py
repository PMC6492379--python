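"""Validation metrics for spinal CSF flow and ICP pulse waveforms.

Flow metrics follow the cardiac-gated cervical-flow conventions: caudal flow
positive, stroke volume as the integral of the caudal lobe of the cycle-mean
flow, and phases expressed in percent of the cardiac cycle anchored at the
caudal-flow maximum (0% = 100%).  Pressure metrics follow ICP pulse-waveform
practice: cycles split minimum-to-minimum, the mean wave amplitude (MWA) is
the height of the first pulse peak above the cycle-start minimum, and P2:P1
is the height ratio of the second to the first peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import CannotSplitError, InvalidParameterError
from .waveforms import SampledWaveform

#: Resampled points per cycle used for envelope statistics.
ENVELOPE_SAMPLES = 256

#: Smoothing window for P1/P2 peak detection, as a fraction of the cycle.
PEAK_SMOOTHING_FRACTION = 0.05


@dataclass(frozen=True)
class FlowMetrics:
    """Summary statistics of a (cycle-mean) spinal flow waveform."""

    sv: float  # ml per cardiac cycle, caudal lobe of the cycle-mean flow
    max_caudal: float  # ml/min
    max_cranial: float  # ml/min, reported negative
    phase_cranial_max: float  # percent of cycle, caudal max anchored at 0
    envelope: Optional[dict[str, np.ndarray]] = field(default=None, compare=False)


@dataclass(frozen=True)
class PulseMetrics:
    """Summary statistics of an ICP recording split into cycles."""

    mean_icp: float
    max_icp: float
    min_icp: float
    mwa: float  # mmHg; nan when no pulse peak is detected
    p2_to_p1: float  # dimensionless; nan when fewer than two peaks
    extrema_spread: float  # largest cycle-to-cycle deviation of max/min


def stroke_volume(wf: SampledWaveform) -> float:
    """Caudal-lobe volume of one cycle, ml (trapezoidal, ml/min -> ml)."""
    return wf.positive_lobe_volume()


def flow_extrema(wf: SampledWaveform) -> tuple[float, float]:
    """(max caudal, max cranial) flow in ml/min; the cranial value is <= 0
    for any physiologic bidirectional cycle."""
    return float(wf.values.max()), float(wf.values.min())


def phase_of_cranial_max(wf: SampledWaveform) -> float:
    """Location of the cranial-directed maximum, percent of the cycle.

    The cycle is circularly re-anchored so the caudal (global) maximum sits at
    0%; the returned value is the position of the global minimum.  Ties break
    to the earliest sample.  A flat waveform has no defined phase -> nan.
    """
    vals = wf.values
    if np.ptp(vals) == 0:
        return math.nan
    rolled = np.roll(vals, -int(np.argmax(vals)))
    return float(np.argmin(rolled)) / vals.size * 100.0


def cycle_split(
    time: np.ndarray,
    values: np.ndarray,
    markers: Optional[np.ndarray] = None,
    period_hint: Optional[float] = None,
    n_resample: int = ENVELOPE_SAMPLES,
) -> list[np.ndarray]:
    """Split a multi-cycle series into per-cycle segments on a 0-100% grid.

    With ``markers`` (sample indices of cycle starts, e.g. from a simulation)
    the split is exact.  Without markers the series is treated as an ICP
    recording and split minimum-to-minimum: local minima are detected with a
    minimum separation of 70% of ``period_hint`` (required in that case).
    Each segment is linearly resampled to ``n_resample`` points.
    """
    time = np.asarray(time, float)
    values = np.asarray(values, float)
    if markers is None:
        if period_hint is None:
            raise InvalidParameterError("period_hint required for minimum-to-minimum split")
        dt = float(time[1] - time[0])
        distance = max(1, int(0.7 * period_hint / dt))
        minima, _ = find_peaks(-values, distance=distance)
        if minima.size < 2:
            raise CannotSplitError("fewer than two cycle minima detected")
        markers = minima
    else:
        markers = np.asarray(markers, int)
        if markers.size < 2:
            raise CannotSplitError("need at least two cycle marks")
    segments = []
    grid = np.linspace(0.0, 1.0, n_resample)
    for a, b in zip(markers[:-1], markers[1:]):
        seg_t = (time[a : b + 1] - time[a]) / (time[b] - time[a])
        segments.append(np.interp(grid, seg_t, values[a : b + 1]))
    return segments


def _pulse_peaks(mean_segment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pulse peaks of the cycle-mean curve (indices, heights above the
    cycle-start minimum).

    Peaks are located on a moving-average-smoothed copy (window 5% of the
    cycle) to suppress ripple, but heights are read off the raw cycle-mean
    curve at the local maximum within one window of each detected peak.
    """
    n = mean_segment.size
    win = max(1, int(round(PEAK_SMOOTHING_FRACTION * n)))
    kernel = np.ones(win) / win
    padded = np.concatenate([mean_segment[:win][::-1], mean_segment, mean_segment[-win:][::-1]])
    smooth = np.convolve(padded, kernel, mode="same")[win : win + n]
    idx, _ = find_peaks(smooth)
    start_min = mean_segment[0]
    refined = []
    heights = []
    for i in idx:
        lo, hi = max(0, i - win), min(n, i + win + 1)
        j = lo + int(np.argmax(mean_segment[lo:hi]))
        refined.append(j)
        heights.append(mean_segment[j] - start_min)
    return np.asarray(refined, int), np.asarray(heights, float)


def icp_stats(segments: Sequence[np.ndarray]) -> PulseMetrics:
    """Pulse metrics from minimum-to-minimum ICP segments.

    Mean/max/min are taken over all samples of all segments; MWA and P2:P1
    come from the first (and second) smoothed peak of the cycle-mean segment.
    ``extrema_spread`` is the larger of the across-cycle spreads of the
    per-cycle maxima and minima (a stability measure of the recording).
    """
    if len(segments) == 0:
        raise InvalidParameterError("need at least one segment")
    stack = np.vstack(segments)
    mean_seg = stack.mean(axis=0)
    peak_idx, peak_heights = _pulse_peaks(mean_seg)
    if peak_idx.size == 0:
        mwa, ratio = math.nan, math.nan
    elif peak_idx.size == 1:
        mwa, ratio = float(peak_heights[0]), math.nan
    else:
        mwa = float(peak_heights[0])
        ratio = float(peak_heights[1] / peak_heights[0])
    per_cycle_max = stack.max(axis=1)
    per_cycle_min = stack.min(axis=1)
    spread = float(max(np.ptp(per_cycle_max), np.ptp(per_cycle_min)))
    return PulseMetrics(
        mean_icp=float(stack.mean()),
        max_icp=float(stack.max()),
        min_icp=float(stack.min()),
        mwa=mwa,
        p2_to_p1=ratio,
        extrema_spread=spread,
    )


def flow_metrics(wf: SampledWaveform, cycles: Optional[Sequence[np.ndarray]] = None) -> FlowMetrics:
    """Bundle the flow statistics of a (cycle-mean) waveform.

    When per-cycle segments are supplied, their pointwise min/mean/max curves
    are attached as the envelope.
    """
    mx, mn = flow_extrema(wf)
    env = None
    if cycles is not None and len(cycles) > 0:
        stack = np.vstack(cycles)
        env = {"min": stack.min(axis=0), "mean": stack.mean(axis=0), "max": stack.max(axis=0)}
    return FlowMetrics(
        sv=stroke_volume(wf),
        max_caudal=mx,
        max_cranial=mn,
        phase_cranial_max=phase_of_cranial_max(wf),
        envelope=env,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Recording vs reference-cohort discrepancies."""

    d_sv: float
    d_max_caudal: float
    d_max_cranial: float
    dt_phase_percent: float  # recording phase minus cohort-mean phase
    within_envelope: dict[str, bool]


def compare(recording: FlowMetrics, cohort: Sequence[FlowMetrics]) -> ComparisonReport:
    """Compare a recording's flow metrics against a reference cohort.

    Differences are recording minus cohort mean; the membership flags state
    whether each recording metric lies inside the cohort's min-max envelope.
    """
    if len(cohort) == 0:
        raise InvalidParameterError("reference cohort must be non-empty")

    def spread(attr: str) -> tuple[float, float, float]:
        vals = np.array([getattr(m, attr) for m in cohort], float)
        return float(vals.mean()), float(vals.min()), float(vals.max())

    report_diffs = {}
    within = {}
    for attr in ("sv", "max_caudal", "max_cranial"):
        mean, lo, hi = spread(attr)
        val = getattr(recording, attr)
        report_diffs[attr] = val - mean
        within[attr] = bool(lo <= val <= hi)
    ph_mean, ph_lo, ph_hi = spread("phase_cranial_max")
    within["phase_cranial_max"] = bool(ph_lo <= recording.phase_cranial_max <= ph_hi)
    return ComparisonReport(
        d_sv=report_diffs["sv"],
        d_max_caudal=report_diffs["max_caudal"],
        d_max_cranial=report_diffs["max_cranial"],
        dt_phase_percent=recording.phase_cranial_max - ph_mean,
        within_envelope=within,
    )
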