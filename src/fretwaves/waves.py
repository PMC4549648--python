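"""Activity traces, dF/F0 normalization, wave-period and onset estimation.

Turns ratio movies and square ROIs into scalar readouts: per-ROI mean-ratio
time series, baseline-normalized dF/F0 traces, maxima-interval wave-period
estimates, onset latencies after a local stimulus, and stalling-normalized
class summaries of edge sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .correction import RatioMovie
from .edges import RegionOfInterest, rect_region_mask, square_region_mask

__all__ = [
    "ActivityTrace",
    "WaveEstimate",
    "ClassRatioSummary",
    "roi_trace",
    "delta_f_over_f",
    "detect_maxima",
    "estimate_period",
    "detect_onset",
    "summarize_classes",
]

MIN_DEFINED_PIXELS = 10


@dataclass
class ActivityTrace:
    """Per-frame mean defined-ratio value inside one ROI."""

    roi_id: str
    times: np.ndarray  # s
    values: np.ndarray  # mean ratio; NaN = missing frame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 1.0


@dataclass
class WaveEstimate:
    """Maxima-interval period estimate: mean +/- SEM over intervals."""

    maxima_times: np.ndarray  # s
    intervals: np.ndarray  # s
    mean_period: float  # s
    sem: float  # s
    n_intervals: int


@dataclass
class ClassRatioSummary:
    """Per-class mean ratio over edge sections, normalized by stalling."""

    means: dict  # class -> raw mean over section means
    normalized: dict  # class -> mean / stalling mean
    sems: dict  # class -> SEM over (normalized) section means
    counts: dict  # class -> number of sections
    section_means: dict = field(default_factory=dict)  # section id -> raw mean


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def roi_trace(
    ratio: RatioMovie,
    roi: RegionOfInterest,
    min_pixels: int = MIN_DEFINED_PIXELS,
    interior_frac_warn: float = 0.95,
) -> ActivityTrace:
    """Mean defined-ratio inside the ROI per frame.

    Frames with fewer than ``min_pixels`` defined pixels are flagged missing
    (NaN).  A warning is emitted when the ROI is not fully interior to the
    defined region on at least ``interior_frac_warn`` of frames (edge
    movement can then contaminate the trace); an ROI with no defined pixels
    on any frame is an error.
    """
    shape = ratio.data.shape[1:]
    if roi.kind == "square":
        region = square_region_mask(shape, roi, ratio.pixel_size)
    else:
        region = rect_region_mask(shape, roi, ratio.pixel_size)
    if not region.any():
        raise ValueError(f"ROI {roi.id!r} does not intersect the image")

    sub = ratio.data[:, region]  # (T, n_px)
    n_defined = np.isfinite(sub).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(sub, axis=1)
    values[n_defined < min_pixels] = np.nan

    if not np.isfinite(values).any():
        raise ValueError(f"ROI {roi.id!r} lies outside the cell mask throughout")
    interior = (n_defined == region.sum()).mean()
    if interior < interior_frac_warn:
        warnings.warn(
            f"ROI {roi.id!r} straddles the cell edge on {1 - interior:.0%} of "
            "frames; edge movement may contaminate the trace",
            stacklevel=2,
        )
    return ActivityTrace(roi_id=roi.id, times=ratio.times, values=values)


def delta_f_over_f(trace: ActivityTrace, m: int = 1) -> np.ndarray:
    """Normalized series ``(F - F0) / F0``.

    ``F0`` is the mean of the first ``m`` non-missing values (default: the
    first frame).  Raises if ``F0 <= 0``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    finite = trace.values[np.isfinite(trace.values)]
    if finite.size == 0:
        raise ValueError("trace has no defined values")
    f0 = float(finite[:m].mean())
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    return (trace.values - f0) / f0


# ---------------------------------------------------------------------------
# maxima / period
# ---------------------------------------------------------------------------


def _fill_short_gaps(values: np.ndarray, times: np.ndarray, max_gap_s: float) -> np.ndarray:
    """Linearly interpolate runs of missing samples no longer than max_gap_s."""
    out = values.copy()
    isnan = ~np.isfinite(values)
    if not isnan.any() or isnan.all():
        return out
    dt = times[1] - times[0] if times.size > 1 else 1.0
    max_run = int(round(max_gap_s / dt))
    i = 0
    n = len(values)
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            if 0 < i and j < n and (j - i) <= max_run:
                out[i:j] = np.interp(times[i:j], [times[i - 1], times[j]], [values[i - 1], values[j]])
            i = j
        else:
            i += 1
    return out


def detect_maxima(
    series: np.ndarray,
    times: np.ndarray,
    smoothing_window_s: float = 5.0,
    min_prominence_sd: float = 0.5,
    max_gap_s: float = 3.0,
) -> np.ndarray:
    """Times of local maxima of the moving-average-smoothed series.

    Maxima must have prominence >= ``min_prominence_sd`` times the standard
    deviation of the (unsmoothed) series; times are reported on the original
    sampling grid.  Missing samples are linearly interpolated when the gap is
    at most ``max_gap_s``; longer gaps split the series and each segment is
    searched independently.  An empty result is allowed.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size < 3:
        return np.array([])
    dt = times[1] - times[0] if times.size > 1 else 1.0
    filled = _fill_short_gaps(series, times, max_gap_s)
    sd = np.nanstd(series)
    if not np.isfinite(sd) or sd == 0:
        return np.array([])
    win = max(1, int(round(smoothing_window_s / dt)))

    out_times = []
    isnan = ~np.isfinite(filled)
    boundaries = np.flatnonzero(np.diff(isnan.astype(int)) != 0) + 1
    segments = np.split(np.arange(series.size), boundaries)
    for seg in segments:
        if seg.size < 3 or isnan[seg[0]]:
            continue
        smooth = ndimage.uniform_filter1d(filled[seg], size=win, mode="nearest")
        peaks, _ = find_peaks(smooth, prominence=min_prominence_sd * sd)
        out_times.extend(times[seg[peaks]])
    return np.asarray(sorted(out_times))


def estimate_period(maxima_times: np.ndarray, max_intervals: int | None = None) -> WaveEstimate:
    """Mean +/- SEM of consecutive maxima intervals.

    With ``max_intervals`` set, only the first that many intervals enter the
    mean (e.g. 10, to pool a fixed number of cycles).  Raises when fewer
    than two maxima are available.
    """
    maxima_times = np.asarray(maxima_times, dtype=float)
    if maxima_times.size < 2:
        raise ValueError("insufficient oscillations: need at least 2 maxima")
    intervals = np.diff(maxima_times)
    if max_intervals is not None:
        intervals = intervals[:max_intervals]
    mean = float(intervals.mean())
    sem = float(intervals.std(ddof=1) / np.sqrt(intervals.size)) if intervals.size > 1 else 0.0
    return WaveEstimate(
        maxima_times=maxima_times,
        intervals=intervals,
        mean_period=mean,
        sem=sem,
        n_intervals=int(intervals.size),
    )


# ---------------------------------------------------------------------------
# onset
# ---------------------------------------------------------------------------


def detect_onset(
    series: np.ndarray,
    times: np.ndarray,
    stimulus_time: float,
    k: float = 3.0,
    sustain_s: float = 5.0,
    min_baseline_s: float = 30.0,
) -> float | None:
    """Latency (s) from the stimulus to a sustained baseline + k*SD crossing.

    The baseline is the pre-stimulus part of the series (must span at least
    ``min_baseline_s``).  The onset is the first post-stimulus time where the
    series exceeds ``baseline mean + k * baseline SD`` for at least
    ``sustain_s`` consecutive seconds; returns None if never exceeded.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if not times[0] <= stimulus_time <= times[-1]:
        raise ValueError("stimulus_time lies outside the record")
    pre = times < stimulus_time
    pre_vals = series[pre]
    pre_vals = pre_vals[np.isfinite(pre_vals)]
    if pre_vals.size < 2 or (times[pre][-1] - times[pre][0]) < min_baseline_s:
        raise ValueError(f"need at least {min_baseline_s} s of pre-stimulus baseline")
    threshold = pre_vals.mean() + k * pre_vals.std(ddof=0)

    dt = times[1] - times[0] if times.size > 1 else 1.0
    need = max(1, int(round(sustain_s / dt)))
    post = np.flatnonzero(times >= stimulus_time)
    above = series[post] > threshold
    run = 0
    for j, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= need:
            onset = times[post[j - need + 1]]
            return float(onset - stimulus_time)
    return None


# ---------------------------------------------------------------------------
# class summary
# ---------------------------------------------------------------------------


def summarize_classes(
    section_means: dict[str, float],
    labels: dict[str, str],
) -> ClassRatioSummary:
    """Stalling-normalized per-class mean ratios over edge sections.

    ``section_means`` maps section/ROI ids to their mean ratio value and
    ``labels`` to class labels.  Class means are means over section-wise
    means; everything is normalized by the stalling-class mean (so the
    normalized stalling mean is exactly 1).  Raises when no stalling section
    exists (normalization undefined).
    """
    by_class: dict[str, list[float]] = {}
    for sid, mean in section_means.items():
        label = labels.get(sid)
        if label is None or label == "unclassified" or not np.isfinite(mean):
            continue
        by_class.setdefault(label, []).append(float(mean))
    if "stalling" not in by_class or not by_class["stalling"]:
        raise ValueError("no stalling section: stalling-normalization undefined")
    stalling_mean = float(np.mean(by_class["stalling"]))

    means, normalized, sems, counts = {}, {}, {}, {}
    for label, vals in sorted(by_class.items()):
        arr = np.asarray(vals)
        means[label] = float(arr.mean())
        normalized[label] = float(arr.mean() / stalling_mean)
        sems[label] = (
            float(arr.std(ddof=1) / stalling_mean / np.sqrt(arr.size))
            if arr.size > 1
            else 0.0
        )
        counts[label] = int(arr.size)
    return ClassRatioSummary(
        means=means,
        normalized=normalized,
        sems=sems,
        counts=counts,
        section_means=dict(section_means),
    )
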