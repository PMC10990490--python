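"""Calcium-trace analysis: ΔF/F_min normalization, event detection, and
stimulus-aligned evoked-response metrics.

The raw quantity is a background-corrected region-mean fluorescence time
series.  Normalization is ``(F - F_min) / F_min`` where ``F_min`` is the mean
of the lowest fraction (default 5%) of background-corrected samples, which is
robust to single-frame dropouts.  Events are maximal supra-threshold
intervals, extended to the half-threshold crossings, with the threshold set
as a multiple of the robust (MAD-based) noise SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import StimulationProtocol, ValidationError

__all__ = [
    "FluorescenceTrace",
    "DffTrace",
    "CalciumEvent",
    "EvokedWindow",
    "BaselineError",
    "compute_dff",
    "robust_noise_sd",
    "detect_events",
    "max_event_amplitude",
    "total_activity",
    "align_to_stimuli",
    "normalize_group_activity",
]


class BaselineError(ValueError):
    """Baseline estimate is non-positive (background exceeds signal)."""


@dataclass
class FluorescenceTrace:
    """Background-corrected fluorescence time series for one region."""

    t_s: np.ndarray
    f_raw: np.ndarray
    f_bg: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.f_raw = np.asarray(self.f_raw, dtype=float)
        self.f_bg = np.asarray(self.f_bg, dtype=float)
        if not (len(self.t_s) == len(self.f_raw) == len(self.f_bg)):
            raise ValidationError("t_s, f_raw, f_bg must have equal length")
        if len(self.t_s) < 2:
            raise ValidationError("trace needs >=2 samples")
        steps = np.diff(self.t_s)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValidationError("t_s must increase with a constant step")
        if not np.all(np.isfinite(self.f_corr)):
            raise ValidationError("f_corr must be finite")

    @property
    def dt_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0])

    @property
    def f_corr(self) -> np.ndarray:
        return self.f_raw - self.f_bg


@dataclass
class DffTrace:
    """ΔF/F_min-normalized trace."""

    t_s: np.ndarray
    dff: np.ndarray
    f_min: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.f_min <= 0:
            raise BaselineError(f"F_min must be positive, got {self.f_min}")
        if np.min(self.dff) < -0.5:
            raise BaselineError(
                f"min dff {np.min(self.dff):.3f} < -0.5; baseline looks wrong"
            )

    @property
    def dt_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0])


@dataclass
class CalciumEvent:
    """One detected supra-threshold interval."""

    t_start_s: float
    t_end_s: float
    peak_dff: float
    area_dff_s: float
    t_peak_s: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if not self.t_start_s < self.t_end_s:
            raise ValidationError("event must have t_start < t_end")
        if self.area_dff_s < 0:
            raise ValidationError("event area must be >= 0")


@dataclass
class EvokedWindow:
    """Per-stimulus response window ``[onset, onset + period)``."""

    stimulus_index: int
    onset_s: float
    window_end_s: float
    max_dff: float
    events: list[CalciumEvent]
    truncated: bool = False


def compute_dff(trace: FluorescenceTrace, baseline_fraction: float = 0.05) -> DffTrace:
    """Normalize a trace to ΔF/F_min.

    ``F_min`` is the mean of the lowest ``baseline_fraction`` of
    background-corrected samples (at least one sample).  The result is
    invariant under multiplication of ``f_raw`` and ``f_bg`` by a common
    positive gain.
    """
    if not 0 < baseline_fraction <= 0.5:
        raise ValueError(f"baseline_fraction must be in (0, 0.5], got {baseline_fraction}")
    f = trace.f_corr
    k = max(int(round(baseline_fraction * len(f))), 1)
    f_min = float(np.mean(np.sort(f)[:k]))
    if f_min <= 0:
        raise BaselineError(f"F_min = {f_min:g} <= 0: background exceeds signal")
    return DffTrace(t_s=trace.t_s, dff=(f - f_min) / f_min, f_min=f_min,
                    source_id=trace.source_id)


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD estimate via the median absolute deviation of first
    differences (insensitive to slow signal), scaled to Gaussian SD."""
    d = np.diff(np.asarray(x, dtype=float))
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _smooth3(x: np.ndarray) -> np.ndarray:
    # light [1,2,1]/4 smoothing for peak read-out only
    return np.convolve(np.pad(x, 1, mode="edge"), [0.25, 0.5, 0.25], mode="valid")


def detect_events(
    dff: DffTrace,
    threshold_sd: float = 3.0,
    min_duration_s: float | None = None,
    noise_sd: float | None = None,
    merge_gap_s: float = 0.5,
) -> list[CalciumEvent]:
    """Detect events as maximal intervals with ``dff >= threshold``.

    The threshold is ``threshold_sd`` times a robust noise SD.  Each interval
    must last at least ``min_duration_s`` (default three frames) and is then
    extended outward to the half-threshold crossings; extended intervals
    closer than ``merge_gap_s`` merge (decay tails re-crossing the threshold
    would otherwise split one transient in two).  Peak amplitude is read from
    a lightly smoothed copy of the trace to suppress single-sample noise
    excursions.
    """
    x = dff.dff
    dt = dff.dt_s
    if min_duration_s is None:
        min_duration_s = 3 * dt
    if noise_sd is None:
        noise_sd = robust_noise_sd(x)
    # threshold sits above the robust dff baseline: F_min is a low-order
    # statistic, so the quiescent dff level is slightly positive on noisy data
    center = float(np.median(x))
    threshold = center + threshold_sd * noise_sd
    if threshold <= 0:
        threshold = np.finfo(float).tiny  # noiseless traces: any positive dff
    above = x >= threshold
    if not np.any(above):
        return []

    # maximal runs of `above`
    idx = np.flatnonzero(above)
    runs: list[tuple[int, int]] = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))

    min_frames = max(int(np.ceil(min_duration_s / dt)), 1)
    half = center + (threshold - center) / 2.0
    n = len(x)
    extended: list[tuple[int, int]] = []
    for a, b in runs:
        if b - a + 1 < min_frames:
            continue
        while a > 0 and x[a - 1] >= half:
            a -= 1
        while b < n - 1 and x[b + 1] >= half:
            b += 1
        gap_frames = int(round(merge_gap_s / dt))
        if extended and a <= extended[-1][1] + 1 + gap_frames:
            extended[-1] = (extended[-1][0], max(extended[-1][1], b))
        else:
            extended.append((a, b))

    # read peaks from a lightly smoothed copy on noisy traces only; on
    # (effectively) noiseless data the raw sample is exact
    noiseless = noise_sd <= 1e-4 * float(np.max(np.abs(x), initial=0.0))
    smoothed = x if noiseless else _smooth3(x)
    events = []
    for a, b in extended:
        seg = smoothed[a: b + 1]
        i_peak = int(np.argmax(seg))
        area = float(np.trapezoid(x[a: b + 1], dx=dt))
        events.append(
            CalciumEvent(
                t_start_s=float(dff.t_s[a]),
                t_end_s=float(dff.t_s[b]),
                peak_dff=float(seg[i_peak]),
                area_dff_s=max(area, 0.0),
                t_peak_s=float(dff.t_s[a + i_peak]),
            )
        )
    return events


def max_event_amplitude(events: list[CalciumEvent]) -> float:
    """Largest event peak ΔF/F_min in the trace; 0 if no events."""
    return max((e.peak_dff for e in events), default=0.0)


def total_activity(
    dff: DffTrace,
    events: list[CalciumEvent] | None = None,
    whole_trace: bool = False,
) -> float:
    """Summed ΔF/F_min area (ΔF/F · s).

    By default the trapezoidal areas of detected events are summed — the
    combined amplitude-and-duration measure.  ``whole_trace=True`` integrates
    the full trace instead.
    """
    if whole_trace:
        return float(np.trapezoid(np.clip(dff.dff, 0, None), dx=dff.dt_s))
    if events is None:
        events = detect_events(dff)
    return float(sum(e.area_dff_s for e in events))


def align_to_stimuli(
    dff: DffTrace,
    protocol: StimulationProtocol,
    events: list[CalciumEvent] | None = None,
) -> list[EvokedWindow]:
    """Score each stimulus window ``[onset, onset + period)``.

    Windows that extend past the trace end are truncated and flagged.
    """
    if events is None:
        events = detect_events(dff)
    period = protocol.period_s
    if period is None:
        onsets = protocol.onset_times_s
        period = float(np.min(np.diff(onsets))) if len(onsets) > 1 else float(
            dff.t_s[-1] - onsets[0]
        )
    t_end = float(dff.t_s[-1])
    windows = []
    for i, onset in enumerate(protocol.onset_times_s):
        if onset > t_end:
            raise ValidationError(f"stimulus onset {onset} s beyond trace end {t_end} s")
        w_end = onset + period
        truncated = w_end > t_end + dff.dt_s / 2
        w_end_eff = min(w_end, t_end + dff.dt_s / 2)
        sel = (dff.t_s >= onset) & (dff.t_s < w_end_eff)
        w_max = float(np.max(dff.dff[sel])) if np.any(sel) else 0.0
        w_events = [e for e in events if e.t_start_s < w_end_eff and e.t_end_s >= onset
                    and onset <= e.t_peak_s < w_end_eff]
        windows.append(
            EvokedWindow(
                stimulus_index=i,
                onset_s=float(onset),
                window_end_s=float(w_end),
                max_dff=w_max,
                events=w_events,
                truncated=bool(truncated),
            )
        )
    return windows


def normalize_group_activity(
    groups: dict[str, np.ndarray], reference_group: str
) -> dict[str, np.ndarray]:
    """Divide every value by the mean of the reference group.

    The reference group maps to mean exactly 1.
    """
    ref = np.asarray(groups[reference_group], dtype=float)
    ref_mean = float(np.mean(ref))
    if ref_mean <= 0:
        raise ValueError(f"reference group mean {ref_mean:g} <= 0")
    return {name: np.asarray(v, dtype=float) / ref_mean for name, v in groups.items()}
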