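"""Kymograph construction and transport quantification.

A kymograph has time on rows and arc-length distance on columns.  Motile
puncta appear as slanted lines; events are extracted by per-frame peak
detection followed by greedy nearest-neighbour linking with a velocity cap,
an automated surrogate for manual counting.  Anterograde means increasing
arc-length coordinate of the supplied path (the user's proximal→distal
orientation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .frap_analysis import GeometryError
from .imaging_io import ImageStack, NeuritePath, ValidationError

__all__ = [
    "Kymograph",
    "TransportEvent",
    "TrackParams",
    "build_kymograph",
    "detect_transport_events",
    "events_per_minute",
    "instantaneous_velocities",
]


@dataclass
class Kymograph:
    """Time × distance intensity matrix along a neurite path."""

    matrix: np.ndarray  # (n_frames, n_arc_samples)
    dt_s: float
    dx_um: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("kymograph matrix must be 2-D")
        if self.dt_s <= 0 or self.dx_um <= 0:
            raise ValidationError("dt_s and dx_um must be positive")

    @property
    def duration_s(self) -> float:
        return self.matrix.shape[0] * self.dt_s

    def mirrored(self) -> "Kymograph":
        """Left-right mirror (reverses the path orientation)."""
        return Kymograph(matrix=self.matrix[:, ::-1].copy(), dt_s=self.dt_s,
                         dx_um=self.dx_um)


@dataclass
class TransportEvent:
    """One motile trajectory extracted from a kymograph."""

    track_t_s: np.ndarray
    track_x_um: np.ndarray
    direction: str  # "anterograde" | "retrograde"
    net_displacement_um: float
    segment_velocities_um_s: list[float] = field(default_factory=list)
    motile: bool = True

    @property
    def mean_speed_um_s(self) -> float:
        if not self.segment_velocities_um_s:
            return 0.0
        return float(np.mean(np.abs(self.segment_velocities_um_s)))


@dataclass
class TrackParams:
    """Knobs of the automated event extraction."""

    min_net_displacement_um: float = 2.0
    max_speed_um_s: float = 5.0  # linking cap
    min_track_frames: int = 5
    threshold_sds: float = 4.0
    pause_speed_um_s: float = 0.1
    pause_min_frames: int = 3
    min_peak_separation_um: float = 1.0


def build_kymograph(stream: ImageStack, path: NeuritePath) -> Kymograph:
    """Average a perpendicular band of ``path.width_px`` pixels at every
    arc-length sample (spacing = 1 px), per frame."""
    if stream.axis_kind != "time" or stream.n_pages < 2:
        raise ValidationError("kymograph needs a time-axis stream with >= 2 frames")
    h, w = stream.shape
    samples, normals = path.resample(spacing_px=1.0)
    offsets = np.arange(path.width_px) - (path.width_px - 1) / 2.0
    rows = samples[:, 1][:, None] + normals[:, 1][:, None] * offsets[None, :]
    cols = samples[:, 0][:, None] + normals[:, 0][:, None] * offsets[None, :]
    if (samples[:, 0].min() < 0 or samples[:, 1].min() < 0
            or samples[:, 0].max() > w - 1 or samples[:, 1].max() > h - 1):
        raise GeometryError("path exits the frame bounds")
    coords = [rows.ravel(), cols.ravel()]
    out = np.empty((stream.n_pages, len(samples)))
    for i, page in enumerate(stream.pages):
        band = map_coordinates(page.astype(float), coords, order=1, mode="nearest")
        out[i] = band.reshape(rows.shape).mean(axis=1)
    return Kymograph(matrix=out, dt_s=float(stream.dt_s), dx_um=stream.px_um)


def _frame_peaks(row: np.ndarray, threshold: float, min_sep_cols: int) -> np.ndarray:
    """Column indices of local maxima above threshold, at least min_sep apart."""
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(row, height=threshold, distance=max(min_sep_cols, 1))
    return peaks


def detect_transport_events(
    kymo: Kymograph, params: TrackParams | None = None
) -> list[TransportEvent]:
    """Extract motile trajectories by greedy frame-to-frame linking.

    Peaks above ``median + threshold_sds·robust SD`` are linked to the nearest
    peak in the next frame within ``max_speed_um_s * dt`` µm.  Tracks lasting
    at least ``min_track_frames`` and moving at least
    ``min_net_displacement_um`` net are motile transport events; shorter or
    stationary tracks are discarded.
    """
    params = params or TrackParams()
    m = kymo.matrix
    med = float(np.median(m))
    sd = 1.4826 * float(np.median(np.abs(m - med)))
    threshold = med + params.threshold_sds * sd if sd > 0 else med + np.finfo(float).eps
    min_sep_cols = max(int(round(params.min_peak_separation_um / kymo.dx_um)), 1)
    max_step_cols = params.max_speed_um_s * kymo.dt_s / kymo.dx_um

    active: list[dict] = []
    done: list[dict] = []
    for f in range(m.shape[0]):
        peaks = _frame_peaks(m[f], threshold, min_sep_cols)
        unused = set(range(len(peaks)))
        # extend existing tracks greedily, closest pair first
        candidates = []
        for ti, tr in enumerate(active):
            last = tr["cols"][-1]
            for pi in unused:
                d = abs(peaks[pi] - last)
                if d <= max_step_cols:
                    candidates.append((d, ti, pi))
        candidates.sort()
        taken_tracks: set[int] = set()
        taken_peaks: set[int] = set()
        for d, ti, pi in candidates:
            if ti in taken_tracks or pi in taken_peaks:
                continue
            active[ti]["frames"].append(f)
            active[ti]["cols"].append(int(peaks[pi]))
            taken_tracks.add(ti)
            taken_peaks.add(pi)
        unused -= taken_peaks
        still_active = []
        for ti, tr in enumerate(active):
            if ti in taken_tracks:
                still_active.append(tr)
            else:
                done.append(tr)
        active = still_active
        for pi in unused:
            active.append({"frames": [f], "cols": [int(peaks[pi])]})
    done.extend(active)

    events = []
    for tr in done:
        if len(tr["frames"]) < params.min_track_frames:
            continue
        t = np.asarray(tr["frames"], float) * kymo.dt_s
        x = np.asarray(tr["cols"], float) * kymo.dx_um
        net = float(x[-1] - x[0])
        if abs(net) < params.min_net_displacement_um:
            continue
        ev = TransportEvent(
            track_t_s=t, track_x_um=x,
            direction="anterograde" if net > 0 else "retrograde",
            net_displacement_um=net,
        )
        ev.segment_velocities_um_s = _segment_velocities(t, x, params)
        events.append(ev)
    events.sort(key=lambda e: (e.track_t_s[0], e.track_x_um[0]))
    return events


def _segment_velocities(t: np.ndarray, x: np.ndarray, params: TrackParams) -> list[float]:
    """Split a track at pauses and reversals; velocity = Δx/Δt per segment."""
    v_inst = np.diff(x) / np.diff(t)
    paused = np.abs(v_inst) < params.pause_speed_um_s
    # suppress pause labels shorter than pause_min_frames
    state = np.zeros(len(v_inst), dtype=int)  # 0 move, 1 pause
    i = 0
    while i < len(paused):
        if paused[i]:
            j = i
            while j < len(paused) and paused[j]:
                j += 1
            if j - i >= params.pause_min_frames:
                state[i:j] = 1
            i = j
        else:
            i += 1
    sign = np.sign(v_inst)
    velocities = []
    start = None
    cur_sign = 0.0
    for i in range(len(v_inst)):
        if state[i] == 1:
            if start is not None:
                velocities.append(_seg_v(t, x, start, i))
                start = None
            continue
        s = sign[i]
        if start is None:
            start = i
            cur_sign = s
        elif s != 0 and cur_sign != 0 and s != cur_sign:
            velocities.append(_seg_v(t, x, start, i))
            start = i
            cur_sign = s
        elif cur_sign == 0:
            cur_sign = s
    if start is not None:
        velocities.append(_seg_v(t, x, start, len(v_inst)))
    return [float(v) for v in velocities]


def _seg_v(t: np.ndarray, x: np.ndarray, i0: int, i1: int) -> float:
    """Least-squares slope over track samples i0..i1 (robust to pixel steps)."""
    tt, xx = t[i0: i1 + 1], x[i0: i1 + 1]
    if len(tt) < 2:
        return 0.0
    if len(tt) == 2:
        return float((xx[1] - xx[0]) / (tt[1] - tt[0]))
    return float(np.polyfit(tt, xx, 1)[0])


def events_per_minute(events: list[TransportEvent] | int, duration_s: float) -> float:
    """Transport-event rate: count × 60 / duration."""
    if duration_s <= 0:
        raise ValidationError("duration must be positive")
    count = events if isinstance(events, int) else len(events)
    return count * 60.0 / duration_s


def instantaneous_velocities(
    events: list[TransportEvent],
) -> tuple[list[tuple[int, int, float]], list[float]]:
    """Per-segment velocities and per-event mean speeds.

    Returns ``(segments, mean_speeds)`` where segments are
    ``(event_index, segment_index, v_um_s)`` rows; pause intervals are
    excluded upstream by the segmenting rules.
    """
    segments = []
    mean_speeds = []
    for ei, ev in enumerate(events):
        for si, v in enumerate(ev.segment_velocities_um_s):
            segments.append((ei, si, float(v)))
        mean_speeds.append(ev.mean_speed_um_s)
    return segments, mean_speeds
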