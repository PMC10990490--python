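"""FRAP quantification: timepoint extraction, the two normalization schemes,
one-phase recovery fitting, nested-model curve comparison, and pre-bleach
linescan puncta areas.

A series covers the schedule [pre, 0, 2, ..., 16] min.  The pre-bleach point
is stored with ``t_min = PRE_T`` (negative sentinel) and is excluded from
recovery fitting — it is not on the recovery curve.

Normalization modes
-------------------
percent   f_norm(t) = 100 * (f(t) - f(0)) / (f(pre) - f(0)); pre maps to 100
          and 0 min maps to 0 by construction.
subtract  f_norm(t) = f(t) - f(0) in raw a.u.; used when groups differ in
          absolute pre-bleach brightness; the pre point is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .imaging_io import ImageStack, NeuritePath, Roi, ValidationError

__all__ = [
    "PRE_T",
    "FrapSeries",
    "FrapFit",
    "CurveComparison",
    "PunctaProfile",
    "ScheduleError",
    "GeometryError",
    "NormalizationError",
    "extract_frap_series",
    "normalize_frap",
    "fit_recovery",
    "compare_recovery_curves",
    "prebleach_puncta_areas",
]

PRE_T = -1.0  # sentinel t_min for the pre-bleach point


class ScheduleError(ValueError):
    """A scheduled timepoint is missing."""


class GeometryError(ValueError):
    """Region or path falls outside the image."""


class NormalizationError(ValueError):
    """Photobleach failed (pre-bleach not above 0-min fluorescence)."""


@dataclass
class FrapSeries:
    """Region fluorescence across the FRAP schedule for one animal."""

    animal_id: str
    t_min: np.ndarray  # PRE_T, 0, 2, ... (pre first)
    f: np.ndarray
    norm_mode: str = "raw"  # raw | percent | subtract
    f_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if len(self.t_min) != len(self.f):
            raise ValidationError("t_min and f must have equal length")
        if not np.all(np.isfinite(self.f)):
            raise ValidationError("fluorescence values must be finite")
        if self.norm_mode == "raw":
            if self.t_min[0] >= 0 or np.any(np.diff(self.t_min[1:]) <= 0):
                raise ValidationError("raw series must start at the pre point "
                                      "and increase afterwards")

    @property
    def has_pre(self) -> bool:
        return bool(np.any(self.t_min < 0))

    @property
    def f_pre(self) -> float:
        if not self.has_pre:
            raise ValidationError("series has no pre-bleach point")
        return float(self.f[self.t_min < 0][0])

    @property
    def f0(self) -> float:
        at0 = np.isclose(self.t_min, 0.0)
        if not at0.any():
            raise ScheduleError("series has no 0-min timepoint")
        return float(self.f[at0][0])

    def post_bleach(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, y) pairs on the recovery curve, using f_norm when present."""
        y = self.f_norm if self.f_norm is not None else self.f
        sel = self.t_min >= 0
        return self.t_min[sel], np.asarray(y)[sel]


@dataclass
class FrapFit:
    """One-phase association fit Y(t) = plateau * (1 - exp(-k t))."""

    plateau: float
    k_per_min: float
    rss: float
    n_points: int
    flagged: bool = False
    note: str = ""

    def predict(self, t_min: np.ndarray) -> np.ndarray:
        return self.plateau * (1.0 - np.exp(-self.k_per_min * np.asarray(t_min, float)))


@dataclass
class CurveComparison:
    """Extra sum-of-squares F-test between two fitted groups."""

    group_a: str
    group_b: str
    F: float
    df_num: int
    df_den: int
    p_raw: float
    p_adj: float
    significant: bool


@dataclass
class PunctaProfile:
    """Width-averaged linescan with detected peaks."""

    s_um: np.ndarray
    intensity: np.ndarray
    peaks: list[tuple[float, float]]  # (position_um, area_above_baseline)
    no_peaks: bool = False

    @property
    def mean_area(self) -> float:
        if not self.peaks:
            return 0.0
        return float(np.mean([a for _, a in self.peaks]))


# ---------------------------------------------------------------------------


def extract_frap_series(
    stacks: Sequence[ImageStack],
    region: Roi,
    background: Roi | None,
    t_min: Sequence[float] | None = None,
    animal_id: str = "",
) -> FrapSeries:
    """Measure region fluorescence at every scheduled timepoint.

    Per timepoint the value is the mean within ``region`` of the
    maximum-intensity z-projection, minus the background-region mean.  The
    first stack is the pre-bleach acquisition.
    """
    if t_min is None:
        t_min = [PRE_T] + [2.0 * i for i in range(len(stacks) - 1)]
    t_min = list(t_min)
    if len(t_min) != len(stacks):
        missing = set(np.round(t_min, 3)) if len(t_min) > len(stacks) else set()
        raise ScheduleError(
            f"{len(stacks)} stacks for {len(t_min)} scheduled timepoints"
            + (f"; missing {sorted(missing)}" if missing else "")
        )
    values = []
    for stack in stacks:
        h, w = stack.shape
        x0, y0, x1, y1 = region.bounds()
        if x0 < -0.5 or y0 < -0.5 or x1 > w - 0.5 or y1 > h - 0.5:
            raise GeometryError(f"region {region.id!r} extends outside the {h}x{w} image")
        proj = stack.pages.max(axis=0).astype(float)
        sig = float(proj[region.mask((h, w))].mean())
        bg = float(proj[background.mask((h, w))].mean()) if background is not None else 0.0
        values.append(sig - bg)
    return FrapSeries(animal_id=animal_id, t_min=np.asarray(t_min), f=np.asarray(values))


def normalize_frap(series: FrapSeries, mode: str) -> FrapSeries:
    """Apply one of the two normalization schemes (see module docstring)."""
    if mode not in ("percent", "subtract"):
        raise ValueError(f"mode must be 'percent' or 'subtract', got {mode!r}")
    f0 = series.f0
    if mode == "percent":
        f_pre = series.f_pre
        if f_pre <= f0:
            raise NormalizationError(
                f"pre-bleach {f_pre:g} <= 0-min {f0:g}: photobleach failed"
            )
        f_norm = 100.0 * (series.f - f0) / (f_pre - f0)
        return FrapSeries(animal_id=series.animal_id, t_min=series.t_min,
                          f=series.f, norm_mode="percent", f_norm=f_norm)
    keep = series.t_min >= 0
    return FrapSeries(animal_id=series.animal_id, t_min=series.t_min[keep],
                      f=series.f[keep], norm_mode="subtract",
                      f_norm=series.f[keep] - f0)


def _one_phase(t, plateau, k):
    return plateau * (1.0 - np.exp(-k * t))


def _fit_pooled(t: np.ndarray, y: np.ndarray) -> FrapFit:
    """Deterministic multi-start least squares of the one-phase model."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(np.unique(t[t > 0])) < 2:
        raise ValidationError("need >= 3 distinct post-bleach timepoints (incl. 0)")
    y_max = float(np.max(np.abs(y)))
    if y_max == 0:
        return FrapFit(plateau=0.0, k_per_min=0.0, rss=0.0, n_points=len(y),
                       flagged=True, note="all-zero data; k unidentifiable")
    span = float(np.max(t[t > 0]))
    best = None
    for k0 in (0.05, 0.2, 0.5, 1.0, 3.0):
        try:
            popt, _ = optimize.curve_fit(
                _one_phase, t, y, p0=[max(np.max(y), 1e-6), k0],
                bounds=([0.0, 0.0], [np.inf, 1e6 / max(span, 1e-9)]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((y - _one_phase(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError("recovery fit failed to converge from every start")
    (plateau, k), rss = best
    flagged = plateau < 0.02 * y_max
    return FrapFit(plateau=float(plateau), k_per_min=float(k), rss=rss,
                   n_points=len(y), flagged=bool(flagged),
                   note="plateau ~ 0; k weakly identified" if flagged else "")


def fit_recovery(series_group: Sequence[FrapSeries]) -> FrapFit:
    """Fit one recovery curve to a group, pooling post-bleach points."""
    ts, ys = [], []
    for s in series_group:
        t, y = s.post_bleach()
        ts.append(t)
        ys.append(y)
    return _fit_pooled(np.concatenate(ts), np.concatenate(ys))


def compare_recovery_curves(
    groups: dict[str, Sequence[FrapSeries]],
    alpha: float = 0.01,
    control: str | None = None,
    all_pairs: bool = False,
) -> list[CurveComparison]:
    """Extra sum-of-squares F-test between group recovery curves.

    For each pair, the shared model fits one curve to the pooled points and
    the separate model fits each group independently;
    ``F = ((SS_shared - SS_sep) / Δdf) / (SS_sep / df_sep)``.  Raw p-values
    are Bonferroni-adjusted over the comparison family (group-vs-control by
    default, all pairs with ``all_pairs=True``); significance is
    ``p_adj < alpha`` (default 0.01).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need >= 2 groups to compare")
    if all_pairs or control is None and len(names) == 2:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    else:
        ctrl = control if control is not None else names[0]
        pairs = [(ctrl, g) for g in names if g != ctrl]

    data = {}
    for name in names:
        ts, ys = [], []
        for s in groups[name]:
            t, y = s.post_bleach()
            ts.append(t)
            ys.append(y)
        data[name] = (np.concatenate(ts), np.concatenate(ys))

    n_params = 2  # plateau, k
    results = []
    for a, b in pairs:
        ta, ya = data[a]
        tb, yb = data[b]
        for name, (t, y) in ((a, (ta, ya)), (b, (tb, yb))):
            if len(y) <= n_params:
                raise ValidationError(f"group {name!r} has fewer points than parameters")
        fit_a = _fit_pooled(ta, ya)
        fit_b = _fit_pooled(tb, yb)
        fit_sh = _fit_pooled(np.concatenate([ta, tb]), np.concatenate([ya, yb]))
        ss_sep = fit_a.rss + fit_b.rss
        ss_shared = max(fit_sh.rss, ss_sep)  # shared model is nested: never better
        n_total = len(ya) + len(yb)
        df_num = n_params
        df_den = n_total - 2 * n_params
        if df_den <= 0:
            raise ValidationError("not enough points for the separate model")
        if ss_sep == 0:
            F = 0.0 if ss_shared == ss_sep else float("inf")
        else:
            F = ((ss_shared - ss_sep) / df_num) / (ss_sep / df_den)
        p_raw = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
        results.append(CurveComparison(
            group_a=a, group_b=b, F=float(F), df_num=df_num, df_den=df_den,
            p_raw=p_raw, p_adj=min(p_raw * len(pairs), 1.0),
            significant=p_raw * len(pairs) < alpha,
        ))
    return results


# ---------------------------------------------------------------------------
# Pre-bleach linescan puncta


def linescan_profile(stack: ImageStack, path: NeuritePath) -> tuple[np.ndarray, np.ndarray]:
    """Width-averaged intensity profile along a neurite path (max z-projection)."""
    from scipy.ndimage import map_coordinates

    img = stack.pages.max(axis=0).astype(float)
    h, w = img.shape
    samples, normals = path.resample(spacing_px=1.0)
    if (samples[:, 0].min() < 0 or samples[:, 1].min() < 0
            or samples[:, 0].max() > w - 1 or samples[:, 1].max() > h - 1):
        raise GeometryError("path exits the image")
    offsets = np.arange(path.width_px) - (path.width_px - 1) / 2.0
    # coords: (n_samples, width) grid of (row, col)
    rows = samples[:, 1][:, None] + normals[:, 1][:, None] * offsets[None, :]
    cols = samples[:, 0][:, None] + normals[:, 0][:, None] * offsets[None, :]
    band = map_coordinates(img, [rows.ravel(), cols.ravel()], order=1, mode="nearest")
    profile = band.reshape(rows.shape).mean(axis=1)
    s_um = np.arange(len(profile)) * stack.px_um
    return s_um, profile


def prebleach_puncta_areas(
    stack: ImageStack,
    path: NeuritePath,
    threshold_sds: float = 3.0,
    baseline_window_um: float = 5.0,
) -> PunctaProfile:
    """Detect puncta along a pre-bleach linescan and integrate their areas.

    The local baseline is a rolling median of the profile; peaks are regions
    exceeding baseline + ``threshold_sds`` robust SDs, and each peak's area is
    the trapezoidal integral of (intensity - local baseline) between its
    threshold crossings (µm · a.u.).
    """
    s_um, profile = linescan_profile(stack, path)
    if len(profile) < 3:
        raise GeometryError("path shorter than 3 samples")
    px_um = float(s_um[1] - s_um[0])
    win = max(int(round(baseline_window_um / px_um)) | 1, 3)
    from scipy.ndimage import median_filter

    baseline = median_filter(profile, size=win, mode="nearest")
    resid = profile - baseline
    sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    thr = threshold_sds * sd
    if thr <= 0:
        # noiseless profile: any positive excursion is a peak
        peak_abs = float(np.max(np.abs(resid), initial=0.0))
        if peak_abs == 0:
            return PunctaProfile(s_um=s_um, intensity=profile, peaks=[], no_peaks=True)
        thr = 1e-9 * peak_abs
    above = resid > thr
    peaks = []
    idx = np.flatnonzero(above)
    if len(idx):
        run_start = idx[0]
        prev = idx[0]
        runs = []
        for i in idx[1:]:
            if i != prev + 1:
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))
        for a, b in runs:
            if b - a + 1 < 2:
                continue
            area = float(np.trapezoid(resid[a: b + 1], dx=px_um))
            pos = float(s_um[a + int(np.argmax(resid[a: b + 1]))])
            peaks.append((pos, max(area, 0.0)))
    return PunctaProfile(s_um=s_um, intensity=profile, peaks=peaks,
                         no_peaks=not peaks)
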