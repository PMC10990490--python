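"""Camera-realistic synthetic microscopy with recorded ground truth.

Every generator returns its outputs together with a :class:`GroundTruth`
record sufficient to score the paired analysis stage by parameter recovery.
Rendering follows a Poisson–Gaussian camera model::

    counts = offset + gain * Poisson(photons_per_unit * blur(field))
                     + Normal(0, read_noise_e * gain)

With ``noise=False`` the expectation is rendered instead, which makes the
end-to-end noiseless identity (generator truth -> analysis estimate) exact
to numerical precision.

Determinism: one global seed fans out to per-object substreams through
``numpy.random.SeedSequence`` spawn keys, so adding an object never
reshuffles the noise of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .calcium_events import FluorescenceTrace
from .imaging_io import ImageStack, NeuritePath, Roi, StimulationProtocol

__all__ = [
    "OpticsModel",
    "GroundTruth",
    "MitoCalciumSpec",
    "ParticleSpec",
    "GenerationError",
    "SamplingError",
    "PlacementError",
    "substream",
    "render_frame",
    "expected_frame",
    "symmetric_z_count",
    "calcium_kernel",
    "kernel_peak_time",
    "kernel_area",
    "gen_calcium_recording",
    "gen_rogfp_scene",
    "gen_frap_experiment",
    "frap_curve",
    "gen_transport_stream",
    "gen_proximity_scene",
    "place_axial_objects",
]


class GenerationError(ValueError):
    """Scene parameters are degenerate (e.g. zero-area objects)."""


class SamplingError(ValueError):
    """Temporal sampling too coarse for the requested kinetics."""


class PlacementError(RuntimeError):
    """Object placement infeasible at the requested density."""


@dataclass
class OpticsModel:
    """Gaussian-PSF camera model for an EMCCD-like detector."""

    psf_sigma_um: float = 0.15
    photons_per_unit: float = 1.0
    read_noise_e: float = 2.0
    offset_counts: float = 100.0
    gain_counts_per_photon: float = 2.0
    px_um: float = 0.1

    def __post_init__(self) -> None:
        if min(self.psf_sigma_um, self.photons_per_unit,
               self.gain_counts_per_photon, self.px_um) <= 0:
            raise GenerationError("optics parameters must be positive")
        if self.read_noise_e < 0 or self.offset_counts < 0:
            raise GenerationError("read noise and offset must be >= 0")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.px_um


@dataclass
class GroundTruth:
    """Scenario-specific truth record attached to every generated dataset."""

    scenario: str
    seed: int
    params: dict = dc_field(default_factory=dict)
    records: list[dict] = dc_field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic per-object RNG: same seed+keys -> same stream."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(keys)))


def expected_frame(brightness_field: np.ndarray, optics: OpticsModel) -> np.ndarray:
    """Noise-free expectation of :func:`render_frame`."""
    f = np.asarray(brightness_field, dtype=float)
    if not np.all(np.isfinite(f)):
        raise GenerationError("brightness field must be finite")
    photons = optics.photons_per_unit * gaussian_filter(f, optics.psf_sigma_px)
    return optics.offset_counts + optics.gain_counts_per_photon * photons


def render_frame(
    brightness_field: np.ndarray,
    optics: OpticsModel,
    seed: int | np.random.Generator,
    noise: bool = True,
) -> np.ndarray:
    """Render one camera frame from a non-negative brightness field."""
    f = np.asarray(brightness_field, dtype=float)
    if not np.all(np.isfinite(f)):
        raise GenerationError("brightness field must be finite")
    photons_mean = optics.photons_per_unit * gaussian_filter(f, optics.psf_sigma_px)
    photons_mean = np.clip(photons_mean, 0.0, None)
    if not noise:
        return optics.offset_counts + optics.gain_counts_per_photon * photons_mean
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = optics.gain_counts_per_photon * rng.poisson(photons_mean).astype(float)
    if optics.read_noise_e > 0:
        counts += rng.normal(0.0, optics.read_noise_e * optics.gain_counts_per_photon,
                             size=counts.shape)
    return np.clip(optics.offset_counts + counts, 0.0, None)


def symmetric_z_count(half_range_um: float, dz_um: float) -> int:
    """Plane count of an inclusive symmetric z-range ±half_range at dz steps."""
    if dz_um <= 0 or half_range_um < 0:
        raise GenerationError("dz_um must be > 0 and half_range_um >= 0")
    return 2 * int(round(half_range_um / dz_um)) + 1


# ---------------------------------------------------------------------------
# Calcium recordings


def kernel_peak_time(rise_s: float, decay_s: float) -> float:
    """Argmax of the difference-of-exponentials kernel."""
    return rise_s * decay_s / (decay_s - rise_s) * math.log(decay_s / rise_s)


def calcium_kernel(t: np.ndarray, rise_s: float = 0.2, decay_s: float = 3.0) -> np.ndarray:
    """Difference-of-exponentials transient, normalized to unit peak; 0 for t<0."""
    if not 0 < rise_s < decay_s:
        raise GenerationError("need 0 < rise_s < decay_s")
    t = np.asarray(t, dtype=float)
    u = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / decay_s)
                 - np.exp(-np.clip(t, 0, None) / rise_s), 0.0)
    tp = kernel_peak_time(rise_s, decay_s)
    peak = math.exp(-tp / decay_s) - math.exp(-tp / rise_s)
    return u / peak


def kernel_area(rise_s: float = 0.2, decay_s: float = 3.0) -> float:
    """Integral of the unit-peak kernel over [0, inf)."""
    tp = kernel_peak_time(rise_s, decay_s)
    peak = math.exp(-tp / decay_s) - math.exp(-tp / rise_s)
    return (decay_s - rise_s) / peak


@dataclass
class MitoCalciumSpec:
    """Per-mitochondrion response description for the calcium generator."""

    amplitudes: Sequence[float]  # peak dF/F per stimulus
    response_class: str = "first-dominant"  # or "late-dominant"
    rise_s: float = 0.2
    decay_s: float = 3.0
    baseline: float = 100.0

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        if np.any(amps < 0):
            raise GenerationError("amplitudes must be >= 0")
        if len(amps) and np.any(amps > 0):
            dominant = int(np.argmax(amps))
            if self.response_class == "first-dominant" and dominant != 0:
                raise GenerationError("first-dominant spec must peak on stimulus 1")
            if self.response_class == "late-dominant" and dominant == 0:
                raise GenerationError("late-dominant spec must peak after stimulus 1")


def gen_calcium_recording(
    protocol: StimulationProtocol,
    mito_specs: Sequence[MitoCalciumSpec],
    noise_sd: float = 0.0,
    duration_s: float = 150.0,
    dt_s: float = 0.25,
    seed: int = 0,
    background: float = 50.0,
) -> tuple[list[FluorescenceTrace], GroundTruth]:
    """Simulate stimulus-locked calcium traces with known events.

    Each trace is ``baseline * (1 + sum_i a_i K(t - onset_i) + noise)`` with
    ``noise ~ N(0, noise_sd)`` in ΔF/F units, so event SNR is
    ``amplitude / noise_sd``.  Truth records onset, peak time, peak ΔF/F and
    analytic area of every event.
    """
    if protocol.onset_times_s[-1] >= duration_s:
        raise GenerationError("protocol does not fit within the recording duration")
    t = np.arange(0.0, duration_s, dt_s)
    truth = GroundTruth(
        scenario="calcium",
        seed=seed,
        params={"duration_s": duration_s, "dt_s": dt_s, "noise_sd": noise_sd,
                "n_stimuli": protocol.n_pulses},
    )
    traces = []
    for m, spec in enumerate(mito_specs):
        if dt_s >= spec.rise_s:
            raise SamplingError(
                f"dt_s={dt_s} too coarse for rise_s={spec.rise_s}; events undersampled"
            )
        signal = np.zeros_like(t)
        a_kernel = kernel_area(spec.rise_s, spec.decay_s)
        for i, (onset, amp) in enumerate(zip(protocol.onset_times_s, spec.amplitudes)):
            if amp <= 0:
                continue
            signal += amp * calcium_kernel(t - onset, spec.rise_s, spec.decay_s)
            truth.records.append({
                "source_id": f"mito{m:03d}",
                "stimulus_index": i,
                "onset_s": float(onset),
                "t_peak_s": float(onset + kernel_peak_time(spec.rise_s, spec.decay_s)),
                "peak_dff": float(amp),
                "area_dff_s": float(amp * a_kernel),
                "response_class": spec.response_class,
                "baseline": spec.baseline,
            })
        rng = substream(seed, 1, m)
        noise = rng.normal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else 0.0
        f_corr = spec.baseline * (1.0 + signal + noise)
        traces.append(
            FluorescenceTrace(
                t_s=t,
                f_raw=f_corr + background,
                f_bg=np.full_like(t, background),
                source_id=f"mito{m:03d}",
            )
        )
    return traces, truth


# ---------------------------------------------------------------------------
# roGFP dual-excitation scenes


def _gaussian_blob(shape: tuple[int, int], x0: float, y0: float,
                   sx_px: float, sy_px: float, cutoff_sigmas: float = 3.0) -> np.ndarray:
    """Elliptical Gaussian with hard compact support (zero beyond the cutoff
    radius), so well-separated objects never cross-talk in noiseless renders."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    r2 = (x - x0) ** 2 / (2 * sx_px**2) + (y - y0) ** 2 / (2 * sy_px**2)
    blob = np.exp(-r2)
    blob[r2 > cutoff_sigmas**2 / 2.0] = 0.0
    return blob


def gen_rogfp_scene(
    n_mito: int = 6,
    ratio_model: dict | None = None,
    optics: OpticsModel | None = None,
    seed: int = 0,
    noise: bool = True,
    shape: tuple[int, int] | None = None,
    n_z: int = 5,
    dz_um: float = 0.25,
    brightness488: float = 400.0,
    mito_sigma_um: tuple[float, float] = (0.45, 0.20),
    noiseless_background: float = 0.0,
) -> tuple[ImageStack, ImageStack, list[Roi], GroundTruth]:
    """Dual-excitation (405/488) z-stacks of elongated mitochondria.

    ``ratio_model`` is ``{"means": [...], "sds": [...], "weights": [...]}``;
    defaults to the unimodal resting population N(0.03, 0.01²).  Each
    mitochondrion carries a true background-corrected 405/488 ratio and a
    focal plane; both are recorded in truth.
    """
    if ratio_model is None:
        ratio_model = {"means": [0.03], "sds": [0.01], "weights": [1.0]}
    optics = optics or OpticsModel()
    if n_mito < 1:
        raise GenerationError("need n_mito >= 1")
    means = np.asarray(ratio_model["means"], dtype=float)
    sds = np.asarray(ratio_model["sds"], dtype=float)
    weights = np.asarray(ratio_model.get("weights", np.ones_like(means) / len(means)),
                         dtype=float)
    weights = weights / weights.sum()
    if np.any(means <= 0):
        raise GenerationError("ratio means must be positive")

    sx = mito_sigma_um[0] / optics.px_um
    sy = mito_sigma_um[1] / optics.px_um
    if sx <= 0 or sy <= 0:
        raise GenerationError("zero-area mitochondria")
    # spacing 9*sx keeps blob support (3 sigma) + PSF kernel support clear of
    # the 3.2*sx ROI half-width of every neighbour
    spacing = 9.0 * sx
    margin = 5.0 * sx
    if shape is None:
        shape = (48, int(np.ceil(2 * margin + (n_mito - 1) * spacing)) + 1)
    h, w = shape
    if w < 2 * margin + (n_mito - 1) * spacing:
        raise PlacementError("too many mitochondria for the field width")
    centers_x = np.linspace(margin, w - margin, n_mito) if n_mito > 1 else \
        np.array([w / 2.0])
    y0 = h * 0.62  # off-centre so background regions have room

    rng = substream(seed, 2)
    comp = rng.choice(len(means), size=n_mito, p=weights)
    ratios = np.abs(rng.normal(means[comp], sds[comp]))
    best_z = rng.integers(1, n_z - 1, size=n_mito) if n_z > 2 else np.zeros(n_mito, int)
    jitter = rng.uniform(-0.5, 0.5, size=n_mito) * sx

    fields405 = np.zeros((n_z, h, w))
    fields488 = np.zeros((n_z, h, w))
    truth = GroundTruth(
        scenario="rogfp", seed=seed,
        params={"n_mito": n_mito, "n_z": n_z, "ratio_model": ratio_model},
    )
    rois: list[Roi] = []
    for m in range(n_mito):
        x0 = centers_x[m] + jitter[m]
        blob = _gaussian_blob((h, w), x0, y0, sx, sy)
        for z in range(n_z):
            zfac = math.exp(-((z - best_z[m]) ** 2) / (2 * 1.0**2))
            fields488[z] += brightness488 * zfac * blob
            fields405[z] += ratios[m] * brightness488 * zfac * blob
        half_w = 3.2 * sx
        half_h = 3.2 * sy + 2
        sig = Roi(id=f"mito{m:03d}", kind="rectangle",
                  vertices=[(x0 - half_w, y0 - half_h), (x0 + half_w, y0 + half_h)],
                  background_id=f"bg{m:03d}")
        bg_y = h * 0.15
        bg = Roi(id=f"bg{m:03d}", kind="rectangle",
                 vertices=[(x0 - half_w, bg_y - 3), (x0 + half_w, bg_y + 3)])
        rois.extend([sig, bg])
        truth.records.append({
            "mito_id": f"mito{m:03d}",
            "ratio_true": float(ratios[m]),
            "best_z": int(best_z[m]),
            "x_px": float(x0),
            "y_px": float(y0),
            "component": int(comp[m]),
        })

    if noiseless_background:
        fields405 += noiseless_background
        fields488 += noiseless_background

    def _render(fields: np.ndarray, key: int) -> ImageStack:
        pages = np.stack([
            render_frame(fields[z], optics, substream(seed, key, z), noise=noise)
            for z in range(n_z)
        ])
        return ImageStack(pages=pages, axis_kind="z", px_um=optics.px_um, dz_um=dz_um)

    stack405 = _render(fields405, 3)
    stack488 = _render(fields488, 4)
    stack405.excitation_nm = 405
    stack488.excitation_nm = 488
    return stack405, stack488, rois, truth


# ---------------------------------------------------------------------------
# FRAP


def frap_curve(t_min: np.ndarray, f_pre: float, f0: float,
               plateau_pct: float, k_per_min: float) -> np.ndarray:
    """Recovery F(t) = F0 + (Fpre - F0) * (plateau/100) * (1 - exp(-k t))."""
    t_min = np.asarray(t_min, dtype=float)
    return f0 + (f_pre - f0) * (plateau_pct / 100.0) * (1.0 - np.exp(-k_per_min * t_min))


def gen_frap_experiment(
    k_per_min: float = 0.2,
    plateau_pct: float = 80.0,
    prebleach_level: float = 1000.0,
    bleach_residual_frac: float = 0.1,
    schedule_min: Sequence[float] | None = None,
    optics: OpticsModel | None = None,
    seed: int = 0,
    noise: bool = True,
    shape: tuple[int, int] = (64, 120),
    z_half_um: float = 2.5,
    dz_um: float = 0.25,
) -> tuple[list[ImageStack], Roi, Roi, GroundTruth]:
    """Pre/post-photobleach image-stack series with a known recovery law.

    Returns one z-stack per timepoint in schedule order (pre-bleach first),
    the measurement region, its paired background region, and the truth
    (k, plateau, Fpre, F0).  The default schedule is pre, 0, 2, ..., 16 min
    (10 stacks); z geometry defaults to an inclusive ±2.5 µm range at
    0.25 µm steps (21 planes).  Background-subtracted region means are
    exactly proportional to the recovery law on noiseless renders.
    """
    if not 0 <= plateau_pct <= 100:
        raise GenerationError("plateau_pct must be within [0, 100]")
    if k_per_min <= 0:
        raise GenerationError("k_per_min must be positive")
    optics = optics or OpticsModel()
    if schedule_min is None:
        schedule_min = [0.0] + list(np.arange(0.0, 16.0 + 1e-9, 2.0))
        is_pre = [True] + [False] * (len(schedule_min) - 1)
    else:
        is_pre = [True] + [False] * (len(schedule_min) - 1)
    h, w = shape
    n_z = symmetric_z_count(z_half_um, dz_um)

    # neurite stripe through the middle (hard 3-sigma support so background
    # rows stay exactly dark); bleach region is the central window
    y, x = np.mgrid[0:h, 0:w]
    stripe_sigma = 4.0
    stripe = np.exp(-((y - h / 2.0) ** 2) / (2 * stripe_sigma**2))
    stripe[np.abs(y - h / 2.0) > 3 * stripe_sigma] = 0.0
    bx0, bx1 = int(w * 0.25), int(w * 0.75)
    margin = int(np.ceil(4 * optics.psf_sigma_px)) + 2
    if bx1 - bx0 <= 2 * margin:
        raise GenerationError("bleach region too small for the PSF margin")
    bg_top = h / 2.0 - 3 * stripe_sigma - 5 * optics.psf_sigma_px - 3
    if bg_top < 3:
        raise GenerationError("image too short for a clean background band")
    region = Roi(id="bleach", kind="rectangle",
                 vertices=[(bx0 + margin, h / 2.0 - 2), (bx1 - margin, h / 2.0 + 2)],
                 background_id="bg")
    background = Roi(id="bg", kind="rectangle",
                     vertices=[(bx0 + margin, 1.0), (bx1 - margin, bg_top)])

    f_pre = prebleach_level
    f0 = bleach_residual_frac * prebleach_level
    truth = GroundTruth(
        scenario="frap", seed=seed,
        params={"k_per_min": k_per_min, "plateau_pct": plateau_pct,
                "f_pre": f_pre, "f0": f0,
                "mobile_fraction": plateau_pct / 100.0,
                "schedule_min": list(schedule_min), "background_roi_id": "bg"},
    )
    stacks = []
    for i, (t, pre) in enumerate(zip(schedule_min, is_pre)):
        level = f_pre if pre else float(frap_curve(np.array([t]), f_pre, f0,
                                                   plateau_pct, k_per_min)[0])
        fld = np.where((x >= bx0) & (x < bx1), level, f_pre) * stripe
        zfac = np.exp(-np.linspace(-1.0, 1.0, n_z) ** 2 / (2 * 0.8**2))
        pages = np.stack([
            render_frame(fld * zf, optics, substream(seed, 5, i, z), noise=noise)
            for z, zf in enumerate(zfac)
        ])
        stacks.append(ImageStack(pages=pages, axis_kind="z", px_um=optics.px_um,
                                 dz_um=dz_um))
        truth.records.append({"timepoint_index": i, "t_min": float(t),
                              "is_pre": bool(pre), "level": level})
    return stacks, region, background, truth


# ---------------------------------------------------------------------------
# Transport streams


@dataclass
class ParticleSpec:
    """Kinematics of one simulated particle on the neurite axis."""

    v_um_s: float  # speed (>=0)
    direction: int = 1  # +1 anterograde, -1 retrograde
    start_pos_um: float = 0.0
    pauses: list[tuple[float, float]] = dc_field(default_factory=list)
    motile: bool = True
    brightness: float = 300.0

    def position_um(self, t_s: np.ndarray) -> np.ndarray:
        """Closed-form axial position with pauses frozen out."""
        t_s = np.asarray(t_s, dtype=float)
        if not self.motile or self.v_um_s == 0:
            return np.full_like(t_s, self.start_pos_um)
        moving_time = t_s.copy()
        for p0, p1 in self.pauses:
            moving_time = moving_time - np.clip(moving_time - p0, 0, p1 - p0)
        return self.start_pos_um + self.direction * self.v_um_s * moving_time


def gen_transport_stream(
    particles: Sequence[ParticleSpec],
    length_um: float = 40.0,
    duration_s: float = 20.0,
    dt_s: float = 0.2,
    optics: OpticsModel | None = None,
    seed: int = 0,
    noise: bool = True,
    background_brightness: float = 2.0,
    height_px: int = 21,
    spot_sigma_um: float = 0.25,
    width_px: int = 9,
) -> tuple[ImageStack, NeuritePath, GroundTruth]:
    """Image stream of motile/stationary spots on a photobleached neurite."""
    if dt_s <= 0:
        raise GenerationError("dt_s must be positive")
    optics = optics or OpticsModel()
    px = optics.px_um
    w = int(round(length_um / px))
    h = height_px
    n_frames = int(round(duration_s / dt_s))
    t = np.arange(n_frames) * dt_s
    y0 = h // 2
    manifest_warnings = []
    for i, p in enumerate(particles):
        if not 0 <= p.start_pos_um <= length_um:
            raise GenerationError(f"particle {i} starts outside the neurite")
        if p.v_um_s * dt_s > 2.0 * optics.psf_sigma_um + 0.5:
            manifest_warnings.append(
                f"particle {i}: step {p.v_um_s * dt_s:.2f} um/frame may exceed "
                "the resolvable tracking step"
            )

    truth = GroundTruth(
        scenario="transport", seed=seed,
        params={"length_um": length_um, "duration_s": duration_s, "dt_s": dt_s,
                "n_frames": n_frames, "warnings": manifest_warnings},
    )
    positions = []
    for i, p in enumerate(particles):
        pos = p.position_um(t)
        positions.append(pos)
        inside = (pos >= 0) & (pos <= length_um)
        net = float(pos[inside][-1] - pos[inside][0]) if np.any(inside) else 0.0
        truth.records.append({
            "particle_id": i,
            "v_um_s": p.v_um_s,
            "direction": p.direction,
            "start_pos_um": p.start_pos_um,
            "motile": p.motile,
            "net_displacement_um": net,
            "n_pauses": len(p.pauses),
            "pause_time_s": float(sum(p1 - p0 for p0, p1 in p.pauses)),
        })

    sy = spot_sigma_um / px
    frames = np.empty((n_frames, h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for f in range(n_frames):
        fld = np.full((h, w), background_brightness, dtype=float)
        for i, p in enumerate(particles):
            x0 = positions[i][f] / px
            if -4 * sy <= x0 <= w + 4 * sy:
                fld += p.brightness * np.exp(
                    -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sy**2)
                )
        frames[f] = render_frame(fld, optics, substream(seed, 6, f), noise=noise)

    stream = ImageStack(pages=frames, axis_kind="time", px_um=px, dt_s=dt_s)
    path = NeuritePath(points=[(0.0, float(y0)), (float(w - 1), float(y0))],
                       width_px=width_px)
    return stream, path, truth


# ---------------------------------------------------------------------------
# Proximity scenes


def place_axial_objects(
    n_mito: int,
    n_puncta: int,
    target_fraction_within_1um: float,
    length_um: float,
    seed: int = 0,
    proximal_gap_um: tuple[float, float] = (0.2, 0.8),
    guard_um: float = 1.5,
    mito_len_um: tuple[float, float] = (1.0, 2.0),
    punctum_len_um: tuple[float, float] = (0.4, 0.8),
    max_tries: int = 50,
) -> tuple[list[dict], list[dict], list[dict]]:
    """Place mito and punctum intervals on [0, length_um] with an exact
    proximal count.

    Exactly ``round(target * n_mito)`` mitochondria get a punctum at a
    boundary gap inside ``proximal_gap_um`` (< 1 µm); every other mito is at
    least ``guard_um`` from any punctum.  Returns (mitos, puncta, truth rows).
    """
    if not 0 <= target_fraction_within_1um <= 1:
        raise GenerationError("target fraction must be within [0, 1]")
    if n_puncta < 1 and target_fraction_within_1um > 0:
        raise GenerationError("need puncta to create proximal mitochondria")
    n_prox = int(round(target_fraction_within_1um * n_mito))
    if n_prox > n_puncta:
        raise PlacementError(
            f"need >= {n_prox} puncta for {n_prox} proximal mitochondria"
        )
    rng = substream(seed, 7)
    for attempt in range(max_tries):
        # build placement units left-to-right with inter-unit gap >= guard
        units = (["pair"] * n_prox
                 + ["mito"] * (n_mito - n_prox)
                 + ["punctum"] * (n_puncta - n_prox))
        rng.shuffle(units)
        cursor = rng.uniform(0.5, 1.5)
        mitos, puncta = [], []
        ok = True
        for u in units:
            if u in ("pair", "mito"):
                mlen = rng.uniform(*mito_len_um)
            plen = rng.uniform(*punctum_len_um)
            if u == "pair":
                gap = rng.uniform(*proximal_gap_um)
                p_iv = (cursor, cursor + plen)
                m_iv = (p_iv[1] + gap, p_iv[1] + gap + mlen)
                puncta.append(p_iv)
                mitos.append((m_iv, True, gap))
                cursor = m_iv[1]
            elif u == "mito":
                m_iv = (cursor, cursor + mlen)
                mitos.append((m_iv, False, None))
                cursor = m_iv[1]
            else:
                p_iv = (cursor, cursor + plen)
                puncta.append(p_iv)
                cursor = p_iv[1]
            cursor += guard_um + rng.uniform(0.1, 0.6)
            if cursor > length_um:
                ok = False
                break
        if ok:
            break
    else:
        raise PlacementError(
            f"could not place {n_mito} mitos + {n_puncta} puncta on {length_um} um"
        )
    if not ok:
        raise PlacementError(
            f"could not place {n_mito} mitos + {n_puncta} puncta on {length_um} um"
        )

    puncta_rows = [{"id": f"p{j:03d}", "channel": "puncta",
                    "s_start_um": float(a), "s_end_um": float(b)}
                   for j, (a, b) in enumerate(puncta)]
    mito_rows, truth_rows = [], []
    for j, ((a, b), prox, gap) in enumerate(mitos):
        mito_rows.append({"id": f"m{j:03d}", "channel": "mito",
                          "s_start_um": float(a), "s_end_um": float(b)})
        dist = min(
            (max(pa - b, a - pb, 0.0) for pa, pb in puncta), default=float("inf")
        )
        truth_rows.append({"mito_id": f"m{j:03d}", "s_start_um": float(a),
                           "s_end_um": float(b), "nearest_gap_um": float(dist),
                           "proximal": bool(prox)})
        if prox and not dist < 1.0:
            raise PlacementError("internal error: proximal mito placed >= 1 um away")
        if not prox and dist < guard_um - 1e-9:
            raise PlacementError("internal error: guard band violated")
    return mito_rows, puncta_rows, truth_rows


def gen_proximity_scene(
    n_mito: int = 20,
    n_puncta: int | None = None,
    target_fraction_within_1um: float = 0.61,
    length_um: float | None = None,
    optics: OpticsModel | None = None,
    seed: int = 0,
    noise: bool = True,
    render: bool = True,
    height_px: int = 25,
    mito_brightness: float = 300.0,
    puncta_brightness: float = 300.0,
) -> tuple[ImageStack | None, ImageStack | None, NeuritePath, GroundTruth]:
    """Two-channel scene (mitochondria, receptor puncta) along a neurite with
    a controlled fraction of mitochondria within 1 µm of a punctum.

    With ``render=False`` only the path and truth (with object intervals in
    the params) are produced, for fast placement-level studies.
    """
    optics = optics or OpticsModel()
    if n_puncta is None:
        n_puncta = max(int(round(target_fraction_within_1um * n_mito)), 1)
    if length_um is None:
        length_um = 7.0 * (n_mito + max(n_puncta - n_mito, 0)) + 10.0
    mitos, puncta, truth_rows = place_axial_objects(
        n_mito, n_puncta, target_fraction_within_1um, length_um, seed=seed
    )
    truth = GroundTruth(
        scenario="proximity", seed=seed,
        params={"n_mito": n_mito, "n_puncta": n_puncta,
                "target_fraction": target_fraction_within_1um,
                "length_um": length_um, "mitos": mitos, "puncta": puncta},
        records=truth_rows,
    )
    px = optics.px_um
    w = int(round(length_um / px))
    y0 = height_px // 2
    path = NeuritePath(points=[(0.0, float(y0)), (float(w - 1), float(y0))],
                       width_px=9)
    if not render:
        return None, None, path, truth

    def _field(objs: list[dict]) -> np.ndarray:
        # axial box profile with subpixel edge coverage: after PSF blur the
        # half-maximum crossings sit exactly at the interval boundaries
        fld = np.zeros((height_px, w))
        yy, xx = np.mgrid[0:height_px, 0:w]
        transverse = np.exp(-((yy[:, 0] - y0) ** 2) / (2 * (0.12 / px) ** 2))
        x = np.arange(w, dtype=float)
        for o in objs:
            a, b = o["s_start_um"] / px, o["s_end_um"] / px
            coverage = np.clip(np.minimum(b, x + 0.5) - np.maximum(a, x - 0.5),
                               0.0, 1.0)
            fld += transverse[:, None] * coverage[None, :]
        return fld

    stack_mito = ImageStack(
        pages=render_frame(mito_brightness * _field(mitos), optics,
                           substream(seed, 8, 0), noise=noise)[None],
        axis_kind="z", px_um=px, dz_um=1.0,
    )
    stack_puncta = ImageStack(
        pages=render_frame(puncta_brightness * _field(puncta), optics,
                           substream(seed, 8, 1), noise=noise)[None],
        axis_kind="z", px_um=px, dz_um=1.0,
    )
    return stack_mito, stack_puncta, path, truth
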