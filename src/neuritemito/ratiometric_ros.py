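"""Per-mitochondrion roGFP ratiometry (405/488 excitation) and
population-level unimodal/bimodal analysis.

The measured quantity per mitochondrion is the background-corrected
excitation ratio ``(F405 - B405) / (F488 - B488)``, evaluated at the single
z-plane where that object's 488-excited signal is highest.  Higher ratios
indicate more oxidation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

from .imaging_io import ImageStack, Roi, ValidationError

__all__ = [
    "RatioMeasurement",
    "ModalityReport",
    "RegistrationError",
    "InsufficientDataError",
    "segment_mitochondria",
    "measure_ratio",
    "population_modality",
]


class RegistrationError(ValueError):
    """The two excitation stacks do not share a common geometry."""


class InsufficientDataError(ValueError):
    """Too few valid ratios for a population-level analysis."""


@dataclass
class RatioMeasurement:
    """Background-corrected 405/488 ratio for one mitochondrion."""

    mito_id: str
    z_index: int
    F405: float
    F488: float
    B405: float
    B488: float
    f_ratio: float
    valid: bool

    def to_dict(self) -> dict:
        return {
            "mito_id": self.mito_id, "z_index": self.z_index,
            "F405": self.F405, "B405": self.B405,
            "F488": self.F488, "B488": self.B488,
            "f_ratio": self.f_ratio, "valid": self.valid,
        }


@dataclass
class ModalityReport:
    """BIC-selected 1- vs 2-component Gaussian-mixture description."""

    n_components: int
    component_means: list[float]
    component_sds: list[float]
    weights: list[float]
    bic_1: float
    bic_2: float

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "component_means": self.component_means,
            "component_sds": self.component_sds,
            "weights": self.weights,
            "bic_1": self.bic_1,
            "bic_2": self.bic_2,
        }


def segment_mitochondria(
    stack488: ImageStack,
    smooth_sigma_px: float = 1.0,
    min_area_px: int = 9,
    background_inner_px: int = 2,
    background_width_px: int = 3,
) -> list[tuple[Roi, Roi, int]]:
    """Find bright objects in a 488-excited z-stack.

    Segmentation runs on the maximum-intensity projection (Gaussian smooth +
    Otsu threshold + connected components), then each object's best z-plane
    is the one maximizing its mean 488 signal.  A background annulus
    (distance ``background_inner_px``, width ``background_width_px``, clipped
    away from every segmented object) is paired with each object.

    Returns ``[(signal_roi, background_roi, best_z), ...]``.  Objects that
    touch end-to-end within the smoothing scale merge — a documented
    limitation of connected-component labelling.
    """
    if stack488.axis_kind != "z" or stack488.n_pages < 3:
        raise ValidationError("segmentation expects a z-stack with >= 3 planes")
    proj = stack488.pages.max(axis=0).astype(float)
    sm = gaussian(proj, sigma=smooth_sigma_px, preserve_range=True)
    if np.ptp(sm) == 0:
        return []
    # Otsu splits pure noise too; floor the threshold at a robust noise level
    med = float(np.median(sm))
    sd_rob = 1.4826 * float(np.median(np.abs(sm - med)))
    thr = max(threshold_otsu(sm), med + 4.0 * sd_rob)
    mask = sm > thr
    labels = label(mask)
    all_objects = labels > 0
    results = []
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        obj_mask = labels == prop.label
        per_z = [float(page[obj_mask].mean()) for page in stack488.pages]
        best_z = int(np.argmax(per_z))
        ys, xs = np.nonzero(obj_mask)
        sig = Roi(id=f"mito{prop.label:03d}", kind="rectangle",
                  vertices=[(float(xs.min()), float(ys.min())),
                            (float(xs.max()), float(ys.max()))],
                  background_id=f"bg{prop.label:03d}")
        inner = ndimage.binary_dilation(obj_mask, iterations=background_inner_px)
        outer = ndimage.binary_dilation(
            inner, iterations=background_width_px)
        annulus = outer & ~inner & ~ndimage.binary_dilation(
            all_objects, iterations=background_inner_px)
        if not np.any(annulus):
            annulus = outer & ~inner
        ys_b, xs_b = np.nonzero(annulus)
        bg = Roi(id=f"bg{prop.label:03d}", kind="rectangle",
                 vertices=[(float(xs_b.min()), float(ys_b.min())),
                           (float(xs_b.max()), float(ys_b.max()))])
        # keep the exact annulus mask for measurement fidelity
        bg._mask_override = annulus  # type: ignore[attr-defined]
        sig._mask_override = obj_mask  # type: ignore[attr-defined]
        results.append((sig, bg, best_z))
    return results


def _roi_mask(roi: Roi, shape: tuple[int, int]) -> np.ndarray:
    override = getattr(roi, "_mask_override", None)
    return override if override is not None else roi.mask(shape)


def measure_ratio(
    stack405: ImageStack,
    stack488: ImageStack,
    roi: Roi,
    background_roi: Roi,
    best_z: int,
    noise_floor_sds: float = 3.0,
) -> RatioMeasurement:
    """Background-corrected 405/488 ratio at one object's best z-plane.

    The measurement is invalid (ratio NaN) when the background-corrected 488
    signal does not exceed ``noise_floor_sds`` background SDs.
    """
    if stack405.pages.shape != stack488.pages.shape:
        raise RegistrationError(
            f"stack geometries differ: {stack405.pages.shape} vs {stack488.pages.shape}"
        )
    shape = stack405.shape
    sig_mask = _roi_mask(roi, shape)
    bg_mask = _roi_mask(background_roi, shape)
    if not sig_mask.any() or not bg_mask.any():
        raise ValidationError("roi produces an empty pixel mask")
    p405, p488 = stack405.pages[best_z].astype(float), stack488.pages[best_z].astype(float)
    F405 = float(p405[sig_mask].mean())
    F488 = float(p488[sig_mask].mean())
    B405 = float(p405[bg_mask].mean())
    B488 = float(p488[bg_mask].mean())
    bg_sd = float(p488[bg_mask].std(ddof=1)) if bg_mask.sum() > 1 else 0.0
    denom = F488 - B488
    valid = denom > noise_floor_sds * bg_sd and denom > 0
    ratio = (F405 - B405) / denom if valid else float("nan")
    return RatioMeasurement(mito_id=roi.id, z_index=int(best_z),
                            F405=F405, F488=F488, B405=B405, B488=B488,
                            f_ratio=ratio, valid=bool(valid))


def population_modality(
    ratios: np.ndarray,
    seed: int = 0,
    n_init: int = 5,
    min_n: int = 20,
) -> ModalityReport:
    """Decide whether a ratio population is unimodal or bimodal.

    One- and two-component Gaussian mixtures are fitted by EM (multi-start,
    deterministic seed) and compared by BIC; the lower BIC wins.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(ratios, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_n:
        raise InsufficientDataError(f"need >= {min_n} valid ratios, got {len(x)}")
    if np.ptp(x) == 0 or np.std(x) == 0:
        raise InsufficientDataError("degenerate (zero-variance) ratio population")
    X = x[:, None]
    gm1 = GaussianMixture(1, n_init=1, random_state=seed).fit(X)
    gm2 = GaussianMixture(2, n_init=n_init, random_state=seed,
                          reg_covar=1e-10).fit(X)
    if not (gm1.converged_ and gm2.converged_):
        raise RuntimeError("EM failed to converge after restarts")
    bic1, bic2 = float(gm1.bic(X)), float(gm2.bic(X))
    best = gm1 if bic1 <= bic2 else gm2
    means = best.means_.ravel()
    order = np.argsort(means)
    return ModalityReport(
        n_components=int(best.n_components),
        component_means=[float(m) for m in means[order]],
        component_sds=[float(s) for s in np.sqrt(best.covariances_.ravel())[order]],
        weights=[float(w) for w in best.weights_[order]],
        bic_1=bic1,
        bic_2=bic2,
    )
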