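"""Calibrated image-stack, ROI, neurite-path and stimulation-protocol I/O.

Conventions
-----------
* Pixel coordinates are 0-based and pixel-centred; ``x`` indexes columns and
  ``y`` indexes rows.  All micrometre quantities derive from ``px_um``.
* Stacks are plain multi-page baseline TIFF, 16-bit unsigned.  Calibration
  metadata travels in a JSON sidecar (``<stack>.json``) so the TIFF itself
  stays maximally interoperable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "Roi",
    "NeuritePath",
    "StimulationProtocol",
    "FormatError",
    "ConfigurationError",
    "RangeError",
    "ValidationError",
    "read_stack",
    "write_stack",
    "load_rois",
    "save_rois",
    "load_path",
    "save_path",
    "load_protocol",
    "save_protocol",
]


class FormatError(ValueError):
    """Malformed image file (e.g. non-uniform page dimensions)."""


class ConfigurationError(ValueError):
    """Missing or inconsistent calibration metadata."""


class RangeError(ValueError):
    """Intensity outside the representable 16-bit range."""


class ValidationError(ValueError):
    """ROI / path / protocol document violates its schema or invariants."""


@dataclass
class ImageStack:
    """An ordered stack of 2-D grayscale pages with spatial calibration.

    ``axis_kind`` declares whether pages advance in time (``dt_s`` set) or
    depth (``dz_um`` set); exactly one of the two step sizes may be present.
    """

    pages: np.ndarray  # (n_pages, h, w) float64 or uint16, intensities >= 0
    axis_kind: Literal["time", "z"]
    px_um: float
    dt_s: float | None = None
    dz_um: float | None = None
    exposure_ms: float | None = None
    excitation_nm: int | None = None

    def __post_init__(self) -> None:
        self.pages = np.asarray(self.pages)
        if self.pages.ndim == 2:
            self.pages = self.pages[None]
        if self.pages.ndim != 3:
            raise FormatError(
                f"pages must form a (n, h, w) array, got shape {self.pages.shape}"
            )
        if not self.px_um > 0:
            raise ConfigurationError(f"px_um must be positive, got {self.px_um}")
        if self.axis_kind == "time":
            if self.dt_s is None or self.dz_um is not None:
                raise ConfigurationError("time-axis stack requires dt_s and no dz_um")
            if not self.dt_s > 0:
                raise ConfigurationError(f"dt_s must be positive, got {self.dt_s}")
        elif self.axis_kind == "z":
            if self.dz_um is None or self.dt_s is not None:
                raise ConfigurationError("z-axis stack requires dz_um and no dt_s")
            if not self.dz_um > 0:
                raise ConfigurationError(f"dz_um must be positive, got {self.dz_um}")
        else:
            raise ConfigurationError(f"axis_kind must be 'time' or 'z', got {self.axis_kind!r}")
        if np.min(self.pages) < 0:
            raise FormatError("negative intensities are not allowed")

    @property
    def n_pages(self) -> int:
        return int(self.pages.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each page."""
        return int(self.pages.shape[1]), int(self.pages.shape[2])

    @property
    def axial_span_um(self) -> float:
        """Axial extent of a z-stack: (n_pages - 1) * dz_um."""
        if self.axis_kind != "z":
            raise ConfigurationError("axial span is defined for z-axis stacks only")
        return (self.n_pages - 1) * float(self.dz_um)

    @property
    def duration_s(self) -> float:
        if self.axis_kind != "time":
            raise ConfigurationError("duration is defined for time-axis stacks only")
        return self.n_pages * float(self.dt_s)

    def metadata(self) -> dict:
        md = {"axis_kind": self.axis_kind, "px_um": self.px_um}
        for key in ("dt_s", "dz_um", "exposure_ms", "excitation_nm"):
            value = getattr(self, key)
            if value is not None:
                md[key] = value
        return md

    def with_pages(self, pages: np.ndarray) -> "ImageStack":
        return replace(self, pages=pages)


@dataclass
class Roi:
    """Rectangle or polygon region with an optional paired background region."""

    id: str
    kind: Literal["rectangle", "polygon"]
    vertices: list[tuple[float, float]]
    background_id: str | None = None

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if self.kind == "rectangle":
            if len(self.vertices) != 2:
                raise ValidationError(
                    f"rectangle roi {self.id!r} needs exactly 2 corners, got {len(self.vertices)}"
                )
            (x0, y0), (x1, y1) = self.vertices
            if x0 == x1 or y0 == y1:
                raise ValidationError(f"rectangle roi {self.id!r} has zero area")
        elif self.kind == "polygon":
            if len(self.vertices) < 3:
                raise ValidationError(
                    f"polygon roi {self.id!r} needs >=3 vertices, got {len(self.vertices)}"
                )
            if self._polygon_area() <= 0:
                raise ValidationError(f"polygon roi {self.id!r} has zero area")
        else:
            raise ValidationError(f"roi kind must be rectangle or polygon, got {self.kind!r}")

    def _polygon_area(self) -> float:
        v = np.asarray(self.vertices)
        x, y = v[:, 0], v[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max)."""
        v = np.asarray(self.vertices)
        return (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask of the region on an (h, w) grid."""
        h, w = shape
        if self.kind == "rectangle":
            x0, y0, x1, y1 = self.bounds()
            mask = np.zeros((h, w), dtype=bool)
            r0, r1 = int(np.ceil(y0 - 0.5)), int(np.floor(y1 + 0.5))
            c0, c1 = int(np.ceil(x0 - 0.5)), int(np.floor(x1 + 0.5))
            mask[max(r0, 0): min(r1 + 1, h), max(c0, 0): min(c1 + 1, w)] = True
            return mask
        from skimage.draw import polygon2mask

        v = np.asarray(self.vertices)
        return polygon2mask((h, w), v[:, ::-1])  # polygon2mask wants (row, col)

    def to_dict(self) -> dict:
        d = {"id": self.id, "kind": self.kind, "vertices": [list(v) for v in self.vertices]}
        if self.background_id is not None:
            d["background_id"] = self.background_id
        return d


@dataclass
class NeuritePath:
    """Ordered polyline along a neurite with a perpendicular averaging width."""

    points: list[tuple[float, float]]
    width_px: int = 20

    def __post_init__(self) -> None:
        self.points = [(float(x), float(y)) for x, y in self.points]
        if len(self.points) < 2:
            raise ValidationError("path needs >=2 points")
        for a, b in zip(self.points[:-1], self.points[1:]):
            if a == b:
                raise ValidationError("consecutive path points must be distinct")
        self.width_px = int(self.width_px)
        if self.width_px < 1:
            raise ValidationError(f"width_px must be >=1, got {self.width_px}")

    def length_px(self) -> float:
        v = np.asarray(self.points)
        return float(np.sum(np.hypot(*np.diff(v, axis=0).T)))

    def length_um(self, px_um: float) -> float:
        return self.length_px() * px_um

    def resample(self, spacing_px: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Arc-length resampling.

        Returns ``(samples, normals)``: (n, 2) x/y positions spaced
        ``spacing_px`` apart along the polyline and the unit normal at each.
        """
        v = np.asarray(self.points)
        seg = np.diff(v, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        n = max(int(np.floor(total / spacing_px)) + 1, 2)
        s = np.linspace(0.0, total, n)
        xs = np.interp(s, cum, v[:, 0])
        ys = np.interp(s, cum, v[:, 1])
        samples = np.column_stack([xs, ys])
        # tangents by central differences, normals by 90 deg rotation
        tang = np.gradient(samples, axis=0)
        norm = np.hypot(tang[:, 0], tang[:, 1])
        norm[norm == 0] = 1.0
        tang = tang / norm[:, None]
        normals = np.column_stack([-tang[:, 1], tang[:, 0]])
        return samples, normals

    def to_dict(self) -> dict:
        return {"points": [list(p) for p in self.points], "width_px": self.width_px}


@dataclass
class StimulationProtocol:
    """Timing of a pulsed stimulation protocol.

    A periodic protocol (1-s pulse every 30 s) has ``frequency_mHz`` of
    1000/30 = 33.3 mHz.
    """

    pulse_duration_s: float
    period_s: float | None = None
    total_duration_s: float | None = None
    onset_times_s: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pulse_duration_s > 0:
            raise ValidationError("pulse_duration_s must be positive")
        if self.period_s is not None:
            if not self.period_s > 0:
                raise ValidationError("period_s must be positive")
            if self.pulse_duration_s >= self.period_s:
                raise ValidationError("pulse_duration_s must be < period_s")
            if not self.onset_times_s:
                if self.total_duration_s is None:
                    raise ValidationError("periodic protocol needs total_duration_s")
                n = int(np.ceil(self.total_duration_s / self.period_s))
                self.onset_times_s = [i * self.period_s for i in range(n)]
        if not self.onset_times_s:
            raise ValidationError("protocol has no pulses")
        onsets = np.asarray(self.onset_times_s, dtype=float)
        if np.any(np.diff(onsets) <= 0):
            raise ValidationError("onset_times_s must be strictly increasing")
        self.onset_times_s = [float(t) for t in onsets]
        if self.total_duration_s is None:
            last = self.onset_times_s[-1]
            self.total_duration_s = last + (self.period_s or self.pulse_duration_s)

    @property
    def n_pulses(self) -> int:
        return len(self.onset_times_s)

    @property
    def frequency_mHz(self) -> float:
        """Pulse repetition frequency in millihertz (periodic protocols)."""
        if self.period_s is None:
            raise ValidationError("frequency is defined for periodic protocols only")
        return 1000.0 / self.period_s

    def to_dict(self) -> dict:
        d = {"pulse_duration_s": self.pulse_duration_s, "onset_times_s": list(self.onset_times_s)}
        if self.period_s is not None:
            d["period_s"] = self.period_s
        if self.total_duration_s is not None:
            d["total_duration_s"] = self.total_duration_s
        return d


# ---------------------------------------------------------------------------
# TIFF stacks


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page 16-bit TIFF plus a JSON calibration sidecar.

    Raises :class:`RangeError` if any intensity exceeds the uint16 range —
    values are never silently clipped.
    """
    path = Path(path)
    pages = np.asarray(stack.pages)
    if np.max(pages, initial=0) > np.iinfo(np.uint16).max:
        raise RangeError(
            f"intensity {np.max(pages):g} exceeds 16-bit range; rescale before writing"
        )
    if np.min(pages, initial=0) < 0:
        raise RangeError("negative intensity cannot be written as uint16")
    data = np.rint(pages).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    _sidecar(path).write_text(json.dumps(stack.metadata(), indent=1))


def read_stack(path: str | Path, calibration: Mapping | None = None) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    ``calibration`` supplies / overrides metadata absent from the sidecar;
    required keys are ``px_um`` plus ``dt_s`` or ``dz_um`` (with matching
    ``axis_kind``).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) != 1:
            raise FormatError(f"non-uniform page dimensions in {path}: {sorted(shapes)}")
        pages = tif.asarray()
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"{path} is not a grayscale multi-page stack (shape {pages.shape})")

    md: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        md.update(json.loads(sidecar.read_text()))
    if calibration:
        md.update(calibration)
    if "axis_kind" not in md:
        md["axis_kind"] = "time" if "dt_s" in md else "z" if "dz_um" in md else None
    if md.get("axis_kind") is None or "px_um" not in md:
        raise ConfigurationError(
            f"missing calibration for {path}: need px_um and dt_s/dz_um"
        )
    kwargs = {k: md[k] for k in ("dt_s", "dz_um", "exposure_ms", "excitation_nm") if k in md}
    return ImageStack(pages=pages, axis_kind=md["axis_kind"], px_um=md["px_um"], **kwargs)


# ---------------------------------------------------------------------------
# JSON documents


def load_rois(path: str | Path) -> list[Roi]:
    doc = json.loads(Path(path).read_text())
    rois = [Roi(**entry) for entry in doc["rois"]]
    ids = {r.id for r in rois}
    if len(ids) != len(rois):
        raise ValidationError("duplicate roi ids")
    for r in rois:
        if r.background_id is not None and r.background_id not in ids:
            raise ValidationError(
                f"roi {r.id!r} references missing background roi {r.background_id!r}"
            )
    return rois


def save_rois(rois: Sequence[Roi], path: str | Path) -> None:
    Path(path).write_text(json.dumps({"rois": [r.to_dict() for r in rois]}, indent=1))


def load_path(path: str | Path) -> NeuritePath:
    doc = json.loads(Path(path).read_text())
    return NeuritePath(points=doc["points"], width_px=doc.get("width_px", 20))


def save_path(neurite: NeuritePath, path: str | Path) -> None:
    Path(path).write_text(json.dumps(neurite.to_dict(), indent=1))


def load_protocol(path: str | Path) -> StimulationProtocol:
    doc = json.loads(Path(path).read_text())
    return StimulationProtocol(
        pulse_duration_s=doc["pulse_duration_s"],
        period_s=doc.get("period_s"),
        total_duration_s=doc.get("total_duration_s"),
        onset_times_s=doc.get("onset_times_s", []),
    )


def save_protocol(protocol: StimulationProtocol, path: str | Path) -> None:
    Path(path).write_text(json.dumps(protocol.to_dict(), indent=1))
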