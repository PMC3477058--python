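"""Domain types shared by the fundus and OCT pipelines.

All rasters are float64 numpy arrays with values in [0, 1]; coordinates are
0-based ``(row, col)`` with rows increasing downward.  Geometry around the
macula is expressed in pixels, with the optic-disc diameter (ODD) serving as
the anatomical distance unit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure

from .exceptions import InvalidImageError, ParameterError

MIN_IMAGE_SIDE = 64  # detectors are meaningless on smaller rasters


def _check_raster(pixels: np.ndarray, ndim: int, name: str) -> np.ndarray:
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != ndim:
        raise InvalidImageError(f"{name}: expected {ndim}-D raster, got {arr.ndim}-D")
    if not np.all(np.isfinite(arr)):
        raise InvalidImageError(f"{name}: non-finite pixel values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise InvalidImageError(
            f"{name}: values outside [0, 1] (min={arr.min():.4g}, max={arr.max():.4g})"
        )
    return arr


@dataclass(frozen=True)
class RgbImage:
    """Color fundus photograph, H x W x 3, values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        arr = _check_raster(self.pixels, 3, "RgbImage")
        if arr.shape[2] != 3:
            raise InvalidImageError("RgbImage: last axis must have size 3")
        if arr.shape[0] < MIN_IMAGE_SIDE or arr.shape[1] < MIN_IMAGE_SIDE:
            raise InvalidImageError(
                f"RgbImage: minimum size is {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
            )
        object.__setattr__(self, "pixels", arr)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def red(self) -> np.ndarray:
        return self.pixels[..., 0]

    @property
    def green(self) -> np.ndarray:
        return self.pixels[..., 1]

    @property
    def blue(self) -> np.ndarray:
        return self.pixels[..., 2]


@dataclass(frozen=True)
class GrayImage:
    """Single-channel raster in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        arr = _check_raster(self.pixels, 2, "GrayImage")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class OctImage:
    """Grayscale OCT B-scan: rows = depth, columns = lateral position.

    ``axial_um_per_px`` is the depth calibration (default 6 um per pixel).
    """

    pixels: np.ndarray
    axial_um_per_px: float = 6.0

    def __post_init__(self):
        arr = _check_raster(self.pixels, 2, "OctImage")
        if self.axial_um_per_px <= 0:
            raise ParameterError("axial_um_per_px must be positive")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Component:
    """One connected component of a binary mask."""

    label: int
    area_px: int
    centroid_rc: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open


@dataclass(frozen=True)
class LesionMask:
    """Binary raster plus its connected-component table (8-connectivity)."""

    mask: np.ndarray
    components: tuple[Component, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if self.components is None:
            object.__setattr__(self, "components", tuple(label_components(mask)))
        total = sum(c.area_px for c in self.components)
        if total != int(mask.sum()):
            raise InvalidImageError(
                f"LesionMask: component areas ({total}) != mask pixel count ({int(mask.sum())})"
            )

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


def label_components(mask: np.ndarray) -> list[Component]:
    """8-connected component table of a binary mask."""
    labeled = measure.label(np.asarray(mask, bool), connectivity=2)
    out = []
    for rp in measure.regionprops(labeled):
        out.append(
            Component(
                label=int(rp.label),
                area_px=int(rp.area),
                centroid_rc=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox=tuple(int(v) for v in rp.bbox),
            )
        )
    return out


@dataclass(frozen=True)
class OpticDisc:
    """Localized optic disc: center, diameter (ODD) and boundary mask."""

    center_rc: tuple[float, float]
    odd_px: float
    mask: np.ndarray

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if self.odd_px <= 0:
            raise ParameterError("OpticDisc: odd_px must be positive")
        r, c = (int(round(v)) for v in self.center_rc)
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
            raise InvalidImageError("OpticDisc: center must lie inside the disc mask")
        if measure.label(mask, connectivity=2).max() != 1:
            raise InvalidImageError("OpticDisc: mask must be a single connected component")


@dataclass(frozen=True)
class FoveaRegion:
    """Fovea landmark; the macular region is the disc of ``radius_px`` around it."""

    center_rc: tuple[float, float]
    radius_px: float

    def __post_init__(self):
        if self.radius_px <= 0:
            raise ParameterError("FoveaRegion: radius_px must be positive")


@dataclass(frozen=True)
class MorphScales:
    """Structuring-element sizes (diameters, px) for the fundus morphology chain.

    s1/s2 drive vessel extraction by closing; s3/s4 drive exudate detection by
    dilation and must exceed s2 so vessels vanish from the dilated images.
    """

    s1_px: int = 3
    s2_px: int = 9
    s3_px: int = 13
    s4_px: int = 25

    def __post_init__(self):
        if not self.s1_px < self.s2_px:
            raise ParameterError("MorphScales: require s1_px < s2_px")
        if not self.s2_px < self.s3_px < self.s4_px:
            raise ParameterError("MorphScales: require s2_px < s3_px < s4_px")
        if self.s1_px < 1:
            raise ParameterError("MorphScales: sizes must be >= 1 px")

    @classmethod
    def for_width(cls, width_px: int, reference_width: int = 700) -> "MorphScales":
        """Scale the default sizes linearly with image width."""
        f = width_px / reference_width
        ref = cls()
        vals = [max(1, round(s * f)) for s in (ref.s1_px, ref.s2_px, ref.s3_px, ref.s4_px)]
        # preserve strict ordering after rounding
        for i in range(1, 4):
            if vals[i] <= vals[i - 1]:
                vals[i] = vals[i - 1] + 1
        return cls(*vals)


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the 8-neighbor anisotropic diffusion.

    ``lam`` is the explicit-Euler step weight.  Values above 1/8 are accepted
    (up to the classical 0.25 bound) but can violate the discrete maximum
    principle with 8 neighbors, so they trigger a warning.  ``K`` is the
    conduction constant; ``None`` selects it statistically from the image as
    the 90th percentile of the gradient-magnitude histogram.
    """

    lam: float = 0.125
    K: float | None = None
    n_iter: int = 20
    neighbors: int = 8

    def __post_init__(self):
        if not (0.0 < self.lam <= 0.25):
            raise ParameterError("DiffusionParams: lam must be in (0, 0.25]")
        if self.lam > 0.125 and self.neighbors == 8:
            warnings.warn(
                "lam > 1/8 with 8 neighbors can violate the maximum principle",
                stacklevel=2,
            )
        if self.K is not None and self.K <= 0:
            raise ParameterError("DiffusionParams: K must be positive")
        if self.n_iter < 1:
            raise ParameterError("DiffusionParams: n_iter must be >= 1")
        if self.neighbors not in (4, 8):
            raise ParameterError("DiffusionParams: neighbors must be 4 or 8")


@dataclass(frozen=True)
class SnakeParams:
    """Greedy active-contour parameters (per-column vertical search)."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.2
    search_window: int = 7
    max_iter: int = 50
    move_fraction_stop: float = 0.02

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ParameterError("SnakeParams: weights must be >= 0")
        if self.search_window < 3 or self.search_window % 2 == 0:
            raise ParameterError("SnakeParams: search_window must be an odd integer >= 3")
        if self.max_iter < 1:
            raise ParameterError("SnakeParams: max_iter must be >= 1")


class BoundaryTrace:
    """Per-column row coordinate of a layer boundary; NaN marks missing columns."""

    def __init__(self, rows: Sequence[float] | np.ndarray, n_cols: int | None = None):
        rows = np.asarray(rows, dtype=float)
        if rows.ndim != 1:
            raise ParameterError("BoundaryTrace: rows must be 1-D")
        if n_cols is not None and n_cols != rows.size:
            raise ParameterError("BoundaryTrace: n_cols does not match rows")
        self.rows = rows
        self.n_cols = rows.size

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.rows)

    @property
    def fully_defined(self) -> bool:
        return bool(self.defined.all())

    def __len__(self) -> int:
        return self.n_cols

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, BoundaryTrace) and np.array_equal(
            self.rows, other.rows, equal_nan=True
        )


GLAUCOMATOUS = "glaucomatous"
NON_GLAUCOMATOUS = "non_glaucomatous"


@dataclass(frozen=True)
class RnflReport:
    """Per-column RNFL thickness in microns plus the screening label."""

    thickness_um: np.ndarray
    mean_thickness_um: float
    label: str

    def __post_init__(self):
        t = np.asarray(self.thickness_um, dtype=float)
        object.__setattr__(self, "thickness_um", t)
        if not math.isfinite(self.mean_thickness_um):
            raise ParameterError("RnflReport: mean thickness must be finite")
        if self.label not in (GLAUCOMATOUS, NON_GLAUCOMATOUS):
            raise ParameterError(f"RnflReport: unknown label {self.label!r}")


DR_GRADES = ("none", "mild", "moderate", "severe", "proliferative")


@dataclass(frozen=True)
class RegionPartition:
    """Fovea-centered partition of the fundus field into ten sub-regions.

    ``label_map`` holds integers 1..10 (0 is reserved for pixels outside the
    retinal field; with a full-frame field it does not occur).
    """

    label_map: np.ndarray
    fovea_center_rc: tuple[float, float]
    odd_px: float

    def __post_init__(self):
        lm = np.asarray(self.label_map)
        if lm.ndim != 2 or not np.issubdtype(lm.dtype, np.integer):
            raise InvalidImageError("RegionPartition: label_map must be a 2-D integer raster")
        if lm.min() < 0 or lm.max() > 10:
            raise InvalidImageError("RegionPartition: labels must lie in 0..10")
        object.__setattr__(self, "label_map", lm)


@dataclass(frozen=True)
class DrReport:
    """Lesion-area tallies and the 5-level diabetic-retinopathy grade."""

    exudate_area_px: int
    mahm_area_px: int
    exudate_fovea_px: int
    mahm_fovea_px: int
    per_region_areas: np.ndarray  # 10 x 2: column 0 exudate, column 1 MAHM
    grade: str

    def __post_init__(self):
        tbl = np.asarray(self.per_region_areas, dtype=int)
        if tbl.shape != (10, 2):
            raise ParameterError("DrReport: per_region_areas must be 10x2")
        object.__setattr__(self, "per_region_areas", tbl)
        if self.grade not in DR_GRADES:
            raise ParameterError(f"DrReport: unknown grade {self.grade!r}")
        if int(tbl[:, 0].sum()) != self.exudate_area_px:
            raise ParameterError("DrReport: per-region exudate areas do not sum to total")
        if int(tbl[:, 1].sum()) != self.mahm_area_px:
            raise ParameterError("DrReport: per-region MAHM areas do not sum to total")

    def to_dict(self) -> dict:
        return {
            "exudate_area_px": self.exudate_area_px,
            "mahm_area_px": self.mahm_area_px,
            "exudate_fovea_px": self.exudate_fovea_px,
            "mahm_fovea_px": self.mahm_fovea_px,
            "per_region_areas": self.per_region_areas.tolist(),
            "grade": self.grade,
        }
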