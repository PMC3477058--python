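"""Severity grading of diabetic retinopathy from the lesion distribution.

The fundus field is partitioned into ten fovea-centered sub-regions
(central macular disc, two quadrant annuli, peripheral remainder) and the
exudate/MAHM pixel tallies per region drive a 5-level grade:
none / mild / moderate / severe / proliferative.  Lesions in the central
macular region dominate the grade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidImageError, ParameterError
from .types import DrReport, FoveaRegion, LesionMask, OpticDisc, RegionPartition

#: region radii in ODD units: central disc, inner annulus, outer annulus
CENTRAL_RADIUS_ODD = 1.0
INNER_RADIUS_ODD = 2.0
OUTER_RADIUS_ODD = 3.5


@dataclass(frozen=True)
class GradingThresholds:
    """Total-lesion-area cutoffs (px at reference ~700 px scale)."""

    mild_max_area_px: int = 500
    severe_min_area_px: int = 10_000

    def __post_init__(self):
        if not 0 < self.mild_max_area_px < self.severe_min_area_px:
            raise ParameterError(
                "GradingThresholds: require 0 < mild_max_area_px < severe_min_area_px"
            )


def fundus_coordinates(
    disc: OpticDisc, fovea: FoveaRegion, shape: tuple[int, int]
) -> RegionPartition:
    """Deterministic ten-region label map about the fovea.

    Region 1 is the central macular disc (radius 1 ODD); regions 2-5 are the
    quadrants of the 1-2 ODD annulus and 6-9 the quadrants of the 2-3.5 ODD
    annulus, with quadrant axes aligned to the fovea-to-disc direction;
    region 10 is the remainder of the field.
    """
    h, w = shape
    fr, fc = fovea.center_rc
    if not (0 <= fr < h and 0 <= fc < w):
        raise InvalidImageError("fovea center lies outside the image")
    dr_, dc_ = disc.center_rc
    if abs(dr_ - fr) < 1e-9 and abs(dc_ - fc) < 1e-9:
        raise ParameterError("fovea and disc centers coincide; quadrant axes undefined")
    odd = disc.odd_px

    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.hypot(rr - fr, cc - fc)
    theta0 = np.arctan2(dr_ - fr, dc_ - fc)
    # quadrant index 0..3, first quadrant centered on the fovea->disc axis
    ang = np.arctan2(rr - fr, cc - fc) - theta0 + np.pi / 4.0
    quadrant = np.floor(np.mod(ang, 2.0 * np.pi) / (np.pi / 2.0)).astype(int)
    quadrant = np.clip(quadrant, 0, 3)

    labels = np.full((h, w), 10, dtype=np.int32)
    outer = dist <= OUTER_RADIUS_ODD * odd
    labels[outer] = 6 + quadrant[outer]
    inner = dist <= INNER_RADIUS_ODD * odd
    labels[inner] = 2 + quadrant[inner]
    labels[dist <= CENTRAL_RADIUS_ODD * odd] = 1
    return RegionPartition(label_map=labels, fovea_center_rc=(fr, fc), odd_px=odd)


def grade_from_region_areas(
    per_region_areas: np.ndarray,
    thresholds: GradingThresholds | None = None,
    neovascularization: bool = False,
) -> str:
    """Apply the grade rule table to a 10x2 (exudate, MAHM) area table.

    Monotone by construction: adding lesion pixels anywhere never lowers the
    grade.  ``proliferative`` is reachable only through the explicit
    neovascularization flag.
    """
    thresholds = thresholds or GradingThresholds()
    tbl = np.asarray(per_region_areas, dtype=np.int64)
    if tbl.shape != (10, 2):
        raise ParameterError("per_region_areas must be 10x2")
    if (tbl < 0).any():
        raise ParameterError("lesion areas must be non-negative")
    if neovascularization:
        return "proliferative"
    total = int(tbl.sum())
    fovea_px = int(tbl[0].sum())
    if total == 0:
        return "none"
    if fovea_px > 0 or total > thresholds.severe_min_area_px:
        return "severe"
    peripheral_only = int(tbl[:9].sum()) == 0
    if peripheral_only and total < thresholds.mild_max_area_px:
        return "mild"
    return "moderate"


def grade_severity(
    exudates: LesionMask,
    mahm: LesionMask,
    partition: RegionPartition,
    thresholds: GradingThresholds | None = None,
    neovascularization: bool = False,
) -> DrReport:
    """Tally lesion areas per sub-region and grade the image."""
    shape = partition.label_map.shape
    if exudates.mask.shape != shape or mahm.mask.shape != shape:
        raise InvalidImageError("lesion masks and partition must share a shape")
    tbl = np.zeros((10, 2), dtype=np.int64)
    for region in range(1, 11):
        sel = partition.label_map == region
        tbl[region - 1, 0] = int((exudates.mask & sel).sum())
        tbl[region - 1, 1] = int((mahm.mask & sel).sum())
    grade = grade_from_region_areas(tbl, thresholds, neovascularization)
    return DrReport(
        exudate_area_px=int(tbl[:, 0].sum()),
        mahm_area_px=int(tbl[:, 1].sum()),
        exudate_fovea_px=int(tbl[0, 0]),
        mahm_fovea_px=int(tbl[0, 1]),
        per_region_areas=tbl,
        grade=grade,
    )
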