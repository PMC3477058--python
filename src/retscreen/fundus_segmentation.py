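"""Fundus-image feature extraction.

The chain mirrors the classical morphological screening pipeline: adaptive
histogram equalization, brightest-region optic-disc localization, multiscale
closing for vessels, multiscale dilation for exudates, parabola-guided fovea
search, and hole-filling for microaneurysms/hemorrhages (MAHM).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import exposure, measure
from skimage.filters import threshold_otsu

from . import morphology as morph
from .exceptions import DiscNotFoundError, NoMainVesselError, ParameterError
from .types import (
    FoveaRegion,
    GrayImage,
    LesionMask,
    MorphScales,
    OpticDisc,
    RgbImage,
)

# threshold offset below the image maximum used to isolate the disc
DISC_THRESHOLD_OFFSET = 0.02

# reference geometry for scale-dependent defaults
REFERENCE_WIDTH_PX = 700
VESSEL_MIN_AREA_REF_PX = 30


def preprocess(img: RgbImage, clip_limit: float = 0.01, kernel_frac: float = 0.125) -> RgbImage:
    """Illumination equalization / background normalization (per-channel CLAHE)."""
    px = img.pixels
    h, w = img.shape
    ksize = (max(8, int(h * kernel_frac)), max(8, int(w * kernel_frac)))
    out = np.empty_like(px)
    for ch in range(3):
        plane = px[..., ch]
        if plane.max() - plane.min() < 1e-12:
            out[..., ch] = plane  # flat field: nothing to equalize
        else:
            out[..., ch] = exposure.equalize_adapthist(
                plane, kernel_size=ksize, clip_limit=clip_limit
            )
    return RgbImage(np.clip(out, 0.0, 1.0))


def rgb_to_intensity(img: RgbImage) -> GrayImage:
    """HSI intensity plane: I = (R + G + B) / 3."""
    return GrayImage(img.pixels.mean(axis=2))


def _gaussian_sigma(shape: tuple[int, int]) -> float:
    return max(1.0, 0.005 * min(shape))


def detect_optic_disc(img: RgbImage, window_pad: float = 1.5) -> OpticDisc:
    """Locate the optic disc as the largest near-maximum-intensity region.

    The intensity plane is low-pass filtered, thresholded at ``I_max - 0.02``,
    and the maximum-area component is taken as the disc candidate.  A window
    around the candidate is re-thresholded (Otsu) to delineate the boundary;
    the returned diameter is the equivalent diameter of that boundary
    component.
    """
    intensity = rgb_to_intensity(img).pixels
    smoothed = ndimage.gaussian_filter(intensity, sigma=_gaussian_sigma(img.shape))
    i_max = smoothed.max()
    if i_max - smoothed.min() < DISC_THRESHOLD_OFFSET:
        raise DiscNotFoundError(
            "image is too flat to contain a distinct bright disc "
            f"(dynamic range {i_max - smoothed.min():.4f})"
        )
    candidates = smoothed > i_max - DISC_THRESHOLD_OFFSET
    labeled = measure.label(candidates, connectivity=2)
    regions = measure.regionprops(labeled)
    if not regions:
        raise DiscNotFoundError("no pixel above the disc threshold")
    best = max(regions, key=lambda rp: rp.area)

    # crop a padded window around the winning candidate and re-threshold it
    r0, c0, r1, c1 = best.bbox
    # pad generously: a vessel can bisect the candidate so its bbox may cover
    # only a fraction of the disc
    ext = max(r1 - r0, c1 - c0)
    pad_r = pad_c = max(4, int(ext * window_pad))
    wr0, wc0 = max(0, r0 - pad_r), max(0, c0 - pad_c)
    wr1, wc1 = min(img.height_px, r1 + pad_r), min(img.width_px, c1 + pad_c)
    window = smoothed[wr0:wr1, wc0:wc1]
    try:
        t = threshold_otsu(window)
    except ValueError as exc:  # constant window
        raise DiscNotFoundError("disc window has no intensity contrast") from exc
    disc_bin = window > t
    # vessels crossing the disc carve dark gaps through it: bridge them so the
    # disc delineates as one component
    bridge = max(3, min(window.shape) // 10)
    disc_bin = ndimage.binary_closing(
        disc_bin, structure=morph.disk_footprint(bridge), border_value=0
    )
    disc_bin = ndimage.binary_fill_holes(disc_bin)
    wl = measure.label(disc_bin, connectivity=2)
    wregions = measure.regionprops(wl)
    if not wregions:
        raise DiscNotFoundError("re-thresholded window contains no disc component")
    wbest = max(wregions, key=lambda rp: rp.area)

    mask = np.zeros(img.shape, dtype=bool)
    mask[wr0:wr1, wc0:wc1] = wl == wbest.label
    center = (wbest.centroid[0] + wr0, wbest.centroid[1] + wc0)
    # snap the nominal center into the mask if the centroid falls just outside
    ri, ci = int(round(center[0])), int(round(center[1]))
    if not mask[min(ri, mask.shape[0] - 1), min(ci, mask.shape[1] - 1)]:
        rows, cols = np.nonzero(mask)
        k = np.argmin((rows - center[0]) ** 2 + (cols - center[1]) ** 2)
        center = (float(rows[k]), float(cols[k]))
    odd = float(wbest.equivalent_diameter_area)
    return OpticDisc(center_rc=center, odd_px=odd, mask=mask)


def vessel_min_area(shape: tuple[int, int]) -> int:
    """Small-component cutoff for vessel cleanup, scaled with image area."""
    scale = (shape[0] * shape[1]) / (REFERENCE_WIDTH_PX * REFERENCE_WIDTH_PX)
    return max(1, int(round(VESSEL_MIN_AREA_REF_PX * scale)))


def extract_vessels(
    img: RgbImage,
    scales: MorphScales | None = None,
    min_area_px: int | None = None,
) -> LesionMask:
    """Blood-vessel mask from the difference of green-channel closings.

    Closing at the large scale fills dark vessels; closing at the small scale
    does not, so the difference highlights vessel segments.  The difference is
    Otsu-thresholded over its nonzero support and small components removed.
    """
    scales = scales or MorphScales.for_width(img.width_px)
    if min_area_px is None:
        min_area_px = vessel_min_area(img.shape)
    g = img.green
    diff = morph.grey_close(g, scales.s2_px) - morph.grey_close(g, scales.s1_px)
    mask = _threshold_nonzero(diff)
    mask = _remove_small(mask, min_area_px)
    return LesionMask(mask)


def _threshold_nonzero(diff: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Otsu threshold computed over strictly positive response pixels."""
    positive = diff > tol
    if not positive.any():
        return np.zeros(diff.shape, dtype=bool)
    vals = diff[positive]
    if vals.max() - vals.min() < tol:  # uniform response: keep all of it
        return positive
    return diff > threshold_otsu(vals)


def _remove_small(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    labeled = measure.label(mask, connectivity=2)
    out = np.zeros_like(mask)
    for rp in measure.regionprops(labeled):
        if rp.area >= min_area_px:
            out[labeled == rp.label] = True
    return out


def detect_exudates(
    img: RgbImage,
    scales: MorphScales | None = None,
    disc: OpticDisc | None = None,
    confirm_green_intensity: bool = True,
) -> LesionMask:
    """Bright-lesion (hard exudate) mask from the difference of dilations.

    Dilation enlarges bright structures; subtracting the two scales leaves the
    exudate boundaries, which are thresholded and hole-filled into solid
    candidates.  Candidates are optionally confirmed by green-channel
    brightness (peak >= mean + 2 sigma).  The optic-disc region is removed:
    any candidate component overlapping the disc mask is dropped entirely,
    since the disc responds to dilation exactly like a large exudate.
    """
    if disc is None:
        raise ParameterError("detect_exudates requires the detected OpticDisc")
    scales = scales or MorphScales.for_width(img.width_px)
    g = img.green
    p = morph.grey_dilate(g, scales.s4_px) - morph.grey_dilate(g, scales.s3_px)
    p_t = _threshold_nonzero(p)
    filled = morph.fill_holes_binary(p_t)
    if filled.any():
        cutoff = g.mean() + 2.0 * g.std()
        labeled = measure.label(filled, connectivity=2)
        keep = np.zeros_like(filled)
        for rp in measure.regionprops(labeled, intensity_image=g):
            comp = labeled == rp.label
            if (comp & disc.mask).any():
                continue
            if confirm_green_intensity and rp.intensity_max < cutoff:
                continue
            keep[comp] = True
        filled = keep
    filled[disc.mask] = False
    return LesionMask(filled)


def detect_fovea(
    img: RgbImage,
    vessels: LesionMask,
    disc: OpticDisc,
    search_min_odd: float = 2.0,
    search_max_odd: float = 3.0,
    axis_halfwidth_odd: float = 0.5,
) -> FoveaRegion:
    """Locate the fovea from the main-vessel parabola and the disc geometry.

    The main vessel is recovered as the course of the vessel tree emanating
    from the disc: the union of all components touching the disc neighborhood
    (thresholded vessel masks fragment where the vessel crosses the bright
    disc, so a single component covers only one arm).  A parabola ``row =
    a (col - cc)^2 + b (col - cc) + v`` is fitted to its pixels in a
    disc-centered frame; the search region is the 2-3 ODD annulus around the
    vertex, restricted to a band around the parabola's symmetry axis on the
    opening side.  The fovea is the darkest intensity pixel there after
    low-pass filtering.
    """
    if vessels.is_empty:
        raise NoMainVesselError("vessel mask is empty")
    neighborhood = morph.grey_dilate(
        disc.mask.astype(float), max(1, int(round(0.25 * disc.odd_px)))
    ).astype(bool)

    labeled = measure.label(vessels.mask, connectivity=2)
    touching = np.unique(labeled[(labeled > 0) & neighborhood])
    if touching.size == 0:
        raise NoMainVesselError("no vessel component touches the optic-disc neighborhood")
    main = np.isin(labeled, touching)

    rows, cols = np.nonzero(main)
    dc_r, dc_c = disc.center_rc
    x = cols.astype(float) - dc_c
    y = rows.astype(float)
    coeffs = np.polyfit(x, y, 2)  # row = a x^2 + b x + v in the disc frame
    a, b, _ = coeffs
    if abs(a) < 1e-12:
        raise NoMainVesselError("main vessel is degenerate (no curvature to model)")

    # vertex = main-vessel pixel nearest the disc center
    k = np.argmin((rows - dc_r) ** 2 + (cols - dc_c) ** 2)
    vr, vc = float(rows[k]), float(cols[k])
    axis_col = dc_c - b / (2.0 * a)  # symmetry axis of the fitted parabola
    open_sign = 1.0 if a > 0 else -1.0  # rows grow downward

    h, w = img.shape
    rr, cc = np.mgrid[0:h, 0:w]
    d = np.hypot(rr - vr, cc - vc)
    odd = disc.odd_px
    region = (
        (d >= search_min_odd * odd)
        & (d <= search_max_odd * odd)
        & (np.abs(cc - axis_col) <= axis_halfwidth_odd * odd)
        & (open_sign * (rr - vr) > 0)
    )
    if not region.any():
        raise NoMainVesselError("fovea search region falls outside the image")
    # low-pass before the darkest-pixel pick so noise and thin vessels do not
    # win over the broad dark macular blob
    intensity = ndimage.gaussian_filter(
        rgb_to_intensity(img).pixels, sigma=max(1.0, 0.35 * odd)
    )
    masked = np.where(region, intensity, np.inf)
    fr, fc = np.unravel_index(np.argmin(masked), masked.shape)
    return FoveaRegion(center_rc=(float(fr), float(fc)), radius_px=odd)


def detect_mahm(
    img: RgbImage,
    vessels: LesionMask,
    vessel_margin_px: int = 2,
    min_area_px: int = 4,
) -> LesionMask:
    """Microaneurysm/hemorrhage mask from gray-scale hole filling.

    Small dark blobs surrounded by brighter tissue are raised by morphological
    filling of the green channel; the fill residue is thresholded at the
    red-channel mean and vessel pixels (with a small safety margin) removed.
    Isolated specks below ``min_area_px`` are discarded as noise.
    """
    g = img.green
    residue = morph.fill_holes_gray(g) - g
    threshold = img.red.mean()
    mask = residue > threshold
    if vessel_margin_px > 0:
        vessel_zone = morph.grey_dilate(
            vessels.mask.astype(float), 2 * vessel_margin_px + 1
        ).astype(bool)
    else:
        vessel_zone = vessels.mask
    mask &= ~vessel_zone
    if min_area_px > 1:
        mask = _remove_small(mask, min_area_px)
    return LesionMask(mask)
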