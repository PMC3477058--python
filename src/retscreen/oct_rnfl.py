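"""RNFL boundary extraction and thickness-based glaucoma screening.

Anterior boundary: binarized gradient magnitude, component cleanup, first
white pixel per column from the top, cubic fill of missing columns, then a
greedy active-contour refinement.  Posterior boundary: mask above the
anterior, anisotropic diffusion, a second gradient binarization with a
cleanup cascade that rejects the anterior echo and the RPE band, first white
pixel per column, and a 50-point median smoothing.  Thickness is the row
difference scaled by the axial pixel pitch; a mean below 105 um flags the
scan as glaucomatous.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .exceptions import BoundaryEstimationError, ParameterError
from .oct_denoise import anisotropic_diffuse, gradient_magnitude
from .types import (
    GLAUCOMATOUS,
    NON_GLAUCOMATOUS,
    BoundaryTrace,
    DiffusionParams,
    OctImage,
    RnflReport,
    SnakeParams,
)

#: mean RNFL thickness (um) separating glaucomatous from healthy scans
RNFL_THICKNESS_THRESHOLD_UM = 105.0

#: anterior cleanup: area filter fraction of total pixel count
ANTERIOR_AREA_FRACTION = 0.0007
#: minimum horizontal extent (px) of a retained edge component
MIN_COMPONENT_LENGTH_PX = 25
#: posterior cleanup: first-pass and second-pass area cutoffs (px)
POSTERIOR_AREA_FIRST_PX = 100
POSTERIOR_AREA_SECOND_PX = 70
#: trailing 1-D median window (points) applied to the posterior trace
POSTERIOR_MEDIAN_POINTS = 50


def anterior_area_threshold(shape: tuple[int, int]) -> int:
    """Small-component cutoff: 0.07% of the total pixel count, rounded down."""
    return int(math.floor(ANTERIOR_AREA_FRACTION * shape[0] * shape[1]))


def fill_missing_cubic(trace: BoundaryTrace, edge_mode: str = "cubic") -> BoundaryTrace:
    """Fill undefined columns with a least-squares cubic through the defined ones.

    ``edge_mode='hold'`` extends the first/last defined value into missing
    border columns instead of extrapolating the polynomial there (cubic
    extrapolation beyond the data span can swing wildly on noisy traces).
    """
    defined = trace.defined
    if defined.all():
        return BoundaryTrace(trace.rows.copy())
    n_def = int(defined.sum())
    if n_def < 4:
        raise BoundaryEstimationError(
            f"cubic fill needs >= 4 defined columns, found {n_def}"
        )
    cols = np.arange(trace.n_cols, dtype=float)
    coeffs = np.polyfit(cols[defined], trace.rows[defined], 3)
    rows = trace.rows.copy()
    rows[~defined] = np.polyval(coeffs, cols[~defined])
    if edge_mode == "hold":
        idx = np.nonzero(defined)[0]
        rows[: idx[0]] = trace.rows[idx[0]]
        rows[idx[-1] + 1 :] = trace.rows[idx[-1]]
    elif edge_mode != "cubic":
        raise ParameterError(f"unknown edge_mode {edge_mode!r}")
    return BoundaryTrace(rows)


def _first_white_per_column(mask: np.ndarray) -> np.ndarray:
    """Row index of the topmost true pixel per column; NaN where none."""
    any_white = mask.any(axis=0)
    first = mask.argmax(axis=0).astype(float)
    first[~any_white] = np.nan
    return first


def _filter_components(
    mask: np.ndarray,
    min_area: int | None = None,
    min_length: int | None = None,
    keep_fn=None,
) -> np.ndarray:
    labeled = measure.label(mask, connectivity=2)
    out = np.zeros_like(mask)
    for rp in measure.regionprops(labeled):
        if min_area is not None and rp.area < min_area:
            continue
        if min_length is not None and (rp.bbox[3] - rp.bbox[1]) < min_length:
            continue
        if keep_fn is not None and not keep_fn(rp, labeled):
            continue
        out[labeled == rp.label] = True
    return out


def initial_anterior(
    img: OctImage,
    binarize_threshold: float | None = None,
) -> BoundaryTrace:
    """First estimate of the anterior RNFL boundary from the gradient field.

    Expects a pre-smoothed image (Gaussian + median chain).  The gradient
    magnitude is binarized (Otsu by default), components smaller than 0.07% of
    the image or shorter than 25 columns are dropped, and the topmost white
    pixel per column forms the trace; gaps are filled with a cubic fit.
    """
    mag = gradient_magnitude(img.pixels)
    if binarize_threshold is None:
        if mag.max() - mag.min() < 1e-12:
            raise BoundaryEstimationError("gradient field is flat; no edges to binarize")
        binarize_threshold = threshold_otsu(mag)
    mask = mag > binarize_threshold
    mask = _filter_components(
        mask,
        min_area=anterior_area_threshold(img.shape),
        min_length=MIN_COMPONENT_LENGTH_PX,
    )
    if not mask.any():
        raise BoundaryEstimationError("no edge component survived anterior cleanup")
    return fill_missing_cubic(BoundaryTrace(_first_white_per_column(mask)))


def _snake_energy(
    rows: np.ndarray, grad_norm: np.ndarray, p: SnakeParams, scale: float
) -> float:
    cont = np.sum(np.diff(rows) ** 2) * scale
    curv = np.sum((rows[:-2] - 2 * rows[1:-1] + rows[2:]) ** 2) * scale
    image = grad_norm[rows, np.arange(rows.size)].sum()
    return float(p.alpha * cont + p.beta * curv - p.gamma * image)


def greedy_snake(img: OctImage, init: BoundaryTrace, p: SnakeParams | None = None) -> BoundaryTrace:
    """Refine a boundary trace by greedy per-point energy descent.

    Each column's point moves within a vertical search window to minimize
    ``alpha * continuity + beta * curvature - gamma * |grad I|`` (gradient
    normalized to [0, 1]); sweeps stop when fewer than ``move_fraction_stop``
    of the points move.  The total energy never increases, so the returned
    trace's energy is <= the initial trace's.
    """
    p = p or SnakeParams()
    h, w = img.shape
    if p.search_window > h:
        raise ParameterError("search_window exceeds image height")
    if not init.fully_defined:
        raise BoundaryEstimationError("snake initialization must be fully defined")

    mag = gradient_magnitude(img.pixels)
    mmax = mag.max()
    grad_norm = mag / mmax if mmax > 0 else mag
    rows = np.clip(np.round(init.rows).astype(int), 0, h - 1)
    half = p.search_window // 2
    scale = 1.0 / float(p.search_window) ** 2  # keeps smoothness terms O(1)

    def point_energy(r: np.ndarray, c: int, cand: int) -> float:
        """All energy terms that involve the point at column c set to row cand."""
        e = -p.gamma * grad_norm[cand, c]
        if c > 0:
            e += p.alpha * (cand - r[c - 1]) ** 2 * scale
        if c < w - 1:
            e += p.alpha * (r[c + 1] - cand) ** 2 * scale
        for cc in (c - 1, c, c + 1):
            if 1 <= cc <= w - 2:
                trip = [r[cc - 1], r[cc], r[cc + 1]]
                trip[c - cc + 1] = cand
                e += p.beta * (trip[0] - 2 * trip[1] + trip[2]) ** 2 * scale
        return e

    for _ in range(p.max_iter):
        moved = 0
        for c in range(w):
            current = rows[c]
            best_r, best_e = current, point_energy(rows, c, current)
            lo = max(0, current - half)
            hi = min(h - 1, current + half)
            for cand in range(lo, hi + 1):
                if cand == current:
                    continue
                e = point_energy(rows, c, cand)
                if e < best_e - 1e-12:
                    best_r, best_e = cand, e
            if best_r != current:
                rows[c] = best_r
                moved += 1
        if moved / w < p.move_fraction_stop:
            break
    return BoundaryTrace(rows.astype(float))


def snake_total_energy(img: OctImage, trace: BoundaryTrace, p: SnakeParams | None = None) -> float:
    """Global energy of a trace under the greedy-snake functional."""
    p = p or SnakeParams()
    mag = gradient_magnitude(img.pixels)
    mmax = mag.max()
    grad_norm = mag / mmax if mmax > 0 else mag
    rows = np.clip(np.round(trace.rows).astype(int), 0, img.shape[0] - 1)
    return _snake_energy(rows, grad_norm, p, 1.0 / float(p.search_window) ** 2)


def median_filter_trace(rows: np.ndarray, points: int = POSTERIOR_MEDIAN_POINTS) -> np.ndarray:
    """1-D running median; the window shrinks symmetrically near the ends."""
    n = rows.size
    half = points // 2
    out = np.empty(n)
    for c in range(n):
        k = min(half, c, n - 1 - c)
        out[c] = np.median(rows[c - k : c + k + 1])
    return out


def estimate_posterior(
    img: OctImage,
    anterior: BoundaryTrace,
    p: DiffusionParams | None = None,
    n_sd: float = 1.0,
    anterior_margin_px: int = 4,
    rpe_depth_px: int = 60,
    snake: SnakeParams | None = None,
) -> BoundaryTrace:
    """Posterior RNFL boundary below a known anterior boundary.

    Everything above the anterior trace is blanked, the field is diffused
    anisotropically, and the normalized gradient is binarized at mean +
    ``n_sd`` sigma (computed below the anterior).  The cleanup cascade removes
    components < 100 px, the anterior's own edge response (a small margin
    below the trace), RPE components deeper than ``rpe_depth_px``, then
    components shorter than 25 px or smaller than 70 px.  The topmost
    surviving pixel per column is median-smoothed over 50 points.
    """
    if not anterior.fully_defined:
        raise BoundaryEstimationError("anterior trace must be fully defined")
    h, w = img.shape
    if anterior.n_cols != w:
        raise ParameterError("anterior trace width does not match the image")

    work = img.pixels.copy()
    rr = np.arange(h)[:, None]
    ant = anterior.rows[None, :]
    work[rr < np.ceil(ant)] = 0.0

    smoothed = anisotropic_diffuse(OctImage(work, img.axial_um_per_px), p)
    mag = gradient_magnitude(smoothed.pixels)
    mmax = mag.max()
    if mmax <= 0:
        raise BoundaryEstimationError("gradient field below the anterior is flat")
    mag = mag / mmax

    below = rr >= np.ceil(ant)
    threshold = mag[below].mean() + n_sd * mag[below].std()
    mask = mag > threshold
    mask = _filter_components(mask, min_area=POSTERIOR_AREA_FIRST_PX)
    # anterior echo: anything within the margin below the anterior trace
    mask[rr <= ant + anterior_margin_px] = False

    def not_rpe(rp, labeled) -> bool:
        rows_, cols_ = np.nonzero(labeled == rp.label)
        depth = float(np.mean(rows_ - anterior.rows[cols_]))
        return depth <= rpe_depth_px

    mask = _filter_components(mask, keep_fn=not_rpe)
    mask = _filter_components(
        mask, min_area=POSTERIOR_AREA_SECOND_PX, min_length=MIN_COMPONENT_LENGTH_PX
    )
    if not mask.any():
        raise BoundaryEstimationError("no candidate survived posterior cleanup")

    trace = fill_missing_cubic(BoundaryTrace(_first_white_per_column(mask)), edge_mode="hold")
    if snake is not None:
        trace = greedy_snake(smoothed, trace, snake)
    rows = median_filter_trace(trace.rows)
    return BoundaryTrace(np.clip(rows, 0, h - 1))


def rnfl_thickness(
    anterior: BoundaryTrace,
    posterior: BoundaryTrace,
    axial_um_per_px: float = 6.0,
) -> RnflReport:
    """Per-column thickness = (posterior - anterior) * axial pitch, in microns."""
    if anterior.n_cols != posterior.n_cols:
        raise ParameterError("boundary traces differ in length")
    if not (anterior.fully_defined and posterior.fully_defined):
        raise BoundaryEstimationError("thickness requires fully defined traces")
    if axial_um_per_px <= 0:
        raise ParameterError("axial_um_per_px must be positive")
    diff_px = posterior.rows - anterior.rows
    if (diff_px < 0).any():
        warnings.warn(
            f"{int((diff_px < 0).sum())} columns have posterior above anterior; "
            "clipping thickness to 0",
            stacklevel=2,
        )
        diff_px = np.clip(diff_px, 0.0, None)
    thickness = diff_px * axial_um_per_px
    mean = float(thickness.mean())
    return RnflReport(
        thickness_um=thickness,
        mean_thickness_um=mean,
        label=classify_glaucoma(mean),
    )


def classify_glaucoma(report: RnflReport | float) -> str:
    """Label a scan from its mean RNFL thickness; exactly 105 um is healthy."""
    mean = report.mean_thickness_um if isinstance(report, RnflReport) else float(report)
    if not math.isfinite(mean):
        raise ParameterError("mean thickness must be finite")
    return GLAUCOMATOUS if mean < RNFL_THICKNESS_THRESHOLD_UM else NON_GLAUCOMATOUS
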