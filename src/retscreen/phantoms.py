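"""Seeded synthetic fundus and OCT phantoms with exact ground truth.

Every generator is a pure function of its spec (including the seed), and the
returned ground-truth masks are the rendering sets themselves, not
re-estimated, so recovery tests have an exact reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ParameterError
from .types import BoundaryTrace, OctImage, RgbImage


@dataclass(frozen=True)
class FundusGroundTruth:
    """Exact masks and landmarks of a rendered fundus phantom."""

    disc_center_rc: tuple[float, float]
    odd_px: float
    disc_mask: np.ndarray
    vessel_mask: np.ndarray
    fovea_center_rc: tuple[float, float] | None
    exudate_mask: np.ndarray
    mahm_mask: np.ndarray
    n_exudates: int
    n_mahm: int


@dataclass(frozen=True)
class FundusPhantomSpec:
    """Geometry and photometry of a synthetic fundus image.

    The main vessel is an exact parabola ``row = curvature * (col -
    disc_col)^2 + disc_row`` with vertex at the disc center, opening downward;
    optional branch vessels are shallower parabolas through the disc.  The
    fovea sits ``fovea_odd`` disc diameters below the vertex on the symmetry
    axis.  Background channels are (red, green, blue) = ``bg_rgb`` plus a
    horizontal illumination gradient.
    """

    shape: tuple[int, int] = (700, 700)
    disc_center_rc: tuple[float, float] = (200.0, 350.0)
    odd_px: float = 80.0
    disc_brightness: float = 0.95
    bg_rgb: tuple[float, float, float] = (0.35, 0.55, 0.25)
    gradient_amplitude: float = 0.03
    vessel_curvature: float = 0.006
    vessel_width_px: float = 5.0
    vessel_depth: float = 0.25
    n_branches: int = 2
    fovea_odd: float | None = 2.5
    fovea_radius_px: float = 45.0
    fovea_depth: float = 0.18
    exudate_centers: tuple[tuple[float, float], ...] = ()
    exudate_radius_px: float = 10.0
    exudate_brightness: float = 0.85
    mahm_centers: tuple[tuple[float, float], ...] = ()
    mahm_radius_px: float = 2.0
    mahm_depth: float = 0.45
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        h, w = self.shape
        if h < 64 or w < 64:
            raise ParameterError("fundus phantom must be at least 64x64")
        if self.odd_px <= 0 or self.vessel_width_px <= 0:
            raise ParameterError("geometry sizes must be positive")
        for name, centers in (("exudate", self.exudate_centers), ("mahm", self.mahm_centers)):
            for r, c in centers:
                if not (0 <= r < h and 0 <= c < w):
                    raise ParameterError(f"{name} blob center ({r}, {c}) outside bounds")


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _parabola_mask(
    shape: tuple[int, int],
    vertex_rc: tuple[float, float],
    curvature: float,
    width: float,
    col_span: float,
) -> np.ndarray:
    """Band of constant perpendicular ``width`` around row = a (col - vc)^2 + vr.

    The curve is rasterized densely and dilated with a disk, so the band keeps
    its caliber even on the steep arms of the parabola.
    """
    from scipy import ndimage as ndi
    from skimage import morphology as skmorph

    h, w = shape
    centerline = np.zeros((h, w), dtype=bool)
    x = np.arange(-col_span, col_span, 0.25)
    rows = curvature * x**2 + vertex_rc[0]
    cols = x + vertex_rc[1]
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    centerline[np.round(rows[ok]).astype(int), np.round(cols[ok]).astype(int)] = True
    radius = max(1, int(round(width / 2.0)))
    return ndi.binary_dilation(centerline, structure=skmorph.disk(radius))


def make_fundus_phantom(spec: FundusPhantomSpec) -> tuple[RgbImage, FundusGroundTruth]:
    """Render a fundus phantom and its exact ground truth."""
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    img = np.empty((h, w, 3))
    grad = spec.gradient_amplitude * (np.arange(w) / max(1, w - 1) - 0.5)[None, :]
    for ch in range(3):
        img[..., ch] = spec.bg_rgb[ch] + grad

    # vessel tree: main parabola plus shallower branches, all through the disc
    span = 0.45 * w
    vessel = _parabola_mask(
        spec.shape, spec.disc_center_rc, spec.vessel_curvature, spec.vessel_width_px, span
    )
    for k in range(spec.n_branches):
        curv = spec.vessel_curvature * (1.8 + 0.9 * k)
        width = max(4.0, spec.vessel_width_px - 1.0)
        vessel |= _parabola_mask(spec.shape, spec.disc_center_rc, curv, width, span * 0.4)
    img[vessel, 0] -= spec.vessel_depth
    img[vessel, 1] -= spec.vessel_depth
    img[vessel, 2] -= 0.5 * spec.vessel_depth

    # fovea: dark blob on the parabola axis, below the vertex
    fovea_center = None
    if spec.fovea_odd is not None:
        fr = spec.disc_center_rc[0] + spec.fovea_odd * spec.odd_px
        fc = spec.disc_center_rc[1]
        if not (0 <= fr < h):
            raise ParameterError("fovea falls outside the image")
        fovea_center = (fr, fc)
        fmask = _disk_mask(spec.shape, fovea_center, spec.fovea_radius_px)
        img[fmask, :] -= spec.fovea_depth

    # optic disc: bright in all channels, drawn over the background but under
    # the vessel tree so the main vessel truly crosses the disc center
    disc_mask = _disk_mask(spec.shape, spec.disc_center_rc, spec.odd_px / 2.0)
    paint = disc_mask & ~vessel
    for ch in range(3):
        img[paint, ch] = spec.disc_brightness

    exu = np.zeros((h, w), dtype=bool)
    for center in spec.exudate_centers:
        exu |= _disk_mask(spec.shape, center, spec.exudate_radius_px)
    exu &= ~vessel
    img[exu, 0] = spec.exudate_brightness
    img[exu, 1] = spec.exudate_brightness
    img[exu, 2] = 0.4 * spec.exudate_brightness

    mahm = np.zeros((h, w), dtype=bool)
    for center in spec.mahm_centers:
        mahm |= _disk_mask(spec.shape, center, spec.mahm_radius_px)
    mahm &= ~vessel
    img[mahm, 0] -= spec.mahm_depth
    img[mahm, 1] -= spec.mahm_depth
    img[mahm, 2] -= 0.3 * spec.mahm_depth

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    truth = FundusGroundTruth(
        disc_center_rc=spec.disc_center_rc,
        odd_px=spec.odd_px,
        disc_mask=disc_mask,
        vessel_mask=vessel,
        fovea_center_rc=fovea_center,
        exudate_mask=exu,
        mahm_mask=mahm,
        n_exudates=len(spec.exudate_centers),
        n_mahm=len(spec.mahm_centers),
    )
    return RgbImage(img), truth


@dataclass(frozen=True)
class OctPhantomSpec:
    """Band geometry and speckle statistics of a synthetic OCT B-scan.

    The anterior boundary row is a cubic in the column index; the RNFL band
    spans ``thickness_px`` rows below it, over a darker sub-RNFL background,
    with a brighter RPE band ``rpe_offset_px`` below the anterior.  ``looks``
    is the multiplicative-speckle look count (None disables speckle).
    ``gap_cols`` blanks whole columns of the band structure to simulate edge
    holes.
    """

    shape: tuple[int, int] = (329, 689)
    anterior_coeffs: tuple[float, float, float, float] = (80.0, 0.0, 0.0, 0.0)
    thickness_px: float | tuple[float, ...] = 28.0
    bg_intensity: float = 0.08
    rnfl_intensity: float = 0.85
    sub_rnfl_intensity: float = 0.30
    rpe_intensity: float = 0.65
    rpe_offset_px: float = 80.0
    rpe_height_px: float = 12.0
    looks: float | None = None
    gap_cols: tuple[tuple[int, int], ...] = ()
    axial_um_per_px: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.rnfl_intensity <= self.sub_rnfl_intensity:
            raise ParameterError("RNFL band must be brighter than the sub-RNFL background")
        if self.looks is not None and self.looks < 1:
            raise ParameterError("speckle look count must be >= 1")


def _anterior_rows(spec: OctPhantomSpec) -> np.ndarray:
    c = np.arange(spec.shape[1], dtype=float)
    a0, a1, a2, a3 = spec.anterior_coeffs
    return a0 + a1 * c + a2 * c**2 + a3 * c**3


def _thickness_profile(spec: OctPhantomSpec) -> np.ndarray:
    t = np.asarray(spec.thickness_px, dtype=float)
    if t.ndim == 0:
        t = np.full(spec.shape[1], float(t))
    if t.size != spec.shape[1]:
        raise ParameterError("thickness profile length must equal the image width")
    return t


def make_oct_phantom(spec: OctPhantomSpec) -> tuple[OctImage, BoundaryTrace, BoundaryTrace]:
    """Render an OCT phantom plus exact anterior/posterior boundary traces."""
    h, w = spec.shape
    anterior = _anterior_rows(spec)
    thickness = _thickness_profile(spec)
    posterior = anterior + thickness
    if (anterior < 1).any() or (posterior + spec.rpe_offset_px + spec.rpe_height_px >= h).any():
        raise ParameterError("band structure exceeds the image height")

    rr = np.arange(h, dtype=float)[:, None]
    img = np.full((h, w), spec.bg_intensity)
    below_ant = rr >= anterior[None, :]
    img[below_ant] = spec.sub_rnfl_intensity
    in_band = below_ant & (rr < posterior[None, :])
    img[in_band] = spec.rnfl_intensity
    rpe_top = anterior + spec.rpe_offset_px
    in_rpe = (rr >= rpe_top[None, :]) & (rr < (rpe_top + spec.rpe_height_px)[None, :])
    img[in_rpe] = spec.rpe_intensity

    for c0, c1 in spec.gap_cols:
        img[:, c0:c1] = spec.bg_intensity

    if spec.looks is not None and not np.isinf(spec.looks):
        img = add_speckle(img, spec.looks, spec.seed)

    return (
        OctImage(np.clip(img, 0.0, 1.0), spec.axial_um_per_px),
        BoundaryTrace(anterior),
        BoundaryTrace(posterior),
    )


def add_speckle(img: np.ndarray, looks: float, seed: int | None = None) -> np.ndarray:
    """Multiply by unit-mean Gamma(L, 1/L) speckle and clip to [0, 1]."""
    if looks < 1:
        raise ParameterError("speckle look count must be >= 1")
    arr = np.asarray(img, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.gamma(shape=looks, scale=1.0 / looks, size=arr.shape)
    return np.clip(arr * noise, 0.0, 1.0)


def default_fundus_lesion_spec(seed: int = 0, **overrides) -> FundusPhantomSpec:
    """A ready-made phantom with well-separated lesions outside the macula."""
    spec = FundusPhantomSpec(
        exudate_centers=((180.0, 140.0), (320.0, 560.0), (120.0, 520.0)),
        mahm_centers=((520.0, 150.0), (560.0, 540.0), (300.0, 120.0)),
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec
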