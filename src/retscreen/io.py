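"""Raster and table I/O for the screening pipelines."""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import InvalidImageError
from .types import BoundaryTrace, GrayImage, LesionMask, OctImage, RgbImage


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Map integer rasters (8/16-bit) and float rasters to [0, 1]."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / info.max
    arr = arr.astype(float)
    if arr.size and arr.max() > 1.0:  # float image stored on a 0-255 scale
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def load_rgb(path: str | Path) -> RgbImage:
    """Read a color raster (PNG/TIFF/JPEG/BMP) as an RgbImage."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidImageError(f"{path}: cannot interpret shape {arr.shape} as RGB")
    return RgbImage(_normalize(arr))


def load_oct(path: str | Path, axial_um_per_px: float = 6.0) -> OctImage:
    """Read a single-channel raster as an OCT B-scan."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return OctImage(_normalize(arr), axial_um_per_px)


def save_image(path: str | Path, image: RgbImage | GrayImage | OctImage | np.ndarray) -> None:
    """Write a [0, 1] raster as 8-bit PNG/TIFF."""
    arr = image if isinstance(image, np.ndarray) else image.pixels
    iio.imwrite(path, (np.clip(arr, 0.0, 1.0) * 255).astype(np.uint8))


def save_mask_png(path: str | Path, mask: LesionMask | np.ndarray) -> None:
    arr = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask, bool)
    iio.imwrite(path, (arr.astype(np.uint8)) * 255)


def save_components_csv(path: str | Path, mask: LesionMask) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "area_px", "centroid_row", "centroid_col"])
        for comp in mask.components:
            writer.writerow(
                [comp.label, comp.area_px, f"{comp.centroid_rc[0]:.2f}", f"{comp.centroid_rc[1]:.2f}"]
            )


def save_traces_csv(
    path: str | Path,
    anterior: BoundaryTrace,
    posterior: BoundaryTrace,
    thickness_um: np.ndarray,
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["col", "anterior_row", "posterior_row", "thickness_um"])
        for c in range(anterior.n_cols):
            writer.writerow(
                [c, f"{anterior.rows[c]:.2f}", f"{posterior.rows[c]:.2f}", f"{thickness_um[c]:.2f}"]
            )


def render_boundary_overlay(
    img: OctImage, anterior: BoundaryTrace, posterior: BoundaryTrace
) -> np.ndarray:
    """RGB overlay: anterior boundary in blue, posterior in red."""
    h, w = img.shape
    out = np.stack([img.pixels] * 3, axis=-1)
    cols = np.arange(w)
    for trace, color in ((anterior, (0.0, 0.0, 1.0)), (posterior, (1.0, 0.0, 0.0))):
        rows = np.clip(np.round(trace.rows).astype(int), 0, h - 1)
        for dr in (-1, 0, 1):
            rr = np.clip(rows + dr, 0, h - 1)
            out[rr, cols] = color
    return out
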