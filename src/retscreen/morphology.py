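"""Gray-scale morphology primitives with pinned border semantics.

Every operation uses replicate ("nearest") borders so that results on small
images can be checked exactly against brute-force sliding-window min/max
oracles.  Structuring elements are discrete disks specified by their *size*
(diameter in pixels): ``size s`` maps to a disk of radius ``s // 2``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import morphology as skmorph

from .exceptions import ParameterError

__all__ = [
    "disk_footprint",
    "grey_dilate",
    "grey_erode",
    "grey_close",
    "fill_holes_binary",
    "fill_holes_gray",
]


def disk_footprint(size_px: int) -> np.ndarray:
    """Disk structuring element for a scale given as a diameter in pixels."""
    if size_px < 1:
        raise ParameterError("structuring-element size must be >= 1 px")
    return skmorph.disk(size_px // 2)


def grey_dilate(img: np.ndarray, size_px: int) -> np.ndarray:
    """Gray-scale dilation by a disk of the given size, replicate borders."""
    return ndimage.grey_dilation(img, footprint=disk_footprint(size_px), mode="nearest")


def grey_erode(img: np.ndarray, size_px: int) -> np.ndarray:
    return ndimage.grey_erosion(img, footprint=disk_footprint(size_px), mode="nearest")


def grey_close(img: np.ndarray, size_px: int) -> np.ndarray:
    """Closing = erosion of the dilation; fills dark structures thinner than the disk."""
    return grey_erode(grey_dilate(img, size_px), size_px)


def fill_holes_binary(mask: np.ndarray) -> np.ndarray:
    """Fill holes of a binary mask (holes = background not reachable from the border)."""
    return ndimage.binary_fill_holes(np.asarray(mask, bool))


def fill_holes_gray(img: np.ndarray) -> np.ndarray:
    """Gray-scale hole filling by morphological reconstruction (erosion).

    Dark blobs fully surrounded by brighter pixels are raised to the level of
    their surroundings; structures connected to the border are untouched.
    Uses 8-connectivity.
    """
    img = np.asarray(img, dtype=float)
    seed = np.full_like(img, img.max())
    seed[0, :] = img[0, :]
    seed[-1, :] = img[-1, :]
    seed[:, 0] = img[:, 0]
    seed[:, -1] = img[:, -1]
    return skmorph.reconstruction(seed, img, method="erosion", footprint=np.ones((3, 3)))
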