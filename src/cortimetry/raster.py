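"""Shared rasterization helpers: one polygon fill rule for the whole package.

Contours are ``(N, 2)`` arrays of ``(x, y)`` pixel coordinates (x = column,
y = row). Using a single fill implementation guarantees that ground-truth
polygons, segmentation inputs and morphometry all agree on which pixels a
contour encloses.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import draw, measure  # draw: perimeter rasterization only

__all__ = [
    "polygon_mask",
    "contour_pixel_mask",
    "boundary_pixels",
    "mask_contour",
    "EIGHT",
]

# 8-connectivity structuring element for foreground labelling
EIGHT = np.ones((3, 3), dtype=bool)


def polygon_mask(contour_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Filled-polygon boolean mask for a closed ``(x, y)`` contour.

    A pixel belongs to the mask when its center lies inside the polygon
    (even-odd rule), evaluated with a vectorized scanline sweep. This is
    the single fill rule used everywhere in the package, so ground-truth
    polygons and segmentation agree bit-for-bit.
    """
    c = np.asarray(contour_xy, dtype=float)
    if c.ndim != 2 or c.shape[0] < 3:
        raise ValueError("contour must have at least 3 vertices")
    H, W = shape
    x1, y1 = c[:, 0], c[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    rows = np.arange(H, dtype=float)[:, None]
    # half-open span rule handles scanlines through vertices consistently
    crosses = (y1[None, :] <= rows) != (y2[None, :] <= rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rows - y1[None, :]) / (y2 - y1)[None, :]
        xs = x1[None, :] + t * (x2 - x1)[None, :]
    xs = np.where(crosses, xs, np.inf)
    xs.sort(axis=1)
    mask = np.zeros(shape, dtype=bool)
    for r in range(H):
        row = xs[r]
        row = row[np.isfinite(row)]
        for i in range(0, row.size - 1, 2):
            lo = int(np.ceil(row[i]))
            hi = int(np.ceil(row[i + 1]))  # center inside iff lo <= c < hi
            if hi > 0 and lo < W:
                mask[r, max(lo, 0) : min(hi, W)] = True
    return mask


def contour_pixel_mask(contour_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the pixels lying on the polygon's perimeter."""
    c = np.asarray(contour_xy, dtype=float)
    if c.ndim != 2 or c.shape[0] < 3:
        raise ValueError("contour must have at least 3 vertices")
    rr, cc = draw.polygon_perimeter(
        np.rint(c[:, 1]).astype(int), np.rint(c[:, 0]).astype(int), shape=shape
    )
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Outer one-pixel rim of a boolean mask (mask minus its erosion)."""
    m = np.asarray(mask, bool)
    return m & ~ndimage.binary_erosion(m, structure=EIGHT, border_value=0)


def mask_contour(mask: np.ndarray) -> np.ndarray:
    """Longest iso-contour of a boolean mask as an ``(x, y)`` polygon."""
    contours = measure.find_contours(np.asarray(mask, float), 0.5)
    if not contours:
        raise ValueError("mask has no contour (empty mask?)")
    longest = max(contours, key=len)
    return longest[:, ::-1].copy()  # (row, col) -> (x, y)
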