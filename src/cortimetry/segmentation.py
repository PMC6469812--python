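"""Section segmentation: from calibrated image to masks, contours and pores.

The fixed processing order is smooth (optional) -> segment tissue -> clean
-> trace periosteal contour -> build cortical compartment. The endosteal
boundary is always a supplied input (a manually drawn polygon or mask), as
in standard cortical-bone workflows; no automatic endosteal detection is
attempted.

Connectivity convention: foreground (tissue objects, pores) is 8-connected,
background 4-connected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import filters

from .raster import EIGHT, mask_contour, polygon_mask
from .types import CalibratedImage, SectionMasks

__all__ = [
    "ContourError",
    "smooth_image",
    "segment_tissue",
    "clean_tissue_mask",
    "trace_periosteal",
    "build_cortical_mask",
    "extract_roi_us",
    "SegmentationConfig",
    "segment_section",
]

FOUR = ndimage.generate_binary_structure(2, 1)


class ContourError(ValueError):
    """Raised when supplied contours are degenerate or inconsistent."""


def smooth_image(
    img: CalibratedImage, sigma_px: float, radius_px: float
) -> CalibratedImage:
    """Truncated Gaussian smoothing; metadata is preserved.

    ``radius_px`` is the kernel truncation radius in pixels (the kernel
    spans ``2*radius_px + 1`` pixels per axis).
    """
    if not (sigma_px > 0 and radius_px > 0):
        raise ValueError("sigma_px and radius_px must be > 0")
    sm = ndimage.gaussian_filter(
        np.asarray(img.pixels, float), sigma=sigma_px, truncate=radius_px / sigma_px
    )
    return CalibratedImage(sm, img.pixel_size, img.modality, img.calibration)


def segment_tissue(
    img: CalibratedImage,
    method: str = "otsu",
    window_px: Optional[int] = None,
    offset: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Threshold the image into a tissue mask.

    ``otsu`` applies a global Otsu threshold (tissue = above threshold);
    ``isodata`` the Ridler-Calvard iterative threshold, which settles midway
    between the two class means and therefore misclassifies symmetrically
    under additive noise (Otsu's criterion with unequal class populations
    sits several noise SDs closer to the background level); ``adaptive``
    thresholds against the local mean over a square window of ``window_px``
    pixels minus ``offset``, which tolerates smooth illumination gradients.
    Returns the mask and a provenance record with the threshold(s) used.
    """
    px = np.asarray(img.pixels, float)
    if method in ("otsu", "isodata"):
        if np.ptp(px) == 0:
            # global thresholds are undefined on a constant image
            return np.zeros(px.shape, bool), {
                "method": method,
                "threshold": None,
                "constant_image": True,
            }
        fn = filters.threshold_otsu if method == "otsu" else filters.threshold_isodata
        thr = float(fn(px))
        return px > thr, {"method": method, "threshold": thr, "constant_image": False}
    if method == "adaptive":
        if window_px is None or window_px <= 1:
            raise ValueError("adaptive thresholding needs window_px > 1")
        block = int(window_px)
        if block % 2 == 0:
            block += 1  # threshold_local requires an odd window
        local = filters.threshold_local(px, block_size=block, method="mean", offset=offset)
        return px > local, {
            "method": "adaptive",
            "window_px": block,
            "offset": float(offset),
        }
    raise ValueError(f"unknown segmentation method: {method!r}")


def clean_tissue_mask(
    mask: np.ndarray, pixel_size: float, min_object_area: float = 0.144
) -> np.ndarray:
    """Remove small unconnected objects, then fill single-pixel pores.

    Foreground objects (8-connected) with area strictly below
    ``min_object_area`` (mm^2) are removed; background components
    (4-connected) of exactly one pixel are filled. Idempotent.
    """
    if min_object_area < 0:
        raise ValueError("min_object_area must be >= 0")
    m = np.asarray(mask, bool).copy()
    min_px = min_object_area / pixel_size**2
    labels, n = ndimage.label(m, structure=EIGHT)
    if n:
        sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_px) + 1
        if small.size:
            m[np.isin(labels, small)] = False
    bg_labels, nb = ndimage.label(~m, structure=FOUR)
    if nb:
        bg_sizes = ndimage.sum_labels(~m, bg_labels, index=np.arange(1, nb + 1))
        singles = np.flatnonzero(bg_sizes == 1) + 1
        if singles.size:
            m[np.isin(bg_labels, singles)] = True
    return m


def trace_periosteal(
    tissue_mask: np.ndarray, pixel_size: float, closing_radius: float = 0.48
) -> tuple[np.ndarray, np.ndarray]:
    """Trace the periosteal contour on a morphologically closed mask.

    The tissue mask is closed with a disk of ``closing_radius`` (mm), the
    largest 8-connected object is kept, and its interior is filled; the
    returned ``total_mask`` covers the whole bone including marrow and
    pores, with its outer boundary polygon as the periosteal contour.
    """
    m = np.asarray(tissue_mask, bool)
    if not m.any():
        raise ValueError("empty tissue mask: cannot trace a periosteal contour")
    r_px = int(round(closing_radius / pixel_size))
    if r_px > 0:
        # Exact Euclidean disk closing via two distance transforms:
        # dilation = {d(p, mask) <= r}, erosion of it = {d(p, ~dilation) > r}.
        pad = r_px + 1
        padded = np.pad(m, pad)
        dilated = ndimage.distance_transform_edt(~padded) <= r_px
        closed = ndimage.distance_transform_edt(dilated) > r_px
        closed = closed[pad:-pad, pad:-pad]
    else:
        closed = m
    labels, n = ndimage.label(closed, structure=EIGHT)
    if n > 1:
        sizes = ndimage.sum_labels(closed, labels, index=np.arange(1, n + 1))
        closed = labels == (int(np.argmax(sizes)) + 1)
    total = ndimage.binary_fill_holes(closed)
    return mask_contour(total), total


def build_cortical_mask(
    total_mask: np.ndarray,
    tissue_mask: np.ndarray,
    endosteal_contour: np.ndarray,
    periosteal_contour: Optional[np.ndarray] = None,
    pixel_size: float = 0.0,
) -> SectionMasks:
    """Carve the cortical compartment and label the intracortical pores.

    The cortical mask is ``total_mask`` minus the interior of the supplied
    endosteal contour. Pores are 8-connected components of non-tissue
    pixels inside the compartment; components touching the marrow cavity or
    the outside background (indistinguishable from marrow notches in 2D)
    are excluded.
    """
    total = np.asarray(total_mask, bool)
    tissue = np.asarray(tissue_mask, bool)
    endo = np.asarray(endosteal_contour, float)
    if endo.ndim != 2 or endo.shape[0] < 3:
        raise ContourError("endosteal contour must have at least 3 vertices")
    endo_interior = polygon_mask(endo, total.shape)
    outside = int(np.count_nonzero(endo_interior & ~total))
    if outside:
        raise ContourError(
            f"endosteal contour leaves the periosteal region ({outside} px outside)"
        )
    cortical = total & ~endo_interior

    candidates = cortical & ~tissue
    # Marrow cavity and exterior background: any non-tissue void outside the
    # compartment. Pores 8-adjacent to it are treated as marrow/background.
    forbidden = ~tissue & ~cortical
    labels, n = ndimage.label(candidates, structure=EIGHT)
    if n:
        near_forbidden = ndimage.binary_dilation(forbidden, structure=EIGHT)
        bad = np.unique(labels[candidates & near_forbidden])
        bad = bad[bad > 0]
        if bad.size:
            labels[np.isin(labels, bad)] = 0
        # relabel sequentially
        labels, _ = ndimage.label(labels > 0, structure=EIGHT)

    if periosteal_contour is None:
        periosteal_contour = mask_contour(total)
    return SectionMasks(
        tissue_mask=tissue,
        total_mask=total,
        cortical_mask=cortical,
        pore_labels=labels.astype(np.int32),
        periosteal_contour=np.asarray(periosteal_contour, float),
        endosteal_contour=endo,
        pixel_size=pixel_size,
    )


def extract_roi_us(
    masks: SectionMasks, sector_center_deg: float, sector_width_deg: float = 60.0
) -> SectionMasks:
    """Restrict the cortical compartment to an angular sector (ROI).

    The sector is taken about the centroid of the whole section, with
    angles in mathematical convention (0 deg = +x, counter-clockwise with y
    pointing up). Pores are kept if and only if their centroid lies inside
    the sector. Emulates the anteromedial region accessible to in vivo
    ultrasound.
    """
    if not (0 < sector_width_deg <= 360):
        raise ValueError("sector_width_deg must be in (0, 360]")
    cy, cx = ndimage.center_of_mass(masks.total_mask)
    rows, cols = np.indices(masks.total_mask.shape)
    angle = np.degrees(np.arctan2(cy - rows, cols - cx))
    delta = (angle - sector_center_deg + 180.0) % 360.0 - 180.0
    in_sector = np.abs(delta) <= sector_width_deg / 2.0

    cortical = masks.cortical_mask & in_sector
    if not cortical.any():
        raise ValueError("ROI sector contains no cortical pixels")

    labels = masks.pore_labels
    new_labels = np.zeros_like(labels)
    n = int(labels.max())
    if n:
        centroids = ndimage.center_of_mass(labels > 0, labels, index=np.arange(1, n + 1))
        next_id = 1
        for lab, (py, px_) in enumerate(centroids, start=1):
            a = np.degrees(np.arctan2(cy - py, px_ - cx))
            d = (a - sector_center_deg + 180.0) % 360.0 - 180.0
            if abs(d) <= sector_width_deg / 2.0:
                new_labels[labels == lab] = next_id
                next_id += 1
    return SectionMasks(
        tissue_mask=masks.tissue_mask,
        total_mask=masks.total_mask,
        cortical_mask=cortical,
        pore_labels=new_labels,
        periosteal_contour=masks.periosteal_contour,
        endosteal_contour=masks.endosteal_contour,
        pixel_size=masks.pixel_size,
    )


@dataclass
class SegmentationConfig:
    """Parameters of the section segmentation stage.

    Defaults follow standard cortical cross-section processing: objects
    below 0.144 mm^2 removed, single-pixel pores filled, periosteal closing
    radius 0.48 mm.
    """

    method: str = "isodata"
    window_px: Optional[int] = 201
    offset: float = 0.0
    sigma_px: Optional[float] = None  # e.g. 1.1 for CT-like smoothing
    radius_px: float = 2.0
    min_object_area: float = 0.144
    closing_radius: float = 0.48

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def segment_section(
    img: CalibratedImage,
    endosteal_contour: np.ndarray,
    config: SegmentationConfig | None = None,
) -> tuple[SectionMasks, dict]:
    """Run the full segmentation chain on one calibrated image.

    Fixed order: (optional) smooth -> segment -> clean -> trace periosteal
    -> build cortical compartment. Returns the section masks and a
    provenance record of the parameters and thresholds used.
    """
    cfg = config or SegmentationConfig()
    provenance: dict = {"order": ["smooth", "segment", "clean", "trace", "build"]}
    work = img
    if cfg.sigma_px is not None:
        work = smooth_image(work, cfg.sigma_px, cfg.radius_px)
        provenance["smooth"] = {"sigma_px": cfg.sigma_px, "radius_px": cfg.radius_px}
    else:
        provenance["smooth"] = None
    tissue, seg_prov = segment_tissue(work, cfg.method, cfg.window_px, cfg.offset)
    provenance["segment"] = seg_prov
    tissue = clean_tissue_mask(tissue, img.pixel_size, cfg.min_object_area)
    provenance["clean"] = {"min_object_area_mm2": cfg.min_object_area}
    peri, total = trace_periosteal(tissue, img.pixel_size, cfg.closing_radius)
    provenance["trace"] = {"closing_radius_mm": cfg.closing_radius}
    masks = build_cortical_mask(
        total, tissue, endosteal_contour, peri, pixel_size=img.pixel_size
    )
    provenance["n_pores"] = masks.n_pores
    return masks, provenance
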