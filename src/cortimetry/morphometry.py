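"""Cross-sectional cortical-bone morphometry.

Computes the standard 2D cortical parameters from segmented section masks:
areal quantities (Tt.Ar, Ct.Ar, T.Ar, Ct.Wba), cortical thickness (Ct.Th,
the most frequent minimum periosteal-to-endosteal distance), porosity
(Ct.Po), pore density (Po.D), per-pore largest-inscribed-circle diameters
(Po.Dm), and the large-pore stratification of pore count and porosity at
fixed diameter thresholds (Po.D_x, relPo.n_x, Ct.Po_x, relCt.Po_x).

Po.Dm convention: the diameter of the largest inscribed circle of a pore is
``2 * (max distance-to-nearest-non-pore-pixel-center - 0.5) * pixel_size``,
so a single-pixel pore has diameter one pixel. Distances come from the
exact Euclidean distance transform; this convention is unbiased for digital
disks snapped to the pixel lattice.

Diameter-threshold comparisons are strict (Po.Dm > x).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import contour_pixel_mask
from .types import CalibratedImage, SectionMasks

__all__ = [
    "THRESHOLDS_UM",
    "PORE_TABLE_COLUMNS",
    "MORPHOMETRY_COLUMNS",
    "pore_diameters",
    "cortical_thickness",
    "areal_metrics",
    "porosity_metrics",
    "calibrated_intensity_stats",
    "analyze_section",
]

#: Default Po.Dm thresholds (µm) separating large to giant pores.
THRESHOLDS_UM: tuple[float, ...] = (60.0, 100.0, 160.0, 300.0, 385.0)

PORE_TABLE_COLUMNS = [
    "label",
    "area_mm2",
    "podm_mm",
    "cx_px",
    "cy_px",
    "dist_endo_mm",
    "in_roi",
]

_DECILES = tuple(range(10, 100, 10))


def _threshold_names(thresholds_um: Sequence[float]) -> list[str]:
    return [f"{int(round(t))}" for t in thresholds_um]


def morphometry_columns(thresholds_um: Sequence[float] = THRESHOLDS_UM) -> list[str]:
    """Ordered column names of a full morphometry record."""
    names = _threshold_names(thresholds_um)
    cols = ["Tt.Ar", "Ct.Ar", "T.Ar", "Ct.Wba", "Ct.Th", "Ct.Po", "Po.D"]
    cols += [f"Po.D_{n}" for n in names]
    cols += [f"relPo.n_{n}" for n in names]
    cols += [f"Ct.Po_{n}" for n in names]
    cols += [f"relCt.Po_{n}" for n in names]
    cols += ["Po.Dm_mean", "Po.Dm_SD"]
    cols += [f"Po.Dm_q{q}" for q in _DECILES]
    cols += ["vcal_mean", "vcal_SD"]
    return cols


MORPHOMETRY_COLUMNS = morphometry_columns()


def pore_diameters(
    pore_labels: np.ndarray,
    pixel_size: float,
    endosteal_contour: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-pore area, largest-inscribed-circle diameter and centroid.

    Parameters
    ----------
    pore_labels : integer label map (0 = non-pore), one label per
        8-connected pore.
    pixel_size : mm per pixel.
    endosteal_contour : optional ``(x, y)`` polygon; when given, the
        distance from each pore centroid to the endosteal surface is
        reported in ``dist_endo_mm``.

    Returns
    -------
    DataFrame with columns ``label, area_mm2, podm_mm, cx_px, cy_px,
    dist_endo_mm, in_roi`` (empty for an empty label map).
    """
    labels = np.asarray(pore_labels)
    if labels.ndim != 2:
        raise ValueError("pore_labels must be a 2D label map")
    n = int(labels.max())
    if n == 0:
        return pd.DataFrame(columns=PORE_TABLE_COLUMNS)

    index = np.arange(1, n + 1)
    pore_mask = labels > 0
    # Exact Euclidean distance to the nearest non-pore pixel center.
    edt = ndimage.distance_transform_edt(pore_mask)
    max_edt = ndimage.maximum(edt, labels=labels, index=index)
    podm_mm = 2.0 * (np.asarray(max_edt) - 0.5) * pixel_size

    areas_px = ndimage.sum_labels(pore_mask, labels=labels, index=index)
    centroids = ndimage.center_of_mass(pore_mask, labels=labels, index=index)
    cy = np.array([c[0] for c in centroids])
    cx = np.array([c[1] for c in centroids])

    if endosteal_contour is not None:
        endo_px = contour_pixel_mask(endosteal_contour, labels.shape)
        dist_map = ndimage.distance_transform_edt(~endo_px)
        rr = np.clip(np.rint(cy).astype(int), 0, labels.shape[0] - 1)
        cc = np.clip(np.rint(cx).astype(int), 0, labels.shape[1] - 1)
        dist_endo = dist_map[rr, cc] * pixel_size
    else:
        dist_endo = np.full(n, np.nan)

    return pd.DataFrame(
        {
            "label": index,
            "area_mm2": areas_px * pixel_size**2,
            "podm_mm": podm_mm,
            "cx_px": cx,
            "cy_px": cy,
            "dist_endo_mm": dist_endo,
            "in_roi": np.ones(n, dtype=bool),
        }
    )


def cortical_thickness(
    periosteal_contour: np.ndarray,
    endosteal_contour: np.ndarray,
    pixel_size: float,
    bin_width_px: float = 1.0,
) -> float:
    """Most frequent minimum periosteal-to-endosteal distance, in mm.

    For every pixel on the periosteal boundary the minimum Euclidean
    distance to the endosteal contour is computed; Ct.Th is the midpoint of
    the most populated histogram bin (default bin width one pixel). Ties
    are broken toward the smaller distance.
    """
    peri = np.asarray(periosteal_contour, float)
    endo = np.asarray(endosteal_contour, float)
    for name, c in (("periosteal", peri), ("endosteal", endo)):
        if c.ndim != 2 or c.shape[0] < 3:
            raise ValueError(f"degenerate {name} contour (<3 vertices)")
    if not (bin_width_px > 0):
        raise ValueError("bin_width_px must be > 0")

    both = np.vstack([peri, endo])
    x0, y0 = np.floor(both.min(axis=0)).astype(int) - 2
    x1, y1 = np.ceil(both.max(axis=0)).astype(int) + 3
    shape = (y1 - y0, x1 - x0)
    shift = np.array([x0, y0], float)

    endo_px = contour_pixel_mask(endo - shift, shape)
    peri_px = contour_pixel_mask(peri - shift, shape)
    if not endo_px.any() or not peri_px.any():
        raise ValueError("contour rasterized to an empty pixel set")

    dist = ndimage.distance_transform_edt(~endo_px)
    d = dist[peri_px]
    counts = np.bincount(np.floor(d / bin_width_px).astype(int))
    mode_bin = int(np.argmax(counts))  # argmax takes the first max: smaller tie
    return (mode_bin + 0.5) * bin_width_px * pixel_size


def areal_metrics(
    masks: SectionMasks, pixel_size: float
) -> tuple[float, float, float, float]:
    """(Tt.Ar, Ct.Ar, T.Ar, Ct.Wba): section, compartment and tissue areas.

    Tt.Ar is the whole cross-section (inside the periosteal contour);
    Ct.Ar the cortical compartment including pores; T.Ar the mineralized
    tissue inside the section; Ct.Wba the cortical-tissue percentage of
    Tt.Ar.
    """
    total = int(np.count_nonzero(masks.total_mask))
    if total == 0:
        raise ValueError("empty total_mask")
    px2 = pixel_size**2
    ct = int(np.count_nonzero(masks.cortical_mask))
    t = int(np.count_nonzero(masks.tissue_mask & masks.total_mask))
    ct_tissue = int(np.count_nonzero(masks.tissue_mask & masks.cortical_mask))
    return total * px2, ct * px2, t * px2, 100.0 * ct_tissue / total


def porosity_metrics(
    pores: pd.DataFrame,
    cortical_pixels: float,
    pixel_size: float,
    thresholds_um: Sequence[float] = THRESHOLDS_UM,
) -> dict:
    """Porosity, pore density and the large-pore stratified metrics.

    ``cortical_pixels`` may be fractional (an analytic compartment area
    divided by ``pixel_size**2``). With zero pores, Ct.Po and Po.D are 0 and
    the relative metrics are reported missing with ``undefined=True``.
    """
    if not (cortical_pixels > 0):
        raise ValueError("cortical_pixels must be > 0")
    px2 = pixel_size**2
    ct_area = cortical_pixels * px2
    names = _threshold_names(thresholds_um)
    out: dict = {}

    n = len(pores)
    if n == 0:
        out["Ct.Po"] = 0.0
        out["Po.D"] = 0.0
        for nm in names:
            out[f"Po.D_{nm}"] = 0.0
            out[f"relPo.n_{nm}"] = np.nan
            out[f"Ct.Po_{nm}"] = 0.0
            out[f"relCt.Po_{nm}"] = np.nan
        out["Po.Dm_mean"] = np.nan
        out["Po.Dm_SD"] = np.nan
        for q in _DECILES:
            out[f"Po.Dm_q{q}"] = np.nan
        out["undefined"] = True
        return out

    area = pores["area_mm2"].to_numpy(float)
    podm = pores["podm_mm"].to_numpy(float)
    pore_area = float(area.sum())
    ct_po = 100.0 * pore_area / ct_area

    out["Ct.Po"] = ct_po
    out["Po.D"] = n / ct_area
    for t_um, nm in zip(thresholds_um, names):
        big = podm > t_um / 1000.0  # strict: diameter > threshold
        big_area = float(area[big].sum())
        out[f"Po.D_{nm}"] = int(big.sum()) / ct_area
        out[f"relPo.n_{nm}"] = 100.0 * int(big.sum()) / n
        out[f"Ct.Po_{nm}"] = 100.0 * big_area / ct_area
        out[f"relCt.Po_{nm}"] = 100.0 * big_area / pore_area if pore_area > 0 else np.nan
    out["Po.Dm_mean"] = float(podm.mean())
    out["Po.Dm_SD"] = float(podm.std(ddof=0))  # population SD within a section
    for q in _DECILES:
        out[f"Po.Dm_q{q}"] = float(np.quantile(podm, q / 100.0))
    out["undefined"] = False
    return out


def calibrated_intensity_stats(
    img: CalibratedImage, mask: np.ndarray
) -> tuple[float, float]:
    """Mean and population SD of calibrated intensity over masked pixels.

    Stands in for vBMD_cort and SD(vBMD_cort) when the image carries a
    density calibration.
    """
    if img.calibration is None:
        raise ValueError(
            "image has no intensity calibration (sidecar field 'calibration')"
        )
    m = np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty mask")
    vals = img.calibration.apply(img.pixels[m])
    return float(vals.mean()), float(vals.std(ddof=0))


def analyze_section(
    masks: SectionMasks,
    img: Optional[CalibratedImage] = None,
    thresholds_um: Sequence[float] = THRESHOLDS_UM,
    bin_width_px: float = 1.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Full morphometry of one segmented section.

    Returns the morphometry record (a Series with the canonical column
    names) and the per-pore table. Calibrated-intensity statistics are
    filled only when ``img`` carries a calibration; pore statistics are
    computed over the cortical tissue (pores excluded).
    """
    px = masks.pixel_size
    if not (px > 0):
        raise ValueError("masks.pixel_size must be set")
    pores = pore_diameters(masks.pore_labels, px, masks.endosteal_contour)
    tt, ct, t_ar, ct_wba = areal_metrics(masks, px)
    ct_th = cortical_thickness(
        masks.periosteal_contour, masks.endosteal_contour, px, bin_width_px
    )
    rec: dict = {"Tt.Ar": tt, "Ct.Ar": ct, "T.Ar": t_ar, "Ct.Wba": ct_wba, "Ct.Th": ct_th}
    ct_px = int(np.count_nonzero(masks.cortical_mask))
    rec.update(porosity_metrics(pores, ct_px, px, thresholds_um))
    rec.pop("undefined", None)
    if img is not None and img.calibration is not None:
        tissue_cort = masks.tissue_mask & masks.cortical_mask
        rec["vcal_mean"], rec["vcal_SD"] = calibrated_intensity_stats(img, tissue_cort)
    else:
        rec["vcal_mean"] = np.nan
        rec["vcal_SD"] = np.nan
    cols = morphometry_columns(thresholds_um)
    return pd.Series({c: rec[c] for c in cols}), pores
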