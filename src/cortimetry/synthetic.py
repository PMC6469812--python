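"""Synthetic cortical cross-sections and cohorts with exact ground truth.

The generator emulates the measurement situation of a calibrated
cross-section scan of a long-bone diaphysis: an annular cortical shell
between a smooth periosteal contour (ellipse or rounded triangle) and an
endosteal contour offset inward by a possibly angle-dependent wall
thickness, pierced by a population of circular pores. The pore diameter
distribution is a right-skewed lognormal mixture — a "small" Haversian
component plus a heavy "large" component — so that a small fraction of
pores above 100 µm carries a disproportionate share of the total porosity,
and large pores are biased toward the endosteal side by rejection sampling
on depth. Defaults reproduce the pore statistics reported for the aged
human tibia: pore density ~17/mm², mean inscribed-circle diameter ~50 µm
(SD ~35 µm), ~7% of pores above 100 µm carrying ~50% of the porosity.

Pore centers are snapped to the pixel lattice and rasterized as filled
circles, which makes the planted largest-inscribed-circle diameter
recoverable to within one pixel.

Cohorts carry a planted linear outcome
``y = b1·z(aBMD latent) + b2·z(relCt.Po_100) + eps`` on the standardized
scale, rescaled to physical femoral stiffness/strength units, so the
association stage has a known answer to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import morphometry
from .types import CalibratedImage, Calibration, SectionMasks
from .raster import polygon_mask

__all__ = [
    "SectionSpec",
    "GroundTruth",
    "CohortSpec",
    "PorePackingError",
    "generate_cross_section",
    "plant_section",
    "rasterize_section",
    "generate_cohort",
    "OUTCOME_COLUMNS",
]

#: diameter (mm) above which a pore counts as "large" for endosteal biasing
LARGE_PORE_MM = 0.100

#: dense angular grid for boundary evaluation
_N_THETA = 2048


class PorePackingError(RuntimeError):
    """Requested pore count cannot be placed without overlap."""


@dataclass
class SectionSpec:
    """Geometry, pore population and imaging parameters of one section.

    Lengths are mm. ``noise_sd`` is the Gaussian intensity noise expressed
    as a fraction of the tissue-background level separation.
    """

    semi_axes_mm: tuple[float, float] = (2.0, 1.7)
    shape: str = "ellipse"  # "ellipse" | "rounded-triangle"
    triangularity: float = 0.10
    endosteal_offset_mm: float = 0.9
    offset_modulation_mm: float = 0.15
    offset_phase_rad: float = 0.0
    pore_density_per_mm2: float = 17.0
    small_median_mm: float = 0.040
    small_sigma: float = 0.35
    large_median_mm: float = 0.130
    large_sigma: float = 0.40
    large_weight: float = 0.08
    large_pore_bias: float = 0.6
    min_diameter_mm: float = 0.030
    pixel_size_mm: float = 0.012
    noise_sd: float = 0.10
    tissue_level: float = 26000.0
    background_level: float = 9000.0
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.semi_axes_mm
        off_min = self.endosteal_offset_mm - abs(self.offset_modulation_mm)
        if not (min(a, b) > self.endosteal_offset_mm > 0):
            raise ValueError("need semi-axes > endosteal offset > 0")
        if off_min <= 0:
            raise ValueError("offset modulation exceeds the endosteal offset")
        if not (0.0 <= self.large_weight <= 1.0):
            raise ValueError("large_weight must be in [0, 1]")
        if not (0.0 <= self.large_pore_bias <= 1.0):
            raise ValueError("large_pore_bias must be in [0, 1]")
        if not (self.pixel_size_mm > 0):
            raise ValueError("pixel_size_mm must be > 0")
        if self.pore_density_per_mm2 < 0 or self.noise_sd < 0:
            raise ValueError("pore density and noise SD must be >= 0")
        if self.shape not in ("ellipse", "rounded-triangle"):
            raise ValueError(f"unknown shape {self.shape!r}")

    # --- boundary model (polar about the section center) -----------------

    def peri_radius(self, theta: np.ndarray) -> np.ndarray:
        a, b = self.semi_axes_mm
        r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        if self.shape == "rounded-triangle":
            r = r * (1.0 + self.triangularity * np.cos(3.0 * theta))
        return r

    def endo_offset(self, theta: np.ndarray) -> np.ndarray:
        return self.endosteal_offset_mm + self.offset_modulation_mm * np.cos(
            theta - self.offset_phase_rad
        )

    def endo_radius(self, theta: np.ndarray) -> np.ndarray:
        return self.peri_radius(theta) - self.endo_offset(theta)


@dataclass
class GroundTruth:
    """Exact planted truth for one synthetic section.

    Polygons are in mm, centered on the section axis; ``pores`` has columns
    ``x_mm, y_mm, d_mm`` (positions are NaN when the section was sampled
    without spatial placement). Porosity/areal truths are raster-based when
    the section was rasterized, analytic otherwise.
    """

    peri_polygon_mm: np.ndarray
    endo_polygon_mm: np.ndarray
    pores: pd.DataFrame
    total_area_mm2: float
    cortical_area_mm2: float
    ct_po: float
    po_d: float
    ct_th: float
    relpo_n: dict
    relct_po: dict
    placed: bool
    pixel_size_mm: float
    center_px: Optional[tuple[float, float]] = None  # (cx, cy) after rasterization

    def polygon_px(self, which: str = "peri") -> np.ndarray:
        """Ground-truth contour in pixel coordinates (rasterized sections)."""
        if self.center_px is None:
            raise ValueError("section was not rasterized")
        poly = self.peri_polygon_mm if which == "peri" else self.endo_polygon_mm
        cx, cy = self.center_px
        return np.column_stack(
            [cx + poly[:, 0] / self.pixel_size_mm, cy + poly[:, 1] / self.pixel_size_mm]
        )


def _sample_diameters(spec: SectionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw pore diameters from the lognormal mixture, with a floor/cap."""
    off_min = spec.endosteal_offset_mm - abs(spec.offset_modulation_mm)
    cap = max(spec.min_diameter_mm * 1.5, 0.7 * off_min)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = n - filled
        is_large = rng.random(m) < spec.large_weight
        d = np.where(
            is_large,
            spec.large_median_mm * np.exp(spec.large_sigma * rng.standard_normal(m)),
            spec.small_median_mm * np.exp(spec.small_sigma * rng.standard_normal(m)),
        )
        ok = (d >= spec.min_diameter_mm) & (d <= cap)
        k = int(ok.sum())
        out[filled : filled + k] = d[ok]
        filled += k
    return out


def _polar_area(r: np.ndarray) -> float:
    """Area enclosed by a polar curve sampled on a uniform theta grid."""
    return float(0.5 * np.sum(r**2) * (2 * np.pi / r.size))


def _mode_binned(values: np.ndarray, bin_width: float) -> float:
    """Midpoint of the most populated bin; ties go to the smaller bin."""
    counts = np.bincount(np.floor(values / bin_width).astype(int))
    return (int(np.argmax(counts)) + 0.5) * bin_width


def _truth_thresholds(d_mm: np.ndarray) -> tuple[dict, dict]:
    relpo_n: dict = {}
    relct_po: dict = {}
    area = np.pi * (d_mm / 2.0) ** 2
    tot_area = area.sum()
    for t in morphometry.THRESHOLDS_UM:
        key = int(round(t))
        if d_mm.size == 0:
            relpo_n[key] = np.nan
            relct_po[key] = np.nan
            continue
        big = d_mm > t / 1000.0
        relpo_n[key] = 100.0 * big.sum() / d_mm.size
        relct_po[key] = 100.0 * area[big].sum() / tot_area if tot_area > 0 else np.nan
    return relpo_n, relct_po


def plant_section(
    spec: SectionSpec,
    rng: Optional[np.random.Generator] = None,
    place: bool = True,
    wall_px: float = 3.0,
    sep_px: float = 2.0,
    max_tries: int = 400,
) -> GroundTruth:
    """Sample the geometry and pore population of one section.

    With ``place=True`` pore centers are positioned inside the cortical
    shell — snapped to the pixel lattice, pairwise non-overlapping with at
    least ``sep_px`` pixels of separation, and at least ``wall_px`` pixels
    clear of both contours — with large pores biased toward the endosteal
    side by rejection sampling on normalized wall depth. ``place=False``
    skips spatial placement (positions NaN) and is used for fast cohort
    sampling where only the diameter population matters.

    Raises
    ------
    PorePackingError
        If the requested pore count cannot be placed within the retry
        budget; the message names achieved vs requested counts.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    px = spec.pixel_size_mm
    theta = np.linspace(0.0, 2.0 * np.pi, _N_THETA, endpoint=False)
    r_peri = spec.peri_radius(theta)
    r_endo = spec.endo_radius(theta)
    if np.any(r_endo <= 0):
        raise ValueError("endosteal radius non-positive; offsets too large")
    peri_poly = np.column_stack([r_peri * np.cos(theta), r_peri * np.sin(theta)])
    endo_poly = np.column_stack([r_endo * np.cos(theta), r_endo * np.sin(theta)])

    total_area = _polar_area(r_peri)
    ct_area = total_area - _polar_area(r_endo)
    n_pores = int(round(spec.pore_density_per_mm2 * ct_area))
    d = _sample_diameters(spec, n_pores, rng)

    if place and n_pores:
        # larger pores first: easier packing, deterministic order
        d = np.sort(d)[::-1]
        wall = wall_px * px
        sep = sep_px * px
        bias_k = 4.0 * spec.large_pore_bias
        placed_xy = np.empty((n_pores, 2))
        placed_r = np.empty(n_pores)
        k = 0
        for di in d:
            r = di / 2.0
            ok = False
            for _ in range(max_tries):
                th = rng.uniform(0.0, 2.0 * np.pi)
                idx = int(th / (2.0 * np.pi) * _N_THETA) % _N_THETA
                lo, hi = r_endo[idx], r_peri[idx]
                usable = (hi - lo) - 2.0 * (wall + r)
                if usable <= 0:
                    continue
                t = rng.uniform()
                if di > LARGE_PORE_MM and bias_k > 0:
                    # rejection on depth: accept near the endosteal side
                    if rng.uniform() > (1.0 - t) ** bias_k:
                        continue
                rho = lo + wall + r + t * usable
                # snap the center to the pixel lattice
                x = np.round(rho * np.cos(th) / px) * px
                y = np.round(rho * np.sin(th) / px) * px
                p = np.array([x, y])
                # exact containment against the dense boundary polylines
                if np.min(np.hypot(*(peri_poly - p).T)) < r + wall:
                    continue
                if np.min(np.hypot(*(endo_poly - p).T)) < r + wall:
                    continue
                if k:
                    dd = np.hypot(
                        placed_xy[:k, 0] - x, placed_xy[:k, 1] - y
                    )
                    if np.any(dd < placed_r[:k] + r + sep):
                        continue
                ok = True
                break
            if not ok:
                raise PorePackingError(
                    f"placed {k} of {n_pores} requested pores; density "
                    f"{spec.pore_density_per_mm2}/mm^2 is infeasible for this geometry"
                )
            placed_xy[k] = (x, y)
            placed_r[k] = r
            k += 1
        pores = pd.DataFrame(
            {"x_mm": placed_xy[:, 0], "y_mm": placed_xy[:, 1], "d_mm": 2 * placed_r}
        )
    else:
        pores = pd.DataFrame(
            {"x_mm": np.full(n_pores, np.nan), "y_mm": np.full(n_pores, np.nan), "d_mm": d}
        )

    pore_area = float(np.sum(np.pi * (pores["d_mm"].to_numpy() / 2.0) ** 2))
    relpo_n, relct_po = _truth_thresholds(pores["d_mm"].to_numpy())

    if place:
        # True thickness: the most-frequent-minimum-distance definition
        # applied to the true contours at the target pixel size. The wall
        # profile is bimodal (stationary points at both modulation
        # extremes), so the histogram mode is only well-defined relative to
        # a sampling rule; using the measurement definition on the exact
        # contours keeps the truth unambiguous.
        ct_th = morphometry.cortical_thickness(peri_poly / px, endo_poly / px, px)
    else:
        # wall-offset approximation, adequate for cohort covariates
        ct_th = _mode_binned(spec.endo_offset(theta), px)

    return GroundTruth(
        peri_polygon_mm=peri_poly,
        endo_polygon_mm=endo_poly,
        pores=pores,
        total_area_mm2=total_area,
        cortical_area_mm2=ct_area,
        ct_po=100.0 * pore_area / ct_area,
        po_d=n_pores / ct_area,
        ct_th=ct_th,
        relpo_n=relpo_n,
        relct_po=relct_po,
        placed=place,
        pixel_size_mm=px,
    )


def rasterize_section(
    truth: GroundTruth, spec: SectionSpec, rng: Optional[np.random.Generator] = None
) -> tuple[CalibratedImage, SectionMasks]:
    """Rasterize a planted section into an image and its exact masks.

    Two intensity levels (tissue high, background/marrow/pores low) plus
    additive Gaussian noise. The emitted masks are rasterized from the
    ground-truth polygons with the package's shared polygon fill, and the
    truth's areal/porosity fields are updated to the raster values.
    """
    if not truth.placed:
        raise ValueError("cannot rasterize a section sampled with place=False")
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    px = spec.pixel_size_mm
    rmax = float(np.max(np.hypot(*truth.peri_polygon_mm.T)))
    half = int(np.ceil(rmax / px)) + 8
    size = 2 * half + 1
    cx = cy = float(half)
    truth.center_px = (cx, cy)

    peri_px = truth.polygon_px("peri")
    endo_px = truth.polygon_px("endo")
    total = polygon_mask(peri_px, (size, size))
    endo_int = polygon_mask(endo_px, (size, size))
    cortical = total & ~endo_int

    pore_mask = np.zeros((size, size), bool)
    labels = np.zeros((size, size), np.int32)
    for i, (x_mm, y_mm, d_mm) in enumerate(
        truth.pores[["x_mm", "y_mm", "d_mm"]].itertuples(index=False), start=1
    ):
        pcx = cx + x_mm / px
        pcy = cy + y_mm / px
        r = d_mm / 2.0 / px
        lo_r, hi_r = int(np.floor(pcy - r)), int(np.ceil(pcy + r)) + 1
        lo_c, hi_c = int(np.floor(pcx - r)), int(np.ceil(pcx + r)) + 1
        rows, cols = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        disk = (rows - pcy) ** 2 + (cols - pcx) ** 2 <= r**2
        pore_mask[lo_r:hi_r, lo_c:hi_c] |= disk
        labels[lo_r:hi_r, lo_c:hi_c][disk] = i
    if np.any(pore_mask & ~cortical):
        raise RuntimeError("internal error: planted pore escapes the cortical mask")

    tissue = cortical & ~pore_mask

    sep = spec.tissue_level - spec.background_level
    img_f = np.full((size, size), spec.background_level, float)
    img_f[tissue] = spec.tissue_level
    if spec.noise_sd > 0:
        img_f += rng.normal(0.0, spec.noise_sd * sep, img_f.shape)
    pixels = np.clip(np.rint(img_f), 0, 65535).astype(np.uint16)

    # default calibration: maps the tissue level to ~8.0 (acoustic impedance)
    cal = Calibration(slope=4.0e-4, intercept=-2.4, unit="MRayl")
    img = CalibratedImage(pixels, px, "acoustic-impedance", cal)
    masks = SectionMasks(
        tissue_mask=tissue,
        total_mask=total,
        cortical_mask=cortical,
        pore_labels=labels,
        periosteal_contour=peri_px,
        endosteal_contour=endo_px,
        pixel_size=px,
    )

    # raster-consistent truth
    ct_px_count = int(np.count_nonzero(cortical))
    truth.total_area_mm2 = int(np.count_nonzero(total)) * px**2
    truth.cortical_area_mm2 = ct_px_count * px**2
    truth.ct_po = 100.0 * int(np.count_nonzero(pore_mask)) / ct_px_count
    truth.po_d = len(truth.pores) / truth.cortical_area_mm2
    return img, masks


def generate_cross_section(
    spec: SectionSpec,
) -> tuple[CalibratedImage, SectionMasks, GroundTruth]:
    """Generate one synthetic section: image, exact masks, ground truth.

    Deterministic: the same spec (including seed) yields bit-identical
    outputs.
    """
    rng = np.random.default_rng(spec.seed)
    truth = plant_section(spec, rng)
    img, masks = rasterize_section(truth, spec, rng)
    return img, masks, truth


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

OUTCOME_COLUMNS = [
    "hvFE_S_stance",
    "hvFE_Fu_stance",
    "hvFE_S_fall",
    "hvFE_Fu_fall",
]

# physical scale of each outcome (mean, SD) and whether the large-pore
# effect is attenuated (sideways-fall loading engages the proximal femur
# differently from one-legged stance)
_OUTCOME_SCALE = {
    "hvFE_S_stance": (3210.0, 1343.0, 1.0, 0.0),
    "hvFE_Fu_stance": (2605.0, 903.0, 1.0, 0.0),
    "hvFE_S_fall": (1314.0, 376.0, 0.5, -0.4),
    "hvFE_Fu_fall": (1456.0, 460.0, 0.5, -0.4),
}


@dataclass
class CohortSpec:
    """A synthetic cohort with a planted linear outcome model.

    On the standardized scale the stance outcomes follow
    ``y = beta_abmd * z(aBMD latent) + beta_large_pore * z(relCt.Po_100)
    + eps``; fall outcomes use an attenuated large-pore effect and a small
    planted left/right shift. ``noise_sd`` is the residual SD on the
    standardized scale; ``None`` picks the value that gives the outcome
    unit variance. Per-subject section geometry and pore populations are
    drawn from the stated ranges.
    """

    n_subjects: int = 19
    beta_abmd: float = 0.72
    beta_large_pore: float = -0.55
    noise_sd: Optional[float] = None
    abmd_mean: float = 529.0
    abmd_sd: float = 96.0
    abmd_side_sd: float = 15.0
    base_section: SectionSpec = field(default_factory=SectionSpec)
    large_weight_range: tuple[float, float] = (0.02, 0.16)
    density_range: tuple[float, float] = (13.0, 21.0)
    offset_range: tuple[float, float] = (0.65, 1.15)
    scale_range: tuple[float, float] = (0.85, 1.15)
    morphometry_mode: str = "analytic"  # "analytic" | "image"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need n >= 3 subjects (statistics undefined below)")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.morphometry_mode not in ("analytic", "image"):
            raise ValueError(f"unknown morphometry_mode {self.morphometry_mode!r}")

    def residual_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        v = 1.0 - self.beta_abmd**2 - self.beta_large_pore**2
        if v < 0:
            raise ValueError("beta_abmd^2 + beta_large_pore^2 must be <= 1")
        return float(np.sqrt(v))


def _subject_spec(cspec: CohortSpec, rng: np.random.Generator) -> SectionSpec:
    base = cspec.base_section
    s = rng.uniform(*cspec.scale_range)
    a, b = base.semi_axes_mm
    return replace(
        base,
        semi_axes_mm=(a * s, b * s),
        endosteal_offset_mm=rng.uniform(*cspec.offset_range),
        offset_modulation_mm=base.offset_modulation_mm
        * rng.uniform(*cspec.offset_range)
        / base.endosteal_offset_mm,
        pore_density_per_mm2=rng.uniform(*cspec.density_range),
        large_weight=rng.uniform(*cspec.large_weight_range),
        offset_phase_rad=rng.uniform(0.0, 2.0 * np.pi),
    )


def _measure_analytic(truth: GroundTruth, spec: SectionSpec) -> pd.Series:
    """Morphometry record from planted geometry via the metric formulas."""
    px = spec.pixel_size_mm
    d = truth.pores["d_mm"].to_numpy()
    pore_tbl = pd.DataFrame(
        {
            "label": np.arange(1, len(d) + 1),
            "area_mm2": np.pi * (d / 2.0) ** 2,
            "podm_mm": d,
            "cx_px": truth.pores["x_mm"] / px,
            "cy_px": truth.pores["y_mm"] / px,
            "dist_endo_mm": np.nan,
            "in_roi": True,
        }
    )
    rec = morphometry.porosity_metrics(
        pore_tbl, truth.cortical_area_mm2 / px**2, px
    )
    rec.pop("undefined", None)
    pore_area = float(pore_tbl["area_mm2"].sum())
    rec["Tt.Ar"] = truth.total_area_mm2
    rec["Ct.Ar"] = truth.cortical_area_mm2
    rec["T.Ar"] = truth.cortical_area_mm2 - pore_area
    rec["Ct.Wba"] = 100.0 * (truth.cortical_area_mm2 - pore_area) / truth.total_area_mm2
    rec["Ct.Th"] = truth.ct_th
    sep = spec.tissue_level - spec.background_level
    cal = Calibration(slope=4.0e-4, intercept=-2.4)
    rec["vcal_mean"] = cal.slope * spec.tissue_level + cal.intercept
    rec["vcal_SD"] = cal.slope * spec.noise_sd * sep
    return pd.Series({c: rec[c] for c in morphometry.MORPHOMETRY_COLUMNS})


def _measure_image(spec: SectionSpec) -> tuple[pd.Series, GroundTruth]:
    from .segmentation import SegmentationConfig, segment_section

    img, _, truth = generate_cross_section(spec)
    masks, _ = segment_section(img, truth.polygon_px("endo"), SegmentationConfig())
    rec, _ = morphometry.analyze_section(masks, img)
    return rec, truth


def generate_cohort(
    cspec: CohortSpec,
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Generate a cohort table with measured morphometry and planted outcomes.

    Morphometry columns are computed by the morphometry module from the
    generated sections — through the full rasterize/segment/measure chain
    in ``image`` mode, or from the planted pore population and compartment
    geometry through the same metric formulas in ``analytic`` mode (fast
    path for Monte-Carlo work). Outcomes are then planted on the measured
    relCt.Po_100 column, never copied from ground truth.

    Returns one wide row per subject: left-tibia morphometry, left/right
    aBMD_neck, and left/right femoral stiffness/strength per load case.
    """
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_subjects
    records: list[pd.Series] = []
    truths: list[GroundTruth] = []
    for i in range(n):
        spec = _subject_spec(cspec, rng)
        spec = replace(spec, seed=int(rng.integers(0, 2**31 - 1)))
        if cspec.morphometry_mode == "image":
            rec, truth = _measure_image(spec)
        else:
            truth = plant_section(spec, np.random.default_rng(spec.seed), place=False)
            rec = _measure_analytic(truth, spec)
        records.append(rec)
        truths.append(truth)
    morpho = pd.DataFrame(records).reset_index(drop=True)

    latent = rng.standard_normal(n)
    abmd_left = cspec.abmd_mean + cspec.abmd_sd * latent
    abmd_right = abmd_left + rng.normal(0.0, cspec.abmd_side_sd, n)

    relpo = morpho["relCt.Po_100"].to_numpy(float)
    z_relpo = (relpo - relpo.mean()) / relpo.std(ddof=1)
    z_abmd = (abmd_left - abmd_left.mean()) / abmd_left.std(ddof=1)

    sd_res = cspec.residual_sd()
    df = pd.DataFrame({"subject": np.arange(1, n + 1)})
    df["aBMD_neck_left"] = abmd_left
    df["aBMD_neck_right"] = abmd_right
    df = pd.concat([df, morpho], axis=1)
    for name, (mean, sd, atten, side_shift) in _OUTCOME_SCALE.items():
        b2 = cspec.beta_large_pore * atten
        lin = cspec.beta_abmd * z_abmd + b2 * z_relpo
        y_left = lin + sd_res * rng.standard_normal(n)
        y_right = lin + sd_res * rng.standard_normal(n) + side_shift
        df[f"{name}_left"] = mean + sd * y_left
        df[f"{name}_right"] = mean + sd * y_right
    return df, truths
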