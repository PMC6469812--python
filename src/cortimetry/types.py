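"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Images and masks are 2D numpy arrays indexed ``[row, col]`` (0-based,
  row-major); pixel centers sit at integer coordinates.
* Contours are ``(N, 2)`` float arrays of ``(x, y) = (col, row)`` pixel
  coordinates, closed implicitly (last vertex connects to the first).
* Areas are pixel counts times ``pixel_size**2``; all physical lengths
  are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["Calibration", "CalibratedImage", "SectionMasks"]


@dataclass(frozen=True)
class Calibration:
    """Linear map from stored intensity to physical units.

    ``physical = slope * intensity + intercept`` — e.g. Hounsfield-style
    conversion to volumetric BMD (mgHA/cm^3) or to acoustic impedance
    (MRayl).
    """

    slope: float
    intercept: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")

    def apply(self, values: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(values, dtype=float) + self.intercept


@dataclass
class CalibratedImage:
    """A 2D grayscale cross-section image with physical pixel size.

    Parameters
    ----------
    pixels : 2D array of intensities (any numeric dtype).
    pixel_size : isotropic pixel edge length in mm (> 0).
    modality : free tag, e.g. ``"acoustic-impedance"`` or ``"density"``.
    calibration : optional linear intensity calibration.
    """

    pixels: np.ndarray
    pixel_size: float
    modality: str = "acoustic-impedance"
    calibration: Optional[Calibration] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError("image must be a 2D grid of at least 2x2 pixels")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SectionMasks:
    """Binary masks and contours describing one segmented cross-section.

    ``total_mask`` covers the whole bone inside the periosteal contour
    (including marrow cavity and pores); ``cortical_mask`` is the cortical
    compartment (total minus the endosteal interior), pores included;
    ``tissue_mask`` marks mineralized-tissue pixels; ``pore_labels`` is a
    non-negative integer map of 8-connected intracortical pores (0 =
    non-pore), each fully enclosed in the cortical compartment.
    """

    tissue_mask: np.ndarray
    total_mask: np.ndarray
    cortical_mask: np.ndarray
    pore_labels: np.ndarray
    periosteal_contour: np.ndarray
    endosteal_contour: np.ndarray
    pixel_size: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tissue_mask", "total_mask", "cortical_mask"):
            m = np.asarray(getattr(self, name))
            setattr(self, name, m.astype(bool))
        self.pore_labels = np.asarray(self.pore_labels).astype(np.int32)

    @property
    def n_pores(self) -> int:
        return int(self.pore_labels.max())

    @property
    def pore_mask(self) -> np.ndarray:
        return self.pore_labels > 0
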