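"""Reading and writing of pipeline artifacts.

Images travel as 16-bit grayscale TIFF with a YAML sidecar carrying the
physical metadata (``pixel_size_mm``, ``modality``, optional linear
``calibration``); masks as 8-bit PNG (0/255); contours and tables as CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .types import CalibratedImage, Calibration

__all__ = [
    "write_image",
    "read_image",
    "write_mask_png",
    "read_mask_png",
    "write_contour_csv",
    "read_contour_csv",
]


def write_image(img: CalibratedImage, path: str | Path) -> Path:
    """Write a 16-bit grayscale TIFF plus a ``<stem>.yaml`` sidecar."""
    path = Path(path)
    px = np.asarray(img.pixels)
    if px.dtype != np.uint16:
        px = np.clip(np.rint(px), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, px, photometric="minisblack")
    meta: dict = {"pixel_size_mm": float(img.pixel_size), "modality": img.modality}
    if img.calibration is not None:
        meta["calibration"] = {
            "slope": float(img.calibration.slope),
            "intercept": float(img.calibration.intercept),
            "unit": img.calibration.unit,
        }
    sidecar = path.with_suffix(".yaml")
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_image(path: str | Path, sidecar: Optional[str | Path] = None) -> CalibratedImage:
    """Read a TIFF/PNG image and its YAML sidecar into a CalibratedImage."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = np.asarray(Image.open(path))
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".yaml")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar metadata {sidecar} (needs pixel_size_mm)"
        )
    meta = yaml.safe_load(sidecar.read_text())
    cal = None
    if meta.get("calibration"):
        c = meta["calibration"]
        cal = Calibration(float(c["slope"]), float(c["intercept"]), c.get("unit", ""))
    return CalibratedImage(
        pixels=px,
        pixel_size=float(meta["pixel_size_mm"]),
        modality=meta.get("modality", "unknown"),
        calibration=cal,
    )


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_contour_csv(contour: np.ndarray, path: str | Path) -> Path:
    """Write a closed polygon as CSV with columns ``x_px, y_px``."""
    path = Path(path)
    pd.DataFrame(np.asarray(contour, float), columns=["x_px", "y_px"]).to_csv(
        path, index=False
    )
    return path


def read_contour_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if not {"x_px", "y_px"} <= set(df.columns):
        raise ValueError(f"{path}: contour CSV must have columns x_px, y_px")
    return df[["x_px", "y_px"]].to_numpy(float)
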