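"""Shared fixtures: generated sections and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cortimetry import morphometry
from cortimetry.segmentation import SegmentationConfig, segment_section
from cortimetry.synthetic import SectionSpec, generate_cross_section


@pytest.fixture(scope="session")
def default_section():
    """One default synthetic section: (image, ground-truth masks, truth)."""
    return generate_cross_section(SectionSpec(seed=42))


@pytest.fixture(scope="session")
def segmented_section(default_section):
    """The default section pushed through the full segmentation chain."""
    img, _, truth = default_section
    masks, prov = segment_section(img, truth.polygon_px("endo"), SegmentationConfig())
    return img, masks, truth, prov


@pytest.fixture(scope="session")
def measured_section(segmented_section):
    img, masks, truth, _ = segmented_section
    record, pores = morphometry.analyze_section(masks, img)
    return record, pores, truth


def brute_force_podm(pore_labels: np.ndarray, label: int, pixel_size: float) -> float:
    """Independent largest-inscribed-circle diameter by exhaustive search.

    For every pixel of the pore, the squared distance to every non-pore
    pixel center in a sufficient crop is enumerated; the inscribed radius
    is the max-min distance. Same pixel metric and -0.5 px convention as
    the production path, but no distance transform.
    """
    pore = pore_labels == label
    rows, cols = np.nonzero(pore)
    # crop with margin larger than any possible inscribed radius
    margin = int(np.ceil((np.ptp(rows) + np.ptp(cols)) / 2)) + 3
    r0, r1 = max(rows.min() - margin, 0), min(rows.max() + margin + 1, pore_labels.shape[0])
    c0, c1 = max(cols.min() - margin, 0), min(cols.max() + margin + 1, pore_labels.shape[1])
    crop_pore = pore[r0:r1, c0:c1]
    crop_all_pores = pore_labels[r0:r1, c0:c1] > 0
    fg = np.argwhere(crop_pore)
    bg = np.argwhere(~crop_all_pores)  # any non-pore pixel, as in the EDT
    d2 = cdist(fg, bg, "sqeuclidean")
    r_max = np.sqrt(d2.min(axis=1).max())
    return 2.0 * (r_max - 0.5) * pixel_size


@pytest.fixture
def podm_oracle():
    return brute_force_podm
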