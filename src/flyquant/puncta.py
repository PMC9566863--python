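"""ApoII puncta counting and Dilp5 integrated density inside an IPC ROI.

The ImageJ-style recipe: maximum-intensity project the stack, restrict
to the manually drawn region of interest (supplied as a mask — ROI
drawing is out of scope), binarize with the moment-preserving automatic
threshold, separate touching particles with a watershed, then count
particles and the percentage of ROI area they cover. Dilp5 abundance is
the integrated density (sum of pixel values) of a z-summation projection
over the ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import stats as fqstats
from .image import (
    DegenerateHistogramError,
    ImageStack,
    max_project,
    moments_threshold,
    sum_project,
    watershed_separate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PunctaConfig",
    "PunctaResult",
    "DensityResult",
    "quantify_puncta",
    "quantify_integrated_density",
    "compare_groups_welch",
]


@dataclass
class PunctaConfig:
    """Particle-analysis settings (ImageJ "Analyze Particles" defaults:
    no size or circularity exclusion unless configured)."""

    min_size_px: int = 1
    use_watershed: bool = True
    roi_first: bool = True   # threshold from ROI pixels (default) or whole frame


@dataclass
class PunctaResult:
    n_puncta: int
    area_fraction: float      # % of ROI area covered by puncta
    threshold_used: float
    roi_area: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_fraction <= 100.0:
            raise ValueError("area_fraction must be a percentage in [0, 100]")
        if (self.n_puncta == 0) != (self.area_fraction == 0.0):
            raise ValueError("n_puncta = 0 iff area_fraction = 0")


@dataclass
class DensityResult:
    integrated_density: float
    roi_area: int


def quantify_puncta(stack: ImageStack, roi: np.ndarray,
                    cfg: PunctaConfig | None = None) -> PunctaResult:
    """Count puncta and their ROI area fraction.

    A degenerate (single-gray-level) histogram inside the ROI means blank
    tissue: the result is 0 puncta with a logged warning, not an error.
    """
    cfg = cfg or PunctaConfig()
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI must be non-empty")
    proj = max_project(stack)
    if roi.shape != proj.shape:
        raise ValueError("ROI shape must match the projected image")
    roi_area = int(roi.sum())
    values = proj[roi] if cfg.roi_first else proj
    try:
        t = moments_threshold(values, bit_depth=stack.bit_depth)
    except DegenerateHistogramError:
        logger.warning("degenerate histogram inside ROI: reporting 0 puncta")
        return PunctaResult(n_puncta=0, area_fraction=0.0,
                            threshold_used=float("nan"), roi_area=roi_area)
    mask = (proj > t) & roi
    if not mask.any():
        return PunctaResult(n_puncta=0, area_fraction=0.0,
                            threshold_used=t, roi_area=roi_area)
    if cfg.use_watershed:
        labels = watershed_separate(mask)
    else:
        from scipy import ndimage as ndi
        labels, _ = ndi.label(mask)
    sizes = np.bincount(labels.ravel())[1:]
    n = int((sizes >= cfg.min_size_px).sum())
    keep_px = int(sizes[sizes >= cfg.min_size_px].sum())
    area_fraction = 100.0 * keep_px / roi_area
    if n == 0:
        area_fraction = 0.0
    return PunctaResult(n_puncta=n, area_fraction=area_fraction,
                        threshold_used=t, roi_area=roi_area)


def quantify_integrated_density(stack: ImageStack, roi: np.ndarray) -> DensityResult:
    """Integrated density: sum of the z-summation projection over the ROI."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI must be non-empty")
    proj = sum_project(stack)
    if roi.shape != proj.shape:
        raise ValueError("ROI shape must match the projected image")
    return DensityResult(integrated_density=float(proj[roi].sum()),
                         roi_area=int(roi.sum()))


def compare_groups_welch(group_a, group_b) -> fqstats.StatResult:
    """Unpaired Welch t test on per-fly scalar quantifications."""
    return fqstats.welch_t(group_a, group_b)
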