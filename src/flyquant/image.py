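"""Shared low-level image operators for the confocal-stack pipelines.

Conventions: stacks are indexed (z, y, x), 0-based, with half-open ranges.
Automatic thresholds depend only on the gray-level histogram (native
integer levels for 8-bit data, 256 equal-width bins otherwise, mirroring
the behaviour class of the original ImageJ analysis).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation

__all__ = [
    "ImageStack",
    "DegenerateHistogramError",
    "max_project",
    "sum_project",
    "moments_threshold",
    "global_threshold",
    "morph_cleanup",
    "watershed_separate",
    "relabel_sequential",
    "write_threshold_log",
]


class DegenerateHistogramError(ValueError):
    """Raised when an automatic threshold is asked for a constant image."""


@dataclass
class ImageStack:
    """A single-channel confocal z-stack with physical voxel size.

    voxels: (z, y, x) non-negative intensity grid.
    voxel_size: (µm per z step, µm per xy pixel) — z-spacing is typically
        0.3 µm for stacks spanning the full depth of the tissue.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float] = (0.3, 0.3)
    channel: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a 3D (z, y, x) array with z >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        vmax = 2 ** self.bit_depth - 1
        if self.voxels.size and (self.voxels.min() < 0 or self.voxels.max() > vmax):
            raise ValueError(f"intensities must lie in [0, {vmax}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dxy = self.voxel_size
        return dz * dxy * dxy

    def to_tiff(self, path) -> None:
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        tifffile.imwrite(path, self.voxels.astype(dtype),
                         photometric="minisblack")

    @classmethod
    def from_tiff(cls, path, voxel_size=(0.3, 0.3), channel="", bit_depth=None):
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:
            voxels = voxels[None]
        if bit_depth is None:
            bit_depth = 8 if voxels.dtype == np.uint8 else 16
        return cls(voxels=voxels, voxel_size=tuple(voxel_size),
                   channel=channel, bit_depth=bit_depth)


def max_project(stack: ImageStack) -> np.ndarray:
    """Maximum-intensity projection along z."""
    return stack.voxels.max(axis=0)


def sum_project(stack: ImageStack) -> np.ndarray:
    """Summation projection along z; dtype widened to avoid overflow."""
    voxels = stack.voxels
    if np.issubdtype(voxels.dtype, np.integer):
        return voxels.sum(axis=0, dtype=np.int64)
    return voxels.sum(axis=0, dtype=np.float64)


# ---------------------------------------------------------------------------
# automatic thresholds
# ---------------------------------------------------------------------------

def _histogram(values: np.ndarray, bit_depth: int = 8):
    """Gray-level histogram: native levels for 8-bit, else 256 equal bins.

    Returns (counts, bin_centers)."""
    values = np.asarray(values).ravel()
    if bit_depth == 8 and np.issubdtype(values.dtype, np.integer):
        counts = np.bincount(values.astype(np.int64), minlength=256)[:256]
        centers = np.arange(256, dtype=float)
        return counts.astype(float), centers
    lo, hi = float(values.min()), float(values.max())
    counts, edges = np.histogram(values, bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def moments_threshold(image, bit_depth: int = 8) -> float:
    """Moment-preserving (Tsai) automatic threshold.

    Chooses the threshold for which the binarized two-level image
    preserves the first three gray-level moments of the input histogram:
    the moments m1–m3 determine a two-delta distribution (levels z0 < z1
    with background fraction p0), and the threshold is the gray level at
    which the cumulative histogram first reaches p0. This is the
    algorithm behind ImageJ's "Moments" auto-threshold.
    """
    values = np.asarray(image)
    counts, centers = _histogram(values, bit_depth=bit_depth)
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("degenerate histogram: fewer than 2 gray levels")
    p = counts / counts.sum()
    # moments over normalized bin index (0..nbins-1); threshold selection
    # depends only on the cumulative fraction so the index scale cancels.
    idx = np.arange(p.size, dtype=float)
    m1 = float((idx * p).sum())
    m2 = float((idx ** 2 * p).sum())
    m3 = float((idx ** 3 * p).sum())
    cd = m2 - m1 * m1
    if cd <= 0:
        raise DegenerateHistogramError("degenerate histogram: zero variance")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    if z1 == z0:
        raise DegenerateHistogramError("degenerate histogram: coincident levels")
    p0 = (z1 - m1) / (z1 - z0)  # background fraction
    cum = np.cumsum(p)
    k = int(np.searchsorted(cum, p0))
    k = min(max(k, 0), p.size - 1)
    # Thresholds spanning a run of empty bins binarize identically, so the
    # quantile is an interval, not a point. Pick the side of the cumulative
    # jump at k whose background fraction is closer to p0, then centre the
    # threshold in that run — deterministic and centred in histogram valleys.
    j = k
    while j + 1 < p.size and cum[j + 1] == cum[k]:
        j += 1
    if k > 0 and p[k - 1] == 0:
        i = k - 1
        while i > 0 and p[i - 1] == 0:
            i -= 1
        i = max(i - 1, 0)  # run starts at the last populated bin below
        if p0 - cum[k - 1] < cum[k] - p0:
            return float(centers[(i + k - 1) // 2])
    return float(centers[(k + j) // 2])


def global_threshold(image, method="otsu", fixed: float | None = None,
                     bit_depth: int = 8):
    """Binarize an image with a global threshold.

    method: "otsu" (default), "moments", or "fixed" (requires ``fixed``).
    Returns (mask, threshold); the mask is image > threshold.
    """
    image = np.asarray(image)
    if method == "fixed":
        if fixed is None:
            raise ValueError("fixed method requires a threshold value")
        t = float(fixed)
    elif method == "moments":
        t = moments_threshold(image, bit_depth=bit_depth)
    elif method == "otsu":
        if np.unique(image).size < 2:
            raise DegenerateHistogramError("degenerate histogram: constant image")
        counts, centers = _histogram(image, bit_depth=bit_depth)
        t = float(filters.threshold_otsu(hist=(counts, centers)))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return image > t, t


# ---------------------------------------------------------------------------
# morphology and watershed
# ---------------------------------------------------------------------------

def morph_cleanup(mask, opening_radius: int = 0, min_area: int = 0,
                  fill_holes: bool = False) -> np.ndarray:
    """Basic binary cleanup: disk opening, optional hole fill, size filter."""
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    if opening_radius > 0:
        selem = morphology.disk(opening_radius)
        out = ndi.binary_erosion(out, structure=selem)
        out = ndi.binary_dilation(out, structure=selem)
    if fill_holes:
        out = ndi.binary_fill_holes(out)
    if min_area > 0:
        comps, n = ndi.label(out)
        sizes = np.bincount(comps.ravel())
        keep = sizes >= min_area
        keep[0] = False
        out = keep[comps]
    return out


def relabel_sequential(labels: np.ndarray) -> np.ndarray:
    """Remap positive labels to consecutive 1..K preserving order."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(present, start=1):
        out[labels == old] = new
    return out


def watershed_separate(mask, h: float = 1.0) -> np.ndarray:
    """Separate touching objects with a distance-transform watershed.

    Seeds are the h-maxima of the Euclidean distance transform of the
    mask (h in pixels, default 1). Every foreground pixel is assigned to
    exactly one label and the union of labels equals the input mask;
    connected components with no detected maximum fall back to a single
    label. Background is untouched (label 0).
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return out
    dist = ndi.distance_transform_edt(mask)
    peaks = morphology.h_maxima(dist, h)
    markers, n_seed = ndi.label(peaks)
    if n_seed == 0:
        comps, _ = ndi.label(mask)
        return relabel_sequential(comps)
    labels = segmentation.watershed(-dist, markers=markers, mask=mask)
    # components whose pixels received no seed keep their own label
    missing = mask & (labels == 0)
    if missing.any():
        comps, _ = ndi.label(missing)
        comps[comps > 0] += labels.max()
        labels = labels + comps
    return relabel_sequential(labels)


def write_threshold_log(path, entries: list[dict]) -> None:
    """JSON provenance sidecar recording every automatic threshold used."""
    Path(path).write_text(json.dumps({"thresholds": entries}, indent=2))
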