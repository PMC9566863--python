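"""Synthetic-data generators with known ground truth.

Three families of fixtures mirror the study's raw inputs:

* two-channel confocal stacks of fat-body nuclei — ellipsoidal nuclei
  whose envelope carries a bright lamin rim, with a nuclear:cytoplasmic
  partition of the FOXO reporter signal;
* per-well FLIC capacitance traces — a sub-threshold baseline with
  injected supra-threshold feeding bouts;
* long-format replicate tables with stated per-cell means and noise,
  standing in for TAG, lipidomics and feeding-count spreadsheets;
* small puncta scenes (diffraction-blurred spots inside an ROI) for the
  particle-counting pipeline.

Every generator takes an explicit integer seed and is bit-reproducible:
identical spec + seed gives identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .image import ImageStack

__all__ = [
    "NucleiSceneSpec",
    "NucleiGroundTruth",
    "generate_nuclei_stack",
    "FlicSceneSpec",
    "generate_flic_series",
    "TableSceneSpec",
    "generate_grouped_table",
    "PunctaSceneSpec",
    "generate_puncta_scene",
    "write_scene_spec",
]

FLIC_EVENT_THRESHOLD = 40.0  # a.u.; any signal above this is a feeding event


class ScenePlacementError(RuntimeError):
    """Raised when non-overlapping object placement fails."""


# ---------------------------------------------------------------------------
# nuclei scenes
# ---------------------------------------------------------------------------

@dataclass
class NucleiSceneSpec:
    """Parameters of a two-channel fat-body nuclei scene.

    Intensities are arbitrary units on the stated bit depth; lengths are
    µm. Nuclei are spheres (axis-aligned ellipsoids in voxel space once
    the anisotropic voxel size is applied) placed by rejection sampling
    so that no two nuclei overlap, rims included.
    """

    image_shape: tuple[int, int, int] = (32, 192, 192)
    voxel_size: tuple[float, float] = (0.3, 0.3)
    n_nuclei: int = 8
    radius_range: tuple[float, float] = (1.5, 2.5)
    rim_width: float = 0.45
    rim_intensity: float = 180.0
    cytoplasm_intensity: float = 20.0
    nuclear_foxo: float = 120.0
    cyto_foxo: float = 40.0
    noise_sd: float = 6.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must be positive and ordered")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        dz, dxy = self.voxel_size
        r_out = self.radius_range[1] + self.rim_width
        nz, ny, nx = self.image_shape
        if 2 * r_out >= min(nz * dz, ny * dxy, nx * dxy):
            raise ValueError("nuclei too large for the volume")


@dataclass
class NucleiGroundTruth:
    """Per-nucleus truth for a generated scene."""

    centers_um: np.ndarray      # (n, 3) in µm, (z, y, x)
    radii_um: np.ndarray        # (n,)
    labels: np.ndarray          # (z, y, x) int16, 0 background, 1..n nuclei
    nuclear_foxo: float         # true mean FOXO inside every nucleus


def _place_spheres(spec: NucleiSceneSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping sphere centers and radii (µm)."""
    dz, dxy = spec.voxel_size
    extent = np.array([spec.image_shape[0] * dz,
                       spec.image_shape[1] * dxy,
                       spec.image_shape[2] * dxy])
    margin_extra = max(dz, dxy)  # one voxel of clearance from walls/neighbours
    centers, radii = [], []
    for _ in range(spec.n_nuclei):
        for attempt in range(1000):
            r = rng.uniform(*spec.radius_range)
            lo = r + spec.rim_width + margin_extra
            c = rng.uniform(lo, extent - lo)
            ok = all(
                np.linalg.norm(c - c2) > r + r2 + 2 * spec.rim_width + margin_extra
                for c2, r2 in zip(centers, radii)
            )
            if ok:
                centers.append(c)
                radii.append(r)
                break
        else:
            raise ScenePlacementError(
                f"could not place nucleus {len(centers) + 1} of {spec.n_nuclei} "
                "without overlap in 1000 attempts"
            )
    return np.array(centers).reshape(-1, 3), np.array(radii)


def generate_nuclei_stack(spec: NucleiSceneSpec):
    """Render a nuclei scene → (lamin stack, foxo stack, ground truth).

    The lamin channel is a bright shell of ``rim_width`` around each
    nucleus over a dim cytoplasm background; the FOXO channel takes
    ``nuclear_foxo`` inside nuclei and ``cyto_foxo`` outside. Gaussian
    noise of ``noise_sd`` is added to both channels, then values are
    rounded and clipped to the bit depth.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.image_shape
    dz, dxy = spec.voxel_size
    centers, radii = _place_spheres(spec, rng)

    lamin = np.full(spec.image_shape, spec.cytoplasm_intensity, dtype=np.float64)
    foxo = np.full(spec.image_shape, spec.cyto_foxo, dtype=np.float64)
    labels = np.zeros(spec.image_shape, dtype=np.int16)

    for k, (c, r) in enumerate(zip(centers, radii), start=1):
        r_out = r + spec.rim_width
        # bounding box in voxel indices
        zlo = max(int((c[0] - r_out) / dz) - 1, 0)
        zhi = min(int((c[0] + r_out) / dz) + 2, nz)
        ylo = max(int((c[1] - r_out) / dxy) - 1, 0)
        yhi = min(int((c[1] + r_out) / dxy) + 2, ny)
        xlo = max(int((c[2] - r_out) / dxy) - 1, 0)
        xhi = min(int((c[2] + r_out) / dxy) + 2, nx)
        zz, yy, xx = np.meshgrid(
            (np.arange(zlo, zhi) + 0.5) * dz - c[0],
            (np.arange(ylo, yhi) + 0.5) * dxy - c[1],
            (np.arange(xlo, xhi) + 0.5) * dxy - c[2],
            indexing="ij",
        )
        d = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
        interior = d <= r
        shell = (d > r) & (d <= r_out)
        sl = np.s_[zlo:zhi, ylo:yhi, xlo:xhi]
        lamin[sl][shell] = spec.rim_intensity
        foxo[sl][interior] = spec.nuclear_foxo
        labels[sl][interior] = k

    vmax = float(2 ** spec.bit_depth - 1)
    out = []
    for chan in (lamin, foxo):
        if spec.noise_sd > 0:
            chan = chan + rng.normal(0.0, spec.noise_sd, size=chan.shape)
        chan = np.clip(np.rint(chan), 0, vmax)
        dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
        out.append(chan.astype(dtype))

    lamin_stack = ImageStack(out[0], voxel_size=spec.voxel_size,
                             channel="lamin", bit_depth=spec.bit_depth)
    foxo_stack = ImageStack(out[1], voxel_size=spec.voxel_size,
                            channel="foxo", bit_depth=spec.bit_depth)
    truth = NucleiGroundTruth(centers_um=centers, radii_um=radii,
                              labels=labels, nuclear_foxo=spec.nuclear_foxo)
    return lamin_stack, foxo_stack, truth


# ---------------------------------------------------------------------------
# FLIC series
# ---------------------------------------------------------------------------

@dataclass
class FlicSceneSpec:
    """Parameters of one synthetic per-well FLIC capacitance trace.

    The default 10 800 s duration matches the 3-hr assessment window in
    which feeding is measured. The instrument's sampling rate is not a
    published constant; 5 Hz is this package's fixture default.
    """

    duration: float = 10_800.0
    sampling_rate: float = 5.0
    baseline_mean: float = 10.0
    baseline_sd: float = 5.0
    bout_rate: float = 0.05            # bouts per minute
    bout_duration_range: tuple[float, float] = (1.0, 5.0)
    bout_amplitude_range: tuple[float, float] = (60.0, 120.0)
    seed: int = 0
    threshold: float = FLIC_EVENT_THRESHOLD

    def __post_init__(self) -> None:
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x sampling_rate must be an integer")
        if self.baseline_mean + 4.0 * self.baseline_sd >= self.threshold:
            raise ValueError(
                "baseline too close to the event threshold: require "
                "baseline_mean + 4*baseline_sd < threshold"
            )
        if self.bout_amplitude_range[0] <= self.threshold:
            raise ValueError("bout amplitudes must be strictly above the threshold")
        if self.bout_rate < 0:
            raise ValueError("bout_rate must be >= 0")
        if self.bout_duration_range[0] <= 0:
            raise ValueError("bout durations must be positive")


def generate_flic_series(spec: FlicSceneSpec, well: str = "w1", diet: str = "NF",
                         state: str = "fed", day: int = 14, genotype: str = "w1118"):
    """Render one FLIC trace → (FlicSeries, list of true FeedingEvent).

    The baseline is Gaussian noise clipped to stay strictly below the
    event threshold (ground truth would otherwise be ill-defined).
    Bouts are plateaus at their drawn amplitude, so every in-bout sample
    is supra-threshold and the injected bout count is exactly what
    runs-mode event detection must recover. Bouts are separated by at
    least one baseline sample.
    """
    from .flic import FeedingEvent, FlicSeries  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate))
    dt = 1.0 / spec.sampling_rate
    times = np.arange(n) * dt
    signal = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    np.clip(signal, 0.0, spec.threshold - 1.0, out=signal)

    n_bouts = rng.poisson(spec.bout_rate * spec.duration / 60.0)
    events = []
    occupied = np.zeros(n, dtype=bool)
    for _ in range(n_bouts):
        for attempt in range(1000):
            dur = rng.uniform(*spec.bout_duration_range)
            width = max(int(round(dur * spec.sampling_rate)), 1)
            if width + 2 >= n:
                continue
            start = rng.integers(1, n - width - 1)
            # require a one-sample baseline buffer on both sides
            if occupied[start - 1:start + width + 1].any():
                continue
            amp = rng.uniform(*spec.bout_amplitude_range)
            signal[start:start + width] = amp
            occupied[start:start + width] = True
            events.append(FeedingEvent(
                start_s=float(times[start]),
                end_s=float(times[start] + width * dt),
                peak=float(amp),
            ))
            break
        else:
            raise ScenePlacementError("could not place a feeding bout without overlap")

    events.sort(key=lambda e: e.start_s)
    series = FlicSeries(times=times, signal=signal, well=well, diet=diet,
                        state=state, day=day, genotype=genotype)
    return series, events


# ---------------------------------------------------------------------------
# replicate tables
# ---------------------------------------------------------------------------

@dataclass
class TableSceneSpec:
    """Long-format replicate table with stated cell means and noise.

    ``factors`` maps factor name → ordered levels; ``cell_means`` and
    ``cell_sds`` are keyed by a tuple of one level per factor (in factor
    order). The default 10 replicates per cell matches the lipidomics
    design (ten biological replicates of n = 10 flies each).
    """

    factors: dict = field(default_factory=lambda: {
        "diet": ("NF", "HSD"), "state": ("fed", "stv")})
    cell_means: dict = field(default_factory=dict)
    cell_sds: dict = field(default_factory=dict)
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        cells = list(itertools.product(*self.factors.values()))
        for cell in cells:
            if cell not in self.cell_means:
                raise ValueError(f"missing mean for cell {cell}")
            if self.cell_sds.get(cell, 0.0) < 0:
                raise ValueError(f"negative SD for cell {cell}")


def generate_grouped_table(spec: TableSceneSpec, response: str = "value") -> pd.DataFrame:
    """Draw the replicate table: one row per replicate, Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    names = list(spec.factors)
    rows = []
    for cell in itertools.product(*spec.factors.values()):
        mu = spec.cell_means[cell]
        sd = spec.cell_sds.get(cell, 0.0)
        draws = mu + sd * rng.standard_normal(spec.replicates)
        for i, v in enumerate(draws, start=1):
            row = dict(zip(names, cell))
            row["replicate"] = i
            row[response] = float(v)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# puncta scenes
# ---------------------------------------------------------------------------

@dataclass
class PunctaSceneSpec:
    """A small stack of diffraction-blurred bright spots inside an ROI."""

    image_shape: tuple[int, int, int] = (5, 128, 128)
    n_puncta: int = 7
    radius_px: float = 3.0
    min_separation_px: float = 12.0
    intensity: float = 200.0
    background: float = 20.0
    blur_sigma_px: float = 0.0
    noise_sd: float = 3.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_puncta < 0 or self.radius_px <= 0:
            raise ValueError("invalid puncta parameters")


def generate_puncta_scene(spec: PunctaSceneSpec):
    """Render puncta → (stack, roi mask, truth dict).

    Spots are rasterized disks of ``radius_px`` placed in the central
    slice's plane (repeated across z with fading), blurred by an optional
    Gaussian to emulate diffraction, over a flat background. The ROI is
    the full frame. Truth records centers and the rasterized disk area.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.image_shape
    margin = spec.radius_px + 4
    centers = []
    for _ in range(spec.n_puncta):
        for attempt in range(1000):
            c = rng.uniform([margin, margin], [ny - margin, nx - margin])
            if all(np.linalg.norm(c - c2) >= spec.min_separation_px for c2 in centers):
                centers.append(c)
                break
        else:
            raise ScenePlacementError("could not place puncta without overlap")
    centers = np.array(centers).reshape(-1, 2)

    yy, xx = np.mgrid[0:ny, 0:nx]
    plane = np.zeros((ny, nx), dtype=bool)
    for c in centers:
        plane |= (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= spec.radius_px ** 2
    disk_area = int(((yy - ny // 2) ** 2 + (xx - nx // 2) ** 2
                     <= spec.radius_px ** 2).sum())

    stack = np.full(spec.image_shape, spec.background, dtype=np.float64)
    z_fade = np.exp(-0.5 * ((np.arange(nz) - (nz - 1) / 2) / max(nz / 4, 1)) ** 2)
    for z in range(nz):
        stack[z][plane] = spec.background + z_fade[z] * (spec.intensity - spec.background)
    if spec.blur_sigma_px > 0:
        for z in range(nz):
            stack[z] = ndi.gaussian_filter(stack[z], spec.blur_sigma_px)
    if spec.noise_sd > 0:
        stack += rng.normal(0.0, spec.noise_sd, size=stack.shape)
    vmax = float(2 ** spec.bit_depth - 1)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    stack = np.clip(np.rint(stack), 0, vmax).astype(dtype)

    roi = np.ones((ny, nx), dtype=bool)
    truth = {"n_puncta": spec.n_puncta, "centers": centers,
             "footprint": plane, "disk_area_px": disk_area}
    return ImageStack(stack, channel="apoii", bit_depth=spec.bit_depth), roi, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_scene_spec(path, spec) -> None:
    """Write a scene spec as a flat TOML section (readable with tomllib)."""
    d = asdict(spec)
    lines = [f"[{type(spec).__name__}]"]
    for k, v in d.items():
        if isinstance(v, str):
            lines.append(f'{k} = "{v}"')
        elif isinstance(v, (tuple, list)):
            lines.append(f"{k} = [{', '.join(repr(x) for x in v)}]")
        elif isinstance(v, dict):
            continue  # nested tables (factor maps) are serialized by the caller
        else:
            lines.append(f"{k} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_labels(path, truth: NucleiGroundTruth) -> None:
    tifffile.imwrite(path, truth.labels.astype(np.uint16),
                     photometric="minisblack")


def write_flic_csv(path, series_list) -> None:
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame(
            {"time_s": s.times, "well": s.well, "signal": s.signal}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
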