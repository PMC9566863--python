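"""Lamin-based 3D nuclear segmentation and FOXO intensity measurement."""

import math

import numpy as np
import pytest

from conftest import footprint_iou_matches
from flyquant import foxo, synth
from flyquant.image import DegenerateHistogramError, ImageStack


def _render_shell_stack(shape, centers_px, r_px, rim=2, hi=200, lo=20):
    """Hand-rendered lamin stack: spherical shells in voxel units
    (isotropic), for fixtures the scene generator cannot express."""
    zz, yy, xx = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]].astype(float)
    vol = np.full(shape, float(lo))
    for cz, cy, cx in centers_px:
        d = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
        vol[(d > r_px) & (d <= r_px + rim)] = hi
    return ImageStack(vol.astype(np.uint8), voxel_size=(1.0, 1.0),
                      channel="lamin", bit_depth=8)


class TestSegment2D:
    def test_well_separated_nuclei_recovered_with_centroids(self):
        spec = synth.NucleiSceneSpec(n_nuclei=5, seed=7)
        lamin, _, truth = synth.generate_nuclei_stack(spec)
        labels, centroids, _ = foxo.segment_nuclei_2d(lamin)
        assert labels.max() == 5
        dxy = spec.voxel_size[1]
        true_yx = truth.centers_um[:, 1:] / dxy - 0.5
        for c in centroids:
            dist = np.linalg.norm(true_yx - np.asarray(c), axis=1).min()
            assert dist < 2.0

    def test_empty_noisy_scene_yields_zero_labels(self):
        spec = synth.NucleiSceneSpec(n_nuclei=0, seed=1)
        lamin, _, _ = synth.generate_nuclei_stack(spec)
        labels, centroids, _ = foxo.segment_nuclei_2d(lamin)
        assert labels.max() == 0 and centroids == []

    def test_constant_stack_propagates_degenerate_error(self):
        stack = ImageStack(np.full((4, 32, 32), 7, np.uint8), bit_depth=8)
        with pytest.raises(DegenerateHistogramError):
            foxo.segment_nuclei_2d(stack)

    def test_touching_rims_split_by_watershed(self):
        # two shells whose projected rings touch: one blob before watershed
        stack = _render_shell_stack((24, 48, 72), [(12, 24, 24), (12, 24, 47)], r_px=10)
        labels, centroids, _ = foxo.segment_nuclei_2d(
            stack, foxo.SegmentationConfig(min_area_px=50))
        assert labels.max() == 2
        ys = sorted(c[1] for c in centroids)
        assert abs(ys[0] - 24) < 3 and abs(ys[1] - 47) < 3


class TestReconstruct3D:
    def test_sphere_volume_within_15pct(self):
        spec = synth.NucleiSceneSpec(n_nuclei=6, noise_sd=0.0, seed=11)
        lamin, _, truth = synth.generate_nuclei_stack(spec)
        cfg = foxo.SegmentationConfig()
        labels, _, t = foxo.segment_nuclei_2d(lamin, cfg)
        masks = foxo.reconstruct_nuclei_3d(lamin, labels, cfg, threshold=t)
        assert len(masks) == 6
        true_vols = sorted((4.0 / 3.0) * math.pi * truth.radii_um ** 3)
        meas_vols = sorted(m.volume_vox * lamin.voxel_volume_um3 for m in masks)
        for vt, vm in zip(true_vols, meas_vols):
            assert abs(vm - vt) / vt < 0.15

    def test_single_slice_stack_mask_is_footprint(self):
        ring = _render_shell_stack((1, 40, 40), [(0, 20, 20)], r_px=8)
        labels, _, t = foxo.segment_nuclei_2d(
            ring, foxo.SegmentationConfig(min_area_px=10))
        masks = foxo.reconstruct_nuclei_3d(ring, labels, threshold=t)
        assert len(masks) == 1
        assert masks[0].z_range == (0, 1)
        assert np.array_equal(masks[0].slice_masks[0], masks[0].footprint)

    def test_volume_monotone_in_rim_fraction(self, default_scene):
        _, lamin, _, _ = default_scene
        base = foxo.SegmentationConfig()
        labels, _, t = foxo.segment_nuclei_2d(lamin, base)
        prev = None
        for f in (0.3, 0.5, 0.7, 0.9):
            cfg = foxo.SegmentationConfig(rim_fraction=f)
            masks = foxo.reconstruct_nuclei_3d(lamin, labels, cfg, threshold=t)
            total = sum(m.volume_vox for m in masks)
            if prev is not None:
                assert total <= prev
            prev = total

    def test_mismatched_labels_rejected(self, default_scene):
        _, lamin, _, _ = default_scene
        with pytest.raises(ValueError):
            foxo.reconstruct_nuclei_3d(lamin, np.zeros((4, 4), int))


def _masks_from_truth(truth):
    """Perfect NucleusMask3D objects built from the ground-truth labels."""
    out = []
    for k in range(1, int(truth.labels.max()) + 1):
        vox = truth.labels == k
        zs = np.flatnonzero(vox.any(axis=(1, 2)))
        z_lo, z_hi = int(zs[0]), int(zs[-1]) + 1
        fp = vox.any(axis=0)
        cy, cx = np.argwhere(fp).mean(axis=0)
        out.append(foxo.NucleusMask3D(
            label=k, footprint=fp, z_range=(z_lo, z_hi),
            slice_masks=vox[z_lo:z_hi], centroid=(float(cy), float(cx))))
    return out


class TestMeasurement:
    def test_constant_foxo_gives_constant_means(self, segmented_scene):
        _, lamin, _, _, _, masks = segmented_scene
        const = ImageStack(np.full(lamin.shape, 37, np.uint8),
                           voxel_size=lamin.voxel_size, bit_depth=8)
        meas = foxo.measure_nuclear_intensity(const, masks)
        assert len(meas) == len(masks)
        assert all(m.mean_intensity == 37.0 for m in meas)

    def test_noiseless_scene_perfect_masks_exact(self):
        spec = synth.NucleiSceneSpec(n_nuclei=4, noise_sd=0.0,
                                     nuclear_foxo=200.0, cyto_foxo=50.0, seed=5)
        _, foxo_stack, truth = synth.generate_nuclei_stack(spec)
        meas = foxo.measure_nuclear_intensity(foxo_stack, _masks_from_truth(truth))
        assert [m.mean_intensity for m in meas] == [200.0] * 4

    def test_volume_unit_conversion(self, segmented_scene):
        _, _, foxo_stack, _, _, masks = segmented_scene
        meas = foxo.measure_nuclear_intensity(foxo_stack, masks)
        dz, dxy = foxo_stack.voxel_size
        for m in meas:
            assert m.volume_um3 == pytest.approx(m.volume_vox * dz * dxy * dxy)

    def test_recovered_masks_within_5pct_under_noise(self, segmented_scene):
        spec, _, foxo_stack, _, _, masks = segmented_scene
        # default scene noise is 5% of the nuclear signal
        assert spec.noise_sd / spec.nuclear_foxo == pytest.approx(0.05)
        meas = foxo.measure_nuclear_intensity(foxo_stack, masks)
        for m in meas:
            assert abs(m.mean_intensity - spec.nuclear_foxo) / spec.nuclear_foxo < 0.05

    def test_empty_mask_list(self, default_scene):
        _, _, foxo_stack, _ = default_scene
        assert foxo.measure_nuclear_intensity(foxo_stack, []) == []

    def test_projected_alternative_ranks_groups_the_same(self):
        # the 2D summation-projection reading also separates high from low
        lo = synth.NucleiSceneSpec(n_nuclei=4, seed=21, nuclear_foxo=90.0)
        hi = synth.NucleiSceneSpec(n_nuclei=4, seed=22, nuclear_foxo=160.0)
        res = {}
        for name, spec in (("lo", lo), ("hi", hi)):
            lamin, fx, _ = synth.generate_nuclei_stack(spec)
            labels, _, t = foxo.segment_nuclei_2d(lamin)
            masks = foxo.reconstruct_nuclei_3d(lamin, labels, threshold=t)
            meas = foxo.measure_nuclear_intensity_projected(fx, masks)
            res[name] = np.mean([m.mean_intensity for m in meas])
        assert res["hi"] > res["lo"]

    def test_results_frame_columns(self, segmented_scene):
        _, _, foxo_stack, _, _, masks = segmented_scene
        meas = foxo.measure_nuclear_intensity(foxo_stack, masks)
        df = foxo.measurements_to_frame(meas, masks)
        assert list(df.columns) == ["label", "mean_intensity", "volume_vox",
                                    "volume_um3", "z_lo", "z_hi",
                                    "centroid_y", "centroid_x"]
        assert len(df) == len(masks)


class TestRecoveryInvariant:
    def test_high_snr_scene_recovers_all_nuclei_no_spurious(self, segmented_scene):
        _, _, _, truth, _, masks = segmented_scene
        matched, spurious = footprint_iou_matches(truth.labels, masks)
        assert matched == truth.labels.max()
        assert spurious == 0


class TestCompare:
    def test_identical_groups_p_one(self):
        g = [foxo.NuclearMeasurement(i, 10.0, 5, 1.0, 3, (0, 0)) for i in range(3)]
        assert foxo.compare_nuclear_foxo(g, list(g)).p_value == 1.0

    def test_exact_enumeration_example(self):
        a = [foxo.NuclearMeasurement(i, v, 5, 1.0, 3, (0, 0))
             for i, v in enumerate([1.0, 2.0])]
        b = [foxo.NuclearMeasurement(i, v, 5, 1.0, 3, (0, 0))
             for i, v in enumerate([3.0, 4.0])]
        assert foxo.compare_nuclear_foxo(a, b).p_value == pytest.approx(1 / 3)

    def test_small_group_rejected(self):
        a = [foxo.NuclearMeasurement(0, 1.0, 5, 1.0, 3, (0, 0))]
        with pytest.raises(ValueError):
            foxo.compare_nuclear_foxo(a, a * 2)

    def test_shift_detected_with_high_power(self):
        # 1.5x nuclear shift at n=30 nuclei per group, 10% biological spread
        rng = np.random.default_rng(0)
        rej = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(110.0, 11.0, 30)
            b = rng.normal(165.0, 16.5, 30)
            ga = [foxo.NuclearMeasurement(i, v, 5, 1.0, 3, (0, 0))
                  for i, v in enumerate(a)]
            gb = [foxo.NuclearMeasurement(i, v, 5, 1.0, 3, (0, 0))
                  for i, v in enumerate(b)]
            rej += foxo.compare_nuclear_foxo(ga, gb).p_value < 0.05
        assert rej / reps > 0.9
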