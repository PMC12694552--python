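import dataclasses

import numpy as np
import pytest

from milletct.phantom import PhantomSpec, make_grain_phantom
from milletct.segmentation import (
    SegmentationParams,
    TissueRule,
    assign_tissues,
    canny_edges,
    dice_coefficient,
    otsu_threshold,
    refine_labels,
    region_grow,
    segment_grain,
)
from milletct.types import DomainError, GRAIN_TISSUES, Tissue, VoxelVolume


def brute_force_otsu(counts):
    """Exhaustive between-class variance maximization over integer levels."""
    counts = np.asarray(counts, float)
    levels = np.arange(len(counts))
    total = counts.sum()
    best_t, best_v = None, -1.0
    for t in range(len(counts) - 1):
        w0 = counts[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (counts[t + 1:] * levels[t + 1:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def volume_from_histogram(counts):
    vals = np.repeat(np.arange(len(counts)), counts)
    return VoxelVolume(vals.reshape(-1, 1, 1), 1.0, 16)


class TestOtsu:
    def test_bimodal_volume_split_cleanly(self):
        data = np.concatenate([np.full(1000, 50), np.full(1000, 200)])
        vv = VoxelVolume(data.reshape(10, 10, 20), 1.0, 8)
        t = otsu_threshold(vv, bins=151)
        assert 50 <= t < 200

    def test_eight_level_histogram_matches_brute_force(self):
        counts = [8, 7, 2, 1, 1, 2, 7, 8]
        vv = volume_from_histogram(counts)
        t = otsu_threshold(vv, bins=8)
        assert int(np.floor(t)) == brute_force_otsu(counts)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_histograms_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 50, size=16)
        vv = volume_from_histogram(counts)
        t = otsu_threshold(vv, bins=16)
        assert int(np.floor(t)) == brute_force_otsu(counts)

    @pytest.mark.parametrize("seed", range(5))
    def test_intensity_inversion_mirrors_threshold(self, seed):
        rng = np.random.default_rng(100 + seed)
        counts = rng.integers(1, 50, size=12)
        sig = _sigma_b(counts)
        if (sig == sig.max()).sum() > 1:  # tie: mirror image ambiguous
            return
        vv = volume_from_histogram(counts)
        L = len(counts)
        inv = VoxelVolume((L - 1) - vv.data, 1.0, 16)
        t = int(np.floor(otsu_threshold(vv, bins=L)))
        t_inv = int(np.floor(otsu_threshold(inv, bins=L)))
        assert t_inv == L - 2 - t

    def test_constant_volume_rejected(self):
        vv = VoxelVolume(np.full((3, 3, 3), 9), 1.0, 8)
        with pytest.raises(DomainError, match="constant"):
            otsu_threshold(vv)

    def test_threshold_shifts_with_global_offset(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 200, size=(8, 8, 8))
        t0 = otsu_threshold(VoxelVolume(data, 1.0, 16), bins=64)
        t1 = otsu_threshold(VoxelVolume(data + 500, 1.0, 16), bins=64)
        assert abs((t1 - t0) - 500) < 1e-9


def _sigma_b(counts):
    counts = np.asarray(counts, float)
    levels = np.arange(len(counts))
    total = counts.sum()
    out = np.full(len(counts) - 1, -np.inf)
    for t in range(len(counts) - 1):
        w0 = counts[: t + 1].sum()
        w1 = total - w0
        if w0 and w1:
            mu0 = (counts[: t + 1] * levels[: t + 1]).sum() / w0
            mu1 = (counts[t + 1:] * levels[t + 1:]).sum() / w1
            out[t] = w0 * w1 * (mu0 - mu1) ** 2
    return out


class TestCanny:
    def test_constant_slice_no_edges(self):
        mask = canny_edges(np.full((16, 16), 7.0), SegmentationParams())
        assert not mask.any()

    def test_step_edge_localized_within_one_pixel(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 100.0
        mask = canny_edges(img, SegmentationParams(canny_sigma_vox=1.0))
        cols = np.where(mask.any(axis=0))[0]
        assert len(cols) > 0
        assert all(abs(c - 15.5) <= 1.5 for c in cols)
        # roughly one-pixel wide: at most 2 columns flagged
        assert len(cols) <= 2

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 10, (24, 24))
        p = SegmentationParams()
        np.testing.assert_array_equal(canny_edges(img, p),
                                      canny_edges(img + 250.0, p))


class TestRegionGrow:
    def test_uniform_volume_single_region(self):
        vv = VoxelVolume(np.full((6, 6, 6), 40), 1.0, 8)
        regions = region_grow(vv, np.zeros((6, 6, 6), bool),
                              SegmentationParams(min_region_vox=1))
        assert regions.max() == 0

    def test_two_blocks_split_by_barrier_plane(self):
        data = np.full((9, 6, 6), 10)
        data[5:] = 200
        barrier = np.zeros((9, 6, 6), bool)
        barrier[4] = True
        vv = VoxelVolume(data, 1.0, 8)
        regions = region_grow(vv, barrier,
                              SegmentationParams(growth_tolerance=5,
                                                 min_region_vox=1))
        assert regions.max() == 1  # exactly two regions
        # barrier plane voxels (value 10) merge to the nearer-intensity block
        assert (regions[:5] == regions[0, 0, 0]).all()
        assert (regions[5:] == regions[8, 0, 0]).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_region_count_nonincreasing_in_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 100, size=(10, 10, 10))
        vv = VoxelVolume(data, 1.0, 8)
        empty = np.zeros(data.shape, bool)
        counts = []
        for tol in (5, 20, 80):
            p = SegmentationParams(growth_tolerance=tol, min_region_vox=1)
            counts.append(region_grow(vv, empty, p).max() + 1)
        assert counts[0] >= counts[1] >= counts[2]

    def test_all_barrier_rejected(self):
        vv = VoxelVolume(np.zeros((3, 3, 3), int), 1.0, 8)
        with pytest.raises(DomainError, match="no seed"):
            region_grow(vv, np.ones((3, 3, 3), bool), SegmentationParams())


class TestAssignAndRefine:
    def test_noise_free_phantom_recovered_exactly(self, small_phantom):
        vv, truth = small_phantom
        seg = segment_grain(vv)
        np.testing.assert_array_equal(seg.labels, truth.labels)

    def test_swapped_intensities_with_swapped_rule(self, small_spec):
        means = dict(small_spec.tissue_mean_intensities)
        means[Tissue.EMBRYO], means[Tissue.ENDOSPERM] = (
            means[Tissue.ENDOSPERM], means[Tissue.EMBRYO])
        spec = dataclasses.replace(small_spec, tissue_mean_intensities=means)
        vv, truth = make_grain_phantom(spec)
        rule = TissueRule(ordering=(Tissue.CAVITY, Tissue.HULL,
                                    Tissue.EMBRYO, Tissue.ENDOSPERM))
        seg = segment_grain(vv, rule=rule)
        for t in GRAIN_TISSUES:
            assert dice_coefficient(seg.mask(t), truth.mask(t)) > 0.99

    def test_featureless_stack_rejected(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 3, size=(12, 12, 12))
        vv = VoxelVolume(data, 1.0, 8)
        with pytest.raises(DomainError):
            segment_grain(vv)

    def test_empty_overrides_identity(self, small_phantom):
        vv, truth = small_phantom
        out = refine_labels(truth, vv, [])
        np.testing.assert_array_equal(out.labels, truth.labels)

    def test_full_range_override_exhausts_source_label(self, small_phantom):
        vv, truth = small_phantom
        out = refine_labels(truth, vv,
                            [((0, 65535), Tissue.ENDOSPERM, Tissue.EMBRYO)])
        assert not (out.labels == int(Tissue.ENDOSPERM)).any()

    def test_override_idempotent(self, noisy_small_phantom):
        vv, truth = noisy_small_phantom
        ov = [((20000, 30000), Tissue.ENDOSPERM, Tissue.HULL)]
        once = refine_labels(truth, vv, ov)
        twice = refine_labels(once, vv, ov)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_contradictory_overrides_rejected(self, small_phantom):
        vv, truth = small_phantom
        with pytest.raises(DomainError, match="contradict"):
            refine_labels(truth, vv, [
                ((0, 100), Tissue.HULL, Tissue.CAVITY),
                ((50, 150), Tissue.HULL, Tissue.EMBRYO),
            ])


class TestSegmentGrain:
    def test_noise_free_dice(self, small_phantom):
        vv, truth = small_phantom
        seg = segment_grain(vv)
        for t in GRAIN_TISSUES:
            assert dice_coefficient(seg.mask(t), truth.mask(t)) >= 0.95

    def test_deterministic(self, noisy_small_phantom):
        vv, _ = noisy_small_phantom
        a = segment_grain(vv)
        b = segment_grain(vv)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_partition_conservation(self, noisy_small_phantom):
        vv, _ = noisy_small_phantom
        seg = segment_grain(vv)
        codes = set(np.unique(seg.labels).tolist())
        assert codes <= {int(t) for t in Tissue}
        assert seg.labels.shape == vv.shape  # every voxel carries one label

    def test_global_offset_invariance(self, small_phantom):
        vv, _ = small_phantom
        shifted = VoxelVolume(vv.data + 700, vv.voxel_size_um, 16)
        a = segment_grain(vv)
        b = segment_grain(shifted)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_noise_degrades_or_preserves_dice(self, small_spec):
        # median Dice over phantoms must not improve when noise doubles
        lo, hi = [], []
        for seed in range(5):
            for sd, acc in ((0.03 * 65535, lo), (0.06 * 65535, hi)):
                spec = dataclasses.replace(small_spec, noise_sd=sd, seed=seed)
                vv, truth = make_grain_phantom(spec)
                seg = segment_grain(vv)
                acc.append(np.mean([
                    dice_coefficient(seg.mask(t), truth.mask(t))
                    for t in GRAIN_TISSUES]))
        assert np.median(hi) <= np.median(lo) + 1e-6
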