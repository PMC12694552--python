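import numpy as np
import pytest

from milletct.morphometry import (
    compute_traits,
    hull_mean_thickness,
    region_surface_area,
    region_volume,
)
from milletct.types import DomainError, LabelVolume, Tissue

from conftest import sphere_label_volume


class TestVolume:
    def test_closed_form_voxel_count(self):
        lab = np.zeros((10, 10, 10), np.uint8)
        lab.ravel()[:1000] = int(Tissue.EMBRYO)
        lv = LabelVolume(lab, 3.0)
        assert region_volume(lv, Tissue.EMBRYO) == pytest.approx(
            1000 * 0.003**3)

    def test_absent_label_zero(self):
        lv = LabelVolume(np.zeros((2, 2, 2), np.uint8), 3.0)
        assert region_volume(lv, Tissue.HULL) == 0.0

    def test_digitized_sphere_within_two_percent(self):
        lv = sphere_label_volume(300.0, 3.0, Tissue.ENDOSPERM)
        v = region_volume(lv, Tissue.ENDOSPERM)
        expected = 4 / 3 * np.pi * 0.3**3
        assert abs(v - expected) / expected < 0.02


class TestSurfaceArea:
    def test_sphere_within_three_percent(self):
        lv = sphere_label_volume(300.0, 3.0, Tissue.ENDOSPERM)
        a = region_surface_area(lv, Tissue.ENDOSPERM)
        expected = 4 * np.pi * 0.3**2
        assert abs(a - expected) / expected < 0.03

    def test_shell_counts_inner_and_outer_surfaces(self):
        lv = sphere_label_volume(300.0, 3.0, Tissue.HULL, r_inner_um=270.0)
        a = region_surface_area(lv, Tissue.HULL)
        expected = 4 * np.pi * (0.3**2 + 0.27**2)
        assert abs(a - expected) / expected < 0.03

    def test_single_voxel_bounded(self):
        lab = np.zeros((5, 5, 5), np.uint8)
        lab[2, 2, 2] = int(Tissue.HULL)
        a = region_surface_area(LabelVolume(lab, 3.0), Tissue.HULL)
        six_faces = 6 * 0.003**2
        assert 0.5 * six_faces <= a <= 1.5 * six_faces

    def test_empty_region_rejected(self):
        lv = LabelVolume(np.zeros((3, 3, 3), np.uint8), 3.0)
        with pytest.raises(DomainError, match="empty"):
            region_surface_area(lv, Tissue.HULL)

    def test_refinement_does_not_diverge(self):
        # both errors sit well under 1%; the fine grid must not be worse
        # than the coarse one beyond sub-resolution noise
        expected = 4 * np.pi * 0.3**2
        errs = []
        for vox in (3.0, 6.0):
            lv = sphere_label_volume(300.0, vox, Tissue.EMBRYO)
            errs.append(abs(region_surface_area(lv, Tissue.EMBRYO) - expected))
        assert errs[0] <= errs[1] + 0.005 * expected
        assert errs[0] < 0.01 * expected


class TestThickness:
    def test_spherical_shell_within_ten_percent(self):
        lv = sphere_label_volume(300.0, 3.0, Tissue.HULL, r_inner_um=270.0)
        t = hull_mean_thickness(lv)
        assert abs(t - 30.0) / 30.0 < 0.10

    def test_slab_within_one_voxel(self):
        lab = np.zeros((20, 9, 9), np.uint8)
        lab[3:8] = int(Tissue.HULL)  # exactly 5 voxels thick
        t = hull_mean_thickness(LabelVolume(lab, 3.0))
        assert abs(t - 15.0) <= 3.0

    def test_scale_equivariance(self):
        thin = sphere_label_volume(150.0, 3.0, Tissue.HULL, r_inner_um=120.0)
        thick = sphere_label_volume(300.0, 3.0, Tissue.HULL, r_inner_um=240.0)
        t1 = hull_mean_thickness(thin)
        t2 = hull_mean_thickness(thick)
        # doubling the geometry doubles the estimate, within a voxel
        assert abs(t2 - 2 * t1) <= 2 * 3.0


class TestComputeTraits:
    def test_phantom_ground_truth_exact_volumes(self, small_phantom):
        _, lv = small_phantom
        tr = compute_traits(lv)
        for tissue, field in [(Tissue.EMBRYO, tr.em_volume_mm3),
                              (Tissue.ENDOSPERM, tr.en_volume_mm3),
                              (Tissue.CAVITY, tr.c_volume_mm3),
                              (Tissue.HULL, tr.h_volume_mm3)]:
            assert field == pytest.approx(region_volume(lv, tissue))
        assert tr.k_volume_mm3 == pytest.approx(
            tr.em_volume_mm3 + tr.en_volume_mm3 + tr.c_volume_mm3
            + tr.h_volume_mm3, abs=1e-9)

    def test_ratios_sum_to_one(self, small_phantom):
        _, lv = small_phantom
        tr = compute_traits(lv)
        assert abs(tr.em_ratio + tr.en_ratio + tr.c_ratio + tr.h_ratio - 1.0) < 1e-9

    def test_axis_permutation_invariance(self, small_phantom):
        _, lv = small_phantom
        tr = compute_traits(lv)
        swapped = LabelVolume(np.transpose(lv.labels, (2, 0, 1)),
                              lv.voxel_size_um)
        tr2 = compute_traits(swapped)
        assert tr2.k_volume_mm3 == pytest.approx(tr.k_volume_mm3)
        assert tr2.k_area_mm2 == pytest.approx(tr.k_area_mm2, rel=1e-6)
        assert tr2.h_a_t_um == pytest.approx(tr.h_a_t_um, rel=1e-6)

    def test_equal_scaling_of_counts_preserves_ratios(self):
        lab = np.zeros((4, 4, 8), np.uint8)
        lab[0, 0, :4] = int(Tissue.EMBRYO)
        lab[1, 0, :2] = int(Tissue.ENDOSPERM)
        lab[2, 0, :1] = int(Tissue.CAVITY)
        lab[3, 0, :1] = int(Tissue.HULL)
        tr1 = compute_traits(LabelVolume(lab, 3.0))
        doubled = np.concatenate([lab, lab], axis=2)
        tr2 = compute_traits(LabelVolume(doubled, 3.0))
        for a, b in [(tr1.em_ratio, tr2.em_ratio), (tr1.en_ratio, tr2.en_ratio),
                     (tr1.c_ratio, tr2.c_ratio), (tr1.h_ratio, tr2.h_ratio)]:
            assert a == pytest.approx(b)

    def test_missing_tissue_named_in_error(self):
        lab = np.zeros((4, 4, 4), np.uint8)
        lab[1] = int(Tissue.HULL)
        lab[2] = int(Tissue.ENDOSPERM)
        lab[3] = int(Tissue.CAVITY)
        with pytest.raises(DomainError, match="EMBRYO"):
            compute_traits(LabelVolume(lab, 3.0))
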