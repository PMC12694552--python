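import numpy as np
import pytest

from milletct.phantom import PhantomSpec, make_grain_phantom
from milletct.popsim import make_grid_map


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A fast ~65^3-voxel grain phantom used by most segmentation tests."""
    return PhantomSpec(
        grain_semi_axes_um=(90.0, 75.0, 60.0),
        hull_thickness_um=12.0,
        cavity_gap_um=15.0,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_grain_phantom(small_spec)


@pytest.fixture(scope="session")
def noisy_small_phantom(small_spec):
    import dataclasses

    spec = dataclasses.replace(small_spec, noise_sd=0.05 * 65535, seed=11)
    return make_grain_phantom(spec)


@pytest.fixture(scope="session")
def grid_map():
    """9 chromosomes x ~100 cM, markers every 5 cM."""
    return make_grid_map(9, 100.0, 5.0)


@pytest.fixture(scope="session")
def small_map():
    """2 chromosomes x 10 markers (null-threshold band tests)."""
    return make_grid_map(2, 95.0, 10.0)


def sphere_label_volume(r_um, voxel_um, label, r_inner_um=None):
    """Digitized sphere or spherical shell with the given tissue label."""
    from milletct.types import LabelVolume

    n = int(np.ceil(r_um / voxel_um)) + 3
    c = np.arange(-n, n + 1) * voxel_um
    zz, yy, xx = np.meshgrid(c, c, c, indexing="ij")
    rr = np.sqrt(zz**2 + yy**2 + xx**2)
    mask = rr <= r_um if r_inner_um is None else (rr <= r_um) & (rr > r_inner_um)
    lab = np.zeros(mask.shape, np.uint8)
    lab[mask] = int(label)
    return LabelVolume(lab, voxel_um)
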