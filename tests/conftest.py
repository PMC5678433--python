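import numpy as np
import pytest

import cortexflow as cf


@pytest.fixture(scope="session")
def small_sphere_spec():
    """Ball phantom small enough for fast unit tests (R = 16 voxels)."""
    return cf.FoldedBrainSpec(
        base_radius_mm=16.0,
        fold_amplitude_mm=0.0,
        fold_frequency=8,
        cortical_thickness_mm=2.5,
        voxel_size_mm=1.0,
        grid_shape=(48, 48, 48),
    )


@pytest.fixture(scope="session")
def small_sphere_volume(small_sphere_spec):
    return cf.make_folded_brain(small_sphere_spec)


@pytest.fixture(scope="session")
def small_folded_spec():
    """Folded phantom at unit-test scale (guard-valid at the default closing)."""
    return cf.FoldedBrainSpec(
        base_radius_mm=16.0,
        fold_amplitude_mm=3.0,
        fold_frequency=8,
        cortical_thickness_mm=2.5,
        voxel_size_mm=1.0,
        grid_shape=(48, 48, 48),
    )


@pytest.fixture(scope="session")
def small_folded_volume(small_folded_spec):
    return cf.make_folded_brain(small_folded_spec)


@pytest.fixture(scope="session")
def scheme():
    return cf.folded_brain_scheme()


@pytest.fixture(scope="session")
def ball_mask():
    """Plain discrete ball, radius 20 voxels, centred in a 56^3 grid."""
    n = 56
    c = (n - 1) / 2.0
    idx = np.indices((n, n, n))
    r2 = sum((idx[i] - c) ** 2 for i in range(3))
    return r2 <= 20.0**2
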