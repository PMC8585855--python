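import numpy as np
import pytest

from sliderasl import NoiseModel, build_forward_operator, build_geometry, \
    make_phantom
from sliderasl.geometry import AcquisitionGeometry


@pytest.fixture(scope="session")
def phantom():
    """Small brain-like phantom on the full 96-slice thin grid."""
    return make_phantom(shape=(20, 20, 96), seed=11)


@pytest.fixture(scope="session")
def slider2():
    return build_geometry("slider2")


@pytest.fixture(scope="session")
def slider2_operator(slider2):
    return build_forward_operator(slider2)


@pytest.fixture
def tiny_geometry():
    """n_set=2 with 3 thick / 6 thin slices - small enough to enumerate."""
    return AcquisitionGeometry(n_set=2, thin_thickness_mm=2.0,
                               thick_thickness_mm=4.0, mb_factor=1, n_groups=3)


@pytest.fixture
def quiet_noise():
    return NoiseModel(var_thermal=0.0, var_physio=0.0, rho=0.0)


def brute_force_operator(geometry: AcquisitionGeometry) -> np.ndarray:
    """Independent dense construction of the averaging matrix.

    Built entry-by-entry from the footprint definition (thick slice t of
    set k covers thin slices t*n_set + k .. + n_set - 1, weight 1/n_set,
    out-of-slab entries dropped), without going through the package's
    sparse assembly.
    """
    n_set, n_thick = geometry.n_set, geometry.n_thick_slices
    n_hr = n_thick * n_set
    A = np.zeros((n_set * n_thick, n_hr))
    for k in range(n_set):
        for t in range(n_thick):
            for j in range(n_hr):
                start = t * n_set + k
                if start <= j < start + n_set:
                    A[k * n_thick + t, j] = 1.0 / n_set
    return A
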