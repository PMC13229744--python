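import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dgcurve import DoseGrid, PhantomSpec, make_sphere_phantom, write_dicom_bundle

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sphere_spec() -> PhantomSpec:
    """Reference phantom: 10 mm target, 13 Gy plateau, 2 Gy/mm fall-off,
    1 mm isotropic grid (the SRS-like default study conditions)."""
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def sphere_bundle(sphere_spec):
    return make_sphere_phantom(sphere_spec)


@pytest.fixture(scope="session")
def fine_spec() -> PhantomSpec:
    """Same phantom on a 0.5 mm grid, for geometry-accuracy checks."""
    return PhantomSpec(spacing_mm=0.5, seed=7)


@pytest.fixture(scope="session")
def fine_bundle(fine_spec):
    return make_sphere_phantom(fine_spec)


@pytest.fixture(scope="session")
def dicom_dir(tmp_path_factory, sphere_bundle):
    """The reference phantom written to disk as a DICOM triplet."""
    out = tmp_path_factory.mktemp("bundle")
    return write_dicom_bundle(sphere_bundle, out)


def uniform_grid(value_gy: float, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)) -> DoseGrid:
    return DoseGrid(
        values=np.full(shape, value_gy, dtype=float), spacing=spacing, origin=(0, 0, 0)
    )
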