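import numpy as np
import pytest
from hypothesis import settings

from mpimfh.catalog import get_particle
from mpimfh.fields import DriveSpec, GradientSpec, ScannerSpec
from mpimfh.imaging import ImagingGrid, build_system_matrix
from mpimfh.phantoms import Phantom

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_scanner():
    """Imaging-session scanner: gradients (1,1,2) T/m, desk-scale Lissajous."""
    return ScannerSpec(gradient=GradientSpec(1.0, 1.0, 2.0), drive=DriveSpec.desk())


@pytest.fixture(scope="session")
def psf_scanner():
    """Full-gradient scanner used for localized-heating characterisation."""
    return ScannerSpec(gradient=GradientSpec(-1.25, -1.25, 2.5), drive=DriveSpec.desk())


@pytest.fixture(scope="session")
def small_grid():
    return ImagingGrid((18.0, 18.0, 6.0), (9, 9, 3))


@pytest.fixture(scope="session")
def thermo_matrices(desk_scanner, small_grid):
    """Hot (45 degC) and cold (23 degC) calibration matrices, shared by the
    thermometry tests."""
    particle = get_particle("synomag-S-90")
    rng = np.random.default_rng(2024)
    sm_hot = build_system_matrix(desk_scanner, small_grid, particle, 45.0,
                                 averages=10, noise_std=0.0, rng=rng)
    sm_cold = build_system_matrix(desk_scanner, small_grid, particle, 23.0,
                                  averages=10, noise_std=0.0, rng=rng)
    return sm_hot, sm_cold


@pytest.fixture()
def single_vial_phantom(small_grid):
    """One vial's worth of tracer in the central voxel of the small grid."""
    conc = np.zeros(small_grid.shape)
    conc[4, 4, 1] = 5.0
    labels = np.where(conc > 0, 1, 0).astype(np.uint8)
    return Phantom(concentration=conc, labels=labels, grid=small_grid,
                   particle="synomag-S-90")
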