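import numpy as np
import pytest

from beamtrack import SetupGeometry, cylinder_phantom, sampling_pitch, simulate_scan


@pytest.fixture(scope="session")
def tomo_geom():
    """The 27 keV tomography configuration: 128 cm propagation, 50 um
    modulator rastered 8x8, 2.6 um pixels."""
    return SetupGeometry(
        z_od=1.28,
        mean_energy=27.0,
        pixel_size=2.6e-6,
        modulator_period=50e-6,
        aperture_diameter=15e-6,
        n_subpitch=8,
    )


@pytest.fixture(scope="session")
def small_geom():
    """Desk-scale variant: same optics, 2x2 raster for fast simulations."""
    return SetupGeometry(
        z_od=1.28,
        mean_energy=16.0,
        pixel_size=2.6e-6,
        modulator_period=50e-6,
        aperture_diameter=15e-6,
        n_subpitch=2,
    )


@pytest.fixture(scope="session")
def noiseless_scan(small_geom):
    """Two-material cylinder scan with no photon or read noise."""
    phantom = cylinder_phantom(n=24, n_slices=4, voxel_size=sampling_pitch(small_geom))
    return simulate_scan(phantom, small_geom, n_projections=3, flux=1e4, seed=None)


def gaussian_spot(n: int, cx: float, cy: float, sigma: float = 2.0) -> np.ndarray:
    y, x = np.mgrid[0:n, 0:n]
    return np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
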