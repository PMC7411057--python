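import numpy as np
import pytest

import xdfstruct as x


@pytest.fixture(scope="session")
def geometry():
    """Symmetric Talbot-Lau geometry: d_S,G2 = 0.571 m, p_G2 = 10 μm."""
    return x.InterferometerGeometry(d_S_G2=0.571, p_G2=10.0, design_energy=45.0)


@pytest.fixture(scope="session")
def source_spectrum():
    return x.simulate_source_spectrum(kVp=120.0, al_filtration_mm=2.0)


@pytest.fixture(scope="session")
def visibility_spectrum():
    return x.visibility_model()


@pytest.fixture(scope="session")
def energy_bins():
    return x.EnergyBin(23.0, 64.0, "low"), x.EnergyBin(64.0, 120.0, "high")


@pytest.fixture(scope="session")
def foam_small():
    """64³ closed-cell foam at 2 μm voxels, medium cell size."""
    spec = x.PhantomSpec(
        kind="voronoi_foam", shape=(64, 64, 64), voxel_size=2.0, n_seeds=40, seed=11
    )
    return x.make_voronoi_foam(spec)


@pytest.fixture(scope="session")
def foam_profile(foam_small):
    vol, _ = foam_small
    return x.correlation_profile(vol)


@pytest.fixture(scope="session")
def sphere_cavity_80():
    """Single spherical cavity, diameter 40 μm, centered in a 160 μm solid cube."""
    from xdfstruct.volumes import _sphere_mask

    mask = _sphere_mask((80, 80, 80), np.array([[40.0, 40.0, 40.0]]), np.array([10.0]))
    pm = x.PhaseMap(mask.astype(np.uint8), 2.0)
    vol = x.Volume3D(np.where(mask, 0.0, 1.0), 2.0)
    return vol, pm
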