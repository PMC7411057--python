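"""Dark-field forward relation, phase stepping and spectral ratios."""

import numpy as np
import pytest

import xdfstruct as x


def _plateau_profile():
    """G drops to 0 immediately: structure far smaller than any sampled length."""
    return x.CorrelationProfile(np.array([0.0, 1e-6, 500.0]), np.array([1.0, 0.0, 0.0]))


def _unity_profile():
    return x.CorrelationProfile(np.array([0.0, 500.0]), np.array([1.0, 1.0]))


def test_no_decorrelation_means_no_signal(geometry):
    """G = 1 at every sampled length: the bracket vanishes and D = 1."""
    mat = x.MaterialModel(5e4, 0.005, _unity_profile())
    assert x.mono_darkfield(mat, 45.0, geometry) == pytest.approx(1.0, abs=1e-12)


def test_unit_optical_depth_gives_inverse_e(geometry):
    """Parameters tuned so sigma*t*(1-G) = 1 at 45 keV: D = exp(-1)."""
    lam = x.energy_to_wavelength(45.0)
    mat = x.MaterialModel(1.0 / (lam**2 * 0.005), 0.005, _plateau_profile())
    assert x.mono_darkfield(mat, 45.0, geometry) == pytest.approx(np.exp(-1.0), rel=1e-12)


def test_plateau_regime_scales_exactly_as_inverse_energy_squared(geometry):
    mat = x.MaterialModel(5e4, 0.005, _plateau_profile())
    E1, E2 = 40.0, 90.0
    r = -np.log(x.mono_darkfield(mat, E1, geometry)) / -np.log(
        x.mono_darkfield(mat, E2, geometry)
    )
    assert r == pytest.approx((E2 / E1) ** 2, rel=1e-12)


def test_signal_decreases_with_energy(geometry, foam_profile):
    mat = x.MaterialModel(5e4, 0.005, foam_profile)
    E = np.linspace(30.0, 110.0, 17)
    neg_log = np.array([-np.log(x.mono_darkfield(mat, float(e), geometry)) for e in E])
    assert np.all(np.diff(neg_log) < 0)


def test_energy_exponent_within_small_angle_bounds(geometry, foam_profile):
    """Fitted -lnD ~ E^-p exponent lies in [2, 4] for generated phantoms."""
    profiles = [foam_profile]
    spec = x.PhantomSpec(
        kind="solid_spheres", shape=(64,) * 3, voxel_size=0.05,
        radius_um=0.12, volume_fraction=0.05, seed=4,
    )
    vol, _ = x.make_solid_spheres(spec)
    profiles.append(x.correlation_profile(vol))
    for prof in profiles:
        mat = x.MaterialModel(5e4, 0.005, prof)
        E = np.linspace(30.0, 100.0, 25)
        nl = np.array([-np.log(x.mono_darkfield(mat, float(e), geometry)) for e in E])
        p = -np.polyfit(np.log(E), np.log(nl), 1)[0]
        assert 2.0 <= p <= 4.0


def test_mono_refuses_lengths_outside_profile(geometry):
    short = x.CorrelationProfile(np.array([0.0, 0.5]), np.array([1.0, 0.9]))
    mat = x.MaterialModel(5e4, 0.005, short)
    with pytest.raises(ValueError, match="extrapolation"):
        x.mono_darkfield(mat, 30.0, geometry)  # xi(30 keV) = 2.36 μm > 0.5


def test_polychromatic_constant_signal_passes_through(geometry):
    mat = x.MaterialModel(0.0, 0.005, _plateau_profile())  # D(E) = 1 everywhere
    E = np.linspace(30.0, 60.0, 61)
    phi = x.SpectralTable(E, np.ones_like(E))
    vis = x.SpectralTable(E, np.full_like(E, 0.3), kind="visibility")
    D = x.polychromatic_darkfield(mat, phi, vis, x.EnergyBin(30.0, 60.0), geometry)
    assert D == pytest.approx(1.0, abs=1e-12)


def test_polychromatic_concentrated_spectrum_equals_mono(geometry, foam_profile):
    mat = x.MaterialModel(5e4, 0.005, foam_profile)
    E = np.arange(30.0, 60.5, 0.5)
    w = np.zeros_like(E)
    w[30] = 1.0  # all weight at 45 keV
    phi = x.SpectralTable(E, w)
    vis = x.SpectralTable(E, np.full_like(E, 0.3), kind="visibility")
    D = x.polychromatic_darkfield(mat, phi, vis, x.EnergyBin(30.0, 60.0), geometry)
    assert D == pytest.approx(x.mono_darkfield(mat, 45.0, geometry), rel=1e-3)


def test_polychromatic_bounded_by_mono_extremes(
    geometry, foam_profile, source_spectrum, visibility_spectrum, energy_bins
):
    mat = x.MaterialModel(5e4, 0.005, foam_profile)
    for b in energy_bins:
        D = x.polychromatic_darkfield(
            mat, source_spectrum, visibility_spectrum, b, geometry
        )
        grid = np.arange(b.E1, b.E2, 1.0)
        monos = [x.mono_darkfield(mat, float(e), geometry) for e in grid]
        assert min(monos) - 1e-12 <= D <= max(monos) + 1e-12


def test_polychromatic_agrees_with_stepping_oracle(
    geometry, foam_profile, source_spectrum, visibility_spectrum, energy_bins
):
    """Weighted-mean combination matches an end-to-end phase-stepping
    simulation (per-energy sinusoids summed, visibility retrieved) to 1%."""
    mat = x.MaterialModel(5e4, 0.005, foam_profile)
    for b in energy_bins:
        phi_eff = x.effective_bin_spectrum(source_spectrum, b, 8.0)
        d_mean = x.polychromatic_darkfield(mat, phi_eff, visibility_spectrum, b, geometry)
        d_step = x.polychromatic_darkfield_stepping(
            mat, phi_eff, visibility_spectrum, b, geometry, n_steps=7
        )
        assert abs(d_mean - d_step) / d_step < 0.01


def test_flat_curve_has_zero_visibility():
    curve = x.simulate_stepping_curve(1000.0, 0.0, 0.3, 7)
    assert np.allclose(curve.intensities, 1000.0)
    _, v, _ = x.retrieve_visibility(curve)
    assert v == pytest.approx(0.0, abs=1e-12)


def test_stepping_roundtrip_noiseless_exact():
    curve = x.simulate_stepping_curve(1000.0, 0.3, 0.7, 7)
    a0, v, phase = x.retrieve_visibility(curve)
    assert a0 == pytest.approx(1000.0, abs=1e-10)
    assert v == pytest.approx(0.3, abs=1e-10)
    assert phase == pytest.approx(0.7, abs=1e-10)


def test_dense_curve_visibility_definition():
    curve = x.simulate_stepping_curve(500.0, 0.42, 0.0, 4096)
    I = curve.intensities
    assert (I.max() - I.min()) / (I.max() + I.min()) == pytest.approx(0.42, rel=1e-6)


def test_poisson_retrieval_nearly_unbiased():
    v_true, reps = 0.30, 500
    est = []
    for i in range(reps):
        curve = x.simulate_stepping_curve(1e5, v_true, 0.7, 7, poisson_seed=i)
        est.append(x.retrieve_visibility(curve)[1])
    assert abs(np.mean(est) - v_true) < 0.01 * v_true


def test_stepping_input_validation():
    with pytest.raises(ValueError):
        x.simulate_stepping_curve(1000.0, 1.2, 0.0, 7)
    with pytest.raises(ValueError):
        x.simulate_stepping_curve(-1.0, 0.2, 0.0, 7)
    with pytest.raises(ValueError):
        x.SteppingCurve(np.array([1.0, 2.0]))


def test_visibility_reduction_is_the_darkfield_signal():
    assert x.darkfield_from_visibilities(0.4, 0.4) == 1.0
    assert x.darkfield_from_visibilities(0.2, 0.4) == 0.5
    with pytest.raises(ValueError):
        x.darkfield_from_visibilities(0.2, 0.0)
    with pytest.warns(UserWarning, match="clipping"):
        assert x.darkfield_from_visibilities(0.5, 0.4) == 1.0


def test_published_low_bin_signal_inverts_to_visibility_ratio():
    # a -lnD of 1.07 corresponds to D = 0.343
    assert round(np.exp(-1.07), 3) == 0.343


@pytest.mark.parametrize(
    "neg_log_D,lam,expected",
    [(1.07, 0.29, 12.72), (0.13, 0.15, 5.78), (0.0, 0.29, 0.0)],
)
def test_wavelength_normalization(neg_log_D, lam, expected):
    assert round(x.normalized_logD(neg_log_D, lam), 2) == expected


def test_normalization_rejects_bad_wavelength():
    with pytest.raises(ValueError):
        x.normalized_logD(1.0, 0.0)


@pytest.mark.parametrize(
    "low,high,expected", [(0.5, 0.5, 1.0), (1.07, 0.36, 2.97), (0.50, 0.13, 3.85)]
)
def test_spectral_ratio_orientation(low, high, expected):
    assert round(x.spectral_ratio(low, high), 2) == expected


def test_spectral_ratio_rejects_zero():
    with pytest.raises(ValueError):
        x.spectral_ratio(1.0, 0.0)


def test_sigma0_calibration_roundtrip(geometry, foam_profile):
    target = 0.8
    s0 = x.calibrate_sigma0(target, 45.0, geometry, foam_profile, 0.005)
    mat = x.MaterialModel(s0, 0.005, foam_profile)
    assert -np.log(x.mono_darkfield(mat, 45.0, geometry)) == pytest.approx(target, rel=1e-12)
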