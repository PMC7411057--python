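"""Energy/wavelength conversion, correlation lengths and spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import xdfstruct as x
from xdfstruct.spectral import HC_KEV_ANGSTROM


@pytest.mark.parametrize(
    "E_keV,lam_A",
    [(43.0, 0.29), (80.9, 0.15), (HC_KEV_ANGSTROM, 1.0)],
)
def test_wavelength_matches_published_values(E_keV, lam_A):
    assert round(x.energy_to_wavelength(E_keV), 2) == round(lam_A, 2)


def test_wavelength_rejects_nonpositive_energy():
    with pytest.raises(ValueError):
        x.energy_to_wavelength(0.0)


@pytest.mark.parametrize("E_keV,xi_um", [(43.0, 1.65), (80.9, 0.88)])
def test_correlation_length_reproduces_bin_values(E_keV, xi_um, geometry):
    assert round(x.correlation_length(E_keV, geometry), 2) == xi_um


def test_correlation_length_linear_in_distance(geometry):
    g2 = x.InterferometerGeometry(2 * geometry.d_S_G2, geometry.p_G2)
    assert x.correlation_length(50.0, g2) == pytest.approx(
        2 * x.correlation_length(50.0, geometry), rel=1e-14
    )


@given(E1=st.floats(10.0, 150.0), ratio=st.floats(1.01, 5.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_correlation_length_inverse_energy_scaling(E1, ratio):
    geom = x.InterferometerGeometry(0.571, 10.0)
    E2 = E1 * ratio
    r = x.correlation_length(E1, geom) / x.correlation_length(E2, geom)
    assert abs(r - ratio) < 1e-12 * ratio


def test_effective_length_delta_weight_returns_mono_value(geometry):
    E = np.arange(30.0, 60.5, 0.5)
    w = np.zeros_like(E)
    w[20] = 1.0  # all weight at E = 40 keV
    phi = x.SpectralTable(E, w)
    vis = x.SpectralTable(E, np.full_like(E, 0.5), kind="visibility")
    xi = x.effective_correlation_length(phi, vis, x.EnergyBin(30.0, 60.0), geometry)
    assert xi == pytest.approx(x.correlation_length(40.0, geometry), rel=1e-3)


def test_effective_length_flat_weights_closed_form(geometry):
    """Flat Phi_eff*V over [40, 50] keV: <xi> = (d/p) hc ln(50/40)/10."""
    E = np.linspace(40.0, 50.0, 401)
    phi = x.SpectralTable(E, np.ones_like(E))
    vis = x.SpectralTable(E, np.full_like(E, 0.3), kind="visibility")
    xi = x.effective_correlation_length(
        phi, vis, x.EnergyBin(40.0, 50.0), geometry, step=0.025
    )
    assert round(xi, 3) == 1.580


def test_effective_length_bounded_by_bin_edges(geometry, source_spectrum, visibility_spectrum):
    b = x.EnergyBin(23.0, 64.0)
    xi = x.effective_correlation_length(source_spectrum, visibility_spectrum, b, geometry)
    assert x.correlation_length(64.0, geometry) <= xi <= x.correlation_length(23.0, geometry)


def test_effective_length_invariant_under_weight_rescaling(geometry, source_spectrum, visibility_spectrum):
    b = x.EnergyBin(23.0, 64.0)
    xi1 = x.effective_correlation_length(source_spectrum, visibility_spectrum, b, geometry)
    phi2 = x.SpectralTable(source_spectrum.energies, 37.0 * source_spectrum.values)
    xi2 = x.effective_correlation_length(phi2, visibility_spectrum, b, geometry)
    assert xi1 == pytest.approx(xi2, rel=1e-12)


def test_effective_length_stable_under_grid_refinement(geometry, source_spectrum, visibility_spectrum):
    b = x.EnergyBin(23.0, 64.0)
    a = x.effective_correlation_length(source_spectrum, visibility_spectrum, b, geometry, step=0.5)
    bb = x.effective_correlation_length(source_spectrum, visibility_spectrum, b, geometry, step=0.25)
    assert abs(a - bb) / bb < 1e-3


def test_effective_length_zero_weight_raises(geometry):
    E = np.linspace(30.0, 60.0, 61)
    phi = x.SpectralTable(E, np.zeros_like(E))
    vis = x.SpectralTable(E, np.full_like(E, 0.5), kind="visibility")
    with pytest.raises(ValueError, match="weight"):
        x.effective_correlation_length(phi, vis, x.EnergyBin(30.0, 60.0), geometry)


def test_source_spectrum_endpoint_and_normalization(source_spectrum):
    E, v = source_spectrum.energies, source_spectrum.values
    assert v[-1] == 0.0  # vanishes at kVp
    assert np.all(v >= 0)
    assert np.trapezoid(v, E) == pytest.approx(1.0, abs=1e-9)


def test_aluminium_filtration_hardens_beam():
    soft = x.simulate_source_spectrum(120.0, 0.0)
    hard = x.simulate_source_spectrum(120.0, 2.0)
    mean = lambda s: np.trapezoid(s.values * s.energies, s.energies)
    assert mean(hard) > mean(soft)


def test_visibility_peak_at_design_energy(visibility_spectrum):
    E, V = visibility_spectrum.energies, visibility_spectrum.values
    assert abs(E[np.argmax(V)] - 45.0) <= 0.5


def test_visibility_minimum_near_gold_edge_dip(visibility_spectrum):
    E, V = visibility_spectrum.energies, visibility_spectrum.values
    window = (E > 50.0) & (E < 78.0)
    assert abs(E[window][np.argmin(V[window])] - 64.0) <= 0.5


def test_visibility_bounded(visibility_spectrum):
    assert visibility_spectrum.values.min() >= 0.0
    assert visibility_spectrum.values.max() <= 1.0


def test_bin_truncation_equals_spectrum_inside(source_spectrum):
    b = x.EnergyBin(23.0, 64.0)
    eff = x.effective_bin_spectrum(source_spectrum, b, response_fwhm=0.0)
    E = source_spectrum.energies
    inside = (E >= 23.0) & (E < 64.0)
    np.testing.assert_array_equal(eff.values[inside], source_spectrum.values[inside])
    assert np.all(eff.values[~inside] == 0.0)


def test_sharp_bins_partition_the_spectrum(source_spectrum):
    low = x.effective_bin_spectrum(source_spectrum, x.EnergyBin(23.0, 64.0), 0.0)
    high = x.effective_bin_spectrum(source_spectrum, x.EnergyBin(64.0, 120.0), 0.0)
    E = source_spectrum.energies
    inside = (E >= 23.0) & (E < 120.0)
    np.testing.assert_allclose(
        low.values + high.values, np.where(inside, source_spectrum.values, 0.0)
    )


def test_detector_response_leaks_counts_across_threshold(source_spectrum):
    """With a finite-width response, photons above 64 keV register in the low bin."""
    E = source_spectrum.energies
    above_only = x.SpectralTable(E, np.where(E >= 66.0, source_spectrum.values, 0.0))
    leak = x.effective_bin_spectrum(above_only, x.EnergyBin(23.0, 64.0), response_fwhm=8.0)
    assert np.trapezoid(leak.values, E) > 0.0


def test_empty_bin_raises(source_spectrum):
    with pytest.raises(ValueError):
        x.effective_bin_spectrum(source_spectrum, x.EnergyBin(150.0, 160.0), 0.0)


def test_spectral_table_validation_and_csv(tmp_path):
    with pytest.raises(ValueError):
        x.SpectralTable(np.array([2.0, 1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        x.SpectralTable(np.array([1.0, 2.0]), np.array([0.5, 1.5]), kind="visibility")
    t = x.SpectralTable(np.array([10.0, 20.0, 30.0]), np.array([0.0, 1.0, 0.5]))
    p = tmp_path / "s.csv"
    t.to_csv(p)
    back = x.SpectralTable.from_csv(p)
    np.testing.assert_allclose(back.energies, t.energies)
    np.testing.assert_allclose(back.values, t.values)
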