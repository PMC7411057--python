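"""Spectra, interferometer geometry and autocorrelation lengths.

A Talbot-Lau grating interferometer at energy E probes microstructural
correlations at the autocorrelation length

    xi_corr(E) = (d_S,G2 / p_G2) * lambda,   lambda = hc / E,

where d_S,G2 is the sample-to-analyzer-grating distance and p_G2 the
analyzer grating period. With a polychromatic source and a photon-counting
detector the effectively sampled length per energy bin is the mean of
xi_corr(E) weighted by the effective bin spectrum Phi_eff(E) times the
setup's visibility spectrum V(E).

Units: energies keV, wavelengths Angstrom, grating period μm, distances m,
autocorrelation lengths μm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "HC_KEV_ANGSTROM",
    "InterferometerGeometry",
    "SpectralTable",
    "EnergyBin",
    "energy_to_wavelength",
    "correlation_length",
    "effective_correlation_length",
    "weighted_energy",
    "simulate_source_spectrum",
    "visibility_model",
    "effective_bin_spectrum",
]

#: h*c in keV·Å; the single place wavelength/energy conversion happens.
HC_KEV_ANGSTROM = 12.3984

# Mass attenuation of aluminium μ/ρ [cm²/g] on a sparse energy grid [keV]
# (tabulated reference values; log-log interpolated in between).
_AL_MU_RHO_E = np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0])
_AL_MU_RHO = np.array([26.23, 7.955, 3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1378])
_AL_DENSITY = 2.699  # g/cm³


@dataclass(frozen=True)
class InterferometerGeometry:
    """Talbot-Lau geometry entering the autocorrelation length."""

    d_S_G2: float  # sample to analyzer grating distance (m)
    p_G2: float  # analyzer grating period (μm)
    design_energy: float = 45.0  # keV, informational

    def __post_init__(self) -> None:
        if self.d_S_G2 <= 0 or self.p_G2 <= 0:
            raise ValueError("d_S_G2 and p_G2 must be positive")


@dataclass
class SpectralTable:
    """Per-energy quantity on a strictly increasing keV grid.

    ``kind`` distinguishes fluence-like tables (values >= 0) from
    visibility tables (values in [0, 1]).
    """

    energies: np.ndarray  # keV
    values: np.ndarray
    kind: Literal["fluence", "visibility"] = "fluence"

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.energies.shape != self.values.shape or self.energies.ndim != 1:
            raise ValueError("energies and values must be equal-length 1D arrays")
        if not np.all(np.diff(self.energies) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("spectral values must be non-negative")
        if self.kind == "visibility" and np.any(self.values > 1):
            raise ValueError("visibility values must not exceed 1")

    def interp(self, energies: np.ndarray) -> np.ndarray:
        """Linear interpolation, zero outside the tabulated range."""
        return np.interp(energies, self.energies, self.values, left=0.0, right=0.0)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "fluence") -> "SpectralTable":
        df = pd.read_csv(path)
        if "energy_keV" not in df.columns or "value" not in df.columns:
            raise ValueError("spectrum CSV needs 'energy_keV' and 'value' columns")
        return cls(df["energy_keV"].to_numpy(), df["value"].to_numpy(), kind=kind)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"energy_keV": self.energies, "value": self.values}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class EnergyBin:
    """Half-open detector threshold interval [E1, E2) in keV."""

    E1: float
    E2: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.E1 < self.E2:
            raise ValueError("EnergyBin requires E1 < E2")


def energy_to_wavelength(E: float | np.ndarray) -> float | np.ndarray:
    """Photon wavelength in Å from energy in keV (lambda = hc/E)."""
    E = np.asarray(E, dtype=np.float64)
    if np.any(E <= 0):
        raise ValueError("energy must be positive")
    out = HC_KEV_ANGSTROM / E
    return float(out) if out.ndim == 0 else out


def correlation_length(
    E: float | np.ndarray, geom: InterferometerGeometry
) -> float | np.ndarray:
    """Autocorrelation length xi_corr(E) in μm.

    xi = (d_S,G2 / p_G2) * hc/E, with d in m, p in μm and lambda in Å;
    strictly decreasing in E.
    """
    lam_m = np.asarray(energy_to_wavelength(E)) * 1e-10
    xi_m = (geom.d_S_G2 / (geom.p_G2 * 1e-6)) * lam_m
    out = xi_m * 1e6
    return float(out) if out.ndim == 0 else out


def _common_grid(
    phi: SpectralTable, vis: SpectralTable, bin: EnergyBin, step: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo = max(bin.E1, phi.energies[0], vis.energies[0])
    hi = min(bin.E2, phi.energies[-1], vis.energies[-1])
    if not lo < hi:
        raise ValueError("energy bin does not overlap the tabulated spectra")
    n = max(int(np.ceil((hi - lo) / step)) + 1, 3)
    grid = np.linspace(lo, hi, n)
    return grid, phi.interp(grid), vis.interp(grid)


def weighted_energy(
    phi_eff: SpectralTable,
    vis: SpectralTable,
    bin: EnergyBin,
    step: float = 0.5,
) -> float:
    """Phi_eff*V-weighted mean photon energy of a bin (keV)."""
    grid, p, v = _common_grid(phi_eff, vis, bin, step)
    w = p * v
    denom = np.trapezoid(w, grid)
    if denom <= 0:
        raise ValueError("zero total weight in bin")
    return float(np.trapezoid(w * grid, grid) / denom)


def effective_correlation_length(
    phi_eff: SpectralTable,
    vis: SpectralTable,
    bin: EnergyBin,
    geom: InterferometerGeometry,
    step: float = 0.5,
) -> float:
    """Weighted effective autocorrelation length <xi_corr>_w of a bin (μm).

    <xi>_w = int Phi_eff V xi dE / int Phi_eff V dE by trapezoid quadrature
    on a common interpolated grid. The result always lies between xi(E2)
    and xi(E1) because xi is decreasing in E.
    """
    grid, p, v = _common_grid(phi_eff, vis, bin, step)
    w = p * v
    denom = np.trapezoid(w, grid)
    if denom <= 0:
        raise ValueError("zero total weight in bin")
    xi = correlation_length(grid, geom)
    return float(np.trapezoid(w * xi, grid) / denom)


def _al_transmission(E: np.ndarray, thickness_mm: float) -> np.ndarray:
    mu = np.exp(
        np.interp(np.log(E), np.log(_AL_MU_RHO_E), np.log(_AL_MU_RHO))
    )  # cm²/g
    return np.exp(-mu * _AL_DENSITY * thickness_mm * 0.1)


def simulate_source_spectrum(
    kVp: float = 120.0,
    al_filtration_mm: float = 2.0,
    grid_step: float = 0.5,
    E_min: float = 5.0,
) -> SpectralTable:
    """Parametric tungsten-tube bremsstrahlung spectrum.

    Kramers shape Phi(E) ~ E*(kVp - E) for 0 < E < kVp, filtered by an
    aluminium slab (beam hardening), normalized to unit integral. A
    simple stand-in for a full tube simulation; characteristic lines are
    not modelled.
    """
    if kVp <= 0:
        raise ValueError("kVp must be positive")
    n = max(int(np.ceil((kVp - E_min) / grid_step)) + 1, 3)
    E = np.linspace(E_min, kVp, n)
    phi = np.clip(E * (kVp - E), 0.0, None)
    if al_filtration_mm > 0:
        phi = phi * _al_transmission(E, al_filtration_mm)
    area = np.trapezoid(phi, E)
    return SpectralTable(E, phi / area, kind="fluence")


def visibility_model(
    design_energy: float = 45.0,
    peak_visibility: float = 0.32,
    peak_width: float = 14.0,
    dip_energy: float = 64.0,
    dip_depth: float = 0.6,
    dip_width: float = 4.5,
    second_peak_scale: float = 0.75,
    second_peak_width: float = 15.0,
    E_min: float = 5.0,
    E_max: float = 150.0,
    grid_step: float = 0.5,
) -> SpectralTable:
    """Parametric visibility spectrum V(E) of a Talbot-Lau setup.

    Primary Gaussian peak at the design energy, a multiplicative dip at
    ``dip_energy`` (high grating transmission just below the gold K-edge
    produces a visibility minimum there), and a secondary peak near twice
    the design energy (odd fractional Talbot orders). All values in [0, 1].
    """
    if design_energy <= 0:
        raise ValueError("design_energy must be positive")
    E = np.arange(E_min, E_max + grid_step / 2, grid_step)
    main = np.exp(-0.5 * ((E - design_energy) / peak_width) ** 2)
    second = second_peak_scale * np.exp(
        -0.5 * ((E - 2 * design_energy) / second_peak_width) ** 2
    )
    dip = 1.0 - dip_depth * np.exp(-0.5 * ((E - dip_energy) / dip_width) ** 2)
    V = peak_visibility * (main + second) * dip
    if np.any(V < 0) or np.any(V > 1):
        raise ValueError("visibility parameterization leaves [0, 1]")
    return SpectralTable(E, V, kind="visibility")


def effective_bin_spectrum(
    phi: SpectralTable, bin: EnergyBin, response_fwhm: float = 0.0
) -> SpectralTable:
    """Effective spectrum of a photon-counting detector bin.

    With ``response_fwhm = 0`` the incident spectrum is hard-truncated to
    [E1, E2). Otherwise each incident energy's counts are first spread by
    a Gaussian detector response of the given FWHM (a one-parameter
    stand-in for a calibrated response model) and then truncated, so
    counts leak across the thresholds.
    """
    if response_fwhm < 0:
        raise ValueError("response_fwhm must be non-negative")
    E = phi.energies
    in_bin = (E >= bin.E1) & (E < bin.E2)
    if not np.any(in_bin):
        raise ValueError("energy bin does not overlap the spectrum grid")
    if response_fwhm == 0:
        vals = np.where(in_bin, phi.values, 0.0)
        return SpectralTable(E, vals, kind="fluence")
    sigma = response_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    # registered-energy redistribution: counts incident at E spread over E'
    dE = np.gradient(E)
    kernel = np.exp(-0.5 * ((E[:, None] - E[None, :]) / sigma) ** 2)
    kernel /= kernel.sum(axis=0, keepdims=True) / 1.0  # column-normalized over grid
    spread = kernel @ (phi.values * dE) / dE
    vals = np.where(in_bin, spread, 0.0)
    return SpectralTable(E, vals, kind="fluence")
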