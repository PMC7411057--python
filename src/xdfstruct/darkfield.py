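"""Dark-field forward model, phase stepping and spectral signal ratios.

For isotropic multiple small-angle scattering the dark-field signal D of a
grating interferometer obeys

    -ln D(xi_corr) = sigma * t * [1 - G(xi_corr)],      sigma = sigma0 * lambda^2,

with t the sample thickness, G the projected real-space correlation
function and xi_corr the autocorrelation length probed at energy E. With a
polychromatic spectrum the measured D of an energy bin is the
Phi_eff*V-weighted mean of the monochromatic D(E) — exactly what a
phase-stepping measurement of the summed intensity curve retrieves, which
the stepping simulation here cross-checks.

The spectral ratio -lnD_low / -lnD_high is the quantity correlated with
the mean chord length: the low-energy bin probes a longer correlation
length, so larger structures suppress its visibility disproportionately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autocorr import CorrelationProfile
from .spectral import (
    EnergyBin,
    InterferometerGeometry,
    SpectralTable,
    correlation_length,
    energy_to_wavelength,
    _common_grid,
)

__all__ = [
    "MaterialModel",
    "SteppingCurve",
    "DarkFieldResult",
    "mono_darkfield",
    "polychromatic_darkfield",
    "simulate_stepping_curve",
    "retrieve_visibility",
    "darkfield_from_visibilities",
    "normalized_logD",
    "spectral_ratio",
    "calibrate_sigma0",
    "polychromatic_darkfield_stepping",
]


@dataclass
class MaterialModel:
    """Scattering material: prefactor, thickness and correlation profile.

    ``sigma0`` is the scattering cross-section per unit thickness per
    squared wavelength (1/(m·Å²)); the cross-section itself is
    sigma0 * lambda^2. It is a free material parameter here — use
    :func:`calibrate_sigma0` to pin it to a target signal.
    """

    sigma0: float  # 1/(m·Å²)
    thickness_t: float  # m
    G_profile: CorrelationProfile

    def __post_init__(self) -> None:
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be non-negative")
        if self.thickness_t <= 0:
            raise ValueError("thickness must be positive")


@dataclass
class SteppingCurve:
    """Intensity curve sampled at n equidistant steps over one grating period."""

    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 1 or len(self.intensities) < 3:
            raise ValueError("need at least 3 phase steps")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_steps(self) -> int:
        return len(self.intensities)


@dataclass
class BinResult:
    D: float
    neg_log_D: float
    xi_w_um: float
    lambda_w_A: float


@dataclass
class DarkFieldResult:
    """Per-bin dark-field signals of one material plus their spectral ratio."""

    bins: dict[str, BinResult]
    ratio_low_over_high: float


def mono_darkfield(
    mat: MaterialModel, E: float, geom: InterferometerGeometry
) -> float:
    """Monochromatic dark-field signal D(E).

    -ln D = sigma0 * lambda(E)^2 * t * [1 - G(xi_corr(E))]; G is linearly
    interpolated on the material's profile and never extrapolated. Where
    G < 0 the bracket exceeds 1 and is applied as written.
    """
    xi = correlation_length(E, geom)
    G = mat.G_profile.interp(xi)
    lam = energy_to_wavelength(E)
    neg_log = mat.sigma0 * lam**2 * mat.thickness_t * (1.0 - G)
    return float(np.exp(-neg_log))


def polychromatic_darkfield(
    mat: MaterialModel,
    phi_eff: SpectralTable,
    vis: SpectralTable,
    bin: EnergyBin,
    geom: InterferometerGeometry,
    step: float = 0.5,
) -> float:
    """Bin dark-field signal: Phi_eff*V-weighted mean of D(E) over the bin."""
    grid, p, v = _common_grid(phi_eff, vis, bin, step)
    w = p * v
    denom = np.trapezoid(w, grid)
    if denom <= 0:
        raise ValueError("zero total weight in bin")
    D = np.array([mono_darkfield(mat, float(E), geom) for E in grid])
    return float(np.trapezoid(w * D, grid) / denom)


def simulate_stepping_curve(
    a0: float,
    visibility: float,
    phase: float,
    n_steps: int = 7,
    poisson_seed: int | None = None,
) -> SteppingCurve:
    """Sinusoidal phase-stepping intensity curve, optionally Poisson-noisy.

    I_k = a0 * [1 + visibility * cos(2 pi k / n_steps + phase)].
    """
    if not 0.0 <= visibility <= 1.0:
        raise ValueError("visibility must lie in [0, 1]")
    if a0 <= 0:
        raise ValueError("a0 must be positive")
    k = np.arange(n_steps)
    I = a0 * (1.0 + visibility * np.cos(2.0 * np.pi * k / n_steps + phase))
    if poisson_seed is not None:
        rng = np.random.default_rng(poisson_seed)
        I = rng.poisson(I).astype(np.float64)
    return SteppingCurve(I)


def retrieve_visibility(curve: SteppingCurve) -> tuple[float, float, float]:
    """Least-squares first-harmonic retrieval of (a0, visibility, phase).

    Equivalent to the first discrete Fourier coefficient of the stepping
    curve; exact on noiseless single-harmonic curves.
    """
    I = curve.intensities
    n = curve.n_steps
    a0 = float(np.mean(I))
    if a0 <= 0:
        raise ValueError("mean intensity must be positive")
    k = np.arange(n)
    c1 = np.sum(I * np.exp(-2j * np.pi * k / n)) / n
    visibility = float(2.0 * np.abs(c1) / a0)
    phase = float(np.angle(c1))
    return a0, visibility, phase


def darkfield_from_visibilities(v_sample: float, v_reference: float) -> float:
    """D = V_sample / V_reference, the visibility reduction due to scattering."""
    if v_reference <= 0:
        raise ValueError("reference visibility must be positive")
    if v_sample < 0:
        raise ValueError("sample visibility must be non-negative")
    D = v_sample / v_reference
    if D > 1.0:
        import warnings

        warnings.warn(f"dark-field signal {D:.4f} > 1; clipping to 1", stacklevel=2)
        D = 1.0
    return D


def normalized_logD(neg_log_D: float, lambda_w: float) -> float:
    """-ln D divided by the squared weighted wavelength (1/Å²)."""
    if lambda_w <= 0:
        raise ValueError("wavelength must be positive")
    if neg_log_D < 0:
        raise ValueError("-ln D must be non-negative")
    return neg_log_D / lambda_w**2


def spectral_ratio(neg_log_D_low: float, neg_log_D_high: float) -> float:
    """Quotient of the two energy-bin dark-field signals, low over high.

    Oriented so the ratio exceeds 1 (the low bin signal is stronger) and
    grows with structure size.
    """
    if neg_log_D_low <= 0 or neg_log_D_high <= 0:
        raise ValueError("both -ln D values must be positive")
    return neg_log_D_low / neg_log_D_high


def calibrate_sigma0(
    target_neg_log_D: float,
    E: float,
    geom: InterferometerGeometry,
    G_profile: CorrelationProfile,
    thickness_t: float,
) -> float:
    """sigma0 that reproduces a target -ln D at one energy."""
    xi = correlation_length(E, geom)
    bracket = 1.0 - G_profile.interp(xi)
    if bracket <= 0:
        raise ValueError("1 - G vanishes at the calibration energy")
    lam = energy_to_wavelength(E)
    return target_neg_log_D / (lam**2 * thickness_t * bracket)


def polychromatic_darkfield_stepping(
    mat: MaterialModel,
    phi_eff: SpectralTable,
    vis: SpectralTable,
    bin: EnergyBin,
    geom: InterferometerGeometry,
    n_steps: int = 7,
    step: float = 0.5,
) -> float:
    """End-to-end stepping-curve route to the bin dark-field signal.

    Per energy, sample and reference sinusoidal stepping curves are
    simulated (sample visibility V(E)*D(E)); intensities are summed over
    the weighted spectrum, visibilities retrieved from both summed curves,
    and their quotient returned. Serves as the physics oracle for
    :func:`polychromatic_darkfield`.
    """
    grid, p, v = _common_grid(phi_eff, vis, bin, step)
    w_counts = p * np.gradient(grid)  # photons per grid energy
    if np.sum(w_counts * v) <= 0:
        raise ValueError("zero total weight in bin")
    ref = np.zeros(n_steps)
    sam = np.zeros(n_steps)
    for counts, V_E, E in zip(w_counts, v, grid):
        if counts <= 0:
            continue
        D_E = mono_darkfield(mat, float(E), geom)
        ref += simulate_stepping_curve(counts, V_E, 0.0, n_steps).intensities
        sam += simulate_stepping_curve(counts, V_E * D_E, 0.0, n_steps).intensities
    _, v_ref, _ = retrieve_visibility(SteppingCurve(ref))
    _, v_sam, _ = retrieve_visibility(SteppingCurve(sam))
    return darkfield_from_visibilities(v_sam, v_ref)
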