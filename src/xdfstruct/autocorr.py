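"""Projected real-space correlation function of a 3D microstructure.

The normalized two-point autocorrelation gamma(r) of the mean-subtracted
density field is computed with the correlation (Wiener-Khinchin) theorem:

    gamma(r) = F^-1[ F(drho) * conj(F(drho)) ] / (zero-shift value),

then reduced to the 1D projected real-space correlation function G(xi):
gamma is summed along the beam axis, the resulting 2D shift map is
normalized at zero perpendicular shift, and averaged over annular radial
bins in the perpendicular plane (the samples are assumed isotropic, so
angular averaging only improves statistics). G(0) = 1 by construction;
because of mean subtraction G can go negative at large shifts, and for
media without long-range order it decays to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .volumes import Volume3D

__all__ = [
    "CorrelationVolume",
    "CorrelationProfile",
    "mean_subtract",
    "autocorrelation_3d",
    "projected_profile",
    "one_minus_G",
    "correlation_profile",
]


@dataclass
class CorrelationVolume:
    """Origin-centered normalized autocorrelation gamma over integer shifts."""

    data: np.ndarray
    voxel_size: float  # μm

    @property
    def origin(self) -> tuple[int, int, int]:
        return tuple(n // 2 for n in self.data.shape)


@dataclass
class CorrelationProfile:
    """Radially averaged projected correlation function G(xi)."""

    xi: np.ndarray  # shift magnitudes, μm, starting at 0
    G: np.ndarray
    one_minus_G: np.ndarray | None = None
    n_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=np.float64)
        self.G = np.asarray(self.G, dtype=np.float64)
        if self.xi.shape != self.G.shape:
            raise ValueError("xi and G must have the same shape")
        if not np.all(np.diff(self.xi) > 0):
            raise ValueError("xi must be strictly increasing")

    def interp(self, xi: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation of G; raises beyond the tabulated range."""
        xi_arr = np.atleast_1d(np.asarray(xi, dtype=np.float64))
        if np.any(xi_arr < self.xi[0]) or np.any(xi_arr > self.xi[-1]):
            raise ValueError(
                f"shift outside profile range [{self.xi[0]:g}, {self.xi[-1]:g}] μm; "
                "no extrapolation"
            )
        out = np.interp(xi_arr, self.xi, self.G)
        return float(out[0]) if np.isscalar(xi) or np.ndim(xi) == 0 else out

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "xi_um": self.xi,
                "G": self.G,
                "one_minus_G": (
                    self.one_minus_G if self.one_minus_G is not None else 1.0 - self.G
                ),
                "n_samples": (
                    self.n_samples
                    if self.n_samples is not None
                    else np.full_like(self.xi, np.nan)
                ),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrelationProfile":
        df = pd.read_csv(path)
        return cls(
            df["xi_um"].to_numpy(),
            df["G"].to_numpy(),
            one_minus_G=df["one_minus_G"].to_numpy() if "one_minus_G" in df else None,
            n_samples=df["n_samples"].to_numpy() if "n_samples" in df else None,
        )


def mean_subtract(vol: Volume3D) -> Volume3D:
    """Density fluctuation field: subtract the volume mean."""
    return Volume3D(vol.data - vol.data.mean(), vol.voxel_size)


def autocorrelation_3d(
    delta: Volume3D, boundary: Literal["zero_pad", "periodic"] = "zero_pad"
) -> CorrelationVolume:
    """Normalized 3D autocorrelation of a zero-mean field via FFT.

    ``zero_pad`` embeds the volume in a grid at least twice each dimension
    so the result is the linear (aperiodic) correlation, i.e. the
    finite-volume overlap integral; ``periodic`` wraps shifts around.
    Normalized so gamma(0) = 1. The output grid is origin-centered
    (zero shift at index ``shape//2``).
    """
    d = delta.data
    if not np.any(d != d.flat[0]) or float(np.sum(d * d)) == 0.0:
        raise ValueError("autocorrelation undefined for zero-variance field")
    if boundary == "zero_pad":
        padded_shape = tuple(2 * n for n in d.shape)
        axes = tuple(range(d.ndim))
        F = np.fft.rfftn(d, s=padded_shape, axes=axes)
        corr = np.fft.irfftn(F * np.conj(F), s=padded_shape, axes=axes)
        # keep shifts in (-n, n); index shape 2n-1 per axis, origin at n-1
        corr = np.fft.fftshift(corr)
        sl = tuple(slice(1, None) for _ in d.shape)
        corr = corr[sl]
    elif boundary == "periodic":
        F = np.fft.rfftn(d)
        corr = np.fft.irfftn(F * np.conj(F), s=d.shape, axes=tuple(range(d.ndim)))
        corr = np.fft.fftshift(corr)
    else:
        raise ValueError("boundary must be 'zero_pad' or 'periodic'")
    origin = tuple(n // 2 for n in corr.shape)
    corr = corr / corr[origin]
    return CorrelationVolume(corr, delta.voxel_size)


def projected_profile(
    gamma: CorrelationVolume,
    beam_axis: int = 0,
    bin_width: float = 1.0,
) -> CorrelationProfile:
    """Beam-axis projection of gamma, radially averaged in the normal plane.

    gamma is summed along ``beam_axis``; the resulting 2D map over
    perpendicular shifts is normalized by its zero-shift value (so
    G(0) = 1), then averaged over annuli of ``bin_width`` voxels with
    count weighting. Annulus k is centered on radius k * bin_width
    (bin index = floor(r / bin_width + 1/2), so ties at annulus edges go
    up); the reported shift of bin k is k * bin_width voxels, converted
    to μm — so the first nonzero shift is one voxel, the resolution floor
    of the voxel grid.
    """
    proj = gamma.data.sum(axis=beam_axis)
    perp_axes = [ax for ax in range(3) if ax != beam_axis]
    origin2d = tuple(gamma.data.shape[ax] // 2 for ax in perp_axes)
    center_val = proj[origin2d]
    if center_val == 0:
        raise ValueError("projected map vanishes at zero shift")
    proj = proj / center_val
    iy, iz = np.indices(proj.shape)
    r = np.hypot(iy - origin2d[0], iz - origin2d[1])
    bins = np.floor(r / bin_width + 0.5).astype(int)
    nbins = bins.max() + 1
    counts = np.bincount(bins.ravel(), minlength=nbins)
    sums = np.bincount(bins.ravel(), weights=proj.ravel(), minlength=nbins)
    G = sums / counts
    xi = np.arange(nbins) * bin_width * gamma.voxel_size
    return CorrelationProfile(xi, G, n_samples=counts)


def one_minus_G(profile: CorrelationProfile) -> CorrelationProfile:
    """Fill the 1 - G field (the quantity the dark-field signal scales with)."""
    return CorrelationProfile(
        profile.xi, profile.G, one_minus_G=1.0 - profile.G, n_samples=profile.n_samples
    )


def correlation_profile(
    vol: Volume3D,
    boundary: Literal["zero_pad", "periodic"] = "zero_pad",
    beam_axis: int = 0,
    bin_width: float = 1.0,
    average_axes: bool = False,
) -> CorrelationProfile:
    """Full chain: mean-subtract, 3D autocorrelation, projection, radial average.

    ``average_axes=True`` averages the profiles obtained by projecting
    along each of the three axes. For isotropic samples the three are
    estimates of the same G and the average only reduces estimator
    variance (each projection draws on a different plane of the power
    spectrum).
    """
    gamma = autocorrelation_3d(mean_subtract(vol), boundary=boundary)
    if not average_axes:
        return one_minus_G(
            projected_profile(gamma, beam_axis=beam_axis, bin_width=bin_width)
        )
    profs = [projected_profile(gamma, beam_axis=ax, bin_width=bin_width) for ax in range(3)]
    n = min(len(p.G) for p in profs)
    return one_minus_G(
        CorrelationProfile(
            profs[0].xi[:n],
            np.mean([p.G[:n] for p in profs], axis=0),
            n_samples=np.sum([p.n_samples[:n] for p in profs], axis=0),
        )
    )
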