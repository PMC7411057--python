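"""Synthetic 3D two-phase porous volumes.

Phantom families that emulate the microstructures probed by grating-based
X-ray dark-field imaging of porous samples: dilute solid/hollow sphere
packings and Voronoi-wall closed-cell foams (structural surrogates for
lung parenchyma), plus a microCT-like blur+noise degradation model.

Conventions (used everywhere in this package):

* axes are ``(x, y, z)`` with ``x`` the beam direction and ``z`` the
  interferometer sensitivity direction;
* the cavity phase (air) carries label 1 in a :class:`PhaseMap`, material
  carries 0;
* grayscale volumes are attenuation proxies: material is bright
  (``MATERIAL_VALUE``), air is dark (``CAVITY_VALUE``);
* voxels are isotropic, one scalar ``voxel_size`` in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "Volume3D",
    "PhaseMap",
    "PhantomSpec",
    "make_solid_spheres",
    "make_hollow_spheres",
    "make_voronoi_foam",
    "make_slab",
    "add_microct_noise",
]

CAVITY_VALUE = 0.0
MATERIAL_VALUE = 1.0


@dataclass
class Volume3D:
    """3D scalar grid (attenuation / electron-density proxy) with isotropic voxels."""

    data: np.ndarray
    voxel_size: float  # μm per voxel edge

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise ValueError("Volume3D requires a 3D grid with all dimensions >= 2")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class PhaseMap:
    """Binary 3D grid: 1 = cavity (air), 0 = material."""

    data: np.ndarray
    voxel_size: float  # μm

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("PhaseMap values must be 0 or 1")
        self.data = arr.astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError("PhaseMap must be 3D")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def cavity_fraction(self) -> float:
        return float(self.data.mean())


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom.

    Feature sizes are in micrometres; ``shape`` is voxels per axis.
    ``spheres_are_cavity`` selects whether sphere interiors are pores
    (cavities in a solid matrix, the default) or solid grains in air.
    """

    kind: Literal["solid_spheres", "hollow_spheres", "voronoi_foam", "slab"]
    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 2.0  # μm
    radius_um: float = 20.0
    radius_sigma_log: float = 0.0  # lognormal shape parameter; 0 = monodisperse
    shell_thickness_um: float = 4.0
    n_seeds: int = 64
    wall_thickness_um: float = 4.0
    slab_thickness_um: float = 20.0
    volume_fraction: float = 0.3  # target cavity fraction (sphere phases see docstrings)
    spheres_are_cavity: bool = True
    min_fraction: float = 0.0  # fail RSA packing below this achieved fraction
    seed: int = 0
    max_attempts: int = 20000

    def __post_init__(self) -> None:
        if not 0 < self.volume_fraction < 1:
            raise ValueError("volume_fraction must lie in (0, 1)")
        if self.kind in ("solid_spheres", "hollow_spheres"):
            if self.radius_um < 2 * self.voxel_size:
                raise ValueError("sphere radius must be at least 2 voxels")
        if self.kind == "voronoi_foam":
            if self.n_seeds < 2:
                raise ValueError("voronoi_foam requires n_seeds >= 2")
            if self.wall_thickness_um < self.voxel_size:
                raise ValueError("wall thickness must be at least 1 voxel")


def _voxel_centers(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    # voxel i occupies [i, i+1); its center sits at i + 0.5 (voxel units)
    return np.meshgrid(
        *(np.arange(n) + 0.5 for n in shape), indexing="ij", sparse=True
    )


def _grayscale_from_phase(phase: np.ndarray) -> np.ndarray:
    return np.where(phase == 1, CAVITY_VALUE, MATERIAL_VALUE).astype(np.float64)


def _rsa_centers(
    rng: np.random.Generator,
    shape_vox: tuple[int, int, int],
    radii_vox: np.ndarray,
    max_attempts: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Random sequential addition of non-overlapping spheres fully inside the box.

    Returns (centers, radii) in voxel units for the spheres that were placed.
    """
    centers: list[np.ndarray] = []
    placed_r: list[float] = []
    lo = np.zeros(3)
    hi = np.asarray(shape_vox, dtype=float)
    i = 0
    attempts = 0
    while i < len(radii_vox) and attempts < max_attempts:
        r = radii_vox[i]
        c = rng.uniform(lo + r, hi - r)
        attempts += 1
        ok = True
        for cj, rj in zip(centers, placed_r):
            if np.sum((c - cj) ** 2) < (r + rj) ** 2:
                ok = False
                break
        if ok:
            centers.append(c)
            placed_r.append(r)
            i += 1
    if not centers:
        return np.empty((0, 3)), np.empty(0)
    return np.array(centers), np.array(placed_r)


def _sphere_mask(
    shape: tuple[int, int, int], centers: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Boolean mask of voxels whose center lies inside any sphere (voxel units)."""
    mask = np.zeros(shape, dtype=bool)
    if len(centers) == 0:
        return mask
    for c, r in zip(centers, radii):
        # only visit the bounding box of each sphere
        lo = np.maximum(np.floor(c - r - 1).astype(int), 0)
        hi = np.minimum(np.ceil(c + r + 1).astype(int), shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        gx, gy, gz = np.meshgrid(
            *(np.arange(a, b) + 0.5 for a, b in zip(lo, hi)),
            indexing="ij",
            sparse=True,
        )
        d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        mask[sl] |= d2 <= r**2
    return mask


def _draw_radii(rng: np.random.Generator, spec: PhantomSpec, n: int) -> np.ndarray:
    r_vox = spec.radius_um / spec.voxel_size
    if spec.radius_sigma_log > 0:
        radii = r_vox * rng.lognormal(0.0, spec.radius_sigma_log, size=n)
        return np.clip(radii, 2.0, None)
    return np.full(n, r_vox)


def make_solid_spheres(spec: PhantomSpec) -> tuple[Volume3D, PhaseMap]:
    """Non-overlapping solid spheres placed by random sequential addition.

    By default sphere interiors are the cavity phase (pores in a solid
    matrix) so that ``spec.volume_fraction`` is the target cavity fraction.
    Deterministic for a fixed ``spec.seed``.
    """
    if spec.kind != "solid_spheres":
        raise ValueError("spec.kind must be 'solid_spheres'")
    rng = np.random.default_rng(spec.seed)
    box_vox = float(np.prod(spec.shape))
    r_vox = spec.radius_um / spec.voxel_size
    n_target = int(np.ceil(spec.volume_fraction * box_vox / ((4 / 3) * np.pi * r_vox**3)))
    radii = _draw_radii(rng, spec, n_target)
    centers, placed = _rsa_centers(rng, spec.shape, radii, spec.max_attempts)
    mask = _sphere_mask(spec.shape, centers, placed)
    achieved = mask.mean()
    if achieved < spec.min_fraction:
        raise RuntimeError(
            f"sphere packing reached fraction {achieved:.4f} < minimum "
            f"{spec.min_fraction:.4f} after {spec.max_attempts} attempts"
        )
    phase = mask.astype(np.uint8)
    if not spec.spheres_are_cavity:
        phase = 1 - phase
    vol = Volume3D(_grayscale_from_phase(phase), spec.voxel_size)
    return vol, PhaseMap(phase, spec.voxel_size)


def make_hollow_spheres(spec: PhantomSpec) -> tuple[Volume3D, PhaseMap]:
    """Packing of thin material shells around air cores, air in between.

    Emulates hollow glass microsphere powders: only the shells are
    material, both the cores and the interstitial space are cavity.
    """
    if spec.kind != "hollow_spheres":
        raise ValueError("spec.kind must be 'hollow_spheres'")
    if spec.shell_thickness_um >= spec.radius_um:
        raise ValueError("shell thickness must be smaller than the sphere radius")
    if spec.shell_thickness_um < spec.voxel_size:
        raise ValueError(
            "shell thinner than one voxel; increase grid resolution or shell thickness"
        )
    rng = np.random.default_rng(spec.seed)
    box_vox = float(np.prod(spec.shape))
    r_vox = spec.radius_um / spec.voxel_size
    # volume_fraction here targets the total sphere (core+shell) packing fraction
    n_target = int(np.ceil(spec.volume_fraction * box_vox / ((4 / 3) * np.pi * r_vox**3)))
    radii = _draw_radii(rng, spec, n_target)
    centers, placed = _rsa_centers(rng, spec.shape, radii, spec.max_attempts)
    t_vox = spec.shell_thickness_um / spec.voxel_size
    outer = _sphere_mask(spec.shape, centers, placed)
    inner = _sphere_mask(spec.shape, centers, placed - t_vox)
    shell = outer & ~inner
    phase = (~shell).astype(np.uint8)  # everything except shells is air
    vol = Volume3D(_grayscale_from_phase(phase), spec.voxel_size)
    return vol, PhaseMap(phase, spec.voxel_size)


def make_voronoi_foam(spec: PhantomSpec) -> tuple[Volume3D, PhaseMap]:
    """Closed-cell foam: walls of a Voronoi tessellation of random seed points.

    A voxel is material when the distance gap between its two nearest seed
    points is below the wall thickness, i.e. it lies within ~half a wall
    thickness of a cell boundary. Mean cell size (and hence the foam's mean
    chord length) is controlled by the seed density.
    """
    if spec.kind != "voronoi_foam":
        raise ValueError("spec.kind must be 'voronoi_foam'")
    rng = np.random.default_rng(spec.seed)
    pts = rng.uniform(0.0, np.asarray(spec.shape, dtype=float), size=(spec.n_seeds, 3))
    tree = cKDTree(pts)
    gx, gy, gz = _voxel_centers(spec.shape)
    coords = np.stack(np.broadcast_arrays(gx, gy, gz), axis=-1).reshape(-1, 3)
    dist, _ = tree.query(coords, k=2)
    w_vox = spec.wall_thickness_um / spec.voxel_size
    wall = (dist[:, 1] - dist[:, 0]) <= w_vox
    phase = (~wall.reshape(spec.shape)).astype(np.uint8)
    material_fraction = 1.0 - phase.mean()
    if material_fraction > 0.9:
        raise RuntimeError(
            f"degenerate foam: walls occupy {material_fraction:.0%} of the volume"
        )
    vol = Volume3D(_grayscale_from_phase(phase), spec.voxel_size)
    return vol, PhaseMap(phase, spec.voxel_size)


def make_slab(spec: PhantomSpec) -> tuple[Volume3D, PhaseMap]:
    """A single cavity slab of given thickness spanning the box in-plane.

    The slab is normal to the z axis and centered; used for the closed-form
    mean-chord-length identity MCL = 2t of a thin gap under isotropic lines.
    """
    if spec.kind != "slab":
        raise ValueError("spec.kind must be 'slab'")
    t_vox = int(round(spec.slab_thickness_um / spec.voxel_size))
    nz = spec.shape[2]
    z0 = (nz - t_vox) // 2
    z1 = z0 + t_vox
    if z0 < 1 or z1 > nz - 1:
        raise ValueError("slab does not fit inside the volume with solid margins")
    phase = np.zeros(spec.shape, dtype=np.uint8)
    phase[:, :, z0:z1] = 1
    vol = Volume3D(_grayscale_from_phase(phase), spec.voxel_size)
    return vol, PhaseMap(phase, spec.voxel_size)


def add_microct_noise(
    vol: Volume3D, blur_sigma: float, noise_sd: float, seed: int | None = 0
) -> Volume3D:
    """MicroCT-like degradation: Gaussian blur then additive Gaussian noise.

    Parameters
    ----------
    blur_sigma : float
        Point-spread standard deviation in μm (0 disables blurring).
    noise_sd : float
        Noise standard deviation as a fraction of the volume's contrast
        (max - min of the input; for a constant volume the contrast
        reference is 1).
    """
    if blur_sigma < 0 or noise_sd < 0:
        raise ValueError("blur_sigma and noise_sd must be non-negative")
    data = vol.data
    if blur_sigma > 0:
        data = ndimage.gaussian_filter(data, sigma=blur_sigma / vol.voxel_size)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        contrast = float(vol.data.max() - vol.data.min())
        if contrast == 0:
            contrast = 1.0
        data = data + rng.normal(0.0, noise_sd * contrast, size=data.shape)
    elif blur_sigma == 0:
        data = data.copy()
    return Volume3D(data, vol.voxel_size)
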