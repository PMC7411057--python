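# Methods

This note records the models, assumptions and numerical choices behind
`xdfstruct`, and what the synthetic phantoms do and do not establish
about real measurements.

## Physical model

The dark-field signal of a grating interferometer is modelled, per
photon energy, as

    −ln D(E) = σ₀ λ(E)² t [1 − G(ξ_corr(E))],   ξ_corr(E) = (d_S,G2/p_G2) · hc/E,

valid for isotropic multiple ultra-small-angle scattering. `σ₀` (units
1/(m·Å²)) absorbs the material's scattering strength per thickness per
squared wavelength; it is a free parameter (default 5·10⁴, thickness
5 mm, chosen so −ln D falls in the 0.1–2 range typical of strongly
scattering foams) and cancels from the low/high-bin ratio. A calibration
helper pins it to a target −ln D at one energy. Where mean subtraction
drives `G < 0`, the bracket exceeds 1 and is applied as written — no
clamping. All energy↔wavelength conversion goes through the single
constant `hc = 12.3984 keV·Å`.

A polychromatic energy bin is combined as the `Φ_eff·V`-weighted mean of
the monochromatic `D(E)` (trapezoid quadrature, 0.5 keV default step on
a common interpolated grid). This is exactly what first-harmonic
retrieval of the summed per-energy stepping curves yields when all
energies share the fringe phase, and the package carries an independent
stepping-curve simulation (`polychromatic_darkfield_stepping`) that the
tests hold against the weighted mean at the 1% level. Phase-stepping
retrieval itself is a least-squares first-harmonic (DFT) fit — exact on
noiseless sinusoids and nearly unbiased (<1%) at 10⁵ counts under
Poisson noise.

### Spectra

The source is a Kramers bremsstrahlung shape `Φ(E) ∝ E(kVp−E)` filtered
by 2 mm Al (tabulated aluminium attenuation, log-log interpolated),
normalized to unit integral; characteristic tungsten lines are omitted.
The visibility spectrum is parametric: a Gaussian peak at the 45 keV
design energy, a multiplicative dip centred at 64 keV (high grating
transmission approaching the gold K-edge) and a secondary peak near
twice the design energy; measured spectra can be loaded from CSV
instead. The photon-counting detector response is a single-parameter
Gaussian broadening (default FWHM 8 keV, a plausible CdTe figure at
these energies) applied before hard threshold truncation at the bin
edges `[E1, E2)`; it produces cross-threshold count leakage but no
charge-sharing, fluorescence-escape or pile-up physics.

## Correlation profile G(ξ)

`γ(r)` is computed by the correlation theorem on the mean-subtracted
field. The default boundary mode zero-pads to twice each dimension, so
the result is the linear (aperiodic) correlation — the finite-volume
overlap integral — without any taper correction; the overlap factor
(1−|s|/N per axis) is below 2% at the shifts the dark-field model
samples. A periodic mode exists for parity checks and for fields that
are periodic by construction. The profile is obtained by summing γ along
the beam axis, normalizing the 2D map at zero perpendicular shift, and
count-weighted averaging over annuli one voxel wide centred on integer
radii (ties at annulus edges round up). The first nonzero ξ is one
voxel — the resolution floor of the input grid, which at 2 μm voxels is
*above* the sampled ξ of 0.88–1.65 μm; sub-voxel shifts are linearly
interpolated, so fine-structure curvature of G below one voxel is
invisible. This resolution limit is intrinsic to computing G from
imaging data and is the reason the study's structural readout is the
spectral ratio rather than G itself.

For isotropic samples the pipeline averages the profiles projected along
all three axes (`average_projection_axes`, default on). Each projection
uses a different plane of the power spectrum, so the average is a pure
variance reduction; single-axis profiles remain available.

Two estimator properties worth knowing: (i) subtracting the sample mean
forces the projected map to integrate to zero, which depresses G by
roughly `Σ C / L²` and lets it go negative at large shifts — the tests
compare against the estimator's expectation, not the bare correlation
function; (ii) a single realization of a random medium carries
irreducible periodogram noise, which the validation suite removes by
synthesizing Gaussian-correlated fields with exact spectral magnitudes
and random phases.

## Mean chord length

Test lines are isotropic uniform random (μ-random): direction uniform on
the hemisphere, position uniform on the half-diagonal disk through the
box centre normal to the direction. Under this design the convex-body
identity MCL = 4V/S (sphere: 2d/3) and the thin-slab value 2t hold, and
both are enforced in the acceptance suite.

Chords are extracted by sampling the cavity indicator every quarter
voxel along each line. The binary map is first low-pass filtered with a
Gaussian of σ = 0.8 voxel and sampled trilinearly at the 0.5 level.
This anti-aliasing step matters: a raw voxelized surface carries a
resolution-independent ~8% surface-area excess (marching-cubes area of a
digitized sphere ≈ 1.08 × the true area), and nearest-voxel sampling
additionally splits grazing chords on the jagged surface; together these
bias a sphere's MCL from 26.7 down to ≈ 19 μm. With smoothing, the
0.5-isosurface tracks the true surface to sub-voxel accuracy and the
sphere identity is recovered within sampling error. Runs or gaps of at
most half a voxel are treated as residual aliasing and bridged/dropped —
genuine features at that scale are below what the grid can represent.
The trade-off is that sharp edges are rounded at the σ scale (a 40 μm
cube's effective 4V/S rises ~3%); bodies a few tens of voxels across
keep this below statistical error.

A chord whose run touches any volume face is excluded (a cavity
truncated by the region of interest would understate its length). The
exclusion is applied per chord, not per connected cavity, which keeps
space-spanning phases (foam cavities, slabs) measurable. Note the rule
biases wide-ROI identities only logarithmically: for the 2t slab it
removes the longest grazing chords, so the check uses a block 4096 μm
wide, where the residual deficit is ~3%. Default 10,000 lines with the
standard error of the chord mean reported alongside.

## Phantoms

All phantoms are two-phase, isotropic, seeded (one integer seed drives
all randomness) and deterministic: cavity = air = label 1; grayscale
volumes put material at 1.0 and air at 0.0, so midpoint thresholding
recovers the exact phase map. Defaults: 128³ voxels at 2 μm.

- **Solid spheres** — random sequential addition of non-overlapping
  spheres (voxel centre inside ⇒ sphere voxel), spheres are pores by
  default. Dilute configurations have analytically known MCL and a
  correlation profile whose 1−G flank peaks at the sphere scale.
- **Hollow spheres** — thin material shells around air cores, air
  between spheres; emulates hollow glass microsphere powders.
- **Voronoi foam** — material where the distance gap between the two
  nearest seed points falls below the wall thickness (default 4 μm);
  cell size, and hence MCL, is controlled by the seed count.
- **microCT degradation** — Gaussian blur (σ in μm) plus additive
  Gaussian noise scaled to the volume's contrast; segmentation back to a
  phase map is Otsu thresholding (≥99% voxel agreement at 5% noise).

The study family uses Voronoi foams with 2000/800/300/100/30 seeds in a
256 μm box, realizing MCL ≈ 12–55 μm. The upper end is box-limited:
under the boundary-exclusion rule, cells much above ~60 μm in a 256 μm
volume lose most interior chords and their single-realization G becomes
noisy, so the family deliberately sits in the steep part of the
ratio-vs-MCL response rather than stretching to the ~140 μm coarse
foams of physical sample sets.

What the phantoms do not emulate: reconstruction artifacts (beam
hardening, rings), anisotropic or graded structures, partial-volume
grey levels beyond Gaussian blur, polydisperse wall thicknesses. Passing
tests establish the correctness of the estimators and the forward
model's internal consistency — not detector-accurate absolute dark-field
values for any physical material.

## Numerical choices and degenerate inputs

- Quadrature: trapezoid on a 0.5 keV grid; halving the step moves
  ⟨ξ⟩_w by <0.1%.
- Interpolation of G is linear and never extrapolates (error outside the
  tabulated range).
- Constant (zero-variance) volumes are rejected by the autocorrelation;
  single-phase maps by the stereology; empty bins and zero spectral
  weight raise immediately.
- The spectral ratio is oriented low/high, making it >1 and increasing
  with structure size; `D > 1` after retrieval is clipped to 1 with a
  warning.
- Determinism: a fixed configuration reproduces every number bit-for-bit
  (generator seeds, stereology seed and quadrature are all explicit).

## Known limitations

- The forward model assumes the sample sits at one position: the decay
  of ξ_corr along a thick sample's depth is not modelled.
- G at ξ below one voxel is a linear interpolation; conclusions that
  depend on sub-voxel curvature of G are out of reach at the default
  resolution.
- The energy exponent of −ln D spans [2, 3] in this implementation's
  regimes (plateau → λ², linear-G → λ³); steeper dependencies up to λ⁴
  reported for certain sphere regimes require correlation shapes the
  voxel phantoms do not resolve.
- Visibility and detector-response models are parametric stand-ins;
  replace them with measured CSV spectra for setup-specific work.
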