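# Methods

## The physical model

The head is idealized as a stack of four planar slabs inside a
14 × 14 × 14 mm³ cube sampled at 0.1 mm isotropic voxels: scalp (3 mm),
skull (5 mm), cerebrospinal fluid (2 mm) and gray matter (4 mm), entered
from the scalp surface at z = 0. Each layer is homogeneous with the
800 nm optical properties

| layer | μa (1/mm) | μs (1/mm) | g | n |
|---|---|---|---|---|
| scalp | 0.018 | 19.0 | 0.9 | 1.37 |
| skull | 0.016 | 16.0 | 0.9 | 1.43 |
| CSF | 0.004 | 2.4 | 0.9 | 1.33 |
| gray matter | 0.036 | 22.0 | 0.9 | 1.37 |

The background outside the cube is air (μa = 0, n = 1) and is treated as
effectively transparent: a photon crossing into it is scored as escaped
energy (after the Fresnel decision at the face, below). Voxels are
0-based and half-open — voxel (i, j, k) spans
[i·Δ, (i+1)·Δ) × [j·Δ, (j+1)·Δ) × [k·Δ, (k+1)·Δ) with Δ = 0.1 mm — and
every module shares this convention.

## Transport

Photon packets of initial weight ≤ 1 are launched on the z = 0 plane
(nudged 10⁻⁶ mm inside the first voxel, so there is no specular launch
loss; a `specular_at_launch` switch restores the Fresnel entry loss for
sensitivity checks). Propagation is the standard voxel Monte Carlo walk:

* **Hop.** A dimensionless step −ln ξ is consumed against the local
  scattering coefficient μs while the ray is traced voxel-by-voxel
  (incremental grid stepping); the remaining step is rescaled whenever
  the label changes. Media with μs = 0 are traversed ballistically.
* **Drop.** Absorption is continuous: over a segment of length l the
  weight attenuates by exp(−μa·l) and the voxel's fluence gains
  w(1 − e^{−μa l})/(μa V) (track-length estimator; the limit w·l/V when
  μa = 0). For optical depths below 0.01 a third-order series replaces
  the exponential (relative error < 10⁻⁹). Absorption density is
  derived afterwards as A = μa F, so that identity is exact by
  construction, and the energy ledger
  absorbed + escaped + residual = launched closes to float precision.
* **Spin.** Deflection cosines are drawn from the Henyey–Greenstein
  inverse CDF; the azimuth is uniform. The new direction is produced by
  an exact branchless orthonormal-basis rotation, so unit norm is
  preserved without renormalization.
* **Interfaces.** At any voxel face where the refractive index changes
  (including the cube's outer faces against air), the packet reflects
  specularly with the unpolarized Fresnel probability — with certainty
  beyond the critical angle — or refracts by Snell's law.
* **Termination.** Escape into the background, the 5 × 10⁻⁸ s time gate
  (inert at head scale: even 10 m of optical path fits inside it), a
  10⁶-step guard, or Russian roulette below weight 10⁻⁴ (survival
  probability 0.1, weight ×10 on survival). Roulette's zero-mean
  bookkeeping imbalance is recorded separately (`roulette_net`); because
  the weights at stake are ≤ 10⁻⁴, the ledger still closes to better
  than 10⁻⁶ relative.

The kernel is a single serial numba routine (~55 ns per voxel segment;
a photon in this model generates ~900 segments on average, so 10⁶
photons take on the order of a minute per source on one core). Random
numbers come from an inlined splitmix64 counter generator; each run is
split into ≥ 8 photon chunks with seeds derived from the master seed via
`numpy.random.SeedSequence`, which makes runs bit-reproducible and gives
chunk-to-chunk spreads from which Monte Carlo standard errors of the
layer percentages and of the center-column profile are estimated.

## Sources

All sixteen sources are centered at (7, 7, 0) mm and aimed along +z;
lengths quoted in grid units convert at 0.1 mm per grid cell (waist and
extent parameters of 10 grid = 1.0 mm, disk radius 0.5 mm, ring
0.5/0.1 mm, 2 × 2 pencil array over 1 × 1 mm, spatial frequencies 2/2
cycles per extent, Fourier parameters [kx, ky, φ0, M] = [1, 1, 0, 0]).
Choices made where the study description leaves latitude:

* **Arcsine** — a wide-angle point emitter with radiance ∝ cos²θ over
  the forward hemisphere (cosθ = u^{1/3}). This keeps the source
  forward-focused, consistent with its grouping among the well-focused
  point sources; no headline quantity depends on this law alone.
* **Angular Gaussian** — point launch with zenith angle |N(0, π/6)|
  re-drawn until below π/2, so every photon enters the tissue.
* **Hyperboloid Gaussian** — each photon rides a ray of the Gaussian
  beam hyperboloid with waist radius 1.0 mm, focus 0.1 mm below the
  surface, and Rayleigh range π/6 grid units (treated as a dimensionless
  shape parameter, i.e. ≈ 0.052 mm). At the launch plane the waist
  sample is magnified by √(1 + (d/zR)²) ≈ 2.16 and rays converge along
  the hyperboloid tangent, making this the most oblique and hence most
  surface-diffusive source — it is the scalp-layer winner.
* **Diffuse line** — emits uniformly over the forward half-circle
  perpendicular to the segment.
* **Isotropic** — full-sphere emission; the downward half is scored as
  escaped at launch.
* **Pattern sources** (spatial-frequency, 1D/2D Fourier) — implemented
  by weight modulation ∝ ½(1 + M cos(2π(kx·u + ky·v) + φ0)) rather than
  rejection sampling, so every source launches exactly n photons and the
  comparison is per unit launched energy. With M = 0 the Fourier types
  reduce to the planar source.

## Quantification

* Volume normalization is the affine map to [0, 100]; axial profiles
  through the center column (voxel column (70, 70), the column whose low
  corner is exactly x = y = 7 mm) are min–max normalized to [0, 1].
* Depth-at-level reports the deepest voxel k with normalized value ≥
  the level, as (k + 1) · 0.1 mm, so the deepest voxel reads 14.0 mm.
  Because the column minimum maps to exactly 0, a strictly decaying
  fluence column can read at most 13.9 mm; absorption columns dip to
  their minimum inside the CSF, which is how full-depth 14.0 mm readings
  arise.
* A noise guard accompanies every depth: the per-voxel relative standard
  error of the column (from chunk spread) at the reported depth must be
  below 0.3, otherwise the depth is flagged as noise-limited. The 0.01%
  level sits close to the Monte Carlo noise floor at desk-scale photon
  budgets and is only trusted when the guard passes.
* FWHM takes the leftmost and rightmost half-maximum crossings of a
  lateral cut, each located by linear interpolation between bracketing
  samples; a side that never crosses half maximum yields a flagged NaN
  rather than a guess. Plateaus count from their outer edges. Within a
  depth slab A = μa F with a single μa, so fluence and absorption widths
  coincide identically — observing that in simulation is a consistency
  check, not new information.

## Problem sizes and presets

The study-scale run uses 10⁸ photons per source. The package presets
are `desk` (10⁶), `standard` (10⁷) and `full` (10⁸). Layer percentages
are already stable to ≲ 0.05 percentage points at 10⁶ photons (verified
against the chunk-spread standard errors); depth-at-level at the 0.1%
and 0.01% levels needs more center-column statistics, so analyses of
propagation depth use ≥ 3 × 10⁶ photons for the collimated Gaussian.
The acceptance script and the test suite run at these sizes; results at
larger budgets differ only within the reported Monte Carlo errors, with
threshold depths drifting slightly shallower as column noise (which can
only extend the deepest-voxel-above-level reading) decreases.

## What the model does and does not capture

The phantom is a planar-slab idealization: no curvature, no tissue
heterogeneity within a layer, no vessels, single wavelength (800 nm),
unpolarized light, no fluorescence and no acoustic step after
absorption. Agreement of the simulated percentages and depths with the
published study values therefore validates the transport and
quantification machinery on the same idealization, not the fidelity of
the slab model to a real head. Within the model, the Monte Carlo engine
is cross-checked against closed forms: Beer–Lambert attenuation in a
pure absorber (2%), Henyey–Greenstein moments, Fresnel
normal-incidence/critical-angle values, exact chord lengths through the
voxel grid (10⁻⁹), and diffusion theory for an embedded isotropic point
source (within 10% at 2–5 transport lengths).

## Known limitations

* Interior refractive-index mismatches are honored at every voxel face;
  reference voxel codes often ignore interior mismatches by default.
  The reflectances involved are ≤ 10⁻³, below the Monte Carlo noise of
  desk-scale runs.
* The deepest-voxel-above-level depth estimator is noise-biased deep;
  the noise guard flags, but does not correct, this bias.
* Russian roulette makes the realized (not expected) energy ledger
  close only to ~10⁻⁶ relative rather than exactly; `roulette_net`
  reports the imbalance.
* The CSF is modeled with the table's μs = 2.4/mm rather than as a
  clear fluid with boundary-guided light piping; thin-CSF effects seen
  in anatomical models are outside scope.
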