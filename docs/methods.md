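# Methods

This note records the models implemented in `spinodal`, the numerical
choices behind them, and what the test conditions do and do not establish.

## Phase-field model

The order parameter φ distinguishes the solid precursor (φ = +1) from the
pore precursor (φ = −1) and evolves by conserved gradient flow of the
Ginzburg–Landau free energy

    F[φ] = ∫ ε²/2 |∇φ|² + (φ² − 1)²/4 dx,
    ∂φ/∂t = M ∇²Ψ,   Ψ = −ε²∇²φ + (φ² − 1)φ,   M = γλ/ε².

Parameters (model units): mobility factor γ = 1, mixing energy density
λ = 0.085, capillary width ε = 0.08. Because the dynamics conserve the
spatial mean of φ exactly, the initialization mean μ fixes the final solid
fraction by the lever rule, p_pore = (1 − μ)/2, for |μ| inside the spinodal
region |μ| < 1/√3; outside it the uniform mixture is metastable and the
noise decays, giving a fully dense (or fully porous) outcome. This is the
mechanism both for porosity control and for dense implant cores.

### Discretization

Semi-implicit Fourier-spectral stepping on a fully periodic grid: the
biharmonic term is implicit, the cubic term explicit, with a linear
stabilization split of strength A = 2 so the step size is not constrained
by the well term,

    φ̂⁺ = [(1 + Δt·M·k²A) φ̂ − Δt·M·k² ĝ] / [1 + Δt·M·ε²k⁴ + Δt·M·k²A].

The k = 0 mode is untouched, so the mean is conserved to machine
precision, and all operations commute exactly with circular shifts.

**Length and time calibration.** The voxel edge is 5/64 model-length units
(a 64³ reference cube spans 5.0 units). With ε = 0.08 this resolves the
diffuse interface (width 2√2·ε ≈ 2.9 voxels) while placing the
fastest-growing wavelength 2π√2·ε at ≈ 9 voxels, so a 64³ box holds many
features and the late-stage mean pore radius sits near 4–11 voxels
depending on the save. The resolution check requires the interface width to
span ≥ 2.5 voxels. The step is Δt = 1.25 × 10⁻³ with 10 substeps per save
and 100 saves; under these defaults the first zero-crossing of the 2-point
autocovariance roughly doubles between saves 10 and 100 (≈ 9 → ≈ 20
voxels), the free energy decreases monotonically, and the per-save L2
change of φ decays strongly over the last 50 saves. Typical overshoot
beyond the wells is ≈ 2% (Gibbs-level); the divergence guard triggers at
|φ| > 1.5.

## Morphology

* **Thresholding** at φ = 0: solid where φ > 0.
* **Connectivity** is counted under 6-connectivity (faces only) *without*
  periodic wrap: fragments joined only through the boundary would be loose
  pieces in a fabricated part. The artifact filter reassigns every
  component smaller than 1000 voxels to the opposite phase (solid pass
  first, then pore; the fixed order makes interacting removals
  deterministic, and the filter is idempotent).
* **Local thickness**: the pore size at a voxel is the radius of the
  largest sphere that lies inside the phase and covers the voxel. Computed
  by thresholding the (periodic, 3×-tiling) Euclidean distance transform at
  descending radii and dilating each seed set with an exact periodic FFT
  ball dilation; radii are floored to 0.1-voxel steps so every ladder value
  has a nonempty seed set. Values are radii by convention (a diameter mode
  exists). An exhaustive sphere-painting oracle reproduces the field
  exactly on small volumes.
* **2-point statistics** S2(r): periodic autocorrelation of the phase
  indicator, radially averaged in 1-voxel bins; S2(0) equals the volume
  fraction and the whole curve is exactly invariant under circular shifts.

## GRF blobs benchmark

White noise smoothed by a periodic Gaussian kernel and thresholded at the
porosity quantile (porosity exact to one voxel by construction). Matching
to a spinodal structure bisects the correlation length until the mean
local-thickness pore radius agrees within 0.1 voxel. At matched porosity
and mean pore size the blobs' pore-size distribution is broader (they have
no mechanism enforcing uniform channel width), which is what makes them the
transport benchmark.

## Transport

The pore network is extracted by watershed of the smoothed (σ = 1 voxel)
pore-space distance transform; peaks closer than the larger of their radii
merge. Throats are shared basin boundaries; the three-segment conduit
(half-pore, throat, half-pore) always sums to the center distance, with the
throat segment floored at 5% of it — this prevents double-counting path
length when basins overlap. Pipe conductances are g = D₀·area/length with
circular cross-sections capped at the domain cross-section; the series
combination gives the pair conductance in j₁₂ = D₁₂(c₁ − c₂). Mass
conservation with Dirichlet inlet/outlet couplings is a sparse linear
solve, and

    D_eff = j·L / ((c_in − c_out)·C·A),  C = 1,

with L and A in voxel units. A 7-point finite-volume solve on the raw pore
voxels (no-flux at solid walls, half-cell Dirichlet faces) serves as the
independent oracle; at 64³ the network estimate tracks it within ~10–30%.
Because single-axis estimates of a finite sample are noisy at the ~10%
level, structure *rankings* use the average of the three axis values.
Absolute diffusivities depend on the unstated open-space diffusivity and
are reported only relative to D₀ = 1.

## Elastic homogenization

The cell problem for a periodic two-phase voxel structure is the
Lippmann–Schwinger equation ε = E − Γ⁰((C(x) − C⁰)ε) with an isotropic
reference C⁰ (arithmetic mean of the phase Lamé constants) and the
classical continuous-frequency Green operator, applied in Fourier space.
Two solvers: the classical fixed point (O(contrast) iterations) and a
conjugate-gradient Krylov solve of the same equation (O(√contrast)),
which is the default and makes the near-void pore contrast of 10⁻⁴
practical on one CPU. Six unit macroscopic strains give the 6×6 Voigt
matrix column by column (engineering-shear convention, tensor order 11,
22, 33, 23, 13, 12).

Numerical details that matter:

* **Nyquist planes.** The unpaired ±N/2 frequencies of even grids carry an
  arbitrary sign (fft axes use −N/2, the rfft axis +N/2), which would make
  the Green operator's cross terms convention-dependent and break exact
  equivariance under axis permutation. The operator is therefore zeroed on
  Nyquist planes (those modes keep their polarization uncorrected), and
  the equilibrium residual excludes them. With this treatment a 50/50
  laminate reproduces the closed form (Backus average) to machine
  precision, the result is independent of the reference medium to solver
  tolerance, and homogenizing an axis-permuted structure equals permuting
  the tensor exactly.
* The pore phase is a very compliant solid (contrast 10⁻⁴, configurable),
  not a true void, keeping the operator invertible.
* The solid is titanium-like (E = 110 GPa, ν = 0.3) — absolute GPa values
  depend on this choice; orderings and self-consistency do not.
* The solver tolerance (relative spectral equilibrium residual) defaults
  to 10⁻⁶; stiffness entries converge far faster than the residual, and
  10⁻⁴ changes them by < 10⁻⁵ GPa.

Directional stiffness surfaces rotate the 4th-rank tensor into a frame
whose first axis is the query direction (deterministic completion: the
helper axis is the coordinate axis of smallest |d| component). The default
surface is C′₁₁₁₁(d) — axial stiffness at fully constrained transverse
strain; a compliance mode returns 1/S′₁₁₁₁(d), the conventional uniaxial
Young's modulus. Both are even in d.

## Learned surrogates

Both networks are built on a small numpy engine whose convolutions are
exact circular (periodic) convolutions evaluated spectrally; circular
padding of a convolution is identical to periodically tiling the input and
cropping after convolving. Gradients are computed analytically in Fourier
space and verified against finite differences. A reflect-padding mode
exists solely as an ablation (it breaks shift equivariance by orders of
magnitude).

**Evolution surrogate** — encoder–decoder with skip connections: per level
a 3³ conv + tanh and 2× average pooling, mirrored by nearest-neighbor
upsampling and concatenation; a zero-initialized 1³ linear head predicts
the *increment* to the input (residual connection), and the output passes
a piecewise soft clamp that is exactly the identity on [−1.1, 1.1] and
saturates toward ±1.5. An untrained model is therefore the identity on
physical fields, and trained rollouts cannot escape the physical range.
Inputs must be divisible by 2^depth per axis; shift equivariance is exact
(float precision) for shifts divisible by that factor. Trained with MSE on
neighboring-save pairs, Adam, cosine learning-rate decay.

**Property surrogate** — conv/tanh/pool stages, global average pooling, a
small dense head to the nine orthotropic constants; predictions are
invariant to circular shifts divisible by the pooling factor. Trained with
MAE; labels are standardized per component on the training split (the MAE
subgradient has fixed magnitude, so unstandardized tens-of-GPa labels
train poorly) and predictions are reported in physical units.

**Scales.** The reference configuration mirrors the study design: 15
simulations at μ = −0.7 … 0.7, 100 neighboring-save pairs each (1500
pairs, 1200/300 split), depth 3 / base 16 channels, 100 epochs at batch
16; the property dataset uses 12 extractions per simulation at saves 9,
11, 14, 18, 23, 29, 36, 44, 53, 63, 74, 86 (21 600 entries at 1800
simulations, split 7/9 : 1/9 : 1/9 at the *simulation* level so
near-duplicate structures never straddle splits). The test suite runs a
desk-scale profile — 32³, 4 simulations, save stride 2 (the learned step
spans two solver saves), depth 2 / base 6, 8 epochs — chosen so the full
pipeline trains and rolls out inside a routine test run. At this scale the
one-step validation MSE plateaus near 10⁻²; the desk-scale acceptance
band is 2 × 10⁻², and full-scale error figures are only reachable with
the reference configuration. What desk-scale passing shows: the rollout
reproduces bicontinuous, 50%-porosity morphology whose 2-point statistics
track the physics run; it does not certify one-step accuracy at the
reference scale.

One-step training only; rollout error accumulates and is measured (via
rollout bicontinuity and S2 agreement), not corrected.

## Design applications

**Screening** is random search, faithful to the workflow it implements:
sample (μ, c, r) → generate → predict the nine constants → verify with the
FFT homogenizer when the prediction is within ε (default 0.05 GPa). The
acceptance metric is the maximum per-component absolute deviation (the
strictest simple reading; a mean-norm mode exists). A candidate is never
accepted on a surrogate prediction alone. With a stateless sampler
(draw k is a pure function of seed and index) screening runs are exactly
replayable.

**Gradient implants** start from a spatially graded noise mean and cut the
decomposed structure with a parametric mask (cylinder, hemispherical
shell, tapered stem). Two findings shape the defaults:

* A prescribed μ profile of amplitude O(0.2–0.7) over tens of voxels is
  itself a near-saturated unstable composition perturbation: given time,
  the dynamics amplify it into macroscopic segregation (dense plug,
  depleted halo, concentric rings) that replaces the designed smooth
  gradient. Gradient structures are therefore extracted early (default
  save 10), right after local decomposition completes and before the
  macro-mode restructures the profile.
* A metastable core (μ ≥ 0.6) stays uniform and dense — the intended
  dental-implant mechanism — but its boundary absorbs material from the
  adjacent decomposed ring (its chemical potential is below the two-phase
  value), producing a depletion halo of ~6–10 voxels. Zone checks are
  therefore placed away from transitions; with that placement, core
  porosity < 5% and rim porosity within 5 percentage points of the lever
  rule hold robustly. The measured porosity-ramp width still increases
  monotonically with the profile transition width, but compressed (2 vs 4
  voxels for transition widths 4 vs 16): uncompressed ramp control would
  need scale separation (implant ≫ feature size) beyond a 10²-voxel box.

## Synthetic data and scope of the tests

Every test input is generated by the package itself (seeded noise fields,
parametric geometries, GRF blobs); nothing is fitted to external data.
Passing tests therefore establish internal consistency of the models at
the stated scales — conservation laws, closed-form limits, independent
oracles, orderings, and counting identities — not agreement with any
physical measurement. Known limitations: model units (no dimensional
fidelity), isotropic surface energy only, solid-phase elasticity constants
are a configurable assumption, and absolute diffusivities are relative to
the open-space value.
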