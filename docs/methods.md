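# Methods

## Scope and model

`lidarpol` links two measurement domains of marine-particle depolarization:

* **Single scattering.** For a suspension measured at a near-backward angle
  with negligible multiple scattering, the particulate linear depolarization
  ratio δ_p and the 2,2-element of the normalized scattering (Mueller)
  matrix at π are equivalent descriptions:
  δ = (1 − M22)/(1 + M22) and M22 = (1 − δ)/(1 + δ). M22(π) = 1 means
  non-depolarizing (homogeneous spheres, molecular seawater scattering);
  smaller values mean stronger single-scattering depolarization.
* **Lidar measurement.** A lidar return from range z mixes single-scattering
  depolarization with depolarization accumulated by multiple near-forward
  scattering. The small-angle solution of the vector radiative-transfer
  equation gives the degree of linear polarization
  g(z) = M22(π)·exp(−2 φ b z), where b (1/m) is the total scattering
  coefficient and φ is a dimensionless depolarization factor that absorbs
  the near-forward Mueller-matrix shape and the instrument geometry. φ
  cannot be measured independently and is treated everywhere as a free
  fitting parameter. δ follows from g by the same bilinear map.

Bulk properties are composed from scattering components n = 1..m:

* M22(π) = Σ M22_n w_n / Σ w_n with w_n = χ_n·b_bn, where χ_n (sr) converts
  the hemispherical backscattering coefficient b_bn to backscatter at π.
  This identifies 2π·β(π) with Σ χ_n·b_bn so the combination is a convex
  average. The cited-literature convention (b_b = 2π·χ·β(π)) would instead
  imply weights b_bn/χ_n; the choice is isolated in `mix_m22`, a one-line
  change, and matters only when components have unequal χ (here 0.5 vs the
  seawater 0.68, a ≲2% reweighting of the seawater term).
* φ = Σ φ_n b_n / b, with b = Σ b_n.

Two water parameterizations are provided. *Single-particle*: components
(particles, seawater) with free (M22_p, φ_p). *Two-particle*: (acid-labile
calcite, acid-stable particles, seawater) with the labile M22 fixed at the
laboratory coccolith-calcite value 0.78, the labile scattering coefficient
reconstructed as b′ = b_b′/0.025 (an assumed coccolith backscattering
ratio), b_acid = b_p − b′, and free (M22_acid, φ′, φ_acid). With b_b′ = 0,
or with identical labile/acid parameters, the two-particle model collapses
exactly to the single-particle model.

## Fixed constants (defaults)

| constant | default | meaning |
|---|---|---|
| χ_p = χ′ = χ_acid | 0.5 sr | particulate backscatter-to-π conversion |
| χ_sw | 0.68 sr | seawater backscatter-to-π conversion |
| M22_sw, φ_sw | 1, 0 | molecular scattering is non-depolarizing |
| M22′ (labile) | 0.78 | laboratory coccolith-calcite value |
| b_b′/b′ | 0.025 | assumed coccolith backscattering ratio |
| z | 6.5 m | along-beam in-water range of the shipboard lidar |
| b_sw, b_bsw | 1.2e−3, 9e−4 1/m | fallback pure-seawater coefficients at 532 nm |

b_sw/b_bsw are configuration constants: computing them from temperature and
salinity is out of scope, and field CSV rows carry their own values. The
range is the along-beam (slant) distance; no geometric correction is applied
for off-nadir pointing.

## Laboratory reduction

Darks are subtracted from every recorded signal, then the blank from each
addition; each addition yields one δ value and δ_p is their unweighted mean
(the weighting of per-addition values is not prescribed by any constraint we
know of; unweighted is the simplest defensible choice). The 95% CI is the
two-sided Student-t interval treating additions as independent replicates.
Additions whose co-polarized excess over the blank is ≤ 0 are dropped with a
warning; an all-dropped series is an error. The reduction is invariant to
any common positive gain applied after dark subtraction.

Acid partitioning assumes the bulk M22(π) is the scattered-flux-weighted
average of labile and stable components; the labile flux fraction comes from
the ratio of signal-vs-stock-concentration slopes before and after
acidification (1 − slope_acid/slope_bulk).

The particle-mixing fit uses the signal-weighted two-component form
M22(v) = (w0·M22_base + k·v·M22_add)/(w0 + k·v), fit over (M22_add, k) by
`scipy.optimize.least_squares` with M22_add initialized at the last observed
bulk value and k at the first addition's signal increment per mL. M22_add is
bounded in (0, 2] so a physically impossible fit (> 1) surfaces as a warning
rather than a silent clip. When the added suspension equals the base, k is
unidentifiable; the initialization already has zero residual, so the fit
returns M22_base deterministically.

Equivalent spherical diameters use Cauchy's theorem (mean projected area =
surface area / 4): spheres map to their own diameter; a cylinder (d, h)
gives ESD = √(d·h + d²/2), continuous down to the coccolith disk limit
(h = 0.07 μm). For right-skewed size distributions the median ESD is the
appropriate summary.

## Inversion

The free parameters are fit by exhaustive evaluation on a regular grid
(defaults: 0.01 steps on M22 axes over [0.5, 1], 0.005 steps on φ axes over
[0, 0.4]; both configurable), scored with
RMSE = √(Σ(δᵢ − δ̂ᵢ)²/(N − k)), k defaulting to the number of free
parameters (2 single, 3 two-particle). No gradient or stochastic optimizer
is used: the sensitivity surface is itself the product of interest. Exact
RMSE ties — flat ridges, degenerate data — are broken deterministically
(smallest φ first, in axis order, then largest M22), so repeated runs return
bit-identical surfaces and stable optima. `ridge_profile` returns the
conditional optimum over the remaining axes for each value of one axis; on
single-particle data the conditional-optimum M22 is nondecreasing in φ
(increased multiple-scattering depolarization must be compensated by weaker
single-scattering depolarization), the compensation structure that elongates
iso-RMSE contours.

The grid kernel is vectorized over observations and nodes but uses the same
component-mixing formulas as the scalar forward model; the test suite
re-scores random nodes through the scalar path and requires agreement to
1e−12. Model comparison (`compare_models`) reports the optimum-RMSE
difference (single minus two). Note the degrees-of-freedom correction makes
RMSE non-nested at equal residuals (k = 3 vs 2); nesting statements are
therefore made at a common k.

## Synthetic data

The generators define the conditions under which the pipeline is tested:

* **Lab series** — blank-corrected co-polarized excess grows linearly with
  addition number; the cross-polarized excess is `true_delta` times it; both
  carry independent multiplicative Gaussian noise (relative sd
  `noise_sd`). Per-addition δ is concentration-independent by construction:
  the simulated bench is free of multiple scattering, matching the regime
  the standard-addition protocol verifies.
* **Mixing series** — bulk M22 follows the two-component mixing law with
  optional additive noise, converted back to signal pairs.
* **Field series** — b_p log-uniform over [0.05, 1.5] 1/m, b_bp/b_p uniform
  over [0.005, 0.03], b_b′/b_bp uniform over [0, 0.8]; draws violating
  b′ = b_b′/0.025 ≤ b_p are resampled (the constraint can bind at high
  labile fractions). δ_obs is the forward model at the true parameters plus
  Gaussian noise, truncated to [0, 1) by resampling. These ranges emulate a
  coccolithophore-bloom-to-coastal transect; they are testing defaults, not
  claims about any particular cruise.

All generators are pure functions of (config, seed), via
`numpy.random.default_rng`.

What the synthetic data do **not** emulate: instrument-specific noise
spectra, spatial autocorrelation along a cruise track, covariation between
particle concentration and composition, χ variability, or any mismatch
between the forward model and the real radiative transfer. Passing recovery
tests therefore demonstrate the correctness and invertibility of the
implementation under the model's own assumptions, not the fidelity of the
model to field data.

## Problem sizes and numerics

The recovery tests use 200–500 synthetic observations and the default
51 × 81 single-particle grid (multi-seed studies use 20 seeds); two-particle
grids in tests use coarser steps since the full default grid
(51 × 81 × 81) is reserved for interactive use. The two-particle kernel
chunks over the M22 axis to bound memory at ~tens of MB. Noise-free
parameter recovery is exact when the truth lies on grid nodes (truths in
tests are taken from the axis values themselves to avoid re-quantization);
with δ-noise sd 0.005 and n = 500, recovered single-particle parameters lie
within one grid step of truth in ≥ 95% of seeds.

Degenerate inputs are handled explicitly: additions indistinguishable from
blank are dropped (warning), an inconsistent acid partition returns its
out-of-range value with a warning, IOP rows with b′ > b_p or b_b′ > b_bp are
rejected with row-numbered errors, and N ≤ k observations are refused by the
RMSE.

## Known limitations

* Measurements at 178.5° are identified with 180° values; off-diagonal
  Mueller elements and near-backward M22(θ) variation are neglected.
* φ is purely empirical; no receiver-geometry model is attempted.
* The χ-weight convention above is a genuine open choice; both conventions
  are defensible and differ slightly in the seawater weighting.
* No uncertainty quantification beyond the RMSE surface (no bootstrap CIs);
  the regression of modeled vs measured δ is reported as a diagnostic only.
* No multiple-scattering correction of laboratory data; the lab reduction
  assumes the standard-addition check holds.
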