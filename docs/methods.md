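# Methods

This note documents the models, estimation procedures, numerical choices and
known limitations of `axomyelin`. Everything quantitative stated here is
computed by the test suite or the example scripts.

## Diffusion forward model

The powder-averaged (spherical-mean) signal of fixed white matter is modeled
with three compartments:

    S(b) = f_ia · S_ia(b; D∥ia, d_a) + f_ec · S_ec(b; D∥ec, D⊥ec) + f_dot

with f_ia + f_ec + f_dot = 1, so S(0) = 1 after normalization by the mean
b = 0 image. The intra-axonal compartment is a bundle of impermeable
parallel cylinders of diameter index d_a: parallel diffusion is free at the
intrinsic diffusivity D0 and perpendicular attenuation follows the Gaussian
phase distribution (GPD) approximation, a series over roots of J₁′. Because
the GPD log-attenuation is quadratic in the gradient strength, the cylinder
behaves exactly like an axisymmetric Gaussian compartment with an effective
perpendicular diffusivity D⊥eff(d_a, δ, Δ, D0) = −ln A / b; the closed-form
spherical mean

    exp(−b·D⊥) · √π · erf(√(b(D∥−D⊥))) / (2·√(b(D∥−D⊥)))

therefore applies to both anisotropic compartments (the tests verify this
against direct orientation integration to 1e−4 and sphere quadrature to
1e−8). The extra-cellular space is hindered and anisotropic with
D∥ec = D∥ia = D0 and D⊥ec expressed as a fraction of D∥ec. The dot
compartment is immobile water producing a non-decaying floor, substantial in
fixed tissue. The model's parameter vector is
θ = (f_ia, f_dot, d_a, D∥ia, D⊥ec/D∥ec, σ).

Units everywhere: ms, µm, mT/m, b in ms/µm², diffusivities in µm²/ms.

Numerical choices:

* GPD series truncated at 14 roots; the truncation moves the attenuation by
  less than 5e−9 against a 5× root count over d_a ∈ [0.1, 10] µm at the
  default timings (asserted in tests). The convergence check is available at
  call time (`check_convergence=True`).
* The erf spherical-mean formula switches to the Taylor branch
  1 − x/3 + x²/10 when x = b(D∥−D⊥) < 1e−6 to avoid 0/0.
* Shell grouping for measured .bval tables: values within 5% (relative)
  share a shell; b < 0.05 ms/µm² counts as b = 0.
* The default acquisition is the 8-shell ex vivo protocol
  (b = 1, 2.5, 5, 7.5, 11.1, 18.1, 25, 43 ms/µm²; 12 directions per shell up
  to b = 7.5 and 32 from 11.1; δ = 11 ms, Δ = 15 ms; one b = 0 per shell).
  Per-shell gradient strengths are derived from the b-values through
  b = (γδG)²(Δ−δ/3); the top shell lands at the 660 mT/m hardware limit.
  All shells are assumed to share one (δ, Δ) pair, and the protocol
  validates stored b-values against their gradients to 1%.

## A near-exact degeneracy, and what is actually identifiable

At these 8 shells the model carries a near-exact degeneracy that shapes
everything downstream: a thin-cylinder state with no dot fraction can
reproduce the signal of a thicker cylinder plus dot floor almost perfectly.
Concretely, (f_ia=0.8, f_dot=0.1, d_a=4.0, D0=0.45, ec=0.4) and
(f_ia≈0.71, f_dot≈0.0, d_a≈1.1, D0≈0.454, ec≈0.14) agree to ~1e−4 RMS on
the normalized spherical means — far below any realistic noise floor and
below the lower bound of the σ prior. The degenerate set forms a connected
ridge in parameter space along which d_a, f_dot, f_ia and the extra-cellular
perpendicular fraction co-vary.

Consequences:

* Single-voxel, single-realization estimates of d_a and f_dot are ridge
  averages, not point identifications. Ensemble statements (means and
  medians over noise realizations, as in the recovery study) are the
  meaningful accuracy claims, and those are what the tests assert.
* D∥ia is well identified (recovered within a few percent in every regime
  we measured, noiseless or noisy).
* A second, exact exchange degeneracy exists because both anisotropic
  compartments are axisymmetric Gaussians sharing D∥: their labels can swap.
  The sampler's prior support therefore includes the ordering constraint
  D⊥ia(d_a) ≤ D⊥ec (the intra-axonal compartment is the more restricted
  one), configurable via `PriorSet(order_perp_diffusivities=...)`. For the
  macaque ground-truth set this caps identifiable d_a at ≈8.8 µm, outside
  the 2–8 µm sensitivity range of the acquisition.

## Posterior sampling

Per voxel, the posterior of θ under uniform priors
(d_a ∈ [0.1, 10] µm, D∥ia ∈ [0.01, 0.9] µm²/ms, ec fraction ∈ [0, 1],
σ ∈ [0.001, 0.1], fractions on the simplex f_ia + f_dot ≤ 1) and a Gaussian
likelihood over the n = 8 shell means is sampled by random-walk
Metropolis–Hastings: 20,000 burn-in iterations, then one retained sample per
100 iterations until 500 samples; estimates are posterior means. Two stages
are run: stage 1 samples everything; stage 2 pins D∥ia and the
extra-cellular perpendicular fraction at their stage-1 posterior means and
re-samples f_ia, d_a, f_dot and σ, roughly halving the posterior SDs of
f_ia and d_a at the same likelihood (asserted in tests). A comparison mode
pins D∥ia to a literature constant (0.6 µm²/ms ex vivo, 1.7 in vivo)
instead of estimating it.

Design choices that the sampler's behavior depends on:

* **Updates**: one parameter per iteration on a deterministic cycle through
  the free parameters, with Gaussian proposals (SDs: 0.02 for fractions and
  diffusivity-like parameters, 0.2 µm for d_a, 0.002 for σ; configurable).
  Out-of-support proposals — including violations of the simplex and
  ordering constraints — are rejected outright.
* **Initialization**: deterministic coarse-grid scan (argmin of the sum of
  squared residuals over a fixed parameter grid, σ started at the residual
  RMS). A prior-midpoint start is available but locks chains into
  init-dependent basins of this multimodal posterior.
* **Annealed burn-in**: the likelihood of the structural parameters is
  tempered with T decaying geometrically from 10 to 1 over the first 60% of
  the burn-in, so chains can cross between the near-degenerate basins early
  and settle by mass. σ updates are never tempered: σ keeps tracking the
  current misfit, which prevents the noise level from diffusing while the
  surface is flattened. Disable with `anneal_t0=1.0` — advisable for
  essentially noiseless data, where the annealing phase only injects ridge
  diffusion.
* **Vectorization and reproducibility**: chains for a whole batch of voxels
  advance together as independent samplers; each chain consumes an RNG
  substream keyed as (seed, stage, voxel index), so results are bit-identical
  across runs and independent of batch composition, mask shape and voxel
  order (asserted in tests).

Measured accuracy under the simulation design (noise σ = 1/SNR added to the
spherical means, 60 realizations, macaque preset, GT d_a = 4 µm, SNR 150):
mean posterior means recover f_ia within ~8%, f_dot within ~0.03 absolute,
D∥ia within ~4%; d_a carries a ~15–20% downward bias from ridge averaging.
Median estimated d_a orders the ground-truth diameters 2–8 µm, and the mean
absolute diameter error over that grid grows when SNR drops to 50. At the
sensitivity floor (GT 2–3 µm) estimates compress toward ~2 µm and per-cell
bias comparisons between SNR levels are not monotone — at low SNR the
posterior shrinks toward the prior middle, which can land *closer* to a
small-diameter truth than the high-SNR ridge estimate.

## T2 spectrum and myelin water fraction

Multi-echo spin-echo (CPMG) trains are decomposed on a 100-point log-spaced
T2 grid (presets: 4–200 ms macaque, 6–250 ms human) by non-negative least
squares with Tikhonov regularization, ‖Ax−s‖² + µ‖x‖², x ≥ 0. The decay
basis is computed by the extended phase graph (EPG) recursion, which tracks
transverse and longitudinal configuration orders through the echo train and
models the stimulated-echo pathways of imperfect refocusing pulses; at a
180° flip the basis reduces exactly to exp(−TE/T2) (asserted to 1e−10, and
the recursion matches a brute-force spin-isochromat simulation to machine
precision at all angles). T1 enters only through stimulated-echo pathways
and is fixed at 1000 ms (insensitive at these echo times; configurable).

* **Flip-angle calibration**: per voxel, grid search 120°–180° in 1° steps
  minimizing the unregularized misfit, refined once by a local quadratic
  fit through the minimum.
* **Regularization**: µ is chosen by bisection so the regularized squared
  misfit is 1.02× the unregularized minimum (χ²-inflation criterion;
  factor configurable). Noiseless, exactly representable trains get µ = 0.
* **MWF**: the fraction of spectral amplitude with T2 strictly inside the
  myelin window — (8, 15) ms macaque, (5, 30) ms human, open intervals;
  window edges outside the grid are clipped to it (the human window's 5 ms
  edge lies below its 6 ms grid minimum).

Limitation, quantified in the tests: at finite SNR the position of the
myelin peak jitters by ~0.1 decades in log-T2, so part of its mass crosses
the 8 ms window edge and windowed MWF is biased low — at SNR 100 a
two-pool phantom with 30% myelin water at T2 = 10 ms yields block means
around 0.15. The *total* short-T2 mass is recovered accurately (~0.31);
the loss is pure window truncation. MWF should therefore be read as a
relative myelination index whose scale depends on SNR, which is also why
voxels with MWF < 0.05 are excluded from correlation analyses.

## Aggregate g-ratio

From aligned MWF and f_ia maps:

    MVF = 0.859·MWF / (0.384·MWF + 0.475)       (ex vivo calibration)
    AVF = (1 − MVF) · f_ia
    g   = (1 + MVF/AVF)^(−1/2)

g ∈ (0, 1], equals 1 iff MVF = 0, is monotone non-increasing in MWF at
fixed f_ia, and MVF + AVF ≤ 1 always (property-tested). Voxels with
AVF = 0 and MVF > 0 are undefined and returned as NaN with a warning. An
optional flag applies the MWF < 0.05 exclusion before the map computation.

## Synthetic data and the recovery study

The generator modules define the study conditions:

* `simulate_spherical_means` adds Gaussian noise of SD 1/SNR directly to
  the noiseless spherical means (b = 0 amplitude 1). This is the default
  noise path of the recovery study; the alternative — per-direction noise
  followed by powder averaging, which reduces the shell-mean noise by √N —
  is provided by the DWI phantom path. Which of the two a real analysis
  sees depends on where in the pipeline noise is characterized; both are
  available and the default is stated here so results are interpretable.
* Tissue presets: macaque (f_ia = 0.8, f_dot = 0.1, D∥ia = 0.45 µm²/ms,
  D⊥ec = 0.4·D∥ia; SNR levels 150/100/50) and human (f_ia = 0.6,
  f_dot = 0.3, D∥ia = 0.65 µm²/ms, D⊥ec = 0.4·D∥ia; SNR levels 150/100/75);
  ground-truth diameters 1–10 µm in 1 µm steps; 100 realizations per cell
  by default. The test suite runs 60 realizations over d_a 2–8 µm at
  SNR 150/50 to stay within its runtime budget; tolerances follow the
  stated ×1.5 widening for reduced realization counts.
* The 3-D phantoms (`generate_dwi_phantom`, `generate_multiecho_phantom`)
  emulate the acquisition: directional signals from the axisymmetric
  compartment model at a fixed per-voxel fiber orientation, direction sets
  of 12/32 per shell from electrostatic repulsion, Gaussian or Rician
  per-measurement noise; two-pool echo trains (myelin T2 = 10 ms,
  intra/extra-cellular T2 = 60 ms) with Gaussian noise. Everything is
  deterministic under a seed and ships with its ground-truth maps.

What the phantoms do **not** emulate — hence what passing tests do not show
about real data: fiber orientation dispersion and crossings, exchange
between pools, compartmental T2 differences in the diffusion signal,
time-dependent extra-cellular diffusion, axonal undulation and caliber
variation, spatially correlated noise, scanner drift, eddy currents, B1/B0
field structure beyond a single per-voxel flip angle, and partial-volume
mixtures at tissue boundaries.

## Correlation analysis

Pairwise Pearson correlations across voxels that are finite in every map,
inside the mask, and (by default) have MWF ≥ 0.05; two-sided p-values with
`**` marking p < 0.01 and `*` p < 0.05, plus a long-format table of the
included voxel values for density plots. Fewer than 3 included voxels is an
error. Note that estimation noise is correlated between parameters along
the degeneracy ridge (d_a and f_ia co-move positively along it), so
map-level correlations mix the tissue relation with an estimation artifact
of the opposite or same sign; the end-to-end tests use construction
phantoms strong enough for the tissue relation to dominate.

## Workflow and provenance

The CLI (`axomyelin powder-average | fit-smt | fit-mwf | gratio |
correlate | simulate`) is a thin layer over the library. Every stage writes
a provenance JSON (arguments, seed, configuration hash, package version)
next to its outputs. NIfTI affines pass through untouched; registration is
out of scope and g-ratio inputs are assumed aligned. All randomness flows
from one top-level seed through named substreams.
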