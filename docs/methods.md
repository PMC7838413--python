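# Methods

`octbayes` implements a Bayesian treatment of voxelwise (depth-resolved)
attenuation-coefficient recovery from optical coherence tomography (OCT)
intensity scans corrupted by fully developed speckle. This note records the
model, the numerical choices, and what the shipped simulations do and do not
demonstrate.

## Signal model

The mean (speckle-free) OCT signal of a weakly absorbing, single-scattering
medium, already calibrated for the confocal point-spread function and
spectral roll-off, is modelled per A-line as

    <I_N> = I_inc * beta_NA * mu(N) * exp( -2 * sum_{i=1}^{N} mu(i) * dz ),

with `mu(N)` the attenuation coefficient (mm^-1) of the N-th depth pixel,
`dz` the axial pitch (mm), `I_inc` the incident intensity (arbitrary units)
and `beta_NA` the fraction of attenuated light back-scattered into the
detection aperture, assumed constant through the medium. Arrays are stored
0-based, but the cumulative sum always includes the voxel's own attenuation
(array indices `0..N-1` inclusive for the 1-based formula index `N`); this
convention is enforced in one place (`speckle_forward.mean_signal`) to avoid
off-by-one drift. Depths are geometric millimetres; no refractive-index path
scaling is applied.

Under fully developed speckle the measured amplitude is Rayleigh and the
intensity exponential, so a speckled scan is drawn voxel-by-voxel as
`I_N ~ Exponential(mean = <I_N>)`. Voxels are sampled independently — no
lateral or axial speckle correlation is simulated, which matches the
fully-developed assumption but means the simulator is optimistic for
scans with lateral pitch finer than a speckle grain. Per-A-line RNG
streams are spawned deterministically from one root seed, so B-scans are
reproducible regardless of how the lateral dimension is traversed.

## Depth-resolved estimation

The voxelwise estimator is the ratio form

    mu_hat(N) = I_N / ( sum_{i=N+1}^{M} 2 dz I_i ),

optionally with the Liu tail completion, which adds `I_M / mu_ref` to every
denominator to stand in for the unmeasured series beyond the imaging depth.
By default `mu_ref` is the layer mean of a first-pass uncorrected estimate,
making the correction self-contained; callers may supply their own. The
deepest 30% of rows are discarded by default (`truncation_fraction = 0.30`,
a by-inspection choice exposed as a parameter); the deepest row (empty sum)
is always masked, and zero denominators at otherwise admissible voxels are
masked with a warning rather than raising, so whole-B-scan processing never
aborts.

Two systematic properties of this estimator matter for interpreting every
downstream number:

1. **Discretization fixed point.** On the noiseless homogeneous signal the
   estimator converges (deep in the scan) not to `mu` but to
   `(e^{2 mu dz} - 1) / (2 dz)`, a relative offset of about `mu dz`
   (+1.4% at mu = 2 mm^-1, dz = 6.8 um). This is the exact discrete sum
   replacing the continuum integral and is verified to 1e-10 in the tests.
2. **Denominator Jensen term.** Under speckle,
   `E[1/D_N] = (1 + C_v^2 + O(C_v^3)) / <D_N>`, so the mean of `mu_hat`
   carries a further `+C_v^2` relative offset (+1.4% at the default
   geometry). Consequently the ML exponential rate fitted to pooled
   estimates of the default homogeneous B-scan sits near 2.06 for a true
   coefficient of 2.00; the acceptance script reports the computed value.

The denominator `D_N` is hypoexponential; its analytic mean and variance
(`sum 2dz <I_i>` and `sum (2dz)^2 <I_i>^2`) give a per-depth coefficient of
variation that is provably below 1 and is ~0.117 over the admissible depths
of the default geometry. The smallness of `C_v` is what licenses treating
the denominator as constant and hence the exponential law below.

## Likelihood, prior, posterior

To leading order in `C_v`, a DR estimate is exponentially distributed around
the true coefficient:

    P(mu_hat | mu) = (1/mu) exp(-mu_hat / mu),

and k independent co-registered estimates multiply. The exponential law is
exact only at leading order: relative errors of order `C_v^2` plus the
discretization offset (0.7–5.5% over mu in 0.5–4 mm^-1 at the default
pitch) are real and detectable. The distributional tests therefore (a) use
domains spanning at least eight attenuation lengths, so the truncated series
has converged at every admissible depth (at 3.4 mm depth and mu = 0.5 mm^-1
the deepest admissible estimate would otherwise be biased by +56%), and
(b) apply the Kolmogorov–Smirnov test to a seeded subsample of 1400 pooled
estimates — beyond roughly `(1.63 e / delta)^2` samples the KS test starts
resolving the known O(C_v^2) mean offset `delta` rather than distributional
shape, which is the property under test.

The prior comes from a particle-counting argument: for a dilute suspension
of identical scatterers the voxel occupancy is Poisson, hence approximately
Gaussian at large counts, giving

    P(mu) = Normal(mean = <mu>, variance = zeta * <mu>),   zeta = sigma_scat / V_voxel,

with `<mu>` the layer mean (in practice: the mean of the truncated DR
estimates of the scan) and `zeta` in mm^-1. The Gaussian is used as printed,
not renormalized to the positive axis; the mass below zero is asserted
negligible (< 1e-3) and a warning is emitted otherwise. Ground-truth maps
are sampled from the same Gaussian truncated at zero.

The posterior for one voxel is the normalized product of likelihood and
prior. Numerics:

* **Grid.** 4096 log-spaced points on `[mu_lo, mu_hi]`,
  `mu_lo = max(1e-6, <mu> * 1e-4)`,
  `mu_hi = <mu> + 10 sqrt(zeta <mu>) + max(mu_hat)`. The log spacing
  resolves the near-origin likelihood spike that appears for small
  estimates; the ceiling covers the prior bulk and the likelihood scale.
* **Evaluation.** Log-domain with per-voxel max-subtraction before
  exponentiation; trapezoidal normalization (checked to 1e-6).
* **Whole-map estimation.** `estimate_map` vectorizes voxels in chunks and
  integrates in `u = log mu`, where each voxel's grid is uniform and the
  Jacobian cancels the `1/mu` likelihood prefactor; this is algebraically
  the same quadrature at ~3x the speed. It agrees with the one-voxel
  reference path to 1e-6 (tested) and with a 1e6-sample importance-sampling
  oracle within Monte-Carlo error.
* **Degenerate input.** `mu_hat = 0` exactly makes the likelihood `1/mu`
  non-integrable against the prior near the origin; the posterior is then
  computed on the finite grid with a warning that the result depends on
  `mu_lo`.
* **Point estimates.** The default estimator is the posterior mean
  (trapezoid of `mu * density`). The MaP (grid argmax refined by a
  quadratic through the three bracketing points, with a warning when the
  argmax touches a grid boundary) is retained for comparison only: for
  sufficiently small `mu_hat` the posterior is bimodal and the MaP is a
  poor summary. Note the inequality `MaP < posterior mean` is *not*
  guaranteed for every bimodal case: at `<mu> = 0.4`, `zeta = 6.87e-2`,
  `mu_hat = 0.015` the global maximum is the bulk peak (0.317) and the
  mean (0.315) sits marginally below it, because the ~5% of mass under the
  origin peak pulls the mean down; only for smaller estimates does the
  origin peak take over the argmax. When the prior is much narrower than a
  quadrature cell (zeta below ~1e-6 at unit layer mean), posterior
  summaries are pinned to within one cell of the layer mean — tests for
  the point-mass limit use one-cell tolerances for this reason.

## Phantom physics

For bead-suspension phantoms the package computes the single-bead Mie
scattering cross-section (Bohren & Huffman series, logarithmic derivative by
downward recurrence; validated against Wiscombe's reference efficiencies and
the Rayleigh closed form), the number density implied by the bead volume
fraction, their product — the bulk attenuation under the independent-
scattering (dilute) approximation, with no dependent-scattering correction,
which at volume fractions near 0.08 may overestimate the effective
attenuation — and `zeta = sigma_scat / V_voxel`.

Two host-medium indices enter: the *phase* index sets the wavelength in the
medium (size parameter `x = pi d n_phase / lambda_vac`), while the bead
contrast uses the *group* index, `m = n_particle / n_medium_group`,
matching how the contrast of water-based silica phantoms is specified at
1.3 um. For the reference silica phantom (d = 0.47 um, n = 1.425, water:
1.32 phase / 1.34 group, lambda = 1309 nm) this yields
sigma_scat = 1.91e-9 mm^2; using the phase index for the contrast as well
would give 3.0e-9 mm^2. Both indices are explicit fields of
`SphereSuspension` so either convention is reproducible.

## Shipped experiments and problem sizes

* **Homogeneous-scan statistics** (`reproduce_fig4`): 500 depths x 1000
  A-lines at mu = 2.00 mm^-1, beta_NA = 0.3, I_inc = 1e7, dz = 0.0068 mm,
  dx = 0.022 mm; reports the ML exponential rate (closed-form MLE = sample
  mean; histograms are for plotting only), the KS statistic, and the
  analytic per-depth `C_v`. The lateral extent is a package default chosen
  to match the 1000-A-line phantom B-scans the geometry emulates.
* **Prior-sampled recovery** (`reproduce_fig5`): truth drawn from the
  prior, speckled, DR-estimated; the posterior-mean map is computed with
  the layer mean taken from the truncated DR estimates (the truth's mean is
  never given to the estimator) and `zeta` from config. The default `zeta`
  derives from a bead cross-section of 1e-6 mm^2 and the scan's own voxel
  (`dx * dx * dz`), ~0.368 mm^-1. The packaged validation runs 50
  replicates of a scaled geometry (1.7 mm deep x 25 A-lines), a problem
  size chosen so the full suite runs comfortably on one CPU; per-replicate
  error contrasts at full scale behave identically because voxels are
  independent.
* **Error sweep** (`reproduce_fig6`): one 2000-depth A-scan per grid point
  over `<mu>` in {0.5, 1, 2, 4} mm^-1 and `zeta` in {1e-3, 1e-2, 1e-1}
  mm^-1 (sweep ranges are package defaults), 30% truncation leaving 1400
  pixels; reports the mean per-pixel L2 error (mean absolute deviation,
  i.e. the per-pixel L2 norm averaged over pixels) for the DR and
  posterior-mean maps. The DR error is approximately flat in `zeta` (which
  enters only the prior), while the posterior-mean error grows with the
  prior width, as expected.

All drivers are deterministic given (config, root seed); replicate seeds are
spawned from the root via `numpy.random.SeedSequence`, and reports embed the
config hash, seeds and package version.

## Known limitations

* Confocal PSF, spectral roll-off, multiple scattering and absorption are
  not modelled; inputs are assumed calibrated, single-scattered and
  scattering-dominated.
* The exponential likelihood is leading-order: pooled DR estimates carry the
  +`mu dz` discretization and +`C_v^2` Jensen offsets described above, so
  pooled-rate agreement with the true coefficient is ~3% at the default
  geometry, not exact.
* `zeta` must be supplied (from phantom physics or config); empirical-Bayes
  estimation of the prior width from data is out of scope.
* No spatial regularization: voxels are independent in both the likelihood
  and the prior, so the posterior-mean map trades speckle variance for bias
  toward the layer mean rather than exploiting spatial structure.
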