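# octbayes

Bayesian voxelwise recovery of OCT attenuation coefficients under speckle.

Optical coherence tomography (OCT) measures depth-resolved backscattered
intensity; the exponential decay rate of that signal — the attenuation
coefficient μ_oct (mm⁻¹) — is a quantitative tissue marker. The
depth-resolved (DR, Vermeer-type) estimator recovers it voxel by voxel as

    μ̂(N) = I_N / Σ_{i=N+1..M} 2Δz · I_i ,

optionally completing the unmeasured tail with the Liu correction I_M/μ_ref.
But OCT intensities fluctuate voxel-to-voxel under fully developed speckle
(exponentially distributed intensity), and those fluctuations pass straight
into μ̂: for a homogeneous medium the voxelwise estimates are themselves
approximately exponentially distributed around the true coefficient —
a ~100% coefficient of variation per voxel.

`octbayes` treats this properly as an inference problem. It combines

* the speckle-derived likelihood  P(μ̂ | μ) = (1/μ) e^(−μ̂/μ)
  (and its k-scan product form),
* a physics-based Gaussian prior  μ ~ N(⟨μ⟩, ζ⟨μ⟩) with ζ = σ_scat/V_voxel
  from a Poisson particle-counting argument (σ_scat via Mie theory for bead
  phantoms),

into a normalized per-voxel posterior, and reports its **mean** as the point
estimate — the posterior can be bimodal for small μ̂, which makes the MaP
unstable (it is provided for comparison). The package is aimed at OCT
methods researchers who want calibrated voxelwise attenuation estimates with
uncertainty, and at anyone validating speckle statistics of DR attenuation
pipelines in simulation.

## What's in the box

| module | contents |
|---|---|
| `octbayes.speckle_forward` | mean-signal model, speckled-scan sampler, prior-sampled truth maps |
| `octbayes.dr_recovery` | DR estimator, Liu tail completion, depth truncation, hypoexponential denominator statistics (C_v) |
| `octbayes.bayes_inference` | likelihood, prior, normalized posterior, posterior mean/MaP/variance, whole-map estimation |
| `octbayes.phantom_physics` | Mie cross-sections, bead number density, bulk attenuation, ζ from voxel geometry |
| `octbayes.cli_workflows` | TOML/JSON configs, `octbayes` CLI, seeded experiment drivers, lateral-averaging baseline |
| `octbayes.io` | float32 TIFF + JSON-sidecar images, CSV tables |

## Worked example

Ground truth sampled from the prior, speckled scan simulated, then both
estimators compared against the truth (the truth's layer mean is *not* given
to the estimator — it is re-estimated from the truncated DR map, as it would
be with real data):

```python
import numpy as np
from octbayes import (AcquisitionGeometry, PriorSpec, dr_estimate, estimate_map,
                      layer_mean, mean_signal, sample_prior_map, speckle_sample)

geo = AcquisitionGeometry(axial_pitch=0.0068, lateral_pitch=0.022,
                          depth_extent=3.4, incident_intensity=1e7,
                          backscatter_fraction=0.3)
truth = sample_prior_map(PriorSpec(layer_mean=2.0, zeta=5e-2), geo,
                         seed=1, n_lateral=100)
scan = speckle_sample(mean_signal(truth), seed=2)

dr = dr_estimate(scan, truncation_fraction=0.30)      # deepest 30% masked
prior = PriorSpec(layer_mean(dr), zeta=5e-2)
recon = estimate_map(dr, prior)                       # posterior-mean map

mask = dr.admissible_mask
err_dr = np.abs(dr.estimates[mask] - truth.values[mask]).mean()
err_post = np.abs(recon.values[mask] - truth.values[mask]).mean()
print(f"layer mean of DR estimates: {prior.layer_mean:.3f} mm^-1")
print(f"mean |error|, raw DR map:        {err_dr:.3f} mm^-1")
print(f"mean |error|, posterior-mean map: {err_post:.3f} mm^-1")
```

Output:

```
layer mean of DR estimates: 2.066 mm^-1
mean |error|, raw DR map:        1.510 mm^-1
mean |error|, posterior-mean map: 0.255 mm^-1
```

The raw DR map is wrong by ~75% of the true value per voxel (speckle passes
through the ratio essentially unattenuated); the posterior mean cuts that by
a factor of ~6 by pulling implausible voxel values toward the layer mean, by
an amount set by the physically derived prior width ζ.

The same pieces are available from the shell. A single-voxel posterior for a
DR estimate of 1.3 mm⁻¹ in a layer with ⟨μ⟩ = 0.4 mm⁻¹, ζ = 6.87×10⁻² mm⁻¹:

```
$ octbayes posterior --mu-hat 1.3 --layer-mean 0.4 --zeta 0.0687
posterior_mean: 0.5125 mm^-1
posterior_map:  0.491817 mm^-1
posterior_var:  0.0172099 mm^-2
```

The observation 1.3 is over twice the layer mean, but the posterior settles
near 0.51: a single speckled estimate carries little evidence against the
prior. Other subcommands: `octbayes simulate | dr | phantom-props |
baseline | reproduce {fig4,fig5,fig6}` (see `--help`; configs are TOML or
JSON, images are float32 TIFF with JSON sidecars).

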