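"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from scipy import stats

from octbayes import AcquisitionGeometry, PriorSpec

# property tests must behave identically on every run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fig4_geometry() -> AcquisitionGeometry:
    """Homogeneous-simulation geometry: 3.4 mm deep at 6.8 um pitch."""
    return AcquisitionGeometry(
        axial_pitch=0.0068,
        lateral_pitch=0.022,
        depth_extent=3.4,
        incident_intensity=1.0e7,
        backscatter_fraction=0.3,
    )


@pytest.fixture(scope="session")
def small_geometry() -> AcquisitionGeometry:
    return AcquisitionGeometry(
        axial_pitch=0.01,
        lateral_pitch=0.02,
        depth_extent=0.6,
        incident_intensity=1.0e6,
        backscatter_fraction=0.5,
    )


def importance_sampling_moments(
    mu_hats, prior: PriorSpec, n_samples: int, seed: int
) -> dict:
    """Brute-force posterior moments by self-normalized importance sampling.

    Proposal: the prior truncated to (0, inf).  The importance weight is then
    the likelihood alone (prior and truncation constants cancel in the
    self-normalized estimator).  Standard errors come from the delta method
    for ratio estimators.  Independent of the quadrature code under test.
    """
    rng = np.random.default_rng(seed)
    mu_hats = np.atleast_1d(np.asarray(mu_hats, dtype=float))
    sd = prior.std
    a = (0.0 - prior.layer_mean) / sd
    x = stats.truncnorm.rvs(
        a, np.inf, loc=prior.layer_mean, scale=sd, size=n_samples, random_state=rng
    )
    k = mu_hats.size
    log_w = -k * np.log(x) - mu_hats.sum() / x
    log_w -= log_w.max()
    w = np.exp(log_w)
    sw = w.sum()
    mean = float((w * x).sum() / sw)
    var = float((w * (x - mean) ** 2).sum() / sw)
    se_mean = float(np.sqrt((w**2 * (x - mean) ** 2).sum()) / sw)
    se_var = float(np.sqrt((w**2 * ((x - mean) ** 2 - var) ** 2).sum()) / sw)
    return {"mean": mean, "var": var, "se_mean": se_mean, "se_var": se_var}


def count_local_maxima(density: np.ndarray) -> int:
    """Strict interior local maxima of a tabulated density."""
    d = np.asarray(density)
    return int(np.sum((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])))
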