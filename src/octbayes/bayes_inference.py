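"""Bayesian inference for the voxelwise attenuation coefficient.

Given a depth-resolved estimate ``mu_hat`` made under fully developed
speckle, the estimate is (to leading order in the denominator's coefficient
of variation) exponentially distributed around the true coefficient,

    P(mu_hat | mu) = (1/mu) exp(-mu_hat / mu),

and k independent co-registered estimates multiply.  A statistical-mechanics
argument for a dilute suspension of identical scatterers gives a Gaussian
prior with mean equal to the layer mean and variance ``zeta * layer_mean``,
where ``zeta = sigma_scat / voxel_volume``.  The posterior is their
normalized product; because it can be bimodal for small ``mu_hat`` (the
likelihood spikes near the origin), the posterior mean rather than the MaP
is the recommended single-number estimator.

All densities are evaluated in the log domain with max-subtraction and
normalized by trapezoidal quadrature on a log-spaced grid, which resolves
both the near-origin likelihood spike and the prior bulk.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PriorSpec",
    "GridSpec",
    "PosteriorGrid",
    "likelihood",
    "likelihood_multi",
    "prior_density",
    "posterior",
    "posterior_mean",
    "posterior_map",
    "posterior_variance",
    "estimate_map",
]


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian prior over the attenuation coefficient.

    ``layer_mean`` (mm^-1) is the layer mean of the DR estimates; ``zeta``
    (mm^-1) is the scattering cross-section divided by the voxel volume, so
    the prior variance is ``zeta * layer_mean`` (mm^-2).
    """

    layer_mean: float
    zeta: float

    def __post_init__(self) -> None:
        if not self.layer_mean > 0:
            raise ValueError("layer_mean must be positive")
        if not self.zeta > 0:
            raise ValueError("zeta must be positive")

    @property
    def variance(self) -> float:
        return self.zeta * self.layer_mean

    @property
    def std(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class GridSpec:
    """Quadrature grid settings for posterior evaluation.

    With bounds left unset, the grid is log-spaced with
    ``mu_lo = max(1e-6, layer_mean * 1e-4)`` and
    ``mu_hi = layer_mean + 10 * prior_std + max(mu_hat)`` — wide enough for
    the prior bulk and any near-origin likelihood peak.
    """

    n_points: int = 4096
    mu_lo: Optional[float] = None
    mu_hi: Optional[float] = None

    def bounds(self, prior: PriorSpec, mu_hat_max: float) -> tuple[float, float]:
        lo = self.mu_lo if self.mu_lo is not None else max(1e-6, prior.layer_mean * 1e-4)
        hi = (
            self.mu_hi
            if self.mu_hi is not None
            else prior.layer_mean + 10.0 * prior.std + mu_hat_max
        )
        if not 0 < lo < hi:
            raise ValueError("grid bounds must satisfy 0 < mu_lo < mu_hi")
        return lo, hi

    def grid(self, prior: PriorSpec, mu_hat_max: float) -> np.ndarray:
        lo, hi = self.bounds(prior, mu_hat_max)
        return np.exp(np.linspace(math.log(lo), math.log(hi), self.n_points))


@dataclass(frozen=True)
class PosteriorGrid:
    """Tabulated normalized posterior density for one voxel."""

    mu_grid: np.ndarray
    density: np.ndarray
    dr_estimates: np.ndarray
    prior: PriorSpec

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_grid, dtype=float)
        d = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "mu_grid", mu)
        object.__setattr__(self, "density", d)
        object.__setattr__(
            self, "dr_estimates", np.atleast_1d(np.asarray(self.dr_estimates, float))
        )
        if mu.ndim != 1 or np.any(np.diff(mu) <= 0):
            raise ValueError("mu_grid must be strictly increasing")
        if d.shape != mu.shape:
            raise ValueError("density and mu_grid shapes differ")
        if np.any(d < 0):
            raise ValueError("density must be non-negative")
        integral = np.trapezoid(d, mu)
        if abs(integral - 1.0) > 1e-6:
            raise ValueError(f"density not normalized (integral={integral!r})")


def likelihood(mu_hat, mu_oct):
    """Exponential likelihood density P(mu_hat | mu_oct) = e^{-mu_hat/mu}/mu."""
    mu_oct = np.asarray(mu_oct, dtype=float)
    mu_hat = np.asarray(mu_hat, dtype=float)
    if np.any(mu_oct <= 0):
        raise ValueError("mu_oct must be positive")
    if np.any(mu_hat < 0):
        raise ValueError("mu_hat must be non-negative")
    out = np.exp(-np.log(mu_oct) - mu_hat / mu_oct)
    return out if out.ndim else float(out)


def likelihood_multi(mu_hats: Sequence[float], mu_oct):
    """Joint likelihood of k independent co-registered estimates."""
    mu_hats = np.atleast_1d(np.asarray(mu_hats, dtype=float))
    if mu_hats.size == 0:
        raise ValueError("at least one estimate is required")
    mu_oct = np.asarray(mu_oct, dtype=float)
    if np.any(mu_oct <= 0):
        raise ValueError("mu_oct must be positive")
    if np.any(mu_hats < 0):
        raise ValueError("estimates must be non-negative")
    k = mu_hats.size
    out = np.exp(-k * np.log(mu_oct) - mu_hats.sum() / mu_oct)
    return out if out.ndim else float(out)


def prior_density(mu, prior: PriorSpec):
    """Gaussian prior density, as printed (not renormalized for positivity).

    The positivity-truncation mass is negligible whenever
    ``layer_mean >= ~3 sqrt(zeta * layer_mean)``; a warning is emitted when
    more than 1e-3 of the mass sits below zero.
    """
    mu = np.asarray(mu, dtype=float)
    z = (0.0 - prior.layer_mean) / prior.std
    truncated_mass = 0.5 * math.erfc(-z / math.sqrt(2.0))
    if truncated_mass > 1e-3:
        warnings.warn(
            f"prior mass below zero is {truncated_mass:.2e}; the printed "
            "(un-renormalized) Gaussian form is a poor fit this wide",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.exp(_log_prior(mu, prior))
    return out if out.ndim else float(out)


def _log_prior(mu: np.ndarray, prior: PriorSpec) -> np.ndarray:
    v = prior.variance
    return -0.5 * math.log(2.0 * math.pi * v) - (mu - prior.layer_mean) ** 2 / (2.0 * v)


def posterior(
    mu_hats,
    prior: PriorSpec,
    grid_spec: Optional[GridSpec] = None,
) -> PosteriorGrid:
    """Normalized posterior of the attenuation coefficient for one voxel.

    ``mu_hats`` is the list of k >= 1 DR estimates the posterior conditions
    on.  The density is evaluated in the log domain on a log-spaced grid and
    trapezoid-normalized.  If every estimate is exactly zero the likelihood
    ``mu^{-k}`` is non-integrable at the origin and the result depends on
    the grid floor; a warning is emitted.
    """
    grid_spec = grid_spec or GridSpec()
    mu_hats = np.atleast_1d(np.asarray(mu_hats, dtype=float))
    if mu_hats.size == 0:
        raise ValueError("at least one estimate is required")
    if np.any(mu_hats < 0):
        raise ValueError("estimates must be non-negative")
    if np.all(mu_hats == 0):
        warnings.warn(
            "all DR estimates are exactly 0: the likelihood is non-integrable "
            "near the origin and the posterior depends on the grid floor mu_lo",
            RuntimeWarning,
            stacklevel=2,
        )
    g = grid_spec.grid(prior, float(mu_hats.max()))
    k = mu_hats.size
    log_post = -k * np.log(g) - mu_hats.sum() / g + _log_prior(g, prior)
    log_post -= log_post.max()
    dens = np.exp(log_post)
    dens /= np.trapezoid(dens, g)
    return PosteriorGrid(mu_grid=g, density=dens, dr_estimates=mu_hats, prior=prior)


def posterior_mean(post: PosteriorGrid) -> float:
    """Posterior expectation of the attenuation coefficient (mm^-1)."""
    return float(np.trapezoid(post.mu_grid * post.density, post.mu_grid))


def posterior_variance(post: PosteriorGrid) -> float:
    """Posterior variance (mm^-2), by trapezoidal quadrature."""
    m = posterior_mean(post)
    return float(np.trapezoid((post.mu_grid - m) ** 2 * post.density, post.mu_grid))


def posterior_map(post: PosteriorGrid) -> float:
    """Maximum a posteriori estimate, refined by quadratic interpolation.

    Retained for comparison only: for small DR estimates the posterior can
    be bimodal and the MaP is then a poor summary; the posterior mean is the
    recommended estimator.
    """
    i = int(np.argmax(post.density))
    if i == 0 or i == post.density.size - 1:
        warnings.warn(
            "posterior mode at grid boundary; it may be truncated",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(post.mu_grid[i])
    x0, x1, x2 = post.mu_grid[i - 1 : i + 2]
    y0, y1, y2 = post.density[i - 1 : i + 2]
    # vertex of the parabola through the three bracketing points
    denom = (x0 - x1) * (y1 - y2) - (x1 - x2) * (y0 - y1)
    if denom == 0:
        return float(x1)
    num = (x0**2 - x1**2) * (y1 - y2) - (x1**2 - x2**2) * (y0 - y1)
    vertex = 0.5 * num / denom
    if not (min(x0, x2) <= vertex <= max(x0, x2)):
        return float(x1)
    return float(vertex)


def estimate_map(
    dr_map,
    prior: PriorSpec,
    grid_spec: Optional[GridSpec] = None,
    chunk_voxels: int = 4096,
):
    """Posterior-mean attenuation map from a DR map (voxelwise, k=1).

    Voxels are treated as independent, so the joint posterior factorizes and
    each admissible voxel's posterior mean is computed on its own log-spaced
    grid (sharing the prior-driven floor, with the ceiling following that
    voxel's estimate).  Masked voxels carry NaN.

    Returns an :class:`~octbayes.speckle_forward.AttenuationProfile` when the
    DR map carries a geometry, else a bare NaN-masked array.
    """
    from .speckle_forward import AttenuationProfile

    grid_spec = grid_spec or GridSpec()
    mask = dr_map.admissible_mask
    if not np.any(mask):
        raise ValueError("DR map has no admissible voxels")
    mu_hats = dr_map.estimates[mask].astype(float)
    lo, _ = grid_spec.bounds(prior, float(mu_hats.max()))
    hi_per_voxel = prior.layer_mean + 10.0 * prior.std + mu_hats
    n = grid_spec.n_points

    means = np.empty_like(mu_hats)
    log_lo = math.log(lo)
    t = np.linspace(0.0, 1.0, n)  # shared log-interpolation parameter
    for start in range(0, mu_hats.size, chunk_voxels):
        sl = slice(start, min(start + chunk_voxels, mu_hats.size))
        # integrate in u = log(mu): the grid is uniform per voxel there and
        # the Jacobian mu du cancels the 1/mu likelihood prefactor, so the
        # u-space log-integrand is -mu_hat/mu + log prior(mu)
        g = np.exp(log_lo + (np.log(hi_per_voxel[sl]) - log_lo)[:, None] * t[None, :])
        log_w = -mu_hats[sl, None] / g + _log_prior(g, prior)
        log_w -= log_w.max(axis=1, keepdims=True)
        w = np.exp(log_w)
        w[:, 0] *= 0.5  # trapezoid end weights (uniform u spacing)
        w[:, -1] *= 0.5
        means[sl] = np.einsum("ij,ij->i", g, w) / w.sum(axis=1)

    out = np.full(dr_map.estimates.shape, np.nan)
    out[mask] = means
    if dr_map.geometry is not None:
        return AttenuationProfile(values=out, geometry=dr_map.geometry)
    return out
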