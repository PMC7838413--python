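"""Forward model of speckled OCT intensity scans.

The mean OCT signal of a weakly absorbing, single-scattering medium decays
exponentially with the accumulated (round-trip) attenuation,

    <I_N> = I_inc * beta_NA * mu_oct(N) * exp(-2 * sum_{i=1..N} mu_oct(i) dz),

where the cumulative sum includes the voxel's own attenuation.  Under fully
developed speckle the measured intensity at each voxel is an exponential
random variable whose mean is the model signal, so a speckled B-scan is
drawn voxel-by-voxel from Exponential(<I_N>).

Intensity units are arbitrary: the depth-resolved estimator downstream is a
ratio of intensities, so no radiometric calibration is modelled.  Depths are
geometric millimetres (no refractive-index path scaling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "AcquisitionGeometry",
    "AttenuationProfile",
    "ScanField",
    "mean_signal",
    "speckle_sample",
    "sample_prior_map",
]

# tolerant floor: depth_extent/axial_pitch is frequently an exact integer
# written in decimal (3.4/0.0068 = 500) that floating point puts a hair below
_FLOOR_EPS = 1e-9


def _tolerant_floor(x: float) -> int:
    return int(math.floor(x + _FLOOR_EPS))


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Scan geometry and illumination constants.

    Parameters
    ----------
    axial_pitch : float
        Axial voxel size ``dz`` in mm.
    lateral_pitch : float
        Lateral A-line spacing ``dx`` in mm.
    depth_extent : float
        Imaging depth ``Z_max`` in mm; the number of depth pixels is
        ``floor(depth_extent / axial_pitch)``.
    incident_intensity : float
        Incident intensity ``I_inc`` (arbitrary power units).
    backscatter_fraction : float
        Fraction ``beta_NA`` in (0, 1] of attenuated light back-scattered
        into the detection numerical aperture.
    """

    axial_pitch: float
    lateral_pitch: float
    depth_extent: float
    incident_intensity: float = 1.0e7
    backscatter_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (self.axial_pitch > 0 and self.lateral_pitch > 0):
            raise ValueError("voxel pitches must be positive")
        if not self.incident_intensity > 0:
            raise ValueError("incident_intensity must be positive")
        if not 0 < self.backscatter_fraction <= 1:
            raise ValueError("backscatter_fraction must lie in (0, 1]")
        if self.n_depth < 2:
            raise ValueError("geometry must resolve at least 2 depth pixels")

    @property
    def n_depth(self) -> int:
        """Number of depth pixels M."""
        return _tolerant_floor(self.depth_extent / self.axial_pitch)

    @property
    def depth_axis(self) -> np.ndarray:
        """Physical depth of each pixel centre, ``z = N dz`` (1-based N)."""
        return self.axial_pitch * np.arange(1, self.n_depth + 1)

    def to_dict(self) -> dict:
        return {
            "axial_pitch_mm": self.axial_pitch,
            "lateral_pitch_mm": self.lateral_pitch,
            "depth_extent_mm": self.depth_extent,
            "incident_intensity": self.incident_intensity,
            "backscatter_fraction": self.backscatter_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(
            axial_pitch=d["axial_pitch_mm"],
            lateral_pitch=d["lateral_pitch_mm"],
            depth_extent=d["depth_extent_mm"],
            incident_intensity=d.get("incident_intensity", 1.0e7),
            backscatter_fraction=d.get("backscatter_fraction", 0.3),
        )


def _as_2d(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("depth-by-lateral grid expected (1-D or 2-D array)")
    return arr


@dataclass(frozen=True)
class AttenuationProfile:
    """A depth x lateral grid of attenuation coefficients (mm^-1).

    NaN entries are permitted as "no value" sentinels (e.g. truncated voxels
    of a reconstructed map); every finite entry must be non-negative.
    """

    values: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_2d(self.values))
        if self.values.shape[0] != self.geometry.n_depth:
            raise ValueError(
                f"profile has {self.values.shape[0]} depth rows, geometry "
                f"expects {self.geometry.n_depth}"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("attenuation coefficients must be non-negative")

    @property
    def n_lateral(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ScanField:
    """A depth x lateral grid of OCT intensities.

    ``is_realization`` distinguishes a speckled draw from the deterministic
    mean signal; for a realization the generating ``seed`` is recorded.
    """

    intensities: np.ndarray
    geometry: AcquisitionGeometry
    is_realization: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensities", _as_2d(self.intensities))
        if self.intensities.shape[0] != self.geometry.n_depth:
            raise ValueError(
                f"scan has {self.intensities.shape[0]} depth rows, geometry "
                f"expects {self.geometry.n_depth}"
            )
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_lateral(self) -> int:
        return self.intensities.shape[1]


def mean_signal(profile: AttenuationProfile) -> ScanField:
    """Evaluate the mean (speckle-free) OCT signal of an attenuation map.

    Per A-line, ``I_N = I_inc * beta_NA * mu(N) * exp(-2 sum_{i<=N} mu(i) dz)``
    with the cumulative attenuation including the voxel's own contribution.

    Returns a :class:`ScanField` with ``is_realization=False``.
    """
    if np.any(~np.isfinite(profile.values)):
        raise ValueError("mean_signal requires a fully defined profile (no NaN)")
    geo = profile.geometry
    mu = profile.values
    optical_depth = 2.0 * geo.axial_pitch * np.cumsum(mu, axis=0)
    intensities = geo.incident_intensity * geo.backscatter_fraction * mu * np.exp(
        -optical_depth
    )
    return ScanField(intensities=intensities, geometry=geo, is_realization=False)


def speckle_sample(mean_scan: ScanField, seed: int) -> ScanField:
    """Draw one fully-developed-speckle realization of a mean scan.

    Each voxel is an independent exponential variate with mean equal to the
    voxel's mean intensity; zero-mean voxels stay exactly zero.  Independent
    per-A-line RNG streams are spawned from the root seed so results do not
    depend on how the lateral dimension is traversed.
    """
    if mean_scan.is_realization:
        raise ValueError("speckle_sample expects a mean (non-realization) scan")
    means = mean_scan.intensities
    if np.any(means < 0):
        raise ValueError("mean intensities must be non-negative")
    out = np.empty_like(means)
    streams = np.random.SeedSequence(seed).spawn(means.shape[1])
    for j, child in enumerate(streams):
        rng = np.random.default_rng(child)
        out[:, j] = rng.exponential(scale=means[:, j])
    out[means == 0] = 0.0
    return ScanField(
        intensities=out,
        geometry=mean_scan.geometry,
        is_realization=True,
        seed=seed,
    )


def sample_prior_map(
    prior: "PriorSpec",
    geometry: AcquisitionGeometry,
    seed: int,
    n_lateral: int = 1,
) -> AttenuationProfile:
    """Sample a ground-truth attenuation map from the physics-based prior.

    Voxels are i.i.d. draws from the Gaussian with mean ``layer_mean`` and
    variance ``zeta * layer_mean``, truncated to non-negative values (the
    particle-count picture does not admit negative attenuation).
    """
    if not (prior.layer_mean > 0 and prior.zeta > 0):
        raise ValueError("prior parameters must be positive")
    sd = math.sqrt(prior.zeta * prior.layer_mean)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    a = (0.0 - prior.layer_mean) / sd  # left truncation bound in sigma units
    draws = stats.truncnorm.rvs(
        a,
        np.inf,
        loc=prior.layer_mean,
        scale=sd,
        size=(geometry.n_depth, n_lateral),
        random_state=rng,
    )
    return AttenuationProfile(values=draws, geometry=geometry)
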