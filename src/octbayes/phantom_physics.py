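"""Optical properties of bead-suspension tissue phantoms.

A monodisperse suspension of dielectric spheres is characterised by the Mie
scattering cross-section of a single bead, the bead number density implied
by the volume fraction, and their product, the bulk attenuation coefficient
(independent-scattering, dilute approximation; absorption neglected).  The
prior-width parameter of the Bayesian model, ``zeta``, is the scattering
cross-section divided by the voxel volume.

The Mie solution is the standard Bohren & Huffman series with the
logarithmic-derivative computed by downward recurrence; it reproduces the
Wiscombe reference values (e.g. x=10, m=1.5: Q_sca = 2.8820) and the
Rayleigh closed form in the small-sphere limit.

Two refractive indices of the host medium enter: the *phase* index sets the
wavelength in the medium (size parameter), while the *group* index is used
for the bead/medium contrast ``m = n_particle / n_medium_group``, matching
how the bead contrast of water-based OCT phantoms is specified at these
wavelengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SphereSuspension",
    "VoxelGeometry",
    "mie_qsca",
    "mie_sigma_scat",
    "number_density",
    "bulk_attenuation",
    "zeta_from_geometry",
    "phantom_report",
]


@dataclass(frozen=True)
class SphereSuspension:
    """A monodisperse sphere suspension.

    Lengths follow the conventions the quantities are usually quoted in:
    ``diameter`` in micron, ``wavelength_vacuum`` in nm; derived
    cross-sections and densities are reported in mm-based units.
    """

    diameter: float  # micron
    n_particle: float
    n_medium_phase: float
    n_medium_group: float
    volume_fraction: float
    wavelength_vacuum: float  # nm

    def __post_init__(self) -> None:
        if not (self.diameter > 0 and self.wavelength_vacuum > 0):
            raise ValueError("diameter and wavelength must be positive")
        if not 0 < self.volume_fraction < 1:
            raise ValueError("volume_fraction must lie in (0, 1)")
        for n in (self.n_particle, self.n_medium_phase, self.n_medium_group):
            if n < 1:
                raise ValueError("refractive indices must be >= 1")

    @property
    def diameter_mm(self) -> float:
        return self.diameter * 1e-3

    @property
    def wavelength_mm(self) -> float:
        return self.wavelength_vacuum * 1e-6

    @property
    def size_parameter(self) -> float:
        """x = pi d n_phase / lambda_vacuum."""
        return math.pi * self.diameter_mm * self.n_medium_phase / self.wavelength_mm

    @property
    def relative_index(self) -> float:
        """m = n_particle / n_medium_group (bead contrast)."""
        return self.n_particle / self.n_medium_group


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel volume with a record of the linear dimensions that produced it."""

    voxel_volume: float  # mm^3
    derivation: Sequence[float] = ()  # the three linear dimensions, mm

    def __post_init__(self) -> None:
        if not self.voxel_volume > 0:
            raise ValueError("voxel_volume must be positive")
        if self.derivation:
            prod = float(np.prod(self.derivation))
            if not math.isclose(prod, self.voxel_volume, rel_tol=1e-9):
                raise ValueError("voxel_volume must equal the product of its dimensions")

    @classmethod
    def from_pitches(cls, dx: float, dy: float, dz: float) -> "VoxelGeometry":
        return cls(voxel_volume=dx * dy * dz, derivation=(dx, dy, dz))


def mie_qsca(x: float, m: complex) -> float:
    """Mie scattering efficiency of a homogeneous sphere.

    Bohren & Huffman series: the logarithmic derivative D_n is computed by
    downward recurrence, the Riccati-Bessel functions by upward recurrence.
    """
    if x <= 0:
        raise ValueError("size parameter must be positive")
    nmax = int(math.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    nmx = max(nmax, int(math.ceil(abs(m * x)))) + 16
    D = np.zeros(nmx + 1, dtype=complex)
    mx = m * x
    for n in range(nmx, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)

    psi_nm2, psi_nm1 = math.cos(x), math.sin(x)  # psi_{-1}, psi_0
    chi_nm2, chi_nm1 = -math.sin(x), math.cos(x)
    xi_nm1 = psi_nm1 - 1j * chi_nm1
    qsca = 0.0
    for n in range(1, nmax + 1):
        psi = (2 * n - 1) / x * psi_nm1 - psi_nm2
        chi = (2 * n - 1) / x * chi_nm1 - chi_nm2
        xi = psi - 1j * chi
        an = ((D[n] / m + n / x) * psi - psi_nm1) / ((D[n] / m + n / x) * xi - xi_nm1)
        bn = ((D[n] * m + n / x) * psi - psi_nm1) / ((D[n] * m + n / x) * xi - xi_nm1)
        qsca += (2 * n + 1) * (abs(an) ** 2 + abs(bn) ** 2)
        psi_nm2, chi_nm2 = psi_nm1, chi_nm1
        psi_nm1, chi_nm1, xi_nm1 = psi, chi, xi
    return 2.0 / x**2 * qsca


def mie_sigma_scat(s: SphereSuspension) -> float:
    """Scattering cross-section of one bead (mm^2)."""
    q = mie_qsca(s.size_parameter, s.relative_index)
    return q * math.pi * (s.diameter_mm / 2.0) ** 2


def number_density(s: SphereSuspension) -> float:
    """Bead number density (mm^-3) implied by the volume fraction."""
    bead_volume = (4.0 / 3.0) * math.pi * (s.diameter_mm / 2.0) ** 3
    return s.volume_fraction / bead_volume


def bulk_attenuation(s: SphereSuspension) -> float:
    """Bulk attenuation coefficient (mm^-1), independent scattering.

    sigma_scat * number_density; linear in the volume fraction, with no
    dependent-scattering correction.
    """
    return mie_sigma_scat(s) * number_density(s)


def zeta_from_geometry(sigma_scat: float, vox: VoxelGeometry) -> float:
    """Prior-width parameter zeta = sigma_scat / voxel_volume (mm^-1)."""
    if sigma_scat < 0:
        raise ValueError("sigma_scat must be non-negative")
    return sigma_scat / vox.voxel_volume


def phantom_report(s: SphereSuspension, vox: VoxelGeometry) -> dict:
    """Flat summary of derived suspension properties."""
    sigma = mie_sigma_scat(s)
    rho = number_density(s)
    return {
        "size_parameter": s.size_parameter,
        "relative_index": s.relative_index,
        "sigma_scat_mm2": sigma,
        "number_density_mm3": rho,
        "mu_bulk_mm1": sigma * rho,
        "zeta_mm1": zeta_from_geometry(sigma, vox),
        "voxel_volume_mm3": vox.voxel_volume,
    }
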