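"""Gouy-Chapman electric double layers in a slit.

The slit walls carry a uniform surface charge density; the intervening
1:1 electrolyte arranges into a diffuse double layer at each wall. The
closed-form Gouy-Chapman solution of the Poisson-Boltzmann equation for
an isolated charged plane is superposed symmetrically from the two walls,
which is accurate whenever the Debye length is small compared to the slit
width (here lambda_D ~ 1.7 nm versus w = 20 nm).

These analytic profiles stand in for measured ion distributions; the flow
solver accepts any tabulated c_i(z), so simulation-derived profiles can be
substituted transparently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import E_CHARGE, EPS0, K_B, MOLAR_TO_MOL_M3, N_A, NM
from .grid import GridProfile

__all__ = [
    "ElectrolyteSpec",
    "debye_length",
    "gouy_chapman_potential",
    "gouy_chapman_profiles",
]


@dataclass(frozen=True)
class ElectrolyteSpec:
    """A symmetric electrolyte between two equally charged walls.

    Parameters
    ----------
    bulk_concentration :
        Bulk (mid-slit) salt concentration c0 in mol/L.
    valences :
        Ion valences, exactly two species; (+1, -1) by default.
    surface_charge :
        Surface charge density sigma_s of each wall in C/m^2.
    dielectric_constant :
        Relative permittivity of the solvent (78 for water-like solvent).
    temperature :
        Absolute temperature in K.
    """

    bulk_concentration: float = 3.4e-2
    valences: tuple[int, int] = (1, -1)
    surface_charge: float = 3.28e-2
    dielectric_constant: float = 78.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if len(self.valences) != 2:
            raise ValueError("exactly two ionic species are supported (M = 2)")
        if self.bulk_concentration <= 0:
            raise ValueError("bulk concentration must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def is_one_one(self) -> bool:
        return sorted(self.valences) == [-1, 1]


def debye_length(spec: ElectrolyteSpec) -> float:
    """Debye screening length lambda_D in nm.

    lambda_D = sqrt(eps eps0 kT / (2 NA e^2 I)) with the ionic strength I
    equal to the bulk concentration for a 1:1 salt.
    """
    n0 = spec.bulk_concentration * MOLAR_TO_MOL_M3 * N_A  # ions per m^3 per species
    lam = np.sqrt(spec.dielectric_constant * EPS0 * K_B * spec.temperature
                  / (2.0 * n0 * E_CHARGE**2))
    return float(lam / NM)


def _wall_potential(spec: ElectrolyteSpec) -> float:
    """Surface potential psi_0 [V] from the Grahame equation for a 1:1 salt."""
    kT = K_B * spec.temperature
    n0 = spec.bulk_concentration * MOLAR_TO_MOL_M3 * N_A
    prefac = np.sqrt(8.0 * n0 * spec.dielectric_constant * EPS0 * kT)
    return float(2.0 * kT / E_CHARGE * np.arcsinh(spec.surface_charge / prefac))


def gouy_chapman_potential(spec: ElectrolyteSpec, z_nm: np.ndarray, w_nm: float) -> np.ndarray:
    """Electrostatic potential psi(z) [V] across the slit.

    Single-wall Gouy-Chapman solutions
    psi(z) = (4 kT / e) artanh(gamma exp(-z/lambda_D)),
    gamma = tanh(e psi_0 / 4kT), superposed from both walls.
    """
    if not spec.is_one_one:
        raise ValueError("Gouy-Chapman closed form requires a 1:1 electrolyte")
    z = np.asarray(z_nm, dtype=float)
    kT = K_B * spec.temperature
    lam = debye_length(spec)
    psi0 = _wall_potential(spec)
    gamma = np.tanh(E_CHARGE * psi0 / (4.0 * kT))

    def one_wall(dist_nm: np.ndarray) -> np.ndarray:
        d = np.maximum(dist_nm, 0.0)
        return 4.0 * kT / E_CHARGE * np.arctanh(gamma * np.exp(-d / lam))

    return one_wall(z) + one_wall(w_nm - z)


def gouy_chapman_profiles(spec: ElectrolyteSpec, w: float = 20.0,
                          n_grid: int = 4001) -> dict[int, GridProfile]:
    """Boltzmann ion concentration profiles c_i(z) for both species.

    Returns a mapping valence -> GridProfile (mol/L) on a uniform grid of
    ``n_grid`` points over [0, w]. Each profile follows
    c_i(z) = c0 exp(-z_i e psi(z) / kT) and tends to c0 at mid-slit.

    Raises
    ------
    ValueError
        If the electrolyte is not 1:1 (the closed form does not apply) or
        the grid is too coarse.
    """
    if n_grid < 3:
        raise ValueError("n_grid must be at least 3")
    z = np.linspace(0.0, w, n_grid)
    psi = gouy_chapman_potential(spec, z, w)
    kT = K_B * spec.temperature
    out: dict[int, GridProfile] = {}
    for zi in spec.valences:
        c = spec.bulk_concentration * np.exp(-zi * E_CHARGE * psi / kT)
        out[zi] = GridProfile(z, c, unit="mol/L")
    return out
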