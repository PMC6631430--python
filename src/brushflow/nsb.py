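"""One-dimensional Navier-Stokes-Brinkman electro-osmotic flow solver.

The steady EOF velocity u(z) across a polymer-coated slit obeys

    d/dz [ mu(z) du/dz ] - 6 pi mu(z) n(z) a_bead K(phi(z)) u(z)
        + rho_e(z) E_ext = 0,

where mu(z) is the fluid viscosity, n(z) the polymer bead number
density, a_bead the effective (Stokes) bead radius, K(phi) a hindered
drag correction at bead volume fraction phi, and rho_e = F sum_i z_i c_i
the local ionic charge density driven by the applied field E_ext. The
first term is the viscous stress divergence, the second the distributed
Brinkman drag of the coating, the third the electric body force.

Boundary conditions: no slip at the hydrodynamic wall plane (z = 0 by
default, configurable offset) and mirror symmetry (du/dz = 0) at the
slit center; the full-slit profile is the mirror image of the half-slit
solution.

The discretization is a conservative-flux second-order finite-difference
scheme with harmonic-mean face viscosities (exact flux matching across
viscosity jumps aligned with cell faces), solved as one tridiagonal
system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import solve_banded

from .constants import FARADAY, MOLAR_TO_MOL_M3, NM, V_PER_NM
from .grid import GridProfile

__all__ = [
    "NSBParams",
    "VelocityProfile",
    "volume_fraction",
    "viscosity_profile",
    "hindrance_K",
    "charge_density",
    "solve_nsb",
    "RANDOM_CLOSE_PACKING",
]

#: VelocityProfile is a GridProfile of u(z) in m/s with u = 0 at the no-slip plane
VelocityProfile = GridProfile

#: random close packing limit for spheres; larger volume fractions are unphysical
RANDOM_CLOSE_PACKING = 0.64


@dataclass(frozen=True)
class NSBParams:
    """Physical constants and numerical controls for the NSB equation.

    Parameters
    ----------
    mu0 :
        Bulk solvent viscosity in Pa s.
    a_bead :
        Effective Stokes radius of a polymer bead, nm; physically
        constrained to [0, a0].
    a0 :
        Physical (Lennard-Jones) bead radius, nm.
    Eext :
        Applied electric field along the slit, V/nm.
    width :
        Slit width w in nm.
    hindrance_model :
        ``"kim-russel"`` (default) or ``"unity"`` (dilute limit K = 1).
    no_slip_offset :
        Distance of the hydrodynamic no-slip plane from the wall, nm.
    faraday :
        Faraday constant, C/mol.
    """

    mu0: float = 0.85e-3
    a_bead: float = 0.019
    a0: float = 0.156
    Eext: float = 1.6e-2
    width: float = 20.0
    hindrance_model: str = "kim-russel"
    no_slip_offset: float = 0.0
    faraday: float = FARADAY

    def __post_init__(self) -> None:
        if self.mu0 <= 0 or self.a0 <= 0 or self.width <= 0:
            raise ValueError("mu0, a0 and width must be positive")
        if not 0.0 <= self.a_bead <= self.a0:
            raise ValueError(f"a_bead must lie in [0, a0 = {self.a0}] nm")
        if self.no_slip_offset < 0:
            raise ValueError("no-slip plane offset must be >= 0")
        if self.hindrance_model not in ("kim-russel", "unity"):
            raise ValueError(f"unknown hindrance model {self.hindrance_model!r}")


def volume_fraction(n: GridProfile, a0: float) -> GridProfile:
    """Bead volume fraction phi(z) = (4 pi / 3) a0^3 n(z).

    ``n`` in nm^-3 and ``a0`` in nm give a dimensionless phi. Warns when
    phi exceeds the random-close-packing limit 0.64 anywhere.
    """
    if a0 <= 0:
        raise ValueError("bead radius must be positive")
    if np.any(n.values < 0):
        raise ValueError("bead density must be non-negative")
    phi = (4.0 * np.pi / 3.0) * a0**3 * n.values
    if phi.max(initial=0.0) > RANDOM_CLOSE_PACKING:
        warnings.warn(
            f"max volume fraction {phi.max():.3f} exceeds random close packing "
            f"({RANDOM_CLOSE_PACKING}); density profile is unphysical",
            stacklevel=2)
    return n.with_values(phi, unit="")


def viscosity_profile(phi: GridProfile, mu0: float) -> GridProfile:
    """Einstein dilute-suspension viscosity mu(z) = mu0 (1 + 2.5 phi(z))."""
    if np.any(phi.values < 0) or np.any(phi.values >= 1.0):
        raise ValueError("volume fraction must lie in [0, 1)")
    return phi.with_values(mu0 * (1.0 + 2.5 * phi.values), unit="Pa s")


def hindrance_K(phi, model: str = "kim-russel"):
    """Hindered-drag correction K(phi) for a random swarm of spheres.

    K multiplies the single-sphere Stokes drag; K(0) = 1 and K grows
    with crowding. The default is the Kim-Russel rational fit for the
    drag on fixed random arrays of spheres,

        K = (1 + 3 sqrt(phi/2) + (135/64) phi ln phi + 16.456 phi)
            / (1 + 0.681 phi - 8.48 phi^2 + 8.16 phi^3),

    valid up to random close packing. ``model="unity"`` selects the
    dilute limit K = 1, which reduces the Brinkman term to a plain
    Stokes swarm drag 6 pi mu n a_bead u.
    """
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0) or np.any(phi_arr > RANDOM_CLOSE_PACKING):
        raise ValueError(f"volume fraction must lie in [0, {RANDOM_CLOSE_PACKING}]")
    if model == "unity":
        K = np.ones_like(phi_arr)
    elif model == "kim-russel":
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(phi_arr > 0, phi_arr * np.log(phi_arr), 0.0)
        num = 1.0 + 3.0 * np.sqrt(phi_arr / 2.0) + (135.0 / 64.0) * plogp + 16.456 * phi_arr
        den = 1.0 + 0.681 * phi_arr - 8.48 * phi_arr**2 + 8.16 * phi_arr**3
        K = num / den
    else:
        raise ValueError(f"unknown hindrance model {model!r}")
    return K if np.ndim(phi) else float(K)


def charge_density(ions: dict[int, GridProfile], faraday: float = FARADAY) -> GridProfile:
    """Ionic charge density rho_e(z) = F sum_i z_i c_i(z) in C/m^3.

    ``ions`` maps the signed valence z_i to its concentration profile;
    profiles tagged ``"mol/L"`` are converted to mol/m^3, profiles tagged
    ``"mol/m^3"`` are used as is.
    """
    if not ions:
        raise ValueError("at least one ionic species is required")
    profiles = list(ions.values())
    base = profiles[0]
    for p in profiles[1:]:
        if not base.same_grid(p):
            raise ValueError("all ion profiles must share one grid")
    rho = np.zeros_like(base.values)
    for valence, prof in ions.items():
        c = prof.values
        if prof.unit in ("mol/L", "M", ""):
            c = c * MOLAR_TO_MOL_M3
        elif prof.unit not in ("mol/m^3", "mol/m3"):
            raise ValueError(f"unsupported concentration unit {prof.unit!r}")
        rho = rho + faraday * valence * c
    return base.with_values(rho, unit="C/m^3")


def _midpoint_index(profile: GridProfile, width: float) -> int:
    m = int(round((width / 2.0 - profile.z[0]) / profile.spacing))
    if not (0 < m < len(profile)) or abs(profile.z[m] - width / 2.0) > 1e-9 * width:
        raise ValueError(
            "grid must contain the slit midpoint w/2 as a node "
            "(use an odd number of points over [0, w])")
    if len(profile) not in (m + 1, 2 * m + 1):
        raise ValueError("grid must cover [0, w/2] or be symmetric over [0, w]")
    return m


def solve_nsb(mu: GridProfile, n: GridProfile, ions: dict[int, GridProfile] | GridProfile,
              params: NSBParams) -> VelocityProfile:
    """Solve the NSB two-point boundary-value problem for u(z).

    Parameters
    ----------
    mu :
        Viscosity profile (Pa s) on a uniform grid over [0, w] containing
        the midpoint w/2 as a node.
    n :
        Bead number density (nm^-3) on the same grid.
    ions :
        Either a valence -> concentration profile mapping, or a
        precomputed charge-density profile tagged ``"C/m^3"``.
    params :
        Physical and numerical parameters.

    Returns
    -------
    VelocityProfile
        u(z) in m/s over the full slit; the half-slit solution is
        mirrored about w/2.
    """
    if isinstance(ions, GridProfile):
        rho = ions
        if rho.unit not in ("C/m^3", "C/m3"):
            raise ValueError("precomputed charge density must be tagged C/m^3")
    else:
        rho = charge_density(ions, params.faraday)
    for name, p in (("n", n), ("rho_e", rho)):
        if not mu.same_grid(p):
            raise ValueError(f"{name} profile is not on the viscosity grid")
    if np.any(mu.values <= 0):
        raise ValueError("viscosity must be positive everywhere (singular system)")

    m = _midpoint_index(mu, params.width)
    h = mu.spacing * NM
    z = mu.z
    mu_v = mu.values[: m + 1]
    n_si = n.values[: m + 1] * 1e27            # nm^-3 -> m^-3
    rho_si = rho.values[: m + 1]
    phi = (4.0 * np.pi / 3.0) * params.a0**3 * n.values[: m + 1]
    K = hindrance_K(np.clip(phi, 0.0, RANDOM_CLOSE_PACKING), params.hindrance_model)
    drag = 6.0 * np.pi * mu_v * n_si * (params.a_bead * NM) * K   # [Pa s / m^2... ] per velocity
    force = rho_si * params.Eext * V_PER_NM                       # N/m^3

    i0 = int(round(params.no_slip_offset / mu.spacing))
    if i0 >= m:
        raise ValueError("no-slip plane offset reaches the slit midpoint")

    npts = m + 1
    mu_face = 2.0 * mu_v[:-1] * mu_v[1:] / (mu_v[:-1] + mu_v[1:])  # harmonic mean
    lower = np.zeros(npts)
    diag = np.zeros(npts)
    upper = np.zeros(npts)
    rhs = np.zeros(npts)

    # clamped region [0, no-slip plane]
    diag[: i0 + 1] = 1.0
    # interior rows
    idx = np.arange(i0 + 1, m)
    lower[idx] = mu_face[idx - 1] / h**2
    upper[idx] = mu_face[idx] / h**2
    diag[idx] = -(mu_face[idx - 1] + mu_face[idx]) / h**2 - drag[idx]
    rhs[idx] = -force[idx]
    # symmetry row at the midpoint (reflected ghost node)
    lower[m] = 2.0 * mu_face[m - 1] / h**2
    diag[m] = -2.0 * mu_face[m - 1] / h**2 - drag[m]
    rhs[m] = -force[m]

    ab = np.zeros((3, npts))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    u_half = solve_banded((1, 1), ab, rhs)
    u_half[: i0 + 1] = 0.0  # exact no-slip despite pivoting roundoff

    z_full = z if len(z) == 2 * m + 1 else np.linspace(z[0], z[0] + 2 * (z[m] - z[0]), 2 * m + 1)
    u = np.empty(2 * m + 1)
    u[: m + 1] = u_half
    u[m:] = u_half[::-1]
    return GridProfile(z_full, u, unit="m/s")
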