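"""End-to-end synthetic flow scenarios.

A scenario bundles everything needed to manufacture the inputs of the
NSB pipeline for a coated slit at a given degree of polymerization N:
the slit geometry, the electrolyte, the applied field, a planted
effective bead radius, and optional measurement noise. Forward-solving a
scenario yields a velocity profile with known ground truth, which is the
test bed for the radius-inference round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coating import CoatingConfiguration, SlitGeometry, free_bead_count
from .density import bead_density_profile, gaussian_mushroom_density, parabolic_brush_density
from .electrolyte import ElectrolyteSpec, gouy_chapman_profiles
from .grid import GridProfile, resample
from .nsb import NSBParams, VelocityProfile, solve_nsb, viscosity_profile, volume_fraction

__all__ = ["SyntheticScenario", "scenario_profiles", "scenario_params", "synthesize_velocity"]


@dataclass(frozen=True)
class SyntheticScenario:
    """Specification of one synthetic coated-slit flow experiment.

    ``density_model`` selects how the bead density n(z) is produced:
    ``"parabolic_brush"`` (default) or ``"gaussian_mushroom"`` parametric
    layers with areal bead density fixed by the grafting lattice
    (one chain of 3N+2 beads per lattice cell per wall), or a
    :class:`CoatingConfiguration` passed via ``coating``.

    The layer height defaults to a * (N/14)^0.65: a gyration-radius-like
    growth law anchored so the layer extent equals the grafting
    separation at the brush/mushroom crossover N = 14.
    """

    degree: int = 14
    geometry: SlitGeometry = field(default_factory=SlitGeometry)
    electrolyte: ElectrolyteSpec = field(default_factory=ElectrolyteSpec)
    Eext: float = 1.6e-2           # V/nm
    a_bead: float = 0.019          # planted Stokes radius, nm
    noise_sd: float = 0.0          # velocity noise, m/s
    seed: int = 0
    n_grid: int = 2001             # odd: midpoint w/2 must be a node
    density_model: str = "parabolic_brush"
    layer_height: float | None = None
    coating: CoatingConfiguration | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_grid % 2 == 0 or self.n_grid < 5:
            raise ValueError("n_grid must be odd and >= 5")
        if self.density_model not in ("parabolic_brush", "gaussian_mushroom", "coating"):
            raise ValueError(f"unknown density model {self.density_model!r}")
        if self.density_model == "coating" and self.coating is None:
            raise ValueError("density model 'coating' requires a coating configuration")

    @property
    def height(self) -> float:
        if self.layer_height is not None:
            return self.layer_height
        return self.geometry.graft_lattice_a * (self.degree / 14.0) ** 0.65


def scenario_params(scenario: SyntheticScenario, a_bead: float | None = None) -> NSBParams:
    """NSB parameter set for the scenario (planted radius by default)."""
    return NSBParams(
        a_bead=scenario.a_bead if a_bead is None else a_bead,
        a0=scenario.geometry.bead_radius,
        Eext=scenario.Eext,
        width=scenario.geometry.width,
    )


def scenario_profiles(scenario: SyntheticScenario) -> dict:
    """Build all coefficient profiles of the NSB equation on one grid.

    Returns a dict with keys ``n`` (bead density, nm^-3), ``phi``
    (volume fraction), ``mu`` (viscosity, Pa s) and ``ions``
    (valence -> mol/L), all on a uniform grid over [0, w].
    """
    geo = scenario.geometry
    w = geo.width
    N = scenario.degree
    areal = free_bead_count(N) / geo.graft_lattice_a**2  # beads per nm^2 per wall
    h = scenario.height

    if scenario.density_model == "parabolic_brush":
        amplitude = 3.0 * areal / (2.0 * h)
        n = parabolic_brush_density(w, h, amplitude, scenario.n_grid)
    elif scenario.density_model == "gaussian_mushroom":
        amplitude = areal / (h * np.sqrt(np.pi / 2.0))
        n = gaussian_mushroom_density(w, h, amplitude, scenario.n_grid)
    else:
        n = bead_density_profile(scenario.coating, n_grid=scenario.n_grid - 1)

    ions = gouy_chapman_profiles(scenario.electrolyte, w=w, n_grid=scenario.n_grid)
    z = ions[scenario.electrolyte.valences[0]].z
    n = resample(n, z)
    phi = volume_fraction(n, geo.bead_radius)
    mu = viscosity_profile(phi, scenario_params(scenario).mu0)
    return {"n": n, "phi": phi, "mu": mu, "ions": ions}


def synthesize_velocity(scenario: SyntheticScenario, profiles: dict | None = None) -> VelocityProfile:
    """Forward-solve the scenario and optionally add measurement noise.

    With ``noise_sd == 0`` the result is bit-identical to the raw solver
    output; otherwise i.i.d. Gaussian noise of the given standard
    deviation (m/s) is added under the scenario seed, so identical
    (scenario, seed) pairs give identical arrays.
    """
    profiles = profiles or scenario_profiles(scenario)
    u = solve_nsb(profiles["mu"], profiles["n"], profiles["ions"], scenario_params(scenario))
    if scenario.noise_sd == 0:
        return u
    rng = np.random.default_rng(scenario.seed)
    noise = rng.normal(0.0, scenario.noise_sd, size=len(u))
    return u.with_values(u.values + noise)
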