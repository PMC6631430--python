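"""Polymer bead number-density profiles n(z) across the slit.

Either binned from an explicit coating configuration (conserving the
bead count) or built from parametric model profiles: the parabolic brush
profile of strong-stretching theory, or a Gaussian layer appropriate for
isolated mushrooms.
"""

from __future__ import annotations

import numpy as np

from .coating import CoatingConfiguration
from .grid import GridProfile

__all__ = [
    "bead_density_profile",
    "parabolic_brush_density",
    "gaussian_mushroom_density",
]


def bead_density_profile(config: CoatingConfiguration, n_grid: int = 400) -> GridProfile:
    """Bin bead z-coordinates into a number-density profile (nm^-3).

    The slit [0, w] is divided into ``n_grid`` equal bins; the profile is
    reported at bin centers as counts / (lateral area * bin width), so
    that sum(n) * A * dz recovers the total bead count exactly.
    """
    beads = config.all_beads()
    if beads.size == 0:
        raise ValueError("empty configuration has no density profile")
    w = config.wall_z[1] - config.wall_z[0]
    edges = np.linspace(config.wall_z[0], config.wall_z[1], n_grid + 1)
    counts, _ = np.histogram(beads[:, 2], bins=edges)
    dz = edges[1] - edges[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    values = counts / (config.lateral_area * dz)
    return GridProfile(centers, values, unit="nm^-3")


def _two_wall(z: np.ndarray, w: float, one_wall) -> np.ndarray:
    return one_wall(z) + one_wall(w - z)


def parabolic_brush_density(w: float, height: float, amplitude: float,
                            n_grid: int = 400) -> GridProfile:
    """Parabolic brush profile n(z) = A (1 - (z/h)^2) from each wall.

    ``height`` is the brush height h (n vanishes at z = h), ``amplitude``
    the contact density A in nm^-3; contributions from both walls are
    superposed. The areal bead density per wall is A * 2h/3.
    """
    if height <= 0 or amplitude < 0:
        raise ValueError("height must be > 0 and amplitude >= 0")
    z = np.linspace(0.0, w, n_grid)

    def one(d: np.ndarray) -> np.ndarray:
        return amplitude * np.clip(1.0 - (d / height) ** 2, 0.0, None)

    return GridProfile(z, _two_wall(z, w, one), unit="nm^-3")


def gaussian_mushroom_density(w: float, height: float, amplitude: float,
                              n_grid: int = 400) -> GridProfile:
    """Gaussian mushroom layer n(z) = A exp(-z^2 / (2 h^2)) from each wall.

    ``height`` sets the layer extent (of order the chain gyration
    radius), ``amplitude`` the wall-contact density in nm^-3.
    """
    if height <= 0 or amplitude < 0:
        raise ValueError("height must be > 0 and amplitude >= 0")
    z = np.linspace(0.0, w, n_grid)

    def one(d: np.ndarray) -> np.ndarray:
        return amplitude * np.exp(-0.5 * (d / height) ** 2)

    return GridProfile(z, _two_wall(z, w, one), unit="nm^-3")
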