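"""Grafted polymer coating configurations and their generation.

A coating is a set of bead chains end-grafted on a square lattice on both
walls of a slit. Chains follow a united-atom-style counting rule: a chain
of polymerization degree N carries 3N + 2 free beads (three backbone beads
per monomer plus two terminal beads; the anchor beads that attach the
chain to the wall are not part of the free chain).

Chains are grown as freely-rotating excluded-volume walks: fixed bond
length b, fixed bond angle (109.5 deg tetrahedral default), uniformly
random dihedral, with a hard-core diameter 2*a0 enforced between beads of
different chains, against the walls, and between beads of the same chain
at least four bonds apart. Because the bond length (0.15 nm) is smaller
than the bead diameter (0.312 nm), bonded and next-nearest neighbours
necessarily overlap; the hard core therefore only applies where the chain
geometry permits avoidance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SlitGeometry",
    "CoatingConfiguration",
    "generate_grafted_coating",
    "free_bead_count",
    "write_xyz",
    "read_xyz",
    "read_gro",
]

#: tetrahedral bond angle in degrees
TETRAHEDRAL_ANGLE = 109.5
#: topological separation (in bonds) from which the hard core applies intra-chain
MIN_EXCLUDED_SEPARATION = 4


def free_bead_count(N: int) -> int:
    """Free beads per grafted chain of polymerization degree N: 3N + 2."""
    if N < 1:
        raise ValueError("degree of polymerization must be >= 1")
    return 3 * N + 2


@dataclass(frozen=True)
class SlitGeometry:
    """Geometry of the polymer-coated slit.

    Parameters
    ----------
    width :
        Slit width w in nm (distance between the innermost wall layers;
        z = 0 at the bottom one).
    graft_lattice_a :
        Square grafting-lattice constant in nm.
    bond_length :
        Intra-chain bead separation b in nm.
    bead_radius :
        Physical (Lennard-Jones) bead radius a0 in nm.
    bond_angle_deg :
        Fixed bond angle of the freely-rotating chain model.
    wall_margin :
        Minimum allowed bead distance from either wall, in nm; defaults
        to the bead radius.
    """

    width: float = 20.0
    graft_lattice_a: float = 2.5
    bond_length: float = 0.15
    bead_radius: float = 0.156
    bond_angle_deg: float = TETRAHEDRAL_ANGLE
    wall_margin: float | None = None

    @property
    def margin(self) -> float:
        return self.bead_radius if self.wall_margin is None else self.wall_margin


@dataclass
class CoatingConfiguration:
    """Bead coordinates of a grafted coating, grouped by chain.

    ``chains`` is a list of (n_beads, 3) coordinate arrays in nm; the box
    is periodic in x and y, with the walls at ``wall_z`` (z positions of
    the two innermost wall layers).
    """

    chains: list[np.ndarray]
    box: tuple[float, float, float]
    wall_z: tuple[float, float]
    graft_lattice_a: float
    bond_length: float
    bead_radius: float
    degree: int
    graft_sites: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def all_beads(self) -> np.ndarray:
        """All bead coordinates stacked into one (n, 3) array."""
        if not self.chains:
            return np.empty((0, 3))
        return np.vstack(self.chains)

    @property
    def lateral_area(self) -> float:
        """Box area in the periodic x,y plane, nm^2."""
        return self.box[0] * self.box[1]


def _rotate_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _next_direction(prev: np.ndarray, bond_angle_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Direction of the next bond: fixed angle to ``prev``, random dihedral."""
    # polar angle between consecutive bond *vectors* is pi - bond angle
    theta = math.pi - bond_angle_rad
    # orthonormal frame around prev
    ref = np.array([1.0, 0.0, 0.0]) if abs(prev[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(prev, ref)
    e1 /= np.linalg.norm(e1)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    d = _rotate_about(prev, phi) @ (_rotate_about(e1, theta) @ prev)
    return d / np.linalg.norm(d)


def _min_image_dist2(dx: np.ndarray, box_xy: tuple[float, float]) -> np.ndarray:
    """Squared distances with minimum-image convention in x,y (open in z)."""
    d = dx.copy()
    for k, L in enumerate(box_xy):
        d[..., k] -= L * np.round(d[..., k] / L)
    return np.einsum("...k,...k->...", d, d)


def generate_grafted_coating(
    N: int,
    n_chains_per_wall: int,
    spec: SlitGeometry | None = None,
    seed: int | np.random.Generator = 0,
    max_bead_tries: int = 60,
    max_chain_restarts: int = 400,
) -> CoatingConfiguration:
    """Grow a grafted coating of 3N+2-bead chains on both slit walls.

    Chains are attached to consecutive sites of the square grafting
    lattice, alternating walls are filled with ``n_chains_per_wall``
    chains each. The box is the smallest square lattice patch that holds
    ``n_chains_per_wall`` sites, so the lattice always tiles the periodic
    box. Growth is reproducible under ``seed``.

    Raises
    ------
    RuntimeError
        If a chain cannot be grown within the retry budget (overcrowded
        geometry); the error names the failing chain index.
    """
    if N < 1:
        raise ValueError("degree of polymerization must be >= 1")
    if n_chains_per_wall < 1:
        raise ValueError("need at least one chain per wall")
    spec = spec or SlitGeometry()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    a = spec.graft_lattice_a
    nx = math.ceil(math.sqrt(n_chains_per_wall))
    ny = math.ceil(n_chains_per_wall / nx)
    box = (nx * a, ny * a, spec.width)
    sites = [((i % nx) * a, (i // nx) * a) for i in range(n_chains_per_wall)]

    n_beads = free_bead_count(N)
    b = spec.bond_length
    d2_min = (2.0 * spec.bead_radius) ** 2
    lo, hi = spec.margin, spec.width - spec.margin
    if lo >= hi:
        raise ValueError("wall margin leaves no interior space")
    angle = math.radians(spec.bond_angle_deg)

    chains: list[np.ndarray] = []
    graft_sites: list[tuple[float, float]] = []
    others: np.ndarray = np.empty((0, 3))  # beads of completed chains

    def grow_chain(site: tuple[float, float], bottom: bool, chain_idx: int) -> np.ndarray:
        z0 = b if bottom else spec.width - b
        start = np.array([site[0], site[1], max(z0, lo) if bottom else min(z0, hi)])
        for _ in range(max_chain_restarts):
            beads = np.empty((n_beads, 3))
            beads[0] = start
            # initial bond points into the slit
            direction = None
            ok = True
            for i in range(1, n_beads):
                placed = False
                for _ in range(max_bead_tries):
                    if direction is None or i == 1:
                        # hemisphere away from the grafting wall
                        v = rng.normal(size=3)
                        v /= np.linalg.norm(v)
                        v[2] = abs(v[2]) if bottom else -abs(v[2])
                        v /= np.linalg.norm(v)
                        cand_dir = v
                    else:
                        cand_dir = _next_direction(direction, angle, rng)
                    cand = beads[i - 1] + b * cand_dir
                    if not (lo < cand[2] < hi):
                        continue
                    # intra-chain hard core, separation >= MIN_EXCLUDED_SEPARATION bonds
                    j_max = i - MIN_EXCLUDED_SEPARATION
                    if j_max >= 0:
                        d2 = _min_image_dist2(beads[: j_max + 1] - cand, box[:2])
                        if np.any(d2 < d2_min):
                            continue
                    # inter-chain hard core
                    if others.size:
                        d2 = _min_image_dist2(others - cand, box[:2])
                        if np.any(d2 < d2_min):
                            continue
                    beads[i] = cand
                    direction = cand_dir
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if ok:
                return beads
        raise RuntimeError(
            f"failed to grow chain {chain_idx} after {max_chain_restarts} restarts: "
            "geometry too crowded (reduce chain count, degree, or hard core)")

    idx = 0
    for bottom in (True, False):
        for site in sites:
            chain = grow_chain(site, bottom, idx)
            chains.append(chain)
            graft_sites.append(site)
            others = np.vstack([others, chain]) if others.size else chain.copy()
            idx += 1

    return CoatingConfiguration(
        chains=chains, box=box, wall_z=(0.0, spec.width),
        graft_lattice_a=a, bond_length=b, bead_radius=spec.bead_radius,
        degree=N, graft_sites=graft_sites)


# ---------------------------------------------------------------------------
# coordinate file I/O


def write_xyz(config: CoatingConfiguration, path) -> None:
    """Write the coating as a single-frame XYZ file (element tag "C").

    The XYZ comment line carries the coating metadata (box, walls,
    lattice constant, bond length, bead radius, degree, chain lengths)
    as JSON so that :func:`read_xyz` can reconstruct the configuration.
    """
    beads = config.all_beads()
    meta = {
        "box": list(config.box),
        "wall_z": list(config.wall_z),
        "graft_lattice_a": config.graft_lattice_a,
        "bond_length": config.bond_length,
        "bead_radius": config.bead_radius,
        "degree": config.degree,
        "chain_lengths": [len(c) for c in config.chains],
    }
    with open(path, "w") as fh:
        fh.write(f"{len(beads)}\n")
        fh.write(json.dumps(meta) + "\n")
        for x, y, z in beads:
            fh.write(f"C {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz(path) -> CoatingConfiguration:
    """Read a coating written by :func:`write_xyz` (coordinates in nm)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: truncated XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: line 1: expected atom count") from exc
    try:
        meta = json.loads(lines[1])
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"{path}: line 2: comment line does not carry coating metadata JSON") from exc
    coords = np.empty((n, 3))
    for i in range(n):
        parts = lines[2 + i].split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {3 + i}: malformed atom row")
        coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
    chains, start = [], 0
    for ln in meta["chain_lengths"]:
        chains.append(coords[start: start + ln].copy())
        start += ln
    return CoatingConfiguration(
        chains=chains, box=tuple(meta["box"]), wall_z=tuple(meta["wall_z"]),
        graft_lattice_a=meta["graft_lattice_a"], bond_length=meta["bond_length"],
        bead_radius=meta["bead_radius"], degree=meta["degree"])


def read_gro(path, geometry: SlitGeometry | None = None, degree: int | None = None) -> CoatingConfiguration:
    """Read a GRO coordinate file; each residue becomes one chain.

    Uses MDAnalysis for parsing (which reports coordinates in Angstrom;
    they are converted back to nm here). Slit metadata not stored in GRO
    files is taken from ``geometry``.
    """
    import MDAnalysis as mda

    geometry = geometry or SlitGeometry()
    u = mda.Universe(str(path))
    chains = [res.atoms.positions.astype(float) / 10.0 for res in u.residues]
    box = u.dimensions[:3] / 10.0 if u.dimensions is not None else None
    if box is None or not np.all(box > 0):
        box_t = (geometry.graft_lattice_a, geometry.graft_lattice_a, geometry.width)
    else:
        box_t = (float(box[0]), float(box[1]), float(box[2]))
    return CoatingConfiguration(
        chains=chains, box=box_t, wall_z=(0.0, box_t[2]),
        graft_lattice_a=geometry.graft_lattice_a, bond_length=geometry.bond_length,
        bead_radius=geometry.bead_radius,
        degree=degree if degree is not None else -1)
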