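"""Structural statistics of polymer coatings.

Non-normalized radial distribution functions, planar orientation
distributions of neighbour beads, exposed far-bead counts, gyration
radii with their chain-length scaling, and the brush/mushroom
conformational classification.

Distances use the minimum-image convention in the periodic x,y
directions only; the slit is bounded by walls in z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coating import CoatingConfiguration

__all__ = [
    "RadialDistribution",
    "OrientationDistribution",
    "FarBeadDistribution",
    "non_normalized_rdf",
    "orientation_distribution",
    "exposed_far_beads",
    "is_exposed",
    "gyration_radius",
    "scaling_exponent",
    "classify_conformation",
    "NEAR_FAR_SPLIT",
]

#: near/far bead split radius r0 in nm (first two RDF peaks are intra-chain)
NEAR_FAR_SPLIT = 0.3


def _min_image(d: np.ndarray, box_xy) -> np.ndarray:
    d = np.array(d, dtype=float, copy=True)
    for k in (0, 1):
        L = box_xy[k]
        d[..., k] -= L * np.round(d[..., k] / L)
    return d


def _pair_scan(beads: np.ndarray, box_xy, block: int = 64):
    """Yield unique-pair displacements blockwise: (row indices, distances,
    displacements) for pairs (i, j) with i < j, minimum-imaged in x,y.
    Keeps memory at O(block * n) for large configurations."""
    n = len(beads)
    for start in range(0, n, block):
        rows = np.arange(start, min(start + block, n))
        d = _min_image(beads[None, :, :] - beads[rows, None, :], box_xy)
        dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        mask = np.arange(n)[None, :] > rows[:, None]
        yield rows, dist[mask], d[mask]


@dataclass(frozen=True)
class RadialDistribution:
    """Pair histogram per reference bead per spherical-shell volume.

    ``counts`` has units nm^-3 when ``per_shell_volume`` (counts divided
    by N_ref * 4 pi r^2 dr) and is a raw per-reference-bead pair count
    otherwise. Deliberately *not* divided by a bulk density — the bead
    density in a grafted coating is strongly inhomogeneous, so a bulk
    normalization would be arbitrary.
    """

    r: np.ndarray                # bin centers, nm
    counts: np.ndarray
    bin_width: float
    normalization: str = "non-normalized"
    per_shell_volume: bool = True

    def peak_positions(self, n_peaks: int = 2) -> list[float]:
        """Bin centers of the largest local maxima, strongest first."""
        c = self.counts
        interior = (c[1:-1] >= c[:-2]) & (c[1:-1] >= c[2:]) & (c[1:-1] > 0)
        idx = np.where(interior)[0] + 1
        if c[0] > c[1]:
            idx = np.append(idx, 0)
        order = idx[np.argsort(c[idx])[::-1]]
        return [float(self.r[i]) for i in order[:n_peaks]]

    @property
    def first_peak(self) -> float:
        """Bin center of the global maximum."""
        return float(self.r[int(np.argmax(self.counts))])


def non_normalized_rdf(config: CoatingConfiguration, r_max: float = 1.0,
                       bin_width: float = 0.005, r_min: float = 0.0,
                       per_shell_volume: bool = True) -> RadialDistribution:
    """Bead-bead radial distribution function of a coating.

    All bead pairs (minimum image in x,y) within ``[r_min, r_max]`` are
    histogrammed; counts are divided by the number of reference beads
    and, by default, by the shell volume 4 pi r^2 dr — but not by any
    bulk density (see :class:`RadialDistribution`).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    beads = config.all_beads()
    n = len(beads)
    if n < 2:
        raise ValueError("need at least two beads for an RDF")
    edges = np.arange(r_min, r_max + bin_width * 0.5, bin_width)
    hist = np.zeros(len(edges) - 1)
    for rows, dist, _ in _pair_scan(beads, config.box[:2]):
        h, _ = np.histogram(dist, bins=edges)
        hist += h
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = 2.0 * hist / n  # both members of a pair act as reference bead
    if per_shell_volume:
        counts = counts / (4.0 * np.pi * centers**2 * bin_width)
    return RadialDistribution(r=centers, counts=counts, bin_width=bin_width,
                              per_shell_volume=per_shell_volume)


@dataclass(frozen=True)
class OrientationDistribution:
    """Angular surface density f(theta) of neighbours on a shell.

    theta is measured against the flow direction (+x) after projecting
    neighbour displacements into the chosen plane, ``(x,z)`` or
    ``(x,y)``. ``f`` is normalized by its bin-average, so the mean of f
    over bins is 1 by construction.
    """

    theta: np.ndarray            # bin centers, degrees
    f: np.ndarray
    plane: str
    shell_radius: float
    n_pairs: int


def orientation_distribution(config: CoatingConfiguration, shell_radius: float = 0.15,
                             shell_tol: float | None = None, plane: str = "xz",
                             bins: int = 18, slab_tol: float | None = None) -> OrientationDistribution:
    """Orientation distribution of neighbour beads at a given separation.

    For every bead, displacement vectors to neighbours with
    ``| |d| - shell_radius | <= shell_tol`` are kept; those lying within
    ``slab_tol`` of the projection plane through the reference bead
    (default half a bead radius) are projected into the plane and the
    angle to the flow direction (+x) is histogrammed on [0, 90] degrees
    (the distribution has the symmetry of the slab). The histogram is
    normalized by its mean.
    """
    if shell_radius <= 0:
        raise ValueError("shell radius must be positive")
    if plane not in ("xz", "xy"):
        raise ValueError("plane must be 'xz' or 'xy'")
    shell_tol = shell_radius * 0.1 if shell_tol is None else shell_tol
    slab_tol = 0.5 * config.bead_radius if slab_tol is None else slab_tol
    beads = config.all_beads()
    kept = []
    for _, dist, d in _pair_scan(beads, config.box[:2]):
        sel = np.abs(dist - shell_radius) <= shell_tol
        if sel.any():
            kept.append(d[sel])
    disp = np.vstack(kept) if kept else np.empty((0, 3))
    disp = np.vstack([disp, -disp])  # both beads of a pair serve as reference
    out_axis = 1 if plane == "xz" else 2   # y is out of (x,z); z out of (x,y)
    in_axis = 2 if plane == "xz" else 1
    slab = np.abs(disp[:, out_axis]) <= slab_tol
    disp = disp[slab]
    edges = np.linspace(0.0, 90.0, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(disp) == 0:
        warnings.warn("no neighbours found in the shell; empty distribution", stacklevel=2)
        return OrientationDistribution(theta=centers, f=np.zeros(bins), plane=plane,
                                       shell_radius=shell_radius, n_pairs=0)
    theta = np.degrees(np.arctan2(np.abs(disp[:, in_axis]), np.abs(disp[:, 0])))
    hist, _ = np.histogram(theta, bins=edges)
    f = hist / hist.mean() if hist.mean() > 0 else hist.astype(float)
    return OrientationDistribution(theta=centers, f=f, plane=plane,
                                   shell_radius=shell_radius, n_pairs=len(disp) // 2)


# ---------------------------------------------------------------------------
# exposed far beads


def is_exposed(i: int, j: int, beads: np.ndarray, box_xy, d_occ: float) -> bool:
    """Whether beads i and j have an unobstructed line of sight.

    A third bead occludes the pair when its perpendicular distance to
    the open segment i-j is below the occlusion diameter ``d_occ`` and
    its projection falls strictly inside the segment (segment endpoints
    themselves never occlude). Displacements are minimum-imaged in x,y
    relative to bead i.
    """
    rel = _min_image(beads - beads[i], box_xy)   # positions relative to bead i
    ab = rel[j]
    L2 = float(ab @ ab)
    if L2 == 0.0:
        return True
    t = rel @ ab / L2
    inside = (t > 0.0) & (t < 1.0)
    inside[i] = inside[j] = False
    if not inside.any():
        return True
    perp = rel[inside] - t[inside, None] * ab[None, :]
    return not np.any(np.einsum("ij,ij->i", perp, perp) < d_occ**2)


@dataclass(frozen=True)
class FarBeadDistribution:
    """Mean exposed far-bead count per reference bead, per unit r.

    ``n_far`` carries units nm^-1: the integral of n_far(r) dr is the
    mean number of exposed far beads around a reference bead in the
    slab. ``r`` are bin centers (nm), all >= the near/far split radius.
    """

    r: np.ndarray
    n_far: np.ndarray
    reference_z: float
    d_occ: float
    degree: int
    n_reference: int

    def total(self) -> float:
        """Mean number of exposed far beads per reference bead."""
        return float(np.sum(self.n_far) * (self.r[1] - self.r[0]))


def exposed_far_beads(config: CoatingConfiguration, reference_z: float = 1.0,
                      slab_half_width: float = 0.15, r_max: float = 2.0,
                      bin_width: float = 0.1, r0: float = NEAR_FAR_SPLIT,
                      d_occ: float | None = None) -> FarBeadDistribution:
    """Count exposed far beads around reference beads in a z-slab.

    Reference beads are those with ``|z - reference_z| <= slab_half_width``.
    For each, partner beads at separation in [r0, r_max] are tested for
    exposure (no third bead within the occlusion diameter
    ``d_occ = 2 a0`` of the open connecting segment); exposed partners
    are histogrammed by separation. The result is the mean count per
    reference bead divided by the bin width.
    """
    if bin_width <= 0 or r_max <= r0:
        raise ValueError("need bin_width > 0 and r_max > r0")
    beads = config.all_beads()
    d_occ = 2.0 * config.bead_radius if d_occ is None else d_occ
    ref_idx = np.where(np.abs(beads[:, 2] - reference_z) <= slab_half_width)[0]
    if len(ref_idx) == 0:
        raise ValueError(f"no reference beads within {slab_half_width} nm of z = {reference_z} nm")
    edges = np.arange(r0, r_max + bin_width * 0.5, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(len(centers))
    for i in ref_idx:
        d = _min_image(beads - beads[i], config.box[:2])
        dist = np.sqrt(np.einsum("ij,ij->i", d, d))
        partners = np.where((dist >= r0) & (dist <= edges[-1]))[0]
        for j in partners:
            if j == i:
                continue
            if is_exposed(i, j, beads, config.box[:2], d_occ):
                k = min(int((dist[j] - r0) / bin_width), len(centers) - 1)
                hist[k] += 1.0
    n_far = hist / (len(ref_idx) * bin_width)
    return FarBeadDistribution(r=centers, n_far=n_far, reference_z=reference_z,
                               d_occ=d_occ, degree=config.degree,
                               n_reference=len(ref_idx))


# ---------------------------------------------------------------------------
# chain size and conformation


def gyration_radius(chain: np.ndarray) -> float:
    """Gyration radius: RMS distance of the beads from their centroid."""
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 2 or len(chain) < 2:
        raise ValueError("need at least two beads for a gyration radius")
    c = chain.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((chain - c) ** 2, axis=1))))


def scaling_exponent(mean_rg: dict[int, float]) -> tuple[float, float]:
    """Least-squares scaling exponent gamma of R_g ~ N^gamma.

    ``mean_rg`` maps chain length N to the ensemble-mean gyration
    radius. Returns (gamma, log-prefactor) from a straight-line fit of
    log R_g against log N; requires at least three chain lengths.
    """
    if len(mean_rg) < 3:
        raise ValueError("need at least three chain lengths to fit a scaling exponent")
    N = np.array(sorted(mean_rg))
    rg = np.array([mean_rg[n] for n in N])
    if np.any(rg <= 0):
        raise ValueError("gyration radii must be positive")
    gamma, logc = np.polyfit(np.log(N), np.log(rg), 1)
    return float(gamma), float(logc)


def classify_conformation(rg: float, graft_separation: float,
                          rtol: float = 1e-9) -> str:
    """Brush/mushroom classification of a grafted chain.

    A chain whose gyration radius exceeds the polymer-polymer (grafting)
    separation overlaps its neighbours and stretches into a brush;
    a smaller chain stays an isolated mushroom. Equality (within
    ``rtol``) is the crossover.
    """
    if rg <= 0 or graft_separation <= 0:
        raise ValueError("gyration radius and grafting separation must be positive")
    if abs(rg - graft_separation) <= rtol * graft_separation:
        return "crossover"
    return "brush" if rg > graft_separation else "mushroom"
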