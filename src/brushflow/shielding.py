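"""Additive far-bead hydrodynamic shielding model.

Near beads (the two bonded neighbours) already reduce the effective
Stokes radius of a bead to a_near ~ 0.18 a0. Far beads — beads of other
chains beyond the near/far split r0 — shield the flow further. Assuming
their contributions add independently, the orientation- and
distance-averaged effective radius at degree of polymerization N is

    a_bead(N) = a_near
        - int_0^{pi/2} d theta int_0^inf dr
              [a_near - a(r, theta)] P_far(r, theta; N),

where a(r, theta) is the tabulated radius of a bead with one shielding
far-bead pair at distance r and orientation theta (the shielding
kernel), and P_far(r, theta; N) = (1/2) n_far(r; N) sin(theta) weights
the kernel by the measured distribution of exposed far beads, assumed
isotropic. (Note the printed normalization: the theta-integral of P_far
is n_far/2, not n_far.)

The kernel saturates at a_near beyond a shielding radius r_s, the
distance past which far beads no longer matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import NEAR_FAR_SPLIT, FarBeadDistribution

__all__ = [
    "ShieldingKernel",
    "FarBeadWeight",
    "build_pfar",
    "effective_radius",
    "parametric_kernel",
    "shielding_radius",
    "radius_vs_N",
    "read_kernel_csv",
    "write_kernel_csv",
    "NEAR_BEAD_RADIUS_OVER_A0",
]

#: effective radius from near-bead shielding alone, in units of a0
NEAR_BEAD_RADIUS_OVER_A0 = 0.18


@dataclass(frozen=True)
class ShieldingKernel:
    """Central-bead Stokes radius a(r, theta_far) on an (r, theta) grid.

    ``values[i, j]`` is the radius (nm) with the shielding far-bead pair
    at distance ``r[i]`` and orientation ``theta[j]`` (degrees, against
    the flow). ``a_near`` is the saturation value: the radius when far
    beads are absent or beyond the shielding radius.
    """

    r: np.ndarray                # nm, increasing
    theta: np.ndarray            # degrees, increasing, within [0, 90]
    values: np.ndarray           # (len(r), len(theta)), nm
    a_near: float                # nm

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        th = np.asarray(self.theta, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "theta", th)
        object.__setattr__(self, "values", v)
        if v.shape != (r.size, th.size):
            raise ValueError("kernel values shape must be (len(r), len(theta))")
        if np.any(np.diff(r) <= 0) or np.any(np.diff(th) <= 0):
            raise ValueError("kernel grids must be strictly increasing")
        if th[0] < 0 or th[-1] > 90:
            raise ValueError("theta grid must lie within [0, 90] degrees")
        if self.a_near <= 0:
            raise ValueError("near-bead radius must be positive")
        if np.any(v < 0) or np.any(v > self.a_near * (1 + 1e-9)):
            raise ValueError("kernel values must lie in [0, a_near]")


@dataclass(frozen=True)
class FarBeadWeight:
    """Separable far-bead weight P_far(r, theta) = (1/2) n_far(r) sin(theta)."""

    r: np.ndarray
    theta: np.ndarray            # degrees
    values: np.ndarray           # (len(r), len(theta)), nm^-1 rad^-1

    def mass(self) -> float:
        """Total weight, double trapezoidal integral of P_far dr dtheta."""
        inner = np.trapezoid(self.values, np.radians(self.theta), axis=1)
        return float(np.trapezoid(inner, self.r))


def build_pfar(n_far: FarBeadDistribution | tuple[np.ndarray, np.ndarray],
               kernel: ShieldingKernel) -> FarBeadWeight:
    """Place a far-bead distribution on the kernel grid as P_far.

    ``n_far`` is either a :class:`FarBeadDistribution` or an (r, n_far)
    pair; it is linearly interpolated onto the kernel's r grid (zero
    outside its support) and combined with the isotropic angular factor
    (1/2) sin(theta).
    """
    if isinstance(n_far, FarBeadDistribution):
        r_in, v_in = n_far.r, n_far.n_far
    else:
        r_in, v_in = (np.asarray(a, dtype=float) for a in n_far)
    if np.any(v_in < 0):
        raise ValueError("n_far must be non-negative")
    nf = np.interp(kernel.r, r_in, v_in, left=0.0, right=0.0)
    sin_t = np.sin(np.radians(kernel.theta))
    values = 0.5 * nf[:, None] * sin_t[None, :]
    return FarBeadWeight(r=kernel.r, theta=kernel.theta, values=values)


def effective_radius(kernel: ShieldingKernel, weight: FarBeadWeight) -> float:
    """Additive-shielding average: the effective radius a_bead in nm.

    Double trapezoidal quadrature of the deficit
    [a_near - a(r, theta)] P_far(r, theta) over the kernel grid,
    subtracted from a_near. A negative result (far-bead mass so large
    that additivity breaks down) is clamped to zero with a warning, as
    is a total weight mass above one.
    """
    if weight.r.shape != kernel.r.shape or not np.allclose(weight.r, kernel.r):
        raise ValueError("weight and kernel must share the r grid")
    if weight.theta.shape != kernel.theta.shape or not np.allclose(weight.theta, kernel.theta):
        raise ValueError("weight and kernel must share the theta grid")
    if weight.mass() > 1.0 + 1e-12:
        warnings.warn("total far-bead weight exceeds 1; the additive-shielding "
                      "assumption is strained", stacklevel=2)
    deficit = (kernel.a_near - kernel.values) * weight.values
    inner = np.trapezoid(deficit, np.radians(kernel.theta), axis=1)
    a = kernel.a_near - float(np.trapezoid(inner, kernel.r))
    if a < 0:
        warnings.warn("additive shielding drove the effective radius below zero; "
                      "clamping to 0 (model validity exceeded)", stacklevel=2)
        a = 0.0
    return a


def parametric_kernel(a_near: float, depth: float = 0.8, decay: float = 0.3,
                      angular=None, r0: float = NEAR_FAR_SPLIT, r_max: float = 3.0,
                      n_r: int = 61, n_theta: int = 19) -> ShieldingKernel:
    """Model kernel a(r, theta) = a_near [1 - depth e^{-(r-r0)/decay} g(theta)].

    Captures the qualitative shape of the measured kernel: strongest
    shielding for close far beads aligned with the flow, decaying over a
    length ``decay`` (nm) and saturating at a_near; ``g`` (default
    cos^2) decreases from g(0) = 1 toward theta = 90 deg, where far
    beads perpendicular to the flow barely shield. Values are clipped at
    zero. ``depth`` must lie in [0, 1].
    """
    if decay <= 0:
        raise ValueError("decay length must be positive")
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    g = angular if angular is not None else (lambda th_deg: np.cos(np.radians(th_deg)) ** 2)
    r = np.linspace(r0, r_max, n_r)
    theta = np.linspace(0.0, 90.0, n_theta)
    vals = a_near * (1.0 - depth * np.exp(-(r[:, None] - r0) / decay) * g(theta)[None, :])
    return ShieldingKernel(r=r, theta=theta, values=np.clip(vals, 0.0, a_near), a_near=a_near)


def shielding_radius(kernel: ShieldingKernel, tol: float = 0.05) -> np.ndarray:
    """Shielding radius r_s per theta column.

    The smallest grid r from which the kernel stays within
    ``tol * a_near`` of its saturation value a_near at all larger r. If
    a column never converges on the grid, the largest grid r is returned
    for it with a warning.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    dev = np.abs(kernel.values - kernel.a_near) <= tol * kernel.a_near
    rs = np.empty(kernel.theta.size)
    unconverged = False
    for j in range(kernel.theta.size):
        ok = dev[:, j]
        # last index before which some deviation persists
        bad = np.where(~ok)[0]
        if len(bad) == 0:
            rs[j] = kernel.r[0]
        elif bad[-1] == len(kernel.r) - 1:
            rs[j] = kernel.r[-1]
            unconverged = True
        else:
            rs[j] = kernel.r[bad[-1] + 1]
    if unconverged:
        warnings.warn("kernel does not saturate within the r grid for some "
                      "orientations; returning the grid maximum", stacklevel=2)
    return rs


def radius_vs_N(kernel: ShieldingKernel,
                n_far_by_N: dict[int, FarBeadDistribution | tuple]) -> dict[int, float]:
    """Effective radius per degree of polymerization.

    Applies the additive-shielding average to each far-bead curve;
    warns when the resulting radii are not monotone non-increasing in N
    while the far-bead populations grow.
    """
    if len(n_far_by_N) < 2:
        raise ValueError("need far-bead curves for at least two N values")
    out = {int(N): effective_radius(kernel, build_pfar(nf, kernel))
           for N, nf in sorted(n_far_by_N.items())}
    radii = list(out.values())
    if any(radii[i + 1] > radii[i] + 1e-12 for i in range(len(radii) - 1)):
        warnings.warn("effective radius is not monotone in N; far-bead curves "
                      "may not be nested", stacklevel=2)
    return out


def read_kernel_csv(path, a_near: float | None = None) -> ShieldingKernel:
    """Read a kernel CSV with columns r_nm,theta_deg,a_bead_nm.

    Rows must form a complete (r, theta) grid. ``a_near`` defaults to
    the maximum tabulated value (the saturation plateau).
    """
    df = pd.read_csv(path)
    for col in ("r_nm", "theta_deg", "a_bead_nm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    r = np.array(sorted(df["r_nm"].unique()))
    theta = np.array(sorted(df["theta_deg"].unique()))
    piv = df.pivot_table(index="r_nm", columns="theta_deg", values="a_bead_nm")
    if piv.isna().any().any():
        raise ValueError(f"{path}: rows do not form a complete (r, theta) grid")
    values = piv.loc[r, theta].to_numpy()
    return ShieldingKernel(r=r, theta=theta, values=values,
                           a_near=float(values.max()) if a_near is None else a_near)


def write_kernel_csv(kernel: ShieldingKernel, path) -> None:
    """Write a kernel as long-format CSV (r_nm,theta_deg,a_bead_nm)."""
    rows = [(r, t, kernel.values[i, j])
            for i, r in enumerate(kernel.r) for j, t in enumerate(kernel.theta)]
    pd.DataFrame(rows, columns=["r_nm", "theta_deg", "a_bead_nm"]).to_csv(path, index=False)
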