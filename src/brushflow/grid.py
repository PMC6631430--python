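"""Scalar fields sampled on a uniform grid across the slit.

The slit coordinate z runs from 0 (center of the innermost bottom-wall
layer) to the slit width w. Every profile consumed or produced by the
package — bead number density n(z), ionic concentrations c_i(z),
viscosity mu(z), volume fraction phi(z), velocity u(z) — is a
:class:`GridProfile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridProfile", "read_profile", "write_profile", "resample"]

#: relative tolerance for grid-uniformity checks
_UNIFORM_RTOL = 1e-8


@dataclass(frozen=True)
class GridProfile:
    """A scalar field tabulated on a strictly increasing uniform z-grid.

    Parameters
    ----------
    z :
        Grid positions in nm, uniform, strictly increasing, length >= 3.
    values :
        Field values at the grid points; NaN-free, same length as ``z``.
    unit :
        Free-form unit tag (e.g. ``"nm^-3"``, ``"mol/L"``, ``"m/s"``).
    """

    z: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "values", v)
        if z.ndim != 1 or z.size < 3:
            raise ValueError("grid must be 1D with at least 3 points")
        if v.shape != z.shape:
            raise ValueError("values shape does not match grid shape")
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise ValueError("grid must be strictly increasing")
        h = dz[0]
        if not np.allclose(dz, h, rtol=_UNIFORM_RTOL, atol=_UNIFORM_RTOL * max(abs(h), 1.0)):
            raise ValueError("grid must be uniform; resample before constructing a GridProfile")
        if np.any(~np.isfinite(v)) or np.any(~np.isfinite(z)):
            raise ValueError("profile contains NaN or Inf")

    @property
    def spacing(self) -> float:
        """Grid spacing h in nm."""
        return float(self.z[1] - self.z[0])

    def __len__(self) -> int:
        return int(self.z.size)

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "GridProfile":
        """Return a new profile on the same grid with different values."""
        return GridProfile(self.z, np.asarray(values, dtype=float),
                           self.unit if unit is None else unit)

    def same_grid(self, other: "GridProfile") -> bool:
        return self.z.shape == other.z.shape and np.allclose(
            self.z, other.z, rtol=_UNIFORM_RTOL, atol=1e-12)

    def integral(self) -> float:
        """Trapezoidal integral of the values over z (z in nm)."""
        return float(np.trapezoid(self.values, self.z))


def resample(profile: GridProfile, z_new: np.ndarray) -> GridProfile:
    """Linearly interpolate a profile onto a new uniform grid.

    Values outside the original grid are held at the boundary values
    (appropriate for profiles that are flat near the slit walls' bin
    centers, e.g. binned densities).
    """
    z_new = np.asarray(z_new, dtype=float)
    v = np.interp(z_new, profile.z, profile.values)
    return GridProfile(z_new, v, profile.unit)


def read_profile(path, unit: str = "") -> GridProfile:
    """Read a two-column text profile ("z value" per row).

    Lines starting with ``#`` or ``@`` (xvg-style) are ignored. A header
    comment of the form ``# z[nm] value[unit]`` sets the unit tag unless
    one is passed explicitly. Non-uniform or decreasing grids are rejected
    with a hint to resample.
    """
    z_col, v_col = [], []
    header_unit = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(("#", "@")):
                if "[" in s and "]" in s and not header_unit:
                    # last bracketed token, e.g. "# z[nm] u[m/s]" -> "m/s"
                    header_unit = s.rsplit("[", 1)[1].split("]", 1)[0]
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns, got {s!r}")
            try:
                z_col.append(float(parts[0]))
                v_col.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric row {s!r}") from exc
    z = np.array(z_col)
    v = np.array(v_col)
    try:
        return GridProfile(z, v, unit or header_unit)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc} (resample onto a uniform increasing grid)") from exc


def write_profile(profile: GridProfile, path, value_label: str = "value") -> None:
    """Write a profile as two-column text with a ``# z[nm] value[unit]`` header.

    Uses full double precision so a write/read round trip is exact.
    """
    with open(path, "w") as fh:
        fh.write(f"# z[nm] {value_label}[{profile.unit}]\n")
        for zi, vi in zip(profile.z, profile.values):
            fh.write(f"{float(zi)!r} {float(vi)!r}\n")
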