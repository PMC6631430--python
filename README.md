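# brushflow

Electro-osmotic flow (EOF) screening by grafted polymer coatings.

Channels and nanocarriers are routinely coated with end-grafted polymers
(PEG brushes and mushrooms) to tune transport. A long-standing puzzle in
modelling such coatings as porous media is that the *effective
hydrodynamic (Stokes) radius* of a polymer bead, `a_bead`, inferred from
flow data, is roughly an order of magnitude smaller than its physical
radius `a0`, and varies with the degree of polymerization `N`.
`brushflow` implements the continuum/structural analysis chain used to
study this effect: a 1D Navier-Stokes-Brinkman (NSB) flow solver,
Stokes-radius inference, coating-structure statistics, and an additive
far-bead shielding model — together with a synthetic-data generator that
emulates the molecular-simulation outputs the analysis normally consumes.

## The model

The steady EOF velocity `u(z)` across a slit of width `w` (walls at
`z = 0, w`) obeys the NSB equation

    d/dz[ μ(z) du/dz ] − 6π μ(z) n(z) a_bead K(φ(z)) u(z) + ρ_e(z) E_ext = 0

with no slip at the walls and mirror symmetry at mid-slit, where

- `μ(z) = μ0 (1 + 2.5 φ(z))` — Einstein viscosity at bead volume
  fraction `φ = (4π/3) a0³ n(z)`,
- `n(z)` — polymer bead number density, `a_bead` — the effective Stokes
  radius of a bead, `K(φ)` — a hindered-drag correction (`K(0) = 1`),
- `ρ_e = F Σ_i z_i c_i(z)` — ionic charge density of the double layer,
  driven by the applied field `E_ext`.

`a_bead` is the single free parameter: it is fitted by matching the NSB
velocity profile to an observed one. The structural side of the analysis
explains its smallness: the two bonded neighbours of a bead already cut
its radius to `a_near ≈ 0.18 a0`, and "far" beads (other chains, beyond
`r0 = 0.3 nm`) with an unobstructed line of sight shield it further. The
additive far-bead average

    a_bead(N) = a_near − ∫∫ [a_near − a(r, θ)] P_far(r, θ; N) dr dθ,
    P_far = ½ n_far(r; N) sin θ,

combines a shielding kernel `a(r, θ)` with the measured distribution
`n_far(r)` of exposed far beads, reproducing the decrease of `a_bead`
with `N`.

## Worked example

```sh
python examples/03_flow_and_radius_fit.py
```

```
mid-slit velocity with the coating: -0.3460 m/s
without bead drag (a_bead = 0):     -0.7292 m/s
the coating screens the flow by a factor 2.11
refitted a_bead = 0.019000 nm (planted 0.019 nm, = 0.122 a0, residual 9.67e-09 m/s)
```

The script builds an N = 14 brush scenario (parabolic bead-density
profile on a 2.5 nm grafting lattice, Gouy-Chapman double layers at
σ_s = 3.28×10⁻² C/m², E_ext = 1.6×10⁻² V/nm), forward-solves the NSB
equation with a planted bead radius of 0.019 nm, and refits the radius
from the velocity profile alone. The fitted 0.019 nm — an order of
magnitude below the physical radius a0 = 0.156 nm — is recovered to
eight significant digits, and the mid-slit velocities show the coating
halving the EOF.

The other examples cover the double layer (`01`), coating generation and
structure statistics (`02`), self-avoiding-walk gyration scaling via the
pivot algorithm (`04`, ν ≈ 0.59 with excluded volume, 0.50 without) and
the far-bead shielding average (`05`). A thin CLI wraps the same stages
(`brushflow demo-n14 --seed 1 --out demo.json` runs the full round trip).

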