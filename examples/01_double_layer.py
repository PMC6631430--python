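"""Electric double layer in a charged slit.

Builds the analytic Gouy-Chapman ion profiles for a 1:1 electrolyte
between two positively charged walls and checks the global charge
balance: the ionic space charge must exactly compensate both wall
charges.
"""

import brushflow as bf
from brushflow.constants import NM
from brushflow.nsb import charge_density

spec = bf.ElectrolyteSpec()  # 0.034 mol/L, sigma_s = 3.28e-2 C/m^2, eps = 78, 300 K
print(f"Debye length: {bf.debye_length(spec):.3f} nm")

ions = bf.gouy_chapman_profiles(spec, w=20.0, n_grid=4001)
print(f"anion concentration at the wall:   {ions[-1].values[0]:.4f} mol/L")
print(f"cation concentration at the wall:  {ions[+1].values[0]:.4f} mol/L")
print(f"both at mid-slit:                  {ions[-1].values[2000]:.4f} mol/L")

total = charge_density(ions).integral() * NM  # C/m^2
print(f"integrated fluid charge: {total:.3e} C/m^2 "
      f"(wall charge to balance: {-2 * spec.surface_charge:.3e})")
# The diffuse-layer charge equals minus the charge of the two walls:
# the slit as a whole is electroneutral.
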