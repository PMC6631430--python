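"""Physical constants (SI) and unit-conversion factors.

Inputs throughout the package follow molecular-simulation conventions
(lengths in nm, concentrations in mol/L, fields in V/nm, forces in
kJ/(mol nm)); everything is converted to SI internally and velocities are
reported in m/s.
"""

from scipy import constants as _sc

#: Elementary charge [C]
E_CHARGE = _sc.e
#: Boltzmann constant [J/K]
K_B = _sc.k
#: Avogadro constant [1/mol]
N_A = _sc.N_A
#: Faraday constant [C/mol]
FARADAY = _sc.physical_constants["Faraday constant"][0]
#: Vacuum permittivity [F/m]
EPS0 = _sc.epsilon_0

#: nm -> m
NM = 1e-9
#: mol/L -> mol/m^3
MOLAR_TO_MOL_M3 = 1e3
#: V/nm -> V/m
V_PER_NM = 1e9
#: kJ/(mol nm) -> N (per molecule)
KJ_MOL_NM_TO_N = 1e3 / N_A / NM
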