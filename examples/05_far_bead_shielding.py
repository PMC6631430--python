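"""Additive far-bead shielding of the effective bead radius.

Combines a model shielding kernel a(r, theta) — the Stokes radius of a
bead with one far-bead pair at distance r and orientation theta — with
far-bead distributions of increasing density, mimicking growing degree
of polymerization: more exposed far beads mean stronger shielding and a
smaller effective radius.
"""

import numpy as np

import brushflow as bf

a0 = 0.156
a_near = 0.18 * a0  # shielding by the two bonded neighbours alone
kernel = bf.parametric_kernel(a_near, depth=0.8, decay=0.3)

rs = bf.shielding_radius(kernel, tol=0.05)
print(f"shielding radius: {rs[0]:.2f} nm along the flow, "
      f"{rs[-1]:.2f} nm perpendicular to it")

# far-bead curves growing with N (exponential falloff beyond r0 = 0.3 nm)
curves = {N: (kernel.r, 0.08 * N * np.exp(-(kernel.r - 0.3) / 0.3)) for N in
          (2, 5, 10, 14, 20, 28)}
table = bf.radius_vs_N(kernel, curves)
print("N    a_bead [nm]   a_bead / a0")
for N, a in table.items():
    print(f"{N:<4d} {a:.5f}       {a / a0:.3f}")
# With no far beads the average returns a_near = 0.18 a0; every exposed
# far bead chips away at the radius, so a_bead falls as N grows.
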