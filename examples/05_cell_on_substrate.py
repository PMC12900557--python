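"""Shape-dependent contractility predictions on the substrate.

Solves the cell-on-substrate model for the rectangular (capped
half-cylinder) and circular (equal-volume half-sphere) geometries in
contracted and relaxed states, and prints the three readouts that the
image analysis measures: order parameter, alpha-actinin volumetric
strain, and peak substrate traction.
"""

import numpy as np

from sarcomech.mech import ModelParams
from sarcomech.mech.fem import solve_contractility
from sarcomech.mech.geometry import GeometrySpec
from sarcomech.mech.readouts import (actinin_volumetric_strain,
                                     stress_order_parameter)

for kind in ("rect", "circ"):
    for state, rho0 in (("contracted", 2.0), ("relaxed", 0.01)):
        sol = solve_contractility(GeometrySpec(kind=kind),
                                  ModelParams(rho0=rho0))
        S = stress_order_parameter(sol).S_sim
        e2 = actinin_volumetric_strain(sol)
        tmax = np.linalg.norm(sol.iface_traction, axis=1).max() * 1e3
        print(f"{kind:4s} {state:10s}  S_sim={S:6.3f}  "
              f"<eps2_kk>={e2: .5f}  max traction={tmax:7.1f} Pa")
print("rectangles align stress (S near 1), strain alpha-actinin more, and")
print("pull hardest at their ends; relaxed cells barely load the substrate.")
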