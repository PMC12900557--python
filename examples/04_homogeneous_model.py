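"""The chemo-mechanical feedback law in a homogeneous (0-D) setting.

Prints the feedback-renormalised and series-effective moduli for the
contracted-state parameters, then the self-consistent traction-free
state: an unconstrained contracting cell reaches a negative volumetric
strain of -rho_eff_v / K_eff.
"""

import numpy as np

from sarcomech.mech import (CONTRACTED, homogeneous_fixed_point,
                            sarcomere_effective)

dm = sarcomere_effective(CONTRACTED)
print(f"K_bar  = {dm.K_bar:.4f} kPa   mu_bar  = {dm.mu_bar:.4f} kPa")
print(f"K_eff  = {dm.K_eff:.4f} kPa   mu_eff  = {dm.mu_eff:.4f} kPa")
print(f"rho_eff_v = {dm.rho_eff_v:.4f} kPa   2*rho_eff_a = {dm.two_rho_eff_a:.4f}")

state = homogeneous_fixed_point(CONTRACTED, "traction-free")
print(f"traction-free volumetric strain = {np.trace(state.eps):.4f} "
      f"(= -rho_eff_v/K_eff = {-dm.rho_eff_v/dm.K_eff:.4f})")
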