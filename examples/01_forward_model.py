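"""Forward model: powder-averaged signal decay of fixed white matter.

Builds the 8-shell ex vivo protocol (b = 1 ... 43 ms/µm², δ = 11 ms,
Δ = 15 ms), evaluates the three-compartment spherical-mean signal for a
macaque-like tissue state, and prints the decay curve.  The signal falls
from ~0.86 at b = 1 toward the dot-compartment floor (f_dot = 0.1) at the
highest b-value — the non-decaying floor is the signature of fixed tissue.
"""

import numpy as np

from axomyelin import (
    GAMMA_PROTON,
    bvalue_from_gradients,
    default_exvivo_protocol,
    model_signal,
)
from axomyelin.synthetic import preset_tissue_params

protocol = default_exvivo_protocol()
theta = preset_tissue_params("macaque", d_a=4.0)

b_max = bvalue_from_gradients(GAMMA_PROTON, delta=11.0, Delta=15.0, G=660.0)
print(f"maximum b at 660 mT/m: {b_max:.2f} ms/um^2 (shell table tops at 43)")

signal = model_signal(theta, protocol)
print("\n b (ms/um^2)   G (mT/m)   S(b)/S(0)")
for shell, s in zip(protocol.shells, signal.means):
    print(f"  {shell.b_value:8.1f}   {shell.gradient_strength:8.1f}   {s:.4f}")
print(f"\n dot-compartment floor f_dot = {theta.f_dot}: the curve levels off"
      f" near {signal.means[-1]:.3f} at b = {protocol.b_values[-1]}")
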