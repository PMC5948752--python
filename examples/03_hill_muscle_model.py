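"""Hill-type musculotendon model landmarks.

Loads the shipped elbow flexor (pooled biceps group) and extensor (pooled
triceps group) constants and prints the characteristic points of the
force-length, force-velocity and pennation relations, plus a tendon-force
inversion round trip.
"""

import numpy as np

from emgelbow import (
    default_params,
    force_length,
    force_velocity,
    inverse_activation,
    pennation,
    tendon_force,
)

for name in ("biceps", "triceps"):
    p = default_params(name)
    print(f"{name}: Fmax = {p.fmax:.2f} N, LMo = {p.lmo*100:.2f} cm, "
          f"phi_o = {p.phi_o:.4f} rad, LdotMmax = {p.ldotmmax:.3f} m/s")
    print(f"  Ffl(LMo) = {force_length(p.lmo, p):.3f}, "
          f"Ffl(LMo*(1+W)) = {force_length(p.lmo*(1+p.w), p):.5f}  (= 1/e)")
    print(f"  Ffv(0) = {force_velocity(0.0, p):.3f}, "
          f"Ffv(-LdotMmax) = {force_velocity(-p.ldotmmax, p):.3f}, "
          f"Ffv(+0.2 m/s) = {force_velocity(0.2, p):.3f}  (eccentric, < gmax={p.gmax})")
    print(f"  pennation at LMo: {pennation(p.lmo, p):.4f} rad")

# inversion round trip at a mid-range elbow angle
p = default_params("biceps")
state = p.state(np.deg2rad(70.0), theta_dot=0.3)
for a in (0.1, 0.5, 0.9):
    f = tendon_force(a, state, p)
    a_back = inverse_activation(f, state, p)
    print(f"a = {a:.1f} -> tendon force {f:7.1f} N -> inverted a = {a_back:.6f}")
# the Hill model is affine in activation, so the inversion used by the
# study's control-activation derivation is exact to machine precision
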