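"""Inverse dynamics of one elbow motion.

Generates a flexion-extension trajectory, decomposes the joint moment into
inertial, damping, gravity and (required) muscle parts, and derives the
control total muscle activation through the single flexor-equivalent unit.
"""

import numpy as np

from emgelbow import (
    SkeletalParameters,
    default_params,
    derive_control_activation,
    differentiate,
    gravity_moment,
)
from emgelbow.synthetic import MotionProtocolEntry, generate_trajectory

sk = SkeletalParameters(body_mass=70.0, forearm_length=0.25)
flexor = default_params("biceps")

theta = generate_trajectory(MotionProtocolEntry("FE", 0, 0.0), seed=0)
theta_dot, theta_ddot = differentiate(theta)

m_inertial = sk.inertia() * theta_ddot.values
m_damping = -sk.b * theta_dot.values
m_gravity = gravity_moment(theta.values, sk)
m_req = -(m_inertial + m_damping + m_gravity)

print(f"trajectory: {theta.duration:.1f} s, "
      f"peak angle {np.rad2deg(theta.values).max():.1f} deg, "
      f"peak velocity {np.abs(theta_dot.values).max():.2f} rad/s")
print(f"moment magnitudes (N*m): inertial {np.abs(m_inertial).max():.3f}, "
      f"damping {np.abs(m_damping).max():.3f}, gravity {np.abs(m_gravity).max():.3f}")
print(f"required muscle torque: {m_req.min():.2f} .. {m_req.max():.2f} N*m")

a_ti = derive_control_activation(
    theta.with_values(m_req, units_label="N*m"), theta, theta_dot, flexor
)
print(f"control activation a_TI: {a_ti.values.min():.4f} .. {a_ti.values.max():.4f}")
# at this slow, unloaded speed gravity dominates; the flexor-equivalent unit
# needs only a few percent of its maximum activation to drive the motion
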