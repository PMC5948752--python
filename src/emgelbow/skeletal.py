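"""Single degree-of-freedom elbow rigid-body dynamics.

Joint convention: theta = 0 at full extension, flexion positive, radians.
In the default "vertical" posture the upper arm is fixed and the forearm
hangs vertically at theta = 0, so the gravity lever arm is sin(theta); the
"horizontal" posture (motion in a horizontal plane) zeroes gravity entirely.

The equation of motion sums joint moments

    M_joint = I*theta_ddot + Mp + Mg + sum_i r_i * F_RTE_i

with Mp = -b*theta_dot (pure damping), Mg the gravity moment of forearm,
hand and any held mass, and r_i the tendon-excursion moment arms
r = -dLMT/dtheta (flexor positive). Segment mass and centre-of-mass location
come from Winter's anthropometric proportionality tables; inertia from a
solid cylinder rotating about its end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .timeseries import TimeSeries

__all__ = [
    "SkeletalParameters",
    "TorqueDecomposition",
    "moment_arm",
    "passive_joint_torque",
    "gravity_moment",
    "inertia_cylinder",
    "joint_torque",
]

#: Winter anthropometry: forearm+hand mass fraction of body mass, and
#: forearm+hand COM location as a fraction of forearm length (proximal).
WINTER_MASS_FRACTION = 0.022
WINTER_COM_FRACTION = 0.682
FOREARM_RADIUS_M = 0.04


@dataclass(frozen=True)
class SkeletalParameters:
    """Anthropometry-derived rigid-body constants of the forearm."""

    body_mass: float                      # kg
    forearm_length: float                 # m
    forearm_mass_fraction: float = WINTER_MASS_FRACTION
    com_fraction: float = WINTER_COM_FRACTION
    forearm_radius: float = FOREARM_RADIUS_M
    b: float = 1.0                        # joint damping, N*m*s/rad
    gravity: float = 9.81                 # m/s^2
    posture: str = "vertical"             # "vertical" or "horizontal"
    held_mass_lever: float | None = None  # defaults to forearm_length

    def __post_init__(self) -> None:
        for key in ("body_mass", "forearm_length", "forearm_mass_fraction",
                    "com_fraction", "forearm_radius", "b", "gravity"):
            if not getattr(self, key) > 0:
                raise InvalidParameterError(f"{key} must be positive")
        if self.posture not in ("vertical", "horizontal"):
            raise InvalidParameterError("posture must be 'vertical' or 'horizontal'")
        if self.held_mass_lever is None:
            object.__setattr__(self, "held_mass_lever", self.forearm_length)

    @property
    def forearm_mass(self) -> float:
        """Forearm + hand mass, kg."""
        return self.forearm_mass_fraction * self.body_mass

    @property
    def com_distance(self) -> float:
        """Forearm + hand centre of mass distance from the elbow, m."""
        return self.com_fraction * self.forearm_length

    def inertia(self, held_mass: float = 0.0) -> float:
        """Total rotating inertia about the elbow axis, kg*m^2.

        Forearm as a solid cylinder about its end plus the held mass as a
        point mass at its lever arm.
        """
        i_arm = inertia_cylinder(self.forearm_mass, self.forearm_length, self.forearm_radius)
        return i_arm + held_mass * self.held_mass_lever**2


@dataclass(frozen=True)
class TorqueDecomposition:
    """Per-sample split of the joint moment; the parts sum to the total."""

    m_inertial: np.ndarray
    m_passive: np.ndarray
    m_gravity: np.ndarray
    m_muscle: np.ndarray

    @property
    def m_joint(self) -> np.ndarray:
        return self.m_inertial + self.m_passive + self.m_gravity + self.m_muscle


def moment_arm(theta, lmt_coeffs):
    """Tendon-excursion moment arm r = -dLMT/dtheta, metres.

    Evaluated analytically from the path-length polynomial; a muscle whose
    path shortens with flexion (the flexor) gets a positive moment arm, so
    positive force produces a flexion moment.
    """
    d = np.polynomial.polynomial.polyder(np.asarray(lmt_coeffs, dtype=float))
    r = -np.polynomial.polynomial.polyval(theta, d)
    return float(r) if np.ndim(theta) == 0 else r


def passive_joint_torque(theta_dot, b: float = 1.0):
    """Damping-only passive joint torque Mp = -b * theta_dot, N*m."""
    out = -b * np.asarray(theta_dot, dtype=float)
    return float(out) if np.ndim(theta_dot) == 0 else out


def gravity_moment(theta, sk: SkeletalParameters, held_mass: float = 0.0):
    """Gravity moment about the elbow, N*m (zero in the horizontal posture).

    Mg = -g * sin(theta) * (m_forearm*d_com + m_held*L); gravity opposes
    flexion over the whole range in the vertical posture.
    """
    if held_mass < 0:
        raise InvalidParameterError("held_mass must be >= 0")
    th = np.asarray(theta, dtype=float)
    if sk.posture == "horizontal":
        out = np.zeros_like(th)
    else:
        lever = sk.forearm_mass * sk.com_distance + held_mass * sk.held_mass_lever
        out = -sk.gravity * np.sin(th) * lever
    return float(out) if np.ndim(theta) == 0 else out


def inertia_cylinder(mass: float, length: float, radius: float) -> float:
    """Solid cylinder rotating about one end: I = m*(L^2/3 + r^2/4), kg*m^2."""
    if mass <= 0 or length <= 0 or radius <= 0:
        raise InvalidParameterError("mass, length and radius must be positive")
    return mass * (length**2 / 3.0 + radius**2 / 4.0)


def joint_torque(
    theta: TimeSeries,
    theta_dot: TimeSeries,
    theta_ddot: TimeSeries,
    muscle_forces: list[np.ndarray],
    moment_arms: list[np.ndarray],
    sk: SkeletalParameters,
    held_mass: float = 0.0,
) -> TorqueDecomposition:
    """Assemble the summation-of-moments decomposition for aligned series."""
    n = theta.n
    if theta_dot.n != n or theta_ddot.n != n:
        raise ValueError("kinematic series must be aligned")
    m_muscle = np.zeros(n)
    for force, arm in zip(muscle_forces, moment_arms, strict=True):
        force = np.asarray(force, dtype=float)
        arm = np.asarray(arm, dtype=float)
        if force.shape != (n,):
            raise ValueError("muscle force series misaligned with kinematics")
        m_muscle = m_muscle + np.broadcast_to(arm * force, (n,))
    return TorqueDecomposition(
        m_inertial=sk.inertia(held_mass) * theta_ddot.values,
        m_passive=passive_joint_torque(theta_dot.values, sk.b),
        m_gravity=gravity_moment(theta.values, sk, held_mass),
        m_muscle=m_muscle,
    )
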