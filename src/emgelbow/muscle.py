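"""Hill-type musculotendon model with a rigid tendon.

Active force:   F_MCE = a * Fmax * Ffl(LM) * Ffv(dLM/dt)
Passive force:  F_MEE = k1*(LM-LS) [+ k2*(LM-LS)^2 above slack]
Tendon force:   F_RTE = (F_MCE + F_MEE) * cos(phi)

with a Gaussian force-length curve, a Hill force-velocity curve whose
eccentric branch is blended through the constant cd so that dFfv/dv is
continuous at v = 0, and a constant-volume pennation relation
sin(phi) = LMo * sin(phi_o) / LM.

The tendon is rigid: joint kinematics map directly onto fibre kinematics
through the shipped length-angle polynomials, so no tendon state needs to be
integrated. Because the model is affine in activation, it inverts in closed
form — ``inverse_activation`` is the algebraic inverse of ``tendon_force``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

from .errors import IndeterminateStateError, InvalidGeometryError, InvalidParameterError

__all__ = [
    "MusculotendonParameters",
    "MuscleKinematicState",
    "load_muscle_defaults",
    "default_params",
    "force_length",
    "force_velocity",
    "passive_force",
    "pennation",
    "tendon_force",
    "inverse_activation",
    "muscle_length",
    "musculotendon_length",
]

_JOINT_RANGE = (0.0, np.deg2rad(150.0))


def _polyval(coeffs, theta):
    """Ascending-power polynomial evaluation."""
    return np.polynomial.polynomial.polyval(theta, np.asarray(coeffs, dtype=float))


def muscle_length(theta, coeffs):
    """Fibre length LM(theta) in metres from an ascending-power polynomial."""
    lm = _polyval(coeffs, theta)
    if np.any(lm <= 0.0):
        raise InvalidGeometryError("muscle length polynomial is non-positive in range")
    return lm


def musculotendon_length(theta, coeffs):
    """Musculotendon path length LMT(theta) in metres."""
    lmt = _polyval(coeffs, theta)
    if np.any(lmt <= 0.0):
        raise InvalidGeometryError("musculotendon length polynomial is non-positive in range")
    return lmt


@dataclass(frozen=True)
class MusculotendonParameters:
    """Constants of one muscle group's Hill model.

    lm_coeffs give LM(theta) in metres (already scaled by the subject's LMo);
    lmt_coeffs give LMT(theta) in metres. Both are ascending-power
    polynomials in the joint angle (radians, 0 = full extension).
    """

    name: str
    fmax: float            # maximum isometric force, N
    lmo: float             # optimal fibre length, m
    phi_o: float           # pennation angle at LMo, rad
    w: float               # force-length shape width, dimensionless
    ldotmmax: float        # maximum shortening velocity, m/s
    a_hill: float          # Hill curvature parameter, dimensionless
    gmax: float            # maximal normalized eccentric force, dimensionless
    ls: float              # slack length of the parallel elastic element, m
    k1: float              # linear passive stiffness, N/m
    k2: float              # quadratic passive stiffness, N/m^2
    lm_coeffs: tuple[float, ...]
    lmt_coeffs: tuple[float, ...]

    def __post_init__(self) -> None:
        positive = {
            "fmax": self.fmax, "lmo": self.lmo, "w": self.w,
            "ldotmmax": self.ldotmmax, "a_hill": self.a_hill, "ls": self.ls,
        }
        for key, value in positive.items():
            if not value > 0:
                raise InvalidParameterError(f"{key} must be positive, got {value}")
        if not self.gmax > 1.0:
            raise InvalidParameterError("gmax must exceed 1")
        theta_grid = np.linspace(*_JOINT_RANGE, 32)
        muscle_length(theta_grid, self.lm_coeffs)  # raises if non-positive

    # -- geometry -----------------------------------------------------------

    def lm(self, theta):
        return muscle_length(theta, self.lm_coeffs)

    def dlm_dtheta(self, theta):
        d = np.polynomial.polynomial.polyder(np.asarray(self.lm_coeffs, dtype=float))
        return np.polynomial.polynomial.polyval(theta, d)

    def lmt(self, theta):
        return musculotendon_length(theta, self.lmt_coeffs)

    def state(self, theta, theta_dot) -> "MuscleKinematicState":
        """Fibre kinematics from joint kinematics (rigid tendon)."""
        lm = self.lm(theta)
        ldot = self.dlm_dtheta(theta) * np.asarray(theta_dot, dtype=float)
        return MuscleKinematicState(lm=lm, ldot=ldot, phi=pennation(lm, self))


@dataclass(frozen=True)
class MuscleKinematicState:
    """Fibre length, fibre velocity (negative = concentric) and pennation."""

    lm: float | np.ndarray
    ldot: float | np.ndarray
    phi: float | np.ndarray


# ---------------------------------------------------------------------------
# defaults file
# ---------------------------------------------------------------------------

def load_muscle_defaults() -> dict:
    """Raw contents of the shipped per-muscle defaults file."""
    text = resources.files("emgelbow.data").joinpath("muscle_defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_params(
    muscle: str,
    lmo: float | None = None,
    *,
    overrides: dict | None = None,
) -> MusculotendonParameters:
    """Build parameters for ``"biceps"`` (flexor) or ``"triceps"`` (extensor).

    ``lmo`` defaults to the midpoint of the shipped subject range; a synthetic
    subject samples it inside the range. The fibre length-angle curve scales
    with LMo; LS follows the defaults file's ls_policy (LS = LMo).
    """
    table = load_muscle_defaults()
    if muscle not in table:
        raise InvalidParameterError(f"unknown muscle {muscle!r}; have {sorted(table)}")
    entry = dict(table[muscle])
    if overrides:
        entry.update(overrides)
    lo, hi = entry["lmo_m"]
    if lmo is None:
        lmo = 0.5 * (lo + hi)
    if not (lo <= lmo <= hi):
        raise InvalidParameterError(f"lmo {lmo} outside shipped range [{lo}, {hi}]")
    if entry["ls_policy"] == "lmo":
        ls = lmo
    else:
        ls = 0.5 * (entry["lslack_m"][0] + entry["lslack_m"][1])
    lm_coeffs = tuple(lmo * c for c in entry["lm_shape_coeffs"])
    return MusculotendonParameters(
        name=muscle,
        fmax=float(entry["fmax_n"]),
        lmo=float(lmo),
        phi_o=float(entry["phi_o_rad"]),
        w=float(entry["w"]),
        ldotmmax=float(entry["ldotmmax_per_lmo"]) * float(lmo),
        a_hill=float(entry["a_hill"]),
        gmax=float(entry["gmax"]),
        ls=float(ls),
        k1=float(entry["k1_n_per_m"]),
        k2=float(entry["k2_n_per_m2"]),
        lm_coeffs=lm_coeffs,
        lmt_coeffs=tuple(float(c) for c in entry["lmt_coeffs"]),
    )


# ---------------------------------------------------------------------------
# force relationships
# ---------------------------------------------------------------------------

def force_length(lm, p: MusculotendonParameters):
    """Gaussian active force-length factor, peak 1 at LM = LMo."""
    x = (np.asarray(lm, dtype=float) - p.lmo) / (p.w * p.lmo)
    out = np.exp(-x * x)
    return float(out) if np.ndim(lm) == 0 else out


def force_velocity(ldot, p: MusculotendonParameters):
    """Hill force-velocity factor; 1 at rest, 0 at -LdotMmax, -> gmax eccentric.

    Concentric branch (v <= 0): (Vmax + v) / (Vmax - v/A).
    Eccentric branch  (v > 0): (gmax*v + cd) / (v + cd),
    cd = Vmax*A*(gmax-1)/(A+1) makes the first derivative continuous at 0.
    Velocities at or below -Vmax are clamped to zero force with a warning.
    """
    v = np.asarray(ldot, dtype=float)
    vm, a = p.ldotmmax, p.a_hill
    cd = vm * a * (p.gmax - 1.0) / (a + 1.0)
    conc = (vm + v) / (vm - v / a)
    ecc = (p.gmax * v + cd) / (v + cd)
    out = np.where(v <= 0.0, conc, ecc)
    below = v < -vm
    if np.any(below):
        warnings.warn(
            "fibre shortening at or beyond LdotMmax; force-velocity clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.where(below, 0.0, out)
    return float(out) if np.ndim(ldot) == 0 else out


def passive_force(lm, p: MusculotendonParameters):
    """Parallel-elastic force, N: linear below slack, linear+quadratic above."""
    d = np.asarray(lm, dtype=float) - p.ls
    out = p.k1 * d + np.where(d > 0.0, p.k2 * d * d, 0.0)
    return float(out) if np.ndim(lm) == 0 else out


def pennation(lm, p: MusculotendonParameters):
    """Constant-volume pennation: phi = arcsin(LMo*sin(phi_o)/LM), in radians."""
    s = np.clip(p.lmo * np.sin(p.phi_o) / np.asarray(lm, dtype=float), 0.0, 1.0)
    out = np.arcsin(s)
    return float(out) if np.ndim(lm) == 0 else out


def tendon_force(a, s: MuscleKinematicState, p: MusculotendonParameters):
    """Force transmitted by the rigid tendon for activation a in [0, 1]."""
    active = np.asarray(a, dtype=float) * p.fmax * force_length(s.lm, p) * force_velocity(s.ldot, p)
    out = (active + passive_force(s.lm, p)) * np.cos(s.phi)
    return float(out) if np.ndim(out) == 0 else out


def inverse_activation(
    f_target,
    s: MuscleKinematicState,
    p: MusculotendonParameters,
    *,
    eps: float = 1e-6,
):
    """Activation producing a target tendon force at a given fibre state.

    a = (F/cos(phi) - F_MEE) / (Fmax * Ffl * Ffv), clipped to [-1, 1]; values
    outside [0, 1] flag torque demands the muscle cannot meet (or that point
    the other way). Near-singular states (Ffl*Ffv ~ 0) are refused.
    """
    gain = force_length(s.lm, p) * force_velocity(s.ldot, p)
    if np.any(np.asarray(gain) <= eps):
        raise IndeterminateStateError(
            "force-length * force-velocity gain vanishes; inversion is singular"
        )
    a = (np.asarray(f_target, dtype=float) / np.cos(s.phi) - passive_force(s.lm, p)) / (
        p.fmax * gain
    )
    out = np.clip(a, -1.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out
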