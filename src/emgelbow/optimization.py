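"""The two-stage optimization procedure of the study.

Stage 1 (inverse): for each trial, find the total muscle torque M_TM(t) that
zeroes the joint equation of motion under the free-motion assumption
(M_joint = 0), then invert it through a single flexor-like musculotendon unit
to get the control total muscle activation a_TI(t). The two antagonists'
individual activations are dynamically coupled and unobservable from a single
net torque, so the single-unit inversion is the standard workaround for that
indeterminacy.

Stage 2 (forward): for each activation model, find the bounded parameters
(shared by both EMG channels) minimizing the squared activation error
sum (a_TI - a_TF)^2, where a_TF = model(u_flexor) - model(u_extensor).
The minimizer is bounded L-BFGS-B in a unit-box parametrisation (log10 scale
for Model 3's A2) with seeded multi-starts; wall time spent inside the
objective is accumulated to give the per-data-point optimization time Tdp.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize as spo

from . import metrics as met
from .activation import (
    MODEL_REGISTRY,
    ActivationModelSpec,
    apply_model,
    make_spec,
    total_activation,
)
from .muscle import MusculotendonParameters, inverse_activation, tendon_force
from .signal_processing import MotionDataset
from .skeletal import SkeletalParameters, gravity_moment, moment_arm, passive_joint_torque
from .timeseries import TimeSeries

__all__ = [
    "FitOptions",
    "InverseResult",
    "ForwardResult",
    "inverse_total_muscle_torque",
    "derive_control_activation",
    "run_inverse",
    "fit_activation_model",
    "estimate_muscle_torque",
]


@dataclass(frozen=True)
class FitOptions:
    """Forward-optimization settings (defaults follow the study procedure)."""

    n_starts: int = 5
    seed: int = 0
    max_iter: int = 200
    ftol: float = 1e-10
    xtol: float = 1e-8


@dataclass(frozen=True)
class InverseResult:
    """Control torque and activation for one trial."""

    m_tm: TimeSeries          # total muscle torque, N*m
    a_ti: TimeSeries          # control total muscle activation, [-1, 1]
    residual: float           # max |equation-of-motion residual| at optimum, N*m


@dataclass(frozen=True)
class ForwardResult:
    """One fitted activation model on one trial."""

    spec: ActivationModelSpec
    a_tf: TimeSeries
    ea: float
    torque_estimate: TimeSeries
    et: float
    t_dp_us: float            # objective wall time per data point, microseconds
    n_iter: int
    n_evals: int
    converged: bool
    seed: int


# ---------------------------------------------------------------------------
# stage 1: inverse optimization
# ---------------------------------------------------------------------------

def _nonmuscle_moments(ds: MotionDataset, sk: SkeletalParameters) -> np.ndarray:
    """I*theta_ddot + Mp + Mg along the trial."""
    inertia = sk.inertia(ds.held_mass)
    return (
        inertia * ds.theta_ddot.values
        + passive_joint_torque(ds.theta_dot.values, sk.b)
        + gravity_moment(ds.theta.values, sk, ds.held_mass)
    )


def torque_bound(
    ds: MotionDataset,
    flexor: MusculotendonParameters,
    extensor: MusculotendonParameters,
) -> float:
    """Physiological search bound: both muscles at Fmax through their peak arms."""
    rf = np.abs(moment_arm(ds.theta.values, flexor.lmt_coeffs))
    re = np.abs(moment_arm(ds.theta.values, extensor.lmt_coeffs))
    return float(flexor.fmax * rf.max() + extensor.fmax * re.max())


def inverse_total_muscle_torque(
    ds: MotionDataset,
    sk: SkeletalParameters,
    flexor: MusculotendonParameters | None = None,
    extensor: MusculotendonParameters | None = None,
    *,
    method: str = "closed_form",
) -> TimeSeries:
    """Per-sample total muscle torque that zeroes the equation of motion.

    With M_joint = 0 (free, unloaded motion — the held mass enters through
    gravity and inertia, not as an external joint load) the residual
    I*theta_ddot + Mp + Mg + M_TM is linear in M_TM, so the closed form
    M_TM = -(I*theta_ddot + Mp + Mg) is exact. ``method="minimize"`` solves
    the same per-sample problems with a bounded scalar minimizer instead and
    exists as a cross-check of the rearrangement.
    """
    target = -_nonmuscle_moments(ds, sk)
    if method == "minimize":
        lo, hi = -1.05 * np.abs(target).max() - 1.0, 1.05 * np.abs(target).max() + 1.0
        sol = np.empty_like(target)
        for i, t in enumerate(target):
            res = spo.minimize_scalar(
                lambda m, t=t: (m - t) ** 2,
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            sol[i] = res.x
        target = sol
    elif method != "closed_form":
        raise ValueError("method must be 'closed_form' or 'minimize'")
    if flexor is not None and extensor is not None:
        bound = torque_bound(ds, flexor, extensor)
        n_clip = int(np.sum(np.abs(target) > bound))
        if n_clip:
            warnings.warn(
                f"{n_clip} samples demand torque beyond both muscles' capacity "
                f"({bound:.1f} N*m); clipped",
                RuntimeWarning,
                stacklevel=2,
            )
            target = np.clip(target, -bound, bound)
    return ds.theta.with_values(target, units_label="N*m")


def derive_control_activation(
    m_tm: TimeSeries,
    theta: TimeSeries,
    theta_dot: TimeSeries,
    flexor: MusculotendonParameters,
    *,
    r_eps: float = 1e-4,
) -> TimeSeries:
    """Invert the control torque through a single flexor-like unit.

    a_TI(t) = inverse_activation(M_TM(t) / r(theta(t))), clipped to [-1, 1].
    Samples where the moment arm collapses below ``r_eps`` metres are masked
    to zero with a warning (they carry no torque authority).
    """
    th = theta.values
    r = moment_arm(th, flexor.lmt_coeffs)
    small = np.abs(r) < r_eps
    if np.any(small):
        warnings.warn(
            f"{int(small.sum())} samples with near-zero flexor moment arm masked",
            RuntimeWarning,
            stacklevel=2,
        )
    r_safe = np.where(small, np.sign(r) * r_eps + (r == 0) * r_eps, r)
    state = flexor.state(th, theta_dot.values)
    a = inverse_activation(m_tm.values / r_safe, state, flexor)
    a = np.where(small, 0.0, a)
    return m_tm.with_values(np.clip(a, -1.0, 1.0), units_label="dimensionless")


def run_inverse(
    ds: MotionDataset,
    sk: SkeletalParameters,
    flexor: MusculotendonParameters,
    extensor: MusculotendonParameters,
) -> InverseResult:
    """Full stage-1 procedure for one trial."""
    m_tm = inverse_total_muscle_torque(ds, sk, flexor, extensor)
    residual = float(np.max(np.abs(_nonmuscle_moments(ds, sk) + m_tm.values)))
    a_ti = derive_control_activation(m_tm, ds.theta, ds.theta_dot, flexor)
    return InverseResult(m_tm=m_tm, a_ti=a_ti, residual=residual)


# ---------------------------------------------------------------------------
# stage 2: forward optimization
# ---------------------------------------------------------------------------

def _unit_box_maps(model_id: int):
    """Maps between the optimizer's unit box and physical parameters."""
    info = MODEL_REGISTRY[model_id]

    def to_params(x: np.ndarray) -> tuple[float, ...]:
        out = []
        for xi, (lo, hi), logp in zip(x, info.bounds, info.log_scale):
            xi = min(max(float(xi), 0.0), 1.0)
            if logp:
                lg = np.log10(lo) + xi * (np.log10(hi) - np.log10(lo))
                p = 10.0**lg
            else:
                p = lo + xi * (hi - lo)
            out.append(min(max(p, lo), hi))  # guard float roundoff at the box edge
        return tuple(out)

    def to_x(params) -> np.ndarray:
        out = []
        for p, (lo, hi), logp in zip(params, info.bounds, info.log_scale):
            if logp:
                out.append((np.log10(p) - np.log10(lo)) / (np.log10(hi) - np.log10(lo)))
            else:
                out.append((p - lo) / (hi - lo))
        return np.asarray(out)

    return to_params, to_x


class _TimedObjective:
    """Counts calls and accumulates wall time spent in the objective."""

    def __init__(self, model_id: int, u_flex: TimeSeries, u_ext: TimeSeries, a_ti: np.ndarray):
        self.model_id = model_id
        self.u_flex = u_flex
        self.u_ext = u_ext
        self.a_ti = a_ti
        self._to_params, _ = _unit_box_maps(model_id)
        self.n_evals = 0
        self.elapsed = 0.0

    def spec(self, x: np.ndarray) -> ActivationModelSpec:
        params = self._to_params(x)
        return make_spec(self.model_id, *params)

    def predict(self, spec: ActivationModelSpec) -> TimeSeries:
        a_f = apply_model(spec, self.u_flex)
        a_e = apply_model(spec, self.u_ext)
        return total_activation(a_f, a_e)

    def __call__(self, x: np.ndarray) -> float:
        t0 = time.perf_counter()
        a_tf = self.predict(self.spec(x))
        sse = float(np.sum((self.a_ti - a_tf.values) ** 2))
        self.elapsed += time.perf_counter() - t0
        self.n_evals += 1
        return sse


def fit_activation_model(
    model_id: int,
    ds: MotionDataset,
    a_ti: TimeSeries,
    options: FitOptions | None = None,
    *,
    flexor: MusculotendonParameters | None = None,
    extensor: MusculotendonParameters | None = None,
    m_tm: TimeSeries | None = None,
) -> ForwardResult:
    """Fit one activation model's parameters to a trial's control activation.

    Both channels share one parameter vector. Multi-start bounded L-BFGS-B:
    the first start sits at the centre of the (transformed) parameter box,
    the remainder are drawn uniformly from a seeded generator; ties between
    equally good starts resolve to the lowest start index. If flexor and
    extensor parameters (and the control torque) are provided, the estimated
    muscle torque and its error eT are attached; otherwise they are zero
    series.
    """
    if options is None:
        options = FitOptions()
    if model_id not in MODEL_REGISTRY:
        raise ValueError(f"unknown model_id {model_id}")
    if a_ti.n != ds.n:
        raise ValueError("a_TI must be aligned with the dataset")
    info = MODEL_REGISTRY[model_id]
    objective = _TimedObjective(model_id, ds.u_flexor, ds.u_extensor, a_ti.values)

    rng = np.random.default_rng(options.seed)
    starts = [np.full(info.n_params, 0.5)]
    for _ in range(max(options.n_starts - 1, 0)):
        starts.append(rng.uniform(0.05, 0.95, size=info.n_params))

    best = None
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for x0 in starts:
            res = spo.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=[(0.0, 1.0)] * info.n_params,
                options={
                    "maxiter": options.max_iter,
                    "ftol": options.ftol,
                    "gtol": 1e-12,
                    "eps": 1e-7,
                },
            )
            converged = converged or bool(res.success)
            if best is None or res.fun < best.fun:  # strict: earliest start wins ties
                best = res

    spec = objective.spec(best.x)
    a_tf = objective.predict(spec)
    ea = met.activation_error(a_ti, a_tf)
    if flexor is not None and extensor is not None and m_tm is not None:
        torque = estimate_muscle_torque(spec, ds, flexor, extensor)
        et = met.torque_error(m_tm, torque)
    else:
        torque = ds.theta.with_values(np.zeros(ds.n), units_label="N*m")
        et = 0.0
    return ForwardResult(
        spec=spec,
        a_tf=a_tf,
        ea=ea,
        torque_estimate=torque,
        et=et,
        t_dp_us=met.datapoint_time(objective.elapsed, ds.n),
        n_iter=int(best.nit),
        n_evals=objective.n_evals,
        converged=converged,
        seed=options.seed,
    )


def estimate_muscle_torque(
    spec: ActivationModelSpec,
    ds: MotionDataset,
    flexor: MusculotendonParameters,
    extensor: MusculotendonParameters,
) -> TimeSeries:
    """Per-muscle forward torque from the fitted model's channel activations.

    Each channel's activation drives its own musculotendon unit;
    M_TF = r_f * F_f + r_e * F_e (flexor arm positive, extensor negative).
    """
    theta = ds.theta.values
    theta_dot = ds.theta_dot.values
    total = np.zeros(ds.n)
    for params, u in ((flexor, ds.u_flexor), (extensor, ds.u_extensor)):
        a = np.clip(apply_model(spec, u).values, 0.0, 1.0)
        force = tendon_force(a, params.state(theta, theta_dot), params)
        total = total + moment_arm(theta, params.lmt_coeffs) * force
    return ds.theta.with_values(total, units_label="N*m")
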