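"""The seven muscle activation models: neural drive u(t) -> mechanical a(t).

Models 1-3 are static nonlinearities (one evaluation per sample); models 4-7
are first-order activation/deactivation ODEs integrated with fixed-step
explicit Euler. All models fix the endpoints a(0)=0, a(1)=1 (static) or share
the fixed point a = u (dynamic), and keep a in [0, 1].

Registry (model_id, author tag, parameters):

==  =========  ========  ==================================================
id  author     n_params  form
==  =========  ========  ==================================================
1   Manal      1         a = (exp(A1*u) - 1) / (exp(A1) - 1)
2   Cavallaro  1         a = (A1**u - 1) / (A1 - 1)
3   Manal      2         piecewise log / linear, knot at (u0, a0)
4   Chadwick   2         da/dt = (u/A1 + (1-u)/A2) * (u - a)
5   Rengifo    2         da/dt = (u - a)/A1 if u >= a else (u - a)/A2
6   Chadwick   2         da/dt = (A1*u + A2) * (u - a)
7   Thelen     2         da/dt = (u - a)/Ta, state-dependent Ta
==  =========  ========  ==================================================

Model 2 is Model 1 reparametrised (base A1 = exp(Model-1 A1)), and Model 6 is
Model 4 with the affine rate written out — the four coefficient boxes do not
coincide, so the fitted families still differ. Parameters of models 4, 5 and
7 are activation/deactivation time constants in seconds; Model 6's A1, A2
enter the rate directly and are bounded by the same 1-70 ms numeric box.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import InvalidParameterError
from .timeseries import TimeSeries

__all__ = [
    "MODEL_IDS",
    "STATIC_MODEL_IDS",
    "DYNAMIC_MODEL_IDS",
    "ModelInfo",
    "MODEL_REGISTRY",
    "ActivationModelSpec",
    "Model3Constants",
    "model3_constants",
    "make_spec",
    "activation_static",
    "activation_dynamic",
    "apply_model",
    "static_inverse",
    "dynamic_inverse",
    "consistent_inverse",
    "track_activation",
    "invert_model",
    "total_activation",
]

MODEL_IDS = (1, 2, 3, 4, 5, 6, 7)
STATIC_MODEL_IDS = (1, 2, 3)
DYNAMIC_MODEL_IDS = (4, 5, 6, 7)

_EPS = 1e-2  # guard distance from singular parameter values (A1=0 / A1=1)


@dataclass(frozen=True)
class ModelInfo:
    """Registry entry: identity, parameter count, bounds and scaling."""

    model_id: int
    author: str
    n_params: int
    bounds: tuple[tuple[float, float], ...]
    #: optimize this parameter on a log10 scale (Model 3's A2 spans 13 decades)
    log_scale: tuple[bool, ...]
    is_dynamic: bool


MODEL_REGISTRY: dict[int, ModelInfo] = {
    1: ModelInfo(1, "Manal", 1, ((-3.0, -_EPS),), (False,), False),
    2: ModelInfo(2, "Cavallaro", 1, ((0.05, 1.0 - _EPS),), (False,), False),
    3: ModelInfo(3, "Manal", 2, ((1e-4, 0.12), (1e-2, 1e11)), (False, True), False),
    4: ModelInfo(4, "Chadwick", 2, ((1e-3, 0.070), (1e-3, 0.070)), (False, False), True),
    5: ModelInfo(5, "Rengifo", 2, ((1e-3, 0.070), (1e-3, 0.070)), (False, False), True),
    6: ModelInfo(6, "Chadwick", 2, ((1e-3, 0.070), (1e-3, 0.070)), (False, False), True),
    7: ModelInfo(7, "Thelen", 2, ((1e-3, 0.070), (1e-3, 0.070)), (False, False), True),
}


@dataclass(frozen=True)
class ActivationModelSpec:
    """One activation model with concrete parameter values.

    A2 is ignored by the one-parameter models (1 and 2). Both EMG channels of
    a trial share a single spec when a model is fitted.
    """

    model_id: int
    A1: float
    A2: float = 0.0

    def __post_init__(self) -> None:
        info = MODEL_REGISTRY.get(self.model_id)
        if info is None:
            raise InvalidParameterError(f"unknown model_id {self.model_id}")
        params = (self.A1, self.A2)[: info.n_params]
        for value, (lo, hi) in zip(params, info.bounds):
            if not (lo <= value <= hi):
                raise InvalidParameterError(
                    f"model {self.model_id}: parameter {value} outside [{lo}, {hi}]"
                )

    @property
    def info(self) -> ModelInfo:
        return MODEL_REGISTRY[self.model_id]

    @property
    def n_params(self) -> int:
        return self.info.n_params

    @property
    def is_dynamic(self) -> bool:
        return self.info.is_dynamic

    @property
    def params(self) -> tuple[float, ...]:
        return (self.A1, self.A2)[: self.n_params]


def make_spec(model_id: int, A1: float, A2: float | None = None) -> ActivationModelSpec:
    """Validated constructor; fills a neutral A2 for one-parameter models."""
    info = MODEL_REGISTRY.get(model_id)
    if info is None:
        raise InvalidParameterError(f"unknown model_id {model_id}")
    if info.n_params == 2:
        if A2 is None:
            raise InvalidParameterError(f"model {model_id} requires A2")
        return ActivationModelSpec(model_id, float(A1), float(A2))
    return ActivationModelSpec(model_id, float(A1), 0.0)


# ---------------------------------------------------------------------------
# Model 3 constants
# ---------------------------------------------------------------------------

_COS45 = math.cos(math.pi / 4.0)
_SIN45 = math.sin(math.pi / 4.0)


@dataclass(frozen=True)
class Model3Constants:
    """Derived constants of the piecewise log/linear model.

    The knot (u0, a0) moves along a 45-degree line from (0.3085, 0.3085) as
    A1 grows; beta is defined so the logarithmic half passes through the knot,
    and c = 1 - m pins the linear half to (1, 1).
    """

    u0: float
    a0: float
    m: float
    c: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.u0 < 1.0 and 0.0 < self.a0 < 1.0):
            raise InvalidParameterError("Model 3 knot must lie strictly inside (0,1)^2")


def model3_constants(A1: float, A2: float) -> Model3Constants:
    """Knot position and curve constants from the two free parameters."""
    u0 = 0.3085 - A1 * _COS45
    a0 = 0.3085 + A1 * _SIN45
    m = (a0 - 1.0) / (u0 - 1.0)
    c = 1.0 - m
    beta = math.expm1(a0 / A2) / u0
    return Model3Constants(u0=u0, a0=a0, m=m, c=c, beta=beta)


# ---------------------------------------------------------------------------
# static models (1-3)
# ---------------------------------------------------------------------------

def activation_static(spec: ActivationModelSpec, u):
    """Evaluate a static activation model at u in [0, 1] (scalar or array)."""
    if spec.model_id not in STATIC_MODEL_IDS:
        raise InvalidParameterError(f"model {spec.model_id} is not static")
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < -1e-12) | (u_arr > 1.0 + 1e-12)):
        raise InvalidParameterError("u must lie in [0, 1]")
    u_arr = np.clip(u_arr, 0.0, 1.0)
    if spec.model_id == 1:
        a = np.expm1(spec.A1 * u_arr) / math.expm1(spec.A1)
    elif spec.model_id == 2:
        a = (np.power(spec.A1, u_arr) - 1.0) / (spec.A1 - 1.0)
    else:
        k = model3_constants(spec.A1, spec.A2)
        log_half = spec.A2 * np.log1p(k.beta * u_arr)
        lin_half = k.m * u_arr + k.c
        a = np.where(u_arr <= k.u0, log_half, lin_half)
    a = np.clip(a, 0.0, 1.0)
    return float(a) if np.isscalar(u) or np.ndim(u) == 0 else a


def static_inverse(spec: ActivationModelSpec, a):
    """Closed-form inverse u(a) of a static model (used by the generator)."""
    if spec.model_id not in STATIC_MODEL_IDS:
        raise InvalidParameterError(f"model {spec.model_id} is not static")
    a_arr = np.clip(np.asarray(a, dtype=float), 0.0, 1.0)
    if spec.model_id == 1:
        u = np.log1p(a_arr * math.expm1(spec.A1)) / spec.A1
    elif spec.model_id == 2:
        u = np.log1p(a_arr * (spec.A1 - 1.0)) / math.log(spec.A1)
    else:
        k = model3_constants(spec.A1, spec.A2)
        log_half = np.expm1(a_arr / spec.A2) / k.beta
        lin_half = (a_arr - k.c) / k.m
        u = np.where(a_arr <= k.a0, log_half, lin_half)
    u = np.clip(u, 0.0, 1.0)
    return float(u) if np.isscalar(a) or np.ndim(a) == 0 else u


# ---------------------------------------------------------------------------
# dynamic models (4-7): explicit Euler with automatic sub-stepping
# ---------------------------------------------------------------------------

@njit(cache=False)
def _step(model_id, ai, ui, h, substeps, A1, A2):  # pragma: no cover
    for _ in range(substeps):
        diff = ui - ai
        if model_id == 4:
            adot = (ui / A1 + (1.0 - ui) / A2) * diff
        elif model_id == 5:
            # boundary u == a assigned to the activation (A1) branch
            if ui >= ai:
                adot = diff / A1
            else:
                adot = diff / A2
        elif model_id == 6:
            adot = (A1 * ui + A2) * diff
        else:  # model 7
            if ui > ai:
                ta = A1 * (0.5 + 1.5 * ai)
            else:
                ta = A2 / (0.5 + 1.5 * ai)
            adot = diff / ta
        ai += h * adot
        if ai < 0.0:
            ai = 0.0
        elif ai > 1.0:
            ai = 1.0
    return ai


@njit(cache=False)
def _euler_kernel(model_id, u, dt, a_init, A1, A2, substeps):  # pragma: no cover
    """Explicit Euler; drive sample i is held constant over the step onto i."""
    n = u.shape[0]
    a = np.empty(n)
    ai = a_init
    if ai < 0.0:
        ai = 0.0
    elif ai > 1.0:
        ai = 1.0
    a[0] = ai
    h = dt / substeps
    for i in range(1, n):
        ai = _step(model_id, ai, u[i], h, substeps, A1, A2)
        a[i] = ai
    return a


def _choose_substeps(spec: ActivationModelSpec, dt: float, substep_factor: int) -> int:
    tau_min = min(spec.A1, spec.A2)
    if dt > 0.2 * tau_min:
        if dt / substep_factor > tau_min:
            warnings.warn(
                f"model {spec.model_id}: sub-stepped dt {dt / substep_factor:.4g} s "
                f"still exceeds the smallest time constant {tau_min:.4g} s",
                RuntimeWarning,
                stacklevel=3,
            )
        return substep_factor
    return 1


def activation_dynamic(
    spec: ActivationModelSpec,
    u_series: TimeSeries,
    a_init: float | None = None,
    *,
    substep_factor: int = 10,
    substeps: int | None = None,
) -> TimeSeries:
    """Integrate a first-order activation ODE over a neural-drive series.

    Fixed-step explicit Euler at the series rate, with automatic
    ``substep_factor``-fold sub-stepping whenever dt exceeds 20 % of the
    smallest time constant (stability guard). The drive is linearly
    interpolated across sub-steps; a is clipped to [0, 1] after every step.

    ``a_init`` defaults to u(0) — the ODE fixed point, which avoids a startup
    transient on trials that begin at rest.
    """
    if spec.model_id not in DYNAMIC_MODEL_IDS:
        raise InvalidParameterError(f"model {spec.model_id} is not an ODE model")
    u = np.clip(u_series.values, 0.0, 1.0)
    if a_init is None:
        a_init = float(u[0])
    if substeps is None:
        substeps = _choose_substeps(spec, u_series.dt, substep_factor)
    a = _euler_kernel(
        spec.model_id, u, u_series.dt, float(a_init), spec.A1, spec.A2, int(substeps)
    )
    return u_series.with_values(a, units_label="dimensionless")


@njit(cache=False)
def _consistent_inverse_kernel(model_id, a_target, dt, A1, A2, substeps):  # pragma: no cover
    """Drive sequence whose Euler integration reproduces a_target.

    The forward kernel holds drive sample i constant over the step landing on
    sample i, so each step is a scalar equation in one unknown. The end-state
    is not guaranteed monotone in the drive for every parameter combination
    (models 4 and 6 can deactivate faster at small positive drives), so a
    coarse scan brackets a sign change before bisection refines it.
    Unreachable targets saturate at the closer of the scanned extremes and
    the achieved state carries forward, so errors do not accumulate.
    """
    n = a_target.shape[0]
    u = np.empty(n)
    achieved = np.empty(n)
    u[0] = a_target[0]
    ai = a_target[0]
    achieved[0] = ai
    h = dt / substeps
    n_scan = 9
    for i in range(1, n):
        target = a_target[i]
        # scan the unit interval for a bracketing sign change of
        # g(v) = step(ai, v) - target
        v_best = 0.0
        err_best = 1e30
        lo = -1.0
        hi = -1.0
        g_prev = 0.0
        for k in range(n_scan):
            v = k / (n_scan - 1.0)
            aa = _step(model_id, ai, v, h, substeps, A1, A2)
            g = aa - target
            err = abs(g)
            if err < err_best:
                err_best = err
                v_best = v
            if k > 0 and lo < 0.0 and (g_prev <= 0.0 <= g or g <= 0.0 <= g_prev):
                lo = (k - 1) / (n_scan - 1.0)
                hi = v
            g_prev = g
        if lo >= 0.0:
            g_lo = _step(model_id, ai, lo, h, substeps, A1, A2) - target
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                g_mid = _step(model_id, ai, mid, h, substeps, A1, A2) - target
                if abs(g_mid) < err_best:
                    err_best = abs(g_mid)
                    v_best = mid
                if (g_lo <= 0.0 <= g_mid) or (g_mid <= 0.0 <= g_lo):
                    hi = mid
                else:
                    lo = mid
                    g_lo = g_mid
                if hi - lo < 1e-15:
                    break
        ai = _step(model_id, ai, v_best, h, substeps, A1, A2)
        u[i] = v_best
        achieved[i] = ai
    return u, achieved


def consistent_inverse(
    spec: ActivationModelSpec,
    a_series: TimeSeries,
    *,
    substep_factor: int = 10,
    substeps: int | None = None,
) -> TimeSeries:
    """Neural drive whose forward Euler integration reproduces ``a_series``.

    The discrete counterpart of :func:`dynamic_inverse`: rather than solving
    the continuous relation u = f(a, da/dt) per sample, it inverts the exact
    macro-step of :func:`activation_dynamic` (same sub-stepping, same drive
    interpolation), so integrating the returned drive reproduces the target
    trajectory to solver precision wherever it is realizable with u in
    [0, 1]. Used by the synthetic generator so that noiseless pipeline runs
    close exactly.
    """
    u, _ = track_activation(spec, a_series, substep_factor=substep_factor, substeps=substeps)
    return u


def track_activation(
    spec: ActivationModelSpec,
    a_series: TimeSeries,
    *,
    substep_factor: int = 10,
    substeps: int | None = None,
) -> tuple[TimeSeries, TimeSeries]:
    """Euler-consistent inversion returning (drive, achieved activation).

    The achieved trajectory equals the target wherever it is realizable with
    u in [0, 1] and otherwise follows the model's saturated best effort
    (declines limited by the zero-drive deactivation rate, rises by the
    full-drive activation rate).
    """
    if spec.model_id not in DYNAMIC_MODEL_IDS:
        raise InvalidParameterError(f"model {spec.model_id} is not an ODE model")
    a = np.clip(a_series.values, 0.0, 1.0)
    if substeps is None:
        substeps = _choose_substeps(spec, a_series.dt, substep_factor)
    u, achieved = _consistent_inverse_kernel(
        spec.model_id, a, a_series.dt, spec.A1, spec.A2, int(substeps)
    )
    return (
        a_series.with_values(u, units_label="dimensionless"),
        a_series.with_values(achieved, units_label="dimensionless"),
    )


def dynamic_inverse(spec: ActivationModelSpec, a_series: TimeSeries) -> TimeSeries:
    """Per-sample neural drive u(t) reproducing a target activation trajectory.

    Uses the exact algebraic relation u = f(a, da/dt) of each ODE (quadratic
    for models 4 and 6, branch-consistent linear for 5 and 7) with da/dt from
    central differences; the result is clipped to [0, 1], so activation
    trajectories steeper than the model can follow are only approximately
    realizable. For a drive that closes exactly under the discrete Euler
    integrator, see :func:`consistent_inverse`.
    """
    if spec.model_id not in DYNAMIC_MODEL_IDS:
        raise InvalidParameterError(f"model {spec.model_id} is not an ODE model")
    a = np.clip(a_series.values, 0.0, 1.0)
    adot = np.gradient(a, a_series.dt)
    A1, A2 = spec.A1, spec.A2
    if spec.model_id == 4:
        p = 1.0 / A1 - 1.0 / A2
        q = 1.0 / A2
        if abs(p) < 1e-12:
            u = a + adot / q
        else:
            disc = np.maximum((q - p * a) ** 2 + 4.0 * p * (q * a + adot), 0.0)
            u = (p * a - q + np.sqrt(disc)) / (2.0 * p)
    elif spec.model_id == 5:
        u = a + adot * np.where(adot >= 0.0, A1, A2)
    elif spec.model_id == 6:
        disc = np.maximum((A2 - A1 * a) ** 2 + 4.0 * A1 * (A2 * a + adot), 0.0)
        u = (A1 * a - A2 + np.sqrt(disc)) / (2.0 * A1)
    else:  # model 7
        u = np.where(
            adot > 0.0,
            a + adot * A1 * (0.5 + 1.5 * a),
            a + adot * A2 / (0.5 + 1.5 * a),
        )
    return a_series.with_values(np.clip(u, 0.0, 1.0), units_label="dimensionless")


# ---------------------------------------------------------------------------
# dispatch helpers
# ---------------------------------------------------------------------------

def apply_model(
    spec: ActivationModelSpec,
    u_series: TimeSeries,
    a_init: float | None = None,
    **euler_options,
) -> TimeSeries:
    """u(t) -> a(t) through either a static map or an ODE integration."""
    if spec.is_dynamic:
        return activation_dynamic(spec, u_series, a_init, **euler_options)
    return u_series.with_values(
        activation_static(spec, u_series.values), units_label="dimensionless"
    )


def invert_model(spec: ActivationModelSpec, a_series: TimeSeries) -> TimeSeries:
    """a(t) -> u(t); closed form for static models, Euler-consistent for ODEs."""
    if spec.is_dynamic:
        return consistent_inverse(spec, a_series)
    return a_series.with_values(
        static_inverse(spec, a_series.values), units_label="dimensionless"
    )


def total_activation(a_flex: TimeSeries, a_ext: TimeSeries) -> TimeSeries:
    """Signed antagonistic combination aT = a_flexor - a_extensor in [-1, 1].

    Flexor-positive convention: aT = 1 is full flexion drive, -1 full
    extension drive.
    """
    if a_flex.n != a_ext.n or a_flex.rate != a_ext.rate:
        raise ValueError("antagonist activation series must share rate and length")
    return a_flex.with_values(
        np.clip(a_flex.values, 0.0, 1.0) - np.clip(a_ext.values, 0.0, 1.0),
        units_label="dimensionless",
    )
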