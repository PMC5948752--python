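"""The seven activation models: static maps, ODE integration, inverses."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from emgelbow.activation import (
    DYNAMIC_MODEL_IDS,
    MODEL_REGISTRY,
    STATIC_MODEL_IDS,
    activation_dynamic,
    activation_static,
    consistent_inverse,
    dynamic_inverse,
    make_spec,
    model3_constants,
    static_inverse,
    total_activation,
    track_activation,
    _euler_kernel,
)
from emgelbow.errors import InvalidParameterError
from emgelbow.timeseries import TimeSeries


def _mid_spec(model_id):
    info = MODEL_REGISTRY[model_id]
    params = [0.5 * (lo + hi) for lo, hi in info.bounds]
    if model_id == 3:
        params[1] = 1.0  # geometric middle of the huge A2 range is friendlier
    return make_spec(model_id, *params)


def _param_strategy(model_id):
    info = MODEL_REGISTRY[model_id]
    strats = []
    for (lo, hi), logp in zip(info.bounds, info.log_scale):
        if logp:
            strats.append(
                st.floats(np.log10(lo), np.log10(hi)).map(lambda z: 10.0**z)
            )
        else:
            strats.append(st.floats(lo, hi))
    return st.tuples(*strats)


class TestStaticModels:
    @pytest.mark.parametrize("model_id", STATIC_MODEL_IDS)
    def test_endpoints(self, model_id):
        spec = _mid_spec(model_id)
        assert activation_static(spec, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert activation_static(spec, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_model1_reference_value(self):
        """(e^{-1.5} - 1)/(e^{-3} - 1) evaluated directly."""
        spec = make_spec(1, -3.0)
        expected = math.expm1(-1.5) / math.expm1(-3.0)
        assert expected == pytest.approx(0.817574, abs=1e-6)
        assert activation_static(spec, 0.5) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("model_id", STATIC_MODEL_IDS)
    def test_monotone_and_bounded_over_parameter_grid(self, model_id):
        info = MODEL_REGISTRY[model_id]
        u = np.linspace(0.0, 1.0, 201)
        grids = [np.linspace(lo, hi, 5) for lo, hi in info.bounds]
        if model_id == 3:
            grids[1] = np.logspace(-2, 11, 7)
        for p0 in grids[0]:
            for p1 in grids[1] if info.n_params == 2 else [None]:
                spec = make_spec(model_id, p0, p1)
                a = activation_static(spec, u)
                assert np.all(np.diff(a) >= -1e-12)
                assert np.all((a >= 0.0) & (a <= 1.0))

    @given(st.floats(1e-4, 0.12), st.floats(-2.0, 11.0).map(lambda z: 10.0**z))
    def test_model3_halves_continuous_at_knot(self, a1, a2):
        k = model3_constants(a1, a2)
        log_half = a2 * math.log1p(k.beta * k.u0)
        lin_half = k.m * k.u0 + k.c
        assert log_half == pytest.approx(k.a0, abs=1e-9)
        assert lin_half == pytest.approx(k.a0, abs=1e-9)

    def test_model3_constants_reference(self):
        k = model3_constants(0.12, 1.0)
        assert k.u0 == pytest.approx(0.3085 - 0.12 * math.cos(math.pi / 4), abs=1e-12)
        assert k.u0 == pytest.approx(0.223647, abs=1e-6)
        assert k.m * 1.0 + k.c == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("model_id", STATIC_MODEL_IDS)
    def test_inverse_round_trip(self, model_id):
        spec = _mid_spec(model_id)
        u = np.linspace(0.0, 1.0, 51)
        assert np.allclose(static_inverse(spec, activation_static(spec, u)), u, atol=1e-9)

    def test_out_of_bounds_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_spec(1, 0.5)
        with pytest.raises(InvalidParameterError):
            make_spec(2, 1.0)
        with pytest.raises(InvalidParameterError):
            make_spec(4, 0.1, 0.02)


class TestDynamicModels:
    @pytest.mark.parametrize("model_id", DYNAMIC_MODEL_IDS)
    def test_fixed_point(self, model_id):
        """Constant u = a_init is an equilibrium of every ODE."""
        spec = _mid_spec(model_id)
        u = TimeSeries(0.0, 100.0, np.full(200, 0.42))
        a = activation_dynamic(spec, u, a_init=0.42)
        assert np.allclose(a.values, 0.42, atol=1e-12)

    @pytest.mark.parametrize("model_id", (4, 5, 7))
    def test_convergence_to_drive_within_one_second(self, model_id):
        """Time constants <= 70 ms pull a to u well inside a second."""
        spec = _mid_spec(model_id)
        u = TimeSeries(0.0, 100.0, np.full(101, 0.5))
        a = activation_dynamic(spec, u, a_init=0.0)
        assert abs(a.values[-1] - 0.5) < 1e-3

    def test_model6_convergence_on_its_own_time_scale(self):
        """Model 6's bounded rate coefficients give relaxation times of tens
        of seconds; it still converges to the shared fixed point a = u."""
        spec = make_spec(6, 0.07, 0.07)
        rate_at_u = 0.07 * 0.5 + 0.07
        horizon = 8.0 / rate_at_u  # ~ 8 relaxation times
        n = int(horizon * 100) + 1
        u = TimeSeries(0.0, 100.0, np.full(n, 0.5))
        a = activation_dynamic(spec, u, a_init=0.0)
        assert abs(a.values[-1] - 0.5) < 1e-3

    def test_model6_matches_linear_ode_solution(self):
        """For constant u the ODE is linear: a(t) = u + (a0-u)e^{-(A1 u + A2)t}."""
        spec = make_spec(6, 0.05, 0.06)
        rate, u0, a0 = 100.0, 0.8, 0.2
        n = 2001
        u = TimeSeries(0.0, rate, np.full(n, u0))
        a = activation_dynamic(spec, u, a_init=a0)
        t = u.times
        lam = spec.A1 * u0 + spec.A2
        exact = u0 + (a0 - u0) * np.exp(-lam * t)
        assert np.max(np.abs(a.values - exact)) < 2.0 * lam * u.dt  # O(dt)

    @pytest.mark.parametrize("model_id", DYNAMIC_MODEL_IDS)
    @given(data=st.data())
    def test_output_stays_in_unit_interval(self, model_id, data):
        params = data.draw(_param_strategy(model_id))
        seed = data.draw(st.integers(0, 2**16))
        spec = make_spec(model_id, *params)
        rng = np.random.default_rng(seed)
        u = TimeSeries(0.0, 100.0, rng.uniform(0.0, 1.0, 150))
        a = activation_dynamic(spec, u, a_init=float(rng.uniform(0.0, 1.0)))
        assert np.all((a.values >= 0.0) & (a.values <= 1.0))

    def test_euler_convergence_order(self):
        """Halving the step size roughly halves the integration error."""
        spec = make_spec(4, 0.01, 0.05)
        t = np.arange(301) / 100.0
        u = TimeSeries(0.0, 100.0, 0.5 + 0.4 * np.sin(2 * np.pi * 0.8 * t))
        ref = activation_dynamic(spec, u, a_init=0.5, substeps=512).values
        errs = []
        for sub in (4, 8, 16):
            a = activation_dynamic(spec, u, a_init=0.5, substeps=sub).values
            errs.append(np.max(np.abs(a - ref)))
        ratios = [errs[i] / errs[i + 1] for i in range(2)]
        for r in ratios:
            assert 1.5 < r < 3.0

    def test_model4_model6_same_family_for_matched_coefficients(self):
        """Model 4's rate u/A1+(1-u)/A2 is Model 6's A1'u+A2' with
        A1' = 1/A1 - 1/A2, A2' = 1/A2; the kernels then integrate identically."""
        a1, a2 = 0.02, 0.05
        p, q = 1.0 / a1 - 1.0 / a2, 1.0 / a2
        rng = np.random.default_rng(0)
        u = rng.uniform(0.0, 1.0, 200)
        traj4 = _euler_kernel(4, u, 0.01, 0.3, a1, a2, 10)
        traj6 = _euler_kernel(6, u, 0.01, 0.3, p, q, 10)
        assert np.allclose(traj4, traj6, atol=1e-12)

    @pytest.mark.parametrize("model_id", DYNAMIC_MODEL_IDS)
    def test_consistent_inverse_round_trip(self, model_id):
        """Integrating the Euler-consistent drive reproduces a trackable target."""
        spec = _mid_spec(model_id)
        t = np.arange(401) / 100.0
        # stay inside (0, 1) and below each model's maximum deactivation rate
        # (Model 6's bounded rate coefficients make it far slower than 4/5/7)
        scale, period = (0.01, 32.0) if model_id == 6 else (0.3, 4.0)
        a_target = TimeSeries(0.0, 100.0, 0.35 + scale * np.sin(2 * np.pi * t / period))
        u, achieved = track_activation(spec, a_target)
        a_rec = activation_dynamic(spec, u, a_init=float(u.values[0]))
        assert np.max(np.abs(a_rec.values - achieved.values)) < 1e-10
        assert np.max(np.abs(achieved.values - a_target.values)) < 1e-6

    def test_algebraic_inverse_matches_on_smooth_interior(self):
        """The continuous-relation inverse agrees with the generating drive
        away from saturation for a fast model."""
        spec = make_spec(5, 0.03, 0.05)
        t = np.arange(601) / 100.0
        u_true = TimeSeries(0.0, 100.0, 0.4 + 0.25 * np.sin(2 * np.pi * t / 3.0))
        a = activation_dynamic(spec, u_true, a_init=float(u_true.values[0]))
        u_back = dynamic_inverse(spec, a)
        assert np.max(np.abs(u_back.values[5:-5] - u_true.values[5:-5])) < 0.02


class TestTotalActivation:
    def test_signed_combination(self):
        mk = lambda v: TimeSeries(0.0, 100.0, np.full(10, v))
        assert np.all(total_activation(mk(0.0), mk(0.0)).values == 0.0)
        assert np.all(total_activation(mk(1.0), mk(0.0)).values == 1.0)
        assert np.all(total_activation(mk(0.0), mk(1.0)).values == -1.0)
        assert total_activation(mk(0.3), mk(0.5)).values[0] == pytest.approx(-0.2)

    def test_length_mismatch_rejected(self):
        a = TimeSeries(0.0, 100.0, np.zeros(10))
        b = TimeSeries(0.0, 100.0, np.zeros(11))
        with pytest.raises(ValueError):
            total_activation(a, b)
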