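"""Inverse torque derivation and forward parameter fitting."""

import numpy as np
import pytest

from emgelbow.activation import apply_model, make_spec, total_activation
from emgelbow.muscle import default_params, tendon_force
from emgelbow.optimization import (
    FitOptions,
    derive_control_activation,
    estimate_muscle_torque,
    fit_activation_model,
    inverse_total_muscle_torque,
    run_inverse,
)
from emgelbow.signal_processing import MotionDataset
from emgelbow.skeletal import SkeletalParameters, gravity_moment, moment_arm
from emgelbow.timeseries import TimeSeries

from conftest import smooth_drive


def _dataset(theta_values, rate=100.0, u_f=None, u_e=None, held_mass=0.0, motion="FE"):
    n = len(theta_values)
    mk = lambda v, u="dimensionless": TimeSeries(0.0, rate, v, u)
    theta = mk(np.asarray(theta_values, float), "rad")
    from emgelbow.signal_processing import differentiate

    vel, acc = differentiate(theta)
    return MotionDataset(
        subject_id="S01",
        motion_id=motion,
        repetition=0,
        held_mass=held_mass,
        u_flexor=mk(u_f if u_f is not None else np.zeros(n)),
        u_extensor=mk(u_e if u_e is not None else np.zeros(n)),
        theta=theta,
        theta_dot=vel,
        theta_ddot=acc,
    )


class TestInverseTorque:
    def test_static_hold_horizontal_needs_no_muscle_torque(self):
        sk = SkeletalParameters(body_mass=70.0, forearm_length=0.25, posture="horizontal")
        ds = _dataset(np.full(50, np.deg2rad(40.0)))
        m = inverse_total_muscle_torque(ds, sk)
        assert np.allclose(m.values, 0.0, atol=1e-12)

    def test_static_hold_vertical_balances_gravity(self, skeletal):
        ds = _dataset(np.full(50, np.pi / 2))
        m = inverse_total_muscle_torque(ds, skeletal)
        assert np.allclose(m.values, -gravity_moment(np.pi / 2, skeletal), atol=1e-10)

    def test_closed_form_agrees_with_scalar_minimizer(self, skeletal, rng):
        t = np.arange(60) / 100.0
        theta = 0.9 + 0.5 * np.sin(2 * np.pi * 0.4 * t) + 0.02 * rng.normal(size=60)
        ds = _dataset(theta, held_mass=1.0, motion="FEM")
        closed = inverse_total_muscle_torque(ds, skeletal, method="closed_form")
        mini = inverse_total_muscle_torque(ds, skeletal, method="minimize")
        assert np.max(np.abs(closed.values - mini.values)) < 1e-6

    def test_unreachable_torque_clipped_with_warning(self, skeletal, biceps, triceps):
        # absurd acceleration demands more torque than both muscles can give
        t = np.arange(50) / 100.0
        ds = _dataset(1.0 + 200.0 * np.sin(2 * np.pi * 5.0 * t))
        with pytest.warns(RuntimeWarning):
            m = inverse_total_muscle_torque(ds, skeletal, biceps, triceps)
        from emgelbow.optimization import torque_bound

        assert np.max(np.abs(m.values)) <= torque_bound(ds, biceps, triceps) + 1e-9


class TestControlActivation:
    def test_passive_only_torque_gives_zero_activation(self, biceps):
        ds = _dataset(np.full(50, 1.0))
        r = moment_arm(1.0, biceps.lmt_coeffs)
        state = biceps.state(1.0, 0.0)
        from emgelbow.muscle import passive_force, pennation

        f_passive = passive_force(state.lm, biceps) * np.cos(state.phi)
        m = ds.theta.with_values(np.full(50, r * f_passive), units_label="N*m")
        a = derive_control_activation(m, ds.theta, ds.theta_dot, biceps)
        assert np.allclose(a.values, 0.0, atol=1e-10)

    def test_round_trip_reproduces_torque(self, biceps, rng):
        t = np.arange(80) / 100.0
        ds = _dataset(0.8 + 0.4 * np.sin(2 * np.pi * 0.3 * t))
        m_target = ds.theta.with_values(rng.uniform(-3.0, 6.0, 80), units_label="N*m")
        a = derive_control_activation(m_target, ds.theta, ds.theta_dot, biceps)
        r = moment_arm(ds.theta.values, biceps.lmt_coeffs)
        state = biceps.state(ds.theta.values, ds.theta_dot.values)
        back = r * tendon_force(a.values, state, biceps)
        unclipped = np.abs(a.values) < 1.0
        assert np.max(np.abs(back[unclipped] - m_target.values[unclipped])) < 1e-6

    def test_extension_directed_torque_gives_negative_activation(self, biceps):
        ds = _dataset(np.full(50, 1.0))
        m = ds.theta.with_values(np.full(50, -4.0), units_label="N*m")
        a = derive_control_activation(m, ds.theta, ds.theta_dot, biceps)
        assert np.all(a.values < 0.0)


class TestForwardFit:
    def _fit_direct(self, truth, rng, model_id=None, n=601, options=None):
        """Fit on a_TI generated directly by the truth model."""
        u_f = smooth_drive(rng, duration=(n - 1) / 100.0)
        u_e = smooth_drive(rng, duration=(n - 1) / 100.0, hi=0.4)
        a_ti = total_activation(apply_model(truth, u_f), apply_model(truth, u_e))
        ds = _dataset(np.full(n, 1.0), u_f=u_f.values, u_e=u_e.values)
        return fit_activation_model(
            model_id or truth.model_id, ds, a_ti, options or FitOptions(seed=7)
        )

    def test_model1_parameter_recovery(self, rng):
        truth = make_spec(1, -2.0)
        u_f = smooth_drive(rng)
        a_ti = apply_model(truth, u_f)
        ds = _dataset(np.full(u_f.n, 1.0), u_f=u_f.values)
        fr = fit_activation_model(1, ds, a_ti, FitOptions(seed=3))
        assert abs(fr.spec.A1 - (-2.0)) < 0.05
        assert fr.ea < 1e-4

    def test_model6_parameter_recovery(self, rng):
        truth = make_spec(6, 0.030, 0.040)
        fr = self._fit_direct(truth, rng)
        assert abs(fr.spec.A1 - 0.030) / 0.030 < 0.2
        assert abs(fr.spec.A2 - 0.040) / 0.040 < 0.2
        assert fr.ea < 1e-3

    def test_degenerate_all_zero_fit(self):
        ds = _dataset(np.full(200, 1.0))
        a_ti = TimeSeries(0.0, 100.0, np.zeros(200))
        fr = fit_activation_model(2, ds, a_ti, FitOptions(seed=1))
        assert fr.ea == pytest.approx(0.0, abs=1e-12)

    def test_fitted_parameters_respect_bounds(self, rng):
        truth = make_spec(5, 0.02, 0.05)
        for model_id in (1, 3, 7):
            fr = self._fit_direct(truth, rng, model_id=model_id)
            info = fr.spec.info
            for p, (lo, hi) in zip(fr.spec.params, info.bounds):
                assert lo <= p <= hi

    def test_accepted_start_improves_on_box_centre(self, rng):
        """The returned optimum is no worse than the first (centre) start."""
        truth = make_spec(4, 0.015, 0.06)
        u_f = smooth_drive(rng)
        a_ti = apply_model(truth, u_f)
        ds = _dataset(np.full(u_f.n, 1.0), u_f=u_f.values)
        fr = fit_activation_model(4, ds, a_ti, FitOptions(seed=5))
        centre = make_spec(4, 0.0355, 0.0355)
        a_centre = apply_model(centre, ds.u_flexor)
        sse_centre = float(np.sum((a_ti.values - a_centre.values) ** 2))
        sse_fit = float(np.sum((a_ti.values - fr.a_tf.values) ** 2))
        assert sse_fit <= sse_centre + 1e-12

    def test_one_parameter_models_use_fewer_objective_evaluations(self, rng):
        truth = make_spec(6, 0.03, 0.05)
        evals = {}
        u_f = smooth_drive(rng)
        u_e = smooth_drive(rng, hi=0.4)
        a_ti = total_activation(apply_model(truth, u_f), apply_model(truth, u_e))
        ds = _dataset(np.full(u_f.n, 1.0), u_f=u_f.values, u_e=u_e.values)
        for model_id in range(1, 8):
            fr = fit_activation_model(model_id, ds, a_ti, FitOptions(seed=11))
            evals[model_id] = fr.n_evals
        one_param = max(evals[1], evals[2])
        two_param = min(evals[m] for m in (3, 4, 5, 6, 7))
        assert one_param < two_param


class TestTorqueEstimate:
    def test_zero_activation_slack_muscles_give_zero_torque(self):
        flexor = default_params("biceps", overrides={"k1_n_per_m": 0.0, "k2_n_per_m2": 0.0})
        extensor = default_params("triceps", overrides={"k1_n_per_m": 0.0, "k2_n_per_m2": 0.0})
        ds = _dataset(np.full(100, 1.0))
        spec = make_spec(2, 0.5)
        torque = estimate_muscle_torque(spec, ds, flexor, extensor)
        assert np.allclose(torque.values, 0.0, atol=1e-12)

    def test_flexor_only_activation_gives_positive_torque(self, biceps, triceps):
        ds = _dataset(np.full(100, 1.0), u_f=np.full(100, 0.6))
        spec = make_spec(2, 0.5)
        torque = estimate_muscle_torque(spec, ds, biceps, triceps)
        assert np.all(torque.values > 0.0)

    def test_identical_torques_have_zero_error(self):
        from emgelbow.metrics import torque_error

        x = np.linspace(-2, 2, 50)
        assert torque_error(x, x) == 0.0
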