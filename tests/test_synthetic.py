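"""Synthetic cohort generator: protocol, trajectories, ground truth, EMG."""

import dataclasses

import numpy as np
import pytest

import emgelbow as eg
from emgelbow.activation import apply_model, total_activation
from emgelbow.muscle import tendon_force
from emgelbow.signal_processing import differentiate, process_emg_channel
from emgelbow.skeletal import SkeletalParameters, moment_arm
from emgelbow.synthetic import (
    FES_START_ANGLES_DEG,
    MotionProtocolEntry,
    generate_cohort,
    generate_ground_truth_activations,
    generate_subject,
    generate_trajectory,
    subject_protocol,
    synthesize_raw_emg,
)
from emgelbow.timeseries import TimeSeries

from conftest import smooth_drive


class TestProtocol:
    def test_thirteen_trials_per_subject(self):
        entries = subject_protocol()
        assert len(entries) == 13
        counts = {}
        for e in entries:
            counts[e.motion_id] = counts.get(e.motion_id, 0) + 1
        assert counts == {"FE": 1, "EF120": 3, "FEM": 3, "FEP": 3, "FES": 3}

    def test_fem_carries_the_held_mass(self):
        assert all(
            e.held_mass == (1.0 if e.motion_id == "FEM" else 0.0)
            for e in subject_protocol()
        )

    def test_fes_start_angles(self):
        fes = [e for e in subject_protocol() if e.motion_id == "FES"]
        assert tuple(e.start_deg for e in fes) == FES_START_ANGLES_DEG


class TestTrajectories:
    def test_fe_attains_protocol_angles(self):
        theta = generate_trajectory(MotionProtocolEntry("FE", 0, 0.0), seed=0)
        deg = np.rad2deg(theta.values)
        assert abs(deg[0]) < 0.5
        assert abs(deg.max() - 120.0) < 0.5
        assert abs(deg[-1]) < 0.5

    @pytest.mark.parametrize("motion,rep", [("FE", 0), ("EF120", 0), ("FEP", 1), ("FES", 2)])
    def test_segment_boundaries_are_at_rest(self, motion, rep):
        entry = [e for e in subject_protocol() if e.motion_id == motion][min(rep, 2)]
        theta = generate_trajectory(entry, seed=5)
        vel, _ = differentiate(theta)
        # every dwell plateau must be genuinely still (central differences
        # need both neighbouring increments to vanish)
        diffs = np.abs(np.diff(theta.values)) < 1e-15
        interior_still = diffs[:-1] & diffs[1:]  # aligned with vel[1:-1]
        assert np.any(interior_still)
        assert np.max(np.abs(vel.values[1:-1][interior_still])) < 1e-6

    def test_fes_repetitions_start_where_the_protocol_says(self):
        for rep, start in enumerate(FES_START_ANGLES_DEG):
            entry = MotionProtocolEntry("FES", rep, start)
            theta = generate_trajectory(entry, seed=3)
            assert np.rad2deg(theta.values[0]) == pytest.approx(start, abs=0.5)

    def test_determinism(self):
        entry = MotionProtocolEntry("FEP", 0, 0.0, n_random_pauses=1)
        a = generate_trajectory(entry, seed=9)
        b = generate_trajectory(entry, seed=9)
        assert np.array_equal(a.values, b.values)
        c = generate_trajectory(entry, seed=10)
        assert not np.array_equal(a.values, c.values)


class TestGroundTruth:
    def test_single_unit_torque_round_trip(self, tiny_cohort):
        """Re-simulating u through the truth model and the flexor-equivalent
        unit reproduces the required torque."""
        subj = tiny_cohort.subjects[0]
        for trial in tiny_cohort.trials[:4]:
            gt = trial.truth
            a_t = total_activation(
                apply_model(gt.truth, gt.u_flexor), apply_model(gt.truth, gt.u_extensor)
            )
            theta_dot, _ = differentiate(trial.position)
            state = subj.flexor.state(trial.position.values, theta_dot.values)
            r = moment_arm(trial.position.values, subj.flexor.lmt_coeffs)
            back = r * tendon_force(a_t.values, state, subj.flexor)
            rmse = np.sqrt(np.mean((back - gt.m_req.values) ** 2))
            assert rmse < 0.05

    def test_static_rest_horizontal_needs_no_activation(self):
        subj = generate_subject("S01", np.random.SeedSequence(2), truth_model=2, posture="horizontal")
        subj = dataclasses.replace(subj, co_contraction=0.0)
        theta = TimeSeries(0.0, 100.0, np.full(300, np.deg2rad(40.0)), "rad")
        gt = generate_ground_truth_activations(theta, subj)
        assert np.max(np.abs(gt.a_flexor.values)) < 1e-3
        assert np.max(np.abs(gt.a_extensor.values)) < 1e-3

    def test_constant_co_contraction_shows_in_the_antagonist(self):
        subj = generate_subject("S01", np.random.SeedSequence(2), truth_model=2, posture="horizontal")
        subj = dataclasses.replace(subj, co_contraction=0.1)
        theta = TimeSeries(0.0, 100.0, np.full(300, np.deg2rad(40.0)), "rad")
        gt = generate_ground_truth_activations(theta, subj)
        assert np.allclose(gt.a_extensor.values, 0.1, atol=1e-3)

    def test_antagonist_difference_equals_control_activation(self, tiny_cohort):
        for trial in tiny_cohort.trials:
            gt = trial.truth
            diff = gt.a_flexor.values - gt.a_extensor.values
            assert np.sqrt(np.mean((diff - gt.a_ti.values) ** 2)) < 1e-3


class TestRawEmg:
    def _cal(self):
        from emgelbow.signal_processing import MVCCalibration

        return MVCCalibration(emg_max=1e-3, emg_min=2e-5, muscle_label="flexor")

    def test_silent_muscle_stays_under_noise_floor(self):
        u = TimeSeries(0.0, 100.0, np.zeros(800), "dimensionless")
        raw = synthesize_raw_emg(u, 4000.0, self._cal(), seed=4)
        env = process_emg_channel(raw, self._cal())
        assert np.max(env.values) < 0.05

    def test_smooth_drive_is_recovered(self, rng):
        u = smooth_drive(rng, duration=8.0, hi=0.8)
        raw = synthesize_raw_emg(u, 4000.0, self._cal(), seed=6)
        env = process_emg_channel(raw, self._cal())
        u_ref = u.interp_at(env.times)
        corr = np.corrcoef(env.values, u_ref)[0, 1]
        assert corr > 0.9

    def test_determinism(self):
        u = TimeSeries(0.0, 100.0, np.linspace(0, 0.5, 200), "dimensionless")
        a = synthesize_raw_emg(u, 4000.0, self._cal(), seed=8)
        b = synthesize_raw_emg(u, 4000.0, self._cal(), seed=8)
        assert np.array_equal(a.values, b.values)


class TestCohort:
    def test_trial_counts_scale_with_subjects(self, tiny_cohort):
        assert len(tiny_cohort.trials) == 13
        six = generate_cohort(6, seed=2, emg_noise=False)
        assert len(six.trials) == 78

    def test_motion_multiset_per_subject(self, tiny_cohort):
        counts = {}
        for t in tiny_cohort.trials:
            counts[t.motion_id] = counts.get(t.motion_id, 0) + 1
        assert counts == {"FE": 1, "EF120": 3, "FEM": 3, "FEP": 3, "FES": 3}

    def test_subject_parameters_within_shipped_ranges(self):
        cohort = generate_cohort(3, seed=5, emg_noise=False)
        from emgelbow.muscle import load_muscle_defaults

        table = load_muscle_defaults()
        for s in cohort.subjects:
            lo, hi = table["biceps"]["lmo_m"]
            assert lo <= s.flexor.lmo <= hi
            lo, hi = table["triceps"]["lmo_m"]
            assert lo <= s.extensor.lmo <= hi
            assert 0.0 <= s.co_contraction <= 0.3

    def test_identical_seed_gives_identical_cohort(self):
        a = generate_cohort(2, seed=21, emg_noise=True)
        b = generate_cohort(2, seed=21, emg_noise=True)
        for ta, tb in zip(a.trials, b.trials):
            assert np.array_equal(ta.position.values, tb.position.values)
            assert np.array_equal(ta.emg_flexor.values, tb.emg_flexor.values)
            assert np.array_equal(ta.truth.u_flexor.values, tb.truth.u_flexor.values)
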