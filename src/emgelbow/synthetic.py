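"""Synthetic cohort generator emulating the study's collection protocol.

A cohort of virtual subjects each performs the 13-trial elbow protocol:

* FE    x1 — full flexion-extension, 0 -> 120 deg -> 0;
* EF120 x3 — starting flexed at 120 deg, extend to 0, return;
* FEM   x3 — FE while holding a 1-kg mass in the hand;
* FEP   x3 — FE with one subject-chosen pause per movement direction;
* FES   x3 — flexion to 120 deg starting from 20, 60 and 100 deg.

Trajectories are concatenated minimum-jerk segments (zero boundary velocity
and acceleration) with dwell pauses, at a nominal 30 deg/s movement speed
(a full 240-degree repetition spends 8 s moving — the "very slow" speed the
protocol asks of subjects).

Ground truth runs the estimation chain in reverse so every pipeline stage
has a known answer: the trajectory's required torque (free motion, joint
moment zero) is inverted through the single flexor-equivalent unit into the
control activation a_TI, split into antagonist activations with a constant
baseline co-contraction (a_f - a_e = a_TI by construction), and each
muscle's activation is pushed backwards through the subject's true
activation model to the neural drive u(t). Raw EMG is then band-limited
Gaussian noise amplitude-modulated by u — only the 3-Hz envelope reaches
the motion model, so no motor-unit structure is needed — and the processed
envelope of the synthetic signal recovers the generating drive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .activation import (
    ActivationModelSpec,
    MODEL_REGISTRY,
    make_spec,
    static_inverse,
    track_activation,
)
from .errors import InfeasibleTrajectoryError, InvalidParameterError
from .muscle import MusculotendonParameters, default_params, load_muscle_defaults
from .optimization import derive_control_activation
from .signal_processing import MVCCalibration, differentiate
from .skeletal import SkeletalParameters, gravity_moment, passive_joint_torque
from .timeseries import TimeSeries

__all__ = [
    "MotionProtocolEntry",
    "SyntheticSubject",
    "GroundTruth",
    "SyntheticTrial",
    "Cohort",
    "subject_protocol",
    "generate_trajectory",
    "generate_ground_truth_activations",
    "synthesize_raw_emg",
    "generate_mvc_recording",
    "generate_subject",
    "generate_cohort",
]

TARGET_ANGLE_DEG = 120.0
FES_START_ANGLES_DEG = (20.0, 60.0, 100.0)
NOMINAL_SPEED_DEG_S = 30.0       # 240 deg of movement in the 8-s budget
DWELL_S = 1.0                    # pause at the turn-around point
MID_PAUSE_S = 0.5                # FEP subject-chosen pauses
LEAD_HOLD_S = 0.5                # rest before/after the movement
EMG_NOISE_FLOOR = 0.02           # resting EMG amplitude as a fraction of MVC


@dataclass(frozen=True)
class MotionProtocolEntry:
    """One trial of the collection protocol."""

    motion_id: str
    repetition: int
    start_deg: float
    target_deg: float = TARGET_ANGLE_DEG
    held_mass: float = 0.0
    n_random_pauses: int = 0     # per movement direction (FEP: 1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_deg < self.target_deg <= 150.0) and self.motion_id != "EF120":
            if not (0.0 <= self.start_deg <= 150.0):
                raise InvalidParameterError("angles must lie in [0, 150] deg")


def subject_protocol() -> list[MotionProtocolEntry]:
    """The 13 trials every subject performs: FE x1 + {EF120, FEM, FEP, FES} x3."""
    entries = [MotionProtocolEntry("FE", 0, 0.0)]
    for rep in range(3):
        entries.append(MotionProtocolEntry("EF120", rep, TARGET_ANGLE_DEG))
    for rep in range(3):
        entries.append(MotionProtocolEntry("FEM", rep, 0.0, held_mass=1.0))
    for rep in range(3):
        entries.append(MotionProtocolEntry("FEP", rep, 0.0, n_random_pauses=1))
    for rep in range(3):
        entries.append(MotionProtocolEntry("FES", rep, FES_START_ANGLES_DEG[rep]))
    return entries


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


def _waypoints(entry: MotionProtocolEntry, rng: np.random.Generator) -> list[tuple[float, float]]:
    """(angle_deg, dwell_after_s) sequence for one trial."""
    if entry.motion_id == "EF120":
        path = [entry.start_deg, 0.0, TARGET_ANGLE_DEG]
        dwells = [0.0, DWELL_S, 0.0]
    else:
        up = [entry.start_deg]
        up_dwell = [0.0]
        for _ in range(entry.n_random_pauses):
            up.append(float(rng.uniform(20.0, 100.0)))
            up_dwell.append(MID_PAUSE_S)
        up.sort()
        down = [0.0]
        down_dwell = [0.0]
        for _ in range(entry.n_random_pauses):
            down.append(float(rng.uniform(20.0, 100.0)))
            down_dwell.append(MID_PAUSE_S)
        down.sort(reverse=True)
        path = up + [entry.target_deg] + down
        dwells = up_dwell + [DWELL_S] + down_dwell
    # pauses must break the path into monotone runs; drop accidental repeats
    out = [(path[0], dwells[0])]
    for ang, dw in zip(path[1:], dwells[1:]):
        if abs(ang - out[-1][0]) < 1e-9:
            continue
        out.append((ang, dw))
    return out


def generate_trajectory(
    entry: MotionProtocolEntry,
    duration: float = 8.0,
    rate: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> TimeSeries:
    """Joint-angle trajectory (radians) for one protocol entry.

    ``duration`` is the movement-time budget of a full repetition (240 deg of
    travel); individual movement segments take time proportional to their
    angular distance, so every motion shares the same nominal speed. Segment
    boundaries have zero velocity and acceleration; FEP's random pause angles
    are drawn from the supplied seed.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    speed = 2.0 * TARGET_ANGLE_DEG / duration  # deg/s
    points = _waypoints(entry, rng)

    segments: list[tuple[str, float, float, float]] = [("hold", LEAD_HOLD_S, points[0][0], 0.0)]
    if points[0][1] > 0:
        segments.append(("hold", points[0][1], points[0][0], 0.0))
    for (a0, _), (a1, dwell) in zip(points[:-1], points[1:]):
        segments.append(("move", abs(a1 - a0) / speed, a0, a1))
        if dwell > 0:
            segments.append(("hold", dwell, a1, 0.0))
    segments.append(("hold", LEAD_HOLD_S, points[-1][0], 0.0))

    lengths = np.array([s[1] for s in segments])
    boundaries = np.concatenate([[0.0], np.cumsum(lengths)])
    total = boundaries[-1]
    n = int(round(total * rate)) + 1
    t = np.arange(n) / rate
    seg_idx = np.clip(np.searchsorted(boundaries, t, side="right") - 1, 0, len(segments) - 1)
    theta = np.empty(n)
    for k, (kind, length, a, b) in enumerate(segments):
        mask = seg_idx == k
        if not np.any(mask):
            continue
        if kind == "hold":
            theta[mask] = a
        else:
            tau = np.clip((t[mask] - boundaries[k]) / length, 0.0, 1.0)
            theta[mask] = a + (b - a) * _min_jerk(tau)
    return TimeSeries(0.0, rate, np.deg2rad(theta), "rad")


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSubject:
    """One virtual participant: anthropometry, muscles, EMG scale, truth model."""

    subject_id: str
    body_mass: float
    height: float
    forearm_length: float
    flexor: MusculotendonParameters
    extensor: MusculotendonParameters
    skeletal: SkeletalParameters
    cal_flexor: MVCCalibration
    cal_extensor: MVCCalibration
    truth: ActivationModelSpec
    co_contraction: float
    seed: int

    def cal(self, muscle: str) -> MVCCalibration:
        return self.cal_flexor if muscle == "flexor" else self.cal_extensor


def sample_truth_spec(model_id: int, rng: np.random.Generator) -> ActivationModelSpec:
    """Ground-truth parameters drawn from the interior of each model's box.

    Interior sampling keeps the recovery problem well-posed (no parameter
    pinned to a bound) and, for the slow Model 6, leaves rate headroom so the
    protocol's activation trajectories stay realizable with u <= 1.
    """
    if model_id == 1:
        return make_spec(1, rng.uniform(-2.5, -0.5))
    if model_id == 2:
        return make_spec(2, rng.uniform(0.1, 0.9))
    if model_id == 3:
        return make_spec(3, rng.uniform(0.02, 0.10), 10.0 ** rng.uniform(-1.3, 1.0))
    if model_id in (4, 5, 6, 7):
        return make_spec(model_id, rng.uniform(0.02, 0.06), rng.uniform(0.02, 0.06))
    raise InvalidParameterError(f"unknown model_id {model_id}")


def generate_subject(
    subject_id: str,
    seed_seq: np.random.SeedSequence,
    *,
    truth_model: int = 6,
    posture: str = "vertical",
) -> SyntheticSubject:
    """Sample one subject's anthropometry, muscle geometry and EMG scales."""
    rng = np.random.default_rng(seed_seq)
    body_mass = float(rng.uniform(55.0, 90.0))
    height = float(rng.uniform(1.55, 1.90))
    forearm = 0.146 * height  # Winter forearm-length proportionality
    table = load_muscle_defaults()
    lmo_f = float(rng.uniform(*table["biceps"]["lmo_m"]))
    lmo_e = float(rng.uniform(*table["triceps"]["lmo_m"]))
    cals = {}
    for muscle in ("flexor", "extensor"):
        v0 = float(rng.uniform(0.5e-3, 1.5e-3))  # MVC envelope amplitude, V
        cals[muscle] = MVCCalibration(
            emg_max=v0, emg_min=EMG_NOISE_FLOOR * v0, muscle_label=muscle
        )
    return SyntheticSubject(
        subject_id=subject_id,
        body_mass=body_mass,
        height=height,
        forearm_length=forearm,
        flexor=default_params("biceps", lmo_f),
        extensor=default_params("triceps", lmo_e),
        skeletal=SkeletalParameters(
            body_mass=body_mass, forearm_length=forearm, posture=posture
        ),
        cal_flexor=cals["flexor"],
        cal_extensor=cals["extensor"],
        truth=sample_truth_spec(truth_model, rng),
        co_contraction=float(rng.uniform(0.05, 0.15)),
        seed=int(seed_seq.generate_state(1)[0] % (2**31)),
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that the pipeline must re-derive."""

    m_req: TimeSeries        # required total muscle torque, N*m
    a_ti: TimeSeries         # control total activation through the flexor unit
    a_flexor: TimeSeries
    a_extensor: TimeSeries
    u_flexor: TimeSeries
    u_extensor: TimeSeries
    truth: ActivationModelSpec


def generate_ground_truth_activations(
    theta: TimeSeries,
    subj: SyntheticSubject,
    held_mass: float = 0.0,
) -> GroundTruth:
    """Reverse the estimation chain: trajectory -> torque -> a_TI -> u per muscle.

    The antagonist split happens in activation space: the agonist carries the
    net single-unit activation on top of the baseline co-contraction c, the
    antagonist holds c, so a_flexor - a_extensor = a_TI identically and a
    noiseless pipeline run can recover the generating model exactly.
    """
    theta_dot, theta_ddot = differentiate(theta)
    sk = subj.skeletal
    m_req = -(
        sk.inertia(held_mass) * theta_ddot.values
        + passive_joint_torque(theta_dot.values, sk.b)
        + gravity_moment(theta.values, sk, held_mass)
    )
    m_req_ts = theta.with_values(m_req, units_label="N*m")
    a_ti = derive_control_activation(m_req_ts, theta, theta_dot, subj.flexor)
    c = subj.co_contraction
    base_f = c + np.maximum(a_ti.values, 0.0)
    base_e = c + np.maximum(-a_ti.values, 0.0)
    worst = max(base_f.max(), base_e.max())
    if worst > 1.0:
        raise InfeasibleTrajectoryError(
            f"required muscle activation {worst:.2f} exceeds 1; slow the motion"
        )
    truth = subj.truth
    if not truth.is_dynamic:
        a_f_ts = theta.with_values(base_f, units_label="dimensionless")
        a_e_ts = theta.with_values(base_e, units_label="dimensionless")
        u_f = a_f_ts.with_values(static_inverse(truth, base_f))
        u_e = a_e_ts.with_values(static_inverse(truth, base_e))
    else:
        # ODE truth models with slow deactivation cannot drop an agonist as
        # fast as the net demand falls; real subjects resolve this with
        # co-contraction bursts at direction changes. The same trick keeps
        # a_f - a_e = a_TI realizable here: whatever one channel cannot shed
        # is added to the other channel instead, iterated until both achieved
        # trajectories are self-consistent.
        a_e_target = theta.with_values(base_e, units_label="dimensionless")
        for _ in range(3):
            a_f_target = a_e_target.with_values(
                np.clip(a_e_target.values + a_ti.values, 0.0, 1.0)
            )
            u_f, a_f_ach = track_activation(truth, a_f_target)
            a_e_target = a_f_ach.with_values(
                np.clip(a_f_ach.values - a_ti.values, 0.0, 1.0)
            )
            u_e, a_e_ach = track_activation(truth, a_e_target)
            a_e_target = a_e_ach
        a_f_ts, a_e_ts = a_f_ach, a_e_ach
    return GroundTruth(
        m_req=m_req_ts,
        a_ti=a_ti,
        a_flexor=a_f_ts,
        a_extensor=a_e_ts,
        u_flexor=u_f,
        u_extensor=u_e,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# raw EMG synthesis
# ---------------------------------------------------------------------------

_RECTIFIED_GAUSSIAN_MEAN = math.sqrt(2.0 / math.pi)  # E|N(0,1)|


def _carrier(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the surface-EMG band."""
    sos = sps.butter(4, [20.0, 300.0], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x / np.std(x)


def synthesize_raw_emg(
    u: TimeSeries,
    rate: float,
    cal: MVCCalibration,
    seed: int | np.random.Generator,
) -> TimeSeries:
    """Raw surface-EMG-like signal whose processed envelope recovers u(t).

    The neural drive amplitude-modulates band-limited Gaussian noise; the
    modulation depth is scaled so the rectified-and-smoothed envelope spans
    [emg_min, emg_max] as the drive spans [0, 1] (E|N(0, sigma)| = sigma *
    sqrt(2/pi)). A resting noise floor at emg_min keeps the envelope of a
    silent muscle at the calibration minimum rather than zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(u.duration * rate)) + 1
    t = u.start_time + np.arange(n) / rate
    drive = np.clip(u.interp_at(t), 0.0, 1.0)
    amplitude = (cal.emg_min + drive * (cal.emg_max - cal.emg_min)) / _RECTIFIED_GAUSSIAN_MEAN
    return TimeSeries(u.start_time, rate, amplitude * _carrier(n, rate, rng), "V")


def generate_mvc_recording(
    subj: SyntheticSubject,
    muscle: str,
    seed: int | np.random.Generator,
    *,
    rate: float = 4000.0,
) -> TimeSeries:
    """Raw MVC trial: rest, ramp to maximum effort, 4-s hold, release."""
    profile_rate = 100.0
    segs = [
        np.zeros(int(1.0 * profile_rate)),
        _min_jerk(np.linspace(0.0, 1.0, int(1.0 * profile_rate))),
        np.ones(int(4.0 * profile_rate)),
        _min_jerk(np.linspace(1.0, 0.0, int(1.0 * profile_rate))),
        np.zeros(int(1.0 * profile_rate) + 1),
    ]
    u = TimeSeries(0.0, profile_rate, np.concatenate(segs), "dimensionless")
    return synthesize_raw_emg(u, rate, subj.cal(muscle), seed)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTrial:
    """One generated trial: raw channels plus retained ground truth."""

    subject_id: str
    motion_id: str
    repetition: int
    held_mass: float
    position: TimeSeries                 # joint angle, rad, position rate
    emg_flexor: TimeSeries | None        # raw volts at the EMG rate (None if noiseless)
    emg_extensor: TimeSeries | None
    truth: GroundTruth


@dataclass(frozen=True)
class Cohort:
    subjects: list[SyntheticSubject]
    trials: list[SyntheticTrial]
    mvc_recordings: dict[tuple[str, str], TimeSeries]  # (subject_id, muscle) -> raw MVC
    seed: int
    emg_noise: bool


def generate_cohort(
    n_subjects: int = 6,
    seed: int = 0,
    *,
    truth_model: int = 6,
    emg_noise: bool = True,
    movement_duration: float = 8.0,
    position_rate: float = 100.0,
    emg_rate: float = 4000.0,
    posture: str = "vertical",
) -> Cohort:
    """Generate the full protocol for ``n_subjects`` virtual participants.

    Each subject contributes 13 trials (FE x1, EF120/FEM/FEP/FES x3), so six
    subjects give the study's 78 datasets. With ``emg_noise=False`` the raw
    EMG channels are omitted and the pipeline consumes the generating neural
    drive directly (the noiseless-envelope mode used by consistency tests).
    Identical (arguments, seed) produce an identical cohort.
    """
    if n_subjects < 1:
        raise InvalidParameterError("n_subjects must be >= 1")
    root = np.random.SeedSequence(seed)
    subject_seqs = root.spawn(n_subjects)
    subjects, trials, mvcs = [], [], {}
    for i, seq in enumerate(subject_seqs):
        subj = generate_subject(
            f"S{i + 1:02d}", seq, truth_model=truth_model, posture=posture
        )
        subjects.append(subj)
        trial_seqs = seq.spawn(14)
        if emg_noise:
            mvc_rng = np.random.default_rng(trial_seqs[13])
            for muscle in ("flexor", "extensor"):
                mvcs[(subj.subject_id, muscle)] = generate_mvc_recording(
                    subj, muscle, mvc_rng, rate=emg_rate
                )
        for entry, tseq in zip(subject_protocol(), trial_seqs[:13]):
            rng = np.random.default_rng(tseq)
            theta = generate_trajectory(entry, movement_duration, position_rate, rng)
            truth = generate_ground_truth_activations(theta, subj, entry.held_mass)
            if emg_noise:
                emg_f = synthesize_raw_emg(truth.u_flexor, emg_rate, subj.cal_flexor, rng)
                emg_e = synthesize_raw_emg(truth.u_extensor, emg_rate, subj.cal_extensor, rng)
            else:
                emg_f = emg_e = None
            trials.append(
                SyntheticTrial(
                    subject_id=subj.subject_id,
                    motion_id=entry.motion_id,
                    repetition=entry.repetition,
                    held_mass=entry.held_mass,
                    position=theta,
                    emg_flexor=emg_f,
                    emg_extensor=emg_e,
                    truth=truth,
                )
            )
    return Cohort(subjects=subjects, trials=trials, mvc_recordings=mvcs, seed=seed, emg_noise=emg_noise)
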