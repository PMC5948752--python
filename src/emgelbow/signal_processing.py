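"""Surface-EMG conditioning and kinematic preprocessing.

The chain implemented here turns two raw EMG channels and one encoder channel
into model inputs on a common time base:

    raw EMG (4000 Hz, V)
        -> band-pass 20-300 Hz (Butterworth, order 2, zero-phase)
        -> full-wave rectification
        -> MVC normalization: (e - EMGmin) / (EMGmax - EMGmin)
        -> low-pass 3 Hz (Butterworth, order 4, zero-phase)  = neural activation u(t)

    joint angle (100 Hz, deg at the file boundary, rad inside)
        -> linear upsample -> low-pass 3 Hz (order 4, zero-phase)
        -> central-difference velocity and acceleration

All filters are bilinear-transform Butterworth designs applied forward and
backward (zero net phase); the effective magnitude response is therefore the
square of the single-pass design, i.e. stop-band attenuation doubles in dB.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateCalibrationError,
    InvalidParameterError,
    SynchronizationError,
    TooShortInputError,
)
from .timeseries import TimeSeries

__all__ = [
    "MVCCalibration",
    "MotionDataset",
    "bandpass_emg",
    "rectify",
    "normalize_emg",
    "neural_activation",
    "resample_position",
    "differentiate",
    "synchronize",
]

logger = logging.getLogger(__name__)

MOTION_IDS = ("FE", "EF120", "FEM", "FEP", "FES")


@dataclass(frozen=True)
class MVCCalibration:
    """Amplitude extremes of one muscle's rectified, enveloped MVC recording.

    ``emg_max``/``emg_min`` are read from the rectified and 3-Hz low-passed
    maximum-voluntary-contraction recording (the processing stage is a package
    design choice; the normalization equation itself only needs the two
    extremes).
    """

    emg_max: float
    emg_min: float
    muscle_label: str = "flexor"

    def __post_init__(self) -> None:
        if not (self.emg_max > self.emg_min >= 0.0):
            raise DegenerateCalibrationError(
                f"require emg_max > emg_min >= 0, got "
                f"max={self.emg_max!r} min={self.emg_min!r}"
            )
        if self.muscle_label not in ("flexor", "extensor"):
            raise ValueError("muscle_label must be 'flexor' or 'extensor'")


@dataclass(frozen=True)
class MotionDataset:
    """Synchronized, processed inputs for one recorded (or synthetic) trial.

    All six series share the same rate and length. Angles are radians,
    flexion positive, 0 = full extension.
    """

    subject_id: str
    motion_id: str
    repetition: int
    held_mass: float
    u_flexor: TimeSeries
    u_extensor: TimeSeries
    theta: TimeSeries
    theta_dot: TimeSeries
    theta_ddot: TimeSeries

    def __post_init__(self) -> None:
        if self.motion_id not in MOTION_IDS:
            raise ValueError(f"motion_id must be one of {MOTION_IDS}")
        if self.held_mass < 0:
            raise ValueError("held_mass must be >= 0")
        series = [self.u_flexor, self.u_extensor, self.theta, self.theta_dot, self.theta_ddot]
        n0, r0 = series[0].n, series[0].rate
        for s in series[1:]:
            if s.n != n0 or s.rate != r0:
                raise ValueError("all channels must share rate and length")

    @property
    def rate(self) -> float:
        return self.u_flexor.rate

    @property
    def n(self) -> int:
        return self.u_flexor.n


# ---------------------------------------------------------------------------
# filtering primitives
# ---------------------------------------------------------------------------

def _check_padlen(values: np.ndarray, sos: np.ndarray) -> None:
    # sosfiltfilt needs > 3 * (2 * n_sections + 1) samples of padding room
    padlen = 3 * (2 * sos.shape[0] + 1)
    if values.size <= padlen:
        raise TooShortInputError(
            f"series of length {values.size} is shorter than the filter "
            f"warm-up length ({padlen + 1} samples required)"
        )


def bandpass_emg(raw: TimeSeries, low: float = 20.0, high: float = 300.0, order: int = 2) -> TimeSeries:
    """Zero-phase Butterworth band-pass; removes DC offset and high-frequency noise."""
    nyq = raw.rate / 2.0
    if not (0.0 < low < high < nyq):
        raise InvalidParameterError(
            f"require 0 < low < high < Nyquist ({nyq} Hz); got low={low}, high={high}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=raw.rate, output="sos")
    _check_padlen(raw.values, sos)
    return raw.with_values(sps.sosfiltfilt(sos, raw.values))


def rectify(filtered: TimeSeries) -> TimeSeries:
    """Full-wave rectification (element-wise absolute value)."""
    return filtered.with_values(np.abs(filtered.values))


def normalize_emg(rectified: TimeSeries, cal: MVCCalibration) -> TimeSeries:
    """Map rectified EMG into [0, 1] through the MVC extremes.

    enorm(t) = (e(t) - EMGmin) / (EMGmax - EMGmin), clipped to [0, 1].
    Values above 1 (trial exceeded the MVC) are clipped with a logged warning.
    """
    e = (rectified.values - cal.emg_min) / (cal.emg_max - cal.emg_min)
    n_over = int(np.sum(e > 1.0))
    if n_over:
        logger.warning(
            "%d samples exceeded the MVC calibration (%s); clipped to 1",
            n_over,
            cal.muscle_label,
        )
    return rectified.with_values(np.clip(e, 0.0, 1.0), units_label="dimensionless")


def neural_activation(enorm: TimeSeries, fc: float = 3.0, order: int = 4) -> TimeSeries:
    """Neural activation u(t): zero-phase low-pass envelope of normalized EMG."""
    if not (0.0 < fc < enorm.rate / 2.0):
        raise InvalidParameterError(f"cut-off {fc} Hz outside (0, Nyquist)")
    sos = sps.butter(order, fc, btype="lowpass", fs=enorm.rate, output="sos")
    _check_padlen(enorm.values, sos)
    u = sps.sosfiltfilt(sos, enorm.values)
    return enorm.with_values(np.clip(u, 0.0, 1.0), units_label="dimensionless")


def resample_position(pos: TimeSeries, target_rate: float, fc: float = 3.0, order: int = 4) -> TimeSeries:
    """Upsample the encoder signal by linear interpolation, then smooth.

    Matches the acquisition chain: position collected at 100 Hz is upsampled
    to the EMG rate and low-pass filtered (4th order, 3 Hz) to remove
    quantization noise.
    """
    if not (target_rate >= pos.rate and target_rate > 0):
        raise InvalidParameterError(
            f"target_rate must be a positive rate >= source rate {pos.rate}"
        )
    n_new = int(round(pos.duration * target_rate)) + 1
    t_new = pos.start_time + np.arange(n_new) / target_rate
    up = np.interp(t_new, pos.times, pos.values)
    upsampled = TimeSeries(pos.start_time, target_rate, up, pos.units_label)
    if not (0.0 < fc < target_rate / 2.0):
        raise InvalidParameterError(f"cut-off {fc} Hz outside (0, Nyquist)")
    sos = sps.butter(order, fc, btype="lowpass", fs=target_rate, output="sos")
    _check_padlen(up, sos)
    return upsampled.with_values(sps.sosfiltfilt(sos, up))


def differentiate(theta: TimeSeries) -> tuple[TimeSeries, TimeSeries]:
    """Central-difference angular velocity and acceleration.

    Interior points use second-order central differences, endpoints one-sided
    (``numpy.gradient`` semantics). Units: rad/s and rad/s^2.
    """
    if theta.n < 3:
        raise TooShortInputError("differentiation requires at least 3 samples")
    dt = theta.dt
    vel = np.gradient(theta.values, dt)
    acc = np.gradient(vel, dt)
    return (
        theta.with_values(vel, units_label="rad/s"),
        theta.with_values(acc, units_label="rad/s^2"),
    )


def synchronize(
    u_flex: TimeSeries,
    u_ext: TimeSeries,
    theta: TimeSeries,
    *,
    subject_id: str,
    motion_id: str,
    repetition: int = 0,
    held_mass: float = 0.0,
    processing_rate: float = 100.0,
) -> MotionDataset:
    """Crop all channels to their common time overlap on one processing grid.

    Channels may arrive with different start times and rates (EMG at 4000 Hz,
    position at 100 Hz); everything is linearly interpolated onto a shared
    grid at ``processing_rate``. All signals entering here are 3-Hz band
    limited, so decimation to 100 Hz is alias-free.
    """
    t0 = max(u_flex.start_time, u_ext.start_time, theta.start_time)
    t1 = min(u_flex.end_time, u_ext.end_time, theta.end_time)
    if t1 - t0 < 2.0 / processing_rate:
        raise SynchronizationError(
            f"channels share no usable overlap (t0={t0:.3f}, t1={t1:.3f})"
        )
    n = int(np.floor((t1 - t0) * processing_rate)) + 1
    t = t0 + np.arange(n) / processing_rate

    def _grid(ts: TimeSeries, label: str) -> TimeSeries:
        return TimeSeries(t0, processing_rate, ts.interp_at(t), label)

    th = _grid(theta, "rad")
    vel, acc = differentiate(th)
    return MotionDataset(
        subject_id=subject_id,
        motion_id=motion_id,
        repetition=repetition,
        held_mass=held_mass,
        u_flexor=_grid(u_flex, "dimensionless"),
        u_extensor=_grid(u_ext, "dimensionless"),
        theta=th,
        theta_dot=vel,
        theta_ddot=acc,
    )


def process_emg_channel(
    raw: TimeSeries,
    cal: MVCCalibration,
    *,
    band: tuple[float, float] = (20.0, 300.0),
    bandpass_order: int = 2,
    envelope_fc: float = 3.0,
    envelope_order: int = 4,
) -> TimeSeries:
    """Full raw-EMG -> neural-activation chain for one channel."""
    x = bandpass_emg(raw, band[0], band[1], bandpass_order)
    x = rectify(x)
    x = normalize_emg(x, cal)
    return neural_activation(x, envelope_fc, envelope_order)


def mvc_calibration_from_recording(
    raw_mvc: TimeSeries,
    muscle_label: str,
    *,
    band: tuple[float, float] = (20.0, 300.0),
    bandpass_order: int = 2,
    envelope_fc: float = 3.0,
    envelope_order: int = 4,
) -> MVCCalibration:
    """Read EMGmax/EMGmin from a raw MVC recording.

    The extremes are taken from the rectified, 3-Hz low-passed recording so
    that single-sample spikes do not define the calibration.
    """
    x = rectify(bandpass_emg(raw_mvc, band[0], band[1], bandpass_order))
    sos = sps.butter(envelope_order, envelope_fc, btype="lowpass", fs=x.rate, output="sos")
    _check_padlen(x.values, sos)
    env = sps.sosfiltfilt(sos, x.values)
    emg_max = float(np.max(env))
    emg_min = float(max(np.min(env), 0.0))
    if emg_max <= emg_min:
        raise DegenerateCalibrationError("MVC recording has no amplitude range")
    return MVCCalibration(emg_max=emg_max, emg_min=emg_min, muscle_label=muscle_label)
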