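"""Uniformly sampled time series, the common currency of every module.

All signals in the pipeline — raw EMG (V), normalized EMG, neural activation
u(t), joint angle (rad) and its derivatives — are carried as :class:`TimeSeries`.
Internal units are SI (volts, radians, seconds); degrees appear only at file
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["TimeSeries"]


@dataclass(frozen=True)
class TimeSeries:
    """A finite, uniformly sampled real-valued signal.

    Parameters
    ----------
    start_time:
        Time of the first sample, in seconds.
    rate:
        Sampling rate in Hz; must be positive.
    values:
        Ordered samples; all finite, length >= 2.
    units_label:
        Free-text unit tag ("V", "rad", "dimensionless", ...).
    """

    start_time: float
    rate: float
    values: np.ndarray
    units_label: str = "dimensionless"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("TimeSeries requires a 1-D array of length >= 2")
        if not np.all(np.isfinite(vals)):
            raise ValueError("TimeSeries samples must all be finite")
        if not (self.rate > 0):
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "values", vals)

    # -- derived quantities -------------------------------------------------

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def end_time(self) -> float:
        """Time of the last sample."""
        return self.start_time + (self.n - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate

    @property
    def duration(self) -> float:
        return (self.n - 1) * self.dt

    # -- helpers ------------------------------------------------------------

    def with_values(self, values: np.ndarray, units_label: str | None = None) -> "TimeSeries":
        """Same time base, new samples (length must match)."""
        vals = np.asarray(values, dtype=float)
        if vals.shape != self.values.shape:
            raise ValueError("with_values requires matching length")
        return replace(
            self,
            values=vals,
            units_label=self.units_label if units_label is None else units_label,
        )

    def crop(self, t0: float, t1: float) -> "TimeSeries":
        """Samples with t0 <= t <= t1 (inclusive, tolerant to rounding)."""
        eps = 0.5 * self.dt
        t = self.times
        mask = (t >= t0 - eps) & (t <= t1 + eps)
        idx = np.flatnonzero(mask)
        if idx.size < 2:
            raise ValueError("crop would leave fewer than 2 samples")
        return replace(
            self,
            start_time=float(t[idx[0]]),
            values=self.values[idx[0] : idx[-1] + 1],
        )

    def interp_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the samples at arbitrary times."""
        return np.interp(t, self.times, self.values)
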