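"""Performance metrics and grouped statistical comparisons.

Three metrics are attached to every (trial, model) fit:

* ``ea``  — RMSE between the inversely-derived and forward-derived total
  muscle activation (dimensionless, on the [-1, 1] activation scale);
* ``eT``  — RMSE between the optimized and estimated total muscle torque (N*m);
* ``Tdp`` — optimization time per data point (microseconds), measured around
  the objective-evaluation loop only, so it reflects optimization cost
  rather than I/O.

Group summaries (by model, motion and parameter count) and pairwise
Kruskal-Wallis H tests mirror the study's reporting; the H statistic is
delegated to :func:`scipy.stats.kruskal` (tie-corrected, chi-square p-value).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .activation import MODEL_REGISTRY
from .timeseries import TimeSeries

__all__ = [
    "MetricsRecord",
    "activation_error",
    "torque_error",
    "datapoint_time",
    "records_to_frame",
    "summarize_groups",
    "compare_groups",
]

ALPHA = 0.05


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)


def _rmse(a, b) -> float:
    a, b = _values(a), _values(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 1:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def activation_error(a_ti, a_tf) -> float:
    """Total muscle activation error ea: RMSE of aTI - aTF, dimensionless."""
    return _rmse(a_ti, a_tf)


def torque_error(m_ti, m_tf) -> float:
    """Total muscle torque error eT: RMSE of the torque residual, N*m."""
    return _rmse(m_ti, m_tf)


def datapoint_time(t_opt: float, n_dp: int) -> float:
    """Optimization time per data point, microseconds."""
    if n_dp <= 0:
        raise ValueError("n_dp must be positive")
    if t_opt < 0:
        raise ValueError("t_opt must be >= 0")
    return 1e6 * t_opt / n_dp


@dataclass(frozen=True)
class MetricsRecord:
    """One row of the long-format results grid."""

    subject_id: str
    motion_id: str
    repetition: int
    model_id: int
    n_params: int
    ea: float
    et: float
    t_dp_us: float
    ns: int

    def __post_init__(self) -> None:
        if self.ea < 0 or self.et < 0 or self.t_dp_us < 0:
            raise ValueError("metrics must be non-negative")
        expected = MODEL_REGISTRY[self.model_id].n_params
        if self.n_params != expected:
            raise ValueError(
                f"model {self.model_id} has {expected} parameters, not {self.n_params}"
            )


def records_to_frame(records: Iterable[MetricsRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([asdict(r) for r in records])


_METRIC_COLS = ("ea", "et", "t_dp_us")


def _group_rows(df: pd.DataFrame, factor: str) -> pd.DataFrame:
    rows = []
    for value, sub in df.groupby(factor, sort=True):
        row = {"factor": factor, "group": value, "n_datasets": len(sub)}
        for col in _METRIC_COLS:
            vals = sub[col].to_numpy()
            row[f"{col}_mean"] = float(np.mean(vals))
            row[f"{col}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_groups(records) -> pd.DataFrame:
    """Mean +/- sd of every metric by model, motion and parameter count.

    Returns one row per model (7 on a full run), per motion (5), per
    parameter count (2) and a pooled "total" row, with per-group dataset
    counts — the layout of the study's comparison table.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    parts = [
        _group_rows(df, "model_id"),
        _group_rows(df, "motion_id"),
        _group_rows(df, "n_params"),
    ]
    total = {"factor": "total", "group": "all", "n_datasets": len(df)}
    for col in _METRIC_COLS:
        vals = df[col].to_numpy()
        total[f"{col}_mean"] = float(np.mean(vals))
        total[f"{col}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    parts.append(pd.DataFrame([total]))
    return pd.concat(parts, ignore_index=True)


def compare_groups(records, factor: str, metric: str) -> pd.DataFrame:
    """Pairwise Kruskal-Wallis H tests of ``metric`` between ``factor`` levels.

    One row per unordered pair of groups with the tie-corrected H statistic,
    its chi-square p-value and a significance flag at alpha = 0.05. Two
    identical samples give H = 0.
    """
    df = records_to_frame(records)
    if metric not in _METRIC_COLS:
        raise ValueError(f"metric must be one of {_METRIC_COLS}")
    groups = {value: sub[metric].to_numpy() for value, sub in df.groupby(factor, sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for value, vals in groups.items():
        if vals.size == 0:
            raise ValueError(f"group {value!r} is empty")
    rows = []
    for ga, gb in itertools.combinations(sorted(groups), 2):
        a, b = groups[ga], groups[gb]
        if np.array_equal(np.sort(a), np.sort(b)):
            h, p = 0.0, 1.0  # identical samples: all rank sums equal
        else:
            h, p = stats.kruskal(a, b)
        rows.append(
            {
                "factor": factor,
                "metric": metric,
                "group_a": ga,
                "group_b": gb,
                "h": float(h),
                "p": float(p),
                "significant": bool(p < ALPHA),
            }
        )
    return pd.DataFrame(rows)
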