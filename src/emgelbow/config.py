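"""Run configuration: one flat, YAML-serialisable record of every knob."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .activation import MODEL_IDS
from .errors import InvalidParameterError

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full evaluation run.

    The cohort comes either from the synthetic generator (default) or from a
    saved cohort directory (``cohort_dir``). Rates and filter settings mirror
    the acquisition chain: EMG at 4000 Hz, encoder at 100 Hz, band-pass
    20-300 Hz order 2, envelope cut-off 3 Hz order 4. Model computation after
    synchronization runs at ``processing_rate_hz``.
    """

    # cohort
    n_subjects: int = 6
    seed: int = 0
    truth_model: int = 6
    emg_noise: bool = True
    posture: str = "vertical"
    movement_duration_s: float = 8.0
    cohort_dir: str | None = None
    # models to fit
    models: tuple[int, ...] = MODEL_IDS
    # signal processing
    emg_rate_hz: float = 4000.0
    position_rate_hz: float = 100.0
    processing_rate_hz: float = 100.0
    bandpass_hz: tuple[float, float] = (20.0, 300.0)
    bandpass_order: int = 2
    envelope_fc_hz: float = 3.0
    envelope_order: int = 4
    # forward optimization
    n_starts: int = 5
    max_iter: int = 200
    # output
    output_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        models = tuple(int(m) for m in self.models)
        if not models or not set(models) <= set(MODEL_IDS):
            raise InvalidParameterError(f"models must be a non-empty subset of {MODEL_IDS}")
        object.__setattr__(self, "models", models)
        object.__setattr__(self, "bandpass_hz", tuple(float(x) for x in self.bandpass_hz))
        if self.n_subjects < 1 and self.cohort_dir is None:
            raise InvalidParameterError("n_subjects must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        d["bandpass_hz"] = list(self.bandpass_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
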