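"""Full-study orchestration: cohort -> inverse -> forward fits -> reports.

``run_full_evaluation`` reproduces the study design end to end: a cohort
(synthetic or loaded from disk) is processed trial by trial; each trial gets
one inverse optimization (control torque and activation) and one forward fit
per requested activation model; every fit yields a metrics record; the
records feed the grouped summary and the pairwise Kruskal-Wallis
comparisons. Failures are isolated per trial — a bad trial is logged and
skipped, the run continues.

Cohort directories are plain CSV: per-channel signal files with columns
``time_s,value`` (angles in degrees at the file boundary), a ``subjects.csv``
with anthropometry, calibration and ground-truth parameters, and a
``trials.csv`` manifest. Saved and reloaded cohorts process identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .activation import MODEL_REGISTRY, make_spec
from .config import RunConfig
from .errors import DatasetFormatError
from .metrics import MetricsRecord, compare_groups, records_to_frame, summarize_groups
from .muscle import default_params
from .optimization import FitOptions, ForwardResult, InverseResult, fit_activation_model, run_inverse
from .signal_processing import (
    MVCCalibration,
    MotionDataset,
    mvc_calibration_from_recording,
    process_emg_channel,
    resample_position,
    synchronize,
)
from .skeletal import SkeletalParameters
from .synthetic import (
    Cohort,
    GroundTruth,
    SyntheticSubject,
    SyntheticTrial,
    generate_cohort,
)
from .timeseries import TimeSeries

__all__ = [
    "RunResult",
    "run_full_evaluation",
    "process_trial",
    "evaluate_trial",
    "save_cohort",
    "load_dataset_dir",
    "results_hash",
]

logger = logging.getLogger(__name__)

_METRIC_FACTORS = ("model_id", "motion_id", "n_params")
_METRICS = ("ea", "et", "t_dp_us")
#: wall-clock columns excluded from determinism hashes
TIMING_COLUMNS = ("t_dp_us",)


@dataclass
class RunResult:
    """Everything a full evaluation produces."""

    config: RunConfig
    records: list[MetricsRecord]
    results: pd.DataFrame          # long format, one row per (trial, model)
    summary: pd.DataFrame
    comparisons: pd.DataFrame
    inverse: dict[tuple[str, str, int], InverseResult]
    forward: dict[tuple[str, str, int, int], ForwardResult]
    failures: list[dict]
    manifest: dict

    @property
    def n_datasets(self) -> int:
        return len({k for k in self.inverse})

    @property
    def n_forward(self) -> int:
        return len(self.forward)


# ---------------------------------------------------------------------------
# per-trial processing
# ---------------------------------------------------------------------------

def process_trial(
    trial: SyntheticTrial,
    cal_flexor: MVCCalibration,
    cal_extensor: MVCCalibration,
    cfg: RunConfig,
) -> MotionDataset:
    """Raw trial channels -> synchronized, processed MotionDataset.

    With raw EMG present the full conditioning chain runs at the EMG rate and
    the encoder channel is upsampled and smoothed before synchronization; in
    noiseless-envelope mode the generator's neural drive enters directly.
    """
    if trial.emg_flexor is not None and trial.emg_extensor is not None:
        kwargs = dict(
            band=cfg.bandpass_hz,
            bandpass_order=cfg.bandpass_order,
            envelope_fc=cfg.envelope_fc_hz,
            envelope_order=cfg.envelope_order,
        )
        u_f = process_emg_channel(trial.emg_flexor, cal_flexor, **kwargs)
        u_e = process_emg_channel(trial.emg_extensor, cal_extensor, **kwargs)
        theta = resample_position(
            trial.position, cfg.emg_rate_hz, cfg.envelope_fc_hz, cfg.envelope_order
        )
    else:
        u_f = trial.truth.u_flexor
        u_e = trial.truth.u_extensor
        theta = trial.position
    return synchronize(
        u_f,
        u_e,
        theta,
        subject_id=trial.subject_id,
        motion_id=trial.motion_id,
        repetition=trial.repetition,
        held_mass=trial.held_mass,
        processing_rate=cfg.processing_rate_hz,
    )


def _fit_seed(run_seed: int, subject_id: str, motion_id: str, rep: int, model_id: int) -> int:
    """Deterministic per-fit seed below 2**31."""
    key = f"{run_seed}|{subject_id}|{motion_id}|{rep}|{model_id}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def evaluate_trial(
    ds: MotionDataset,
    subj: SyntheticSubject,
    cfg: RunConfig,
) -> tuple[InverseResult, dict[int, ForwardResult], list[MetricsRecord]]:
    """Inverse optimization plus one forward fit per requested model."""
    inv = run_inverse(ds, subj.skeletal, subj.flexor, subj.extensor)
    forwards: dict[int, ForwardResult] = {}
    records: list[MetricsRecord] = []
    for model_id in cfg.models:
        options = FitOptions(
            n_starts=cfg.n_starts,
            max_iter=cfg.max_iter,
            seed=_fit_seed(cfg.seed, ds.subject_id, ds.motion_id, ds.repetition, model_id),
        )
        fr = fit_activation_model(
            model_id,
            ds,
            inv.a_ti,
            options,
            flexor=subj.flexor,
            extensor=subj.extensor,
            m_tm=inv.m_tm,
        )
        forwards[model_id] = fr
        records.append(
            MetricsRecord(
                subject_id=ds.subject_id,
                motion_id=ds.motion_id,
                repetition=ds.repetition,
                model_id=model_id,
                n_params=MODEL_REGISTRY[model_id].n_params,
                ea=fr.ea,
                et=fr.et,
                t_dp_us=fr.t_dp_us,
                ns=ds.n,
            )
        )
    return inv, forwards, records


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _cohort_calibrations(cohort: Cohort) -> dict[tuple[str, str], MVCCalibration]:
    """Pipeline-visible calibrations: measured from MVC recordings when present."""
    cals: dict[tuple[str, str], MVCCalibration] = {}
    for subj in cohort.subjects:
        for muscle in ("flexor", "extensor"):
            rec = cohort.mvc_recordings.get((subj.subject_id, muscle))
            if rec is None:
                cals[(subj.subject_id, muscle)] = subj.cal(muscle)
            else:
                cals[(subj.subject_id, muscle)] = mvc_calibration_from_recording(rec, muscle)
    return cals


def run_full_evaluation(cfg: RunConfig, cohort: Cohort | None = None) -> RunResult:
    """Run the whole study under one configuration.

    Counts on a default run: n_subjects*13 datasets and datasets*len(models)
    forward results (6 subjects, 7 models -> 78 and 546).
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    t_start = time.perf_counter()
    if cohort is None:
        if cfg.cohort_dir is not None:
            cohort = load_dataset_dir(cfg.cohort_dir)
        else:
            cohort = generate_cohort(
                cfg.n_subjects,
                cfg.seed,
                truth_model=cfg.truth_model,
                emg_noise=cfg.emg_noise,
                movement_duration=cfg.movement_duration_s,
                position_rate=cfg.position_rate_hz,
                emg_rate=cfg.emg_rate_hz,
                posture=cfg.posture,
            )
    cals = _cohort_calibrations(cohort)
    subjects = {s.subject_id: s for s in cohort.subjects}

    records: list[MetricsRecord] = []
    inverse: dict[tuple[str, str, int], InverseResult] = {}
    forward: dict[tuple[str, str, int, int], ForwardResult] = {}
    failures: list[dict] = []
    for trial in cohort.trials:
        key = (trial.subject_id, trial.motion_id, trial.repetition)
        try:
            subj = subjects[trial.subject_id]
            ds = process_trial(
                trial, cals[(subj.subject_id, "flexor")], cals[(subj.subject_id, "extensor")], cfg
            )
            inv, fwd, recs = evaluate_trial(ds, subj, cfg)
        except Exception as exc:  # failure isolation: keep the batch running
            logger.exception("trial %s failed", key)
            failures.append({"trial": key, "error": f"{type(exc).__name__}: {exc}"})
            continue
        inverse[key] = inv
        for model_id, fr in fwd.items():
            forward[key + (model_id,)] = fr
        records.extend(recs)

    results = records_to_frame(records)
    summary = summarize_groups(records) if records else pd.DataFrame()
    comparisons = _all_comparisons(results) if records else pd.DataFrame()
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_datasets": len(inverse),
        "n_forward_results": len(forward),
        "n_failures": len(failures),
        "results_sha256": results_hash(results),
        "wall_time_s": round(time.perf_counter() - t_start, 3),
    }
    run = RunResult(
        config=cfg,
        records=records,
        results=results,
        summary=summary,
        comparisons=comparisons,
        inverse=inverse,
        forward=forward,
        failures=failures,
        manifest=manifest,
    )
    if cfg.output_dir is not None:
        write_outputs(run, cfg.output_dir)
    return run


def _all_comparisons(results: pd.DataFrame) -> pd.DataFrame:
    frames = []
    for factor in _METRIC_FACTORS:
        if results[factor].nunique() < 2:
            continue
        for metric in _METRICS:
            frames.append(compare_groups(results, factor, metric))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def results_hash(results: pd.DataFrame) -> str:
    """Content hash of the results grid, wall-clock timing columns excluded."""
    stable = results.drop(columns=[c for c in TIMING_COLUMNS if c in results], errors="ignore")
    return hashlib.sha256(stable.to_csv(index=False, float_format="%.12g").encode()).hexdigest()


def write_outputs(run: RunResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run.results.to_csv(out / "results.csv", index=False)
    run.summary.to_csv(out / "summary.csv", index=False)
    run.comparisons.to_csv(out / "comparisons.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(run.manifest, fh, indent=2)


# ---------------------------------------------------------------------------
# cohort directory I/O
# ---------------------------------------------------------------------------

def _write_series(path: Path, ts: TimeSeries, degrees: bool = False) -> None:
    values = np.rad2deg(ts.values) if degrees else ts.values
    pd.DataFrame({"time_s": ts.times, "value": values}).to_csv(
        path, index=False, float_format="%.10g"
    )


def _read_series(path: Path, units: str, degrees: bool = False) -> TimeSeries:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "value"]:
        raise DatasetFormatError(f"{path}: expected header 'time_s,value'")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise DatasetFormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise DatasetFormatError(f"{path}: non-uniform sampling")
    values = df["value"].to_numpy()
    if degrees:
        values = np.deg2rad(values)
    return TimeSeries(float(t[0]), 1.0 / float(dt[0]), values, units)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort as the documented CSV layout (angles in degrees)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subj_rows, trial_rows, truth_rows = [], [], []
    for subj in cohort.subjects:
        subj_rows.append(
            {
                "subject_id": subj.subject_id,
                "body_mass_kg": subj.body_mass,
                "height_m": subj.height,
                "forearm_length_m": subj.forearm_length,
                "lmo_flexor_m": subj.flexor.lmo,
                "lmo_extensor_m": subj.extensor.lmo,
                "cal_flexor_max_v": subj.cal_flexor.emg_max,
                "cal_flexor_min_v": subj.cal_flexor.emg_min,
                "cal_extensor_max_v": subj.cal_extensor.emg_max,
                "cal_extensor_min_v": subj.cal_extensor.emg_min,
                "truth_model": subj.truth.model_id,
                "truth_a1": subj.truth.A1,
                "truth_a2": subj.truth.A2,
                "co_contraction": subj.co_contraction,
                "posture": subj.skeletal.posture,
                "seed": subj.seed,
            }
        )
        sdir = out / subj.subject_id
        sdir.mkdir(exist_ok=True)
        for muscle in ("flexor", "extensor"):
            rec = cohort.mvc_recordings.get((subj.subject_id, muscle))
            if rec is not None:
                _write_series(sdir / f"mvc_{muscle}.csv", rec)
    for trial in cohort.trials:
        stem = f"{trial.motion_id}_r{trial.repetition}"
        sdir = out / trial.subject_id
        _write_series(sdir / f"{stem}_position_deg.csv", trial.position, degrees=True)
        has_emg = trial.emg_flexor is not None
        if has_emg:
            _write_series(sdir / f"{stem}_emg_flexor.csv", trial.emg_flexor)
            _write_series(sdir / f"{stem}_emg_extensor.csv", trial.emg_extensor)
        _write_series(sdir / f"{stem}_u_flexor.csv", trial.truth.u_flexor)
        _write_series(sdir / f"{stem}_u_extensor.csv", trial.truth.u_extensor)
        trial_rows.append(
            {
                "subject_id": trial.subject_id,
                "motion_id": trial.motion_id,
                "repetition": trial.repetition,
                "held_mass_kg": trial.held_mass,
                "has_emg": has_emg,
            }
        )
        truth_rows.append(
            {
                "subject_id": trial.subject_id,
                "motion_id": trial.motion_id,
                "repetition": trial.repetition,
                "truth_model": trial.truth.truth.model_id,
                "truth_a1": trial.truth.truth.A1,
                "truth_a2": trial.truth.truth.A2,
            }
        )
    pd.DataFrame(subj_rows).to_csv(out / "subjects.csv", index=False)
    pd.DataFrame(trial_rows).to_csv(out / "trials.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    with open(out / "cohort.json", "w") as fh:
        json.dump({"seed": cohort.seed, "emg_noise": cohort.emg_noise}, fh)


def load_dataset_dir(path: str | Path) -> Cohort:
    """Reload a saved cohort; schema violations raise with the offending file."""
    root = Path(path)
    subjects_csv = root / "subjects.csv"
    trials_csv = root / "trials.csv"
    for req in (subjects_csv, trials_csv):
        if not req.exists():
            raise DatasetFormatError(f"missing {req}")
    meta = {}
    if (root / "cohort.json").exists():
        meta = json.loads((root / "cohort.json").read_text())

    subjects = []
    for row in pd.read_csv(subjects_csv).to_dict("records"):
        truth = make_spec(
            int(row["truth_model"]),
            float(row["truth_a1"]),
            float(row["truth_a2"]) if MODEL_REGISTRY[int(row["truth_model"])].n_params == 2 else None,
        )
        subjects.append(
            SyntheticSubject(
                subject_id=str(row["subject_id"]),
                body_mass=float(row["body_mass_kg"]),
                height=float(row["height_m"]),
                forearm_length=float(row["forearm_length_m"]),
                flexor=default_params("biceps", float(row["lmo_flexor_m"])),
                extensor=default_params("triceps", float(row["lmo_extensor_m"])),
                skeletal=SkeletalParameters(
                    body_mass=float(row["body_mass_kg"]),
                    forearm_length=float(row["forearm_length_m"]),
                    posture=str(row["posture"]),
                ),
                cal_flexor=MVCCalibration(
                    float(row["cal_flexor_max_v"]), float(row["cal_flexor_min_v"]), "flexor"
                ),
                cal_extensor=MVCCalibration(
                    float(row["cal_extensor_max_v"]), float(row["cal_extensor_min_v"]), "extensor"
                ),
                truth=truth,
                co_contraction=float(row["co_contraction"]),
                seed=int(row["seed"]),
            )
        )
    subj_by_id = {s.subject_id: s for s in subjects}

    mvcs = {}
    trials = []
    from .synthetic import generate_ground_truth_activations  # local to avoid cycle at import

    for row in pd.read_csv(trials_csv).to_dict("records"):
        sid = str(row["subject_id"])
        if sid not in subj_by_id:
            raise DatasetFormatError(f"trials.csv references unknown subject {sid}")
        sdir = root / sid
        stem = f"{row['motion_id']}_r{int(row['repetition'])}"
        pos_file = sdir / f"{stem}_position_deg.csv"
        if not pos_file.exists():
            raise DatasetFormatError(f"missing position channel {pos_file}")
        position = _read_series(pos_file, "rad", degrees=True)
        held = float(row["held_mass_kg"])
        truth = generate_ground_truth_activations(position, subj_by_id[sid], held)
        if bool(row["has_emg"]):
            emg_f_file = sdir / f"{stem}_emg_flexor.csv"
            emg_e_file = sdir / f"{stem}_emg_extensor.csv"
            for f in (emg_f_file, emg_e_file):
                if not f.exists():
                    raise DatasetFormatError(f"missing EMG channel {f}")
            emg_f = _read_series(emg_f_file, "V")
            emg_e = _read_series(emg_e_file, "V")
        else:
            emg_f = emg_e = None
            # noiseless trials carry the generating drive explicitly
            u_f = _read_series(sdir / f"{stem}_u_flexor.csv", "dimensionless")
            u_e = _read_series(sdir / f"{stem}_u_extensor.csv", "dimensionless")
            truth = dataclasses.replace(truth, u_flexor=u_f, u_extensor=u_e)
        trials.append(
            SyntheticTrial(
                subject_id=sid,
                motion_id=str(row["motion_id"]),
                repetition=int(row["repetition"]),
                held_mass=held,
                position=position,
                emg_flexor=emg_f,
                emg_extensor=emg_e,
                truth=truth,
            )
        )
    for subj in subjects:
        for muscle in ("flexor", "extensor"):
            f = root / subj.subject_id / f"mvc_{muscle}.csv"
            if f.exists():
                mvcs[(subj.subject_id, muscle)] = _read_series(f, "V")
    return Cohort(
        subjects=subjects,
        trials=trials,
        mvc_recordings=mvcs,
        seed=int(meta.get("seed", 0)),
        emg_noise=bool(meta.get("emg_noise", True)),
    )
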