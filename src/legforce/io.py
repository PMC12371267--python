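"""On-disk formats: trial CSVs with JSON sidecars, configs, metrics tables.

A trial is a CSV with columns ``time_s, force_bw, target_bw`` (or
``force_n`` when stored in Newtons) plus a ``<stem>.meta.json`` sidecar
holding participant, condition, task, repetition, body weight, sample rate,
unit flag, and target onsets.  EMG travels as ``<stem>.emg.csv`` with
columns ``time_s, <muscle>...`` at 2000 Hz.  The canonical force unit is BW;
a Newton-stored trial is converted on read using the sidecar body weight.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, load_config
from .trace import Condition, EMGChannelSet, SampledTrace, Task, TrialRecord

__all__ = [
    "read_trial",
    "write_trial",
    "read_config",
    "write_metrics_table",
    "METRIC_COLUMNS",
]

_REL_TOL = 1e-6


class TrialFormatError(ValueError):
    """A trial file violated the CSV/sidecar contract."""


def _check_uniform(time_s: np.ndarray, sample_rate_hz: float) -> None:
    if time_s.size < 2:
        return
    dt = 1.0 / sample_rate_hz
    gaps = np.diff(time_s)
    bad = np.abs(gaps - dt) > dt * 1e-3
    if np.any(bad):
        i = int(np.argmax(bad))
        raise TrialFormatError(
            f"non-uniform time stamps: gap of {gaps[i]:.6g} s at row {i + 1} "
            f"(expected {dt:.6g} s)"
        )


def write_trial(record: TrialRecord, path: str | Path) -> Path:
    """Write a trial as CSV + ``.meta.json`` sidecar (and ``.emg.csv`` if present).

    Values are written at full precision (float round-trip format), so a
    write/read cycle reproduces the record exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = record.force.times_s
    df = pd.DataFrame(
        {"time_s": t, "force_bw": record.force.values, "target_bw": record.target.values}
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "participant_id": record.participant_id,
        "condition": record.condition.value,
        "task": record.task.value,
        "repetition": record.repetition,
        "body_weight_n": record.body_weight_n,
        "sample_rate_hz": record.sample_rate_hz,
        "t0_s": record.force.t0_s,
        "force_unit": "BW",
        "onsets_s": list(record.onsets_s) if record.onsets_s else None,
        "on_duration_s": record.on_duration_s,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    if record.emg is not None:
        emg_df = pd.DataFrame({"time_s": record.emg[record.emg.names[0]].times_s})
        for name in record.emg.names:
            emg_df[name] = record.emg[name].values
        emg_df.to_csv(_emg_path(path), index=False, float_format="%.17g")
    return path


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def _emg_path(path: Path) -> Path:
    return path.with_suffix(".emg.csv")


def read_trial(path: str | Path) -> TrialRecord:
    """Read a trial CSV plus sidecar; exposes force in BW regardless of storage unit."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise TrialFormatError(f"missing sidecar metadata file {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    for key in ("participant_id", "condition", "task", "repetition",
                "body_weight_n", "sample_rate_hz", "force_unit"):
        if key not in meta:
            raise TrialFormatError(f"sidecar {sidecar.name} missing key {key!r}")

    df = pd.read_csv(path, float_precision="round_trip")
    unit = meta["force_unit"]
    force_col = {"BW": "force_bw", "N": "force_n"}.get(unit)
    if force_col is None:
        raise TrialFormatError(f"unknown force_unit {unit!r} (expected 'BW' or 'N')")
    for col in ("time_s", force_col, "target_bw"):
        if col not in df.columns:
            raise TrialFormatError(f"{path.name}: missing column {col!r}")

    fs = float(meta["sample_rate_hz"])
    time_s = df["time_s"].to_numpy(dtype=float)
    _check_uniform(time_s, fs)
    t0 = float(time_s[0]) if time_s.size else float(meta.get("t0_s", 0.0))

    force = df[force_col].to_numpy(dtype=float)
    if unit == "N":
        force = force / float(meta["body_weight_n"])
    target = df["target_bw"].to_numpy(dtype=float)

    emg = None
    emg_file = _emg_path(path)
    if emg_file.exists():
        emg_df = pd.read_csv(emg_file, float_precision="round_trip")
        names = [c for c in emg_df.columns if c != "time_s"]
        et = emg_df["time_s"].to_numpy(dtype=float)
        if et.size > 1:
            emg_fs = 1.0 / (et[1] - et[0])
            _check_uniform(et, emg_fs)
        else:
            emg_fs = 2000.0
        emg = EMGChannelSet(
            {n: SampledTrace(emg_df[n].to_numpy(dtype=float), round(emg_fs, 6), float(et[0]))
             for n in names}
        )

    onsets = meta.get("onsets_s")
    return TrialRecord(
        participant_id=str(meta["participant_id"]),
        condition=Condition(meta["condition"]),
        task=Task(meta["task"]),
        repetition=int(meta["repetition"]),
        body_weight_n=float(meta["body_weight_n"]),
        force=SampledTrace(force, fs, t0),
        target=SampledTrace(target, fs, t0),
        emg=emg,
        onsets_s=tuple(onsets) if onsets else None,
        on_duration_s=meta.get("on_duration_s"),
    )


def read_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load and validate a YAML/JSON run configuration (``None`` -> defaults)."""
    return load_config(path)


#: Stable column order of the per-segment metrics table.
METRIC_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "condition",
    "task",
    "repetition",
    "step_index",
    "excluded",
    "exclusion_reasons",
    "rise_time_ms",
    "bandwidth_hz",
    "fall_time_ms",
    "overshoot_pct",
    "steady_state_error_pct",
    "steady_state_variability_pct",
)


def write_metrics_table(rows: list[dict] | pd.DataFrame, path: str | Path) -> Path:
    """Write per-segment metrics as CSV with a stable column order.

    Excluded segments keep their row, with ``excluded=True`` and empty
    metric fields.  Deterministic: identical inputs give byte-identical
    files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows.copy()
    for col in METRIC_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(dtype=object)
    extra = [c for c in df.columns if c not in METRIC_COLUMNS]
    df = df[list(METRIC_COLUMNS) + sorted(extra)]
    if "excluded" in df.columns and len(df):
        metric_cols = METRIC_COLUMNS[7:]
        mask = df["excluded"].fillna(False).astype(bool)
        df.loc[mask, list(metric_cols)] = np.nan
    df.to_csv(path, index=False, float_format="%.10g")
    return path
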