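"""Plain-CSV persistence for cohort streams and analysis reports.

One CSV per stream, ISO-8601 timestamps, plus a JSON ground-truth
sidecar written by the generator (read back only by tests; the
feature/analysis stages never touch it).
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .circadian import EpochSeries
from .synthetic import Cohort

_SCHEMAS = {
    "participants": ["participant_id", "group_true", "sex", "age", "isi_screening_total"],
    "questionnaires": ["participant_id", "sex", "instrument", "item_index", "rating"],
    "ema": ["participant_id", "date", "kind", "slot", "magnitude"],
    "sleep": ["participant_id", "date", "total_inactive_min", "total_awake_min",
              "rem_min", "light_min", "deep_min", "n_wakeups"],
    "series": ["participant_id", "timestamp", "value", "missing"],
}


class SchemaError(ValueError):
    pass


def series_to_frame(series_by_pid: Mapping[str, EpochSeries],
                    value_name: str = "value") -> pd.DataFrame:
    frames = []
    for pid in sorted(series_by_pid):
        s = series_by_pid[pid]
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "timestamp": [t.isoformat() for t in s.timestamps()],
            value_name: s.values,
            "missing": s.missing.astype(int),
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["participant_id", "timestamp", value_name, "missing"])


def frame_to_series(df: pd.DataFrame, value_name: str = "value") -> dict[str, EpochSeries]:
    _check(df, ["participant_id", "timestamp", value_name, "missing"], "series")
    out: dict[str, EpochSeries] = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        sub = sub.sort_values("timestamp")
        ts = pd.to_datetime(sub["timestamp"])
        if len(ts) > 1:
            step = (ts.iloc[1] - ts.iloc[0]).total_seconds() / 60.0
        else:
            step = 5.0
        out[str(pid)] = EpochSeries(
            participant_id=str(pid),
            start=ts.iloc[0].to_pydatetime(),
            epoch_minutes=int(round(step)),
            values=sub[value_name].to_numpy(dtype=float),
            missing=sub["missing"].to_numpy(dtype=bool),
        )
    return out


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write every generated stream plus the truth sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path

    _write("participants", cohort.participants)
    if cohort.questionnaires is not None:
        _write("questionnaires", cohort.questionnaires)
    if cohort.ema is not None:
        _write("ema", cohort.ema)
    if cohort.sleep is not None:
        _write("sleep", cohort.sleep)
    if cohort.heart_rate is not None:
        _write("heart_rate", series_to_frame(cohort.heart_rate, "bpm"))
    if cohort.steps is not None:
        _write("steps", series_to_frame(cohort.steps, "cumulative_steps"))

    truth = {
        "config": _jsonable(dataclasses.asdict(cohort.truth.config)),
        "scale_group_means": {k: list(v) for k, v in cohort.truth.scale_group_means.items()},
        "participants": [_jsonable(dataclasses.asdict(p)) for p in cohort.truth.participants],
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    written["truth"] = truth_path
    return written


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check(df, _SCHEMAS[schema], schema)
    return df


def read_heart_rate(path: str | Path) -> dict[str, EpochSeries]:
    df = pd.read_csv(path)
    _check(df, ["participant_id", "timestamp", "bpm", "missing"], "heart_rate")
    return frame_to_series(df, "bpm")


def read_steps(path: str | Path) -> dict[str, EpochSeries]:
    df = pd.read_csv(path)
    _check(df, ["participant_id", "timestamp", "cumulative_steps", "missing"], "steps")
    return frame_to_series(df, "cumulative_steps")


def write_report(report: dict, outdir: str | Path) -> dict[str, Path]:
    """Write report.json (full) and report.csv (flat table rows)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    payload = {"groups": report["groups"], "rows": report["report"]}
    json_path.write_text(json.dumps(payload, indent=1, default=_default))
    flat = []
    for row in report["report"]:
        flat.append({k: v for k, v in row.items() if k != "pairwise"})
    csv_path = outdir / "report.csv"
    pd.DataFrame(flat).to_csv(csv_path, index=False)
    return {"json": json_path, "csv": csv_path}


def _check(df: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}.csv is missing column(s): {', '.join(missing)}")


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (datetime,)) or hasattr(obj, "isoformat"):
        return obj.isoformat()
    return obj
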