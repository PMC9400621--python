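"""File layouts: trials.csv, per-trial trace CSVs, features.csv, session_meta.json.

All tabular output is plain CSV (times in ms, forces in N); all metadata is
JSON.  Trace files are two-column ``t_ms,value`` CSVs named
``<participant>_<trial>_<part>.csv`` under ``traces/``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .force import ForceTrace
from .simulate import DesignSpec, PopulationSpec, TrialRecord, trials_to_frame


def write_session(out_dir, records: list[TrialRecord], traces: dict,
                  design: DesignSpec, pop: PopulationSpec,
                  write_traces: bool = True) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = trials_to_frame(records)
    trials_path = out / "trials.csv"
    header = not trials_path.exists()
    frame.to_csv(trials_path, mode="a", header=header, index=False)
    if write_traces:
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        for (trial_index, part), trace in traces.items():
            df = pd.DataFrame({"t_ms": trace.times_ms, "value": trace.samples})
            df.to_csv(tdir / f"{trace.participant_id}_{trial_index}_{part}.csv",
                      index=False, float_format="%.6g")
    meta = {"design": asdict(design), "population": asdict(pop),
            "seed": pop.seed}
    (out / "session_meta.json").write_text(json.dumps(meta, indent=2))
    return out


def read_trials(session_dir) -> pd.DataFrame:
    return pd.read_csv(Path(session_dir) / "trials.csv")


def read_traces(session_dir, sample_rate_hz: float = 1000.0,
                channel: str = "force_N") -> dict:
    """Load all trace CSVs; keys are (participant_id, trial_index, part)."""
    traces = {}
    for path in sorted(Path(session_dir).glob("traces/*.csv")):
        pid, trial, part = path.stem.rsplit("_", 2)
        df = pd.read_csv(path)
        traces[(pid, int(trial), part)] = ForceTrace(
            samples=df["value"].to_numpy(), sample_rate_hz=sample_rate_hz,
            t0_ms=float(df["t_ms"].iloc[0]), channel=channel,
            participant_id=pid, trial_index=int(trial), part=part)
    return traces


def write_features(out_dir, features: pd.DataFrame) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "features.csv"
    features.to_csv(path, index=False)
    return path


def read_features(path_or_dir) -> pd.DataFrame:
    p = Path(path_or_dir)
    return pd.read_csv(p / "features.csv" if p.is_dir() else p)


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
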