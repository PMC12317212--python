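"""Canonical file formats: sample CSV, trial CSV, clean-trial CSV, configs.

All files are comma-separated UTF-8 with a mandatory header and "." decimals.
Time is in integer milliseconds relative to test-stimulus onset (0 = onset,
baseline negative). Missing pupil samples are encoded as an empty field with
``valid=0``.

Columns
-------
samples CSV : subject, trial, time_ms, pupil, valid
trials CSV  : subject, item, condition, image_type, response, rt_ms
              (optional: accuracy — checked against the derived value)
clean CSV   : one row per retained trial × bin with metadata repeated
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CleanTrials, TraceSet
from .simulate import SimulationConfig, design_levels

SAMPLE_COLUMNS = ["subject", "trial", "time_ms", "pupil", "valid"]
TRIAL_COLUMNS = ["subject", "item", "condition", "image_type", "response", "rt_ms"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_samples(path) -> TraceSet:
    """Read a long-format sample CSV into a :class:`TraceSet`.

    Rows may arrive in any order (sorting by subject, trial, time is
    canonical); all trials must share one constant-interval time grid.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SAMPLE_COLUMNS, path)
    df = df.sort_values(["subject", "trial", "time_ms"], kind="stable")
    dup = df.duplicated(["subject", "trial", "time_ms"])
    if dup.any():
        bad = df.loc[dup, ["subject", "trial"]].iloc[0]
        raise ValueError(f"{path}: duplicate (trial, time) rows in subject "
                         f"{bad['subject']} trial {bad['trial']}")
    pupil = df["pupil"].to_numpy(dtype=float)
    pupil = np.where(df["valid"].to_numpy(dtype=float) == 0, np.nan, pupil)

    grouped = df.groupby(["subject", "trial"], sort=True)
    times_ref = None
    traces, meta_rows = [], []
    pos = 0
    for (subject, trial), g in grouped:
        t = g["time_ms"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: non-monotone time in subject {subject} "
                             f"trial {trial}")
        if times_ref is None:
            times_ref = t
        elif len(t) != len(times_ref) or not np.array_equal(t, times_ref):
            raise ValueError(f"{path}: subject {subject} trial {trial} is not "
                             "on the common time grid")
        traces.append(pupil[pos:pos + len(t)])
        pos += len(t)
        meta_rows.append({"subject": subject, "trial": trial})
    if times_ref is None:
        raise ValueError(f"{path}: no sample rows")
    return TraceSet(times_ref, np.vstack(traces), pd.DataFrame(meta_rows))


def write_samples(traces: TraceSet, path) -> None:
    # 17 significant digits make every double round-trip exactly
    traces.to_long().to_csv(path, index=False, na_rep="", float_format="%.17g")


def derive_accuracy(df: pd.DataFrame) -> np.ndarray:
    resp_old = df["response"].astype(str).str.lower() == "old"
    is_old = df["image_type"] == "Old"
    return (resp_old == is_old).to_numpy()


def read_trials(path, design: str | None = None) -> pd.DataFrame:
    """Read the behavioral trial table, deriving and validating accuracy."""
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, path)
    levels = set(design_levels(design)) if design else \
        set(design_levels("cue")) | set(design_levels("preview"))
    unknown = sorted(set(df["condition"].astype(str)) - levels)
    if unknown:
        raise ValueError(f"{path}: unknown condition level(s) {unknown}; "
                         f"allowed: {sorted(levels)}")
    bad_type = sorted(set(df["image_type"].astype(str)) - {"Old", "Lure"})
    if bad_type:
        raise ValueError(f"{path}: unknown image_type value(s) {bad_type}; "
                         "allowed: ['Lure', 'Old']")
    derived = derive_accuracy(df)
    if "accuracy" in df.columns:
        given = df["accuracy"].astype(bool).to_numpy()
        if not np.array_equal(given, derived):
            n_bad = int((given != derived).sum())
            raise ValueError(f"{path}: accuracy column contradicts the "
                             f"response × image_type derivation in {n_bad} row(s)")
    df["accuracy"] = derived
    if "trial" not in df.columns:
        df["trial"] = df["item"]
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_COLUMNS + ["accuracy", "trial"] if c in trials.columns]
    trials[cols].to_csv(path, index=False)


def write_clean_trials(clean: CleanTrials, path) -> None:
    clean.to_long().to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationConfig.from_dict(data)


def save_simulation_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
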