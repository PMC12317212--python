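"""In-memory containers shared across the pipeline.

The two central objects mirror the shape of the data on disk:

* :class:`TraceSet` — raw (or repaired) sample-level pupil recordings, one row
  per trial on a common 1-ms time grid, missing samples as NaN.
* :class:`CleanTrials` — preprocessed trials: a trials × bins matrix of
  baseline-corrected pupil values plus per-trial metadata (condition,
  accuracy, missing fraction, exclusion status).

Both follow the X-plus-obs layout (a numeric matrix and an aligned metadata
DataFrame) common to scientific Python containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every TraceSet carries
TRACE_META_COLUMNS = ("subject", "trial")


@dataclass
class TraceSet:
    """Sample-level pupil traces on a shared time grid.

    Parameters
    ----------
    times
        1-D integer array of sample times in ms relative to stimulus onset
        (onset = 0, baseline negative), strictly increasing, 1-ms spacing.
    pupil
        ``(n_trials, n_times)`` float array of pupil size in arbitrary
        tracker units; missing samples (blinks, tracking loss) are NaN.
    meta
        DataFrame with one row per trial; must contain ``subject`` and
        ``trial`` and may carry condition / image_type / accuracy labels.
    """

    times: np.ndarray
    pupil: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.pupil.ndim != 2 or self.pupil.shape != (len(self.meta), len(self.times)):
            raise ValueError(
                f"pupil must be (n_trials={len(self.meta)}, n_times={len(self.times)}), "
                f"got {self.pupil.shape}"
            )
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.all(dt > 0):
                raise ValueError("times must be strictly increasing")
            if len(np.unique(dt)) != 1:
                raise ValueError("sampling interval must be constant")
        for col in TRACE_META_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"meta missing required column {col!r}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return len(self.meta)

    @property
    def sampling_interval_ms(self) -> int:
        return int(self.times[1] - self.times[0]) if len(self.times) > 1 else 1

    def copy(self) -> "TraceSet":
        return TraceSet(self.times.copy(), self.pupil.copy(), self.meta.copy())

    def to_long(self) -> pd.DataFrame:
        """Long-format sample table (subject, trial, time_ms, pupil, valid)."""
        n, t = self.pupil.shape
        valid = (~np.isnan(self.pupil)).astype(int).ravel()
        return pd.DataFrame(
            {
                "subject": np.repeat(self.meta["subject"].to_numpy(), t),
                "trial": np.repeat(self.meta["trial"].to_numpy(), t),
                "time_ms": np.tile(self.times, n),
                "pupil": self.pupil.ravel(),
                "valid": valid,
            }
        )


@dataclass
class CleanTrials:
    """Preprocessed trials: binned baseline-corrected traces + metadata.

    ``bins`` is ``(n_trials, n_bins)``; rows of excluded trials are NaN.
    ``meta`` carries subject, trial, condition, image_type, accuracy,
    missing_fraction, excluded, exclusion_reason.
    """

    bins: np.ndarray
    meta: pd.DataFrame
    bin_width_ms: int = 20

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape[0] != len(self.meta):
            raise ValueError("bins and meta must have one row per trial")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_bins(self) -> int:
        return self.bins.shape[1]

    def retained(self) -> "CleanTrials":
        keep = ~self.meta["excluded"].to_numpy(dtype=bool)
        return CleanTrials(self.bins[keep], self.meta.loc[keep].reset_index(drop=True),
                           self.bin_width_ms)

    def bin_times_ms(self) -> np.ndarray:
        """Left edge of each bin in ms after stimulus onset."""
        return np.arange(self.n_bins) * self.bin_width_ms

    def to_long(self) -> pd.DataFrame:
        """One row per retained trial × bin, with trial metadata repeated."""
        kept = self.retained()
        n, b = kept.bins.shape
        out = kept.meta.loc[kept.meta.index.repeat(b)].reset_index(drop=True)
        out["bin"] = np.tile(np.arange(b), n)
        out["time_ms"] = np.tile(kept.bin_times_ms(), n)
        out["pupil"] = kept.bins.ravel()
        return out


@dataclass
class BinSeries:
    """Trials × bins matrix with labels, the unit of cluster inference."""

    values: np.ndarray
    labels: pd.DataFrame  # subject, item/trial, condition, accuracy
    bin_width_ms: int = 20

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.labels):
            raise ValueError("values and labels must have one row per trial")
        if np.isnan(self.values).any():
            raise ValueError("BinSeries must not contain missing bins")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def bin_series_from_clean(clean: CleanTrials, subset: dict | None = None) -> BinSeries:
    """Build a :class:`BinSeries` from retained trials, optionally subset.

    ``subset`` maps metadata column → required value, e.g.
    ``{"image_type": "Old", "accuracy": False}`` selects miss trials on old
    images.
    """
    kept = clean.retained()
    mask = np.ones(len(kept.meta), dtype=bool)
    if subset:
        for col, val in subset.items():
            if col not in kept.meta.columns:
                raise KeyError(f"subset column {col!r} not in trial metadata")
            mask &= kept.meta[col].to_numpy() == val
    return BinSeries(kept.bins[mask], kept.meta.loc[mask].reset_index(drop=True),
                     clean.bin_width_ms)
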