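"""Pupil trace preprocessing: blink repair, smoothing, exclusion, binning.

The pipeline mirrors standard pupillometry practice for 1-kHz tracker data:

1. detect maximal runs of missing samples (blinks / tracking loss);
2. extend each run by 100 ms on both sides and linearly interpolate across
   the extended gap;
3. zero-phase low-pass smoothing (Butterworth, default order 3, 4 Hz);
4. flag trials with anomalous dilation-speed spikes (interpolation failures);
5. exclude trials (and participants) with more than 20% missing samples;
6. baseline-correct by the mean of the 400 ms preceding stimulus onset;
7. average into 150 consecutive 20-ms bins covering the 3-s test window.

Exclusions are data, not errors: `preprocess_all` returns every input trial
with an exclusion flag and reason plus a summary report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal

from .containers import CleanTrials, TraceSet


@dataclass
class PreprocessConfig:
    blink_extension_ms: int = 100
    lowpass_cutoff_hz: float = 4.0
    lowpass_order: int = 3
    missing_threshold: float = 0.20
    spike_mad_multiplier: float = 16.0
    baseline_window_ms: int = 400
    bin_width_ms: int = 20
    n_bins: int = 150

    def validate(self) -> None:
        for name in ("blink_extension_ms", "lowpass_cutoff_hz", "lowpass_order",
                     "spike_mad_multiplier", "baseline_window_ms",
                     "bin_width_ms", "n_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.missing_threshold < 1:
            raise ValueError("missing_threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def detect_missing_runs(times: np.ndarray, values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of missing (NaN) samples as half-open [start, end) ms.

    Returned intervals are disjoint and sorted; ``end`` is the time of the
    first sample after the run (run end + one sampling interval at the trace
    edge).
    """
    times = np.asarray(times)
    missing = np.isnan(np.asarray(values, dtype=float))
    if not missing.any():
        return []
    dt = int(times[1] - times[0]) if len(times) > 1 else 1
    padded = np.concatenate([[False], missing, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(times[s]), int(times[e - 1]) + dt) for s, e in zip(starts, ends)]


def extend_runs(runs: list[tuple[int, int]], extension_ms: int,
                t_min: int, t_max: int) -> list[tuple[int, int]]:
    """Grow runs by ``extension_ms`` on both sides, clip to [t_min, t_max),
    and merge any overlapping or touching results."""
    if not runs:
        return []
    grown = sorted((max(t_min, s - extension_ms), min(t_max, e + extension_ms))
                   for s, e in runs)
    merged = [list(grown[0])]
    for s, e in grown[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


def extend_and_interpolate(times: np.ndarray, values: np.ndarray,
                           runs: list[tuple[int, int]],
                           extension_ms: int = 100):
    """Repair blink runs: grow by ``extension_ms``, linearly interpolate.

    Samples inside the grown runs are replaced by linear interpolation
    between the nearest valid samples outside; runs touching a trace edge
    are filled with the nearest valid value. Samples outside grown runs are
    returned bit-identical. Returns ``(repaired, grown_runs)``; if no valid
    sample remains, ``repaired`` is None (trial must be excluded upstream).
    """
    times = np.asarray(times)
    values = np.asarray(values, dtype=float)
    dt = int(times[1] - times[0]) if len(times) > 1 else 1
    grown = extend_runs(runs, extension_ms, int(times[0]), int(times[-1]) + dt)
    if not grown:
        return values.copy(), grown
    mask = np.zeros(len(times), dtype=bool)
    for s, e in grown:
        mask |= (times >= s) & (times < e)
    if mask.all() or np.isnan(values[~mask]).all():
        return None, grown
    out = values.copy()
    good = ~mask & ~np.isnan(values)
    out[mask | np.isnan(values)] = np.interp(
        times[mask | np.isnan(values)], times[good], values[good])
    return out, grown


def lowpass_smooth(values: np.ndarray, sampling_rate_hz: float = 1000.0,
                   cutoff_hz: float = 4.0, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis (DC gain 1)."""
    if cutoff_hz >= sampling_rate_hz / 2.0:
        raise ValueError(f"cutoff_hz {cutoff_hz} must be below the Nyquist "
                         f"frequency {sampling_rate_hz / 2.0}")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sampling_rate_hz,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(values, dtype=float), axis=-1)


def missing_fraction(times: np.ndarray, grown_runs: list[tuple[int, int]]) -> float:
    """Fraction of samples falling inside the grown blink runs."""
    times = np.asarray(times)
    if not grown_runs:
        return 0.0
    mask = np.zeros(len(times), dtype=bool)
    for s, e in grown_runs:
        mask |= (times >= s) & (times < e)
    return float(mask.mean())


def dilation_speeds(values: np.ndarray) -> np.ndarray:
    return np.abs(np.diff(np.asarray(values, dtype=float)))


def detect_spike_artifact(values: np.ndarray, mad_multiplier: float = 16.0) -> bool:
    """True iff the max sample-to-sample dilation speed is an outlier.

    Threshold: median + ``mad_multiplier`` × MAD of within-trial speeds. A
    constant trace (all speeds zero) is never flagged.
    """
    sp = dilation_speeds(values)
    if len(sp) == 0 or sp.max() == 0:
        return False
    med = np.median(sp)
    mad = np.median(np.abs(sp - med))
    return bool(sp.max() > med + mad_multiplier * mad)


def baseline_correct(times: np.ndarray, values: np.ndarray,
                     window_ms: int = 400) -> np.ndarray:
    """Subtract the mean over [-window_ms, 0) from every sample."""
    times = np.asarray(times)
    values = np.asarray(values, dtype=float)
    win = (times >= -window_ms) & (times < 0)
    expected = window_ms // (int(times[1] - times[0]) if len(times) > 1 else 1)
    if win.sum() < expected:
        raise ValueError(f"baseline window [-{window_ms}, 0) ms not fully covered")
    base = values[..., win].mean(axis=-1, keepdims=True)
    return values - base


def bin_downsample(times: np.ndarray, values: np.ndarray,
                   bin_width_ms: int = 20, n_bins: int = 150) -> np.ndarray:
    """Average post-onset samples into ``n_bins`` half-open 20-ms bins.

    Bin k is the mean over [k·w, (k+1)·w) ms. Requires full coverage of
    [0, n_bins·w) ms.
    """
    times = np.asarray(times)
    values = np.asarray(values, dtype=float)
    dt = int(times[1] - times[0]) if len(times) > 1 else 1
    sel = (times >= 0) & (times < n_bins * bin_width_ms)
    per_bin = bin_width_ms // dt
    if sel.sum() != n_bins * per_bin:
        raise ValueError(
            f"post-onset coverage must span [0, {n_bins * bin_width_ms}) ms "
            f"at a {dt}-ms interval; found {sel.sum()} samples")
    v = values[..., sel]
    return v.reshape(*v.shape[:-1], n_bins, per_bin).mean(axis=-1)


def preprocess_all(traces: TraceSet, config: PreprocessConfig | None = None):
    """Run the full preprocessing pipeline on a set of trials.

    Returns ``(clean, report)``. ``clean`` is a :class:`CleanTrials` with one
    row per *input* trial (excluded rows carry NaN bins and a reason);
    ``report`` summarizes exclusions by reason and participant.
    """
    config = config or PreprocessConfig()
    config.validate()
    n = traces.n_trials
    t = traces.times
    fs = 1000.0 / traces.sampling_interval_ms

    repaired = np.empty_like(traces.pupil)
    frac = np.zeros(n)
    reason = np.array(["none"] * n, dtype=object)

    for i in range(n):
        runs = detect_missing_runs(t, traces.pupil[i])
        rep, grown = extend_and_interpolate(t, traces.pupil[i], runs,
                                            config.blink_extension_ms)
        frac[i] = missing_fraction(t, grown)
        if rep is None:
            reason[i] = "missing"
            repaired[i] = np.nan
            frac[i] = 1.0
        else:
            repaired[i] = rep

    ok = reason == "none"
    if ok.any():
        repaired[ok] = lowpass_smooth(repaired[ok], fs, config.lowpass_cutoff_hz,
                                      config.lowpass_order)
    for i in np.flatnonzero(ok):
        if frac[i] > config.missing_threshold:
            reason[i] = "missing"
        elif detect_spike_artifact(repaired[i], config.spike_mad_multiplier):
            reason[i] = "spike"

    # participant-level rule: same threshold applied to the pooled samples
    subjects = traces.meta["subject"].to_numpy()
    excluded_subjects = []
    for s in pd.unique(subjects):
        m = subjects == s
        if frac[m].mean() > config.missing_threshold:
            excluded_subjects.append(s)
            reason[m] = "missing"

    excluded = reason != "none"
    bins = np.full((n, config.n_bins), np.nan)
    keep = np.flatnonzero(~excluded)
    if len(keep):
        corrected = baseline_correct(t, repaired[keep], config.baseline_window_ms)
        bins[keep] = bin_downsample(t, corrected, config.bin_width_ms, config.n_bins)

    meta = traces.meta.copy()
    meta["missing_fraction"] = frac
    meta["excluded"] = excluded
    meta["exclusion_reason"] = reason
    clean = CleanTrials(bins, meta, config.bin_width_ms)

    report = {
        "n_trials": int(n),
        "n_retained": int((~excluded).sum()),
        "n_excluded": int(excluded.sum()),
        "n_excluded_missing": int((reason == "missing").sum()),
        "n_excluded_spike": int((reason == "spike").sum()),
        "excluded_subjects": [int(s) if isinstance(s, (int, np.integer)) else s
                              for s in excluded_subjects],
        "percent_removed": float(100.0 * excluded.sum() / n) if n else 0.0,
        "config": config.to_dict(),
    }
    return clean, report
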