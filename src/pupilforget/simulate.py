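"""Synthetic item-method directed-forgetting experiments.

Generates complete experiments — trial-level recognition behavior, 1-kHz
pupil traces, and a ground-truth record — with the statistical structure the
downstream analyses assume:

* a 2×2 within-subject design (memory condition × old/lure image),
  counterbalanced across items and subjects;
* recognition responses from an equal-variance signal-detection model with
  condition-specific sensitivity d′ and criterion c, plus additive subject-
  and item-level random effects on d′;
* lognormal reaction times with condition shifts and a small contamination
  of extreme outliers (so the 3-SD screening rule has work to do);
* pupil traces = baseline level + subject intercept + AR(1) noise
  + a stimulus-locked dilation shared by all trials
  + a late-window dilation whose amplitude is set per condition ×
  subsequent-accuracy cell (the quantity the cluster analysis hunts for);
* Poisson blink process producing missing-sample runs for preprocessing to
  repair.

Everything is driven by one integer seed; identical configs give
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .containers import TraceSet

CUE_LEVELS = ("R", "F")
PREVIEW_LEVELS = ("Previewed", "NonPreviewed")


def design_levels(design: str) -> tuple[str, str]:
    if design == "cue":
        return CUE_LEVELS
    if design == "preview":
        return PREVIEW_LEVELS
    raise ValueError(f"design must be 'cue' or 'preview', got {design!r}")


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic experiment.

    Defaults emulate Experiment-1-style conditions: 90 subjects, 40 scenes,
    remember/forget cueing, sensitivity and bias consistent with the
    reported probit coefficients, and a late (1880–2820 ms) extra dilation
    only on forget-cued miss trials.
    """

    n_subjects: int = 90
    n_items: int = 40
    design: str = "cue"  # "cue" (R/F) or "preview" (Previewed/NonPreviewed)

    # equal-variance SDT parameters per condition: {condition: (dprime, c)}
    sdt: dict = field(default_factory=lambda: {"R": (1.755, -0.28), "F": (1.265, -0.29)})
    subject_sd_dprime: float = 0.4
    item_sd_dprime: float = 0.3

    # reaction times (log-ms scale)
    rt_meanlog: float = 7.0
    rt_sdlog: float = 0.35
    rt_condition_shift: dict = field(default_factory=lambda: {"R": 0.0, "F": 0.07})
    rt_lure_shift: float = 0.12
    rt_outlier_prob: float = 0.005  # contamination with +6-SD draws

    # pupil trace model
    sampling_rate_hz: int = 1000
    baseline_ms: int = 2000       # pre-stimulus period covered by the mask
    trial_ms: int = 3000          # post-onset test window
    baseline_level: float = 800.0  # arbitrary tracker units
    pupil_subject_sd: float = 10.0
    noise_sd: float = 20.0        # stationary SD of the AR(1) noise
    noise_ar1: float = 0.995      # per-sample autocorrelation at 1 kHz
    response_amplitude: float = 60.0  # stimulus-locked dilation, all trials
    # extra late dilation per (condition, accuracy) cell
    effect_amplitude: dict = field(default_factory=lambda: {
        ("R", True): 0.0, ("F", True): 0.0, ("R", False): 0.0, ("F", False): 30.0})
    effect_onset_ms: int = 1880
    effect_duration_ms: int = 940
    kernel_n: float = 10.1
    kernel_tmax_ms: float = 930.0

    # blink process
    blink_rate_per_s: float = 0.3
    blink_duration_mean_ms: float = 120.0
    blink_duration_sd_ms: float = 40.0

    seed: int = 0

    def conditions(self) -> tuple[str, str]:
        return design_levels(self.design)

    def validate(self) -> None:
        """Raise ValueError naming the offending field if any invariant fails."""
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_items < 4 or self.n_items % 4 != 0:
            raise ValueError("n_items must be a positive multiple of 4 "
                             "(condition x image-type counterbalance)")
        levels = self.conditions()
        for cond in levels:
            if cond not in self.sdt:
                raise ValueError(f"sdt missing condition {cond!r}")
            if cond not in self.rt_condition_shift:
                raise ValueError(f"rt_condition_shift missing condition {cond!r}")
        for name in ("subject_sd_dprime", "item_sd_dprime", "rt_sdlog",
                     "pupil_subject_sd", "noise_sd", "blink_duration_sd_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must be in [0, 1)")
        if self.trial_ms % 20 != 0:
            raise ValueError("trial_ms must be a multiple of 20 ms")
        if self.baseline_ms < 400:
            raise ValueError("baseline_ms must cover at least 400 ms")
        if self.blink_rate_per_s < 0:
            raise ValueError("blink_rate_per_s must be >= 0")
        if self.blink_duration_mean_ms <= 0:
            raise ValueError("blink_duration_mean_ms must be > 0")
        if self.kernel_n <= 0 or self.kernel_tmax_ms <= 0:
            raise ValueError("kernel_n and kernel_tmax_ms must be > 0")
        if not 0 <= self.rt_outlier_prob < 1:
            raise ValueError("rt_outlier_prob must be in [0, 1)")
        for cell, amp in self.effect_amplitude.items():
            if cell[0] not in levels or not isinstance(cell[1], (bool, np.bool_)):
                raise ValueError(f"effect_amplitude has invalid cell {cell!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # JSON/YAML-safe representation of tuple-keyed dict
        d["effect_amplitude"] = {f"{c}|{int(a)}": v
                                 for (c, a), v in self.effect_amplitude.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "effect_amplitude" in d and d["effect_amplitude"] and \
                isinstance(next(iter(d["effect_amplitude"])), str):
            d["effect_amplitude"] = {
                (k.split("|")[0], bool(int(k.split("|")[1]))): v
                for k, v in d["effect_amplitude"].items()}
        if "sdt" in d:
            d["sdt"] = {k: tuple(v) for k, v in d["sdt"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Record of the latent quantities behind one simulated experiment."""

    trial_truth: pd.DataFrame      # one row per trial: latent evidence, cell, amplitude, blinks
    subject_effects: pd.DataFrame  # per-subject d' offset and pupil intercept
    item_effects: pd.DataFrame     # per-item d' offset
    config: SimulationConfig


def pupil_response_kernel(t, kernel_n: float = 10.1, kernel_tmax: float = 930.0):
    """Peak-normalized pupil impulse response h(t) = t^n exp(-n t / t_max).

    The classic Erlang-shaped pupil kernel: rises from 0, peaks at exactly
    ``t = kernel_tmax`` with value 1, then decays. ``t`` is in ms and may be
    scalar or array; negative ``t`` raises ValueError.
    """
    t = np.asarray(t, dtype=float)
    if kernel_n <= 0 or kernel_tmax <= 0:
        raise ValueError("kernel_n and kernel_tmax must be > 0")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    with np.errstate(divide="ignore"):
        # log-space evaluation avoids overflow of t**n for large n
        logh = kernel_n * np.log(t / kernel_tmax) + kernel_n * (1.0 - t / kernel_tmax)
    out = np.exp(logh)
    out = np.where(t == 0, 0.0, out)
    return out if out.ndim else float(out)


def response_probability(dprime: float, c: float, image_type: str) -> float:
    """P(respond "old") under the equal-variance SDT model.

    Old images: Phi(d'/2 - c); lures: Phi(-d'/2 - c).
    """
    mu = dprime / 2.0 if image_type == "Old" else -dprime / 2.0
    return float(stats.norm.cdf(mu - c))


def simulate_trial_behavior(dprime: float, c: float, image_type: str,
                            rng: np.random.Generator):
    """Draw one recognition response; returns (response, accuracy)."""
    p_old = response_probability(dprime, c, image_type)
    response = "old" if rng.random() < p_old else "lure"
    accuracy = (response == "old") == (image_type == "Old")
    return response, accuracy


def inject_blinks(trace: TraceSet, rate_per_s: float, dur_mean_ms: float,
                  dur_sd_ms: float, rng: np.random.Generator) -> TraceSet:
    """Mask Poisson-process blink runs as NaN; non-blink samples untouched.

    Blink count per trial ~ Poisson(rate × trace duration); onsets uniform;
    durations truncated normal (>= 1 ms); runs are clipped at trace edges.
    """
    if dur_mean_ms <= 0:
        raise ValueError("dur_mean_ms must be > 0")
    out = trace.copy()
    if rate_per_s <= 0:
        return out
    n_samples = len(out.times)
    duration_s = n_samples / 1000.0 * out.sampling_interval_ms
    for i in range(out.n_trials):
        n_blinks = rng.poisson(rate_per_s * duration_s)
        for _ in range(n_blinks):
            dur = max(1, int(round(rng.normal(dur_mean_ms, dur_sd_ms))))
            start = rng.integers(0, n_samples)
            out.pupil[i, start:start + dur] = np.nan
    return out


def _ar1_noise(rng: np.random.Generator, shape: tuple, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd`` along the last axis."""
    if sd == 0:
        return np.zeros(shape)
    eps = rng.standard_normal(shape) * sd * np.sqrt(1.0 - rho ** 2)
    eps[..., 0] = rng.standard_normal(shape[:-1]) * sd  # stationary start
    if rho == 0:
        return eps
    return signal.lfilter([1.0], [1.0, -rho], eps, axis=-1)


def _effect_regressors(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus-locked and late-window dilation time courses, peak-normalized.

    Each is a boxcar (stimulus duration, or the late effect window) convolved
    with the pupil impulse response and rescaled to peak at 1 within the
    recorded window, so amplitudes in the config are in trace units.
    """
    times = np.arange(-config.baseline_ms, config.trial_ms)
    kern_t = np.arange(0, 4000)
    kern = pupil_response_kernel(kern_t, config.kernel_n, config.kernel_tmax_ms)
    kern = kern / kern.sum()

    def convolved_boxcar(on: int, off: int) -> np.ndarray:
        box = ((times >= on) & (times < off)).astype(float)
        resp = signal.convolve(box, kern)[: len(times)]
        peak = resp.max()
        return resp / peak if peak > 0 else resp

    stim = convolved_boxcar(0, config.trial_ms)
    late = convolved_boxcar(config.effect_onset_ms,
                            config.effect_onset_ms + config.effect_duration_ms)
    return stim, late


def _assign_design(config: SimulationConfig, subject: int) -> pd.DataFrame:
    """Counterbalanced assignment of items to condition × image type.

    Items are split into four equal cells; the mapping rotates with the
    subject index so that across subjects every item serves every cell.
    """
    cond_levels = config.conditions()
    cells = [(c, t) for c in cond_levels for t in ("Old", "Lure")]
    cell_idx = (np.arange(config.n_items) + subject) % 4
    rows = [{"subject": subject, "item": item,
             "condition": cells[cell_idx[item]][0],
             "image_type": cells[cell_idx[item]][1]}
            for item in range(config.n_items)]
    return pd.DataFrame(rows)


def simulate_behavior(config: SimulationConfig,
                      rng: np.random.Generator | None = None):
    """Generate the trial table (and truth) without pupil traces.

    Returns (trials, truth) where ``trials`` has one row per subject × item
    with condition, image_type, response, accuracy and rt_ms.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    subj_d = rng.normal(0.0, config.subject_sd_dprime, config.n_subjects)
    subj_pupil = rng.normal(0.0, config.pupil_subject_sd, config.n_subjects)
    item_d = rng.normal(0.0, config.item_sd_dprime, config.n_items)

    frames = []
    for s in range(config.n_subjects):
        design = _assign_design(config, s)
        d0 = np.array([config.sdt[c][0] for c in design["condition"]])
        c0 = np.array([config.sdt[c][1] for c in design["condition"]])
        design["dprime_true"] = d0 + subj_d[s] + item_d[design["item"].to_numpy()]
        design["criterion_true"] = c0
        frames.append(design)
    trials = pd.concat(frames, ignore_index=True)

    # SDT responses
    is_old = trials["image_type"].to_numpy() == "Old"
    mu = np.where(is_old, trials["dprime_true"] / 2.0, -trials["dprime_true"] / 2.0)
    p_old = stats.norm.cdf(mu - trials["criterion_true"])
    resp_old = rng.random(len(trials)) < p_old
    trials["response"] = np.where(resp_old, "old", "lure")
    trials["accuracy"] = resp_old == is_old

    # lognormal RTs with condition/lure shifts and rare extreme outliers
    shift = np.array([config.rt_condition_shift[c] for c in trials["condition"]])
    shift = shift + np.where(is_old, 0.0, config.rt_lure_shift)
    logrt = config.rt_meanlog + shift + rng.normal(0.0, config.rt_sdlog, len(trials))
    outlier = rng.random(len(trials)) < config.rt_outlier_prob
    logrt = logrt + outlier * 6.0 * config.rt_sdlog
    trials["rt_ms"] = np.exp(logrt)

    trials["trial"] = trials["item"]
    truth = GroundTruth(
        trial_truth=trials[["subject", "item", "condition", "image_type",
                            "dprime_true", "criterion_true"]].copy(),
        subject_effects=pd.DataFrame({"subject": np.arange(config.n_subjects),
                                      "dprime_offset": subj_d,
                                      "pupil_intercept": subj_pupil}),
        item_effects=pd.DataFrame({"item": np.arange(config.n_items),
                                   "dprime_offset": item_d}),
        config=config,
    )
    return trials, truth


def simulate_experiment(config: SimulationConfig):
    """Generate a full synthetic experiment.

    Returns ``(trials, traces, truth)``: the behavioral trial table, the
    sample-level :class:`TraceSet` (one trace per trial, NaN blinks), and a
    :class:`GroundTruth` record. Identical configs give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    trials, truth = simulate_behavior(config, rng)
    subj_pupil = truth.subject_effects["pupil_intercept"].to_numpy()

    times = np.arange(-config.baseline_ms, config.trial_ms)
    stim_reg, late_reg = _effect_regressors(config)

    amp = np.array([config.effect_amplitude.get((c, bool(a)), 0.0)
                    for c, a in zip(trials["condition"], trials["accuracy"])])
    n = len(trials)
    noise = _ar1_noise(rng, (n, len(times)), config.noise_sd, config.noise_ar1)
    pupil = (config.baseline_level
             + subj_pupil[trials["subject"].to_numpy()][:, None]
             + noise
             + config.response_amplitude * stim_reg[None, :]
             + amp[:, None] * late_reg[None, :])

    meta = trials[["subject", "trial", "item", "condition", "image_type",
                   "accuracy"]].copy()
    traces = TraceSet(times, pupil, meta)
    traces = inject_blinks(traces, config.blink_rate_per_s,
                           config.blink_duration_mean_ms,
                           config.blink_duration_sd_ms, rng)

    truth.trial_truth["effect_amplitude_true"] = amp
    truth.trial_truth["accuracy"] = trials["accuracy"].to_numpy()
    return trials, traces, truth
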