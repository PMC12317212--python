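"""End-to-end orchestration: simulate/load → preprocess → behavior → clusters.

A :class:`PipelineConfig` names the inputs (either a simulation config or a
pair of sample/trial CSVs), the preprocessing and cluster parameters, and
the trial subsets to contrast (by default old-image miss trials and
old-image hit trials, the two planned comparisons). :func:`run_pipeline`
executes every stage, writes all outputs under one directory, and records a
machine-readable manifest (config hash, seed, versions, exclusion counts)
sufficient to replay the run; identical config + seed give identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, cluster, io
from .preprocess import PreprocessConfig, preprocess_all
from .simulate import SimulationConfig, simulate_experiment

log = logging.getLogger("pupilforget")

DEFAULT_SUBSETS = {
    "old_miss": {"image_type": "Old", "accuracy": False},
    "old_hit": {"image_type": "Old", "accuracy": True},
}


@dataclass
class PipelineConfig:
    output_dir: str = "pupilforget_output"
    # either simulate ...
    simulation: SimulationConfig | None = None
    # ... or load from files
    samples_path: str | None = None
    trials_path: str | None = None

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster_spec: str = "subject"     # per-bin model inside and outside permutations
    alpha: float = 0.05
    min_cluster_len: int = 10
    n_permutations: int = 1000
    shuffle_scope: str = "within_subject"
    statistic: str = "max_abs"
    estimator: str = "plain"
    subsets: dict = field(default_factory=lambda: dict(DEFAULT_SUBSETS))
    seed: int = 0
    make_plots: bool = True

    def validate(self) -> None:
        has_sim = self.simulation is not None
        has_files = self.samples_path is not None and self.trials_path is not None
        if not has_sim and not has_files:
            raise ValueError("config needs either a simulation block or both "
                             "samples_path and trials_path")
        if has_files:
            for p in (self.samples_path, self.trials_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        self.preprocess.validate()
        if self.simulation is not None:
            self.simulation.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["preprocess"] = self.preprocess.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        return cls(**d)


def config_hash(config: PipelineConfig) -> str:
    """Hash of the analysis parameters (output location excluded)."""
    d = config.to_dict()
    d.pop("output_dir", None)
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _glmm_to_dict(res: behavior.GlmmResult) -> dict:
    return {"formula": res.formula, "link": res.link,
            "random_structure": res.random_structure,
            "converged": res.converged, "reliable": res.reliable,
            "vc": res.vc, "coefficients": res.coef.to_dict(orient="records")}


def _ttest_to_dict(t: behavior.TTestResult) -> dict:
    return dataclasses.asdict(t)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory result bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: acquire data -------------------------------------------
    if config.simulation is not None:
        log.info("simulating experiment (seed=%d)", config.simulation.seed)
        trials, traces, truth = simulate_experiment(config.simulation)
        io.write_trials(trials, out / "trials.csv")
        truth.trial_truth.to_csv(out / "ground_truth.csv", index=False)
    else:
        log.info("reading %s and %s", config.samples_path, config.trials_path)
        traces = io.read_samples(config.samples_path)
        trials = io.read_trials(config.trials_path)
        # attach condition/accuracy labels to the traces by (subject, trial)
        traces.meta = traces.meta.merge(
            trials[["subject", "trial", "condition", "image_type", "accuracy"]],
            on=["subject", "trial"], how="left", validate="one_to_one")
        if traces.meta["condition"].isna().any():
            n = int(traces.meta["condition"].isna().sum())
            raise ValueError(f"{n} trace(s) have no matching behavioral trial")

    # --- stage 2: preprocessing ------------------------------------------
    clean, report = preprocess_all(traces, config.preprocess)
    io.write_clean_trials(clean, out / "clean_trials.csv")
    io.write_json(report, out / "exclusion_report.json")
    log.info("preprocessing removed %.1f%% of trials", report["percent_removed"])

    # --- stage 3: behavior ------------------------------------------------
    beh = behavior.behavior_report(trials)
    beh["sdt_summary"].to_csv(out / "sdt_summary.csv", index=False)
    beh["accuracy_model"].coef.to_csv(out / "accuracy_model.csv", index=False)
    beh["rt_model"].coef.to_csv(out / "rt_model.csv", index=False)
    io.write_json({
        "dprime_test": _ttest_to_dict(beh["dprime_test"]),
        "criterion_test": _ttest_to_dict(beh["criterion_test"]),
        "rt_outlier_fraction": beh["rt_outlier_fraction"],
        "accuracy_model": _glmm_to_dict(beh["accuracy_model"]),
        "rt_model": _glmm_to_dict(beh["rt_model"]),
    }, out / "behavior_results.json")

    # --- stage 4: cluster contrasts per subset ----------------------------
    contrasts: dict[str, cluster.ContrastResult] = {}
    cluster_rows = []
    for name, subset in config.subsets.items():
        log.info("contrast %s on subset %s", name, subset)
        try:
            res = cluster.run_contrast(
                clean, subset, spec=config.cluster_spec,
                n_perm=config.n_permutations, alpha=config.alpha,
                min_len=config.min_cluster_len, seed=config.seed,
                shuffle_scope=config.shuffle_scope,
                statistic=config.statistic, estimator=config.estimator)
        except ValueError as e:
            raise ValueError(f"contrast {name!r}: {e}") from e
        contrasts[name] = res
        res.bin_stats.assign(subset=name).to_csv(
            out / f"bin_stats_{name}.csv", index=False)
        pd.DataFrame({"null_max_mass": res.permutation.null_max_mass}).to_csv(
            out / f"null_distribution_{name}.csv", index=False)
        for c in res.permutation.clusters:
            lo, hi = c.time_window_ms(clean.bin_width_ms)
            cluster_rows.append({"subset": name, "start_bin": c.start_bin,
                                 "end_bin": c.end_bin, "start_ms": lo,
                                 "end_ms": hi, "sign": c.sign,
                                 "mass": c.mass, "p": c.p})
        if config.make_plots:
            from .plotting import plot_contrast
            plot_contrast(res, out / f"contrast_{name}.png", title=name,
                          bin_width_ms=clean.bin_width_ms)
    cluster_table = pd.DataFrame(
        cluster_rows, columns=["subset", "start_bin", "end_bin", "start_ms",
                               "end_ms", "sign", "mass", "p"])
    cluster_table.to_csv(out / "clusters.csv", index=False)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {"pupilforget": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "n_trials": report["n_trials"],
        "n_retained": report["n_retained"],
        "exclusions": {k: report[k] for k in
                       ("n_excluded", "n_excluded_missing", "n_excluded_spike",
                        "percent_removed")},
        "clusters": cluster_rows,
    }
    io.write_json(manifest, out / "manifest.json")

    return {"trials": trials, "clean": clean, "exclusion_report": report,
            "behavior": beh, "contrasts": contrasts,
            "cluster_table": cluster_table, "manifest": manifest}
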