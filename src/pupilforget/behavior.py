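"""Behavioral analyses: multilevel probit models, SDT summaries, RT models.

Implements the behavioral arm of the analysis:

* trial-level recognition responses modeled with a probit-link mixed model
  (condition × image type, crossed subject/item random effects) whose
  coefficients live on the d′ scale;
* subject-level d′ and criterion c from loglinear-corrected hit and
  false-alarm rates, compared across conditions with paired t-tests
  (effect size Cohen's d_z);
* log-transformed reaction times screened by a global 3-SD rule and modeled
  with a linear mixed model (condition × accuracy × image type).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import glmm
from .glmm import GlmmResult, fit_with_ladder
from .simulate import design_levels

IMAGE_LEVELS = ("Lure", "Old")


def loglinear_rates(hits: int, n_old: int, fas: int, n_lure: int) -> tuple[float, float]:
    """Loglinear-corrected hit and false-alarm rates: (count + 0.5) / (n + 1).

    Keeps both rates strictly inside (0, 1) even at 0% or 100% raw rates.
    """
    if n_old <= 0 or n_lure <= 0:
        raise ValueError("n_old and n_lure must be positive")
    if not 0 <= hits <= n_old or not 0 <= fas <= n_lure:
        raise ValueError("counts must lie within their trial totals")
    return (hits + 0.5) / (n_old + 1), (fas + 0.5) / (n_lure + 1)


def dprime_criterion(hr: float, far: float) -> tuple[float, float]:
    """Equal-variance SDT indices: d' = z(HR) - z(FAR), c = -(z(HR)+z(FAR))/2."""
    if not (0 < hr < 1 and 0 < far < 1):
        raise ValueError("rates must be strictly inside (0, 1); "
                         "apply the loglinear correction first")
    zh, zf = stats.norm.ppf(hr), stats.norm.ppf(far)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def sdt_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject × condition SDT table with corrected rates, d' and c."""
    rows = []
    for (subject, condition), g in trials.groupby(["subject", "condition"],
                                                  sort=True):
        old = g[g["image_type"] == "Old"]
        lure = g[g["image_type"] == "Lure"]
        hits = int((old["response"] == "old").sum())
        fas = int((lure["response"] == "old").sum())
        hr, far = loglinear_rates(hits, len(old), fas, len(lure))
        d, c = dprime_criterion(hr, far)
        rows.append({"subject": subject, "condition": condition,
                     "n_old": len(old), "n_lure": len(lure),
                     "hits": hits, "fas": fas, "hr_corr": hr, "far_corr": far,
                     "dprime": d, "criterion": c})
    return pd.DataFrame(rows)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    dz: float          # Cohen's d_z = mean(diff) / sd(diff)
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float


def paired_test(values_a, values_b) -> TTestResult:
    """Classical paired t-test on per-subject values, with Cohen's d_z."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be equal-length 1-D vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if diff.mean() == 0:
            return TTestResult(0.0, len(a) - 1, 1.0, 0.0, a.mean(), b.mean(),
                               a.std(ddof=1), b.std(ddof=1))
        raise OverflowError("zero variance of differences with nonzero mean: "
                            "t statistic is infinite")
    t = diff.mean() / (sd / np.sqrt(len(a)))
    df = len(a) - 1
    p = float(2 * stats.t.sf(abs(t), df))
    return TTestResult(float(t), df, p, float(diff.mean() / sd),
                       float(a.mean()), float(b.mean()),
                       float(a.std(ddof=1)), float(b.std(ddof=1)))


def compare_conditions(summary: pd.DataFrame, column: str,
                       levels: tuple[str, str]) -> TTestResult:
    """Paired t-test of a subject-level SDT index across the two conditions."""
    wide = summary.pivot(index="subject", columns="condition", values=column)
    wide = wide.dropna()
    return paired_test(wide[levels[0]].to_numpy(), wide[levels[1]].to_numpy())


def rt_prepare(trials: pd.DataFrame, sd_cutoff: float = 3.0):
    """Remove RT outliers beyond ``sd_cutoff`` SDs of the raw global mean,
    then add a log-transformed column. Returns (prepared, removed_fraction)."""
    rt = trials["rt_ms"].to_numpy(dtype=float)
    if np.any(rt <= 0):
        raise ValueError("rt_ms must be positive")
    mean, sd = rt.mean(), rt.std(ddof=1) if len(rt) > 1 else 0.0
    keep = np.abs(rt - mean) <= sd_cutoff * sd if sd > 0 else np.ones(len(rt), bool)
    out = trials.loc[keep].copy()
    out["log_rt"] = np.log(out["rt_ms"].to_numpy(dtype=float))
    return out, float(1.0 - keep.mean())


def _condition_levels(trials: pd.DataFrame) -> tuple[str, str]:
    present = set(trials["condition"].unique())
    for design in ("cue", "preview"):
        levels = design_levels(design)
        if present <= set(levels):
            return levels
    raise ValueError(f"unknown condition levels {sorted(present)}; allowed: "
                     f"{list(design_levels('cue'))} or {list(design_levels('preview'))}")


def fit_accuracy_glmm(trials: pd.DataFrame,
                      ladder: list[str] | None = None) -> GlmmResult:
    """Probit mixed model of P(respond "old") ~ condition × image type.

    With ±0.5 sum coding the image-type coefficient estimates the average
    d′ and the condition × type interaction the d′ difference between
    conditions; the condition main effect captures the criterion shift.
    Random structure starts maximal (subject/item intercepts + condition
    slopes) and is reduced stepwise on non-convergence.
    """
    levels = _condition_levels(trials)
    data = trials.copy()
    data["_y"] = (data["response"] == "old").astype(float)
    factors = {"condition": levels, "image_type": IMAGE_LEVELS}
    if ladder is None:
        ladder = glmm.reduction_ladder(("condition", "image_type"))

    def fit_one(structure):
        return glmm.fit_probit_mixed(data, factors, structure)

    return fit_with_ladder(fit_one, ladder)


def fit_rt_model(trials: pd.DataFrame,
                 ladder: list[str] | None = None) -> GlmmResult:
    """Linear mixed model of log RT ~ condition × accuracy × image type.

    Expects trials prepared by :func:`rt_prepare` (outlier-screened, with a
    ``log_rt`` column); accuracy is coded Incorrect/Correct.
    """
    if "log_rt" not in trials.columns:
        raise ValueError("run rt_prepare first (log_rt column missing)")
    levels = _condition_levels(trials)
    data = trials.copy()
    data["accuracy_label"] = np.where(data["accuracy"].astype(bool),
                                      "Correct", "Incorrect")
    factors = {"condition": levels,
               "accuracy_label": ("Incorrect", "Correct"),
               "image_type": IMAGE_LEVELS}

    def fit_one(structure):
        return glmm.fit_linear_mixed(data, "log_rt", factors, structure,
                                     link_label="identity-on-log-RT")

    return fit_with_ladder(fit_one, ladder)


def behavior_report(trials: pd.DataFrame) -> dict:
    """Full behavioral analysis bundle for one experiment."""
    levels = _condition_levels(trials)
    summary = sdt_summary(trials)
    d_test = compare_conditions(summary, "dprime", levels)
    c_test = compare_conditions(summary, "criterion", levels)
    acc_model = fit_accuracy_glmm(trials)
    prepared, removed = rt_prepare(trials)
    rt_model = fit_rt_model(prepared)
    return {
        "condition_levels": levels,
        "sdt_summary": summary,
        "dprime_test": d_test,
        "criterion_test": c_test,
        "accuracy_model": acc_model,
        "rt_model": rt_model,
        "rt_outlier_fraction": removed,
    }
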