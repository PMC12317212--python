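"""Per-bin models and cluster-based permutation inference on pupil series.

The test window is divided into 150 consecutive 20-ms bins. For every bin a
model of baseline-corrected pupil size with a fixed effect of condition is
fit; runs of at least ``min_len`` consecutive bins that are individually
significant (p < alpha) with a common effect sign form clusters, each
scored by the sum of its per-bin statistics (the cluster mass). Family-wise
correction compares each observed mass to the distribution of maximal
absolute cluster masses over experiments with condition labels randomly
re-shuffled (by default within subject), and reports the plain proportion
of null masses at least as large.

Three per-bin model specs are available, statistically nested:

* ``"mixed"``   — linear mixed model with crossed subject/item random
  intercepts and by-item condition slopes (reduced stepwise on
  non-convergence); the spec used for final reported fits.
* ``"subject"`` — fixed subject intercepts + condition effect, vectorized
  across bins; the fast desk-scale spec used inside permutation loops.
* ``"ols"``     — condition effect only (equivalent to a pooled two-sample
  t-test per bin).

Permutations always reuse the spec of the observed fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import glmm
from .containers import BinSeries, CleanTrials, bin_series_from_clean
from .glmm import fit_with_ladder

#: reduction ladder for the per-bin mixed spec (subject/item intercepts and
#: by-item condition slopes, matching the reported per-bin model)
PER_BIN_LADDER = ["subject, item, item_slope(condition)",
                  "subject, item", "subject", ""]


@dataclass
class Cluster:
    start_bin: int
    end_bin: int          # inclusive
    sign: int             # +1 or -1
    mass: float           # sum of member-bin statistics
    p: float | None = None

    @property
    def length(self) -> int:
        return self.end_bin - self.start_bin + 1

    def time_window_ms(self, bin_width_ms: int = 20) -> tuple[int, int]:
        """Half-open [start, end) window in ms after stimulus onset."""
        return (self.start_bin * bin_width_ms, (self.end_bin + 1) * bin_width_ms)


@dataclass
class PermutationResult:
    clusters: list[Cluster]
    null_max_mass: np.ndarray
    n_perm: int
    seed: int | None
    shuffle_scope: str
    statistic: str
    bin_stats: pd.DataFrame
    spec: str


def _condition_contrast(labels: pd.DataFrame,
                        levels: tuple[str, str] | None = None):
    """±0.5 contrast codes; the estimate reads level2 − level1.

    Levels default to the canonical design order (R, F) / (Previewed,
    NonPreviewed), so a positive effect means greater dilation for the
    forget-cued (or non-previewed) condition.
    """
    from .simulate import CUE_LEVELS, PREVIEW_LEVELS

    cond = labels["condition"].to_numpy()
    if levels is None:
        present = set(pd.unique(cond))
        for canonical in (CUE_LEVELS, PREVIEW_LEVELS):
            if present == set(canonical):
                levels = canonical
                break
        else:
            levels = tuple(sorted(present))
    if len(levels) != 2:
        raise ValueError(f"need exactly two condition levels, got {list(levels)}")
    return glmm.sum_code(cond, levels), levels


def _vectorized_stats(values: np.ndarray, x: np.ndarray,
                      subject: np.ndarray | None) -> pd.DataFrame:
    """Closed-form per-bin OLS of pupil ~ condition (optionally after
    within-subject demeaning), vectorized across bins."""
    y = values.astype(float)
    n, n_bins = y.shape
    if subject is not None:
        # absorb subject fixed intercepts by demeaning y and x per subject
        df_lost = len(np.unique(subject)) + 1
        codes = pd.Categorical(subject).codes
        counts = np.bincount(codes).astype(float)
        y = y - (np.add.reduceat(y[np.argsort(codes, kind="stable")], np.r_[0, np.cumsum(counts)[:-1].astype(int)], axis=0) / counts[:, None])[codes]
        x = x - np.bincount(codes, weights=x)[codes] / counts[codes]
    else:
        df_lost = 2
        y = y - y.mean(axis=0)
        x = x - x.mean()
    sxx = float(np.dot(x, x))
    dof = n - df_lost
    if sxx <= 0 or dof <= 0:
        est = np.zeros(n_bins)
        return pd.DataFrame({"bin": np.arange(n_bins), "estimate": est,
                             "se": est, "stat": est, "p": np.ones(n_bins),
                             "structure": "degenerate"})
    sxy = x @ y
    est = sxy / sxx
    rss = np.einsum("ij,ij->j", y, y) - est * sxy
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / dof / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2 * stats.t.sf(np.abs(t), dof), 1.0)
    return pd.DataFrame({"bin": np.arange(n_bins), "estimate": est, "se": se,
                         "stat": t, "p": p,
                         "structure": "subject-FE" if subject is not None else "OLS"})


def per_bin_stats(series: BinSeries, spec: str = "subject",
                  levels: tuple[str, str] | None = None) -> pd.DataFrame:
    """Fit the condition model in every bin; one row per bin.

    Columns: bin, estimate (condition contrast, level2 − level1), se,
    stat (t), p, structure (random structure actually used).
    """
    x, levels = _condition_contrast(series.labels, levels)
    if spec == "ols":
        return _vectorized_stats(series.values, x, None)
    if spec == "subject":
        return _vectorized_stats(series.values, x,
                                 series.labels["subject"].to_numpy())
    if spec != "mixed":
        raise ValueError(f"unknown per-bin spec {spec!r}")

    data = series.labels.copy()
    if "item" not in data.columns:
        data["item"] = data.get("trial", np.arange(len(data)))
    factors = {"condition": levels}
    rows = []
    for b in range(series.n_bins):
        y = series.values[:, b]
        if np.ptp(y) == 0:
            rows.append({"bin": b, "estimate": 0.0, "se": 0.0, "stat": 0.0,
                         "p": 1.0, "structure": "degenerate"})
            continue
        data["_pupil"] = y

        def fit_one(structure):
            return glmm.fit_linear_mixed(data, "_pupil", factors, structure)
        try:
            res = fit_with_ladder(fit_one, PER_BIN_LADDER)
            row = res["condition"]
            rows.append({"bin": b, "estimate": row["estimate"], "se": row["se"],
                         "stat": row["stat"], "p": row["p"],
                         "structure": res.random_structure})
        except glmm.ConvergenceError:
            # a bin that defeats the whole ladder cannot seed clusters
            rows.append({"bin": b, "estimate": np.nan, "se": np.nan,
                         "stat": 0.0, "p": 1.0, "structure": "failed"})
    return pd.DataFrame(rows)


def find_clusters(bin_stats: pd.DataFrame, alpha: float = 0.05,
                  min_len: int = 10) -> list[Cluster]:
    """Maximal runs of consecutive significant bins with a common sign.

    Bins qualify when p < alpha; a run splits wherever the statistic's sign
    flips; only runs of at least ``min_len`` bins are kept. Mass is the sum
    of the member statistics.
    """
    p = bin_stats["p"].to_numpy(dtype=float)
    t = bin_stats["stat"].to_numpy(dtype=float)
    sig = p < alpha
    clusters: list[Cluster] = []
    i, n = 0, len(p)
    while i < n:
        if not sig[i] or t[i] == 0:
            i += 1
            continue
        sign = 1 if t[i] > 0 else -1
        j = i
        while j + 1 < n and sig[j + 1] and t[j + 1] != 0 and \
                (1 if t[j + 1] > 0 else -1) == sign:
            j += 1
        if j - i + 1 >= min_len:
            clusters.append(Cluster(i, j, sign, float(t[i:j + 1].sum())))
        i = j + 1
    return clusters


def cluster_mass(stats_in_cluster) -> float:
    """Sum of per-bin statistics over the member bins."""
    return float(np.sum(np.asarray(stats_in_cluster, dtype=float)))


def _shuffled_labels(labels: pd.DataFrame, rng: np.random.Generator,
                     scope: str) -> np.ndarray:
    cond = labels["condition"].to_numpy()
    out = cond.copy()
    if scope == "global":
        return cond[rng.permutation(len(cond))]
    if scope == "within_subject":
        subj = labels["subject"].to_numpy()
        for s in pd.unique(subj):
            idx = np.flatnonzero(subj == s)
            out[idx] = cond[idx[rng.permutation(len(idx))]]
        return out
    raise ValueError(f"unknown shuffle scope {scope!r}")


def permutation_test(series: BinSeries, spec: str = "subject",
                     n_perm: int = 1000, alpha: float = 0.05,
                     min_len: int = 10, seed: int | None = 0,
                     shuffle_scope: str = "within_subject",
                     statistic: str = "max_abs",
                     estimator: str = "plain") -> PermutationResult:
    """Cluster-based permutation correction for the condition contrast.

    Each iteration re-shuffles trial-level condition labels (within subject
    by default), reruns the full per-bin + cluster pipeline with the same
    model spec, and contributes the maximal |mass| over its clusters (0 if
    none). Each observed cluster's p is the plain proportion of null maxima
    at least as large as its |mass| (or the (b+1)/(n+1) estimator when
    ``estimator="add_one"``). ``statistic="max_signed"`` keeps the signed
    maximum instead, for one-sided use.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("max_abs", "max_signed"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if estimator not in ("plain", "add_one"):
        raise ValueError(f"unknown estimator {estimator!r}")
    x, levels = _condition_contrast(series.labels)
    obs_stats = per_bin_stats(series, spec, levels)
    clusters = find_clusters(obs_stats, alpha, min_len)

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    labels = series.labels
    for it in range(n_perm):
        shuffled = labels.copy()
        shuffled["condition"] = _shuffled_labels(labels, rng, shuffle_scope)
        perm_series = BinSeries(series.values, shuffled, series.bin_width_ms)
        pstats = per_bin_stats(perm_series, spec, levels)
        pclusters = find_clusters(pstats, alpha, min_len)
        if pclusters:
            masses = np.array([c.mass for c in pclusters])
            null[it] = (np.abs(masses).max() if statistic == "max_abs"
                        else masses[np.argmax(np.abs(masses))])
        # else 0: iterations without qualifying clusters count as mass 0
    for c in clusters:
        exceed = int((np.abs(null) >= abs(c.mass)).sum())
        c.p = (exceed / n_perm if estimator == "plain"
               else (exceed + 1) / (n_perm + 1))
    return PermutationResult(clusters, null, n_perm, seed, shuffle_scope,
                             statistic, obs_stats, spec)


@dataclass
class ContrastResult:
    permutation: PermutationResult
    bin_stats: pd.DataFrame
    condition_means: pd.DataFrame  # per condition × bin: mean, sem, n
    subset: dict | None
    levels: tuple


def condition_bin_means(series: BinSeries) -> pd.DataFrame:
    """Plot-ready per-condition mean ± SEM for every bin."""
    rows = []
    t_ms = np.arange(series.n_bins) * series.bin_width_ms
    for cond in sorted(pd.unique(series.labels["condition"])):
        v = series.values[series.labels["condition"].to_numpy() == cond]
        sem = (v.std(axis=0, ddof=1) / np.sqrt(len(v)) if len(v) > 1
               else np.zeros(series.n_bins))
        for b in range(series.n_bins):
            rows.append({"condition": cond, "bin": b, "time_ms": t_ms[b],
                         "mean": v[:, b].mean(), "sem": sem[b], "n": len(v)})
    return pd.DataFrame(rows)


def run_contrast(clean: CleanTrials, subset: dict | None = None,
                 spec: str = "subject", n_perm: int = 1000,
                 alpha: float = 0.05, min_len: int = 10,
                 seed: int | None = 0,
                 shuffle_scope: str = "within_subject",
                 statistic: str = "max_abs",
                 estimator: str = "plain") -> ContrastResult:
    """Full condition contrast on a trial subset (e.g. old-image misses).

    Selects the subset, verifies both condition levels are present, and runs
    the per-bin model + cluster formation + permutation correction, returning
    the per-bin table, clusters with corrected p values, and plot-ready
    condition means.
    """
    series = bin_series_from_clean(clean, subset)
    present = set(pd.unique(series.labels["condition"])) if len(series.labels) else set()
    all_levels = set(pd.unique(clean.meta["condition"]))
    missing = sorted(all_levels - present)
    if missing or len(present) < 2:
        raise ValueError(
            f"condition level(s) {missing or sorted(all_levels)} absent from "
            f"subset {subset!r}; cannot contrast")
    perm = permutation_test(series, spec, n_perm, alpha, min_len, seed,
                            shuffle_scope, statistic, estimator)
    _, levels = _condition_contrast(series.labels)
    return ContrastResult(perm, perm.bin_stats, condition_bin_means(series),
                          subset, levels)
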