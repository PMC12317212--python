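"""Mixed-effects machinery: Laplace probit GLMM and linear-mixed wrappers.

Two fitting routes live here:

* :class:`ProbitMixedModel` — a maximum-likelihood probit-link GLMM with
  independent crossed Gaussian random effects (subject / item intercepts and
  slopes), fit by the Laplace approximation: for each candidate vector of
  random-effect SDs the conditional mode of the latent effects is found by
  damped Newton on the penalized log-likelihood (jointly with the fixed
  effects), and the profiled Laplace log-likelihood is maximized over the
  SDs with Nelder–Mead. This is the same approximation lme4's ``glmer``
  uses at its default setting.
* :func:`fit_linear_mixed` — linear mixed models via statsmodels ``MixedLM``
  with variance components encoding crossed random intercepts and
  independent random slopes.

Both are consumed through :func:`fit_with_ladder`, which walks a stepwise
reduction of the random structure on convergence failure: drop item slopes,
then subject slopes, then all slopes, then item intercepts; subject
intercepts are never dropped (below that the model degrades to an ordinary
GLM/OLS fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

__all__ = [
    "ConvergenceError", "GlmmResult", "ProbitMixedModel",
    "fit_linear_mixed", "fit_probit_mixed", "fit_with_ladder",
    "RANDOM_LADDER",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class GlmmResult:
    """Coefficient table and bookkeeping for one mixed-model fit."""

    formula: str
    coef: pd.DataFrame          # name, estimate, se, stat, p
    link: str                   # "probit" or "identity-on-log-RT" / "identity"
    random_structure: str       # structure actually used after reduction
    converged: bool
    reliable: bool = True       # False under separation / boundary pathology
    vc: dict = field(default_factory=dict)  # random-effect SDs

    def __getitem__(self, name: str) -> pd.Series:
        row = self.coef.loc[self.coef["name"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


# ---------------------------------------------------------------------------
# Laplace probit GLMM
# ---------------------------------------------------------------------------

class ProbitMixedModel:
    """Probit GLMM with independent Gaussian random-effect blocks.

    Parameters
    ----------
    y : (n,) array of 0/1 outcomes
    X : (n, p) fixed-effect design matrix
    z_blocks : mapping name -> (n, q_k) indicator/design matrix for one
        random-effect block; each block has a single SD parameter and its
        effects are mutually independent.
    """

    def __init__(self, y, X, z_blocks: dict[str, np.ndarray]):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.sign = 2.0 * self.y - 1.0
        self.blocks = {k: np.asarray(v, dtype=float) for k, v in z_blocks.items()}
        self.p = self.X.shape[1]
        self.q = sum(v.shape[1] for v in self.blocks.values())

    def _zmat(self, sigmas: np.ndarray) -> np.ndarray:
        if not self.blocks:
            return np.zeros((len(self.y), 0))
        return np.hstack([s * Z for s, Z in zip(sigmas, self.blocks.values())])

    def _penalized_mode(self, sigmas: np.ndarray, start: np.ndarray | None = None):
        """Damped Newton for the joint (beta, u) mode at fixed sigmas."""
        A = np.hstack([self.X, self._zmat(sigmas)])
        m = A.shape[1]
        pen = np.zeros(m)
        pen[self.p:] = 1.0  # unit-normal penalty on scaled random effects
        gamma = start if start is not None else np.zeros(m)

        def objective(g):
            z = self.sign * (A @ g)
            return stats.norm.logcdf(z).sum() - 0.5 * (pen * g * g).sum()

        obj = objective(gamma)
        for _ in range(100):
            eta = A @ gamma
            z = self.sign * eta
            r = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
            grad = A.T @ (self.sign * r) - pen * gamma
            w = r * (r + z)  # positive curvature weights
            H = (A * w[:, None]).T @ A
            H[np.diag_indices_from(H)] += pen + 1e-10
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError as e:
                raise ConvergenceError(f"singular Hessian: {e}") from e
            # backtracking line search
            t = 1.0
            for _ in range(30):
                new = gamma + t * step
                new_obj = objective(new)
                if new_obj >= obj - 1e-12:
                    break
                t *= 0.5
            gamma, improved = gamma + t * step, new_obj - obj
            obj = new_obj
            if np.max(np.abs(grad)) < 1e-7 or abs(improved) < 1e-10:
                break
        else:
            raise ConvergenceError("inner Newton did not converge")
        if not np.isfinite(obj):
            raise ConvergenceError("non-finite penalized likelihood")
        return gamma, obj, A, pen

    def _laplace_loglik(self, log_sigmas: np.ndarray, state: dict) -> float:
        sigmas = np.exp(log_sigmas)
        try:
            gamma, obj, A, pen = self._penalized_mode(sigmas, state.get("gamma"))
        except ConvergenceError:
            return 1e10
        state["gamma"] = gamma
        eta = A @ gamma
        z = self.sign * eta
        r = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
        w = r * (r + z)
        if self.q:
            Zs = A[:, self.p:]
            M = (Zs * w[:, None]).T @ Zs
            M[np.diag_indices_from(M)] += 1.0
            sgn, logdet = np.linalg.slogdet(M)
            if sgn <= 0:
                return 1e10
        else:
            logdet = 0.0
        return -(obj - 0.5 * logdet)

    def fit(self, start_sigma: float = 0.5) -> dict:
        nb = len(self.blocks)
        state: dict = {}
        if nb:
            x0 = np.full(nb, np.log(start_sigma))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(self._laplace_loglik, x0, args=(state,),
                                        method="Nelder-Mead",
                                        options={"xatol": 1e-3, "fatol": 1e-4,
                                                 "maxiter": 400 * nb})
            if not np.isfinite(res.fun) or res.fun >= 1e9:
                raise ConvergenceError("outer optimization failed")
            sigmas = np.exp(res.x)
        else:
            sigmas = np.array([])
        gamma, obj, A, pen = self._penalized_mode(sigmas, state.get("gamma"))

        # approximate covariance of beta from the joint curvature at the mode
        eta = A @ gamma
        z = self.sign * eta
        r = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
        w = r * (r + z)
        H = (A * w[:, None]).T @ A
        H[np.diag_indices_from(H)] += pen + 1e-10
        try:
            cov = np.linalg.inv(H)[: self.p, : self.p]
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular information matrix: {e}") from e
        beta = gamma[: self.p]
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        reliable = bool(np.all(np.abs(beta) < 15) and np.all(se > 1e-8)
                        and np.all(se < 1e3))
        return {"beta": beta, "se": se,
                "sigmas": dict(zip(self.blocks.keys(), sigmas)),
                "loglik": float(obj), "reliable": reliable}


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def sum_code(values: np.ndarray, levels: tuple) -> np.ndarray:
    """Two-level sum-to-zero coding: first level -> -0.5, second -> +0.5."""
    if len(levels) != 2:
        raise ValueError("sum_code expects exactly two levels")
    out = np.where(np.asarray(values) == levels[1], 0.5, -0.5)
    missing = ~np.isin(np.asarray(values), levels)
    if missing.any():
        bad = sorted(set(np.asarray(values)[missing]))
        raise ValueError(f"unknown level(s) {bad}; allowed: {list(levels)}")
    return out.astype(float)


def fixed_design(data: pd.DataFrame, factors: dict[str, tuple]) -> tuple[np.ndarray, list[str]]:
    """Intercept + sum-coded main effects + all interactions."""
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    coded = {f: sum_code(data[f].to_numpy(), lv) for f, lv in factors.items()}
    keys = list(factors)
    # main effects then interactions of increasing order
    from itertools import combinations
    for order in range(1, len(keys) + 1):
        for combo in combinations(keys, order):
            col = np.ones(len(data))
            for f in combo:
                col = col * coded[f]
            cols.append(col)
            names.append(":".join(combo))
    return np.column_stack(cols), names


def indicator(values: np.ndarray) -> np.ndarray:
    cats = pd.Categorical(values)
    return np.eye(len(cats.categories))[cats.codes]


def random_blocks(data: pd.DataFrame, structure: str,
                  factors: dict[str, tuple]) -> dict[str, np.ndarray]:
    """Build the Z blocks named by a random-structure descriptor.

    Structure grammar: comma-joined terms among ``subject``, ``item``
    (random intercepts) and ``subject_slope(f)`` / ``item_slope(f)`` —
    independent random slopes for the sum-coded factor ``f``.
    """
    blocks: dict[str, np.ndarray] = {}
    terms = [t.strip() for t in structure.split(",") if t.strip()] if structure else []

    def slope_col(factor: str) -> np.ndarray:
        if factor not in factors:
            raise ValueError(f"unknown slope factor {factor!r}")
        return sum_code(data[factor].to_numpy(), factors[factor])

    for term in terms:
        if term == "subject":
            blocks["subject"] = indicator(data["subject"].to_numpy())
        elif term == "item":
            blocks["item"] = indicator(data["item"].to_numpy())
        elif term.startswith(("subject_slope(", "item_slope(")) and term.endswith(")"):
            grp, factor = term[:-1].split("(")
            col = "subject" if grp == "subject_slope" else "item"
            blocks[term] = indicator(data[col].to_numpy()) * slope_col(factor)[:, None]
        else:
            raise ValueError(f"unknown random term {term!r}")
    return blocks


def reduction_ladder(slope_factors: tuple[str, ...]) -> list[str]:
    """Stepwise random-structure reduction: drop item-side slopes first,
    then subject-side slopes, then item intercepts; subject intercepts are
    never dropped (the final rung is an ordinary fixed-effects fit)."""
    subj_slopes = [f"subject_slope({f})" for f in slope_factors]
    item_slopes = [f"item_slope({f})" for f in slope_factors]
    maximal = ", ".join(["subject", "item"] + subj_slopes + item_slopes)
    no_item_slopes = ", ".join(["subject", "item"] + subj_slopes)
    ladder = [maximal]
    if item_slopes:
        ladder.append(no_item_slopes)
    if subj_slopes:
        ladder.append("subject, item")
    ladder += ["subject", ""]
    return ladder


#: default ladder with condition slopes only (RT / per-bin style models)
RANDOM_LADDER = reduction_ladder(("condition",))


def fit_probit_mixed(data: pd.DataFrame, factors: dict[str, tuple],
                     structure: str) -> GlmmResult:
    """One probit GLMM fit at a fixed random structure."""
    y = data["_y"].to_numpy(dtype=float)
    X, names = fixed_design(data, factors)
    blocks = random_blocks(data, structure, factors)
    if structure == "":
        # plain probit GLM via statsmodels (the ladder's last rung)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Probit()))
            res = glm.fit()
        beta, se = res.params, res.bse
        reliable = bool(np.all(np.abs(beta) < 15) and np.all(se < 1e3))
        fit = {"beta": beta, "se": se, "sigmas": {}, "reliable": reliable}
    else:
        fit = ProbitMixedModel(y, X, blocks).fit()
    z = np.divide(fit["beta"], fit["se"], out=np.zeros_like(fit["beta"]),
                  where=fit["se"] > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    coef = pd.DataFrame({"name": names, "estimate": fit["beta"], "se": fit["se"],
                         "stat": z, "p": p})
    formula = "_y ~ " + " * ".join(factors)
    return GlmmResult(formula, coef, "probit", structure or "none (GLM)", True,
                      fit["reliable"], {k: float(v) for k, v in fit["sigmas"].items()})


def fit_linear_mixed(data: pd.DataFrame, response: str,
                     factors: dict[str, tuple], structure: str,
                     link_label: str = "identity") -> GlmmResult:
    """One linear mixed fit (statsmodels MixedLM, variance components)."""
    X, names = fixed_design(data, factors)
    y = data[response].to_numpy(dtype=float)
    blocks = random_blocks(data, structure, factors)
    if structure == "":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.OLS(y, X).fit()
        coef = pd.DataFrame({"name": names, "estimate": res.params, "se": res.bse,
                             "stat": res.tvalues, "p": res.pvalues})
        return GlmmResult(f"{response} ~ " + " * ".join(factors), coef, link_label,
                          "none (OLS)", True, True, {})
    groups = np.zeros(len(data), dtype=int)  # single group: crossed effects via VCs
    from statsmodels.regression.mixed_linear_model import VCSpec
    vcs = VCSpec(list(blocks), [[[f"{k}{j}" for j in range(v.shape[1])]]
                                for k, v in blocks.items()],
                 [[v] for v in blocks.values()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups, exog_re=None, exog_vc=vcs)
        try:
            res = model.fit(reml=True, method=["lbfgs", "bfgs"], maxiter=200)
        except Exception as e:  # numerical failures bubble up as ladder steps
            raise ConvergenceError(str(e)) from e
    if not res.converged:
        raise ConvergenceError("MixedLM did not converge")
    k = len(names)
    coef = pd.DataFrame({"name": names, "estimate": res.params[:k],
                         "se": res.bse[:k], "stat": res.tvalues[:k],
                         "p": res.pvalues[:k]})
    vc = {nm: float(np.sqrt(max(v, 0.0)))
          for nm, v in zip(blocks, res.params[k:k + len(blocks)])}
    return GlmmResult(f"{response} ~ " + " * ".join(factors), coef, link_label,
                      structure, True, True, vc)


def fit_with_ladder(fit_one, ladder: list[str] | None = None) -> GlmmResult:
    """Try random structures from maximal to minimal; return the first fit
    that converges, annotated with the structure used."""
    ladder = RANDOM_LADDER if ladder is None else ladder
    last_err: Exception | None = None
    for structure in ladder:
        try:
            return fit_one(structure)
        except (ConvergenceError, np.linalg.LinAlgError) as e:
            last_err = e
            continue
    raise ConvergenceError(f"no random structure converged: {last_err}")
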