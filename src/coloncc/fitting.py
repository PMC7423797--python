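"""Censored maximum-likelihood fitting and model-development workflow.

Fits the four candidate parametric families (Gompertz, Weibull,
log-normal, log-logistic) to right-censored records by maximizing
``sum(event * log h(t) - H(t))``, selects the family by lowest AIC, and
performs forward covariate selection with Wald tests at a two-sided
significance threshold of 0.157 (the AIC-equivalent rule, |z| ~ sqrt(2)).

Records are flat tables (one row per subject) with a positive
``time_months`` column, a binary ``event`` column and covariate columns;
categorical covariates are dummy-coded against the first canonical level
(see :data:`coloncc.parameters.COVARIATE_LEVELS`).  Rows with a missing
value in any requested covariate are excluded (complete-case analysis).

Positivity of rate/scale/shape parameters is enforced by optimizing on
the log scale; reported standard errors for those parameters are
delta-method transforms back to the natural scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from . import survdist
from .parameters import COVARIATE_LEVELS, ParametricSurvivalModel

__all__ = [
    "FittingError",
    "FitResult",
    "FamilySelection",
    "ForwardSelectionResult",
    "fit_parametric",
    "select_family",
    "forward_select",
    "wald_test",
    "SIGNIFICANCE_THRESHOLD",
]

SIGNIFICANCE_THRESHOLD = 0.157


class FittingError(RuntimeError):
    """Optimization failure; carries the final gradient norm when known."""

    def __init__(self, message: str, gradient_norm: float | None = None):
        super().__init__(message)
        self.gradient_norm = gradient_norm


@dataclass
class FitResult:
    model: ParametricSurvivalModel
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    n_events: int
    standard_errors: dict[str, float]
    wald_p: dict[str, float]
    covariance: np.ndarray = field(repr=False)
    param_names: list[str] = field(repr=False)


def wald_test(estimate: float, se: float) -> float:
    """Two-sided Wald p-value ``2 * Phi(-|estimate / se|)``."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(2.0 * stats.norm.sf(abs(estimate / se)))


def _design(records: pd.DataFrame, covariates) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Complete-case records, dummy design matrix and coefficient names."""
    covariates = list(covariates)
    df = records.dropna(subset=covariates) if covariates else records
    cols = []
    names: list[str] = []
    for cov in covariates:
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
            continue
        levels = COVARIATE_LEVELS.get(cov)
        if levels is None:
            levels = tuple(sorted(col.astype(str).unique()))
        unknown = set(col.astype(str).unique()) - set(map(str, levels))
        if unknown:
            raise ValueError(f"unknown level(s) {sorted(unknown)} for covariate {cov!r}")
        for level in levels[1:]:
            cols.append((col.astype(str) == str(level)).to_numpy(dtype=float))
            names.append(f"{cov}={level}")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return df, X, names


def _nll_factory(family, t, d, X):
    def unpack(theta):
        if family == "gompertz":
            shape = theta[0]
        else:
            shape = np.exp(theta[0])
        scale = np.exp(theta[1])
        beta = theta[2:]
        return shape, scale, beta

    def nll(theta):
        shape, scale, beta = unpack(theta)
        lp = X @ beta if X.shape[1] else 0.0
        with np.errstate(over="ignore", invalid="ignore"):
            logh = survdist.log_hazard(family, t, shape, scale, lp)
            H = survdist.cumhaz(family, t, shape, scale, lp)
            val = -(np.sum(d * logh) - np.sum(H))
        return val if np.isfinite(val) else 1e12

    return unpack, nll


def _start_values(family, t, d, n_beta):
    crude = max(d.sum() / t.sum(), 1e-8)
    med = float(np.median(t[d == 1])) if d.sum() else float(np.median(t))
    starts = {
        "gompertz": [0.0, np.log(crude)],
        "weibull": [0.0, np.log(1.0 / crude)],
        "lognormal": [0.0, np.log(max(med, 1e-6))],
        "loglogistic": [0.0, np.log(max(med, 1e-6))],
    }
    return np.array(starts[family] + [0.0] * n_beta)


def fit_parametric(
    records: pd.DataFrame,
    family: str,
    covariates=(),
    time_col: str = "time_months",
    event_col: str = "event",
) -> FitResult:
    """Censored maximum-likelihood fit of one family with covariates.

    Deterministic given the data (quasi-Newton from fixed starting values
    with a Nelder-Mead fallback).  Raises :class:`FittingError` on
    non-convergence and :class:`ValueError` on degenerate data.
    """
    if family not in survdist.FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    df, X, names = _design(records, covariates)
    t = df[time_col].to_numpy(dtype=float)
    d = df[event_col].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.isin(d, (0.0, 1.0)).all():
        raise ValueError("event column must be binary")
    if d.sum() == 0:
        raise ValueError("all records are censored; nothing to fit")
    if len(np.unique(t[d == 1])) < 2:
        raise ValueError("need at least two distinct event times")

    _, nll = _nll_factory(family, t, d, X)
    theta0 = _start_values(family, t, d, X.shape[1])
    res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    best = res
    if not res.success or not np.isfinite(res.fun):
        res2 = optimize.minimize(nll, res.x if np.isfinite(res.fun) else theta0,
                                 method="Nelder-Mead",
                                 options={"maxiter": 5000, "fatol": 1e-10, "xatol": 1e-8})
        if res2.fun < best.fun:
            best = res2
    grad = optimize.approx_fprime(best.x, nll, 1e-6)
    gnorm = float(np.linalg.norm(grad))
    scale_ref = max(abs(best.fun), 1.0)
    if not np.isfinite(best.fun) or gnorm > 1e-2 * scale_ref:
        raise FittingError(
            f"{family} fit did not converge (gradient norm {gnorm:.3g})", gnorm
        )

    theta = best.x
    k = len(theta)
    loglik = -float(best.fun)
    hess = numdiff.approx_hess(theta, nll)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        warnings.warn("singular observed information; using pseudo-inverse", stacklevel=2)
        cov = np.linalg.pinv(hess)
    se_theta = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    if family == "gompertz":
        shape, se_shape = float(theta[0]), float(se_theta[0])
    else:
        shape = float(np.exp(theta[0]))
        se_shape = float(se_theta[0] * shape)
    scale = float(np.exp(theta[1]))
    se_scale = float(se_theta[1] * scale)
    beta = theta[2:]

    ses = {"shape": se_shape, "rate_or_scale": se_scale}
    wald = {}
    for i, name in enumerate(names):
        ses[name] = float(se_theta[2 + i])
        wald[name] = wald_test(beta[i], ses[name]) if ses[name] > 0 else float("nan")

    model = ParametricSurvivalModel(
        family=family, shape=shape, rate_or_scale=scale,
        coefficients={name: float(b) for name, b in zip(names, beta)},
    )
    return FitResult(
        model=model, loglik=loglik, aic=2.0 * k - 2.0 * loglik, n_params=k,
        n_obs=len(df), n_events=int(d.sum()), standard_errors=ses, wald_p=wald,
        covariance=cov, param_names=["shape", "rate_or_scale", *names],
    )


@dataclass
class FamilySelection:
    best_family: str
    table: pd.DataFrame     # per-family AIC for the visual-inspection step
    fits: dict[str, FitResult]


def select_family(records, families=survdist.FAMILIES, covariates=()) -> FamilySelection:
    """Fit each family and pick the lowest AIC (ties: listed order).

    Families that fail to fit are excluded with a warning.  The AIC table
    is returned for the human visual-inspection step, which is not
    automated.
    """
    families = list(families)
    if len(families) < 2:
        raise ValueError("need at least two candidate families")
    rows, fits = [], {}
    for fam in families:
        try:
            fit = fit_parametric(records, fam, covariates)
        except (FittingError, ValueError) as exc:
            warnings.warn(f"family {fam!r} excluded: {exc}", stacklevel=2)
            rows.append({"family": fam, "aic": np.nan, "loglik": np.nan,
                         "n_params": np.nan, "error": str(exc)})
            continue
        fits[fam] = fit
        rows.append({"family": fam, "aic": fit.aic, "loglik": fit.loglik,
                     "n_params": fit.n_params, "error": ""})
    if not fits:
        raise FittingError("no candidate family could be fitted")
    table = pd.DataFrame(rows)
    best = min(fits, key=lambda f: (fits[f].aic, families.index(f)))
    return FamilySelection(best_family=best, table=table, fits=fits)


def _joint_wald_p(fit: FitResult, covariate: str) -> float:
    """Joint Wald test of all coefficients belonging to one covariate."""
    idx = [i for i, name in enumerate(fit.param_names)
           if name == covariate or name.startswith(f"{covariate}=")]
    if not idx:
        raise KeyError(f"covariate {covariate!r} not in fit")
    beta = np.array([fit.model.coefficients[fit.param_names[i]] for i in idx])
    sub = fit.covariance[np.ix_(idx, idx)]
    try:
        w = float(beta @ np.linalg.solve(sub, beta))
    except np.linalg.LinAlgError:
        return float("nan")
    return float(stats.chi2.sf(w, df=len(idx)))


@dataclass
class ForwardSelectionResult:
    selected: list[str]
    steps: pd.DataFrame     # candidate p-values per step, in inclusion order


def forward_select(
    records: pd.DataFrame,
    family: str,
    candidate_covariates,
    alpha: float = SIGNIFICANCE_THRESHOLD,
) -> ForwardSelectionResult:
    """Forward covariate selection with Wald tests.

    At each step the candidate with the smallest Wald p-value (joint
    chi-square across its dummy coefficients) is added if it falls below
    ``alpha``; all parameters are refitted at every step.  Deterministic
    given the data.
    """
    remaining = list(candidate_covariates)
    selected: list[str] = []
    rows = []
    step = 0
    while remaining:
        step += 1
        pvals = {}
        for cand in remaining:
            try:
                fit = fit_parametric(records, family, [*selected, cand])
                pvals[cand] = _joint_wald_p(fit, cand)
            except (FittingError, ValueError) as exc:
                warnings.warn(f"candidate {cand!r} skipped at step {step}: {exc}",
                              stacklevel=2)
                pvals[cand] = float("nan")
        finite = {c: p for c, p in pvals.items() if np.isfinite(p)}
        best = min(finite, key=finite.get) if finite else None
        for cand, p in pvals.items():
            rows.append({"step": step, "covariate": cand, "wald_p": p,
                         "included": bool(best == cand and finite.get(cand, 1.0) < alpha)})
        if best is None or finite[best] >= alpha:
            break
        selected.append(best)
        remaining.remove(best)
    return ForwardSelectionResult(selected=selected, steps=pd.DataFrame(rows))
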