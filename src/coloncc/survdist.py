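"""Parametric survival mathematics for the four candidate families.

Hazards, cumulative hazards, survival functions, discrete monthly
transition probabilities and inverse-CDF sampling for the Gompertz,
Weibull, log-normal and log-logistic families, in the flexsurv-style
parameterization:

* Gompertz: ``h(t) = rate * exp(lp) * exp(shape * t)`` -- covariates act
  proportionally on the hazard (``lp`` is a log hazard ratio).  A negative
  shape makes the distribution defective (cure fraction
  ``exp(-rate * exp(lp) / |shape|)``).
* Weibull / log-normal / log-logistic: accelerated failure time --
  covariates multiply the scale via ``exp(lp)`` (``lp`` is a log time
  ratio).

Time is measured in months throughout; ``t = 0`` is state entry.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "gompertz_hazard",
    "gompertz_cumhaz",
    "loglogistic_survival",
    "hazard",
    "cumhaz",
    "log_hazard",
    "survival",
    "monthly_event_probability",
    "sample_event_time",
]

FAMILIES = ("gompertz", "weibull", "lognormal", "loglogistic")


def _expm1_over_x(x):
    """``expm1(x)/x`` with the removable singularity at 0 filled in."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0.0
    out[nz] = np.expm1(x[nz]) / x[nz]
    return out


def gompertz_hazard(t, shape, rate, linear_predictor=0.0):
    """Gompertz hazard ``rate * exp(lp) * exp(shape * t)`` per month."""
    if rate <= 0:
        raise ValueError("Gompertz rate must be positive")
    t = np.asarray(t, dtype=float)
    return rate * np.exp(linear_predictor + shape * t)


def gompertz_cumhaz(t, shape, rate, linear_predictor=0.0):
    """Gompertz cumulative hazard, continuous in ``shape`` at 0.

    ``(rate * exp(lp) / shape) * (exp(shape*t) - 1)`` for nonzero shape,
    ``rate * exp(lp) * t`` in the exponential limit.
    """
    if rate <= 0:
        raise ValueError("Gompertz rate must be positive")
    t = np.asarray(t, dtype=float)
    return rate * np.exp(linear_predictor) * t * _expm1_over_x(shape * t)


def loglogistic_survival(t, shape, scale, linear_predictor=0.0):
    """Log-logistic survival ``1 / (1 + (t / (scale * exp(lp)))**shape)``."""
    if shape <= 0 or scale <= 0:
        raise ValueError("log-logistic shape and scale must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return 1.0 / (1.0 + (t / (scale * np.exp(linear_predictor))) ** shape)


def _eff_scale(scale, linear_predictor):
    return scale * np.exp(linear_predictor)


def cumhaz(family, t, shape, rate_or_scale, linear_predictor=0.0):
    """Cumulative hazard ``H(t)`` for any of the four families."""
    t = np.asarray(t, dtype=float)
    if family == "gompertz":
        return gompertz_cumhaz(t, shape, rate_or_scale, linear_predictor)
    s = _eff_scale(rate_or_scale, linear_predictor)
    if family == "weibull":
        return (t / s) ** shape
    if family == "lognormal":
        # shape = sigma of log-time; scale = exp(mu)
        with np.errstate(divide="ignore"):
            z = np.where(t > 0, (np.log(np.maximum(t, 1e-300)) - np.log(s)) / shape, -np.inf)
        return -stats.norm.logsf(z)
    if family == "loglogistic":
        return np.log1p((t / s) ** shape)
    raise ValueError(f"unknown family {family!r}")


def log_hazard(family, t, shape, rate_or_scale, linear_predictor=0.0):
    """``log h(t)``; ``t`` must be positive for the AFT families."""
    t = np.asarray(t, dtype=float)
    if family == "gompertz":
        return np.log(rate_or_scale) + linear_predictor + shape * t
    s = _eff_scale(rate_or_scale, linear_predictor)
    logt_s = np.log(t / s)
    if family == "weibull":
        return np.log(shape / s) + (shape - 1.0) * logt_s
    if family == "lognormal":
        z = logt_s / shape
        return stats.norm.logpdf(z) - np.log(shape * t) - stats.norm.logsf(z)
    if family == "loglogistic":
        return (np.log(shape / s) + (shape - 1.0) * logt_s
                - np.log1p((t / s) ** shape))
    raise ValueError(f"unknown family {family!r}")


def hazard(family, t, shape, rate_or_scale, linear_predictor=0.0):
    return np.exp(log_hazard(family, t, shape, rate_or_scale, linear_predictor))


def survival(family, t, shape, rate_or_scale, linear_predictor=0.0):
    """``S(t) = exp(-H(t))``."""
    return np.exp(-cumhaz(family, t, shape, rate_or_scale, linear_predictor))


def monthly_event_probability(survival_at, t: int) -> float:
    """Discrete monthly event probability ``q(t) = 1 - S(t)/S(t-1)``.

    ``survival_at`` is any non-increasing survival function with
    ``S(0) = 1``; by convention ``q = 1`` once ``S(t-1) = 0`` (absorbing).
    """
    s_prev = float(survival_at(t - 1))
    if s_prev == 0.0:
        return 1.0
    return 1.0 - float(survival_at(t)) / s_prev


def sample_event_time(family, shape, rate_or_scale, linear_predictor, u):
    """Inverse-CDF event time: the ``t`` with ``S(t) = u``.

    ``u`` may be a scalar or array in (0, 1).  For a defective Gompertz
    (negative shape) values of ``u`` below the cure mass return ``+inf``.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly in (0, 1)")
    if family == "gompertz":
        if rate_or_scale <= 0:
            raise ValueError("Gompertz rate must be positive")
        target = -np.log(u)  # required cumulative hazard
        level = rate_or_scale * np.exp(linear_predictor)
        if shape == 0.0:
            return target / level
        arg = 1.0 + shape * target / level
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(arg > 0.0, np.log(np.maximum(arg, 1e-300)) / shape, np.inf)
        return t
    s = _eff_scale(rate_or_scale, linear_predictor)
    if family == "weibull":
        return s * (-np.log(u)) ** (1.0 / shape)
    if family == "lognormal":
        return stats.lognorm.isf(u, s=shape, scale=s)
    if family == "loglogistic":
        return s * ((1.0 - u) / u) ** (1.0 / shape)
    raise ValueError(f"unknown family {family!r}")
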