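"""Discrimination and calibration statistics for censored risk predictions.

Uno's inverse-probability-of-censoring-weighted C-statistic and the
Greenwood-D'Agostino-Nam (GND) chi-square calibration test on predicted
risk groups at a landmark time (default 36 months).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = ["UnoCResult", "GNDResult", "uno_c", "gnd_test", "DEFAULT_LANDMARK"]

logger = logging.getLogger(__name__)

DEFAULT_LANDMARK = 36.0


@dataclass
class UnoCResult:
    c: float
    se: float
    ci_low: float
    ci_high: float
    n_comparable_pairs: int


@dataclass
class GNDResult:
    statistic: float
    p_value: float
    df: int
    table: pd.DataFrame


def _censoring_survival_left(time, event):
    """Left-continuous KM of the censoring distribution, as a callable."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - np.asarray(event))
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)

    def g_left(t):
        # S(t-): step value just before t
        idx = np.searchsorted(times, np.asarray(t, dtype=float), side="left") - 1
        return np.where(idx < 0, 1.0, vals[np.clip(idx, 0, len(vals) - 1)])

    return g_left


def uno_c(time, event, risk, tau: float, jackknife_se: bool = True,
          alpha: float = 0.05) -> UnoCResult:
    """Censoring-adjusted concordance for event-risk predictions.

    Pairs (i, j) with ``t_i < t_j``, ``t_i < tau`` and an observed event
    for i are weighted by ``1 / G(t_i-)**2`` where G is the Kaplan-Meier
    estimate of the censoring distribution; a higher predicted risk for
    the earlier failure counts as concordant, ties count one half.  The
    confidence interval comes from a leave-one-subject-out jackknife that
    holds the censoring estimate fixed.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    r = np.asarray(risk, dtype=float)
    n = len(t)
    g_left = _censoring_survival_left(t, d)
    g_ti = g_left(t)

    usable = (d == 1) & (t < tau) & (g_ti > 0)
    # pairwise comparisons, vectorized (row i: candidate earlier failure)
    earlier = usable[:, None] & (t[:, None] < t[None, :])
    w = np.where(usable, 1.0 / g_ti**2, 0.0)[:, None] * earlier
    conc = (r[:, None] > r[None, :]) * 1.0 + (r[:, None] == r[None, :]) * 0.5

    num_rows = (w * conc).sum(axis=1)
    den_rows = w.sum(axis=1)
    num, den = num_rows.sum(), den_rows.sum()
    n_pairs = int(earlier.sum())
    if den == 0:
        raise ValueError("no comparable pairs before tau")
    c = num / den

    se = float("nan")
    lo = hi = float("nan")
    if jackknife_se:
        num_cols = (w * conc).sum(axis=0)
        den_cols = w.sum(axis=0)
        num_l = num - num_rows - num_cols
        den_l = den - den_rows - den_cols
        valid = den_l > 0
        c_l = np.where(valid, num_l / np.where(valid, den_l, 1.0), c)
        m = len(c_l)
        se = float(np.sqrt((m - 1) / m * np.sum((c_l - c_l.mean()) ** 2)))
        z = stats.norm.isf(alpha / 2)
        lo, hi = float(c - z * se), float(c + z * se)
    return UnoCResult(float(c), se, lo, hi, n_pairs)


def _km_risk_and_var(time, event, tau):
    """KM event risk at tau and its Greenwood variance."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    s_tau = float(kmf.predict(tau))
    table = kmf.event_table
    upto = table[(table.index > 0) & (table.index <= tau)]
    at_risk = upto["at_risk"].to_numpy(dtype=float)
    deaths = upto["observed"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > deaths, deaths / (at_risk * (at_risk - deaths)), np.inf)
    var = s_tau**2 * float(np.sum(terms))
    n_events = int(deaths.sum())
    return 1.0 - s_tau, var, n_events


def gnd_test(time, event, risk, tau: float = DEFAULT_LANDMARK,
             n_groups: int = 10) -> GNDResult:
    """Greenwood-D'Agostino-Nam calibration test at a landmark time.

    Subjects are grouped by predicted-risk quantiles (ties assigned to the
    lower group); per group the Kaplan-Meier observed risk at ``tau`` is
    compared to the mean predicted risk, with the variance of the observed
    risk from Greenwood's formula.  Groups with no events by ``tau`` (or a
    degenerate variance) are merged with their upper neighbour; the
    statistic is chi-square with (groups - 1) degrees of freedom.
    """
    if n_groups < 2:
        raise ValueError("need at least two risk groups (df = groups - 1)")
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    r = np.asarray(risk, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("predicted risks must lie in [0, 1]")

    edges = np.quantile(r, np.arange(1, n_groups) / n_groups)
    group = np.searchsorted(edges, r, side="left")

    # merge event-free / degenerate groups upward (last group merges down)
    labels = sorted(set(group))
    merged = {g: g for g in labels}
    stats_by_group: dict[int, tuple] = {}

    def group_stats(members):
        obs, var, n_ev = _km_risk_and_var(t[members], d[members], tau)
        return obs, var, n_ev

    i = 0
    while i < len(labels):
        g = labels[i]
        members = np.isin(group, [k for k, v in merged.items() if v == g])
        obs, var, n_ev = group_stats(members)
        if (n_ev == 0 or var <= 0 or not np.isfinite(var)) and len(labels) > 1:
            target = labels[i + 1] if i + 1 < len(labels) else labels[i - 1]
            logger.info("GND: merging risk group %d into %d (no usable events)", g, target)
            for k in list(merged):
                if merged[k] == g:
                    merged[k] = target
            labels.pop(i)
            if target < g:   # merged downward into an already-processed group
                i = labels.index(target)
                stats_by_group.pop(target, None)
            continue
        stats_by_group[g] = (members, obs, var, n_ev)
        i += 1

    rows = []
    statistic = 0.0
    for g in labels:
        members, obs, var, n_ev = stats_by_group[g]
        pred = float(r[members].mean())
        contrib = (obs - pred) ** 2 / var
        statistic += contrib
        expected = float(r[members].mean() * members.sum())
        if expected < 5:
            warnings.warn(
                f"GND group {g} has fewer than 5 expected events ({expected:.1f})",
                stacklevel=2,
            )
        rows.append({"group": g, "n": int(members.sum()), "events": n_ev,
                     "observed_km": obs, "predicted_mean": pred,
                     "variance": var, "contribution": contrib})
    df = len(labels) - 1
    if df < 1:
        raise ValueError("fewer than two usable risk groups after merging")
    p = float(stats.chi2.sf(statistic, df))
    return GNDResult(float(statistic), p, df, pd.DataFrame(rows))
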