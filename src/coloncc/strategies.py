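"""Cohort construction and treatment-allocation strategy evaluation.

The evaluation cohort is built by independent combination of marginal
prevalences (age from a truncated normal, lymph-node category, pT stage,
sidedness) with the external biomarker distribution -- independence of
biomarker status from clinical/pathological factors is an explicit
modeling assumption.  A strategy maps each subgroup to a treated
fraction; treated arms multiply the recurrence hazard by the regimen
hazard ratio (default FOLFOX vs no adjuvant treatment).

Named strategies:

* ``A_full_nvmo``  -- 100% adherence to the 2018 NVMO guideline: all
  pT4, microsatellite-stable patients treated;
* ``B_observed``   -- observed adherence: 21% of pT4 & MSS patients and
  4% of everyone else treated;
* ``C_biomarker``  -- biomarker-driven: all MSS patients with a BRAF or
  KRAS mutation treated, regardless of pT stage;
* ``D_none``       -- no adjuvant chemotherapy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .engine import CohortTrace, run_cohort, summarize
from .parameters import (
    AGE_BAND_LABELS,
    BIOMARKER_LEVELS,
    ConfigurationError,
    EffectRegistry,
    SubgroupProfile,
    TransitionSet,
    all_subgroups,
    default_effects,
)

__all__ = [
    "DEFAULT_MARGINALS",
    "CohortComposition",
    "Strategy",
    "STRATEGY_NAMES",
    "build_cohort_weights",
    "allocate",
    "named_strategy",
    "effective_rec_hazard_multiplier",
    "evaluate_strategy",
    "StrategyOutcome",
]

#: Default marginal prevalences (registry cohort counts, unknowns excluded)
#: and the external biomarker cohort fractions.
DEFAULT_MARGINALS = {
    "pt4_prev": 214 / 2221,
    "ge10_nodes_prev": 946 / 2144,
    "left_prev": 987 / 2238,
    "age_mean": 70.7,
    "age_sd": 10.9,
    "biomarker_prev": (28 / 103, 39 / 103, 36 / 103),
}


@dataclass
class CohortComposition:
    """Weights over the 216 subgroup cells (non-negative, summing to 1)."""

    weights: dict[SubgroupProfile, float]

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if np.any(w < 0):
            raise ConfigurationError("composition weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"composition weights sum to {w.sum()!r}, expected 1")

    def mixture(self, other: "CohortComposition", alpha: float) -> "CohortComposition":
        """``alpha`` of ``self`` mixed with ``1 - alpha`` of ``other``."""
        cells = set(self.weights) | set(other.weights)
        return CohortComposition({
            c: alpha * self.weights.get(c, 0.0) + (1 - alpha) * other.weights.get(c, 0.0)
            for c in cells
        })


def build_cohort_weights(
    pt4_prev: float = DEFAULT_MARGINALS["pt4_prev"],
    ge10_nodes_prev: float = DEFAULT_MARGINALS["ge10_nodes_prev"],
    left_prev: float = DEFAULT_MARGINALS["left_prev"],
    age_mean: float = DEFAULT_MARGINALS["age_mean"],
    age_sd: float = DEFAULT_MARGINALS["age_sd"],
    biomarker_prev=DEFAULT_MARGINALS["biomarker_prev"],
) -> CohortComposition:
    """Independent-marginals cohort weights over the 216 cells.

    Age-band weights are the masses of a Normal(``age_mean``, ``age_sd``)
    truncated to [50, 95) in each 5-year band, renormalized; the remaining
    marginals multiply independently.
    """
    for name, p in (("pt4_prev", pt4_prev), ("ge10_nodes_prev", ge10_nodes_prev),
                    ("left_prev", left_prev)):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
    bm = np.asarray(biomarker_prev, dtype=float)
    if bm.shape != (3,) or np.any(bm < 0) or abs(bm.sum() - 1.0) > 1e-9:
        raise ConfigurationError("biomarker_prev must be 3 non-negative fractions summing to 1")
    if age_sd <= 0:
        raise ConfigurationError("age_sd must be positive")

    edges = 50.0 + 5.0 * np.arange(10)
    cdf = stats.norm(loc=age_mean, scale=age_sd).cdf(edges)
    age_w = np.diff(cdf)
    age_w = age_w / age_w.sum()

    marg = {
        "lymph_nodes": {"lt10": 1 - ge10_nodes_prev, "ge10": ge10_nodes_prev},
        "pt_stage": {"pT3": 1 - pt4_prev, "pT4": pt4_prev},
        "sidedness": {"right": 1 - left_prev, "left": left_prev},
        "biomarker": dict(zip(BIOMARKER_LEVELS, bm)),
    }
    weights = {
        sg: (age_w[sg.age_band] * marg["lymph_nodes"][sg.lymph_nodes]
             * marg["pt_stage"][sg.pt_stage] * marg["sidedness"][sg.sidedness]
             * marg["biomarker"][sg.biomarker])
        for sg in all_subgroups()
    }
    return CohortComposition(weights)


@dataclass
class Strategy:
    """A treatment-allocation rule plus regimen hazard ratio."""

    name: str
    treated_fraction: Callable[[SubgroupProfile], float]
    regimen_hr: float = field(default_factory=lambda: default_effects().hr_folfox_vs_none)

    def fraction(self, subgroup: SubgroupProfile) -> float:
        f = float(self.treated_fraction(subgroup))
        if not 0.0 <= f <= 1.0:
            raise ConfigurationError(f"treated fraction {f} outside [0, 1]")
        return f


STRATEGY_NAMES = ("A_full_nvmo", "B_observed", "C_biomarker", "D_none")
_ALIASES = {"A": "A_full_nvmo", "B": "B_observed", "C": "C_biomarker", "D": "D_none"}


def _is_mss(subgroup: SubgroupProfile) -> bool:
    # "MSS" in the guideline rules spans both MSS biomarker classes.
    return subgroup.biomarker in ("MSSdwt", "MSSmut")


def allocate(strategy_name: str, subgroup: SubgroupProfile) -> float:
    """Treated fraction for a named strategy and subgroup."""
    name = _ALIASES.get(strategy_name, strategy_name)
    if name == "A_full_nvmo":
        return 1.0 if (subgroup.pt_stage == "pT4" and _is_mss(subgroup)) else 0.0
    if name == "B_observed":
        return 0.21 if (subgroup.pt_stage == "pT4" and _is_mss(subgroup)) else 0.04
    if name == "C_biomarker":
        return 1.0 if subgroup.biomarker == "MSSmut" else 0.0
    if name == "D_none":
        return 0.0
    raise ConfigurationError(
        f"unknown strategy {strategy_name!r}; valid names: {STRATEGY_NAMES}"
    )


def named_strategy(strategy_name: str, regimen_hr: float | None = None) -> Strategy:
    name = _ALIASES.get(strategy_name, strategy_name)
    if name not in STRATEGY_NAMES:
        raise ConfigurationError(
            f"unknown strategy {strategy_name!r}; valid names: {STRATEGY_NAMES}"
        )
    kwargs = {} if regimen_hr is None else {"regimen_hr": regimen_hr}
    return Strategy(name, lambda sg, _n=name: allocate(_n, sg), **kwargs)


def effective_rec_hazard_multiplier(
    subgroup: SubgroupProfile,
    treated: bool,
    effects: EffectRegistry,
    regimen_hr: float,
) -> float:
    """Total multiplier on the covariate-adjusted recurrence hazard."""
    return effects.hr_biomarker[subgroup.biomarker] * (regimen_hr if treated else 1.0)


@dataclass
class StrategyOutcome:
    """Population-level results of one strategy evaluation."""

    strategy: str
    fraction_treated: float
    summary: pd.DataFrame           # per-1,000 outcomes at the requested months
    curves: pd.DataFrame            # per-cycle aggregated state masses
    trace: CohortTrace              # aggregated population trace


def evaluate_strategy(
    strategy: Strategy | str,
    composition: CohortComposition | None = None,
    transitions: TransitionSet | None = None,
    effects: EffectRegistry | None = None,
    at_months=(12, 24, 36, 48, 60),
    horizon: int | None = None,
    **run_kwargs,
) -> StrategyOutcome:
    """Weighted evaluation over all 216 cells, split into treated and
    untreated arms by the strategy's allocated fractions.

    Outcomes are linear in the composition weights, so the aggregated
    trace is the weight-and-fraction mixture of per-arm cohort runs.
    """
    from .parameters import load_default_parameters

    if isinstance(strategy, str):
        strategy = named_strategy(strategy)
    if composition is None:
        composition = build_cohort_weights()
    if transitions is None:
        transitions = load_default_parameters("updated_2015")
    effects = effects if effects is not None else default_effects()
    at_months = sorted(at_months)
    if horizon is None:
        horizon = max(at_months)

    n = horizon + 1
    agg = CohortTrace(*(np.zeros(n) for _ in range(6)))
    frac_treated = 0.0
    for sg, w in composition.weights.items():
        if w == 0.0:
            continue
        f = strategy.fraction(sg)
        frac_treated += w * f
        for arm_w, treated in ((w * (1 - f), False), (w * f, True)):
            if arm_w == 0.0:
                continue
            tr = run_cohort(sg, treated, transitions, effects, horizon=horizon,
                            regimen_hr=strategy.regimen_hr, **run_kwargs)
            agg.alive_no_rec += arm_w * tr.alive_no_rec
            agg.rec_occupancy += arm_w * tr.rec_occupancy
            agg.dead_90dm += arm_w * tr.dead_90dm
            agg.dead_doc += arm_w * tr.dead_doc
            agg.dead_dcc += arm_w * tr.dead_dcc
            agg.cum_recurrence += arm_w * tr.cum_recurrence

    summary = summarize(agg, at_months)
    summary.insert(0, "strategy", strategy.name)
    curves = pd.DataFrame({
        "cycle": np.arange(n),
        "alive_no_rec": agg.alive_no_rec,
        "recurrence": agg.rec_occupancy,
        "dead_90dm": agg.dead_90dm,
        "dead_doc": agg.dead_doc,
        "dead_dcc": agg.dead_dcc,
        "cum_recurrence": agg.cum_recurrence,
        "recurrence_free_survival": agg.alive_no_rec,
        "overall_survival": agg.overall_survival(),
    })
    return StrategyOutcome(strategy.name, frac_treated, summary, curves, agg)
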