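"""Patient-level synthetic data generator.

Emulates the statistical structure the fitting and validation modules
assume: covariate-dependent Gompertz recurrence and other-cause death
times, a constant 90-day surgical-mortality hazard over the first three
months, log-logistic post-recurrence survival split into other-cause and
colon-cancer deaths, and right censoring (administrative plus uniform
dropout).  The registry cohorts behind the packaged estimates are not
public; this generator stands in for them as a fixture source and as the
Monte-Carlo oracle for the cohort engine.

Competing events are generated as independent latent cause-specific
times, which is the patient-level equivalent of the cohort engine's
cause-specific hazards plus CICR allocation.  The 90-day mortality is a
latent exponential on (0, 3] months with hazard ``-log(1 - p90)/3`` so
that its marginal probability is exactly ``p90`` while remaining on the
same cause-specific-hazard footing as the other transitions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    EffectRegistry,
    SubgroupProfile,
    TransitionSet,
    default_effects,
    load_default_parameters,
)
from .strategies import CohortComposition, Strategy, build_cohort_weights
from . import survdist

__all__ = [
    "SimulationConfig",
    "simulate_patient_histories",
    "simulate_patients",
    "records_for_transition",
    "state_occupancy",
    "make_external_validation_set",
]

RECORD_COLUMNS = ["id", "transition", "time_months", "event", "age_band",
                  "lymph_nodes", "pt_stage", "sidedness", "biomarker", "treated"]


@dataclass
class SimulationConfig:
    n: int
    seed: int
    transitions: TransitionSet | None = None
    composition: CohortComposition | None = None
    effects: EffectRegistry | None = None
    strategy: Strategy | None = None            # None: nobody treated
    administrative_censor_months: float | None = 60.0
    dropout_uniform_max: float | None = 120.0   # U(0, max) dropout; None disables

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.transitions is None:
            self.transitions = load_default_parameters("updated_2015")
        if self.composition is None:
            self.composition = build_cohort_weights()
        if self.effects is None:
            self.effects = default_effects()
        for name in ("administrative_censor_months", "dropout_uniform_max"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive (or None)")


def _sample_gompertz(rng, shape, rate, lp):
    u = rng.uniform(size=np.shape(lp))
    return survdist.sample_event_time("gompertz", shape, rate, lp, u)


def simulate_patient_histories(config: SimulationConfig) -> pd.DataFrame:
    """One row per patient with latent times and discretized outcomes.

    Continuous latent times feed the fitting records; the discretized
    month columns (``rec_month``, ``death_month``) use the same monthly
    conventions as the cohort engine (a time in ``(c-1, c]`` belongs to
    cycle ``c``; post-recurrence death months count from the recurrence
    cycle), so empirical state occupancies are directly comparable to a
    cohort trace.
    """
    tr = config.transitions
    eff = config.effects
    rng = np.random.default_rng(config.seed)
    cells = list(config.composition.weights)
    weights = np.array([config.composition.weights[c] for c in cells])

    idx = rng.choice(len(cells), size=config.n, p=weights)
    age = np.array([cells[i].age_band for i in idx])
    frame = pd.DataFrame({
        "id": np.arange(config.n),
        "age_band": [cells[i].age_band_label for i in idx],
        "lymph_nodes": [cells[i].lymph_nodes for i in idx],
        "pt_stage": [cells[i].pt_stage for i in idx],
        "sidedness": [cells[i].sidedness for i in idx],
        "biomarker": [cells[i].biomarker for i in idx],
    })

    if config.strategy is not None:
        frac = np.array([config.strategy.fraction(cells[i]) for i in idx])
        treated = rng.uniform(size=config.n) < frac
        regimen_hr = config.strategy.regimen_hr
    else:
        treated = np.zeros(config.n, dtype=bool)
        regimen_hr = eff.hr_folfox_vs_none
    frame["treated"] = treated

    # latent 90-day mortality: exponential hazard on (0, 3] months
    p90 = np.array(tr.p90dm_by_age)[age]
    lam90 = -np.log1p(-p90) / 3.0
    u = rng.uniform(size=config.n)
    with np.errstate(divide="ignore"):
        t90 = np.where(lam90 > 0, -np.log(u) / np.where(lam90 > 0, lam90, 1.0), np.inf)
    t90 = np.where(t90 <= 3.0, t90, np.inf)

    # latent other-cause death since diagnosis
    lp_doc = np.array([
        tr.diag_doc.linear_predictor({"age_band": cells[i].age_band_label}) for i in idx
    ])
    tdoc = _sample_gompertz(rng, tr.diag_doc.shape, tr.diag_doc.rate_or_scale, lp_doc)

    # latent recurrence (defective Gompertz); biomarker and treatment HRs
    # enter the linear predictor as log multipliers of the hazard
    lp_rec = np.array([tr.diag_rec.linear_predictor(cells[i].levels()) for i in idx])
    hr = np.array([eff.hr_biomarker[cells[i].biomarker] for i in idx])
    hr = hr * np.where(treated, regimen_hr, 1.0)
    trec = _sample_gompertz(rng, tr.diag_rec.shape, tr.diag_rec.rate_or_scale,
                            lp_rec + np.log(hr))

    first = np.minimum(np.minimum(t90, tdoc), trec)
    event_type = np.select(
        [trec == first, tdoc == first, t90 == first],
        ["rec", "doc", "90dm"],
        default="none",
    )

    # post-recurrence all-cause survival and cause split
    m = tr.rec_death
    lp_rd = np.array([
        m.coefficients[f"age_band={cells[i].age_band_label}"] for i in idx
    ])
    u = rng.uniform(size=config.n)
    tau = survdist.sample_event_time("loglogistic", m.shape, m.rate_or_scale, lp_rd, u)
    k = np.ceil(tau)
    scale = m.rate_or_scale * np.exp(lp_rd)
    s_prev = 1.0 / (1.0 + ((k - 1) / scale) ** m.shape)
    s_k = 1.0 / (1.0 + (k / scale) ** m.shape)
    q_all = 1.0 - s_k / s_prev
    q_doc = np.array(tr.rec_doc_by_age)[age]
    p_doc_given_death = np.clip(np.where(q_all > 0, q_doc / np.where(q_all > 0, q_all, 1.0), 0.0), 0.0, 1.0)
    death_cause = np.where(rng.uniform(size=config.n) < p_doc_given_death, "doc", "dcc")

    is_rec = event_type == "rec"
    rec_month = np.where(is_rec, np.ceil(trec), np.nan)
    death_month = np.where(is_rec, rec_month + k, np.nan)

    # right censoring
    cens = np.full(config.n, np.inf)
    if config.administrative_censor_months is not None:
        cens = np.minimum(cens, config.administrative_censor_months)
    if config.dropout_uniform_max is not None:
        cens = np.minimum(cens, rng.uniform(0.0, config.dropout_uniform_max, size=config.n))
    if np.any(cens <= 0.0):
        raise ValueError("degenerate censoring configuration: censoring time <= 0")

    frame["t_90dm"] = t90
    frame["t_doc"] = tdoc
    frame["t_rec"] = trec
    frame["t_first"] = first
    frame["event_type"] = event_type
    frame["tau_rec_death"] = np.where(is_rec, tau, np.nan)
    frame["death_cause"] = np.where(is_rec, death_cause, None)
    frame["rec_month"] = rec_month
    frame["death_month"] = death_month
    frame["censor_time"] = cens
    return frame


def simulate_patients(config: SimulationConfig) -> pd.DataFrame:
    """Long-format right-censored survival records, one row per patient
    per transition outcome (``diag_rec``, ``diag_doc``, and ``rec_death``
    for patients with an observed recurrence).

    Within each transition the competing events act as censoring, matching
    the cause-specific estimation the fitting workflow performs.  Fully
    reproducible given the seed.
    """
    wide = simulate_patient_histories(config)
    covs = ["age_band", "lymph_nodes", "pt_stage", "sidedness", "biomarker", "treated"]
    rows = []

    t_obs = np.minimum(wide["t_first"].to_numpy(), wide["censor_time"].to_numpy())
    for name, latent in (("diag_rec", "t_rec"), ("diag_doc", "t_doc")):
        df = wide[["id", *covs]].copy()
        df.insert(1, "transition", name)
        df.insert(2, "time_months", t_obs)
        df.insert(3, "event", ((wide[latent] == wide["t_first"])
                               & (wide["t_first"] <= wide["censor_time"])).astype(int))
        rows.append(df)

    rec = wide[(wide["event_type"] == "rec")
               & (wide["t_rec"] <= wide["censor_time"])]
    if len(rec):
        fu = (rec["censor_time"] - rec["t_rec"]).to_numpy()
        tau = rec["tau_rec_death"].to_numpy()
        df = rec[["id", *covs]].copy()
        df.insert(1, "transition", "rec_death")
        df.insert(2, "time_months", np.minimum(tau, fu))
        df.insert(3, "event", (tau <= fu).astype(int))
        df["cause"] = np.where(tau <= fu, rec["death_cause"], None)
        rows.append(df)

    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["id", "transition"], kind="stable").reset_index(drop=True)


def records_for_transition(records: pd.DataFrame, transition: str) -> pd.DataFrame:
    """Rows of one transition in the flat fitting schema."""
    sub = records[records["transition"] == transition].drop(columns=["transition"])
    return sub.reset_index(drop=True)


def state_occupancy(histories: pd.DataFrame, months) -> pd.DataFrame:
    """Empirical state fractions at the requested months (uncensored view).

    Uses the discretized outcome columns, so the fractions estimate the
    cohort engine's state occupancies directly.
    """
    n = len(histories)
    t_first = histories["t_first"].to_numpy()
    is_rec = (histories["event_type"] == "rec").to_numpy()
    is_doc = (histories["event_type"] == "doc").to_numpy()
    is_90 = (histories["event_type"] == "90dm").to_numpy()
    rec_month = histories["rec_month"].to_numpy()
    death_month = histories["death_month"].to_numpy()
    cause = histories["death_cause"].to_numpy()

    rows = []
    for mth in months:
        pre_rec = is_rec & (rec_month <= mth)
        post_death = pre_rec & (death_month <= mth)
        rows.append({
            "month": mth,
            "alive_no_rec": np.mean(t_first > mth),
            "recurrence": np.mean(pre_rec & ~post_death),
            "dead_90dm": np.mean(is_90 & (t_first <= mth)),
            "dead_doc": (np.mean(is_doc & (t_first <= mth))
                         + np.mean(post_death & (cause == "doc"))),
            "dead_dcc": np.mean(post_death & (cause == "dcc")),
            "cum_recurrence": np.mean(pre_rec),
        })
    return pd.DataFrame(rows)


def make_external_validation_set(config: SimulationConfig, shift: dict) -> pd.DataFrame:
    """Simulate a cohort under multiplicatively shifted coefficients.

    ``shift`` maps coefficient keys to positive multipliers; keys may be
    ``"<transition>:<covariate>=<level>"`` or a bare coefficient key,
    which is applied to the recurrence transition.  An empty map gives a
    cohort distributionally identical to :func:`simulate_patients`.
    """
    transitions = copy.deepcopy(config.transitions)
    for key, mult in shift.items():
        if mult <= 0:
            raise ValueError(f"shift multiplier for {key!r} must be positive")
        trans_name, _, coef = key.rpartition(":")
        trans_name = trans_name or "diag_rec"
        model = getattr(transitions, trans_name)
        if coef not in model.coefficients:
            raise KeyError(f"no coefficient {coef!r} in transition {trans_name!r}")
        model.coefficients[coef] *= mult
    shifted = copy.copy(config)
    shifted.transitions = transitions
    return simulate_patients(shifted)
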