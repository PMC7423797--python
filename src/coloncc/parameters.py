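"""Transition-parameter registry for the stage II colon cancer cohort model.

The model distinguishes five parameterized transitions out of the two
transient clinical states (post-resection "diagnosis" and "recurrence"):

* ``DIAG-90DM``   -- death within 90 days of resection, a time-constant
  probability per 5-year age band, active in cycles 1-3 only;
* ``DIAG-DOC``    -- death from other causes, Gompertz hazard with
  age-band log-hazard-ratio coefficients;
* ``DIAG-REC``    -- recurrence, Gompertz hazard with lymph-node, pT-stage
  and sidedness coefficients (and, at run time, biomarker and treatment
  hazard ratios);
* ``REC-DEATH``   -- all-cause death after recurrence, log-logistic
  accelerated-failure-time model with age-band log-time offsets;
* ``REC-DOC``     -- the other-cause share of post-recurrence death, a
  monthly probability per age band; the colon-cancer share (REC-DCC) is
  the remainder.

This module houses the packaged default estimates for all of these, the
216-cell subgroup space (9 age bands x 2 lymph-node x 2 pT x 2 sidedness
x 3 biomarker levels), the hazard-ratio registry for biomarker and
treatment effects, and a schema-validated YAML registry format.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "AGE_BAND_LABELS",
    "LYMPH_LEVELS",
    "PT_LEVELS",
    "SIDEDNESS_LEVELS",
    "BIOMARKER_LEVELS",
    "MODEL_VERSIONS",
    "COVARIATE_LEVELS",
    "ConfigurationError",
    "SubgroupProfile",
    "ParametricSurvivalModel",
    "TransitionSet",
    "EffectRegistry",
    "clinical_subgroups",
    "all_subgroups",
    "default_effects",
    "load_default_parameters",
    "load_registry",
    "save_registry",
    "p90dm_to_monthly",
    "calibrate_doc_baseline_rate",
    "DOC_BASELINE_RATE",
]

# The model covers ages 50-95; the youngest published band ("<=54") is
# realized as 50-54 because patients younger than 50 are outside the
# modeled population.
AGE_BAND_LABELS: tuple[str, ...] = (
    "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85-89", "90-95",
)
LYMPH_LEVELS: tuple[str, ...] = ("lt10", "ge10")
PT_LEVELS: tuple[str, ...] = ("pT3", "pT4")
SIDEDNESS_LEVELS: tuple[str, ...] = ("right", "left")
BIOMARKER_LEVELS: tuple[str, ...] = ("MSI", "MSSdwt", "MSSmut")
MODEL_VERSIONS: tuple[str, ...] = ("original_2002_2008", "updated_2015")

#: Canonical level order per covariate (first level = reference in fits).
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "age_band": AGE_BAND_LABELS,
    "lymph_nodes": LYMPH_LEVELS,
    "pt_stage": PT_LEVELS,
    "sidedness": SIDEDNESS_LEVELS,
    "biomarker": BIOMARKER_LEVELS,
}


class ConfigurationError(ValueError):
    """Raised for invalid registry files, version tokens or option values."""


@dataclass(frozen=True)
class SubgroupProfile:
    """One cell of the 216-cell subgroup space.

    ``age_band`` is the band index 0-8 (see :data:`AGE_BAND_LABELS`).
    """

    age_band: int
    lymph_nodes: str
    pt_stage: str
    sidedness: str
    biomarker: str

    def __post_init__(self) -> None:
        if not 0 <= self.age_band <= 8:
            raise ConfigurationError(f"age_band index out of range: {self.age_band}")
        for name, levels in (
            ("lymph_nodes", LYMPH_LEVELS),
            ("pt_stage", PT_LEVELS),
            ("sidedness", SIDEDNESS_LEVELS),
            ("biomarker", BIOMARKER_LEVELS),
        ):
            if getattr(self, name) not in levels:
                raise ConfigurationError(
                    f"invalid {name} level {getattr(self, name)!r}; expected one of {levels}"
                )

    @property
    def age_band_label(self) -> str:
        return AGE_BAND_LABELS[self.age_band]

    def levels(self) -> dict[str, str]:
        """Covariate name -> level mapping (age band by label)."""
        return {
            "age_band": self.age_band_label,
            "lymph_nodes": self.lymph_nodes,
            "pt_stage": self.pt_stage,
            "sidedness": self.sidedness,
            "biomarker": self.biomarker,
        }


def clinical_subgroups() -> Iterator[tuple[int, str, str, str]]:
    """The 72 clinical subgroups (age band x lymph nodes x pT x sidedness)."""
    for a in range(9):
        for ln in LYMPH_LEVELS:
            for pt in PT_LEVELS:
                for sd in SIDEDNESS_LEVELS:
                    yield a, ln, pt, sd


def all_subgroups() -> Iterator[SubgroupProfile]:
    """All 216 cells (72 clinical subgroups x 3 biomarker classes)."""
    for a, ln, pt, sd in clinical_subgroups():
        for bm in BIOMARKER_LEVELS:
            yield SubgroupProfile(a, ln, pt, sd, bm)


@dataclass
class ParametricSurvivalModel:
    """A parametric survival model for one transition.

    ``family`` is one of ``gompertz``, ``weibull``, ``lognormal``,
    ``loglogistic``.  For the Gompertz family, ``shape`` is the per-month
    log-hazard slope, ``rate_or_scale`` the baseline hazard per month, and
    coefficients are log hazard ratios acting multiplicatively on the rate
    (proportional hazards).  For the accelerated-failure-time families
    (Weibull, log-normal, log-logistic), ``rate_or_scale`` is the scale in
    months and coefficients are log time ratios acting multiplicatively on
    the scale.  Coefficient keys are ``"<covariate>=<level>"``, e.g.
    ``"pt_stage=pT4"``.
    """

    family: str
    shape: float
    rate_or_scale: float
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("gompertz", "weibull", "lognormal", "loglogistic"):
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        if self.rate_or_scale <= 0:
            raise ConfigurationError("rate/scale must be positive")
        if self.family != "gompertz" and self.shape <= 0:
            raise ConfigurationError(f"{self.family} shape must be positive")

    def linear_predictor(self, levels: Mapping[str, str]) -> float:
        """Sum of coefficients matching the given covariate levels.

        Reference levels simply have no matching key and contribute 0.
        """
        lp = 0.0
        for cov, level in levels.items():
            lp += self.coefficients.get(f"{cov}={level}", 0.0)
        return lp


@dataclass
class TransitionSet:
    """The five parameterized transitions of the model."""

    p90dm_by_age: tuple[float, ...]
    diag_doc: ParametricSurvivalModel
    diag_rec: ParametricSurvivalModel
    rec_death: ParametricSurvivalModel
    rec_doc_by_age: tuple[float, ...]
    model_version: str = "original_2002_2008"

    def __post_init__(self) -> None:
        self.p90dm_by_age = tuple(float(p) for p in self.p90dm_by_age)
        self.rec_doc_by_age = tuple(float(p) for p in self.rec_doc_by_age)
        for name, probs in (("p90dm_by_age", self.p90dm_by_age),
                            ("rec_doc_by_age", self.rec_doc_by_age)):
            if len(probs) != 9:
                raise ConfigurationError(f"{name} must have 9 entries, got {len(probs)}")
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ConfigurationError(f"{name} entries must lie in [0, 1]")
        if self.model_version not in MODEL_VERSIONS:
            raise ConfigurationError(
                f"unknown model version {self.model_version!r}; expected one of {MODEL_VERSIONS}"
            )


@dataclass
class EffectRegistry:
    """Hazard ratios applied on top of the DIAG-REC transition.

    Biomarker hazard ratios act multiplicatively on the covariate-adjusted
    Gompertz recurrence hazard; the treatment hazard ratio for the chosen
    regimen multiplies it further in treated arms.  The FOLFOX-vs-none
    ratio is the product of the two trial-derived ratios.
    """

    hr_biomarker: dict[str, float] = field(
        default_factory=lambda: {"MSI": 0.247, "MSSdwt": 0.880, "MSSmut": 1.528}
    )
    hr_fluoropyrimidine_vs_none: float = 0.78
    hr_folfox_vs_fluoropyrimidine: float = 0.94
    pt4_update_factor: float = 1.36

    def __post_init__(self) -> None:
        if set(self.hr_biomarker) != set(BIOMARKER_LEVELS):
            raise ConfigurationError("hr_biomarker must have exactly the three biomarker classes")
        hrs = [*self.hr_biomarker.values(), self.hr_fluoropyrimidine_vs_none,
               self.hr_folfox_vs_fluoropyrimidine, self.pt4_update_factor]
        if any(h <= 0 for h in hrs):
            raise ConfigurationError("all hazard ratios must be positive")

    @property
    def hr_folfox_vs_none(self) -> float:
        return self.hr_fluoropyrimidine_vs_none * self.hr_folfox_vs_fluoropyrimidine


def default_effects() -> EffectRegistry:
    return EffectRegistry()


# Log hazard ratios underlying the printed biomarker/treatment HRs
# (exp of these reproduces 0.247, 0.880, 1.528, 0.779, 0.939 at 3 decimals).
LOG_HR_MSI = -1.398
LOG_HR_MSSDWT = -0.128
LOG_HR_MSSMUT = 0.424
LOG_HR_FLUOROPYRIMIDINE = -0.250
LOG_HR_FOLFOX_VS_FLUORO = -0.063

#: Calibrated DIAG-DOC baseline hazard per month (the published table rounds
#: it to 0.000 with CI (0.000; 0.001)); see :func:`calibrate_doc_baseline_rate`.
DOC_BASELINE_RATE = 2.2883875817988135e-04


def p90dm_to_monthly(p90: float) -> float:
    """Convert a total 90-day death probability to its constant monthly value.

    Returns the ``q`` with ``1 - (1 - q)**3 == p90`` so that three compounded
    monthly probabilities reproduce the 90-day total; applied in cycles 1-3
    only and 0 thereafter.
    """
    if not 0.0 <= p90 < 1.0:
        raise ValueError(f"p90 must lie in [0, 1), got {p90}")
    return 1.0 - (1.0 - p90) ** (1.0 / 3.0)


def calibrate_doc_baseline_rate(
    rec_doc_by_age,
    diag_doc_age_coefficients,
    bounds: tuple[float, float] = (0.0, 0.001),
) -> float:
    """Least-squares baseline rate matching ``r * exp(beta_age)`` to the
    published monthly REC-DOC probabilities.

    The published DIAG-DOC baseline rate rounds to 0.000, but the REC-DOC
    probability column is, by the model's own assumption, the same
    other-cause hazard evaluated per age band; solving the 1-D least-squares
    problem recovers a usable rate.  The closed-form optimum is
    ``sum(q * exp(b)) / sum(exp(2b))``; a result outside ``bounds`` is
    clamped (with a warning via the return path of the caller).
    """
    q = np.asarray(rec_doc_by_age, dtype=float)
    b = np.asarray(diag_doc_age_coefficients, dtype=float)
    if q.shape != b.shape:
        raise ValueError("probability and coefficient columns must have equal length")
    eb = np.exp(b)
    denom = float(np.sum(eb**2))
    if denom == 0.0:
        raise ValueError("degenerate coefficient column")
    r = float(np.sum(q * eb) / denom)
    lo, hi = bounds
    if not lo < r <= hi:
        import warnings

        warnings.warn(
            f"calibrated DOC baseline rate {r:.3e} outside ({lo}, {hi}]; clamping",
            stacklevel=2,
        )
        r = min(max(r, lo if lo > 0 else np.finfo(float).tiny), hi)
    return r


# ---------------------------------------------------------------------------
# Packaged defaults and registry I/O
# ---------------------------------------------------------------------------

_AGE_KEY = "age_band"


def _age_map(values) -> dict[str, float]:
    return {label: float(v) for label, v in zip(AGE_BAND_LABELS, values)}


def _model_to_dict(m: ParametricSurvivalModel) -> dict:
    return {
        "family": m.family,
        "shape": float(m.shape),
        "rate_or_scale": float(m.rate_or_scale),
        "coefficients": {k: float(v) for k, v in m.coefficients.items()},
    }


_MODEL_KEYS = {"family", "shape", "rate_or_scale", "coefficients"}
_REGISTRY_KEYS = {"model_version", "p90dm_by_age", "diag_doc", "diag_rec",
                  "rec_death", "rec_doc_by_age"}


def _model_from_dict(d: dict, where: str) -> ParametricSurvivalModel:
    if not isinstance(d, dict):
        raise ConfigurationError(f"{where}: expected a mapping")
    unknown = set(d) - _MODEL_KEYS
    if unknown:
        raise ConfigurationError(f"{where}: unknown keys {sorted(unknown)}")
    missing = _MODEL_KEYS - set(d)
    if missing:
        raise ConfigurationError(f"{where}: missing keys {sorted(missing)}")
    coefs = d["coefficients"]
    if not isinstance(coefs, dict):
        raise ConfigurationError(f"{where}: coefficients must be a mapping")
    for key, val in coefs.items():
        if "=" not in key:
            raise ConfigurationError(f"{where}: coefficient key {key!r} is not '<covariate>=<level>'")
        cov, level = key.split("=", 1)
        if cov not in COVARIATE_LEVELS or level not in COVARIATE_LEVELS[cov]:
            raise ConfigurationError(f"{where}: unknown covariate level in key {key!r}")
        if not isinstance(val, (int, float)):
            raise ConfigurationError(f"{where}: coefficient {key!r} must be numeric")
    try:
        return ParametricSurvivalModel(
            family=d["family"], shape=float(d["shape"]),
            rate_or_scale=float(d["rate_or_scale"]),
            coefficients={k: float(v) for k, v in coefs.items()},
        )
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{where}: {exc}") from exc


def _age_column(d, where: str) -> tuple[float, ...]:
    if not isinstance(d, dict) or set(d) != set(AGE_BAND_LABELS):
        raise ConfigurationError(f"{where}: must map exactly the nine age-band labels")
    return tuple(float(d[label]) for label in AGE_BAND_LABELS)


def registry_to_dict(transitions: TransitionSet) -> dict:
    return {
        "model_version": transitions.model_version,
        "p90dm_by_age": _age_map(transitions.p90dm_by_age),
        "diag_doc": _model_to_dict(transitions.diag_doc),
        "diag_rec": _model_to_dict(transitions.diag_rec),
        "rec_death": _model_to_dict(transitions.rec_death),
        "rec_doc_by_age": _age_map(transitions.rec_doc_by_age),
    }


def registry_from_dict(data: dict) -> TransitionSet:
    if not isinstance(data, dict):
        raise ConfigurationError("registry must be a mapping")
    unknown = set(data) - _REGISTRY_KEYS
    if unknown:
        raise ConfigurationError(f"registry: unknown keys {sorted(unknown)}")
    missing = _REGISTRY_KEYS - set(data)
    if missing:
        raise ConfigurationError(f"registry: missing keys {sorted(missing)}")
    return TransitionSet(
        p90dm_by_age=_age_column(data["p90dm_by_age"], "p90dm_by_age"),
        diag_doc=_model_from_dict(data["diag_doc"], "diag_doc"),
        diag_rec=_model_from_dict(data["diag_rec"], "diag_rec"),
        rec_death=_model_from_dict(data["rec_death"], "rec_death"),
        rec_doc_by_age=_age_column(data["rec_doc_by_age"], "rec_doc_by_age"),
        model_version=data["model_version"],
    )


def save_registry(transitions: TransitionSet, path) -> None:
    """Write a transition registry as YAML (round-trips bit-exactly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(registry_to_dict(transitions), fh, sort_keys=False)


def load_registry(path) -> TransitionSet:
    """Load and schema-validate a transition registry YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return registry_from_dict(data)


def _default_registry_dict() -> dict:
    text = resources.files("coloncc").joinpath("data/default_registry.yaml").read_text()
    return yaml.safe_load(text)


def load_default_parameters(model_version: str = "original_2002_2008") -> TransitionSet:
    """The packaged default transition registry.

    ``updated_2015`` multiplies the DIAG-REC pT4 log-hazard coefficient by
    the external-validation update factor 1.36 (1.081 -> 1.470, matching the
    re-estimated 1.47); all other parameters are identical.
    """
    if model_version not in MODEL_VERSIONS:
        raise ConfigurationError(
            f"unknown model version {model_version!r}; expected one of {MODEL_VERSIONS}"
        )
    transitions = registry_from_dict(_default_registry_dict())
    if model_version == "updated_2015":
        diag_rec = copy.deepcopy(transitions.diag_rec)
        diag_rec.coefficients["pt_stage=pT4"] *= default_effects().pt4_update_factor
        transitions = replace(transitions, diag_rec=diag_rec, model_version=model_version)
    return transitions
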