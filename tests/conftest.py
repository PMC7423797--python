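import numpy as np
import pytest

from coloncc.parameters import (
    EffectRegistry,
    ParametricSurvivalModel,
    TransitionSet,
    load_default_parameters,
)


@pytest.fixture(scope="session")
def transitions_original():
    return load_default_parameters("original_2002_2008")


@pytest.fixture(scope="session")
def transitions_updated():
    return load_default_parameters("updated_2015")


@pytest.fixture(scope="session")
def effects():
    return EffectRegistry()


@pytest.fixture(scope="session")
def neutral_effects():
    """Biomarker hazard ratios of 1 (isolates the clinical transition models)."""
    return EffectRegistry(hr_biomarker={"MSI": 1.0, "MSSdwt": 1.0, "MSSmut": 1.0})


def make_transitions(
    p90=0.0,
    doc_shape=0.010,
    doc_rate=1e-30,
    rec_shape=-0.016,
    rec_rate=1e-30,
    rec_death_shape=1.17,
    rec_death_scale=1390.0,
    rec_doc=0.0,
):
    """Minimal transition set for targeted engine tests (no covariates)."""
    return TransitionSet(
        p90dm_by_age=(p90,) * 9,
        diag_doc=ParametricSurvivalModel("gompertz", doc_shape, doc_rate),
        diag_rec=ParametricSurvivalModel("gompertz", rec_shape, rec_rate),
        rec_death=ParametricSurvivalModel("loglogistic", rec_death_shape, rec_death_scale),
        rec_doc_by_age=(rec_doc,) * 9,
    )


@pytest.fixture
def single_risk_transitions():
    """Only the recurrence transition is active (Gompertz -0.016, 0.004)."""
    return make_transitions(rec_rate=0.004)


def rng(seed=0):
    return np.random.default_rng(seed)
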