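import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from coloncc import survdist

FAMILY_PARAMS = {
    "gompertz": (0.010, 0.0004),
    "weibull": (1.3, 40.0),
    "lognormal": (0.9, 30.0),
    "loglogistic": (1.17, 44.75),
}


class TestGompertz:
    def test_zero_shape_is_exponential(self):
        t = np.array([0.0, 1.0, 50.0, 360.0])
        assert np.allclose(survdist.gompertz_hazard(t, 0.0, 0.002), 0.002)
        assert np.allclose(survdist.gompertz_cumhaz(t, 0.0, 0.002), 0.002 * t)

    def test_hazard_at_entry_with_pt4_predictor(self):
        h = survdist.gompertz_hazard(0.0, -0.016, 0.004, 1.081)
        assert h == pytest.approx(0.004 * math.exp(1.081), rel=1e-12)
        assert h == pytest.approx(0.01179, abs=5e-5)

    def test_hazard_at_year_one_for_elderly_doc(self):
        h = survdist.gompertz_hazard(12.0, 0.010, 0.0004, 1.701)
        assert h == pytest.approx(0.0004 * math.exp(1.701) * math.exp(0.12), rel=1e-12)
        assert h == pytest.approx(0.00247, abs=5e-5)

    def test_cumhaz_example(self):
        H = survdist.gompertz_cumhaz(60.0, 0.010, 0.0003)
        assert H == pytest.approx(0.03 * math.expm1(0.6), rel=1e-10)

    def test_cumhaz_zero_at_origin_and_continuous_in_shape(self):
        assert survdist.gompertz_cumhaz(0.0, -0.5, 0.1, 2.0) == 0.0
        near = survdist.gompertz_cumhaz(37.0, 1e-12, 0.002, 0.3)
        at = survdist.gompertz_cumhaz(37.0, 0.0, 0.002, 0.3)
        assert near == pytest.approx(at, rel=1e-9)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            survdist.gompertz_hazard(1.0, 0.0, 0.0)


class TestLogLogistic:
    def test_median_and_boundaries(self):
        alpha, lp = 1390.0, -3.439
        med = alpha * math.exp(lp)
        assert survdist.loglogistic_survival(med, 1.17, alpha, lp) == pytest.approx(0.5)
        assert survdist.loglogistic_survival(0.0, 1.17, alpha, lp) == 1.0
        assert med == pytest.approx(44.61, abs=0.05)

    def test_strictly_decreasing(self):
        t = np.linspace(0, 360, 500)
        s = survdist.loglogistic_survival(t, 1.17, 44.75)
        assert np.all(np.diff(s) < 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survdist.loglogistic_survival(-1.0, 1.17, 44.75)


class TestGenericFamilies:
    @pytest.mark.parametrize("family", survdist.FAMILIES)
    @pytest.mark.parametrize("t", [6.0, 60.0, 360.0])
    def test_cumhaz_matches_integrated_hazard(self, family, t):
        shape, scale = FAMILY_PARAMS[family]
        lp = 0.3
        H, _ = integrate.quad(
            lambda u: survdist.hazard(family, u, shape, scale, lp), 0.0, t, limit=200
        )
        assert survdist.cumhaz(family, t, shape, scale, lp) == pytest.approx(H, rel=1e-6)

    def test_aft_families_match_scipy_survival(self):
        t = np.array([1.0, 10.0, 80.0])
        assert np.allclose(
            survdist.survival("loglogistic", t, 1.17, 44.75),
            stats.fisk.sf(t, c=1.17, scale=44.75),
        )
        assert np.allclose(
            survdist.survival("weibull", t, 1.3, 40.0),
            stats.weibull_min.sf(t, c=1.3, scale=40.0),
        )
        assert np.allclose(
            survdist.survival("lognormal", t, 0.9, 30.0),
            stats.lognorm.sf(t, s=0.9, scale=30.0),
        )


class TestMonthlyProbability:
    def test_constant_hazard_is_memoryless(self):
        S = lambda t: math.exp(-0.01 * t)
        for t in (1, 7, 240):
            q = survdist.monthly_event_probability(S, t)
            assert q == pytest.approx(1 - math.exp(-0.01), rel=1e-12)

    def test_tabulated_survival(self):
        vals = {0: 1.0, 1: 0.9, 2: 0.81}
        S = vals.get
        assert survdist.monthly_event_probability(S, 1) == pytest.approx(0.1)
        assert survdist.monthly_event_probability(S, 2) == pytest.approx(0.1)

    def test_first_month_loglogistic(self):
        S = lambda t: float(survdist.loglogistic_survival(t, 1.17, 44.75))
        assert survdist.monthly_event_probability(S, 1) == pytest.approx(0.0117, abs=5e-4)

    def test_absorbing_convention(self):
        S = {0: 1.0, 1: 0.0, 2: 0.0}.get
        assert survdist.monthly_event_probability(S, 2) == 1.0


class TestSampling:
    def test_median_properties(self):
        assert survdist.sample_event_time("loglogistic", 1.17, 44.75, 0.0, 0.5) \
            == pytest.approx(44.75)
        t = survdist.sample_event_time("gompertz", 0.010, 0.0004, 1.701, 0.5)
        assert survdist.survival("gompertz", t, 0.010, 0.0004, 1.701) == pytest.approx(0.5)

    def test_u_near_one_gives_time_near_zero(self):
        for family in survdist.FAMILIES:
            shape, scale = FAMILY_PARAMS[family]
            t_hi = survdist.sample_event_time(family, shape, scale, 0.0, 1 - 1e-12)
            t_mid = survdist.sample_event_time(family, shape, scale, 0.0, 0.5)
            assert 0.0 < t_hi < 0.1 < t_mid

    def test_defective_gompertz_cure_mass(self):
        # limiting event probability 1 - exp(-rate/|shape|) = 1 - e^{-0.25}
        cure = math.exp(-0.004 / 0.016)
        assert survdist.sample_event_time("gompertz", -0.016, 0.004, 0.0, 0.70) == np.inf
        assert np.isfinite(survdist.sample_event_time("gompertz", -0.016, 0.004, 0.0,
                                                      cure + 1e-6))

    def test_invalid_u_rejected(self):
        for u in (0.0, 1.0, -0.2, 2.0):
            with pytest.raises(ValueError):
                survdist.sample_event_time("gompertz", 0.0, 0.01, 0.0, u)

    @pytest.mark.parametrize("family", survdist.FAMILIES)
    def test_empirical_survival_within_dkw_band(self, family):
        shape, scale = FAMILY_PARAMS[family]
        if family == "gompertz":
            shape = 0.02  # proper distribution for the distributional check
        n = 100_000
        rng = np.random.default_rng(12345)
        times = survdist.sample_event_time(family, shape, scale, 0.1, rng.uniform(size=n))
        eps = math.sqrt(math.log(2 / 0.01) / (2 * n))  # DKW at alpha = 0.01
        grid = np.linspace(0.5, 360.0, 100)
        emp = (times[:, None] > grid[None, :]).mean(axis=0)
        assert np.max(np.abs(emp - survdist.survival(family, grid, shape, scale, 0.1))) < eps

    def test_defective_fraction_matches_cure_probability(self):
        rng = np.random.default_rng(99)
        n = 200_000
        times = survdist.sample_event_time("gompertz", -0.016, 0.004, 0.3,
                                           rng.uniform(size=n))
        cure = math.exp(-0.004 * math.exp(0.3) / 0.016)
        frac_inf = np.mean(np.isinf(times))
        assert frac_inf == pytest.approx(cure, abs=3 * math.sqrt(cure * (1 - cure) / n))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    shape=st.floats(-0.05, 0.05),
    rate=st.floats(1e-5, 0.05),
    lp=st.floats(-2.0, 2.0),
    t=st.floats(0.0, 360.0),
)
def test_gompertz_survival_consistency(shape, rate, lp, t):
    """-log S equals the cumulative hazard and S is a valid survival value."""
    s = survdist.survival("gompertz", t, shape, rate, lp)
    assert 0.0 <= s <= 1.0
    H = float(survdist.gompertz_cumhaz(t, shape, rate, lp))
    if s > 1e-280:  # below this, exp underflow makes -log(S) imprecise
        assert -math.log(s) == pytest.approx(H, rel=1e-9, abs=1e-10)
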