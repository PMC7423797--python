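import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coloncc import survdist
from coloncc.fitting import (
    FittingError,
    fit_parametric,
    forward_select,
    select_family,
    wald_test,
)


def simulate_records(family, shape, scale, n, seed, beta=None, censor_frac=0.3,
                     covariate=None):
    """Right-censored records from a single parametric model.

    ``beta`` attaches one binary covariate effect; censoring is uniform on
    (0, T) tuned so roughly ``censor_frac`` of subjects are censored.
    """
    rng = np.random.default_rng(seed)
    lp = np.zeros(n)
    cov = None
    if beta is not None:
        cov = rng.integers(0, 2, size=n)
        lp = beta * cov
    t = survdist.sample_event_time(family, shape, scale, lp, rng.uniform(size=n))
    finite = np.where(np.isfinite(t), t, np.inf)
    horizon = np.nanquantile(np.where(np.isfinite(t), t, np.nan), 0.9)
    c = rng.uniform(0, horizon / max(1 - censor_frac, 0.1), size=n)
    obs = np.minimum(finite, c)
    frame = pd.DataFrame({
        "time_months": np.maximum(obs, 1e-6),
        "event": (finite <= c).astype(int),
    })
    if cov is not None:
        frame[covariate or "x"] = cov
    return frame


class TestWald:
    def test_zero_estimate(self):
        assert wald_test(0.0, 1.0) == pytest.approx(1.0)

    def test_classic_quantiles(self):
        assert wald_test(1.96, 1.0) == pytest.approx(0.05, abs=5e-4)
        # the 0.157 threshold corresponds to |z| ~ sqrt(2) (AIC-equivalent rule)
        assert wald_test(np.sqrt(2), 1.0) == pytest.approx(0.157, abs=1e-3)

    def test_bad_se(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)


class TestFitParametric:
    def test_gompertz_recovery_with_censoring(self):
        df = simulate_records("gompertz", -0.016, 0.004, 2000, seed=5)
        fit = fit_parametric(df, "gompertz")
        assert abs(fit.model.shape - (-0.016)) < 3 * fit.standard_errors["shape"]
        assert abs(fit.model.rate_or_scale - 0.004) < 3 * fit.standard_errors["rate_or_scale"]

    def test_exponential_data_gives_near_zero_gompertz_shape(self):
        df = simulate_records("gompertz", 0.0, 0.01, 2000, seed=6)
        fit = fit_parametric(df, "gompertz")
        assert abs(fit.model.shape) < 3 * fit.standard_errors["shape"]

    def test_loglogistic_shape_recovery(self):
        df = simulate_records("loglogistic", 1.17, 44.75, 2000, seed=7)
        fit = fit_parametric(df, "loglogistic")
        assert abs(fit.model.shape - 1.17) < 3 * fit.standard_errors["shape"]

    def test_covariate_effect_recovery(self):
        df = simulate_records("gompertz", 0.005, 0.01, 3000, seed=8, beta=0.7)
        fit = fit_parametric(df, "gompertz", ["x"])
        assert abs(fit.model.coefficients["x"] - 0.7) < 3 * fit.standard_errors["x"]

    def test_aic_definition(self):
        df = simulate_records("gompertz", 0.0, 0.01, 500, seed=9)
        fit = fit_parametric(df, "gompertz")
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_all_censored_rejected(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
        with pytest.raises(ValueError, match="censored"):
            fit_parametric(df, "gompertz")

    def test_needs_two_distinct_event_times(self):
        df = pd.DataFrame({"time_months": [2.0, 2.0, 5.0], "event": [1, 1, 0]})
        with pytest.raises(ValueError, match="distinct"):
            fit_parametric(df, "weibull")

    def test_missing_covariates_excluded_complete_case(self):
        df = simulate_records("gompertz", 0.0, 0.01, 400, seed=10, beta=0.5)
        df.loc[df.index[:50], "x"] = np.nan
        fit = fit_parametric(df, "gompertz", ["x"])
        assert fit.n_obs == 350

    def test_optimum_beats_truth_loglik(self):
        """Optimizer sanity: fitted likelihood >= likelihood at truth."""
        wins = 0
        for seed in range(10):
            df = simulate_records("gompertz", -0.01, 0.006, 800, seed=100 + seed)
            fit = fit_parametric(df, "gompertz")
            t = df["time_months"].to_numpy()
            d = df["event"].to_numpy()
            ll_true = float(np.sum(d * survdist.log_hazard("gompertz", t, -0.01, 0.006))
                            - np.sum(survdist.cumhaz("gompertz", t, -0.01, 0.006)))
            wins += fit.loglik >= ll_true - 1e-6
        assert wins == 10


class TestFlexsurvOracle:
    def test_gompertz_fit_matches_flexsurv(self, tmp_path):
        """Independent maximum-likelihood oracle: the same small dataset
        fitted with R's flexsurv gives the same shape and rate."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = simulate_records("gompertz", 0.02, 0.01, 300, seed=21)
        csv = tmp_path / "records.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(flexsurv))
            d <- read.csv("{csv}")
            f <- flexsurvreg(Surv(time_months, event) ~ 1, data = d, dist = "gompertz")
            cat(sprintf("%.10f %.10f\\n", f$res["shape","est"], f$res["rate","est"]))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             check=True)
        r_shape, r_rate = map(float, out.stdout.split())
        fit = fit_parametric(df, "gompertz")
        assert fit.model.shape == pytest.approx(r_shape, abs=1e-4)
        assert fit.model.rate_or_scale == pytest.approx(r_rate, rel=1e-3)


class TestSelectFamily:
    @pytest.mark.parametrize("truth", ["gompertz", "loglogistic"])
    def test_selection_consistency(self, truth):
        params = {"gompertz": (0.02, 0.01), "loglogistic": (1.17, 44.75)}
        shape, scale = params[truth]
        hits = 0
        for seed in range(3):
            df = simulate_records(truth, shape, scale, 2000, seed=300 + seed)
            sel = select_family(df)
            hits += sel.best_family == truth
        assert hits == 3

    def test_failed_family_excluded_with_warning(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0, 3.0, 4.0] * 5,
                           "event": [1, 1, 0, 0] * 5})
        sel = select_family(df, families=["gompertz", "weibull"])
        assert sel.best_family in ("gompertz", "weibull")

    def test_needs_two_families(self):
        df = simulate_records("gompertz", 0.0, 0.01, 100, seed=1)
        with pytest.raises(ValueError):
            select_family(df, families=["gompertz"])


class TestForwardSelect:
    def test_strong_effect_is_included(self):
        df = simulate_records("gompertz", 0.0, 0.01, 2000, seed=31,
                              beta=np.log(3.0), covariate="x")
        res = forward_select(df, "gompertz", ["x"])
        assert res.selected == ["x"]

    def test_empty_candidate_set(self):
        df = simulate_records("gompertz", 0.0, 0.01, 200, seed=32)
        res = forward_select(df, "gompertz", [])
        assert res.selected == []

    def test_inclusion_order_strongest_first(self):
        rng = np.random.default_rng(33)
        n = 3000
        strong = rng.integers(0, 2, n)
        weak = rng.integers(0, 2, n)
        lp = 1.0 * strong + 0.25 * weak
        t = survdist.sample_event_time("gompertz", 0.0, 0.01, lp, rng.uniform(size=n))
        c = rng.uniform(0, 200, n)
        df = pd.DataFrame({"time_months": np.minimum(t, c), "event": (t <= c).astype(int),
                           "strong": strong, "weak": weak})
        res = forward_select(df, "gompertz", ["weak", "strong"])
        assert res.selected[0] == "strong"
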