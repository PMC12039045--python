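import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from rxits import (
    StudyCalendar,
    build_design_matrix,
    coefficient_table,
    fit_itsa,
    fit_poisson_itsa,
    newey_west_covariance,
)
from rxits.model import ConvergenceError, DesignError, SingularDesignError
from rxits.simulate import simulate_count_series

from conftest import glm_truth, truth_beta


def make_series(counts, denominators):
    return pd.DataFrame(
        {
            "month": np.arange(len(counts)),
            "numerator": counts,
            "denominator": denominators,
        }
    )


def poisson_series(calendar, seed=0, **overrides):
    return simulate_count_series(glm_truth(seed=seed, **overrides), calendar)


class TestDesignMatrix:
    def test_first_row_is_baseline(self, covid_calendar):
        s = poisson_series(covid_calendar)
        d = build_design_matrix(covid_calendar, s)
        row = d.X.iloc[0]
        assert row["const"] == 1 and row["time"] == 0
        assert row["step_restriction"] == 0 and row["slope_restriction"] == 0
        assert row["step_recovery"] == 0 and row["slope_recovery"] == 0
        assert row["season_sin1"] == 0 and row["season_cos1"] == 1

    def test_interruption_row_coding(self, covid_calendar):
        s = poisson_series(covid_calendar)
        d = build_design_matrix(covid_calendar, s)
        row = d.X.iloc[covid_calendar.interruption_1]
        assert row["step_restriction"] == 1
        assert row["slope_restriction"] == 1  # slope takes value 1 at onset
        assert row["outlier_2020-03"] == 1 and row["outlier_2020-04"] == 0
        # slope terms then increase by exactly 1 per month
        r1 = d.X["slope_restriction"].to_numpy()
        post = r1[covid_calendar.interruption_1 :]
        assert np.array_equal(np.diff(post), np.ones(len(post) - 1))

    def test_alternative_slope_coding(self, covid_calendar):
        s = poisson_series(covid_calendar)
        d = build_design_matrix(covid_calendar, s, slope_starts_at_one=False)
        assert d.X.iloc[covid_calendar.interruption_1]["slope_restriction"] == 0
        assert d.X.iloc[covid_calendar.interruption_1 + 1]["slope_restriction"] == 1

    def test_full_rank(self, covid_calendar):
        s = poisson_series(covid_calendar)
        d = build_design_matrix(covid_calendar, s)
        assert np.linalg.matrix_rank(d.values()) == d.X.shape[1]

    def test_gap_detected(self, covid_calendar):
        s = poisson_series(covid_calendar).drop(index=30)
        with pytest.raises(DesignError, match="every month"):
            build_design_matrix(covid_calendar, s)

    def test_zero_denominator_detected(self, covid_calendar):
        s = poisson_series(covid_calendar)
        s.loc[10, "denominator"] = 0
        with pytest.raises(DesignError, match="denominator"):
            build_design_matrix(covid_calendar, s)


class TestPoissonFit:
    def test_intercept_only_closed_form(self, covid_calendar):
        """With only an intercept and a log-N offset the MLE is the overall
        rate: b0 = log(sum y / sum N)."""
        s = poisson_series(covid_calendar, seed=4)
        d = build_design_matrix(covid_calendar, s)
        d.X = d.X[["const"]]
        fit = fit_poisson_itsa(d, s["numerator"])
        expected = np.log(s["numerator"].sum() / s["denominator"].sum())
        assert fit.beta["const"] == pytest.approx(expected, abs=1e-10)

    def test_recovers_exact_generating_coefficients(self, covid_calendar):
        """Noise-free counts round(exp(X beta* + offset)) at large N give
        back beta* to better than 1e-3."""
        truth = glm_truth(population_start=5_000_000, population_growth=0)
        s = simulate_count_series(truth, covid_calendar)
        d = build_design_matrix(covid_calendar, s)
        beta_star = truth_beta(truth, d.columns)
        exact = np.round(np.exp(d.values() @ beta_star.to_numpy() + d.offset))
        fit = fit_poisson_itsa(d, exact)
        assert np.max(np.abs(fit.beta.to_numpy() - beta_star.to_numpy())) < 1e-3

    def test_matches_independent_newton_optimiser(self, small_calendar):
        """IRLS agrees to 1e-8 with a generic Newton-type optimiser run on
        the raw Poisson log-likelihood of a 12-month fixture."""
        rng = np.random.default_rng(8)
        den = np.full(12, 5_000)
        counts = rng.poisson(60, size=12)
        s = make_series(counts, den)
        d = build_design_matrix(small_calendar, s)
        fit = fit_poisson_itsa(d, counts)

        X, off, y = d.values(), d.offset, counts.astype(float)

        def negll(b):
            eta = X @ b + off
            return -(y @ eta - np.exp(eta).sum())

        def grad(b):
            return -(X.T @ (y - np.exp(X @ b + off)))

        def hess(b):
            mu = np.exp(X @ b + off)
            return (X * mu[:, None]).T @ X

        b0 = np.zeros(X.shape[1])
        b0[0] = np.log(y.sum() / np.exp(off).sum())
        res = minimize(
            negll,
            b0,
            jac=grad,
            hess=hess,
            method="trust-exact",
            options={"gtol": 1e-9, "maxiter": 500},
        )
        assert np.linalg.norm(grad(res.x), ord=np.inf) < 1e-6
        assert np.max(np.abs(fit.beta.to_numpy() - res.x)) < 1e-8

    def test_score_is_zero_and_likelihood_dominates_truth(self, covid_calendar):
        truth = glm_truth(seed=21)
        s = simulate_count_series(truth, covid_calendar)
        d = build_design_matrix(covid_calendar, s)
        fit = fit_poisson_itsa(d, s["numerator"])
        assert np.max(np.abs(fit.score())) < 1e-8
        beta_star = truth_beta(truth, d.columns).to_numpy()
        mu_star = np.exp(d.values() @ beta_star + d.offset)
        y = s["numerator"].to_numpy()
        ll_star = np.sum(y * np.log(mu_star) - mu_star)
        ll_hat = np.sum(y * np.log(fit.fitted_mu) - fit.fitted_mu)
        assert ll_hat >= ll_star - 1e-8

    def test_offset_equivariance(self, covid_calendar):
        """Adding a constant c to the offset shifts the intercept by -c and
        leaves every other coefficient unchanged."""
        s = poisson_series(covid_calendar, seed=5)
        d = build_design_matrix(covid_calendar, s)
        fit = fit_poisson_itsa(d, s["numerator"])
        d2 = build_design_matrix(covid_calendar, s)
        d2.offset = d.offset + 3.7
        fit2 = fit_poisson_itsa(d2, s["numerator"])
        assert fit2.beta["const"] == pytest.approx(fit.beta["const"] - 3.7, abs=1e-6)
        others = [c for c in d.columns if c != "const"]
        assert np.allclose(
            fit2.beta[others].to_numpy(), fit.beta[others].to_numpy(), atol=1e-6
        )

    def test_rank_deficiency_raises(self, covid_calendar):
        s = poisson_series(covid_calendar)
        d = build_design_matrix(covid_calendar, s)
        d.X["dup"] = d.X["time"]
        with pytest.raises(SingularDesignError):
            fit_poisson_itsa(d, s["numerator"])

    def test_nonconvergence_carries_trace(self, covid_calendar):
        s = poisson_series(covid_calendar)
        d = build_design_matrix(covid_calendar, s)
        with pytest.raises(ConvergenceError) as exc:
            fit_poisson_itsa(d, s["numerator"], max_iter=1)
        assert len(exc.value.trace) == 1


class TestNeweyWest:
    def test_lag_zero_equals_hc0_sandwich(self, covid_calendar):
        s = poisson_series(covid_calendar, seed=6)
        d = build_design_matrix(covid_calendar, s)
        fit = fit_poisson_itsa(d, s["numerator"])
        V0 = newey_west_covariance(fit, lag=0)
        X = d.values()
        u = X * (s["numerator"].to_numpy() - fit.fitted_mu)[:, None]
        bread = np.linalg.inv((X * fit.fitted_mu[:, None]).T @ X)
        hc0 = bread @ (u.T @ u) @ bread
        assert np.allclose(V0, (hc0 + hc0.T) / 2, rtol=1e-12)

    def test_symmetric_positive_semidefinite(self, covid_calendar):
        s = poisson_series(covid_calendar, seed=7)
        fit = fit_itsa(covid_calendar, s, lag=2)
        V = fit.cov_hac
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() >= -1e-10

    def test_lag2_close_to_lag0_for_independent_data(self, covid_calendar):
        """For serially independent Poisson noise the Bartlett terms carry
        no signal, so lag-2 SEs track lag-0 SEs on average. At the MLE the
        score contributions sum exactly to zero, which biases empirical lag
        covariances downward by roughly the regressor count over the series
        length; hence a wider band on the 60-month window (10 regressors)
        and a tight one on a 240-month window."""

        def mean_ratio(calendar, truths):
            se0s, se2s = [], []
            for truth in truths:
                s = simulate_count_series(truth, calendar)
                d = build_design_matrix(calendar, s)
                fit = fit_poisson_itsa(d, s["numerator"])
                se0s.append(np.sqrt(np.diag(newey_west_covariance(fit, lag=0))))
                se2s.append(np.sqrt(np.diag(newey_west_covariance(fit, lag=2))))
            return np.mean(se2s, axis=0) / np.mean(se0s, axis=0)

        ratio = mean_ratio(
            covid_calendar, [glm_truth(seed=100 + s) for s in range(30)]
        )
        assert np.all(np.abs(ratio - 1) < 0.20)

        long_cal = StudyCalendar(
            start_month="2000-01",
            end_month="2019-12",
            restrictions_start="2008-03",
            recovery_start="2012-03",
        )
        from rxits import SimulationTruth

        ratio = mean_ratio(
            long_cal,
            [
                SimulationTruth(
                    baseline_rate=0.003,
                    population_start=200_000,
                    seasonal_amplitude_sin=0.03,
                    seed=s,
                )
                for s in range(30)
            ],
        )
        assert np.all(np.abs(ratio - 1) < 0.10)

    def test_excessive_lag_rejected(self, covid_calendar):
        s = poisson_series(covid_calendar)
        d = build_design_matrix(covid_calendar, s)
        fit = fit_poisson_itsa(d, s["numerator"])
        with pytest.raises(ValueError, match="lag"):
            newey_west_covariance(fit, lag=60)

    def test_agrees_with_statsmodels_hac(self, covid_calendar):
        """Independent route: statsmodels GLM with HAC covariance reproduces
        both the coefficients and the Newey-West SEs."""
        sm = pytest.importorskip("statsmodels.api")
        s = poisson_series(covid_calendar, seed=9)
        d = build_design_matrix(covid_calendar, s)
        fit = fit_poisson_itsa(d, s["numerator"])
        fit.cov_hac = newey_west_covariance(fit, lag=2)
        glm = sm.GLM(
            s["numerator"].to_numpy(),
            d.values(),
            family=sm.families.Poisson(),
            offset=d.offset,
        ).fit(cov_type="HAC", cov_kwds={"maxlags": 2, "use_correction": False})
        assert np.allclose(fit.beta.to_numpy(), glm.params, atol=1e-6)
        assert np.allclose(fit.se().to_numpy(), glm.bse, rtol=1e-4)


class TestCoefficientTable:
    def test_percentage_scale(self, covid_calendar):
        s = poisson_series(covid_calendar, seed=10)
        fit = fit_itsa(covid_calendar, s)
        # force known coefficients to check the reporting transform
        fit.beta["time"] = np.log(1.003)
        fit.beta["step_restriction"] = -0.285
        tab = coefficient_table(fit).set_index("term")
        assert tab.loc["pre-period monthly slope", "estimate_pct"] == pytest.approx(
            0.3, abs=1e-9
        )
        assert tab.loc["restrictions level shift", "estimate_pct"] == pytest.approx(
            (np.exp(-0.285) - 1) * 100, abs=1e-9
        )
        assert tab.loc["restrictions level shift", "estimate_pct"] == pytest.approx(
            -24.8, abs=0.05
        )

    def test_zero_coefficient_zero_interval(self, covid_calendar):
        s = poisson_series(covid_calendar, seed=11)
        fit = fit_itsa(covid_calendar, s)
        fit.beta[:] = 0.0
        fit.cov_hac = np.zeros_like(fit.cov_hac)
        tab = coefficient_table(fit)
        assert (tab[["estimate_pct", "ci_low_pct", "ci_high_pct"]] == 0).all().all()
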