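import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from crsim.cohort_simulator import CRScenario, effective_pm, simulate_cohort
from crsim.exceptions import DomainError, IntegrityError
from crsim.survival_inference import (
    city_relative_risk,
    cox_fit,
    fit_spline,
    null_loglik,
    partial_loglik,
)
from tests.conftest import random_small_instance

# single event time, two cities, x=(0,1), n=(10,10), d=(1,2):
# LL(beta) = 2*beta - 3*log(10 + 10*exp(beta)), maximized at beta = ln 2
WORKED = (np.array([[1], [2]]), np.array([[10], [10]]), np.array([0.0, 1.0]))


def disaggregate(deaths, at_risk, x):
    """Per-individual (time, event, covariate) records for oracle fits."""
    rows = []
    n_years = deaths.shape[1]
    for j in range(deaths.shape[0]):
        for t in range(n_years):
            rows += [(t + 1.0, True, x[j])] * int(deaths[j, t])
        survivors = int(at_risk[j, -1] - deaths[j, -1])
        rows += [(float(n_years), False, x[j])] * survivors
    return rows


class TestPartialLoglik:
    def test_zero_beta_collapses_to_risk_set_counts(self, small_cohort):
        x = np.linspace(0, 3, small_cohort.n_cities)
        d_t = small_cohort.deaths.sum(axis=0)
        expected = -np.sum(d_t * np.log(small_cohort.at_risk.sum(axis=0)))
        assert partial_loglik(0.0, small_cohort, x) == pytest.approx(expected)
        assert null_loglik(small_cohort) == pytest.approx(expected)

    @pytest.mark.parametrize("beta", [-1.0, 0.0, 0.4, 2.0])
    def test_hand_expanded_two_city_instance(self, beta):
        deaths, at_risk, x = WORKED
        expected = 2 * beta - 3 * np.log(10 + 10 * np.exp(beta))
        assert partial_loglik(beta, (deaths, at_risk), x) == pytest.approx(expected)

    def test_covariate_shift_leaves_ll_and_maximizer_unchanged(self):
        # the shift's contribution cancels between the event term and the
        # risk-set term, so the partial likelihood is location-invariant
        rng = np.random.default_rng(3)
        deaths, at_risk, x = random_small_instance(rng)
        beta, c = 0.3, 5.0
        shifted = partial_loglik(beta, (deaths, at_risk), x + c)
        base = partial_loglik(beta, (deaths, at_risk), x)
        assert shifted == pytest.approx(base, rel=1e-10)
        f1 = cox_fit((deaths, at_risk), x)
        f2 = cox_fit((deaths, at_risk), x + c)
        assert f1.beta == pytest.approx(f2.beta, abs=1e-7)

    def test_empty_risk_set_at_event_time_rejected(self):
        deaths = np.array([[5, 1]])
        at_risk = np.array([[5, 0]])
        with pytest.raises(IntegrityError):
            partial_loglik(0.1, (deaths, at_risk), np.array([1.0]))


class TestCoxFit:
    def test_closed_form_worked_instance(self):
        deaths, at_risk, x = WORKED
        fit = cox_fit((deaths, at_risk), x)
        assert fit.converged
        assert fit.beta == pytest.approx(np.log(2), abs=1e-7)

    def test_covariate_rescaling_halves_beta_leaves_ll(self):
        rng = np.random.default_rng(8)
        deaths, at_risk, x = random_small_instance(rng)
        f1 = cox_fit((deaths, at_risk), x)
        f2 = cox_fit((deaths, at_risk), 2 * x)
        assert f2.beta == pytest.approx(f1.beta / 2, abs=1e-7)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-8)

    def test_matches_brute_force_maximization(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            deaths, at_risk, x = random_small_instance(rng)
            fit = cox_fit((deaths, at_risk), x)
            res = optimize.minimize_scalar(
                lambda b: -partial_loglik(b, (deaths, at_risk), x),
                bounds=(-6, 6), method="bounded",
                options={"xatol": 1e-12},
            )
            assert fit.beta == pytest.approx(res.x, abs=1e-6)

    def test_matches_established_breslow_implementation(self):
        sksurv = pytest.importorskip("sksurv.linear_model")
        rng = np.random.default_rng(21)
        for _ in range(20):
            deaths, at_risk, x = random_small_instance(rng)
            rows = disaggregate(deaths, at_risk, x)
            y = np.array([(e, t) for t, e, _ in rows],
                         dtype=[("event", bool), ("time", float)])
            X = np.array([[v] for _, _, v in rows])
            if np.ptp(X) == 0:
                continue
            oracle = sksurv.CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12)
            oracle.fit(X, y)
            fit = cox_fit((deaths, at_risk), x)
            assert fit.beta == pytest.approx(oracle.coef_[0], abs=1e-4)

    def test_efron_variant_agrees_with_efron_oracle(self):
        sksurv = pytest.importorskip("sksurv.linear_model")
        rng = np.random.default_rng(33)
        deaths, at_risk, x = random_small_instance(rng)
        rows = disaggregate(deaths, at_risk, x)
        y = np.array([(e, t) for t, e, _ in rows],
                     dtype=[("event", bool), ("time", float)])
        X = np.array([[v] for _, _, v in rows])
        oracle = sksurv.CoxPHSurvivalAnalysis(ties="efron", tol=1e-12)
        oracle.fit(X, y)
        fit = cox_fit((deaths, at_risk), x, ties="efron")
        assert fit.beta == pytest.approx(oracle.coef_[0], abs=1e-4)

    def test_concavity_hessian_negative_everywhere(self):
        from crsim.survival_inference import _loglik_derivs

        rng = np.random.default_rng(17)
        deaths, at_risk, x = random_small_instance(rng)
        for beta in np.linspace(-3, 3, 13):
            _, _, hess = _loglik_derivs(beta, (deaths, at_risk), x)
            assert hess < 0

    def test_wald_ci_brackets_hazard_ratio(self):
        rng = np.random.default_rng(29)
        deaths, at_risk, x = random_small_instance(rng)
        fit = cox_fit((deaths, at_risk), x)
        assert fit.ci_low <= fit.hr <= fit.ci_high

    def test_constant_covariate_rejected(self, small_cohort):
        with pytest.raises(DomainError):
            cox_fit(small_cohort, np.zeros(small_cohort.n_cities))

    def test_parameter_recovery_without_measurement_error(
        self, small_cities, small_schedule
    ):
        """With the correct hinge and no error, the CI covers ln(h)."""
        scenario = CRScenario(8.5, 1.05, 1.0)
        hits = 0
        for seed in range(10):
            out = simulate_cohort(small_cities, small_schedule, scenario,
                                  persons_per_city=20_000, seed=seed)
            fit = cox_fit(out, effective_pm(small_cities.true_pm, 8.5))
            hits += fit.ci_low <= 1.05 <= fit.ci_high
        assert hits >= 8


class TestCityRelativeRisk:
    def test_identical_rates_give_unit_rr(self, small_cities, small_schedule):
        out = simulate_cohort(small_cities, small_schedule,
                              CRScenario(0.0, 1.0, 1.0), 2000, seed=1)
        deaths = np.full_like(out.deaths, 3)
        from crsim.cohort_simulator import CohortOutcome

        at_risk = np.empty_like(deaths)
        at_risk[:, 0] = 2000
        for t in range(1, deaths.shape[1]):
            at_risk[:, t] = at_risk[:, t - 1] - deaths[:, t - 1]
        flat = CohortOutcome(cities=out.cities, at_risk=at_risk, deaths=deaths,
                             persons_per_city=2000, years=out.years)
        rr = city_relative_risk(flat, small_cities.true_pm)
        np.testing.assert_allclose(rr["rr"], 1.0)

    def test_reference_is_lowest_observed_not_true_exposure(self, small_cohort):
        pm_obs = np.arange(small_cohort.n_cities, dtype=float)[::-1]  # reversed
        rr = city_relative_risk(small_cohort, pm_obs)
        ref_city = rr.loc[rr["observed_pm"].idxmin(), "city"]
        assert ref_city == small_cohort.cities[-1]
        assert rr.loc[rr["observed_pm"].idxmin(), "rr"] == pytest.approx(1.0)

    def test_rate_ratio_definition(self):
        from crsim.cohort_simulator import CohortOutcome

        out = CohortOutcome(
            cities=("a", "b"),
            at_risk=np.array([[100, 90], [100, 80]]),
            deaths=np.array([[10, 0], [20, 0]]),
            persons_per_city=100, years=2,
        )
        rr = city_relative_risk(out, np.array([5.0, 9.0]))
        # rates: 10/190 vs 20/180; reference = city a
        assert rr["rr"].iloc[1] == pytest.approx((20 / 180) / (10 / 190))


class TestFitSpline:
    def make_rr(self, y_fn, n=40):
        x = np.sort(np.random.default_rng(2).uniform(5, 15, n))
        return pd.DataFrame({"observed_pm": x, "rr": y_fn(x)})

    def test_reproduces_straight_line_exactly(self):
        curve = fit_spline(self.make_rr(lambda x: 0.8 + 0.11 * x))
        np.testing.assert_allclose(curve.fitted, 0.8 + 0.11 * curve.grid, atol=1e-9)

    def test_constant_rr_gives_flat_curve(self):
        curve = fit_spline(self.make_rr(lambda x: np.ones_like(x)))
        np.testing.assert_allclose(curve.fitted, 1.0, atol=1e-9)

    def test_basis_has_four_spline_columns(self):
        curve = fit_spline(self.make_rr(lambda x: 1 + 0.01 * x**2))
        assert curve.df == 4
        assert curve.coefficients.size == 5  # intercept + 4 spline columns
        assert curve.knots.size == 5  # boundaries + 25/50/75th percentiles

    def test_natural_linearity_beyond_boundary_knots(self):
        rr = self.make_rr(lambda x: 1 + 0.05 * (x - 10) ** 2)
        lo, hi = rr["observed_pm"].min(), rr["observed_pm"].max()
        grid = np.linspace(lo - 3, hi + 3, 121)
        curve = fit_spline(rr, grid=grid)
        # windows of three consecutive grid points entirely beyond a boundary
        fully_outside = ((grid[:-2] < lo) & (grid[2:] < lo)) | (
            (grid[:-2] > hi) & (grid[2:] > hi)
        )
        assert fully_outside.any()
        second_diff = np.diff(curve.fitted, 2)
        assert np.abs(second_diff[fully_outside]).max() < 1e-8

    def test_too_few_distinct_exposures_rejected(self):
        rr = pd.DataFrame({"observed_pm": [1.0, 2.0, 3.0], "rr": [1, 1, 1]})
        with pytest.raises(DomainError):
            fit_spline(rr)
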