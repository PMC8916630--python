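import numpy as np
import pytest

from crsim.baseline_mortality import gompertz_schedule
from crsim.cohort_simulator import CRScenario, simulate_cohort
from crsim.exposure_model import CityExposureSet


@pytest.fixture
def small_cities() -> CityExposureSet:
    """Eight cities spanning the policy-relevant PM2.5 range."""
    pm = np.array([5.5, 6.8, 7.9, 8.6, 9.4, 10.8, 12.5, 15.0])
    return CityExposureSet(cities=tuple(f"c{i}" for i in range(8)), true_pm=pm)


@pytest.fixture
def small_schedule():
    """Five follow-up years with a realistic rising annual hazard from age 60."""
    return gompertz_schedule(q0=0.011, doubling_time=8.3, start_age=60, n_years=5)


@pytest.fixture
def small_cohort(small_cities, small_schedule):
    """A modest simulated cohort with a strong threshold effect."""
    scenario = CRScenario(threshold=8.5, hazard_ratio=1.05, sigma=1.0)
    return simulate_cohort(
        small_cities, small_schedule, scenario, persons_per_city=3000, seed=42
    )


def random_small_instance(rng: np.random.Generator):
    """A tiny random aggregated survival dataset for oracle comparisons.

    Returns (deaths, at_risk, covariate) with 2-5 cities, 1-3 years, a
    non-constant covariate, and at least one death.
    """
    while True:
        n_cities = int(rng.integers(2, 6))
        n_years = int(rng.integers(1, 4))
        n0 = rng.integers(5, 31, size=n_cities)
        x = np.round(rng.uniform(0, 4, size=n_cities), 2)
        if np.ptp(x) == 0:
            continue
        at_risk = np.zeros((n_cities, n_years), dtype=np.int64)
        deaths = np.zeros_like(at_risk)
        alive = n0.copy()
        for t in range(n_years):
            at_risk[:, t] = alive
            deaths[:, t] = rng.binomial(alive, 0.15)
            alive = alive - deaths[:, t]
        if deaths.sum() >= 1 and np.ptp(x[at_risk[:, 0] > 0]) > 0:
            return deaths, at_risk, x
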