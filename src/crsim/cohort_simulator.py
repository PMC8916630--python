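"""Survival simulation for the city-structured cohort under a hockey-stick hazard.

Each city enrolls a fixed number of identical individuals (males aged 60) who
are followed annually for 20 years.  In year t the probability that a
survivor in city j dies is

    P_jt = min(1, B_t * h ** max(0, PM_j - T))

where B_t is the baseline annual death probability from the mortality
schedule, h the hazard ratio per µg/m³ of effective exposure, PM_j the city's
true annual-mean PM2.5 and T the concentration-response threshold.  All risk
acts in the year of exposure — no lags or cumulative effects.

Because every individual in a city-year shares the same death probability,
the number of deaths among n survivors is exactly Binomial(n, P_jt); the
simulator draws one binomial per city-year instead of one uniform per person,
which is identical in distribution and makes the 2-million-person cohort
cheap.  A literal per-individual implementation is kept for the equivalence
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crsim.baseline_mortality import MortalitySchedule
from crsim.exceptions import DomainError, IntegrityError
from crsim.exposure_model import CityExposureSet


@dataclass(frozen=True)
class CRScenario:
    """One true concentration-response condition: threshold, slope, error SD.

    ``threshold`` (µg/m³) is the hinge location T; ``hazard_ratio`` the
    multiplicative hazard h per µg/m³ above it; ``sigma`` (µg/m³) the SD of
    the classical measurement error applied at the analysis stage (it does
    not enter the simulation truth).
    """

    threshold: float
    hazard_ratio: float
    sigma: float

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise DomainError("threshold must be non-negative")
        if self.hazard_ratio < 1:
            raise DomainError("hazard ratio must be ≥ 1")

    @property
    def label(self) -> str:
        return f"T{self.threshold:g}_h{self.hazard_ratio:g}_s{self.sigma:g}"


@dataclass(frozen=True)
class CohortOutcome:
    """Aggregated survival outcomes: at-risk and death counts per (city, year).

    ``at_risk`` and ``deaths`` are integer arrays of shape (n_cities, years);
    ``at_risk[j, 0]`` equals ``persons_per_city`` and
    ``at_risk[j, t+1] = at_risk[j, t] - deaths[j, t]``.
    """

    cities: tuple[str, ...]
    at_risk: np.ndarray = field(repr=False)
    deaths: np.ndarray = field(repr=False)
    persons_per_city: int
    years: int
    scenario: CRScenario | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        n = np.asarray(self.at_risk, dtype=np.int64)
        d = np.asarray(self.deaths, dtype=np.int64)
        shape = (len(self.cities), self.years)
        if n.shape != shape or d.shape != shape:
            raise IntegrityError(f"count arrays must have shape {shape}")
        if np.any(d < 0) or np.any(n < 0) or np.any(d > n):
            raise IntegrityError("need 0 ≤ deaths ≤ at-risk in every city-year")
        if np.any(n[:, 0] != self.persons_per_city):
            raise IntegrityError("every city must start with persons_per_city at risk")
        if not np.array_equal(n[:, 1:], n[:, :-1] - d[:, :-1]):
            raise IntegrityError("at-risk counts must carry survivors forward")
        object.__setattr__(self, "at_risk", n)
        object.__setattr__(self, "deaths", d)
        object.__setattr__(self, "cities", tuple(self.cities))

    @property
    def n_cities(self) -> int:
        return len(self.cities)

    @property
    def n_individuals(self) -> int:
        """Total enrolled subjects."""
        return self.n_cities * self.persons_per_city

    @property
    def total_deaths(self) -> int:
        return int(self.deaths.sum())

    def person_years(self) -> np.ndarray:
        """Per-city person-years; a death contributes a full year in its death year."""
        return self.at_risk.sum(axis=1).astype(float)

    def to_frame(self) -> pd.DataFrame:
        j, t = np.divmod(np.arange(self.at_risk.size), self.years)
        return pd.DataFrame(
            {
                "city": np.asarray(self.cities)[j],
                "year": t,
                "at_risk": self.at_risk.ravel(),
                "deaths": self.deaths.ravel(),
            }
        )


def effective_pm(pm, threshold: float):
    """Hinge transform: max(0, pm - threshold), the exposure that carries risk."""
    if threshold < 0:
        raise DomainError("threshold must be non-negative")
    return np.maximum(0.0, np.asarray(pm, dtype=float) - threshold)


def mortality_probability(baseline, hazard_ratio: float, pm_eff):
    """Annual death probability min(1, B * h**pm_eff)."""
    p = np.asarray(baseline, dtype=float) * hazard_ratio ** np.asarray(
        pm_eff, dtype=float
    )
    return np.minimum(1.0, p)


def simulate_cohort(
    cities: CityExposureSet,
    schedule: MortalitySchedule,
    scenario: CRScenario,
    persons_per_city: int,
    years: int | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> CohortOutcome:
    """Simulate annual deaths for every city with one binomial draw per city-year."""
    years = schedule.n_years if years is None else years
    if years != schedule.n_years:
        raise DomainError(
            f"follow-up of {years} years does not match schedule of {schedule.n_years}"
        )
    if persons_per_city < 1:
        raise DomainError("persons_per_city must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pm_eff = effective_pm(cities.true_pm, scenario.threshold)
    at_risk = np.empty((cities.n_cities, years), dtype=np.int64)
    deaths = np.empty_like(at_risk)
    alive = np.full(cities.n_cities, persons_per_city, dtype=np.int64)
    for t in range(years):
        p = mortality_probability(schedule.q[t], scenario.hazard_ratio, pm_eff)
        at_risk[:, t] = alive
        deaths[:, t] = rng.binomial(alive, p)
        alive = alive - deaths[:, t]
    return CohortOutcome(
        cities=cities.cities,
        at_risk=at_risk,
        deaths=deaths,
        persons_per_city=persons_per_city,
        years=years,
        scenario=scenario,
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_cohort_individual(
    cities: CityExposureSet,
    schedule: MortalitySchedule,
    scenario: CRScenario,
    persons_per_city: int,
    years: int | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> CohortOutcome:
    """Reference implementation: one uniform draw per person-year.

    Identical in distribution to :func:`simulate_cohort` (all individuals in
    a city-year share the same death probability); kept for the equivalence
    test and small-scale checks.  O(persons) memory and time — do not use at
    full scale.
    """
    years = schedule.n_years if years is None else years
    if years != schedule.n_years:
        raise DomainError(
            f"follow-up of {years} years does not match schedule of {schedule.n_years}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pm_eff = effective_pm(cities.true_pm, scenario.threshold)
    at_risk = np.empty((cities.n_cities, years), dtype=np.int64)
    deaths = np.empty_like(at_risk)
    for j in range(cities.n_cities):
        alive = np.ones(persons_per_city, dtype=bool)
        for t in range(years):
            p = mortality_probability(schedule.q[t], scenario.hazard_ratio, pm_eff[j])
            at_risk[j, t] = alive.sum()
            u = rng.uniform(size=persons_per_city)
            dying = alive & (u < p)
            deaths[j, t] = dying.sum()
            alive &= ~dying
    return CohortOutcome(
        cities=cities.cities,
        at_risk=at_risk,
        deaths=deaths,
        persons_per_city=persons_per_city,
        years=years,
        scenario=scenario,
        seed=seed if isinstance(seed, int) else None,
    )
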