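"""Baseline (no-pollution) annual mortality probabilities for the simulated cohort.

The simulated stratum is homogeneous — males enrolled at age 60 and followed
for 20 years — so the baseline hazard reduces to a single vector B_t of annual
death probabilities, one per follow-up year.  B_t comes either from a cohort
life table (annual probability q of dying within the year, tabulated on a
decadal birth-year grid, linearly interpolated in birth year) or from a
Gompertz stand-in in which the annual probability doubles every fixed number
of years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from crsim.exceptions import DomainError, FormatError, IntegrityError

_REQUIRED_COLUMNS = ("birth_year", "sex", "age", "q")


@dataclass(frozen=True)
class LifeTable:
    """Cohort life table for one sex on a decadal birth-year grid.

    Parameters
    ----------
    sex
        Sex label ("M" here; the cohort is male-only).
    birth_years
        Strictly increasing integer grid of birth years.
    ages
        Contiguous integer ages covered by every grid year.
    q
        Array of shape ``(len(birth_years), len(ages))`` of annual death
        probabilities, each in [0, 1].
    """

    sex: str
    birth_years: np.ndarray
    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        by = np.asarray(self.birth_years, dtype=int)
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        if by.ndim != 1 or np.any(np.diff(by) <= 0):
            raise IntegrityError("birth-year grid must be strictly increasing")
        if ages.ndim != 1 or np.any(np.diff(ages) != 1):
            raise IntegrityError("age coverage must be contiguous")
        if q.shape != (by.size, ages.size):
            raise IntegrityError(
                f"q has shape {q.shape}, expected {(by.size, ages.size)}"
            )
        if np.any(q < 0) or np.any(q > 1) or not np.all(np.isfinite(q)):
            raise IntegrityError("death probabilities must lie in [0, 1]")
        object.__setattr__(self, "birth_years", by)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)


@dataclass(frozen=True)
class MortalitySchedule:
    """Annual baseline death probabilities B_t, t = 0 .. n_years-1."""

    start_age: int
    n_years: int
    q: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (self.n_years,):
            raise IntegrityError("schedule length must equal follow-up length")
        if np.any(q < 0) or np.any(q > 1):
            raise IntegrityError("schedule probabilities must lie in [0, 1]")
        object.__setattr__(self, "q", q)


def load_life_table(source: str | Path, sex: str = "M") -> LifeTable:
    """Read a life-table CSV (columns birth_year, sex, age, q) for one sex.

    Rows for other sexes are dropped.  Raises :class:`FormatError` on missing
    columns and :class:`IntegrityError` on duplicated (birth_year, age) keys,
    ragged age coverage, or q outside [0, 1].
    """
    df = pd.read_csv(source)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"life table is missing column(s): {', '.join(missing)}")
    df = df[df["sex"] == sex]
    if df.empty:
        raise IntegrityError(f"life table has no rows for sex={sex!r}")
    if df.duplicated(subset=["birth_year", "age"]).any():
        raise IntegrityError("duplicated (birth_year, age) keys in life table")
    wide = df.pivot(index="birth_year", columns="age", values="q").sort_index()
    if wide.isna().any().any():
        raise IntegrityError("age coverage differs across birth years")
    return LifeTable(
        sex=sex,
        birth_years=wide.index.to_numpy(dtype=int),
        ages=wide.columns.to_numpy(dtype=int),
        q=wide.to_numpy(dtype=float),
    )


def packaged_life_table(sex: str = "M") -> LifeTable:
    """The packaged synthetic male life table (birth years 1930/1940/1950, ages 60-80)."""
    with resources.as_file(
        resources.files("crsim.data") / "life_table_males_synthetic.csv"
    ) as path:
        return load_life_table(path, sex=sex)


def interpolate_schedule(
    table: LifeTable, birth_year: int, start_age: int, n_years: int
) -> MortalitySchedule:
    """B_t for a birth year, linearly interpolated between bracketing grid years.

    Exact table values are returned for birth years on the grid.  Ages
    ``start_age .. start_age + n_years - 1`` must be covered.
    """
    by = table.birth_years
    if birth_year < by[0] or birth_year > by[-1]:
        raise DomainError(
            f"birth year {birth_year} outside life-table grid [{by[0]}, {by[-1]}]"
        )
    ages_needed = np.arange(start_age, start_age + n_years)
    if ages_needed[0] < table.ages[0] or ages_needed[-1] > table.ages[-1]:
        raise DomainError(
            f"ages {ages_needed[0]}..{ages_needed[-1]} not covered by life table"
        )
    cols = ages_needed - table.ages[0]
    hi = int(np.searchsorted(by, birth_year, side="left"))
    if by[hi] == birth_year:
        q = table.q[hi, cols]
    else:
        lo = hi - 1
        w = (birth_year - by[lo]) / (by[hi] - by[lo])
        q = (1.0 - w) * table.q[lo, cols] + w * table.q[hi, cols]
    return MortalitySchedule(start_age=start_age, n_years=n_years, q=q)


def gompertz_schedule(
    q0: float, doubling_time: float, start_age: int, n_years: int
) -> MortalitySchedule:
    """Parametric schedule B_t = min(1, q0 * 2^(t / doubling_time)).

    A Gompertz-type stand-in for a life table: the annual death probability at
    the enrollment age is ``q0`` and doubles every ``doubling_time`` years
    (clamped at 1).
    """
    if not 0.0 < q0 < 1.0:
        raise DomainError("q0 must lie in (0, 1)")
    if doubling_time <= 0:
        raise DomainError("doubling_time must be positive")
    t = np.arange(n_years, dtype=float)
    q = np.minimum(1.0, q0 * 2.0 ** (t / doubling_time))
    return MortalitySchedule(start_age=start_age, n_years=n_years, q=q)
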