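"""True city-mean PM2.5 exposures and classical measurement-error draws.

The "true" exposure of each hypothetical city is a single annual-mean PM2.5
value (µg/m³), constant over the follow-up.  Cities are drawn by stratified
sampling from a candidate pool of city means — equal numbers from each
quartile — and each is perturbed by an independent Uniform(-1, 1) µg/m³ draw.
The packaged pool is synthetic: 229 deterministic quantiles of a shifted
lognormal calibrated so that 7, 8.5, and 9.5 µg/m³ fall near the 15th, 40th,
and 55th percentiles of the generated 100-city set, emulating the
distributional position of monitor-derived US city means relative to the
thresholds under study.

"Observed" exposures add classical measurement error: i.i.d. draws from a
mean-zero normal with SD sigma, truncated to an absolute ±4 µg/m³ band, one
draw per city per replicate, constant over the follow-up years.  The same
replicated error sets are reused across every concentration-response scenario
with that sigma (common random numbers), so differences in detectability
across scenarios are never an artifact of different error draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from crsim.exceptions import DomainError, IntegrityError

#: Absolute truncation bound on the error distribution, µg/m³.
DEFAULT_ERROR_BOUND = 4.0


@dataclass(frozen=True)
class CityExposureSet:
    """True city-mean PM2.5 values, one per city, constant over time."""

    cities: tuple[str, ...]
    true_pm: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pm = np.asarray(self.true_pm, dtype=float)
        if pm.shape != (len(self.cities),):
            raise IntegrityError("one true PM value required per city")
        if len(set(self.cities)) != len(self.cities):
            raise IntegrityError("duplicated city identifiers")
        if np.any(pm <= 0):
            raise IntegrityError("true PM2.5 must be positive")
        object.__setattr__(self, "true_pm", pm)
        object.__setattr__(self, "cities", tuple(self.cities))

    @property
    def n_cities(self) -> int:
        return len(self.cities)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"city": self.cities, "true_pm": self.true_pm})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CityExposureSet":
        df = pd.read_csv(path)
        return cls(cities=tuple(df["city"].astype(str)), true_pm=df["true_pm"].to_numpy())


@dataclass(frozen=True)
class ExposureErrorSet:
    """Replicated classical-error draws e[r, j] for one error SD.

    ``errors`` has shape (n_sets, n_cities); every entry lies within
    ±``bound`` µg/m³.  A replicate's draw for a city is constant over the
    follow-up years.
    """

    sigma: float
    bound: float
    errors: np.ndarray = field(repr=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.errors, dtype=float)
        if e.ndim != 2:
            raise IntegrityError("errors must be a (replicate, city) matrix")
        if np.any(np.abs(e) > self.bound):
            raise IntegrityError(f"error draw outside ±{self.bound} bound")
        object.__setattr__(self, "errors", e)

    @property
    def n_sets(self) -> int:
        return self.errors.shape[0]

    def observed(self, true_pm: np.ndarray, replicate: int) -> np.ndarray:
        """Observed PM for one replicate: true + error, no clamping."""
        return observe(np.asarray(true_pm, dtype=float), self.errors[replicate])

    def to_frame(self, cities: CityExposureSet) -> pd.DataFrame:
        r, j = np.divmod(np.arange(self.errors.size), self.errors.shape[1])
        return pd.DataFrame(
            {
                "sigma": self.sigma,
                "replicate": r,
                "city": np.asarray(cities.cities)[j],
                "error": self.errors.ravel(),
                "observed_pm": (cities.true_pm[j] + self.errors.ravel()),
            }
        )


def packaged_base_pool() -> np.ndarray:
    """The packaged synthetic pool of 229 candidate city-mean PM2.5 values."""
    with resources.as_file(
        resources.files("crsim.data") / "city_pm_pool_synthetic.csv"
    ) as path:
        return pd.read_csv(path)["mean_pm25"].to_numpy(dtype=float)


def generate_true_exposures(
    n_cities: int,
    base_pool: np.ndarray | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    jitter: float = 1.0,
) -> CityExposureSet:
    """Stratified sample of city means from a candidate pool, plus jitter.

    The pool is split at its quartiles; ``n_cities/4`` candidates are sampled
    without replacement from each quartile, each perturbed by an independent
    Uniform(-jitter, +jitter) µg/m³ draw, and the result is randomly assigned
    to city labels.
    """
    if base_pool is None:
        base_pool = packaged_base_pool()
    pool = np.asarray(base_pool, dtype=float)
    if n_cities % 4 != 0:
        raise DomainError("n_cities must be divisible by 4 (quartile strata)")
    if pool.size < n_cities:
        raise DomainError(f"pool of {pool.size} too small for {n_cities} cities")
    rng = _as_rng(seed)
    per_stratum = n_cities // 4
    q1, q2, q3 = np.quantile(pool, [0.25, 0.5, 0.75])
    strata = [
        pool[pool <= q1],
        pool[(pool > q1) & (pool <= q2)],
        pool[(pool > q2) & (pool <= q3)],
        pool[pool > q3],
    ]
    for s in strata:
        if s.size < per_stratum:
            raise DomainError("a quartile stratum is too small for the requested sample")
    picks = np.concatenate(
        [rng.choice(s, size=per_stratum, replace=False) for s in strata]
    )
    values = picks + rng.uniform(-jitter, jitter, size=n_cities) if jitter > 0 else picks
    rng.shuffle(values)
    width = len(str(n_cities - 1))
    names = tuple(f"city_{i:0{width}d}" for i in range(n_cities))
    return CityExposureSet(cities=names, true_pm=values)


def truncated_normal_draws(
    sigma: float,
    size: int | tuple[int, ...],
    bound: float = DEFAULT_ERROR_BOUND,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean-zero normal draws with SD sigma truncated to [-bound, +bound].

    Sampling is by inverse CDF on a uniform restricted to
    [Phi(-b/sigma), Phi(b/sigma)], so exactly one uniform is consumed per
    draw and the stream is stable under truncation.
    """
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    if bound <= 0:
        raise DomainError("bound must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    phi = stats.norm.cdf(bound / sigma)
    u = rng.uniform(1.0 - phi, phi, size=size)
    draws = sigma * stats.norm.ppf(u)
    # ppf is exact at the open interval; clip guards the representable edge
    return np.clip(draws, -bound, bound)


def draw_error_sets(
    cities: CityExposureSet | int,
    sigma: float,
    n_sets: int,
    bound: float = DEFAULT_ERROR_BOUND,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> ExposureErrorSet:
    """Replicated classical-error matrices: n_sets draws per city.

    ``cities`` may be a :class:`CityExposureSet` or a plain city count.
    """
    if n_sets < 1:
        raise DomainError("n_sets must be at least 1")
    n_cities = cities if isinstance(cities, int) else cities.n_cities
    rng = _as_rng(seed)
    errors = truncated_normal_draws(sigma, (n_sets, n_cities), bound=bound, rng=rng)
    raw_seed = seed if isinstance(seed, int) else None
    return ExposureErrorSet(sigma=sigma, bound=bound, errors=errors, seed=raw_seed)


def observe(true_pm: np.ndarray | float, error: np.ndarray | float):
    """Observed PM2.5 = true + error; may be ≤ 0, never clamped.

    Only hinge-transformed values enter the hazard models, so small or
    negative observed values are legitimate inputs downstream.
    """
    return true_pm + error


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
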