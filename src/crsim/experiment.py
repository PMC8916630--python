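"""Full factorial experiment: thresholds × hazard ratios × error SDs × replicates.

One cohort is simulated per (T, h, σ) combination; the same σ-specific set of
replicated error draws is reused across all combinations sharing that σ
(common random numbers), so scenario-to-scenario differences in detectability
never stem from different error draws.  Each replicate then fits the
no-threshold and true-threshold Cox models, runs the threshold-vs-null
comparison, grid-searches the best-fitting threshold, and checks whether the
best fit's confidence interval excludes the true hazard ratio from below.

Summary builders aggregate the per-replicate rows into detection-count
tables (one per decision criterion), best-threshold frequency matrices, and
coverage-failure counts, with hazard-ratio estimates kept per replicate for
strip plots.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from crsim._seeds import child_rng
from crsim.baseline_mortality import (
    MortalitySchedule,
    interpolate_schedule,
    packaged_life_table,
)
from crsim.cohort_simulator import CohortOutcome, CRScenario, simulate_cohort
from crsim.exceptions import DomainError
from crsim.exposure_model import (
    DEFAULT_ERROR_BOUND,
    CityExposureSet,
    ExposureErrorSet,
    draw_error_sets,
    generate_true_exposures,
)
from crsim.survival_inference import city_relative_risk, cox_fit, fit_spline
from crsim.threshold_analysis import (
    compare_threshold_models,
    hr_coverage_check,
    scan_thresholds,
)
from crsim.cohort_simulator import effective_pm

#: The study grid: 3 thresholds × 5 hazard ratios × 3 error SDs = 45 combinations.
DEFAULT_THRESHOLDS = (7.0, 8.5, 9.5)
DEFAULT_HAZARD_RATIOS = (1.0025, 1.005, 1.01, 1.02, 1.05)
DEFAULT_SIGMAS = (1.0, 2.0, 4.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Run configuration; the defaults reproduce the full study grid.

    ``scale`` presets: "full" = 100 cities × 20,000 persons × 20 years with
    100 error replicates; "desk" = 2,000 persons and 25 replicates for quick
    runs with the same schema.
    """

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    hazard_ratios: tuple[float, ...] = DEFAULT_HAZARD_RATIOS
    sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    replicates: int = 100
    n_cities: int = 100
    persons_per_city: int = 20_000
    years: int = 20
    start_age: int = 60
    first_year: int = 2000
    error_bound: float = DEFAULT_ERROR_BOUND
    seed: int = 0
    fit_splines: bool = False
    shared_cohort_across_sigma: bool = False

    @classmethod
    def preset(cls, scale: str = "full", **overrides) -> "ExperimentConfig":
        if scale == "full":
            base = cls()
        elif scale == "desk":
            base = cls(persons_per_city=2_000, replicates=25)
        else:
            raise DomainError(f"unknown scale preset {scale!r}")
        return replace(base, **overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scale = raw.pop("scale", "full")
        for key in ("thresholds", "hazard_ratios", "sigmas"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls.preset(scale, **raw)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def birth_year(self) -> int:
        """Enrollment birth year: first calendar year minus enrollment age."""
        return self.first_year - self.start_age

    @property
    def n_individuals(self) -> int:
        return self.n_cities * self.persons_per_city

    def scenarios(self) -> list[CRScenario]:
        return [
            CRScenario(threshold=t, hazard_ratio=h, sigma=s)
            for t in self.thresholds
            for h in self.hazard_ratios
            for s in self.sigmas
        ]


@dataclass
class ExperimentResult:
    """Per-replicate rows plus the inputs needed to rebuild every summary."""

    config: ExperimentConfig
    replicates: pd.DataFrame
    scan_candidates: pd.DataFrame
    cities: CityExposureSet
    splines: pd.DataFrame | None = None
    failures: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.replicates.to_csv(out / "replicates.csv", index=False)
        self.scan_candidates.to_csv(out / "scan_candidates.csv", index=False)
        self.cities.to_csv(out / "cities.csv")
        if self.splines is not None:
            self.splines.to_csv(out / "splines.csv", index=False)
        manifest = {
            "config": self.config.to_dict(),
            "failures": self.failures,
            "n_rows": int(len(self.replicates)),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read(cls, out_dir: str | Path) -> "ExperimentResult":
        out = Path(out_dir)
        manifest = json.loads((out / "manifest.json").read_text())
        cfg_raw = manifest["config"]
        for key in ("thresholds", "hazard_ratios", "sigmas"):
            cfg_raw[key] = tuple(cfg_raw[key])
        splines_path = out / "splines.csv"
        return cls(
            config=ExperimentConfig(**cfg_raw),
            replicates=pd.read_csv(out / "replicates.csv"),
            scan_candidates=pd.read_csv(out / "scan_candidates.csv"),
            cities=CityExposureSet.from_csv(out / "cities.csv"),
            splines=pd.read_csv(splines_path) if splines_path.exists() else None,
            failures=list(manifest.get("failures", [])),
        )


def default_schedule(config: ExperimentConfig) -> MortalitySchedule:
    """Baseline schedule from the packaged life table at the cohort's birth year."""
    return interpolate_schedule(
        packaged_life_table(),
        birth_year=config.birth_year,
        start_age=config.start_age,
        n_years=config.years,
    )


def run_scenario(
    scenario: CRScenario,
    cities: CityExposureSet,
    schedule: MortalitySchedule,
    error_set: ExposureErrorSet,
    config: ExperimentConfig,
    cohort: CohortOutcome | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """One (T, h, σ) combination: simulate the cohort, analyze every replicate.

    Returns (per-replicate rows, per-candidate scan rows, spline rows or
    None).  Replicates that fail to converge are recorded with
    ``converged=False`` rather than aborting the scenario.
    """
    if error_set.sigma != scenario.sigma:
        raise DomainError("error set sigma does not match scenario")
    if error_set.n_sets < config.replicates:
        raise DomainError("error set has fewer replicates than requested")
    if cohort is None:
        cohort_key = (
            ("cohort", scenario.threshold, scenario.hazard_ratio)
            if config.shared_cohort_across_sigma
            else ("cohort", scenario.threshold, scenario.hazard_ratio, scenario.sigma)
        )
        cohort = simulate_cohort(
            cities,
            schedule,
            scenario,
            persons_per_city=config.persons_per_city,
            years=config.years,
            seed=child_rng(config.seed, *cohort_key),
        )
    n_deaths = cohort.total_deaths
    n_ind = cohort.n_individuals
    rows, scan_rows, spline_rows = [], [], []
    for r in range(config.replicates):
        observed = error_set.observed(cities.true_pm, r)
        fit_null = cox_fit(cohort, observed)
        hinge_true = effective_pm(observed, scenario.threshold)
        degenerate = np.ptp(hinge_true) == 0
        fit_thr = None if degenerate else cox_fit(cohort, hinge_true)
        row = {
            "scenario": scenario.label,
            "threshold": scenario.threshold,
            "hazard_ratio": scenario.hazard_ratio,
            "sigma": scenario.sigma,
            "replicate": r,
            "n_deaths": n_deaths,
            "n_individuals": n_ind,
            "ll_null": fit_null.loglik,
            "converged": fit_null.converged and (degenerate or fit_thr.converged),
        }
        if fit_thr is not None and fit_thr.converged and fit_null.converged:
            cmpres = compare_threshold_models(fit_thr, fit_null, n_deaths, n_ind)
            row.update(
                ll_threshold=fit_thr.loglik,
                stat_2dll=cmpres.statistic,
                detect_aic=cmpres.detect_aic,
                detect_bic_deaths=cmpres.detect_bic_deaths,
                detect_bic_individuals=cmpres.detect_bic_individuals,
            )
        scan = scan_thresholds(cohort, observed, scenario.threshold)
        best = scan.best_fit
        row.update(
            best_threshold=scan.best_threshold,
            best_beta=np.nan if best is None else best.beta,
            best_hr=np.nan if best is None else best.hr,
            best_ci_low=np.nan if best is None else best.ci_low,
            best_ci_high=np.nan if best is None else best.ci_high,
            coverage_fail=(
                np.nan
                if best is None or not best.converged
                else hr_coverage_check(best, scenario.hazard_ratio)
            ),
        )
        rows.append(row)
        for cand, ll in zip(scan.candidates, scan.logliks):
            scan_rows.append(
                {
                    "scenario": scenario.label,
                    "replicate": r,
                    "candidate": cand,
                    "loglik": ll,
                    "is_best": cand == scan.best_threshold,
                }
            )
        if config.fit_splines:
            rr = city_relative_risk(cohort, observed)
            curve = fit_spline(rr)
            spline_rows.append(
                pd.DataFrame(
                    {
                        "scenario": scenario.label,
                        "replicate": r,
                        "pm_grid": curve.grid,
                        "rr_fitted": curve.fitted,
                    }
                )
            )
    splines = pd.concat(spline_rows, ignore_index=True) if spline_rows else None
    return pd.DataFrame(rows), pd.DataFrame(scan_rows), splines


def run_grid(config: ExperimentConfig, progress: bool = False) -> ExperimentResult:
    """Execute every scenario combination under hierarchical seeding.

    The master seed spawns named child streams ("exposure", "errors:σ",
    "cohort:T,h,σ"), so the error sets are common across scenarios with the
    same σ and adding scenarios never perturbs existing streams.  The run is
    fully reproducible from (config, seed).
    """
    cities = generate_true_exposures(
        config.n_cities, seed=child_rng(config.seed, "exposure")
    )
    schedule = default_schedule(config)
    error_sets = {
        s: draw_error_sets(
            cities,
            sigma=s,
            n_sets=config.replicates,
            bound=config.error_bound,
            seed=child_rng(config.seed, "errors", s),
        )
        for s in config.sigmas
    }
    rep_frames, scan_frames, spline_frames, failures = [], [], [], []
    for scenario in config.scenarios():
        try:
            reps, scans, splines = run_scenario(
                scenario, cities, schedule, error_sets[scenario.sigma], config
            )
        except Exception as exc:  # record and continue: one bad cell is not fatal
            failures.append(f"{scenario.label}: {exc}")
            continue
        rep_frames.append(reps)
        scan_frames.append(scans)
        if splines is not None:
            spline_frames.append(splines)
        if progress:
            n_conv = int(reps["converged"].sum())
            print(
                f"{scenario.label}: {len(reps)} replicates, {n_conv} converged",
                flush=True,
            )
    return ExperimentResult(
        config=config,
        replicates=pd.concat(rep_frames, ignore_index=True),
        scan_candidates=pd.concat(scan_frames, ignore_index=True),
        cities=cities,
        splines=pd.concat(spline_frames, ignore_index=True) if spline_frames else None,
        failures=failures,
    )


def build_tables(result: ExperimentResult) -> dict[str, pd.DataFrame]:
    """Summary tables from per-replicate rows.

    Returns a dict with:

    - ``detection_bic_individuals`` / ``detection_aic`` / ``detection_bic_deaths``:
      counts of replicates preferring the true-threshold model, rows indexed
      by (hazard_ratio, sigma), one column per true threshold;
    - ``best_threshold_T{T}``: frequency of each scanned candidate winning,
      per (hazard_ratio, sigma), for each true threshold T (rows sum to the
      replicate count);
    - ``coverage_fail``: counts of replicates whose best-fit CI upper limit
      fell below the true hazard ratio;
    - ``hr_estimates``: per-replicate best-fit hazard ratios (strip-plot data).
    """
    df = result.replicates
    tables: dict[str, pd.DataFrame] = {}
    for crit in ("detect_bic_individuals", "detect_aic", "detect_bic_deaths"):
        name = "detection_" + crit.removeprefix("detect_")
        tables[name] = (
            df.assign(count=lambda d, c=crit: d[c].eq(True).astype(int))
            .pivot_table(
                index=["hazard_ratio", "sigma"],
                columns="threshold",
                values="count",
                aggfunc="sum",
            )
            .rename_axis(columns="true_threshold")
        )
    for t in result.config.thresholds:
        sub = df[df["threshold"] == t]
        if sub.empty:
            continue
        tables[f"best_threshold_T{t:g}"] = (
            sub.pivot_table(
                index=["hazard_ratio", "sigma"],
                columns="best_threshold",
                values="replicate",
                aggfunc="count",
                fill_value=0,
            )
            .rename_axis(columns="candidate")
        )
    tables["coverage_fail"] = (
        df.assign(count=lambda d: d["coverage_fail"].eq(1).astype(int))
        .pivot_table(
            index=["hazard_ratio", "sigma"],
            columns="threshold",
            values="count",
            aggfunc="sum",
        )
        .rename_axis(columns="true_threshold")
    )
    tables["hr_estimates"] = df[
        ["threshold", "hazard_ratio", "sigma", "replicate", "best_threshold", "best_hr"]
    ].copy()
    return tables
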