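"""Threshold machinery: hinge covariates, the non-nested threshold-vs-linear
model comparison, the grid search for the best-fitting threshold, and the
hazard-ratio coverage check.

The threshold (hinge) model and the no-threshold (linear-in-PM) model are not
nested, so a likelihood-ratio test does not apply.  Instead the statistic
S = 2 * (LL_threshold - LL_null) is compared against the per-parameter
penalty of an information criterion: 2 for AIC, ln(n) for BIC with n taken as
either the number of deaths or the number of enrolled individuals.  The
headline decision rule is the most stringent one, S > ln(n_individuals).
The threshold model is charged exactly one extra parameter regardless of how
many candidate thresholds a grid search examined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from crsim.cohort_simulator import CohortOutcome, effective_pm
from crsim.exceptions import DomainError, IntegrityError
from crsim.survival_inference import CoxFit, cox_fit, null_loglik


@dataclass(frozen=True)
class ThresholdComparison:
    """Outcome of the 2ΔLL-vs-penalty comparison for one replicate."""

    ll_threshold: float
    ll_null: float
    n_deaths: int
    n_individuals: int

    @property
    def statistic(self) -> float:
        """S = 2 * (LL_threshold - LL_null)."""
        return 2.0 * (self.ll_threshold - self.ll_null)

    @property
    def penalty_aic(self) -> float:
        return 2.0

    @property
    def penalty_bic_deaths(self) -> float:
        return float(np.log(self.n_deaths))

    @property
    def penalty_bic_individuals(self) -> float:
        return float(np.log(self.n_individuals))

    @property
    def detect_aic(self) -> bool:
        return self.statistic > self.penalty_aic

    @property
    def detect_bic_deaths(self) -> bool:
        return self.statistic > self.penalty_bic_deaths

    @property
    def detect_bic_individuals(self) -> bool:
        """Headline rule: threshold model preferred iff 2ΔLL > ln(n individuals)."""
        return self.statistic > self.penalty_bic_individuals

    @property
    def detected(self) -> bool:
        return self.detect_bic_individuals


@dataclass(frozen=True)
class ThresholdScan:
    """Grid-search result: candidate thresholds, their log-likelihoods, the winner."""

    candidates: np.ndarray
    logliks: np.ndarray = field(repr=False)
    best_threshold: float
    best_fit: CoxFit | None

    def __post_init__(self) -> None:
        c = np.asarray(self.candidates, dtype=float)
        ll = np.asarray(self.logliks, dtype=float)
        if c.shape != ll.shape or c.size == 0:
            raise IntegrityError("candidates and log-likelihoods must align")
        object.__setattr__(self, "candidates", c)
        object.__setattr__(self, "logliks", ll)


def compare_threshold_models(
    fit_thr: CoxFit, fit_null: CoxFit, n_deaths: int, n_individuals: int
) -> ThresholdComparison:
    """Compare a true-threshold hinge fit against the no-threshold fit.

    Both fits must come from the same data; the counts define the BIC
    penalties ln(n_deaths) and ln(n_individuals).
    """
    if not (fit_thr.converged and fit_null.converged):
        raise IntegrityError("both fits must have converged")
    if n_deaths < 1 or n_individuals < 1 or n_deaths > n_individuals:
        raise IntegrityError("need 1 ≤ n_deaths ≤ n_individuals")
    return ThresholdComparison(
        ll_threshold=fit_thr.loglik,
        ll_null=fit_null.loglik,
        n_deaths=int(n_deaths),
        n_individuals=int(n_individuals),
    )


def scan_thresholds(
    data: CohortOutcome,
    observed_pm: np.ndarray,
    true_threshold: float,
    step: float = 1.0,
    halfwidth: float = 4.0,
) -> ThresholdScan:
    """Grid search for the best-fitting threshold around the true value.

    Candidates run from ``true_threshold - halfwidth`` to
    ``true_threshold + halfwidth`` in steps of ``step`` (9 values at the
    defaults).  For each candidate T* the hinge covariate
    max(0, observed_pm - T*) is fitted by Cox partial likelihood; a candidate
    whose hinge is identically zero is degenerate and is recorded at the
    covariate-free log-likelihood.  The winner is the maximum-likelihood
    candidate, ties broken toward the smallest.
    """
    pm = np.asarray(observed_pm, dtype=float)
    n_cand = int(round(2 * halfwidth / step)) + 1
    candidates = true_threshold + step * np.arange(n_cand) - halfwidth
    if candidates.size == 0:
        raise DomainError("empty candidate grid")
    logliks = np.empty(candidates.size)
    fits: list[CoxFit | None] = []
    for i, cand in enumerate(candidates):
        x = effective_pm(pm, max(0.0, float(cand)))
        if np.ptp(x) == 0:
            logliks[i] = null_loglik(data)
            fits.append(None)
        else:
            fit = cox_fit(data, x)
            logliks[i] = fit.loglik
            fits.append(fit)
    best = int(np.argmax(logliks))  # first max → smallest candidate on ties
    return ThresholdScan(
        candidates=candidates,
        logliks=logliks,
        best_threshold=float(candidates[best]),
        best_fit=fits[best],
    )


def hr_coverage_check(fit: CoxFit, true_h: float) -> int:
    """1 iff the 95% CI's upper limit on the hazard ratio lies strictly below true_h.

    One-sided by construction: only failures where the interval sits entirely
    below the truth (attenuation) count.
    """
    if not fit.converged:
        raise IntegrityError("coverage check requires a converged fit")
    return int(fit.ci_high < true_h)
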