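"""Cox proportional-hazards fitting on aggregated cohort counts, plus the
city-level relative-risk spline diagnostic.

With a single city-level covariate and annual event times shared by everyone
who dies in a year, the Breslow tied-time partial log-likelihood collapses to
a function of the aggregated (city, year) counts:

    LL(beta) = sum_t [ beta * sum_j d_jt x_j  -  D_t * log sum_j n_jt exp(beta x_j) ]

where n_jt is the number at risk in city j entering year t, d_jt the deaths
in that city-year, D_t the total deaths in year t, and x_j the city's
covariate (observed PM2.5, raw or hinge-transformed).  The time axis is years
since enrollment; since everyone enrolls at age 60 it is equivalently age.
LL is concave in beta, so the fit is a one-dimensional safeguarded Newton
iteration; the standard error comes from the observed information and the
95% CI is Wald on the log-hazard scale.

The spline diagnostic regresses each city's crude relative risk (rate ratio
against the city with the lowest observed exposure) on a natural cubic spline
of observed PM2.5 with four degrees of freedom, mirroring the exploratory
plots used to eyeball a threshold before any parametric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix

from crsim.cohort_simulator import CohortOutcome
from crsim.exceptions import DomainError, IntegrityError

_Z95 = 1.959963984540054  # two-sided 95% normal quantile
_EXP_CLIP = 700.0  # exp argument guard


@dataclass(frozen=True)
class CoxFit:
    """A fitted single-covariate Cox model on aggregated counts."""

    beta: float
    se: float
    loglik: float
    converged: bool
    n_iter: int

    @property
    def hr(self) -> float:
        """Hazard ratio per unit of the covariate."""
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - _Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + _Z95 * self.se))


@dataclass(frozen=True)
class SplineCurve:
    """A fitted natural-cubic-spline relative-risk curve."""

    knots: np.ndarray
    df: int
    coefficients: np.ndarray
    grid: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)


def _counts(data: CohortOutcome | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, CohortOutcome):
        return data.deaths, data.at_risk
    deaths, at_risk = data
    return np.asarray(deaths, dtype=float), np.asarray(at_risk, dtype=float)


def partial_loglik(
    beta: float,
    data: CohortOutcome | tuple,
    covariate: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Tied-time partial log-likelihood at ``beta`` for a per-city covariate.

    ``data`` is a :class:`CohortOutcome` or a ``(deaths, at_risk)`` pair of
    (city, year) arrays.  ``ties`` selects the Breslow (default) or Efron
    approximation; with the heavy annual ties here the difference is
    second-order, and the Efron variant exists for sensitivity checks.
    Years with no deaths contribute nothing; a year with deaths but an empty
    risk set is an integrity error.
    """
    ll, _, _ = _loglik_derivs(
        float(beta), data, np.asarray(covariate, dtype=float), ties=ties
    )
    return ll


def _loglik_derivs(beta, data, x, ties="breslow"):
    """(LL, score, hessian) of the aggregated tied-time partial likelihood."""
    if ties not in ("breslow", "efron"):
        raise DomainError(f"unknown ties method {ties!r}")
    deaths, at_risk = _counts(data)
    if x.shape[0] != deaths.shape[0]:
        raise IntegrityError("covariate must have one value per city")
    d_t = deaths.sum(axis=0)  # D_t
    event_years = np.flatnonzero(d_t > 0)
    if np.any(at_risk.sum(axis=0)[event_years] <= 0):
        raise IntegrityError("empty risk set at an event time")
    eta = np.clip(beta * x, -_EXP_CLIP, _EXP_CLIP)
    w = np.exp(eta)  # exp(beta x_j)
    s0 = (w @ at_risk)[event_years]  # per-year sum n_jt exp(beta x_j)
    s1 = ((w * x) @ at_risk)[event_years]
    s2 = ((w * x * x) @ at_risk)[event_years]
    d_ev = d_t[event_years]
    sum_dx = float((deaths * x[:, None]).sum())
    if ties == "breslow":
        ll = beta * sum_dx - float(d_ev @ np.log(s0))
        score = sum_dx - float(d_ev @ (s1 / s0))
        hess = -float(d_ev @ (s2 / s0 - (s1 / s0) ** 2))
        return ll, score, hess
    # Efron: at each event year the d tied deaths progressively discount the
    # deaths' own contribution to the risk-set sums, A_l = S0 - (l/d) S0d.
    sd0 = (w @ deaths)[event_years]
    sd1 = ((w * x) @ deaths)[event_years]
    sd2 = ((w * x * x) @ deaths)[event_years]
    ll = beta * sum_dx
    score = sum_dx
    hess = 0.0
    for k in range(d_ev.size):
        frac = np.arange(d_ev[k]) / d_ev[k]
        a0 = s0[k] - frac * sd0[k]
        a1 = s1[k] - frac * sd1[k]
        a2 = s2[k] - frac * sd2[k]
        ll -= float(np.log(a0).sum())
        score -= float((a1 / a0).sum())
        hess -= float((a2 / a0 - (a1 / a0) ** 2).sum())
    return ll, score, hess


def null_loglik(data: CohortOutcome | tuple) -> float:
    """Partial log-likelihood at beta=0 (covariate-free): -sum_t D_t log(sum_j n_jt)."""
    deaths, at_risk = _counts(data)
    d_t = deaths.sum(axis=0)
    ev = d_t > 0
    return -float(d_t[ev] @ np.log(at_risk.sum(axis=0)[ev]))


def cox_fit(
    data: CohortOutcome | tuple,
    covariate: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    ties: str = "breslow",
) -> CoxFit:
    """Maximize the Breslow partial likelihood by safeguarded Newton iteration.

    Convergence is declared when |score| falls below ``tol`` scaled by the
    magnitude of the event-weighted covariate sum (the score's own natural
    scale, so the criterion is attainable in double precision at any cohort
    size); the likelihood is concave so each Newton step is ascent after
    step-halving.  A covariate constant across all cities (e.g. an all-zero
    hinge) leaves beta unidentified and raises :class:`DomainError`.
    """
    x = np.asarray(covariate, dtype=float)
    deaths, _ = _counts(data)
    if deaths.sum() < 1:
        raise DomainError("no deaths: partial likelihood is flat")
    if np.ptp(x) == 0:
        raise DomainError("covariate constant across cities: beta unidentified")
    score_scale = max(1.0, float(np.abs(deaths * x[:, None]).sum()))
    beta = 0.0
    ll, score, hess = _loglik_derivs(beta, data, x, ties=ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if abs(score) < tol * score_scale:
            converged = True
            break
        step = -score / hess if hess < 0 else np.sign(score)
        # step-halving keeps the iteration inside the concave ascent region
        for _ in range(60):
            cand = beta + step
            ll_new, score_new, hess_new = _loglik_derivs(cand, data, x, ties=ties)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        if cand == beta:  # step underflowed: no further progress possible
            break
        beta, ll, score, hess = cand, ll_new, score_new, hess_new
    else:
        it = max_iter
    if abs(score) < tol * score_scale:
        converged = True
    se = float(np.sqrt(-1.0 / hess)) if hess < 0 else float("inf")
    return CoxFit(beta=float(beta), se=se, loglik=float(ll), converged=converged, n_iter=it)


def city_relative_risk(
    data: CohortOutcome, observed_pm: np.ndarray
) -> pd.DataFrame:
    """Crude city death rates and relative risks against the lowest-PM city.

    Rates are total deaths over total person-years of follow-up (a death
    contributes a full year in its death year).  The reference city is the
    one with the minimum *observed* exposure — it can change from one error
    replicate to the next.  Returns a DataFrame with columns
    ``city, observed_pm, rate, rr``.
    """
    pm = np.asarray(observed_pm, dtype=float)
    if pm.shape[0] != data.n_cities:
        raise IntegrityError("observed_pm must have one value per city")
    rate = data.deaths.sum(axis=1) / data.person_years()
    ref = int(np.argmin(pm))
    if rate[ref] <= 0:
        raise IntegrityError("reference city has no deaths: relative risk undefined")
    return pd.DataFrame(
        {
            "city": data.cities,
            "observed_pm": pm,
            "rate": rate,
            "rr": rate / rate[ref],
        }
    )


def fit_spline(
    rr: pd.DataFrame, df: int = 4, grid: np.ndarray | None = None
) -> SplineCurve:
    """Least-squares natural cubic spline of relative risk on observed PM2.5.

    The basis has ``df`` columns (plus an intercept): boundary knots at the
    observed exposure extremes and ``df - 1`` interior knots at equally
    spaced quantiles (the 25th/50th/75th percentiles for df=4).  Natural
    splines are linear beyond the boundary knots.
    """
    x = rr["observed_pm"].to_numpy(dtype=float)
    y = rr["rr"].to_numpy(dtype=float)
    if np.unique(x).size < df + 1:
        raise DomainError(f"need at least {df + 1} distinct exposure values")
    lo, hi = float(x.min()), float(x.max())
    interior = np.quantile(x, np.linspace(0, 1, df + 1)[1:-1])
    # raw cr basis on df+1 knots spans the natural-spline space including
    # constants; drop its first column against an explicit intercept to get
    # a full-rank intercept + df spline-column design of the same span
    raw = dmatrix(
        "cr(x, knots=interior, lower_bound=lo, upper_bound=hi) - 1",
        {"x": x, "interior": interior, "lo": lo, "hi": hi},
        return_type="dataframe",
    )
    design = np.column_stack([np.ones(x.size), raw.to_numpy()[:, 1:]])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise IntegrityError("rank-deficient spline basis")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    if grid is None:
        grid = np.linspace(lo, hi, 101)
    grid = np.asarray(grid, dtype=float)
    grid_raw = np.asarray(
        build_design_matrices([raw.design_info], {"x": grid})[0]
    )
    grid_basis = np.column_stack([np.ones(grid.size), grid_raw[:, 1:]])
    return SplineCurve(
        knots=np.concatenate(([lo], interior, [hi])),
        df=df,
        coefficients=coef,
        grid=grid,
        fitted=grid_basis @ coef,
    )
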