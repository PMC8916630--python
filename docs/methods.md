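# Methods

## The simulated study design

`crsim` emulates a prospective multi-city cohort study of chronic PM2.5
exposure and all-cause mortality. The cohort is deliberately homogeneous —
100 cities × 20,000 males enrolled at age 60, followed for 20 annual cycles
(calendar years 2000–2019, so the enrollment birth cohort is 1940) — so that
the only systematic mortality gradient across cities is the exposure effect
under study. Everything else (age and sex structure, competing risks,
confounders, time-varying exposure, lagged effects) is deliberately absent;
the question is what measurement error alone does to threshold detection
under otherwise ideal conditions.

## Baseline mortality

The baseline annual death probability B_t comes from a cohort life table
(columns `birth_year, sex, age, q`), linearly interpolated age-wise in birth
year between the decadal grid columns. The packaged table is synthetic: a
Gompertz form q(age) = q0 · 2^((age−60)/8.3) with q0 = 0.011 for the 1940
birth cohort, 21 ages (60–80), and a 5%-per-decade mortality improvement
across the 1930/1940/1950 grid so the interpolation path is non-trivial. The
1940 column — the only one the default cohort uses — therefore rises from
q = 0.011 at 60 to q ≈ 0.054 at 79, doubling roughly every 8.3 years, the
qualitative shape of male mortality at these ages. Under the null (h = 1)
this schedule yields a 20-year cumulative mortality of 1 − Π(1 − B_t) ≈ 0.42,
about 850,000 deaths among the 2 million enrolled.

Life-table q values are treated as conditional annual Bernoulli
probabilities exactly as tabulated, with no within-year timing adjustment.
A `gompertz_schedule` constructor exposes the parametric stand-in directly.

## Exposures

Each city's true exposure is one annual-mean PM2.5 value, constant over
follow-up. Cities are sampled from a packaged pool of 229 candidate means:
the pool is split at its quartiles, 25 candidates are drawn without
replacement from each quartile, and each is jittered by an independent
Uniform(−1, 1) µg/m³ draw.

The pool itself is synthetic, built as the deterministic quantiles of a
bounded Johnson-SB-type distribution on (lo, 20) µg/m³ whose three free
parameters are solved so that the jitter-convolved CDF passes exactly
through F(7) = 0.15, F(8.5) = 0.40, F(9.5) = 0.55 — placing the three
thresholds under study at the 15th/40th/55th percentiles of the generated
100-city set. The resulting pool (min 5.8, median 9.1, SD 2.6, max 17.8) is
a realistic stand-in for the distribution of monitor-derived US city-level
annual means. Two caveats follow. First, the stratified-sampling-plus-jitter
procedure has irreducible Monte Carlo spread: the realized percentile rank
of 8.5 µg/m³ varies with SD ≈ 2.6 points across seeds. Second, the anchors
pin the central density but not the upper tail, and grid-search behavior at
high hazard ratios is sensitive to tail geometry (see Limitations).

## Measurement error

Observed exposure = true + e, with e ~ Normal(0, σ²) truncated to an
absolute ±4 µg/m³ band for every σ ∈ {1, 2, 4}. Draws use the inverse-CDF on
a restricted uniform, so exactly one uniform is consumed per draw and
streams are reproducible. One draw per city per replicate, constant over
years; 100 replicates per σ, generated once and reused across all scenarios
(common random numbers). Observed values are never clamped at zero — only
hinge-transformed covariates enter the models, so small negatives are
harmless.

## Cohort simulation

Deaths in city j, year t among n survivors are Binomial(n, P_jt) with
P_jt = min(1, B_t · h^max(0, PM_j − T)). One binomial per city-year is
identical in distribution to per-individual uniform draws because the
stratum is homogeneous; a literal per-individual simulator is retained and
the equivalence is tested. The min(1, ·) clamp is the only
probability-respecting completion of the multiplicative model and is never
active at the study's parameter ranges. A death contributes a full
person-year in its death year (annual resolution).

One cohort is simulated per (T, h, σ) combination, mirroring the study
design even though σ does not enter the truth; a
`shared_cohort_across_sigma` switch exposes the variance-reduction
alternative. Seeding is hierarchical: a master seed spawns named,
order-independent child streams ("exposure", "errors:σ", "cohort:T,h,σ"), so
adding scenarios never shifts existing streams and error sets stay common
across scenarios within a σ.

## Survival inference

With a single city-level covariate and annual ties, the Breslow partial
log-likelihood is a function of aggregated counts only:

    LL(β) = Σ_t [ β Σ_j d_jt x_j − D_t log Σ_j n_jt e^{β x_j} ]

The fit is a safeguarded 1-D Newton iteration (step-halving; LL is concave).
Convergence requires the score to fall below 1e-8 × the magnitude of the
event-weighted covariate sum — the score's natural scale, so the criterion
is attainable in double precision at any cohort size and reduces to an
absolute 1e-8 on small instances. SE comes from the observed information;
the 95% CI is Wald on the log-hazard scale (z = 1.96). The time axis is
years since enrollment (equivalently age); censoring at 20 years.

Ties: Breslow by default, because it admits the exact aggregated
computation; an Efron variant (`ties="efron"`) exists for sensitivity
checks and is cross-checked against an independent implementation in the
tests. With ~40,000 tied deaths per year the two differ in β̂ only in the
third decimal at this design's effect sizes.

The spline diagnostic computes each city's crude death rate (deaths per
person-year), scales by the rate of the city with the lowest *observed*
exposure (so the reference city can change across error replicates), and
fits relative risk on a natural cubic spline of observed PM with exactly
four basis columns plus intercept: boundary knots at the observed extremes,
interior knots at the 25th/50th/75th percentiles. Natural splines are linear
beyond the boundary knots; this is verified numerically.

## Threshold machinery

The hinge (threshold) and linear (no-threshold) Cox models are non-nested,
so the comparison statistic S = 2·(LL_threshold − LL_null) is compared to
per-parameter information-criterion penalties: 2 (AIC), ln(total deaths),
and ln(enrolled individuals) ≈ 14.509 — the headline, most stringent rule.
The threshold model is charged exactly one extra parameter regardless of how
many candidates the grid search visits; no multiplicity correction is
applied, by design.

The grid search scans T ± 4 µg/m³ in 1-µg/m³ steps (9 candidates), fitting
the hinge Cox model at each; a candidate whose hinge is identically zero is
recorded at the covariate-free log-likelihood (it is exactly the null
model). Ties break toward the smallest candidate; with continuous
likelihoods they have measure zero. The coverage check flags a replicate
when the best fit's CI upper limit on exp(β̂) is strictly below the true h —
one-sided, attenuation only.

## Problem sizes and determinism

The aggregated formulation makes full scale the default: a complete
45-scenario × 100-replicate run (≈ 50,000 Cox fits) takes on the order of a
minute on one core, and each acceptance-style scenario a second or two. A
`desk` preset (2,000 persons/city, 25 replicates) exists for quick
schema-identical runs. Identical (config, seed) pairs reproduce outputs
byte-for-byte; all randomness flows from the master seed through the named
child streams.

## Design choices made where the design was open

- Interpolation acts on q directly, not log q.
- Tabulated q used as-is as annual Bernoulli probabilities.
- Truncation bound is an absolute ±4 µg/m³, not ±4σ.
- RR denominators use person-years with deaths contributing a full year.
- Wald CIs with z = 1.96; quantile knot placement for splines.
- n for the BIC penalties: total simulated deaths, or enrolled subjects.
- Independent cohort streams per scenario combination (switchable).

## Limitations

- The exposure pool and life table are synthetic stand-ins calibrated to
  distributional anchors, not real monitor or registry extracts. Quantities
  driven by the anchored central density (detection power at the boundary
  cells, percentile calibration, all directional/monotone patterns)
  transfer; quantities sensitive to the exposure set's upper-tail geometry
  — notably the exact frequency with which the grid search lands on the
  true threshold at low σ, and coverage counts in borderline cells — can
  shift by tens of replicates between equally plausible tails, so their
  absolute values should be read as tail-conditional.
- Passing tests demonstrate behavior under this idealized design: no
  Berkson error, no confounding, no cohort heterogeneity, no time-varying
  exposure, proportional hazards exactly true. Real-data analyses face all
  of these at once; the simulation isolates one mechanism.
- The spline diagnostic is exploratory (unweighted least squares on crude
  RRs, no confidence bands), matching its role as a visual check.
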