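# Methods

## Scope and model

The package computes prevalence-based health expectancy on abridged
period life tables. The quantity of interest is the expected remaining
years free of a chronic condition for a synthetic cohort exposed to
current age-specific mortality and current cross-sectional prevalence —
the Sullivan estimator. It is a period measure: no cohort is actually
followed, and the method assumes the prevalence schedule is in
(approximate) equilibrium. Incidence, recovery and differential
mortality by health state are not modelled; a population undergoing
rapid epidemiological change will be portrayed with bias that the
Sullivan framework cannot detect internally.

## Life table

* **qₓ conversion.** `ₙqₓ = n·mₓ / (1 + (n − aₓ)·mₓ)`, clamped to 1
  (with a warning) for rates extreme enough to push it above 1. The
  terminal open interval always has q = 1.
* **Separation factor aₓ.** Two interpretations are implemented because
  the literature's shorthand "aₓ = 0.5" is ambiguous:
  * `FRACTION` (default): aₓ = 0.5·n person-years, i.e. deaths at the
    interval midpoint — the convention of standard abridged tables and
    of the practical guides for Sullivan calculations;
  * `YEARS`: a literal 0.5 person-years in every closed interval,
    selectable to probe the literal reading. Both are exposed in the
    config; neither is asserted to be "the" published choice.
* **Terminal closure.** `L(open) = l(open)/m(open)`, the constant-force
  closure; it is the only closure expressible in the same inputs as the
  q-conversion, and the synthetic generator sets the terminal rate to
  the reciprocal of remaining expectancy under its continuous hazard so
  the closure is exact for generated scenarios.
* **Radix** 100,000, configurable; all columns carried at full float
  precision, rounding happens only in display writers.

## Sullivan estimator and uncertainty

`HLEₓ = Σ_{i≥x} Lᵢ(1−πᵢ) / lₓ`. The variance treats each prevalence
cell as an independent binomial proportion and ignores mortality
sampling variation (the standard convention for this estimator; vital
registration denominators dwarf survey cells). Consequences built into
the API:

* a starting age whose own prevalence is an *assumption* (the young-age
  extension below) reports variance NaN — "CI not estimable" — rather
  than a spuriously tight zero-width interval;
* any surveyed cell with 0 < π < 1 but no sample size poisons the
  variance of every starting age at or below it, again yielding NaN;
* the percentage of remaining life with the condition is
  `100·(eₓ − HLEₓ)/eₓ`; in the terminal interval this equals the
  terminal prevalence exactly, for any mortality schedule — a useful
  end-to-end identity test because it survives every upstream
  transformation.

Contrasts between two groups use `z = (HLE_A − HLE_B)/√(Var_A+Var_B)`
with a two-sided normal p-value and star markers at 0.05/0.01/0.001.
A zero standard error with a non-zero difference is flagged degenerate
and reported as signed infinity rather than raising.

## Age conventions

Adult health surveys report from age 18; the life table starts at
birth. The pipeline (a) assigns zero prevalence to ages 0–14, flagged
`assumed` (supported by the very low measured prevalence of both
conditions in children; the flag suppresses CIs there), and (b) maps
the 18–19 survey cell onto the whole 15–19 interval. Both conventions
are logged at INFO level once per run. Age labels of the form "74–79"
(start off by one against a five-year grid) are normalized to the
standard interval by trusting the endpoint.

## Comorbidity coherence

Hard constraint: `both ≤ min(pH, pD)` (strict, up to float epsilon).
The either-series constraints `max(pH,pD) ≤ either ≤ min(pH+pD, 1)`
and the identity `either = pH + pD − both` are enforced within a
tolerance (default 0.005, i.e. 0.5 percentage points) because the two
biomarkers are typically measured on different subsamples of the same
survey, and published tables drift by up to a couple of rounding digits
— including, in one published national table used as a fixture here, a
0.1-point breach of the upper either-bound itself. Within tolerance:
warning; beyond: error. When `either` is absent it is derived by
inclusion–exclusion and flagged as derived in the run log.

## Synthetic scenarios

The generator emulates the statistical structure the analysis assumes,
for testing and calibration studies — it is not fitted to any
microdata.

* **Mortality**: μ(x) = α + β·e^{γx} (Gompertz–Makeham) plus an
  additive infant excess on the first interval; interval rates are the
  time-average of μ. Defaults (α = 1.5·10⁻³ /yr, β = 3.2·10⁻⁵ /yr,
  γ = 0.095 /yr, infant excess 2.2·10⁻² /yr) give e₀ ≈ 72, e(1–4) > e₀
  (the infant hump), and e(15–19) ≈ 60 — a South-Asian national profile
  circa 2018. Sex is a proportional hazard ratio (male 1.15, female
  0.86), giving a female advantage of ≈ 3.9 years at birth.
* **Prevalence**: logistic in age per condition evaluated at interval
  midpoints (terminal at start + 7.5 years), additive sex offsets.
  Defaults approximate a national adult survey: hypertension ceiling
  0.66, midpoint 46 y, steepness 0.075/y, female +3.5 points; diabetes
  ceiling 0.165, midpoint 42 y, steepness 0.09/y, male +1.2 points.
* **Comorbidity overlap** ω ∈ [0,1] interpolates `p_both` between the
  independence product (ω = 0) and full nesting min(pH,pD) (ω = 1);
  default 0.5. All four series are then coherent by construction.
* **Survey noise**: each age-sex cell draws N individuals (default
  N = 500, a plausible DHS biomarker cell size) from the four-category
  joint distribution, so sampled marginals, either and both remain
  exactly coherent.
* **Randomness**: one root seed; survey sampling and microsimulation
  consume disjoint derived streams (`default_rng([stream_id, seed])`),
  so adding draws to one never perturbs the other.

What the generator does **not** emulate: survey design effects
(clustering, weights — cells are simple binomial), age misreporting
and heaping, state-dependent mortality, and trends over time. Tests
passing on synthetic data therefore certify the estimator's arithmetic
and its CI calibration under simple random sampling, not robustness to
real survey complexity.

## Microsimulation oracle

Death ages are drawn from the interval rates treated as
piecewise-constant hazards (terminal: exponential with the open-interval
rate, consistent with the lₓ/mₓ closure); each simulated year lived in
an interval counts as healthy with that interval's true condition-free
proportion. Morbidity is deliberately prevalence-matched rather than an
onset/recovery process, because the question the oracle answers is
whether the Sullivan arithmetic reproduces the expectation it claims to
estimate — not the multistate bias of the method, which is a documented
limitation, not a test target. Two residual discrepancies remain
between the oracle and the analytic table: Monte-Carlo noise
(≈ 0.02 years at cohort 10⁶ for e₀) and the midpoint-death
approximation of aₓ = n/2 against exact exponential waiting times
(≈ 0.03–0.04 years across the default scenario). Their sum stays well
under 0.1 years, the agreement bound used in the tests.

## Problem sizes

The test suite and the acceptance script run the microsimulation at
cohort 10⁶, CI-calibration at 200 survey replicates of cell size 500,
and the brute-force oracle over 100 random schedules — sizes at which
the Monte-Carlo error terms above are comfortably below the asserted
tolerances while the whole suite completes in seconds on one CPU.

## Known limitations

* Period, prevalence-based measure: no recovery, no incidence, no
  health-state-specific mortality; biased under rapid change.
* Mortality sampling variance ignored in CIs (standard, but a real
  approximation when death rates come from small-area samples).
* Chiang-style data-estimated separation factors and rate
  smoothing/graduation are out of scope; rates are taken as given.
* Sub-population life tables use one global aₓ convention per run.
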