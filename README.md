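# sullivan-hle

Abridged period life tables and Sullivan-method condition-free life
expectancy, built for prevalence-based health-expectancy studies of the
kind national statistical offices and DHS-style surveys support: an
age-group × sex × region mortality schedule on one side, survey
prevalences of one or more chronic conditions (here hypertension and
diabetes, singly and jointly) on the other.

## The method

From age-specific central death rates *ₙmₓ* the probability of dying in
an interval of width *n* is

    ₙqₓ = n·mₓ / (1 + (n − aₓ)·mₓ)

with *aₓ* the mean person-years lived in the interval by those dying in
it (default: half the interval). The life table cascades survivors *lₓ*
from a radix of 100,000, accumulates person-years *ₙLₓ* (the open 80+
interval is closed with *Lₓ = lₓ/mₓ*), and yields remaining expectancy
*eₓ = Tₓ/lₓ*.

The Sullivan estimator weights person-years by the cross-sectional
proportion free of a condition, with prevalence *πᵢ* per interval:

    HLEₓ = Σ_{i≥x} Lᵢ·(1 − πᵢ) / lₓ

Its sampling variance treats each prevalence cell as an independent
binomial proportion of size *Nᵢ*:

    Var(HLEₓ) = Σ_{i≥x} Lᵢ²·πᵢ(1 − πᵢ)/Nᵢ / lₓ²

Confidence intervals and group contrasts (male − female, urban − rural,
…) use a normal Z test; significance stars mark p ≤ 0.05 / 0.01 / 0.001.

Four linked prevalence series — each condition, *either*, and *both*
(comorbidity) — are validated against the individual-level constraints
`both ≤ min(pH, pD)` and inclusion–exclusion `either = pH + pD − both`
(the identity is enforced only within a tolerance, since surveys often
measure the two conditions on different subsamples).

The package also ships a synthetic-data module: Gompertz–Makeham
mortality with an infant excess, logistic-in-age prevalence with sex
offsets and a tunable comorbidity overlap, joint binomial survey noise,
and an individual-level microsimulation that re-estimates condition-free
expectancy from simulated lifelines — an oracle that is independent of
the life-table arithmetic.

## Worked example

The packaged fixtures hold a published national adult prevalence table
(hypertension, diabetes, either, both; ages 18–19 through 80+, by sex)
and a synthetic mortality schedule calibrated to a remaining expectancy
of about 60 years at ages 15–19:

```python
from sullivan_hle import (build_life_table, fixture_path, health_expectancy,
                          read_mortality_csv, read_prevalence_csv)
from sullivan_hle.pipeline import extend_prevalence_young_ages

mort = next(m for m in read_mortality_csv(fixture_path("bgd2018_like_mortality.csv"))
            if m.stratum.sex == "total")
lt = build_life_table(mort)

prev = next(s for s in read_prevalence_csv(fixture_path("table1_prevalence.csv"))
            if s.condition == "hypertension" and s.stratum.sex == "total")
het = health_expectancy(lt, extend_prevalence_young_ages(prev))

i15 = lt.grid.index_of(15.0)
print(f"e(15-19)    = {lt.ex[i15]:.1f} years")
print(f"HFLE(15-19) = {het.hle[i15]:.1f} years")
print(f"% of remaining life with hypertension = {het.pct_with[i15]:.1f}%")
print(f"% with hypertension at 80+            = {het.pct_with[-1]:.1f}%")
```

prints

```
e(15-19)    = 60.1 years
HFLE(15-19) = 40.1 years
% of remaining life with hypertension = 33.2%
% with hypertension at 80+            = 63.5%
```

A 15-year-old under these conditions can expect 60.1 further years of
life, 40.1 of them free of hypertension — one third of remaining life
lived with the condition. At 80+ the share equals the 80+ prevalence
itself (63.5%), a structural identity of the Sullivan estimator in the
terminal interval: both remaining person-years and condition-weighted
person-years come from the single open interval, so everything except
the prevalence cancels.

`extend_prevalence_young_ages` applies the study's age conventions
explicitly: prevalence below 15 is assumed zero (flagged so no CI is
produced there), and the 18–19 survey cell stands in for the whole
15–19 interval.

The same analysis over every stratum, with difference tests and
table-shaped CSV output, runs from the command line:

```sh
hle run --config study.yaml
hle lifetable --mortality mortality.csv --out tables/
hle validate --prevalence prevalence.csv
```

## Layout

| module | contents |
|---|---|
| `sullivan_hle.grids` | abridged age grids, strata labels |
| `sullivan_hle.lifetable` | qₓ conversion, life-table construction, mortality CSV I/O |
| `sullivan_hle.sullivan` | Sullivan estimator, variance, CIs, Z contrasts, prevalence CSV I/O |
| `sullivan_hle.comorbidity` | four-series condition sets, coherence validation, inclusion–exclusion |
| `sullivan_hle.pipeline` | age conventions, multi-stratum orchestration, table writers, YAML config |
| `sullivan_hle.synthetic` | scenario generators, survey sampling, microsimulation oracle |
| `sullivan_hle.cli` | the `hle` command |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
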