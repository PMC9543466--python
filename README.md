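# lwfgsim

A stochastic population model for the Lesser White-fronted Goose (*Anser
erythropus*, LWfG) at its northern-Kazakhstan staging grounds, built to ask a
management question: **how much illegal or accidental hunting offtake can the
population absorb before growth turns negative or extinction becomes
likely?** The package also ships the survey-side toolkit used to study the
behaviour behind that offtake — a synthetic-data generator for hunter
surveys, the unmatched count technique (list experiment) estimator with a
design-effect screen, species-protection knowledge scoring, and
AICc-based model selection with natural model averaging.

It is aimed at quantitative ecologists and conservation analysts who want a
reproducible, scriptable version of this class of harvest-sustainability
analysis.

## The population model

The number of geese observed at the staging area evolves year to year
through four processes:

1. survival and return along the flyway:
   `N_{a,t+1} ~ Binomial(N_t, φ)`, where φ is the *return rate*;
2. recruitment: `N_{j,t+1} ~ Poisson(r·F)` with
   `F = ⌊½ p N_{a,t+1}⌋` breeding females, `p ~ Normal(0.5, 0.05)`
   (clamped to [0, 1]) drawn each year, and brood size `r = 1.26`;
3. offtake: `H` birds removed from the combined returned pool
   (adults + juveniles, no age bias), clamped at zero;
4. density dependence: every individual dies with probability
   `ψ = min(1, max(0, (pool − K)/K))`, `K = 250,000`, applied as
   `N_{t+1} ~ Binomial(pool, 1 − ψ)`.

Starting from `N₀ = 32,000` birds, the model sweeps `H` from 0 to 10,000
(step 100) and φ from 0.60 to 0.84, running 100 replicates of the 20-year
management period per scenario, and summarises each scenario by total
growth `(N₂₀ − N₀)/N₀`, mean annual growth `mean{(N_{t+1} − N_t)/N_t}`,
and extinction probability. Smooth response surfaces of the metrics over
(H, φ) are fitted with generalised additive models (Gaussian family for
growth, binomial for extinction; `mgcv` via `Rscript`), from which the
package extracts the zero-growth frontier and extinction-probability
contours, plus a carrying-capacity sensitivity check.

## Worked example

How risky is the estimated accidental offtake from licensed hunting?
The 2017 regional goose quota was 71,240 birds and misidentification of the
protected LWfG among legal quarry runs at roughly 1 per 100:

```python
from lwfgsim import (DemographicParams, run_scenario, extinction_probability,
                     expected_accidental_offtake, QUOTA_2017, MISID_RATE_TYPICAL)

est = expected_accidental_offtake(QUOTA_2017, MISID_RATE_TYPICAL)
print(f"expected accidental offtake: {est.expected_offtake:.1f} birds/year")

rec = run_scenario(DemographicParams(phi=0.71), offtake=700, replicates=100, seed=0)
print(f"mean 20-year growth:  {rec.growth_total.mean():+.3f}")
print(f"mean annual growth:   {rec.mean_annual_growth.mean():+.3f}")
print(f"extinction probability: {extinction_probability(rec):.2f}")
```

```
expected accidental offtake: 712.4 birds/year
mean 20-year growth:  -0.989
mean annual growth:   -0.196
extinction probability: 0.44
```

At a return rate of 0.71, an offtake of ~700 birds/year — just the
*accidental* kill implied by the quota — drives the population down by 99%
over 20 years and makes outright extinction a coin flip: sustainability
depends critically on survival conditions along the rest of the flyway.

The same analysis from the shell:

```bash
lwfgsim sweep --out metrics.csv --summary summary.csv
lwfgsim surfaces --metrics metrics.csv --out surfaces/
lwfgsim risk --quota 71240 --rate 0.01 --metrics metrics.csv
```

## Survey toolkit

`generate_respondents` / `generate_uct_responses` synthesise a hunter
survey with the study population's structure (166 male respondents, 46
sites, 42% licence ownership, 80:109 control/treatment split).
`uct_prevalence` estimates the prevalence of the sensitive behaviour as
the treatment-minus-control difference in mean item counts;
`design_effect_check` is a parametric-bootstrap screen for violations of
the list-experiment assumption; `knowledge_score` scores the five-species
protection quiz; `aicc_top_set` and `natural_model_average` implement
ΔAICc < 4 top-set selection and natural-method coefficient averaging over
mixed-model fit summaries.

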