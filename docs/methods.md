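# Methods

## Population model

The model is a scalar stochastic process for the LWfG count at the
northern-Kazakhstan staging area, observed once per year over a 20-year
management horizon. One year composes four stages:

| stage | distribution | parameters |
|---|---|---|
| survival & return | `N_a ~ Binomial(N_t, φ)` | φ ∈ [0.60, 0.84] |
| recruitment | `N_j ~ Poisson(r·⌊½ p N_a⌋)` | `p ~ N(0.5, 0.05)`, `r = 1.26` |
| offtake | `pool = max(N_a + N_j − H, 0)` | `H ∈ [0, 10,000]` |
| density dependence | `N_{t+1} ~ Binomial(pool, 1 − ψ)` | `ψ = clamp((pool − K)/K, 0, 1)`, `K = 250,000` |

Assumptions worth making explicit:

* **Additive mortality.** Flyway mortality (in φ) and hunting mortality
  (H) are additive; offtake is removed after all birds have returned.
* **Independent fates.** Binomial survival assumes individuals live or die
  independently; no catastrophes, disease outbreaks or correlated weather
  effects.
* **No age structure beyond recruitment.** All survivors become adults the
  following year; first-year and adult survival are conflated in φ.
* **Uniform harvest.** Offtake does not distinguish adults from juveniles
  (the hunted flock contains both, since juveniles accompany returning
  adults). Removal happens before density thinning, and ψ is evaluated on
  the post-offtake pool; a switch (`psi_before_offtake`) evaluates it
  pre-offtake instead — at these parameter values the two are
  indistinguishable because ψ > 0 only near K, which harvested populations
  never approach.
* **Interannual breeding variation.** The breeding proportion p is redrawn
  every replicate-year (switch `p_redraw="per_replicate"` holds one draw
  per trajectory instead). Draws are clamped to [0, 1]; at (0.5, 0.05)
  clamping is a ~1e-23 event.
* **Absorbing extinction.** A count of zero stays zero.

Useful closed forms: below K the conditional expectation is linear,
`E[N_{t+1} | N_t = n] ≈ φ n (1 + ½ p̄ r) − H` (exact up to the floor in
the breeding-female count), so the per-year factor is `λ = 1.315·φ`
(λ = 0.789 at φ = 0.60, 1.1046 at φ = 0.84). The deterministic recursion
`N ← λN − H` gives the zero-growth offtake `H* = N₀(λ − 1)` (≈ 3,347 at
φ = 0.84) and extinction within the horizon whenever `H > H*·λ^T/(λ^T − 1)`.
These oracles anchor the test suite.

One subtlety the deterministic oracle misses: at φ = 0.84 and H = 0 a
minority of replicates brush the carrying capacity before year 20, so the
Monte-Carlo mean growth (~6.14) sits slightly below the pure
branching-process value `λ²⁰ − 1 = 6.31`. This is a real feature of the
capped process, not sampling error.

## Scenario sweep and seeding

The default grid is 101 offtake levels × 13 return rates (φ step 0.02,
chosen to give the φ axis a density comparable to the offtake axis; the
study states only the range) × 100 replicates = 131,300 trajectories
(~2 s on one CPU). Each cell's random stream is
`SeedSequence([base_seed, phi_index, offtake_index])`, so cells are
statistically independent, any cell can be re-run in isolation, and the
whole table is bit-reproducible across runs and platforms.

Per-replicate metrics: total growth `(N_T − N₀)/N₀` (−1 exactly iff
extinct at the horizon), mean annual growth over years with `N_t > 0`
(the yearly rate is undefined at `N_t = 0`, and padding with −1/0 would
bias the mean, so post-extinction years are excluded), and the extinction
flag.

## Response surfaces

Surfaces of each metric over (offtake, φ) are fitted with `mgcv` GAMs
(Gaussian family on per-cell replicate means for the growth metrics;
binomial with extinct/survived counts for extinction probability),
driven through `Rscript`. Two smoother specifications are exposed:

* **tensor product** `te(offtake, phi)` — the default. The two covariates
  differ in scale by five orders of magnitude (birds vs. probability), so
  an isotropic smooth is inappropriate; a tensor-product smooth is
  invariant to axis rescaling. Marginal basis dimensions default to
  (15, 8), capped at the number of grid levels, with GCV smoothness
  selection (typical effective degrees of freedom ~110 on the full grid,
  fit RMSE ~0.1 against cell means).
* **isotropic thin plate** `s(offtake_std, phi_std)` on standardised
  covariates, for comparison. On this surface GCV selects very heavy
  smoothing (edf ≈ 7–14), flattening the steep growth cliff: it predicts
  ~0.8 at the (H = 0, φ = 0.84) corner where the raw cell mean is ~6.1.

Every fit records its engine, smoother, basis dimensions and edf as
provenance, because **surface-derived thresholds are smoother-dependent**:
the zero-growth frontier and extinction contours read off a smooth can
differ materially from raw-grid crossings when the surface is this steep.
For that reason the package always computes raw (cell-mean) thresholds
alongside smoothed ones (`empirical_zero_growth_frontier`,
`empirical_extinction_threshold`), and the tensor default was chosen
because its predictions track the cell means (the quantity the surface is
supposed to summarise) rather than flatten them. With the tensor smooth,
the smoothed frontier at φ = 0.84 lands within ~1% of the deterministic
fixed-point oracle `H* ≈ 3,347`.

Contours and frontiers are extracted by linear interpolation between
adjacent prediction-grid points (grid resolution 100 birds; no
root-polishing below that), and predictions are only made on the training
grid's hull — never extrapolated. A φ whose predicted growth is already
non-positive at H = 0 has no frontier (NaN); the global frontier is the
maximum per-φ threshold, or 0 when growth is negative everywhere.

The K-sensitivity check re-runs a reduced sweep at K ∈ {125k, 250k, 500k}
and recomputes the thresholds: because harvested populations near the
frontier never approach the capacity, the frontier moves by only a few
birds (far less than one grid step), while the zero-offtake growth corner
is visibly capped at K = 125,000. This separation — thresholds insensitive,
corner sensitive — is the expected signature of purely supra-K density
dependence.

## Offtake risk

Expected accidental offtake is quota × misidentification rate. The
published rates are 1–3 protected birds per 100 legal geese, with a local
extreme of 1 per 20–30; constants encode the extreme at its upper end
(1/20, which matches the reported "up to ~3,500 in the extreme" for a
71,240-bird quota better than 1/30 does), and the typical rate at 1/100
(712.4 ≈ "~700"). Classification against the sweep looks up the nearest
simulated offtake and labels each φ *growing* (positive mean growth),
*extinction-risk* (extinction probability ≥ 0.5 by default) or
*declining*.

## Synthetic survey and list-experiment analysis

The generator emulates the study's survey *structure*, not its people:
166 male respondents over 46 sites, licence shares (58% none / 9% single /
33% goose-and-duck — i.e. 42% licensed with goose-and-duck most common),
five-species protection-knowledge marginals (the LWfG marginal follows the
published male breakdown: 65.1% correct / 6.6% wrong / 28.3% don't know;
the other four species use plausible synthetic values), and simple
demographic distributions (truncated-normal age, binomial months employed,
Poisson household employment). Goose-hunting propensity is latent and
licence-dependent (5% / 55% / 80% by licence class), giving ~34% true
prevalence. None of these choices affect the *correctness* of the
estimators — only the regimes in which they are exercised — and all are
configurable.

UCT responses: control counts are sums of four independent non-sensitive
item indicators with default endorsement probabilities (0.35, 0.10, 0.15,
0.30) — never published, so chosen to give a mid-range control mean —
and treatment counts add the sensitive indicator. Per-question sensitive
rules default to compliance (hunters endorse for "past year" and
"autumn/winter" only; nobody for "spring/summer" or "for cash"),
overridable to simulate non-compliance. Item indicators are drawn
independently across the four questions, a simplification: real
respondents' period-specific answers would be correlated.

The prevalence estimator is the difference in group means with the
two-sample variance formula and a normal CI. The design-effect check is a
deliberately simplified screen (distinct from the published
likelihood-ratio item-count test): under the null, treatment counts are
the control distribution convolved with Bernoulli(θ̂); the statistic is
the sup-distance between the observed treatment CDF and that convolution,
with a parametric bootstrap (re-estimating θ̂ per resample) for the
p-value. Its type-I error at n = 400 is calibrated (0.03–0.07 at α = 0.05
over 1,000 simulations). A limitation follows from the null itself: any
violation that only shifts the treatment mean — e.g. a uniform inflation
of one non-sensitive item — is absorbed into θ̂ and is undetectable by
construction (the residual CDF gap is <0.01); the screen has power only
against shape-distorting violations such as evasive zero-reporting, where
measured power is ~0.95 at n = 400.

Model selection and averaging operate on fit summaries (term set, AICc,
coefficients) rather than on fitted model objects: the mixed-model
machinery itself (site random intercepts, bootstrap CIs) is standard and
left to whatever estimation engine produced the summaries. The top set is
all models strictly within ΔAICc < 4 of the best; natural-method
averaging weights each coefficient by Akaike weights renormalised over
only the models containing that term, so a term appearing in one model
keeps its coefficient unchanged.

## Problem sizes and numerical choices

The default sweep (131,300 twenty-year trajectories) runs in ~2 s and a
full-grid GAM fit in ~5 s, so the headline results are recomputed from
scratch on every run of `scripts/acceptance.py`. Reduced sweeps used in
tests (coarser offtake axis, 3 φ levels, 40–50 replicates) preserve the
frontier geometry at every included φ. Monte-Carlo assertions use 2–3
standard-error tolerances; monotonicity checks allow ties because cells
past certain extinction are exactly −1 with zero variance. Counts are
64-bit integers throughout; growth metrics are floats; no trajectory value
is ever negative or fractional.

## Known limitations

* φ conflates survival and site fidelity; a bird that survives but stages
  elsewhere counts as dead.
* No demographic structure (age, sex ratio fixed at 50%), no spatial
  structure, no environmental autocorrelation — variance is likely
  understated, so extinction risk at a given offtake is, if anything,
  conservative.
* Surface-derived thresholds inherit the smoother choice; report them with
  their provenance and alongside raw-grid crossings.
* The synthetic survey reproduces marginal structure, not the joint
  behavioural correlations of real respondents; passing estimator tests
  demonstrates statistical correctness of the procedures, not conclusions
  about any real population of hunters.
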