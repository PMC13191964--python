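# Methods

## The model

`lbwsae` estimates district-level prevalence of low birth weight (LBW, birth
weight < 2500 g) from nested cluster-survey microdata. The observation model
is a four-level random-intercept logistic regression. For birth *i* in
cluster *j*, district *k*, state *l*:

```
Y_ijkl ~ Bernoulli(p_jkl)
logit(p_jkl) = beta0 + u_jkl + v_kl + f_l
u_jkl ~ N(0, sigma2_u)    between clusters within a district
v_kl  ~ N(0, sigma2_v)    between districts within a state
f_l   ~ N(0, sigma2_f)    between states
```

There are no covariates, so all births in a cluster share one success
probability and the likelihood reduces *exactly* to per-cluster binomial
sufficient statistics (y_j successes of n_j births). All samplers and the
likelihood evaluator operate on those statistics; this is a reformulation,
not an approximation, and is what makes simulation studies at a few hundred
thousand births cheap.

The cluster-level predicted probability is the posterior mean of
`invlogit(beta0 + u + v + f)` over MCMC draws. Because the multilevel
posterior pulls a sparsely observed cluster's intercept toward its parent
means in proportion to the information in its data, this is a
precision-weighted (shrinkage) estimate. District prevalence is the
unweighted mean of member clusters' probabilities, in percent; no survey
design weights enter anywhere (the estimator is deliberately unweighted).

## Priors and sampling

* `beta0`: improper flat prior. Variances: InverseGamma(0.001, 0.001),
  the long-standing default of the multilevel-modelling software family
  this analysis style comes from. Both are overridable in `FitConfig`.
* Default sampler (`"mh"`): Metropolis-within-Gibbs. Adaptive random-walk
  MH for `beta0`; element-wise vectorised random-walk MH for each residual
  level (units within a level are conditionally independent); conjugate
  inverse-gamma Gibbs updates for variances. In addition, one
  likelihood-invariant *translation move* per level proposes shifting mass
  delta between `beta0` and an entire residual vector; it is accepted on the
  Gaussian prior ratio alone. Without it the intercept performs a slow random
  walk against the sum of ~30 state intercepts; with it the intercept chain
  reaches effective sample sizes of several hundred per 2000 draws at the
  reference design. Proposal scales adapt toward 0.44 acceptance with a
  decaying Robbins–Monro step during burn-in only, so retained draws form a
  valid Markov chain.
* Cross-check sampler (`"pg"`): full Gibbs via exact Pólya-Gamma data
  augmentation. The PG(1, z) draw uses the alternating-series rejection
  sampler (exponential and inverse-Gaussian proposals split at t = 0.64),
  implemented in `lbwsae/pg.py` and verified against the closed-form mean
  `tanh(z/2)/(2z)`; PG(n, z) sums n independent PG(1, z) draws. It is exact
  but scalar, intended for modest instances; both samplers must agree with
  the deterministic quadrature oracle (below), and do.
* Starting values: `beta0` at the logit of the pooled prevalence (clamped
  away from 0/1), variances at 0.1, residuals at 0. A preliminary
  frequentist fit would only change how fast the chain reaches
  stationarity, never the posterior, so it is not implemented.
* Defaults: 500 burn-in, 5000 kept iterations, thin 1. Chains are
  reproducible given a seed, and input row order is irrelevant because
  units are canonicalised by sorted identifier.
* Variance components can be pinned via `FitConfig.fixed_sigma2`; pinning
  to 0 removes a level. This supports reduced models whose posterior is
  low-dimensional enough for deterministic verification.

## Verification strategy

* **Quadrature oracle.** For one state/district with two or three clusters
  and fixed `sigma2_u`, the posterior over (beta0, u_1..u_K) is integrated
  on a dense tensor grid (`lbwsae/quadrature.py`). MCMC posterior means must
  match within 3 Monte-Carlo standard errors (MCSE from arviz effective
  sample size). The oracle shares nothing with the samplers beyond the
  Bernoulli likelihood formula.
* **Parameter recovery.** 20 replicates of a 30-state x 10-district x
  20-cluster x 25-birth design with truth beta0 = -1.5, variances
  (0.30, 0.20, 0.15), fitted with 500 + 2000 iterations: 95% credible
  intervals must cover truth in at least 15/20 replicates per parameter and
  mean intercept bias must stay below 0.1. Observed: 18–20/20 coverage,
  |bias| ≈ 0.02.
* **Degenerate limit.** With all true variances 0 the model must collapse:
  every fitted district prevalence within ±1.0 pp of
  100·invlogit(-1.5) = 18.24%. The check uses 50 districts x 30 clusters x
  220 births (330k births); at this size the worst district deviates by
  roughly 0.4–0.85 pp depending on seed. Smaller designs leave enough
  binomial noise that the worst of 50 districts can brush past 1 pp, which
  is a sample-size effect, not a estimator defect.
* **Diagnostics.** `diagnose()` reports arviz effective sample size and
  split-chain R-hat per scalar parameter, flagging ESS < 100 and degenerate
  (constant) chains. The ESS integration is itself tested against the AR(1)
  closed form n(1-rho)/(1+rho).

## Change analytics conventions

* Prevalences are rounded to 2 decimals (half away from zero) **before**
  differencing, so changes are exact multiples of 0.01; banding is done on
  integer hundredths. The published national table's change column (e.g.
  18.24 − 18.21 = +0.03) reproduces only under this convention.
* Seven bands partition the rounded line: ≤ −5.00, −4.99..−3.00,
  −2.99..−1.00, −0.99..0.99, 1.00..2.99, 3.00..4.99, ≥ 5.00. The bottom
  band is closed at −5.00 to mirror the open-ended top band; otherwise the
  printed labels would leave a gap at exactly −5.00.
* Band-table percentages are 2-dp rounded shares of the group total; the
  ">3-point" aggregates sum the two extreme *rounded* percentages per side.
  This reproduces the published 18.05 (= 9.44 + 8.61) where raw count
  arithmetic gives 130/720 = 18.06.
* Quartiles use linear interpolation between order statistics (the default
  of mainstream statistical software); IQR = Q3 − Q1.
* Quadrant classification ties go to the lower side; cutoffs default to
  the medians of each axis and are user-configurable.
* Districts present in only one wave are excluded from change analytics
  (reported in `attrs["unmatched"]`) but remain in single-wave summaries.
* The state→region fixture maps the 36 Indian states/UTs to six regions
  (North, North-East, South, East, West, Central). The ADP fixture has
  exactly 117 district slots; because the real programme's district list is
  not bundled, the shipped file is a synthetic stand-in keyed to the
  generator's India preset (`adp_districts.synthetic.csv`) — replace it for
  real analyses.

## The synthetic generator

`generate_survey` draws state, district and cluster intercepts from the
three normal components, Bernoulli outcomes per birth, and then masks
outcomes missing-completely-at-random at a single configurable rate
(default 0.15, between the roughly 25% and 10% incomplete-outcome rates of
the two real survey rounds). Defaults emulate the real frame: ~30 states,
~24 districts per state, 20–40 clusters per district, 10–40 births per
cluster (cluster-size distributions are not published; these are uniform
placeholders exposed in the config). The India preset uses the real 36
state/UT names with 20 districts each (720 total; real per-state counts
are not bundled) so the packaged region map applies end-to-end.

Ground-truth effects go to a sidecar `*.truth.csv`, never the survey file,
so fitting code cannot read truth. Waves are generated independently —
fresh clusters *and* fresh random effects per wave. Passing tests therefore
demonstrate correct recovery and aggregation arithmetic, **not** realistic
between-wave persistence: real district prevalences correlate strongly
across rounds, while two independently simulated waves correlate near zero,
and simulated change-band tables are correspondingly wider than real ones.
The generator also does not emulate design weights, informative missingness,
boundary changes between waves, or recall-error in reported birth weight.

## Pipeline and reproducibility

`run_pipeline` chains exclusions → per-wave fit → cluster/district
estimates → change analytics, writing CSV/JSON artefacts and a manifest
(config echo, per-stage seeds, row counts, acceptance rates, diagnostics).
Every stage's seed derives from one root seed via
`blake2b(f"{root}:{stage}") mod 2^31`, so any stage re-runs reproducibly in
isolation; re-running an unchanged config reproduces every numeric output
byte-for-byte (single-threaded reduction order), with only the manifest
timestamp differing.

## Known limitations

* MCAR missingness only; the complete-case step is unbiased under the
  generator but would not be under informative missingness.
* No covariates, no survey weights, and no spatial smoothing — by design,
  matching the estimator the package implements.
* The PG cross-check sampler is scalar Python and impractical beyond a few
  hundred clusters; the default MH sampler is the scalable path.
* District realignment between waves is handled only through a
  user-supplied cluster→district crosswalk; no geometry is computed.
* The quadrature oracle is limited to ≤ 3 clusters (tensor-grid cost).
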