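# Methods

## The model

The unit of analysis is one paired cover-crop / fallow comparison. The
effect size is the log response ratio `ESᵢ = ln(X̄_CC,i / X̄_NCC,i)`;
logging symmetrises increases and decreases and makes the effect
independent of measurement units, so leaching (kg N ha⁻¹) and drainage
(mm) are handled identically. Because most field reports state means
without dispersion, the sampling variance is the nonparametric
`vᵢ = (n_CC + n_NCC)/(n_CC·n_NCC)`, a function of replicate counts only:
an unreplicated comparison gets v = 2, a 4+4-replicate one v = 0.5.
This is a precision proxy, not an estimated variance — it ranks studies
by replication effort rather than by observed noise.

True effects are assumed to vary across observations (a random-effects
model): `ESᵢ = θᵢ + εᵢ`, `θᵢ ~ N(μ, τ²)`, `εᵢ ~ N(0, vᵢ)`. Observations
from the same article are treated as independent, matching the
compilation convention the pipeline is built for; the generator has an
optional article-level variance component for sensitivity work, off by
default.

### Estimators and inference

* Cochran's `Q` with fixed-effect weights `wᵢ = 1/vᵢ`, df = k − 1,
  upper-tail chi-square p (defined as 1 at df = 0). The conventional
  significance level for heterogeneity is .10 because the Q test is
  low-powered; the level is a reporting convention only and is
  configurable.
* `I² = max(0, (Q − df)/Q·100)`, truncated to exactly 0 when Q ≤ df or
  Q = 0.
* `τ²` by DerSimonian–Laird, `max(0, (Q − df)/C)`, `C = Σw − Σw²/Σw`.
  DL (the method-of-moments one-step estimator, and the default of the
  mainstream commercial meta-analysis package) is used for pooling and
  subgroup tables; REML is reserved for meta-regression, where the
  profiled likelihood is well-behaved in one dimension.
* Pooling with weights `1/(vᵢ + τ²)`; CIs and p-values use the standard
  normal reference (multiplier 1.959964 at 95%); no Knapp–Hartung
  adjustment in pooling, matching z-style intervals.
* Subgroup tables: per-level Q/df/p/I² with fixed-effect weights;
  `Q_within = Σ level Q`; `Q_between = Q_overall − Q_within` with
  df = #levels − 1. This subtraction form is exact in full precision
  (floating-point discrepancies are clipped at 0) and reproduces the
  additive rows of a classical moderator table. Per-level pooled
  summaries use a level-specific DL τ² by default; `tau2_mode="pooled"`
  shares the overall τ² across levels for users who prefer the
  mixed-effects convention. Levels require support from ≥ 3 distinct
  articles and ≥ 2 surviving levels; when article identifiers are wholly
  absent the rule degrades to ≥ 3 observations, with a warning.
* Begg–Mazumdar: standardized deviates
  `tᵢ = (ESᵢ − ĒS_fixed)/√(vᵢ − 1/Σw)` are rank-correlated with the vᵢ.
  Kendall's τ-b (tie-corrected denominator) is essential here: Eq.-type
  variances tie massively (every n = 1/1 row shares v = 2). The normal
  approximation for S uses the tie-corrected variance — the familiar
  `k(k−1)(2k+5)/18` plus tie terms — with a ±1 continuity correction;
  with heavy ties the uncorrected variance would make the test badly
  conservative. |τ| < 0.20 is flagged as no material asymmetry.
* Meta-regression: τ² maximises the restricted likelihood, profiled over
  `[0, 10·Var(ES)]` with a bounded scalar minimizer at tolerance 1e-8
  (robustness over speed for a 1-D problem); a τ²-grid search at 1e-4
  resolution serves as an independent oracle in the tests. Coefficients
  are WLS at the REML τ², uncentered (the intercept is the expected
  ln-ratio at covariate zero); the model test is the Wald chi-square of
  the slope (df 1). Knapp–Hartung (scaled covariance, t reference) is
  available behind a flag. Rows missing the covariate are dropped from
  that regression only.

### Degenerate inputs and tie-breaks

Q = 0 and Q ≤ df truncate I² and τ² to exactly 0. k = 1 pools to the
single effect with τ² = 0 and se = √v. A fully tied variance ranking
defines τ = 0 with a warning. Non-positive means are rejected at
ingestion (the log ratio is undefined); blank replicate counts impute 1,
the convention for unreplicated overall means.

## The synthetic-data generator

`generate(SimConfig)` draws tables from exactly the assumed model: level
means additive across moderators plus centered covariate slopes, an
N(0, τ²) observation-level deviation, a log-normal control mean, and a
multiplicative error with variance vᵢ implied by the drawn replicate
counts. The shipped leaching default mirrors a 41-article compilation:
14–40 observations per article (≈1100 rows), five families with nonzero
means only on family (ratios 0.25–1.0), twelve genera nested within
family, six soil orders, eight textures, eleven main crops and three
tillage systems drawn at the compiled marginal shares (with realistic
missingness for soil order, main crop and tillage), ~60% unreplicated
rows, rainfall uniform on 300–1400 mm and temperature on 4–18 °C with
zero slopes. The drainage default uses ratios near 1 and τ² = 0,
matching a response with no detectable effect or heterogeneity.

Design choices worth knowing:

* Heterogeneity is injected per observation, not per article, because
  observations are treated as independent downstream; `sigma2_article`
  exists for sensitivity studies.
* Moderator labels are masked *after* the true effect is drawn, like an
  unreported soil type in real data. Consequently a masked family also
  masks the genus; nonzero genus-level means combined with family
  missingness would make the genus truth bookkeeping approximate, so the
  defaults keep genus means at zero.
* Covariate slopes act on covariates centered at the range midpoint, so
  configured level means remain the level truths when slopes are on.
* Marginal τ² as seen by the overall pooled analysis equals the
  configured τ² plus the variance of the systematic mean structure;
  `recovery_report` accounts for this when comparing.

What the generator does not emulate: correlated effects within articles,
publication selection (a hook, deliberately unimplemented), non-normal
effect distributions, covariate–moderator confounding, and reporting
quirks like digitisation error. Passing recovery tests therefore
demonstrate that the estimators are correct under the assumed model, not
that the model captures every feature of a real literature compilation.

## Problem sizes in the tests

The suite checks the estimators at sizes a desk machine handles in
seconds: level-mean recovery on a 2000-row table (±3 percentage points),
DL bias over 2000 replicates of k = 50, CI coverage over 2000 replicates
of k = 30, meta-regression recovery over 500 replicates of k = 500, and
the Begg null over 2000 replicates of k = 40; the law-of-large-numbers
variance check uses one 10⁵-row table. These sizes make Monte-Carlo error
small relative to each tolerance while keeping the default test run
fast.

## Known limitations

* The nonparametric variance ignores observed dispersion even when a
  study reports it; no per-row variance column exists in the schema.
* No small-sample bias correction is applied to ln R.
* Between-group inference uses the fixed-weight subtraction Q, which is
  exact algebraically but, like all Q-based tests, approximate in
  distribution under heterogeneity.
* Robust (cluster-aware) variance estimation is out of scope by design;
  treat article-level dependence with the generator's sensitivity hook.
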