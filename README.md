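# ccmeta

Random-effects meta-analysis of paired cover-crop field comparisons.

Cover crops — crops grown between cash-crop cycles to protect the soil —
can intercept nitrate before it leaches below the root zone. Field trials
report this as a pair of means: nitrate leaching (kg N ha⁻¹) or water
drainage (mm) under a cover crop (CC) and under bare fallow (NCC).
`ccmeta` implements the full analysis pipeline such a compilation needs,
for agronomists and biogeochemists synthesising paired CC/NCC trial data:

* **Effect sizes** — the log response ratio `ES = ln R = ln(X̄_CC / X̄_NCC)`,
  weighted by the nonparametric variance
  `v = (n_CC + n_NCC)/(n_CC·n_NCC)` (replicate counts only; most field
  reports omit dispersion), back-transformed to `%Change = 100·(e^ES − 1)`.
* **Heterogeneity and pooling** — Cochran's `Q = Σ wᵢ(ESᵢ − ĒS)²`,
  `I² = max(0, (Q − df)/Q·100)`, DerSimonian–Laird
  `τ² = max(0, (Q − df)/C)` with `C = Σw − Σw²/Σw`, and the
  random-effects pooled mean with weights `1/(vᵢ + τ²)` and normal 95% CIs.
* **Subgroup (moderator) analysis** — exact partition
  `Q_overall = Q_within + Q_between` across the levels of a categorical
  moderator (cover-crop family/genus, soil order, soil texture, main crop,
  tillage), with per-level pooled summaries; levels enter only when backed
  by ≥ 3 articles.
* **Publication bias** — Begg–Mazumdar rank correlation (tie-corrected
  Kendall τ-b with continuity correction) between standardized effects and
  their variances, plus funnel-plot data export.
* **Meta-regression** — single-covariate mixed model
  `ESᵢ = β₀ + β₁xᵢ + uᵢ + εᵢ`, `uᵢ ~ N(0, τ²)`, `εᵢ ~ N(0, vᵢ)`, with τ²
  by restricted maximum likelihood, for rainfall and temperature.
* **Synthetic data** — a generator that draws observation tables from
  exactly this model with known truth, so every stage is testable without
  a literature extraction.

## Worked example

```python
from ccmeta import default_config, generate, run_analysis

obs = generate(default_config("nitrate_leaching"), seed=1)
run = run_analysis(obs, moderators=["cc_family"])
p = run.overall_pooled
print(f"k={p.k}  tau2={p.tau2:.3f}  pooled %change={p.pct_change:.1f}%")
print(run.tables["cc_family"].rows[["level", "n", "I2", "pct_change"]])
```

prints

```
k=1087  tau2=0.420  pooled %change=-59.0%
          level    n         I2  pct_change
0       Poaceae  631  25.392996  -55.123257
1   Multigenera  109  17.427002  -52.582136
2  Brassicaceae  239  19.350751  -76.243225
3   Leguminosae   94  24.287745  -40.714493
4    Asteraceae   14  32.377764   53.768386
```

The synthetic table was generated with family-level true reductions of
52% (Poaceae, mixtures), 75% (Brassicaceae), 40% (legumes) and 0%
(Asteraceae) with τ² = 0.3 between-observation heterogeneity; the pooled
table recovers them within Monte-Carlo error (the tiny Asteraceae level is
the noisy one). `examples/` contains one short script per capability:
effect sizes, pooling, subgroup tables, bias testing, meta-regression and
truth-recovery reports. A thin CLI wraps the same calls:

```sh
ccmeta simulate --response nitrate_leaching --seed 42 --out obs.csv
ccmeta analyze --input obs.csv --response nitrate_leaching --out run1/
ccmeta bias --input obs.csv --response nitrate_leaching --out run1/
ccmeta metareg --input obs.csv --response nitrate_leaching --covariate rainfall_mm --out run1/
```

Input CSVs carry one row per paired comparison with the columns
`article_id,obs_id,response,mean_cc,mean_ncc,n_cc,n_ncc,cc_family,cc_genus,
soil_order,soil_texture,main_crop,tillage,rainfall_mm,temp_c`; blank
replicate counts are imputed as 1 (the convention for unreplicated
reports) and blank moderator cells keep the row in the overall analysis
while excluding it from that moderator's subgroups.

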