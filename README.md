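# rivertrends

Trend analysis for riverine fish community time series.

Freshwater fish communities are being reorganized by decades of human
pressure — land use, infrastructure, introductions of non-native
species. Long-running electrofishing surveys record who was caught
where, year after year, but turning those records into defensible
statements like *"composition is turning over by X% per decade, fastest
in historically degraded, downstream reaches"* takes a full pipeline:
strict series selection, community-change metrics, hierarchical trend
models that respect the nesting of sites within river basins, pressure
covariates, and a typology of site trajectories. `rivertrends`
implements that pipeline end to end, with a synthetic-data module so
every stage is testable against known ground truth.

## What it computes

**Metrics per site-year** (against the site's first sampled year):
total abundance; raw and coverage-standardized species richness
(rarefaction/extrapolation to a fixed 98.5% sample coverage, with
pseudo-counts for density/CPUE data); non-native shares of abundance and
richness; Jaccard dissimilarity `J = (S_gain + S_loss)/S_tot` with its
turnover/nestedness partition
`J_t = 2·min(S_gain, S_loss)/(S_common + 2·min(S_gain, S_loss))`,
`J_n = 1 − J_t`; and an abundance-weighted Simpson-based dissimilarity
`H_d = Σ(p_i − p'_i)² / (Σp_i² + Σp'_i² − Σp_i p'_i)`.

**Trend models.** Each metric follows a Gaussian hierarchical model

    Y_{i|n,t} = α + β₀·log(t + 1) + ε,
    α  = α₀ + a_n + a_{i|n},   β₀ = μ + b_n + b_{i|n},

with random intercepts and time-slopes at the basin (n) and
site-within-basin (i|n) levels, fitted by a blocked Gibbs sampler with
N(0, 1000) priors on fixed effects and Gamma(1, 5·10⁻⁵) priors on
precisions. A driver variant adds three covariates — past human
footprint, recent footprint change (log₂ 2009/1993 ratio) and a
varimax-rotated upstream–downstream axis — as main effects plus two- and
three-way interactions with time. Outputs: per-site trends
(posterior means of μ + b_n + b_{i|n}, back-transformed to % per
decade), evidence tiers from 80/90/95% HPD intervals, marginal and
conditional R², WAIC, VIFs, and baseline (t = 0) predictions and
contrasts.

**Typology.** PCA over the per-site trends in four metrics, then
trimmed k-means (k = 6, 5% trimming) with an affiliation filter that
leaves ambiguous sites unassigned, and cluster frequency tables by
biogeographic realm.

## Worked example

Simulate a survey with known structure, compute metrics, and fit the
abundance trend model:

```python
from rivertrends.simulate import SimConfig, simulate_communities
from rivertrends import io, metrics, HierarchicalTrendModel

cfg = SimConfig(n_basins=12, sites_per_basin=5, n_years=12)
records, covariates, origin, truth = simulate_communities(cfg, seed=1)
records["origin"] = io.lookup_origin(records, origin)

table = metrics.metrics_table(records)
fit = HierarchicalTrendModel(spec="total_abundance", n_chains=2,
                             n_draws=500, n_warmup=500, seed=1).fit(table)
print(fit.global_trend())
print(fit.site_trends().head(3))
```

prints

```
{'response': 'total_abundance', 'slope_mean': 0.042,
 'trend_per_decade': 11.036, 'evidence': 'none', 'unit': 'percent',
 'hpd80_lo': -1.87, 'hpd80_hi': 23.284, ...}
    site_id basin_id  slope  trend_per_decade
0  B000S000     B000 -0.016            -3.658
1  B000S001     B000 -0.063           -13.926
2  B000S002     B000  0.162            47.395
```

The generator's default multiplicative drift corresponds to a true
+12.7% abundance change per decade; the fitted average is +11.0% with a
95% HPD of (−2.8, +31.8) — at 60 sites the sign is right but the
evidence tier is honestly `none`, while individual site trends spread
widely around the average, which is exactly the heterogeneity the
random-slope structure is there to capture.

The same pipeline runs from the shell:

```bash
rivertrends run-all --seed 42 --out results/
rivertrends simulate --seed 1 --out sim/          # survey + ground truth
rivertrends filter --survey sim/survey.csv --covariates sim/covariates.csv
rivertrends metrics --survey sim/survey.csv --origin sim/origin.csv
```

`run-all` writes every intermediate table (filter audit, metrics,
drivers, coefficient and trend tables, cluster assignments) plus
per-metric trend histograms.

## Layout

| module | contents |
| --- | --- |
| `rivertrends.io` | survey/covariate/origin CSV readers, dialects, round-trip writers |
| `rivertrends.filtering` | protocol/seasonal/annual selection cascade, audit log, series summaries |
| `rivertrends.metrics` | dissimilarities, pseudo-counts, coverage-standardized richness, non-native shares |
| `rivertrends.drivers` | footprint change, varimax stream-position axis, predictor scaling |
| `rivertrends.model` | design construction, blocked Gibbs sampler, HPD/evidence/R²/WAIC/VIF, baseline predictions |
| `rivertrends.typology` | trend PCA, trimmed k-means, affiliation filter, cluster frequencies |
| `rivertrends.simulate` | model-exact, driver and community generators with ground truth |
| `rivertrends.pipeline` / `cli` | `run-all` orchestration, YAML config, click CLI |
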