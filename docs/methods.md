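# Methods

`rivertrends` analyses annual riverine fish community time series: it
cleans the raw survey records into one sample per site and year, computes
community-change metrics against each site's first sampled year, fits
hierarchical Bayesian trend models over a nested basin/site structure,
relates the trends to anthropogenic-pressure covariates, and classifies
sites into trajectory types. This note documents the models, the
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## Series selection

Sites are reduced to one comparable annual series by four rules applied
in order: (1) keep only sampling events using the site's most frequent
protocol (ties: lexicographically first); (2) keep events within 45 days
— circular day-of-year distance, so winter-sampled sites spanning the
new year survive — of the centre of the most frequently sampled month;
(3) where a year retains several events, keep the one closest to the
site's modal sampling day (ties: earlier date); (4) retain a site only
if it has at least 5 sampled years spanning at least 10 calendar years
inclusive (`span_years >= 9`) and is not flagged as limed. The inclusive
reading of the 10-year window is a deliberate choice; a 2000–2009 series
qualifies. Completeness is `n_years / (span_years + 1)`, so a gap-free
series scores 1. Every removal is written to an audit log.

## Community metrics

For each site-year, with the site's first sampled year as the baseline:

* **Jaccard dissimilarity** `J = (S_gain + S_loss) / S_tot` over
  presences, partitioned into turnover
  `J_t = 2 min(S_gain, S_loss) / (S_common + 2 min(S_gain, S_loss))`
  (species replacement) and nestedness `J_n = 1 − J_t` (gains/losses
  from a nested pool). `J_t + J_n = 1` whenever any species changed.
* **Simpson-based dissimilarity**
  `H_d = Σ(p_i − p'_i)² / (Σp_i² + Σp'_i² − Σp_i p'_i)` over relative
  abundances on the union species pool (absent species contribute 0).
  `H_d` is 0 for identical and 1 for disjoint communities and weights
  the dominant species most. (Printed statements of this index sometimes
  carry an extra complement that contradicts those boundary values; we
  use the orientation in which high values mean change.)
* **Coverage-standardized richness.** Sampled richness is negatively
  biased, so richness is rarefied/extrapolated to a fixed sample
  coverage of 98.5%. Coverage is estimated from singletons and
  doubletons, `C = 1 − (f1/n)·[(n−1)f1 / ((n−1)f1 + 2f2)]`. Rarefaction
  uses exact hypergeometric expectations for richness and coverage at
  integer subsample sizes with linear interpolation in coverage between
  adjacent sizes (the interpolation scheme is a package choice, tested
  against a Monte-Carlo subsampling oracle). Extrapolation uses the
  asymptotic singleton/doubleton richness estimator, capped at twice the
  observed sample size; capped values are flagged. Densities, CPUE and
  Leslie-index abundances are first converted to pseudo-counts by
  dividing by the within-sample minimum and rounding half away from
  zero, which guarantees at least one singleton and hence a defined
  coverage.
* **Non-native shares** of total abundance and of richness, from a
  species-origin table resolved by a (species, basin) lookup with a
  (species, country) fallback. Unresolved species count as native: this
  keeps the proportions defined and cannot inflate an invasion signal.

## Drivers

Three per-site covariates: past pressure (human footprint index 1993, a
0–50 composite), recent pressure change (log2 of the 2009/1993 footprint
ratio, so −1/+1 mean halving/doubling; zero footprints are offset by
0.5, half the index resolution, before the ratio), and longitudinal
stream position. The stream axis is built from altitude, slope,
discharge, distance from source and Strahler order: log-transform (after
shifting any variable with non-positive values by |min| + 1),
standardize, PCA, varimax-rotate the first two components, and keep the
component loading positively on discharge, distance from source and
Strahler order, signed so downstream is positive. Past pressure and
stream position are centred and scaled; the change ratio is scaled but
*not* centred, so main effects retain their baseline (no-recent-change)
interpretation. Time is left in natural log-year units rather than
SD-scaled, because the per-decade back-transform presumes them.

## Trend models

Each metric `Y` at site i (in basin n) and time t follows a Gaussian
linear mixed model with `Time_t = log(years since first survey + 1)`:

    Y_{i|n,t} = α + β₀ Time_t + ε,   α = α₀ + a_n + a_{i|n},
    β₀ = μ + b_n + b_{i|n},          a, b, ε ~ N(0, σ²)

Abundance and richness are log-transformed (trends are multiplicative);
proportions and dissimilarities are modelled on the identity scale —
Gaussian throughout, a deliberate trade of distributional purity for
comparable, directly interpretable slopes. Responses are divided by
their SD before fitting and slopes rescaled afterwards. For total
abundance the measurement unit enters as a categorical main effect and
unit-by-time interaction with raw counts as the reference level. For
dissimilarities the baseline rows are deterministic zeros: they are
dropped from the likelihood and the model carries no intercept, fixed or
random (a fixed zero intercept beside a free random intercept would be
contradictory); random time-slopes are retained. The driver model adds
driver main effects (not for dissimilarities), two-way Time×driver and
three-way Time×driver×driver interactions. Random slopes attach to the
Time column only.

The per-decade back-transform uses a time value of log(10 + 1):
`(e^{β·ln 11} − 1)·100` percent for log responses, `β·ln 11` response
units otherwise. Per-site trends are posterior means of
`μ + b_n + b_{i|n}`. Effects earn *weak*, *moderate* or *strong*
evidence when the 80, 90 or 95% highest-posterior-density interval
excludes zero; HPD intervals are the shortest contiguous window of
sorted draws (first window on ties).

### Inference

Priors follow the study setting: N(0, 1000) on fixed effects and
Gamma(shape 1, rate 5·10⁻⁵) on each precision. Sampling is a blocked
Gibbs sampler exploiting full conjugacy, with two structural choices
that matter for mixing:

* **Hierarchical centring.** Site effects are drawn around basin means
  and basin means around the global fixed effect; draws are stored in
  the additive form. The additive parameterization mixes pathologically
  when a variance component is small (the chain gets trapped with the
  precision at a huge value).
* **Joint site blocks and collapsed basin precisions.** Because time is
  not centred, each site's intercept and slope are strongly negatively
  correlated given the data; they are sampled as a joint 2×2 Gaussian
  block. Basin-level precisions are updated with the basin means
  integrated out (a one-dimensional slice-sampling step on the log
  precision), then the basin means redrawn conjugately — a partially
  collapsed update that removes the remaining zero-trap.

The sampler was validated three ways: exact agreement with the
closed-form conjugate posterior in the no-random-effects known-variance
case; parameter recovery on nested simulations; and agreement with an
independent MCMC implementation of the identical model and priors on the
same data. Defaults are 4 chains × 2,000 kept draws after 1,000 warm-up;
split-R̂ is reported per fixed effect and a warning is raised above 1.05.

A known property of the Gamma(1, 5·10⁻⁵) precision prior, which
transforms to p(σ) ∝ σ⁻³ exp(−5·10⁻⁵/σ²): when a variance component is
weakly identified (few groups, small true variance), its posterior is
pulled toward σ ≈ 0.01. The basin-level *intercept* SD in the default
recovery design behaves this way — identically so under the independent
MCMC cross-check — so recovery tests assert the slope and residual
components, which are data-identified. Interval calibration inherits a
mild version of this: empirical 95% HPD coverage for the global slope
runs near 91% rather than 95% at the simulation sizes used.

### Fit summaries

Marginal and conditional R² are computed per draw with a shared
denominator: `R²_m = Var_fit / D` and
`R²_c = (Var_fit + σ²_{a_n} + σ²_{a_i|n}) / D` with
`D = Var_fit + σ²_{a_n} + σ²_{a_i|n} + Var_res`, where `Var_fit` is the
variance of the fixed-effect predictions and `Var_res` the variance of
the full-model residuals of that draw. Only intercept random effects
enter, matching the convention that slope-variance terms are omitted.
WAIC is `−2(lppd − p_waic)` from a pointwise log-likelihood matrix
(thinned to at most 1,000 draws); variance inflation factors are
`1/(1−R²_j)` per fixed-effect column. Baseline (t = 0) predictions put
non-focal drivers at their medians and the abundance unit at its
reference level; contrasts are `100·(pred_a/pred_b − 1)` with HPDs.

## Trajectory typology

Per-site per-decade trends in total abundance, coverage-standardized
richness, Simpson dissimilarity and turnover form the clustering matrix
(non-native share trends are excluded: their site-level distributions
are heavy-tailed and would dominate the geometry; column kurtosis is
reported). A standardized-variable PCA summarizes the covariation.
Clustering is trimmed k-means, k = 6, α = 5%: concentration steps that
assign, trim the ⌈αn⌉ points farthest from any centre, and update
centres from untrimmed points; the trimmed within-cluster sum of squares
never increases. Fifty random initializations by default, minimum 100
and maximum 125 iterations, best objective wins, ties to the first
start. Clustering operates on standardized trend units (scale
comparability); trends are reported in natural per-decade units. A site
is left *unassigned* when its second-best centre lies within 1.5× the
distance of its best centre — the distance-ratio operationalization of
an ambiguous affiliation; the threshold is configurable. Cluster names
are post-hoc labels comparing centres to the overall spread.

## Synthetic data

The generator produces the structures the analysis assumes rather than
mechanistic population dynamics — the validation surface is parameter
recovery, not ecology:

* `simulate_from_model` draws responses exactly under the hierarchical
  model, for recovery and calibration experiments.
* `simulate_drivers` emits covariate tables with ~92% of sites above the
  footprint degradation threshold of 4 in 1993, a 2009/1993 ratio
  centred slightly below 1 (mild average easing), and stream variables
  on one latent gradient independent of the footprint, keeping pairwise
  driver |Spearman| near zero (≲ 0.02 at n = 4,000).
* `simulate_communities` builds long-format survey records: lognormal
  abundances with a site-level multiplicative drift drawn from the
  nested slope hierarchy (site-level slope SD twice the basin-level SD
  by default), species replacement at a configurable yearly rate,
  non-native introductions with yearly probability proportional to the
  site's 1993 footprint, abundance units mixed across sites in the
  proportions seen in compiled survey databases (counts 47%, densities
  52%, CPUE 1%, Leslie 0.1%), and years thinned to a target
  completeness with the endpoints kept (so completeness varies, span
  does not).

What passing tests show: the estimators agree with independent oracles,
the sampler recovers known parameters at realistic nested sizes, and the
full pipeline propagates a footprint-linked introduction process into a
positive Time×past-pressure effect on the non-native richness share.
What they do not show: behaviour under real-data features the generator
omits — temporal autocorrelation of residuals, observation error
correlated with protocol, spatial autocorrelation along the river
network, detection differences among species, or drifting sampling
effort.

## Problem sizes and defaults

Tests and the acceptance script run deliberately scaled-down designs
chosen to keep each experiment identified: recovery and calibration use
50 basins × 10 sites × 10 years (5,000 observations; 100 calibration
replicates with single 400+400 chains), the WAIC comparison 2,000
observations, the end-to-end driver experiment 20 replicates of 12
basins × 5 sites × 12 years, and typology recovery ~315 sites in six
archetypes plus 5% outliers. Production defaults remain 4 × 2,000 draws
after 1,000 warm-up, coverage target 0.985, seasonal window 45 days,
k = 6, α = 0.05, affiliation threshold 1.5.

## Known limitations

Gaussian likelihoods for bounded responses can predict outside [0, 1];
predictions are clamped for display only, never in the likelihood. The
origin cascade treats unresolved species as native. The vague precision
prior shrinks weakly identified variance components toward zero (see
above). No spatial or temporal autocorrelation terms; no imputation of
missing years; covariates are taken as given (no GIS extraction).
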