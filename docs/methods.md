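# Methods

## The model

`triselect` models third-order habitat selection: how an animal splits its
relocations among the habitat types of its own home range, whose
composition is treated as fixed and known.  For animal *i* in site *s*
with `N_{s,i}` relocations counted into three habitat types (shrub, pole
stage, coppice-with-standards):

```
n_{s,i}  ~  Multinomial(N_{s,i}, p_{s,i})
log(p_{s,i,h} / p_{s,i,3})  =  f_h(d_{s,i,1}, d_{s,i,2}) + eps_{s,i,h}
eps_{s,i,h}  ~  Normal(0, sigma^2)                      h in {1, 2}
```

CWS is the reference habitat (its logit is 0).  The mean logit is linear
in the availability proportions of the two non-reference habitats,
`f_h = a0_h + a1_h d_shrub + a2_h d_pole` (CWS availability enters
implicitly through closure).  Two forms are fitted: **pooled**
(coefficients shared by all sites, 6 free coefficients) and
**site-specific** (coefficients per site, 6 per site).  Because the
linear predictor depends on availability, the model expresses functional
responses directly: predicted use at a given availability can sit below
or above proportional use, and the crossing point is the availability
threshold at which selection switches sign.

The per-individual residual `eps` is an overdispersion device: GPS fixes
taken every few hours are temporally autocorrelated (Schoener's ratio
well below 2), so raw multinomial variance understates between-animal
spread.  Residuals are independent across individuals and across the two
logits, sharing a single variance `sigma^2`.

Assumptions worth keeping in mind: availability is error-free; animals
are independent given the coefficients; selection depends on the whole
availability composition but only linearly on the logit scale; there are
no covariates other than availability, and no temporal or spatial random
effects.

## Priors

* `a ~ Normal(0, variance 1000)` (SD ~ 31.6) on every coefficient.  Note
  the BUGS convention would read "N(0, 1000)" as *precision* 1000, i.e. a
  sharply informative prior; that reading contradicts a non-informative
  intent, so variance is the default here.  `prior_var` is a parameter of
  `sample_posterior` for anyone wanting the other convention.
* `sigma^2 ~ Uniform(0, 100)`; logits beyond +-10 saturate the
  probabilities, so the bound is not restrictive.

## Sampling

`sample_posterior` runs a bespoke Metropolis-within-Gibbs sampler; all
chains advance together as a numpy batch axis, so runs are fast on one
CPU and bit-reproducible for a given seed.  Per iteration:

1. **Coefficient blocks** — one random-walk Metropolis update per
   (site, logit) triple `(a0, a1, a2)`.  Proposal covariance is adapted
   Haario-style during burn-in (scaled empirical covariance of the block,
   factor `2.38^2 / 3`, refreshed every 25 iterations from iteration 200)
   with a Robbins–Monro scalar tuned toward 28% acceptance; all
   adaptation freezes at the end of burn-in, preserving detailed balance.
   Only the records of the block's own site enter its likelihood ratio.
2. **Translation moves** — for each block, a proposal that shifts the
   coefficients by `delta` and the residuals of its records by
   `-delta . x_k`, leaving every likelihood term untouched; acceptance
   depends only on the two priors.  Intercepts and the mean of the
   residuals are strongly anticorrelated in the posterior, and blocked
   updates alone mix very slowly along that ridge; these moves sample it
   directly.
3. **Residuals** — all per-individual pairs `(eps_1, eps_2)` proposed at
   once with record-wise accept/reject (valid because the likelihood
   factorizes over individuals given the coefficients).
4. **sigma^2** — an exact Gibbs draw: under the uniform prior the full
   conditional is inverse-gamma(K - 1, sum(eps^2)/2) truncated to
   (0, 100), sampled by rejection on the gamma-distributed precision.
   With no data the draw reverts to the uniform prior, which is how the
   prior-recovery test exercises the sampler.

Initialization is `a = 0`, `sigma^2 = 1`, `eps = 0` (with overdispersed
restarts if the posterior is not finite there — impossible for valid
records, kept as a guard).  Default schedule: 3 chains x 5,000 iterations,
1,000 burn-in, thinning 5, i.e. 2,400 kept draws; one site-contrast fit
(60 animals, N = 900) takes a few seconds.  The schedule is configuration:
analyses of real datasets should scale it up (e.g. chains of 10^6
iterations thinned by 50) and confirm convergence with `gelman_rubin`
(classic potential-scale-reduction factor; parameters above 1.1 are
flagged and reported in every CLI manifest, as a warning rather than a
hard failure).

## Model comparison

`dic` computes the *conditional* DIC — deviance evaluated given the
sampled residuals, the flavor BUGS-family software reports for this
parameterization: `DIC = Dbar + pD`, `pD = Dbar - D(theta_bar)`, with the
plug-in point the posterior mean of coefficients and residuals on the
sampled scale.  The variance-based alternative `pD_var = var(D)/2` is
reported alongside.  `compare_dic` returns
`deltaDIC = DIC(pooled) - DIC(site_specific)` (positive favors
site-specific selection) with a standard error from a nonparametric
bootstrap over individuals of the per-individual DIC contributions —
individuals are the model's independent units, and DIC decomposes
additively over them.  This SE is an approximation: it captures
between-individual variability but not MCMC noise, so very small
|deltaDIC| values should not be over-read.  A consequence of bootstrapping
the *sum* is that the SE of the mean contribution shrinks as 1/sqrt(K)
while the SE of deltaDIC itself grows as sqrt(K).

## Posterior predictive check

For each posterior draw, a replicate dataset is simulated from
`Multinomial(N_{s,i}, p_{s,i}(theta^r))` using that draw's own residuals;
draws are cycled to reach `n_rep` replicates (default 10,000; raise it
for publication-grade checks).  Per animal x habitat cell, the
equal-tailed 95% interval is formed from empirical order statistics of
the simulated counts and membership is closed, so bounds are achievable
integers.  With discrete counts this is conservative: realized coverage
sits at or above the nominal level even for a perfectly specified model,
so coverage *below* nominal is the fit signal to act on.  Standardized
Pearson residuals `(n - N p) / sqrt(N p (1 - p))` at the posterior-mean
probabilities are provided for residual inspection.

## Geometry on the triangle

Compositions close to 1 within 1e-9 (inputs inside tolerance are
silently renormalized, beyond it rejected).  The ternary embedding is the
standard barycentric map onto an equilateral triangle of unit side,
vertex order (shrub, pole, CWS) counter-clockwise; the round trip is
exact to < 1e-12.  Marginality length is reported in this planar
embedding so "length" matches distances measured on a drawn ternary
plot; the raw 3-vector norm is exposed as `norm3` and differs by the
constant factor sqrt(2) (deltas are zero-sum).  Selection ratios with
zero availability are undefined and returned as NaN, never clamped.
`delta_proportions` computes used-minus-available on raw proportion
vectors without enforcing closure, for reproducing arithmetic on
published (rounded, occasionally inconsistent) composition values.

Log-ratio maps evaluate `P(log(p_{s1,h} / p_{s2,h}) > 0)` per cell of a
barycentric lattice (default step 0.01, 5,151 cells; resolution is
configurable).  Classes: `greater_in_A` above 0.95, `greater_in_B` below
0.05, `no_difference` between, `infeasible` outside the joint feasibility
region — the intersection of the two sites' convex hulls of observed
availability compositions in the ternary plane (degenerate hulls fall
back to a minimally buffered segment).  Ties at exactly zero count 1/2,
making the map exactly antisymmetric under site swap.  Representative
animals are chosen by Ward clustering of availability points in the
ternary plane, cutting the tree into k = 8 groups and sampling one
member per group with a seeded generator.

## GPS preprocessing

Fixes are kept if PDOP is strictly below 5 and the calendar date falls in
April 1 – August 31 (month-day comparison, so multi-year collars
contribute every season).  Home ranges are minimum convex polygons; the
estimator behind published availability compositions is usually
unstated, so the level (default 100%, trimming by distance from the
centroid below that) is explicit configuration and results conditional
on it.  Availability counts raster cells whose centers fall in the
polygon (boundary inclusive); fixes map to cells by half-open intervals.
Grassland, a small and often absent fraction of forest home ranges, is
removed from availability and its fixes excluded from both numerator and
denominator; reassigning them to the nearest retained habitat was
rejected as an unstated alternative.  Schoener's ratio `t^2 / r^2` uses
the n - 1 successive-move distances and the population centroid; values
near 2 indicate temporal independence, values well below 2 the
autocorrelation that motivates the overdispersion residual.

## The synthetic generator

`simulate_dataset` draws, per animal, an availability composition from a
site-specific Dirichlet, residuals from `N(0, sigma^2)`, and counts from
the exact generative model — i.e. the data satisfy the model's
assumptions by construction.  Preset scenarios fix the study conditions
used by the tests: three sites, 20 animals per site, 900 fixes per
animal (the approximate yield of a 4-hour fix cadence over one
April–August season), overdispersion SD 0.3, and Dirichlet
concentrations giving availability clouds of realistic spread.
`site_contrast` places large between-site differences on the shrub
logit; `threshold_fr` uses a steep shrub response (`a0 = -4`,
`a1 = 16`) whose mean use crosses proportionality near 20% shrub
availability — avoidance below, selection above.  `simulate_gps`
additionally produces raw fixes on a patch-mosaic raster via a biased
jump walk with 4-hour timestamps and a 10% fraction of high-PDOP fixes,
to round-trip the preprocessing chain.

What passing tests on these data do *not* show: robustness to
misspecified availability (home-range error), non-linear functional
responses, residual temporal structure beyond exchangeable
overdispersion, or habitat classification error.  Real mosaics are also
spatially autocorrelated in ways the block mosaic only caricatures.

## Numerical choices and test-scale conditions

* Inverse-logit evaluations subtract the maximum logit; probabilities are
  exact to overflow even at |logit| = 700.
* The likelihood kernel drops the multinomial coefficient inside the
  sampler (it cancels in every ratio) but includes it in `log_likelihood`
  and the DIC, which are exact log-pmfs (enumeration for N <= 6 sums to 1
  within 1e-10).
* Empirical-quantile endpoints for PPC intervals take the lower order
  statistic for the lower bound and the upper for the upper bound
  (conservative, achievable counts).
* Recovery and model-selection tests run 50 and 20 replicates of the
  preset scenarios at the default 3 x 5,000 schedule; calibration is
  judged pooled across coefficients and replicates (a 90–98% band around
  the nominal 95%), since per-coefficient rates at 50 replicates carry
  +-3% binomial noise.
* `sigma` is weakly identified relative to the coefficients; its
  posterior median is expected within +-50% of truth at 60 animals.

## Known limitations

Exactly three habitat categories are supported in the core geometry; no
Aitchison log-ratio transforms (the analysis works on raw proportions by
design); no kernel home ranges, trajectory interpolation, or coordinate
reprojection; no Dirichlet-multinomial overdispersion variant; no WAIC or
cross-validation.  The DIC bootstrap SE and the MCP home-range default
are documented approximations, not the only defensible choices.
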