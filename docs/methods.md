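# Methods

`dustshed` re-implements, as a tested pipeline on synthetic data, the
analysis workflow of a road-dust impact study: lichen species richness
(LSR) declines toward a mining haul road, and the decline is modelled
spatially and summarised over a landscape grid, alongside the standard
community-ecology statistics (MRPP, indicator species analysis,
ordination overlays) that identify which taxa drive the change.

## The spatial model

Per-plot species richness is a count, modelled as

    Y_i ~ Poisson(lambda_i)
    log lambda_i = beta0 + beta1 * d_i + delta_i + eta_i + eps(s_i)

where `d_i = log10(distance to road centreline in m)`, `delta` is a
binary side-of-road effect (north = 1), `eta` a binary habitat effect
(the two upland shrub/tussock land-cover types; first level is the
baseline), and `eps` a zero-mean Gaussian field with exponential
covariance

    C(h) = theta1 * 1(h = 0) + theta2 * exp(-h / theta3)

with nugget `theta1` (micro-scale variance; i.i.d. at observed sites),
partial sill `theta2` (spatially structured variance) and range `theta3`
(metres; correlation decays by 1/e per range). `log10` is used for the
distance covariate: it only rescales `beta1` relative to a natural-log
convention, and plotting conventions in this literature are decimal.

### Priors

Regression effects get independent Normal(0, sd = 100) priors — diffuse
on the log scale of a count that never exceeds a few dozen. For the
covariance parameters we use proper, pluggable priors instead of an
improper reference prior: half-Normal(sd = 5) on `theta1` and `theta2`
and a log-uniform prior on `theta3` bounded by the minimum plot spacing
and twice the domain diameter. These guarantee a proper posterior, admit
direct quadrature checks, and make prior-sensitivity analysis a matter of
swapping hyperparameters. The upper range bound deliberately allows
ranges much larger than the domain; the translation move below keeps the
sampler well behaved in that regime.

### Sampler

`run_mcmc` combines four updates per iteration:

1. **Elliptical slice sampling** for the latent field `eps` — tuning-free
   given its Gaussian prior, with the Poisson likelihood as the slice
   target.
2. **Adaptive random-walk Metropolis** for `beta` (Haario-style empirical
   covariance adaptation during burn-in, frozen afterwards). Covariate
   columns are centred internally so the intercept decorrelates from the
   slopes; draws are stored on the original scale. With the diffuse
   Normal(0, 100) priors this reparametrisation has no practical effect
   on the posterior.
3. **Adaptive RWM on log theta**, with the Jacobian term, recomputing the
   field's Cholesky factor per proposal (cheap at n <= a few hundred).
4. Two exact reparametrisation moves that plain conditional updates mix
   slowly on: a **translation move** — `(beta, eps) -> (beta + c,
   eps - Xc)` leaves the likelihood invariant and `c` has a closed-form
   Gaussian conditional from the field and beta priors — which resolves
   the confounding between regression effects and a long-range field; and
   a **funnel (rescaling) move** that scales `eps` and the free variance
   components jointly, with the exact Metropolis correction, which fixes
   the classic slow mixing of a variance component near zero.

Chain management defaults follow the study protocol: 1,000 burn-in
iterations, 20,000 post-burn-in with every 100th retained, i.e. 200
samples per chain; 4 chains by default (the original report is ambiguous
about chain count). Convergence is summarised by the split-chain
potential scale reduction factor; on the default synthetic study the
maximum across parameters is ~1.03-1.05 at default controls.

Plots are canonically ordered (sorted `plot_id`) before any random draw,
and each chain uses a counter-based (Philox) stream, so retained draws
are exactly invariant to input row order. The sampler can pin covariance
components (`fix={"theta2": 0.0}`) to obtain the non-spatial
(nugget-only) limit, under which posterior means of the regression
effects agree with maximum-likelihood Poisson regression to a small
fraction of a standard error.

Known limitation: with `theta2` free the marginal posterior of
(`theta2`, `theta3`) is weakly identified at n = 96 plots (long-range,
high-sill states trade off against each other); `beta` remains well
identified thanks to the translation move, which is what the downstream
predictions use.

## Posterior prediction

For each retained draw, `eps` at grid points is simulated from its
conditional Gaussian given that draw's field values and covariance
parameters (kriging mean plus a conditional-covariance draw). Only the
`theta2 exp(-h/theta3)` component links sites: the nugget is micro-scale
variance at observed plots and does not propagate to predictions, so a
grid point coincident with a plot interpolates that plot's field value
exactly when `theta1 = 0`. Predicted richness is reported on the
intensity (`lambda`) scale, not as integer Poisson draws — stratum means
like 9.4 are meaningful fractions.

Summaries:

* **Per point**: posterior mean, 2.5/97.5 percentiles, CV, and quartile
  classes of 1/CV (a mapping-precision index).
* **Per distance class** (strata 0-50-100-300-1000-2000-3000-4000 m,
  half-open, final edge inclusive): the stratum mean is the area-weighted
  mean intensity over the class's points *within each draw*; Mean/SE and
  percentiles summarise that per-draw quantity, Min/Max are extremes of
  per-point posterior means, and **Pr Decrease** is the percentage of
  paired draws in which the class's stratum mean is strictly below the
  next farther class's (ties count as non-decreases). The "SE" column is
  the posterior SD of the stratum mean; both interpretations are recorded
  here because the original summary protocol leaves them implicit.
* **By area threshold**: points are classified by posterior-mean
  intensity relative to the farthest stratum's mean into left-closed
  half-open classes (<25%, 25-50%, 50-75%, 75-95%, >=95%), with areas,
  cumulative areas and an inside/outside industrial-easement split. The
  classes partition the total grid area exactly.

## Community statistics

* **Cover transform**: `x -> log10(x + 0.01) + 2`, which maps 0 exactly
  to 0 and compresses the skewed percent-cover scale; strictly monotone.
* **Filtering**: empty plots are removed first, then taxa with one or
  fewer occurrences; no cascade (plots emptied by taxon deletion stay).
* **Distances**: Sorenson = quantitative Bray-Curtis
  `sum|a-b| / sum(a+b)` (bounded [0,1], semi-metric — the triangle
  inequality is deliberately not asserted); Euclidean permits empty plots
  and is used for the pre-filter outlier screen.
* **Outliers**: a plot is flagged when its mean dissimilarity to all
  other plots exceeds the grand mean of those averages by more than 2 SD.
* **MRPP**: delta = sum over groups of (n_i/N) x mean within-group
  dissimilarity (the common group-size weighting; the original report
  does not state its weight), expected delta from relabelling, and
  `A = 1 - delta_obs/delta_exp`. Permutation tests enumerate all distinct
  label assignments when there are at most 10,000 (making small-fixture
  p-values exact), otherwise use seeded Monte Carlo with the +1
  correction so p is never 0.
* **ISA**: Dufrene-Legendre `IndVal = relative abundance x relative
  frequency`, reported as the maximum over groups on the [0,1] scale,
  with the same permutation rule applied to the per-taxon maxima.
* **Ordination overlays**: the NMS embedding itself is consumed, not
  computed (the original used proprietary software; scores from any
  nonmetric-MDS implementation can be supplied). `rotate_scores` finds
  the direction in axis space maximally correlated with a target
  variable (numerically, Nelder-Mead on the unit sphere with multiple
  starts) and completes it to an orthonormal basis, so all inter-plot
  distances are preserved; `axis_correlations` overlays Spearman
  correlations with pairwise deletion of missing values.
* **Class summaries**: per-distance-class mean, SE = SD/sqrt(n) and
  one-way ANOVA across classes.

Missing covariate values (the field rule for two uncollectable moss
samples) are imputed as the mean of the other plots from the same side of
the road in the same distance class — the class, not the exact distance.

## Synthetic data

No raw data from the original campaign is deposited, so the
`simulate` module generates study-shaped datasets with known truth:

* **Layout**: 12 transects, 2.5 km apart along a straight road, on
  alternating sides, with plots at 10/50/100/300/1000/2000/4000 m, plus
  one autocorrelation plot per transect 10-20 m from a random plot in the
  >= 1000 m classes (96 plots total).
* **Richness**: from the spatial Poisson model with default truth
  `beta0 = 1.0, beta1 = 0.75, delta = eta = 0.1,
  theta = (0.02, 0.05, 800 m)`, chosen to reproduce the observed span of
  class-mean LSR, roughly 9 near the road to 42 at 4000 m. (At
  `beta1 = 0.75` the noise-free mean at 4000 m is
  `exp(1 + 0.75 log10 4000) ~ 40.5`.)
* **Community**: each of 113 taxa occurs only beyond its sensitivity
  threshold (15% of taxa tolerant with threshold 0, the rest uniform on
  [0, 3000] m), with occupancy noise and lognormal cover; covers below 1%
  are recorded as 0.1%, the walkaround-survey convention. This mechanism
  is the simplest one consistent with the indicator-species findings (no
  indicators near the road, most taxa associated with far classes); it
  does not model species interactions, dispersal or cover dynamics.
* **Covariates**: element concentrations decay as
  `background + (near - background) (d/10)^-k` times unit-mean lognormal
  noise, calibrated to the observed magnitudes (e.g. Zn 566 mg/kg at
  10 m falling to ~77 mg/kg background).
* **Grid**: the default prediction grid is distance-banded — rows of
  points denser near the road with area weight = x-spacing x band width —
  because a uniform grid at affordable spacing leaves the 0-50 m stratum
  empty; the uniform square grid (equal `spacing^2` weights) is also
  available. Grid points closer than 10 m to the centreline are dropped
  (the log-distance covariate is undefined at 0 and 10 m is the closest
  sampled distance).

What passing tests on this generator do *not* show: robustness to
taxonomic lumping, detection error, non-Poisson overdispersion beyond the
latent field, curved road geometry, or covariate measurement error —
none of which the generator emulates.

## Numerical choices

* Cholesky factorisations retry with jitter (1e-10 -> 1e-6 of the mean
  diagonal) when a covariance matrix is numerically singular, e.g.
  coincident points with zero nugget.
* Distance classes and area-threshold classes are half-open [lo, hi);
  the final distance edge (4000 m) is inclusive.
* Permutation p-values use the +1 correction under Monte Carlo and exact
  proportions under enumeration; ties in Pr Decrease count as
  non-decreases (conservative).
* CSV floats are written with 17 significant digits so read/write round
  trips are exact.
* Problem sizes used in the shipped analysis and checks — 96 plots, a
  ~960-point banded grid, 200 retained draws per chain — follow the
  original study's design; replicate-based calibration checks use
  shortened chains (5,000-6,000 iterations) after verifying that default
  and shortened chains agree on the parameters they examine.
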