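# dustshed

Spatial modelling and community statistics for vegetation gradients along
a mining haul road.

Fugitive dust from ore haulage deposits heavy metals (Zn, Pb, Cd) and
crustal elements in the tundra flanking the road, and macrolichens are
among the most sensitive receptors: lichen species richness (LSR) per
plot collapses near the road and recovers over kilometres. This package
implements the full analysis workflow for such gradient studies —
aimed at quantitative ecologists and monitoring programs — on
synthetic, study-shaped data with known ground truth (the original field
data is not publicly deposited).

Two pillars:

1. **A Bayesian spatial Poisson model** for plot-level richness counts,

       Y_i ~ Poisson(lambda_i),
       log lambda_i = beta0 + beta1 * log10(dist_i) + delta_i + eta_i + eps(s_i),

   with side-of-road and habitat effects and a latent Gaussian field
   `eps` with exponential covariance
   `C(h) = theta1*1(h=0) + theta2*exp(-h/theta3)` (nugget, partial sill,
   range). Fitted by MCMC (elliptical slice sampling for the field,
   adaptive Metropolis for effects and covariance parameters), checked
   with the split-chain potential scale reduction factor, and extended to
   a landscape grid by conditional (kriging-style) posterior simulation.
   Predictions are summarised per distance class — including the
   probability that each class's mean is lower than the next farther
   class's — and as areas above/below fractions of the far-field mean,
   split inside/outside the industrial easement.

2. **Community statistics** for plots x taxa percent-cover matrices: the
   `log10(x + 0.01) + 2` cover transform (zeros stay zero), rare-taxon and
   empty-plot filtering, Sorenson (Bray-Curtis) and Euclidean distance
   matrices, mean-distance outlier screening, multi-response permutation
   procedures (MRPP, with exact enumeration on small problems), indicator
   species analysis (Dufrene-Legendre IndVal), relativization by species
   maximum, orthogonal rotation of ordination scores toward a target
   variable, and Spearman overlay correlations.

See `docs/methods.md` for the model, priors, sampler and design choices.

## Worked example

The `analysis/` scripts run the pipeline end to end and write their
tables under `results/`:

```sh
python analysis/01_simulate.py 42   # plots, community matrix, grid
python analysis/02_community.py 42  # MRPP, ISA, outliers, class summaries
python analysis/03_fit.py 42        # MCMC fit, posterior, diagnostics
python analysis/04_predict.py 42    # grid predictions, strata, areas
```

With seed 42 the simulated study has 96 plots (12 transects at
10-4000 m plus one autocorrelation plot each) whose observed mean
richness climbs from ~6 species per plot at 10 m to ~40 at 4000 m. The
community stage reports

```
MRPP: 13/21 class pairs with strong community differences (A >= 0.10); max A = 0.28
ISA (<1000 m vs >=1000 m): 89 significant indicator taxa, 88 of them for the far group
```

— i.e. community structure separates near-road from far plots, and
essentially all indicator taxa indicate the far group, the signature of a
deposition gradient that removes species rather than adding any. The fit
and prediction stages print

```
retained 200 draws x 4 chains
max PSRF across parameters: 1.031
beta1 (log10-distance slope): posterior mean 0.734, SD 0.066 (simulation truth 0.75)

 class distance_m   n  mean_lsr  se_lsr  min_lsr  max_lsr  pctl_2.5  pctl_97.5  pr_decrease
     1       0-50 192       8.8     0.8      4.2     13.9       7.3       10.5        100.0
     2     50-100 128      11.9     0.9      7.9     20.0      10.3       13.8        100.0
     3    100-300 128      16.2     1.0      9.6     25.3      14.5       18.4        100.0
     4   300-1000 128      23.4     1.3     14.9     37.8      21.1       26.5        100.0
     5  1000-2000 128      30.9     1.9     17.5     49.6      27.5       35.3        100.0
     6  2000-3000 128      36.9     2.6     24.4     50.9      32.4       43.3         99.2
     7  3000-4000 128      40.7     3.2     29.9     52.2      35.6       47.8          NaN
```

Reading the table: modelled richness rises monotonically from ~9 in the
0-50 m stratum to ~41 at 3000-4000 m; `pr_decrease` is the percentage of
paired posterior draws in which a class's area-weighted mean is below the
next farther class's — 100% out to 3000 m (an unequivocal impact
gradient) and near-certain for the farthest pair. The slope estimate
recovers the simulation truth within one posterior SD, and the
convergence diagnostic is comfortably below the conventional 1.1.

The same steps are available as a CLI
(`dustshed simulate|community|fit|predict|summarize`), each writing a
run manifest (config, seed, input hashes) next to its outputs.

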