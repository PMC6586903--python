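# Methods

## The model

For sample *i* with covariate row **x**_i (length k, intercept first) and
count vector **Y**_i over D taxa, the generative model is

```
β_jk ~ Normal(0, σ)                      # prior on every coefficient
η_i  = alr⁻¹(x_i β)                      # softmax with a zero prepended
Y_i  ~ Multinomial(N_i, η_i)             # N_i = observed sequencing depth
```

with β a (D−1)×k matrix in additive log-ratio (alr) coordinates. The alr
reference is the first taxon in table order (selectable); the choice does
not affect the fitted proportions η_i, and the clr view
`clr(alr⁻¹(β_k))` — the form reported and ranked — is reference-invariant
at the maximum-likelihood optimum. With a proper prior on the alr
coordinates the invariance is exact only in the flat-prior limit; at the
default σ = 1 the residual reference dependence is far below the
statistical noise of any realistic fit, and the test suite checks
invariance explicitly at σ = 100.

The multinomial normalization constant does not depend on β and is dropped
from the objective. Sampling zeros are handled natively by the likelihood;
no pseudocounts are added anywhere in the fitting path.

### Estimation

MAP estimation by mini-batch stochastic gradient descent:

- the optimized objective is the negative log posterior scaled by 1/n
  (mean per-sample NLL plus prior/n). The argmin is identical to the
  unscaled MAP, but the fixed learning rate then has the same meaning at
  any sample size;
- batches are drawn without replacement each epoch; β starts at the prior
  mode (zero); the gradient step on the likelihood is followed by an exact
  proximal shrink for the quadratic prior, `β ← β̃ / (1 + lr/(σ²n))`, which
  keeps the iteration stable for arbitrarily small prior scales;
- convergence is declared when the relative change of the full objective
  over a 10-epoch window drops below `convergence_tol`; divergence (a
  non-finite objective or coefficient) raises with advice to lower the
  learning rate;
- the fit is bit-for-bit reproducible from `FitConfig` (seed governs batch
  order only, since the initialization is deterministic).

Defaults: `prior_scale = 1.0` (σ is a standard deviation), `learning_rate
= 1e-3`, `batch_size = min(n, 32)` (full-batch — hence deterministic
gradient descent — below 32 samples), `epochs = 1000`, `convergence_tol =
1e-6`. The learning rate trades stability for speed: the contraction per
step is governed by `lr · depth · p(1−p)`, so very deep samples
(depth ≫ 10⁵) may need a smaller rate, and near-saturated designs benefit
from more epochs with `convergence_tol = 0`.

### Design matrices

Categorical covariates with L levels become L−1 indicators against a
reference level, the first level *in order of appearance* in the metadata
(deterministic and visible in `encoding_map`). Continuous covariates pass
through unscaled (optional centering). Rank-deficient designs warn rather
than error: the prior keeps the fit well-posed, mirroring its role as
regularization in high dimensions.

## Ranking and its interpretation

Taxa are ranked ascending by their clr differential per covariate; ties
break by taxon id (stable, deterministic). Because the load bias shifts
every taxon's differential by the same constant, the ordering — and any
pairwise difference `clr_i − clr_j`, which equals the log-fold change of
the ratio i:j — is bias-free, while individual values are not. The API
therefore never labels a taxon "unchanged"; every `RankResult` carries the
caveat string. `suggest_references` operationalizes the two desiderata for
a log-ratio denominator — present in most samples, plausibly stable — as a
prevalence filter followed by distance-to-median-rank ordering; the
quantile band is a user parameter with no hidden default because no
quantitative rule for "extreme rank" exists.

## Log-ratio tests

`compute_log_ratio` evaluates, per sample, the log of the geometric mean
of the numerator set over the geometric mean of the denominator set.
Geometric-mean aggregation is the natural extension of single-taxon
ratios (an average in log space); single-taxon sets are unaffected. Any
sample with a zero in either set is dropped and recorded — zeros are
treated strictly as missing, never imputed — and retained + dropped always
partitions the input. Paired t-tests (two-sided, via the scipy
one-sample t on differences) and Pearson/Spearman correlations run on
retained samples only. No multiple-testing correction is applied by
default; a Benjamini–Hochberg option exists for the naive per-taxon table,
which is the one place a family of tests is produced.

Absolute-abundance reconstruction divides counts by per-taxon copy numbers
(if given), re-closes to proportions, and multiplies by the per-sample
load, so row sums equal the load exactly. Because the load enters as a
per-sample scalar, every log-ratio statistic is identical before and after
reconstruction — the property the acceptance checks assert at 1e-10.

## The simulator

`simulate_differentials` draws true log-fold differentials from
Normal(center, spread). The generating distribution of real effect sizes
is unknowable; a normal with adjustable center is the minimal documented
choice, and a negative center reproduces the scenario where the average
taxon declines and center-of-mass reference frames mislead.
`apply_load_bias` implements `δ̂ = δ − log K` *exactly* (the class invariant
is asserted with zero tolerance). FP/FN labels use explicit thresholds:
truly changed iff |δ| > 0.5, detected iff |δ̂| > 0.5 by default — the
directional phenomenon itself is threshold-free, but confusion counts need
a bar, and 0.5 (≈1.6-fold) is a conventional minimal effect of interest.

`simulate_count_experiment` draws group A multinomially from a base
composition (uniform by default) and group B from
`closure(base · exp(δ))`, with paired metadata and per-sample loads
reflecting log K. It emulates multinomial sequencing noise only — no
overdispersion, no taxon correlation structure, no compositional
zeros beyond sampling zeros, equal depth across samples. Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to the extra-multinomial variability of real
libraries.

## Problem sizes and numerics

The test suite and acceptance script use 16–200 samples, 8–50 taxa and
depths of 1500–5000 — large enough that parameter recovery is
informative (Spearman ≥ 0.9 between true and estimated clr differentials
at n = 200, D = 50, depth = 5000) while the whole battery runs in seconds.
Transform invariants (alr/alr⁻¹ round trip, clr zero-sum, ilr isometry)
are asserted at 1e-10 absolute, comfortable for double precision up to
D ~ 10⁵. The default ilr basis is the sequential-binary-partition of a
balanced bifurcation of the taxa in table order — deterministic and
orthonormal by construction; user-supplied bases (e.g. phylogeny-derived)
are accepted but never built from trees here.

## Known limitations

- No overdispersed likelihoods (Dirichlet-multinomial, negative binomial)
  and no posterior uncertainty on β; the MAP point estimate is the product.
- Reference-set optimization (searching the 2^D possible frames) is out of
  scope; `suggest_references` is a heuristic shortlist, not an optimum.
- Zeros preclude a log-ratio for the affected sample; when two taxa never
  co-occur the ratio test is impossible and presence/absence methods are
  the alternative.
- BIOM is read-only; all outputs are TSV/JSON by design.
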