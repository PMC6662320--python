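# Methods

## The estimation problem

Two data sources report the proportion of a habitat in each cell of a
regional grid. A ground survey visits a small subset of cells and maps them
essentially without bias but with some recording error; a remote-sensing
census classifies every cell but with error and with bias that can drift
across the region (different satellite composites, climatic gradients in the
spectral signal). Neither source observes the true proportion `Z_i`. The
package estimates the latent field `Z` and the regional total `sum_i Z_i`
from both sources jointly, propagating each source's bias and precision.

## Model

For cell `i` with easting `E_i`, northing `N_i`:

    Y_i ~ N0(Z_i, sigma^2)                      (ground survey, observed on a subset)
    Q_i ~ N0(alpha_i + beta_i Z_i, tau^2)       (remote-sensing census, all cells)

    alpha_i = delta1 + theta1 N_i + theta2 E_i
    beta_i  = delta2 + theta3 N_i + theta4 E_i

`N0(m, s^2)` is the normal distribution truncated at zero and renormalized:
proportions cannot be negative but the observation noise is otherwise
treated as symmetric. Truncation is at zero only — there is deliberately no
upper truncation at 1 in the likelihood; the upper bound is enforced through
the prior on `Z` instead. The bias surface `(alpha, beta)` is linear in the
coordinates: `alpha` is bias irrespective of patch size, `beta` bias
proportional to it.

### Priors

- `Z_i ~ TN_[0,1](z_mu, z_sd^2)` independently, with hyperpriors
  `z_mu ~ U(0, 1)` and `z_sd ~ U(0.01, 2)`. The hierarchical prior is the
  package's deliberate design choice over a flat `U(0, 1)` prior on each
  cell. With a flat prior and a habitat occupying only a small fraction of
  each cell (the common case), the marginal likelihood genuinely prefers a
  collapsed explanation — treat the census layer as one zero-truncated noise
  blob (`beta ~ 0`) and leave the thousands of unsurveyed `Z_i` free on
  `[0, 1]` — because a concentrated latent field wastes flat-prior mass on
  every cell. Letting the field learn its own location and spread removes
  that pathology; the flat prior remains available as
  `PriorSpec(z_prior="uniform")` (and is the `z_sd -> large` limit of the
  hierarchical one).
- `sigma ~ U(sigma_lower, sigma_upper)`: informative, ideally elicited from
  QA repeat visits (`elicit_sigma_prior`: point estimate
  `sd(y_first - y_second)/sqrt(2)`, inflated by a factor of 2 into an upper
  bound). An informative survey-error prior is what makes the bias
  parameters identifiable: without it the model cannot decide which source
  to calibrate against which.
- `tau ~ U(0, tau_upper)` with `tau_upper = 1` by default: the census error
  is left flexible.
- Bias coefficients: zero-mean Gaussians with sd 10 *on standardized
  coordinates*. Eastings and northings are centred and scaled to unit sd
  internally (metre-scale coordinates make raw `theta` magnitudes ~1e-6 and
  condition the sampler badly); draws are reported back on the original
  scale. `log_joint` evaluates the same standardized-coordinate prior, so
  the library's density and the sampler's target coincide.

## Inference

Metropolis-within-Gibbs, three kinds of move per sweep:

1. **Latent field.** Given the scalars, the `Z_i` are conditionally
   independent, so all cells update simultaneously. The proposal for each
   cell is a Laplace approximation of its full conditional: the Gaussian
   precision-weighted combination of the survey term, the census term and
   the latent prior, followed by one Newton step restoring the gradient and
   curvature of the z-dependent truncation constants (`-log Phi` terms) of
   both observation models, truncated to `[0, 1]`. The Metropolis accept
   step uses the exact truncated likelihood, so the approximation costs
   acceptance rate (typically >0.9), never correctness.
2. **Joint scalar move.** All free scalars — the coefficients, `log sigma`,
   `log tau`, and the latent hyperparameters — take an adaptive random-walk
   step (empirical covariance learned during adaptation), and the *entire
   latent field is refreshed* from its Laplace conditional under the
   proposed scalars. Because the refresh density appears in the
   Metropolis-Hastings ratio, this behaves like a random walk on the
   marginal posterior of the scalars. This move is what crosses the ridge
   between the bias coefficients and the latent field: when `tau` is small
   the census ties them together so tightly that single-block updates have
   effective sample sizes in the single digits.
3. **Single-block refinements.** A joint adaptive random walk on the
   coefficients alone, log-scale walks for `sigma` and `tau` inside their
   uniform supports, and random-walk updates for `z_mu` (plain) and `z_sd`
   (log-scale). These are cheap conditional refinements between joint jumps.

Adaptation (proposal scales by Robbins-Monro toward standard acceptance
targets, covariances from running moments) is frozen after `n_adapt`
iterations, preserving the correct stationary distribution afterwards.

Initialization: `Z_i` at the survey value where present, else the census
value clamped to `[0.001, 0.999]`; `delta2 = 1`, other coefficients 0;
`sigma` at its prior midpoint; `tau` at half the empirical sd of the census
layer (starting `tau` at a large prior midpoint can strand the chain in the
collapsed basin described above). A non-finite starting density triggers
re-initialization from the priors, up to 20 attempts.

Numerical guards: error sds are floored at 1e-7 (duplicated or noise-free
layers otherwise drive `sigma` or `tau` to zero, where the likelihood
`~ sd^-n` at zero residual underflows); conditional precisions are floored
and proposal sds capped at 3; inverse-CDF truncated sampling falls back to
scipy's rejection sampler for intervals saturating the normal CDF
(|z-score| beyond ~7).

Defaults: 3 chains, 2,000 adaptation, 5,000 burn-in, 10,000 kept iterations
thinned by 10. Full latent draws are stored up to 20,000 cells; above that
only per-draw totals and running moments are kept — sufficient for
`total_extent`, which reports the posterior median and central 95% interval
of `sum_i Z_i * cell_area * area_scale` over draws (median-of-totals, not
total-of-medians).

Convergence is assessed by split-Rhat and effective sample size (arviz) on
every free scalar and a random subsample of 100 latent components (the
per-draw total when full draws are not stored); any Rhat above 1.1 flags the
fit. A flagged fit is a warning state, not an exception: summaries are still
produced, carrying an explicit not-converged marker.

## Single-source estimators

`census_total` sums the census proportions times the cell area.
`survey_total` is unstratified mean expansion: grid size times the mean of
the surveyed proportions (the benchmark design has no strata; stratified
expansion as used by operational ground surveys is out of scope).
`source_agreement` is the squared Pearson correlation between paired
`(Y_i, Q_i)`; a constant side returns 0 with a degenerate-variance warning.

## Synthetic-data generator

`simulate_dataset` emulates the benchmark design on a `g x g` grid (default
100): per replicate draw `z_mean ~ U(0, 0.2)`, `z_var ~ U(0.01, 0.05)`,
`tau ~ U(0, 0.15)`, `alpha ~ U(-0.02, 0.02)`, `sigma ~ U(0, 0.02)` (low
regime) or `U(0, 0.2)` (high regime); then `Z_i ~ N0(z_mean, z_var)`,
`Q_i ~ N0(Z_i + alpha, tau^2)` on every cell, and `Y_i ~ N0(Z_i, sigma^2)`
on 25 cells drawn uniformly without replacement (redrawn each replicate).
The constant bias is placed inside the truncated mean rather than added
after truncation — distributionally equivalent up to the truncation
interaction and consistent with the census observation model. Generated
proportions are clipped into `[0, 1]` (exceedances are negligible at these
parameter levels). Each replicate uses two independent random substreams —
one for the latent field and census, one for the survey — so the census
layer is bit-identical across regimes at matched seeds and study results do
not depend on execution order or worker count.

What the generator does *not* emulate: spatial autocorrelation of the
habitat, spatially varying generating bias (`theta = 0`, `beta = 1` in
generation, although the full spatial model is fitted), stratified survey
designs, and classification errors that depend on the habitat itself.
Passing tests therefore demonstrate correct inference under the stated
noise model, not robustness to real survey or classification artefacts.

`simulate_discordant_dataset` builds the pathological regime where the two
sources disagree fundamentally: the survey sees moderate cover while the
census reports essentially none anywhere (agreement R^2 ~ 0). The census
then demands `alpha + beta Z ~ 0` almost noiselessly while the survey pins
`Z` at moderate values — the identifiability conflict under which the joint
model is expected, and observed, to fail convergence.

## Study harness and problem sizes

`run_study` scores the combined posterior-median estimator and the two
single-source estimators over independent replicates (parallelizable with
joblib; bit-reproducible across worker counts). Non-converged fits are
retained in the RMSE with their flag recorded; `exclude_nonconverged`
offers the sensitivity variant. The package's test suite runs the study at
30x30 with 100 replicates and shortened chains
(2 chains, 300/200/600 thinned by 3), its parameter-recovery check at 30x30
with 100 surveyed cells (2 chains, 800/600/1200 thinned by 3), and the tiny
quadrature-oracle comparison at 4 cells with 3 chains of 14,000 kept
iterations; the full 100x100, 1,000-replicate study with the combined model
is an overnight CLI run (`habfuse simstudy`). `scripts/acceptance.py`
recomputes the single-source RMSEs at the full benchmark scale (1,000
replicates, 100x100), which needs no MCMC and runs in minutes.

## Known limitations

- The hierarchical latent prior pools all cells exchangeably; a strongly
  multimodal habitat distribution (e.g. all-or-nothing cells) is summarized
  by a single truncated Gaussian.
- With a discordant census the model resolves cleanly to "census is noise"
  (`beta ~ 0`) under the hierarchical prior and mixes well; the classic
  non-convergence signature appears when the census is both precise and
  contradictory, or under the flat latent prior.
- The survey-only estimator is deliberately the naive mean expansion;
  design-based variants (stratification, finite-population corrections)
  are out of scope.
- Quantile summaries assume enough kept draws; with heavy thinning the 95%
  interval endpoints carry Monte-Carlo noise of their own.
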