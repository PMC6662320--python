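# habfuse

Bayesian fusion of sparse ground-survey and dense remote-sensing habitat
proportions.

## The problem

Regional habitat extent can be estimated two ways: extrapolate from a small
ground survey (accurate and unbiased where it looks, but it looks at very
little), or sum a satellite-derived land-cover map (full coverage, but the
classification carries error and spatially drifting bias). `habfuse` treats
the true habitat proportion of each grid cell as a latent variable observed
imperfectly by both sources, and estimates the latent field — and the
regional total — from the two layers jointly, with the bias and precision of
each source quantified and propagated. It is aimed at ecologists and
biostatisticians combining field campaigns (professional or citizen-science)
with remote-sensing products, and ships the full simulation machinery used
to benchmark the combined estimator against either source alone.

## Model

With `Z_i` the true proportion in cell `i`, `Y_i` the ground-survey
proportion (observed on a sparse subset) and `Q_i` the remote-sensing
proportion (observed everywhere):

    Y_i ~ N0(Z_i, sigma^2)
    Q_i ~ N0(alpha_i + beta_i * Z_i, tau^2)

    alpha_i = delta1 + theta1 * Nrth_i + theta2 * East_i
    beta_i  = delta2 + theta3 * Nrth_i + theta4 * East_i

where `N0` denotes the normal distribution truncated at zero. The survey is
assumed unbiased; the census layer may be biased, with the bias surface
`(alpha, beta)` varying linearly over the region. Fitting is by
Metropolis-within-Gibbs MCMC with an informative prior on `sigma` elicited
from quality-assurance repeat surveys (`sd(y_first - y_second)/sqrt(2)`),
a flexible uniform prior on `tau`, and a hierarchical truncated-normal prior
on the latent field. See `docs/methods.md` for the sampler design, prior
choices and their rationale.

## Worked example

Simulate one benchmark dataset (30x30 grid, low survey error, 100 surveyed
cells), fit the model, and compare the three extent estimators:

```python
import habfuse as hf

regime = hf.SimRegime.low_sigma(grid_side=30, n_survey=100, n_reps=1, seed=3)
data = hf.simulate_dataset(regime)

config = hf.SamplerConfig(n_chains=3, n_adapt=2000, n_burnin=2000,
                          n_iter=6000, thin=6, seed=1)
draws = hf.sample_posterior(data.census, data.survey,
                            hf.PriorSpec(sigma_lower=0, sigma_upper=0.02), config)
report = hf.check_convergence(draws)
median, lo, hi = hf.total_extent(draws)
print(f"combined extent: {median:.1f} (95% CI {lo:.1f}-{hi:.1f})")
print("census-only:", round(hf.census_total(data.census).total, 1))
print("survey-only:", round(hf.survey_total(len(data.census), data.survey).total, 1))
print("R2 agreement:", round(hf.source_agreement(data.census, data.survey), 3))
```

prints (with `data.true_z.sum() = 159.4` the known truth):

```
combined extent: 156.7 (95% CI 143.6-170.7)
census-only: 198.9
survey-only: 166.3
R2 agreement: 0.439
```

The census-only total overshoots badly — summing zero-truncated noisy
proportions inflates sparse habitats, on top of the constant bias `alpha` —
while the combined posterior both covers the truth and is tighter than the
survey-only expansion. `summarize_posterior(draws, diagnostics=report)`
tabulates posterior quantiles of all scalar parameters with the convergence
marker attached; in this run the fit converges (no split-Rhat above 1.1) and
the generating values (`tau = 0.135`, `alpha = 0.005`, `beta = 1`) fall
inside their 95% intervals.

The same workflow is available from the shell: `habfuse simulate`,
`habfuse fit` (census/survey/QA tables in, draws/summary/diagnostics/extent
out), `habfuse summarize`, and `habfuse simstudy` for the full replicate
study (at the benchmark scale of 100x100 cells and 1,000 replicates with the
combined model this is an overnight run; restrict `--methods` to the
single-source estimators for a fast pass).

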