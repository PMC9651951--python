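# timecells

Hierarchical Bayesian analysis of hippocampal **time cells** — neurons
that fire at reliable latencies within a delay period — aimed at one
quantitative question: *is the population's timeline logarithmically
compressed?*

The package is for computational neuroscientists and biostatisticians
who want to (a) fit trial/cell/population hierarchies to delay-period
spike trains, (b) test the Weber-Fechner prediction on their own data,
or (c) study the estimator itself on synthetic populations with known
ground truth.

## The model

Given spike times t₁…t_m on trial *i* of cell *c*, spikes follow a
field-plus-background mixture; the field location jitters across
trials; and the peaks M_c follow a bounded power law across the
population:

    p(t)  = a₁ · N(t | μᵢ, σ_w²) + (1 − a₁) / L
    μᵢ    ~ N(M_c, σ_t²)
    M_c   ~ M^(−α) / C(α)          on [min, max]

All levels are fitted jointly by MCMC (an adaptive
Metropolis-within-Gibbs sampler written for this hierarchy — see
`docs/methods.md`).  Logarithmic compression makes two sharp
predictions: **α = 1** (peaks uniform on a log-time axis) and
**σ_w increasing linearly with M**.  Separating the within-trial width
σ_w from the across-trial jitter σ_t is what lets the second prediction
be tested without the trial-averaging artifact.

Four alternative hierarchies (log-normal field, trial-varying width,
exponential and Weibull population laws) are fitted the same way and
compared by WAIC.  Upstream of the hierarchy, a maximum-likelihood
screen selects time cells (rate ceiling, 5.66-nat likelihood-ratio
threshold, even/odd reliability, peak-within-delay) and a
Kolmogorov–Smirnov grid search chooses the power law's support.
Downstream, `popstats` reproduces the population statistics:
width-vs-peak regressions with Bayes factors, early/late splits, the
sign-split χ², event-timing correlations, and the log-CDF diagnostic.

## Worked example

Fit the main model to a synthetic population generated with known
α = 1 and width law σ_w = 0.11 + 0.14·M:

```python
from timecells import GeneratorConfig, generate_population, TimeCellModel
from timecells.popstats import (alpha_posterior_summary, regress_quadratic,
                                sign_split_chi2)

cfg = GeneratorConfig(n_time_cells=60, n_distractor_cells=0,
                      n_interneurons=0, trials_per_cell=25,
                      alpha=1.0, seed=7)
dataset, truth = generate_population(cfg)

model = TimeCellModel(dataset, unit_ids=truth.time_cell_ids(),
                      variant="main", peak_min=0.35, peak_max=7.2)
res = model.fit(n_chains=4, warmup=1000, samples=500, seed=1)

a = alpha_posterior_summary(res.alpha_draws)
cells = res.cell_summary()
rep = regress_quadratic(cells["sigma_w"], cells["M"])
n_gt = int((cells["sigma_t"] > cells["sigma_w"]).sum())
chi2, p = sign_split_chi2(n_gt, len(cells))
```

This prints (≈30 s on one core):

```
alpha posterior mean = 1.11, 95% CI [0.84, 1.40]
posterior mass in [0.9, 1.1] = 0.36
width-vs-peak slope = 0.164 +/- 0.014 (generating value 0.14)
best regression model by Bayes factor: linear
sigma_t > sigma_w for 45/60 cells (chi2(1) = 14.0, p = 0.00018)
```

Reading: the compression exponent's credible interval comfortably
covers the generating value 1 (and excludes 0 — the uniform-population
hypothesis); the width-law slope is recovered within two standard
errors and the Bayesian regression comparison picks the purely linear
model; and for most cells the across-trial jitter exceeds the
within-trial width — the trial-averaging artifact the hierarchy exists
to remove.  At the study's full size (131 cells) the α interval
tightens to roughly ±0.2.

## Pipeline

The same stages run from the shell, with content-hash caching and all
stage seeds derived from one global seed:

```sh
timecells run --seed 5 --out artifacts          # simulate → screen → bounds → fit → analyze
timecells init config.yaml                      # editable default config
timecells run --config config.yaml
```

`artifacts/report/report.json` holds the machine-readable population
report; `report.md` and `heatmap.png` (peak-sorted normalized rates on
linear and log time axes) are the human-readable views.

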