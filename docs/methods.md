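# Methods

This note documents the statistical models implemented by `timecells`,
the synthetic data they are exercised on, the numerical choices made
where the design was genuinely open, and the limitations of both.

## The hierarchy

Hippocampal time cells fire within a circumscribed window (a "time
field") at a reliable latency after a delay-initiating event.  The
package models spike times within a fixed delay of length *L* (8 s by
default) at three levels simultaneously.

**Trial level.**  Given *m* spike times on trial *i* of cell *c*, each
spike is an independent draw from a two-component mixture: with
probability *a₁* from a Gaussian field centered at the trial-level
location μᵢ with within-trial width σ_w, otherwise from a uniform
background over the delay,

    p(t) = a₁ · N(t | μᵢ, σ_w²) + (1 − a₁) / L .

This deliberately ignores spike-history dependence; the mixture is a
density over spike times conditional on the spike count, so any count
law is compatible (the generator uses Poisson counts).

**Cell level.**  The field location shifts across trials,
μᵢ ~ N(M_c, σ_t²).  Separating the within-trial width σ_w from the
across-trial jitter σ_t is the point of the hierarchy: trial-averaged
field widths confound the two, and the averaging artifact grows with
the delay.

**Population level.**  The cell peaks M_c follow a bounded power law on
[min, max],

    p(M = τ) = τ^(−α) / C(α),   C = (max^(1−α) − min^(1−α)) / (1 − α),

with C = ln(max) − ln(min) at α = 1.  α = 0 is a uniform population;
α = 1 means the peaks uniformly tile the *logarithmic* time axis — the
Weber-Fechner arrangement, equivalently: peak density ∝ 1/τ and
geometric spacing of adjacent fields.

**Alternative variants** replace exactly one level: a log-normal
(skewed) field whose median exp(μ) serves as the peak summary and whose
width is reported as the log-normal sd √((e^{σ²}−1)·e^{2μ+σ²}); a
trial-varying-width model (location pinned at M_c, per-trial width
σ_wi ~ N(σ_W, σ_t²)); and exponential or Weibull population laws,
renormalized to the same bounded support on which the peaks were
selected.

## Priors

Unstated quantities carry weakly-informative, support-respecting
priors: α ~ Uniform(0, 10); a₁ ~ Beta(2, 2) per cell; σ_w, σ_t, σ_W ~
Half-Normal(0, 2 s); the log-normal shape σ ~ Half-Normal(0, 1)
(dimensionless); β ~ Uniform(0, 10 s⁻¹); Weibull k ~ Uniform(0.05, 10),
λ ~ Uniform(0.01, 20 s).  All are switchable through `PriorSettings`.
a₁ is one parameter per cell, constant across trials — the minimal
model consistent with the hierarchy's plate structure.

## Boundary convention

A Gaussian field near the delay edge leaks mass outside [0, L].  The
generator resamples out-of-window field spikes and trial locations
(truncated-normal behavior), keeping every emitted spike inside the
window.  The model mirrors this by default (`truncate_field=True`): the
field density is renormalized to [0, L], trial locations are confined
to the window, and the truncated-normal normalizer of the μᵢ prior is
carried in the M and σ_t updates.  The literal untruncated mixture is
available with `truncate_field=False`; fitting it against
edge-resampled data visibly deflates σ_w for cells peaking after ~6 s
(we measured a −0.24 s bias at 8 s delays), which propagates into the
width-vs-peak slope.  The public one-spike primitives
(`trial_mixture_logpdf`, `lognormal_field_logpdf`) are the literal
untruncated forms.

## Sampler

No probabilistic-programming backend is used; the posterior is sampled
with an adaptive Metropolis-within-Gibbs scheme written directly on the
flattened (cell, trial, spike) arrays:

- every trial-level latent, every cell-level parameter block, and the
  population parameters are updated with random-walk proposals
  (log-scale for scales, logit-scale for a₁, with the matching Jacobian
  terms); per-parameter step sizes adapt toward 44% acceptance during
  warm-up (Robbins-Monro, gain t^−0.6) and are frozen afterwards;
- a joint scale move rescales σ_t together with the trial deviations
  (μᵢ − M_c); the trial-prior change cancels the transform Jacobian
  exactly, so the move traverses the funnel that appears when σ_t is
  small;
- an independence proposal redraws μᵢ from its prior, for which the
  Hastings ratio reduces to the spike-likelihood ratio; this lets
  ambiguous trials jump between field and background interpretations;
- all trial- and cell-level updates are vectorized (one pass over the
  spike array per block; accepted proposals patch a cached per-spike
  log-mixture), so a 131-cell × 25-trial fit with 4 chains ×
  (1000 + 500) iterations takes ~30 s on one core.

Default chain settings are 8 chains × (4800 warm-up + 200 kept); tests
and the pipeline default run a documented reduced schedule (4 × (1000 +
500)).  Convergence is summarized by split-R̂ over the cell-level and
population parameters (arviz); a fit with max R̂ > 1.05 is flagged
`converged=False` rather than rejected.  At the reduced schedule a few
cell-level σ_t parameters typically sit near R̂ ≈ 1.1; the population
α is far tighter (R̂ < 1.01).

Point estimates reported downstream are posterior means throughout.

## WAIC

Model comparison uses WAIC on the deviance scale,
−2·Σⱼ(lppd_j − p_j), with lppd_j = log mean_draws exp(ll_j) and the
variance penalty p_j = Var_draws(ll_j).  The pointwise unit j is the
(cell, trial) pair, the exchangeable replication unit of the hierarchy,
and ll_j sums the trial's spike log-mixture, the trial-latent prior
density, and an equal per-trial share of the cell peak's population log
density.  Including the latent levels matters: the population law
touches the observed-data likelihood only through prior shrinkage, so a
spikes-only pointwise likelihood cannot distinguish population variants
at all (measured differences of ~10 against standard errors of ~12 at
30 cells).  Even with the joint likelihood, the exponential and Weibull
population alternatives are near-indistinguishable from the power law
at a few dozen cells — the KL divergence from the α = 1 bounded power
law to the best truncated exponential is only ≈ 0.045 nats per cell —
whereas the field-shape and trial-variability alternatives separate by
hundreds to thousands of WAIC units.

## Screening and boundary search

Candidate units pass a conservative multi-criterion screen before any
hierarchical fitting: mean delay rate < 5 Hz (excludes interneurons); a
Gaussian-bump rate model λ(t) = a₀ + a₁·exp(−(t−μ)²/2σ²) must beat the
constant-rate model by > 5.66 nats of log-likelihood (the χ²(3)/2 tail
at p < .01), on all trials and on even and odd trials separately; and
the fitted μ must lie inside the delay.  The likelihood is the
continuous-time inhomogeneous point-process form Σⱼ log λ(tⱼ) −
n_trials·∫₀ᴸ λ, maximized by multi-start L-BFGS-B (16 seeded starts)
with μ unconstrained so out-of-window fields can be detected and
rejected.

Because μ and σ are unidentified under the constant model, the
maximized LLR behaves as a scan statistic, not a χ²(3)/2 variable; left
unconstrained it false-positives at 5–10% where the 5.66 threshold
nominally implies ~1%.  The screen therefore floors the field width at
`sigma_min` (default 0.3 s), bounding the number of effective field
placements; the measured null rate is then ≈ 2% (three independent
400-unit constant-rate batches).

The support [min, max] of the peak power law is chosen by grid search
(lower 100–400 ms in 50 ms steps, upper 6400–8000 ms in 400 ms steps):
for each pair, peaks inside the pair are fitted (α posterior mean under
a flat prior, computed by dense 1-D quadrature; or ML in fast mode) and
KS-tested against the fitted CDF; the pair with the highest p wins.
Note a structural limitation: any outlier-free sub-range of a power-law
sample is itself an exact power-law sample, so the search can only
*exclude contaminated* ranges, not *pin* the true edge; with ~150 peaks
the upper boundary in particular is close to a tie among all clean
candidates, and planted contamination of a few points in the sparse
upper tail is statistically invisible.  The lower boundary, where the
power law concentrates its mass, is recovered reliably.

## Population statistics

- Width-vs-peak and jitter-vs-peak relations use OLS with intercept,
  linear and quadratic terms; Bayesian model comparison over the four
  nested candidates uses the BIC approximation BF ≈ exp(ΔBIC/2), with
  the winning model's posterior-odds BF_M against equal prior odds.
  An exactly collinear design raises; an exact fit assigns the most
  parsimonious exact model posterior mass 1.
- The early/late split (threshold 2 s) tests compression within groups:
  KS against a uniform law over each group's observed peak range, a
  width regression per group, and a two-sample KS on min-max normalized
  peaks across groups.
- χ² for the "σ_t exceeds σ_w in k of n cells" sign split uses the
  Yates-corrected one-degree-of-freedom form 2(|k − n/2| − ½)²/(n/2);
  for (93, 131) the corrected form gives 22.3 where the uncorrected
  form gives 23.1.
- Bayesian t-tests (event-timing correlations; early > late contrasts)
  use the JZS Bayes factor with a Cauchy(0, √2/2) prior on the
  standardized effect, computed by noncentral-t quadrature; one-sided
  versions truncate the prior.  BF magnitudes from GUI packages are
  comparable only qualitatively.
- The log-CDF diagnostic regresses the empirical CDF of peaks on
  log(peak): R² ≈ 1 indicates α ≈ 1 (a geometric peak sequence gives
  R² = 1 exactly).

## Synthetic data

The generator emulates the structure the analysis assumes: 131 time
cells by default, 8 s delay, peaks ∝ M^−α on [0.35, 7.2] s with α = 1;
σ_w = 0.11 + 0.14·M; σ_t(M) = −0.33 + 0.84·M − 0.11·M² clipped below at
0.05 s (the fitted quadratic is negative near M = 0); in-field fraction
a₁ = 0.7; Poisson spike counts with mean 12 per trial (≈1.5 Hz, safely
under the 5 Hz interneuron ceiling); uniform-firing distractors at the
same rate and "interneurons" at 6–10 Hz to exercise the screen.
Per-trial behavioral event offsets ~ N(0, 0.3² s) shift the field
location with gain 0.5·max(0, 1 − M/2), i.e. coupling that decays to
zero for cells peaking after 2 s, emulating the early-cell sensitivity
to delay-onset timing.  Values not fixed by the study conditions
(a₁, spike rate, event scale and coupling) were chosen once as
physiologically reasonable for dorsal CA1 pyramidal cells and are all
configurable.

What the generator does **not** emulate: position/velocity/kinematic
confounds (behavior enters only as scalar event offsets), theta
rhythmicity or spike-history structure, ramping "temporal context"
cells, bursting, or recording artifacts.  Passing recovery tests on
this generator therefore shows the estimator is correct under the
model's own assumptions plus known violations we inject (distractors,
interneurons, event coupling) — not that real recordings satisfy those
assumptions.

## Problem sizes used in tests

Recovery tests run 131 cells × 25 trials at the reduced MCMC schedule
(3 seeds); model-comparison tests run 30 cells × 25 trials against the
two likelihood-level alternatives (3 seeds); screen calibration uses
500 constant-rate units; the full pipeline test runs a 15-unit
population end to end.  These sizes keep the complete suite to a few
minutes while leaving every quantitative contract at its stated
tolerance.

## Known limitations

- The sampler is single-chain-serial and pure numpy; it is fast at the
  study's scale but has no gradient information, so very large
  populations (thousands of cells) would favor an HMC backend.
- WAIC standard errors between separately-fitted models include Monte
  Carlo noise from both fits; orderings closer than ~2 SE should be
  treated as ties.
- The σ_t(M) quadratic is a descriptive law; near the delay edges σ_t
  estimates are attenuated by the window even with the truncation
  handled, so edge cells' jitter is conservatively estimated.
- KS p-values in the boundary search are uncorrected for α being
  estimated from the same peaks, matching the described procedure; they
  are upward-biased as goodness-of-fit p-values.
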