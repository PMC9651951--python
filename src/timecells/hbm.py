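"""Hierarchical Bayesian models of time-cell firing.

Five model variants share one three-level hierarchy.  For the Main
Model, spikes on trial i of cell c follow the mixture

    p(t) = a1_c * N(t | mu_ci, sigma_w_c^2) + (1 - a1_c) / L,

the trial-level field location follows

    mu_ci ~ Normal(M_c, sigma_t_c^2),

and the cell-level peaks follow the bounded power law

    M_c ~ M^-alpha / C(alpha)   on [peak_min, peak_max].

Variants replace exactly one level:

``lognormal_field``   log-normal (skewed) field; the trial-level
                      parameter is the field median p_ci = exp(mu), with
                      p_ci ~ Normal(M_c, sigma_t_c^2).
``trial_vary_width``  field location fixed at M_c; the width varies by
                      trial, sigma_w_ci ~ Normal(sigma_W_c, sigma_t_c^2).
``exponential_pop``   peaks M_c ~ Exponential(beta), renormalized to the
                      bounded support.
``weibull_pop``       peaks M_c ~ Weibull(k, lambda), renormalized to
                      the bounded support.

Sampling is by adaptive Metropolis-within-Gibbs: every latent block
(trial level, cell level, population level) is updated with a
random-walk proposal whose scale adapts during warm-up toward a 44%
acceptance rate; all trial- and cell-level updates are vectorized.
Posterior summaries follow the posterior-mean convention; model
comparison uses WAIC on per-(cell, trial) pointwise log-likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit, ndtr

from .distributions import (
    bounded_powerlaw_logpdf,
    bounded_powerlaw_norm,
    lognormal_sd,
    population_logpdf,
    trial_mixture_logpdf,       # noqa: F401  (re-exported API)
    lognormal_field_logpdf,     # noqa: F401
)
from .spikeio import SpikeTrainDataset

__all__ = [
    "VARIANTS",
    "ModelSpec",
    "PriorSettings",
    "TimeCellModel",
    "TimeCellResults",
    "WaicResult",
    "compute_waic",
    "waic_compare",
    "trial_mixture_logpdf",
    "lognormal_field_logpdf",
]

VARIANTS = ("main", "lognormal_field", "trial_vary_width",
            "exponential_pop", "weibull_pop")

_TARGET_ACC = 0.44
_RHAT_FLAG = 1.05


@dataclass
class PriorSettings:
    """Weakly-informative, support-respecting priors (all in seconds
    where dimensional).  ``alpha ~ Uniform(0, alpha_max)``; scales are
    half-normal; ``a1 ~ Beta(2, 2)``."""

    alpha_max: float = 10.0
    sigma_w_scale: float = 2.0
    sigma_t_scale: float = 2.0
    sigma_shape_scale: float = 1.0   # log-normal field shape parameter
    beta_max: float = 10.0           # exponential population rate (1/s)
    k_max: float = 10.0              # Weibull shape
    lam_max: float = 20.0            # Weibull scale (s)


@dataclass
class ModelSpec:
    variant: str = "main"
    peak_min: float = 0.35
    peak_max: float = 7.2
    truncate_field: bool = True
    priors: PriorSettings = dc_field(default_factory=PriorSettings)
    n_chains: int = 8
    warmup: int = 4800
    samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.n_chains < 1 or self.warmup < 1 or self.samples < 1:
            raise ValueError("mcmc counts must be >= 1")


# ---------------------------------------------------------------------------
# WAIC


@dataclass
class WaicResult:
    waic: float            # deviance scale; lower is better
    lppd: float
    p_waic: float
    pointwise_elpd: np.ndarray   # per-(cell, trial) lppd_j - p_waic_j

    @property
    def n_points(self) -> int:
        return len(self.pointwise_elpd)


def compute_waic(loglik: np.ndarray) -> WaicResult:
    """WAIC from a (draws, points) pointwise log-likelihood matrix.

    WAIC = -2 (lppd - p_waic) with lppd_j = log mean_d exp(ll_dj) and the
    variance-based penalty p_waic_j = Var_d(ll_dj).
    """
    ll = np.asarray(loglik, float)
    if ll.ndim != 2:
        raise ValueError("loglik must be 2-D (draws, points)")
    if ll.shape[0] < 2:
        raise ValueError("need at least 2 draws for the variance penalty")
    if not np.all(np.isfinite(ll)):
        raise ValueError("loglik contains non-finite values")
    m = ll.max(axis=0)
    lppd_j = m + np.log(np.mean(np.exp(ll - m), axis=0))
    p_j = np.var(ll, axis=0)
    elpd_j = lppd_j - p_j
    return WaicResult(
        waic=float(-2.0 * elpd_j.sum()),
        lppd=float(lppd_j.sum()),
        p_waic=float(p_j.sum()),
        pointwise_elpd=elpd_j,
    )


def waic_compare(results: dict) -> pd.DataFrame:
    """Rank models by WAIC; difference SEs from pointwise contributions.

    ``d_waic`` is each model's WAIC minus the best model's, with the
    standard error sqrt(n * var(pointwise difference)).
    """
    names = list(results)
    table = pd.DataFrame(
        {"waic": [results[k].waic for k in names],
         "p_waic": [results[k].p_waic for k in names]},
        index=names,
    ).sort_values("waic")
    best = table.index[0]
    d, se = [], []
    for name in table.index:
        diff = -2.0 * (results[name].pointwise_elpd
                       - results[best].pointwise_elpd)
        d.append(diff.sum())
        se.append(np.sqrt(len(diff) * np.var(diff, ddof=1)) if name != best else 0.0)
    table["d_waic"] = d
    table["d_se"] = se
    return table


# ---------------------------------------------------------------------------
# Sampler internals


def _norm_logpdf(x, loc, scale):
    z = (x - loc) / scale
    return -0.5 * z * z - np.log(scale) - 0.9189385332046727


class _Sampler:
    """One-chain adaptive Metropolis-within-Gibbs for all variants."""

    def __init__(self, model: "TimeCellModel", spec: ModelSpec, seed):
        self.m = model
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        self.L = model.delay_l
        self.variant = spec.variant
        self.it = 0
        self._init_state()
        self._init_scales()

    # -- state -------------------------------------------------------------

    def _init_state(self):
        m, rng = self.m, self.rng
        C, T = m.n_cells, m.n_trials
        lo, hi = self.spec.peak_min, self.spec.peak_max
        eps = 1e-3 * (hi - lo)

        mu0 = np.empty(T)
        for i in range(T):
            t = m.spike_t[m.spike_trial == i] if m.trial_nspikes[i] else None
            mu0[i] = np.median(t) if t is not None and len(t) else np.nan
        cell_med = np.array([
            np.median(m.spike_t[m.spike_cell == c])
            if np.any(m.spike_cell == c) else 0.5 * (lo + hi)
            for c in range(C)
        ])
        fill = cell_med[m.trial_cell]
        mu0 = np.where(np.isnan(mu0), fill, mu0)
        mu0 = np.clip(mu0 + rng.normal(0, 0.05, T), 0.01, self.L - 0.01)

        self.M = np.clip(cell_med + rng.normal(0, 0.05, C), lo + eps, hi - eps)
        self.st = np.full(C, 0.5) * np.exp(rng.normal(0, 0.1, C))
        self.a1 = np.clip(0.5 + rng.normal(0, 0.05, C), 0.05, 0.95)
        if self.variant == "lognormal_field":
            self.sw = np.full(C, 0.2) * np.exp(rng.normal(0, 0.1, C))
            self.mu = np.maximum(mu0, 0.05)
            self.swi = None
        elif self.variant == "trial_vary_width":
            self.sw = np.full(C, 0.5) * np.exp(rng.normal(0, 0.1, C))  # sigma_W
            self.mu = None
            self.swi = np.full(T, 0.5) * np.exp(rng.normal(0, 0.1, T))
        else:
            self.sw = np.full(C, 0.5) * np.exp(rng.normal(0, 0.1, C))
            self.mu = mu0
            self.swi = None

        pr = self.spec.priors
        if self.variant == "exponential_pop":
            self.pop = {"beta": min(rng.uniform(0.2, 1.0), 0.5 * pr.beta_max)}
        elif self.variant == "weibull_pop":
            self.pop = {"k": min(rng.uniform(0.8, 1.5), 0.5 * pr.k_max),
                        "lam": min(rng.uniform(1.0, 4.0), 0.5 * pr.lam_max)}
        else:
            self.pop = {"alpha": min(rng.uniform(0.5, 1.5), 0.5 * pr.alpha_max)}

        self.cur = self._spike_logmix()

    def _init_scales(self):
        m = self.m
        self.s_mu = np.full(m.n_trials, 0.3)
        self.s_swi = np.full(m.n_trials, 0.2)
        self.s_M = np.full(m.n_cells, 0.2)
        self.s_sw = np.full(m.n_cells, 0.3)
        self.s_st = np.full(m.n_cells, 0.3)
        self.s_stg = np.full(m.n_cells, 0.3)
        self.s_a1 = np.full(m.n_cells, 0.5)
        self.s_pop = {k: 0.1 for k in self.pop}

    # -- spike mixture -------------------------------------------------------

    def _field_logpdf(self, loc_trial=None, scale_cell=None, scale_trial=None):
        """Per-spike log field density under (possibly proposed) params.

        With ``truncate_field`` the field is renormalized to [0, L]
        (matching a generator that resamples out-of-window field
        spikes); otherwise the literal untruncated density is used.
        """
        m = self.m
        tc = m.trial_cell
        if self.variant == "trial_vary_width":
            loc_t = loc_trial if loc_trial is not None else self.M[tc]
            scale_t = scale_trial if scale_trial is not None else self.swi
        else:
            loc_t = loc_trial if loc_trial is not None else self.mu
            scale_t = (scale_cell if scale_cell is not None else self.sw)[tc]
        if self.variant == "lognormal_field":
            f = (_norm_logpdf(m.spike_logt, np.log(loc_t)[m.spike_trial],
                              scale_t[m.spike_trial]) - m.spike_logt)
            if self.spec.truncate_field:
                z = ndtr((np.log(self.L) - np.log(loc_t)) / scale_t)
                f = f - np.log(z)[m.spike_trial]
            return f
        f = _norm_logpdf(m.spike_t, loc_t[m.spike_trial], scale_t[m.spike_trial])
        if self.spec.truncate_field:
            z = ndtr((self.L - loc_t) / scale_t) - ndtr(-loc_t / scale_t)
            f = f - np.log(z)[m.spike_trial]
        return f

    def _prior_logZ(self, M=None, st=None):
        """Per-cell log mass of Normal(M, st^2) inside [0, L] (the
        normalizer of the truncated trial-location prior)."""
        M = self.M if M is None else M
        st = self.st if st is None else st
        return np.log(ndtr((self.L - M) / st) - ndtr(-M / st))

    @property
    def _latent_bounded(self) -> bool:
        # every variant with a trial-location latent confines it to the
        # delay window when the field is truncated
        return self.spec.truncate_field and self.variant != "trial_vary_width"

    def _spike_logmix(self, field_logpdf=None, a1_cell=None):
        m = self.m
        f = self._field_logpdf() if field_logpdf is None else field_logpdf
        a = (a1_cell if a1_cell is not None else self.a1)[m.spike_cell]
        return np.log(a * np.exp(f) + (1.0 - a) / self.L)

    # -- adaptation ----------------------------------------------------------

    def _adapt(self, scale, acc):
        if self.it < self.spec.warmup:
            g = min(0.3, (self.it + 1.0) ** -0.6)
            np.multiply(scale, np.exp(g * (acc - _TARGET_ACC)), out=scale)
            np.clip(scale, 1e-4, 10.0, out=scale)

    def _adapt_scalar(self, key, acc):
        if self.it < self.spec.warmup:
            g = min(0.3, (self.it + 1.0) ** -0.6)
            self.s_pop[key] = float(np.clip(
                self.s_pop[key] * np.exp(g * (acc - _TARGET_ACC)), 1e-4, 10.0))

    # -- population conditional ----------------------------------------------

    def _pop_logpdf_sum(self, M, pop=None):
        pop = pop or self.pop
        lo, hi = self.spec.peak_min, self.spec.peak_max
        if self.variant == "exponential_pop":
            return float(np.sum(population_logpdf(M, "exponential_pop",
                                                  {"beta": pop["beta"]}, lo, hi)))
        if self.variant == "weibull_pop":
            return float(np.sum(population_logpdf(M, "weibull_pop",
                                                  {"k": pop["k"], "lam": pop["lam"]},
                                                  lo, hi)))
        a = pop["alpha"]
        return float(-a * np.sum(np.log(M))
                     - len(M) * np.log(bounded_powerlaw_norm(a, lo, hi)))

    def _pop_logpdf_vec(self, M, pop=None):
        # closed forms inline (sampler hot path); the public
        # distributions.population_logpdf is the cross-checked reference
        pop = pop or self.pop
        lo, hi = self.spec.peak_min, self.spec.peak_max
        if self.variant == "exponential_pop":
            b = pop["beta"]
            mass = np.exp(-b * lo) - np.exp(-b * hi)
            return np.log(b) - b * M - np.log(mass)
        if self.variant == "weibull_pop":
            k, lam = pop["k"], pop["lam"]
            z = M / lam
            mass = np.exp(-((lo / lam) ** k)) - np.exp(-((hi / lam) ** k))
            return (np.log(k / lam) + (k - 1.0) * np.log(z) - z**k
                    - np.log(mass))
        return bounded_powerlaw_logpdf(M, pop["alpha"], lo, hi)

    # -- update blocks ---------------------------------------------------------

    def _accept_spikes(self, group_ids, new_mix, log_acc, size):
        """Metropolis accept per group; patch per-spike cached mixture."""
        acc = np.log(self.rng.random(size)) < log_acc
        if new_mix is not None:
            mask = acc[group_ids]
            self.cur = np.where(mask, new_mix, self.cur)
        return acc

    def _update_mu(self):
        m = self.m
        T = m.n_trials
        prop = self.mu + self.s_mu * self.rng.standard_normal(T)
        if self._latent_bounded:
            valid = (prop >= 0.0) & (prop <= self.L)
            if self.variant == "lognormal_field":
                valid &= prop > 0.0
        elif self.variant == "lognormal_field":
            valid = prop > 0.0
        else:
            valid = np.ones(T, bool)
        safe = np.where(valid, prop, self.mu)
        new = self._spike_logmix(self._field_logpdf(loc_trial=safe))
        d_spike = np.bincount(m.spike_trial, new - self.cur, minlength=T)
        Mc = self.M[m.trial_cell]
        stc = self.st[m.trial_cell]
        d_prior = (_norm_logpdf(safe, Mc, stc) - _norm_logpdf(self.mu, Mc, stc))
        log_acc = np.where(valid, d_spike + d_prior, -np.inf)
        acc = self._accept_spikes(m.spike_trial, new, log_acc, T)
        self.mu = np.where(acc, safe, self.mu)
        self._adapt(self.s_mu, acc)

    def _update_mu_prior_proposal(self):
        """Independence proposal mu_i' ~ Normal(M_c, sigma_t_c).

        With the prior as proposal the Hastings ratio is the spike
        likelihood ratio alone; lets trial locations jump between the
        field and background interpretations of ambiguous trials.
        """
        m = self.m
        T = m.n_trials
        prop = (self.M[m.trial_cell]
                + self.st[m.trial_cell] * self.rng.standard_normal(T))
        if self._latent_bounded:
            valid = (prop >= 0.0) & (prop <= self.L) & \
                ((self.variant != "lognormal_field") | (prop > 0.0))
        elif self.variant == "lognormal_field":
            valid = prop > 0
        else:
            valid = np.ones(T, bool)
        prop = np.where(valid, prop, self.mu)
        new = self._spike_logmix(self._field_logpdf(loc_trial=prop))
        d_spike = np.bincount(m.spike_trial, new - self.cur, minlength=T)
        log_acc = np.where(valid, d_spike, -np.inf)
        acc = self._accept_spikes(m.spike_trial, new, log_acc, T)
        self.mu = np.where(acc, prop, self.mu)

    def _update_swi(self):
        m = self.m
        T = m.n_trials
        prop = self.swi + self.s_swi * self.rng.standard_normal(T)
        valid = prop > 1e-4
        safe = np.where(valid, prop, self.swi)
        new = self._spike_logmix(self._field_logpdf(scale_trial=safe))
        d_spike = np.bincount(m.spike_trial, new - self.cur, minlength=T)
        swc = self.sw[m.trial_cell]
        stc = self.st[m.trial_cell]
        d_prior = (_norm_logpdf(safe, swc, stc) - _norm_logpdf(self.swi, swc, stc))
        log_acc = np.where(valid, d_spike + d_prior, -np.inf)
        acc = self._accept_spikes(m.spike_trial, new, log_acc, T)
        self.swi = np.where(acc, safe, self.swi)
        self._adapt(self.s_swi, acc)

    def _update_M(self):
        m = self.m
        C = m.n_cells
        lo, hi = self.spec.peak_min, self.spec.peak_max
        prop = self.M + self.s_M * self.rng.standard_normal(C)
        valid = (prop >= lo) & (prop <= hi)
        safe = np.where(valid, prop, self.M)
        d_pop = self._pop_logpdf_vec(safe) - self._pop_logpdf_vec(self.M)
        if self.variant == "trial_vary_width":
            loc_trial = safe[m.trial_cell]
            new = self._spike_logmix(self._field_logpdf(loc_trial=loc_trial))
            d_spike_trial = np.bincount(m.spike_trial, new - self.cur,
                                        minlength=m.n_trials)
            d_lat = np.bincount(m.trial_cell, d_spike_trial, minlength=C)
        else:
            new = None
            Mc_new = safe[m.trial_cell]
            Mc_old = self.M[m.trial_cell]
            stc = self.st[m.trial_cell]
            lat = self.mu
            d_trial = (_norm_logpdf(lat, Mc_new, stc)
                       - _norm_logpdf(lat, Mc_old, stc))
            d_lat = np.bincount(m.trial_cell, d_trial, minlength=C)
            if self._latent_bounded:
                d_lat -= m.cell_ntrials * (self._prior_logZ(M=safe)
                                           - self._prior_logZ())
        log_acc = np.where(valid, d_pop + d_lat, -np.inf)
        acc = np.log(self.rng.random(C)) < log_acc
        if new is not None:
            mask = acc[m.spike_cell]
            self.cur = np.where(mask, new, self.cur)
        self.M = np.where(acc, safe, self.M)
        self._adapt(self.s_M, acc)

    def _update_st(self):
        m = self.m
        C = m.n_cells
        lsp = np.log(self.st) + self.s_st * self.rng.standard_normal(C)
        prop = np.exp(lsp)
        s0 = self.spec.priors.sigma_t_scale
        d_prior = (-(prop**2 - self.st**2) / (2 * s0 * s0)
                   + (lsp - np.log(self.st)))          # half-normal + Jacobian
        lat = self.swi if self.variant == "trial_vary_width" else self.mu
        center = (self.sw if self.variant == "trial_vary_width" else self.M)
        cc = center[m.trial_cell]
        d_trial = (_norm_logpdf(lat, cc, prop[m.trial_cell])
                   - _norm_logpdf(lat, cc, self.st[m.trial_cell]))
        d_lat = np.bincount(m.trial_cell, d_trial, minlength=C)
        if self._latent_bounded:
            d_lat -= m.cell_ntrials * (self._prior_logZ(st=prop)
                                       - self._prior_logZ())
        acc = np.log(self.rng.random(C)) < d_prior + d_lat
        self.st = np.where(acc, prop, self.st)
        self._adapt(self.s_st, acc)

    def _update_st_scale(self):
        """Joint rescaling of sigma_t and the trial-level deviations.

        Proposes sigma_t' = r * sigma_t together with
        lat_i' = center + r * (lat_i - center); the trial-level prior
        change cancels the transform Jacobian exactly, so acceptance is
        driven by the spike likelihood and the sigma_t prior.  This move
        traverses the funnel that plain coordinate updates mix slowly in
        when sigma_t is small.
        """
        m = self.m
        C = m.n_cells
        r = np.exp(self.s_stg * self.rng.standard_normal(C))
        stp = self.st * r
        trial_vary = self.variant == "trial_vary_width"
        lat = self.swi if trial_vary else self.mu
        center = (self.sw if trial_vary else self.M)[m.trial_cell]
        latp = center + (lat - center) * r[m.trial_cell]
        if trial_vary:
            bad_trial = latp <= 1e-4
        elif self._latent_bounded:
            bad_trial = (latp < 0.0) | (latp > self.L)
            if self.variant == "lognormal_field":
                bad_trial |= latp <= 0.0
        elif self.variant == "lognormal_field":
            bad_trial = latp <= 0.0
        else:
            # untruncated mu prior: any real value is valid
            bad_trial = np.zeros(m.n_trials, bool)
        valid = np.bincount(m.trial_cell, bad_trial, minlength=C) == 0
        safe_lat = np.where(bad_trial, lat, latp)
        if trial_vary:
            new = self._spike_logmix(self._field_logpdf(scale_trial=safe_lat))
        else:
            new = self._spike_logmix(self._field_logpdf(loc_trial=safe_lat))
        d_spike_trial = np.bincount(m.spike_trial, new - self.cur,
                                    minlength=m.n_trials)
        d_spike = np.bincount(m.trial_cell, d_spike_trial, minlength=C)
        s0 = self.spec.priors.sigma_t_scale
        d_prior = -(stp**2 - self.st**2) / (2 * s0 * s0) + np.log(r)
        if self._latent_bounded:
            d_prior = d_prior - m.cell_ntrials * (self._prior_logZ(st=stp)
                                                  - self._prior_logZ())
        log_acc = np.where(valid, d_spike + d_prior, -np.inf)
        acc = np.log(self.rng.random(C)) < log_acc
        acc_trial = acc[m.trial_cell]
        self.cur = np.where(acc[m.spike_cell], new, self.cur)
        if trial_vary:
            self.swi = np.where(acc_trial, safe_lat, self.swi)
        else:
            self.mu = np.where(acc_trial, safe_lat, self.mu)
        self.st = np.where(acc, stp, self.st)
        self._adapt(self.s_stg, acc)

    def _update_sw(self):
        m = self.m
        C = m.n_cells
        lsp = np.log(self.sw) + self.s_sw * self.rng.standard_normal(C)
        prop = np.exp(lsp)
        if self.variant == "lognormal_field":
            s0 = self.spec.priors.sigma_shape_scale
        else:
            s0 = self.spec.priors.sigma_w_scale
        d_prior = (-(prop**2 - self.sw**2) / (2 * s0 * s0)
                   + (lsp - np.log(self.sw)))
        if self.variant == "trial_vary_width":
            # sigma_W: center of the per-trial width distribution
            stc = self.st[m.trial_cell]
            d_trial = (_norm_logpdf(self.swi, prop[m.trial_cell], stc)
                       - _norm_logpdf(self.swi, self.sw[m.trial_cell], stc))
            d_lat = np.bincount(m.trial_cell, d_trial, minlength=C)
            acc = np.log(self.rng.random(C)) < d_prior + d_lat
            new = None
        else:
            new = self._spike_logmix(self._field_logpdf(scale_cell=prop))
            d_spike = np.bincount(m.spike_cell, new - self.cur, minlength=C)
            acc = np.log(self.rng.random(C)) < d_prior + d_spike
            mask = acc[m.spike_cell]
            self.cur = np.where(mask, new, self.cur)
        self.sw = np.where(acc, prop, self.sw)
        self._adapt(self.s_sw, acc)

    def _update_a1(self):
        m = self.m
        C = m.n_cells
        lp = logit(self.a1) + self.s_a1 * self.rng.standard_normal(C)
        prop = expit(lp)
        # Beta(2,2) prior plus logit-transform Jacobian
        d_prior = 2.0 * (np.log(prop) + np.log1p(-prop)
                         - np.log(self.a1) - np.log1p(-self.a1))
        new = self._spike_logmix(a1_cell=prop)
        d_spike = np.bincount(m.spike_cell, new - self.cur, minlength=C)
        acc = np.log(self.rng.random(C)) < d_prior + d_spike
        mask = acc[m.spike_cell]
        self.cur = np.where(mask, new, self.cur)
        self.a1 = np.where(acc, prop, self.a1)
        self._adapt(self.s_a1, acc)

    def _update_pop(self):
        pr = self.spec.priors
        bounds = {"alpha": (0.0, pr.alpha_max),
                  "beta": (1e-12, pr.beta_max),
                  "k": (min(0.05, 0.5 * pr.k_max), pr.k_max),
                  "lam": (min(0.01, 0.5 * pr.lam_max), pr.lam_max)}
        for key in self.pop:
            lo, hi = bounds[key]
            prop = dict(self.pop)
            prop[key] = self.pop[key] + self.s_pop[key] * self.rng.standard_normal()
            if not (lo <= prop[key] <= hi):
                self._adapt_scalar(key, 0.0)
                continue
            d = self._pop_logpdf_sum(self.M, prop) - self._pop_logpdf_sum(self.M)
            acc = np.log(self.rng.random()) < d
            if acc:
                self.pop = prop
            self._adapt_scalar(key, float(acc))

    def sweep(self):
        if self.variant == "trial_vary_width":
            self._update_swi()
        else:
            self._update_mu()
            self._update_mu_prior_proposal()
        self._update_M()
        self._update_st()
        self._update_st_scale()
        self._update_sw()
        self._update_a1()
        self._update_pop()
        self.it += 1

    def pointwise_loglik(self):
        """Per-(cell, trial) log-likelihood of the full hierarchy.

        Each trial's entry sums the spike-level mixture log density, the
        trial-latent prior (mu_i or sigma_wi given the cell parameters)
        and an equal per-trial share of the cell peak's population log
        density, so model comparison is sensitive to every level.
        """
        m = self.m
        out = np.bincount(m.spike_trial, self.cur, minlength=m.n_trials)
        if self.variant == "trial_vary_width":
            lat = _norm_logpdf(self.swi, self.sw[m.trial_cell],
                               self.st[m.trial_cell])
        else:
            lat = _norm_logpdf(self.mu, self.M[m.trial_cell],
                               self.st[m.trial_cell])
            if self._latent_bounded:
                lat = lat - self._prior_logZ()[m.trial_cell]
        pop = self._pop_logpdf_vec(self.M) / m.cell_ntrials
        return out + lat + pop[m.trial_cell]


# ---------------------------------------------------------------------------
# Model / Results


class TimeCellModel:
    """Hierarchical Bayesian time-field model, statsmodels-style.

    Parameters
    ----------
    dataset : SpikeTrainDataset
        Spike trains; typically the unit subset surviving the screen.
    unit_ids : sequence, optional
        Units to fit (defaults to all units in *dataset*).
    variant : str
        One of ``main``, ``lognormal_field``, ``trial_vary_width``,
        ``exponential_pop``, ``weibull_pop``.
    peak_min, peak_max : float
        Support of the population law for the peaks (seconds), chosen by
        the KS boundary search.
    truncate_field : bool
        Renormalize the spike field to the delay window [0, L] and
        confine trial locations to it (default).  With ``False`` the
        literal untruncated mixture is fitted; field mass leaking past
        the window then deflates width estimates for late-peaking cells.

    Examples
    --------
    >>> model = TimeCellModel(ds, variant="main", peak_min=0.35, peak_max=7.2)
    >>> res = model.fit(n_chains=4, warmup=1000, samples=500, seed=1)
    >>> res.alpha_summary()["mean"]    # doctest: +SKIP
    """

    def __init__(self, dataset: SpikeTrainDataset, unit_ids=None,
                 variant: str = "main", peak_min: float = 0.35,
                 peak_max: float = 7.2, truncate_field: bool = True,
                 priors: PriorSettings | None = None):
        if unit_ids is not None:
            dataset = dataset.subset(unit_ids)
        if not dataset.unit_ids:
            raise ValueError("empty unit subset")
        self.dataset = dataset
        self.variant = variant
        self.peak_min = peak_min
        self.peak_max = peak_max
        self.truncate_field = truncate_field
        self.priors = priors or PriorSettings()
        self._flatten()

    @classmethod
    def from_dataframe(cls, spikes: pd.DataFrame, delay_l: float,
                       trials: pd.DataFrame | None = None, **kwargs):
        """Build from a (unit_id, trial_id, spike_time_s) frame."""
        ds = SpikeTrainDataset(delay_l=delay_l, spikes=spikes, trials=trials)
        return cls(ds, **kwargs)

    def _flatten(self):
        ds = self.dataset
        self.unit_ids = ds.unit_ids
        self.n_cells = len(self.unit_ids)
        cell_of = {u: i for i, u in enumerate(self.unit_ids)}
        trials = ds.trials.reset_index(drop=True)
        self.trial_table = trials
        self.n_trials = len(trials)
        self.trial_cell = trials["unit_id"].map(cell_of).to_numpy()
        key = {(u, t): i for i, (u, t) in
               enumerate(trials[["unit_id", "trial_id"]].itertuples(index=False))}
        sp = ds.spikes
        self.spike_t = sp["spike_time_s"].to_numpy(float)
        self.spike_trial = np.array([key[(u, t)] for u, t in
                                     sp[["unit_id", "trial_id"]].itertuples(index=False)])
        self.spike_cell = self.trial_cell[self.spike_trial]
        with np.errstate(divide="ignore"):
            self.spike_logt = np.log(np.maximum(self.spike_t, 1e-12))
        self.trial_nspikes = np.bincount(self.spike_trial, minlength=self.n_trials)
        self.cell_ntrials = np.bincount(self.trial_cell, minlength=self.n_cells)
        self.delay_l = ds.delay_l

    @property
    def pop_param_names(self):
        return {"exponential_pop": ["beta"],
                "weibull_pop": ["k", "lam"]}.get(self.variant, ["alpha"])

    def fit(self, n_chains: int = 8, warmup: int = 4800, samples: int = 200,
            seed: int = 0, thin: int = 1) -> "TimeCellResults":
        """Run MCMC and return a results object with draws and diagnostics."""
        spec = ModelSpec(variant=self.variant, peak_min=self.peak_min,
                         peak_max=self.peak_max,
                         truncate_field=self.truncate_field,
                         priors=self.priors,
                         n_chains=n_chains, warmup=warmup, samples=samples,
                         seed=seed)
        ss = np.random.SeedSequence(seed)
        chain_seeds = ss.spawn(n_chains)
        C, T = self.n_cells, self.n_trials
        n_keep = samples
        store = {
            "M": np.empty((n_chains, n_keep, C)),
            "sigma_w": np.empty((n_chains, n_keep, C)),
            "sigma_t": np.empty((n_chains, n_keep, C)),
            "a1": np.empty((n_chains, n_keep, C)),
        }
        trial_name = "sigma_wi" if self.variant == "trial_vary_width" else "mu"
        store[trial_name] = np.empty((n_chains, n_keep, T))
        for p in self.pop_param_names:
            store[p] = np.empty((n_chains, n_keep))
        pointwise = np.empty((n_chains, n_keep, T))

        for ch in range(n_chains):
            s = _Sampler(self, spec, chain_seeds[ch])
            for _ in range(warmup):
                s.sweep()
            for d in range(n_keep):
                for _ in range(thin):
                    s.sweep()
                store["M"][ch, d] = s.M
                store["sigma_w"][ch, d] = s.sw
                store["sigma_t"][ch, d] = s.st
                store["a1"][ch, d] = s.a1
                store[trial_name][ch, d] = s.swi if s.swi is not None else s.mu
                for p in self.pop_param_names:
                    store[p][ch, d] = s.pop[p]
                pointwise[ch, d] = s.pointwise_loglik()

        return TimeCellResults(self, spec, store, pointwise)


class TimeCellResults:
    """Posterior draws, summaries and diagnostics for one fitted variant.

    Cell- and population-level point estimates are posterior means.
    """

    def __init__(self, model: TimeCellModel, spec: ModelSpec,
                 draws: dict, pointwise: np.ndarray):
        self.model = model
        self.spec = spec
        self.draws = draws
        self.pointwise = pointwise        # (chain, draw, trial)
        self._rhat = None

    # -- population level ---------------------------------------------------

    def pop_draws(self, name=None) -> np.ndarray:
        name = name or self.model.pop_param_names[0]
        return self.draws[name].reshape(-1)

    @property
    def alpha_draws(self) -> np.ndarray:
        if "alpha" not in self.draws:
            raise AttributeError(f"variant {self.model.variant!r} has no alpha")
        return self.draws["alpha"].reshape(-1)

    def alpha_summary(self) -> dict:
        a = self.alpha_draws
        lo, hi = np.percentile(a, [2.5, 97.5])
        return {"mean": float(a.mean()), "sd": float(a.std(ddof=1)),
                "ci95": (float(lo), float(hi))}

    # -- cell level -----------------------------------------------------------

    def cell_summary(self) -> pd.DataFrame:
        """Posterior means of (M, sigma_w, sigma_t, a1) per cell.

        For the log-normal field variant ``sigma_w`` is the field sd
        implied by the fitted shape parameter at the cell's peak
        (sqrt((e^{s^2}-1) e^{2 mu + s^2}) with e^mu at the peak).
        """
        d = self.draws
        M = d["M"].reshape(-1, self.model.n_cells)
        sw = d["sigma_w"].reshape(-1, self.model.n_cells)
        if self.model.variant == "lognormal_field":
            width = lognormal_sd(np.log(M), sw)
        else:
            width = sw
        return pd.DataFrame({
            "unit_id": self.model.unit_ids,
            "M": M.mean(axis=0),
            "sigma_w": width.mean(axis=0),
            "sigma_t": d["sigma_t"].reshape(-1, self.model.n_cells).mean(axis=0),
            "a1": d["a1"].reshape(-1, self.model.n_cells).mean(axis=0),
        })

    # -- trial level -----------------------------------------------------------

    def trial_summary(self) -> pd.DataFrame:
        """Posterior mean of the per-trial latent (mu_i, or sigma_wi)."""
        name = "sigma_wi" if self.model.variant == "trial_vary_width" else "mu"
        vals = self.draws[name].reshape(-1, self.model.n_trials).mean(axis=0)
        out = self.model.trial_table[["unit_id", "trial_id", "event_offset_s"]].copy()
        out[name] = vals
        return out

    # -- diagnostics -------------------------------------------------------------

    def to_inferencedata(self):
        """Full posterior as an arviz InferenceData with named dims
        (chain, draw, cell, trial), including the pointwise
        log-likelihood."""
        import arviz as az
        trial_name = ("sigma_wi" if self.model.variant == "trial_vary_width"
                      else "mu")
        coords = {"cell": np.asarray(self.model.unit_ids, dtype=object),
                  "trial": np.arange(self.model.n_trials)}
        dims = {"M": ["cell"], "sigma_w": ["cell"], "sigma_t": ["cell"],
                "a1": ["cell"], trial_name: ["trial"]}
        return az.from_dict(posterior=dict(self.draws),
                            log_likelihood={"trial": self.pointwise},
                            coords=coords, dims=dims)

    def _diag_idata(self):
        import arviz as az
        data = {k: self.draws[k] for k in
                ("M", "sigma_w", "sigma_t", "a1", *self.model.pop_param_names)}
        return az.from_dict(posterior=data)

    @property
    def rhat_max(self) -> float:
        if self._rhat is None:
            import arviz as az
            if self.spec.n_chains < 2:
                self._rhat = np.nan
            else:
                r = az.rhat(self._diag_idata())
                self._rhat = float(max(np.nanmax(np.atleast_1d(r[v].values))
                                       for v in r.data_vars))
        return self._rhat

    @property
    def converged(self) -> bool:
        r = self.rhat_max
        return bool(np.isnan(r) or r <= _RHAT_FLAG)

    # -- model comparison ----------------------------------------------------------

    def waic(self) -> WaicResult:
        ll = self.pointwise.reshape(-1, self.model.n_trials)
        return compute_waic(ll)

    # -- reporting -----------------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        rows = []
        for p in self.model.pop_param_names:
            d = self.draws[p].reshape(-1)
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append([p, d.mean(), d.std(ddof=1), lo, hi])
        cs = self.cell_summary()
        for col in ("M", "sigma_w", "sigma_t", "a1"):
            v = cs[col].to_numpy()
            rows.append([f"{col} (cell means)", v.mean(), v.std(ddof=1),
                         np.min(v), np.max(v)])
        out = pd.DataFrame(rows, columns=["param", "mean", "sd", "lo", "hi"])
        out.attrs["variant"] = self.model.variant
        out.attrs["rhat_max"] = self.rhat_max
        return out

    def to_frames(self) -> dict:
        """Flat frames for serialization (cells, trials, population)."""
        pop = pd.DataFrame({p: self.draws[p].reshape(-1)
                            for p in self.model.pop_param_names})
        return {"cells": self.cell_summary(), "trials": self.trial_summary(),
                "pop_draws": pop}
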