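"""Probability primitives shared by the generator, the screen and the models.

The central object is the bounded (truncated) power law

    p(tau) = tau^(-alpha) / C(alpha, min, max),   min <= tau <= max,

the population law for time-field peaks under logarithmic compression
(alpha = 1 corresponds to peaks uniform on a log-time axis).  The
normalizer has two analytic branches,

    C = (max^(1-alpha) - min^(1-alpha)) / (1 - alpha)   for alpha != 1
    C = ln(max) - ln(min)                               for alpha  = 1

which meet continuously at alpha = 1.  The generic branch is evaluated
through expm1/log1p so it stays accurate arbitrarily close to alpha = 1
(naive powers cancel catastrophically there); the log branch is used at
alpha = 1 itself.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "bounded_powerlaw_norm",
    "bounded_powerlaw_cdf",
    "bounded_powerlaw_ppf",
    "bounded_powerlaw_logpdf",
    "sample_bounded_powerlaw",
    "trial_mixture_logpdf",
    "lognormal_field_logpdf",
    "lognormal_sd",
    "population_logpdf",
]

# |alpha - 1| below which the exact logarithmic branch is used; the
# expm1-based generic branch is itself stable, so the window is tiny
_ALPHA_ONE_WINDOW = 1e-12

_LOG_2PI = np.log(2.0 * np.pi)


def _check_bounds(peak_min: float, peak_max: float) -> None:
    if peak_min <= 0.0:
        raise ValueError("peak_min must be positive (power law undefined at 0)")
    if peak_max <= peak_min:
        raise ValueError("peak_max must exceed peak_min")


def bounded_powerlaw_norm(alpha, peak_min: float, peak_max: float):
    """Normalizing constant C of the bounded power law."""
    _check_bounds(peak_min, peak_max)
    alpha = np.asarray(alpha, dtype=float)
    near_one = np.abs(alpha - 1.0) < _ALPHA_ONE_WINDOW
    e = np.where(near_one, 1.0, 1.0 - alpha)   # dummy 1.0 where masked out
    log_ratio = np.log(peak_max / peak_min)
    # (max^e - min^e)/e = min^e * expm1(e * log(max/min)) / e, stable as e -> 0
    generic = np.exp(e * np.log(peak_min)) * np.expm1(e * log_ratio) / e
    out = np.where(near_one, log_ratio, generic)
    return out if out.ndim else float(out)


def bounded_powerlaw_cdf(x, alpha: float, peak_min: float, peak_max: float):
    """CDF of the bounded power law; domain error outside [min, max]."""
    _check_bounds(peak_min, peak_max)
    x = np.asarray(x, dtype=float)
    if np.any(x < peak_min) or np.any(x > peak_max):
        raise ValueError("x outside [peak_min, peak_max]")
    if abs(alpha - 1.0) < _ALPHA_ONE_WINDOW:
        out = np.log(x / peak_min) / np.log(peak_max / peak_min)
    else:
        e = 1.0 - alpha
        out = np.expm1(e * np.log(x / peak_min)) / np.expm1(e * np.log(peak_max / peak_min))
    return out if out.ndim else float(out)


def bounded_powerlaw_ppf(u, alpha: float, peak_min: float, peak_max: float):
    """Inverse CDF (quantile function); u in [0, 1]."""
    _check_bounds(peak_min, peak_max)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("u outside [0, 1]")
    if abs(alpha - 1.0) < _ALPHA_ONE_WINDOW:
        out = peak_min * (peak_max / peak_min) ** u
    else:
        e = 1.0 - alpha
        # min * exp(log1p(u * expm1(e log(max/min))) / e), stable as e -> 0
        out = peak_min * np.exp(np.log1p(u * np.expm1(e * np.log(peak_max / peak_min))) / e)
    return out if out.ndim else float(out)


def bounded_powerlaw_logpdf(tau, alpha, peak_min: float, peak_max: float):
    """Log density; -inf outside [min, max] (supports truncated sampling)."""
    tau = np.asarray(tau, dtype=float)
    log_c = np.log(bounded_powerlaw_norm(alpha, peak_min, peak_max))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            (tau >= peak_min) & (tau <= peak_max),
            -np.asarray(alpha) * np.log(np.where(tau > 0, tau, 1.0)) - log_c,
            -np.inf,
        )
    return out if out.ndim else float(out)


def sample_bounded_powerlaw(alpha: float, peak_min: float, peak_max: float,
                            n: int, seed=None) -> np.ndarray:
    """i.i.d. draws by inversion of the bounded power-law CDF."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return bounded_powerlaw_ppf(rng.random(n), alpha, peak_min, peak_max)


def _normal_logpdf(x, loc, scale):
    z = (x - loc) / scale
    return -0.5 * (z * z + _LOG_2PI) - np.log(scale)


def trial_mixture_logpdf(t, a1, mu_i, sigma_w, delay_l: float):
    """Log density of a spike time under the field-plus-background mixture.

    p(t) = a1 * N(t | mu_i, sigma_w^2) + (1 - a1) / delay_l
    for 0 <= t <= delay_l.  The Gaussian field is not truncated; spikes far
    from the field are absorbed by the uniform background term.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or np.any(t > delay_l):
        raise ValueError("spike time outside [0, delay_l]")
    a1 = np.asarray(a1, dtype=float)
    if np.any(a1 < 0.0) or np.any(a1 > 1.0):
        raise ValueError("a1 must be in [0, 1]")
    field = np.exp(_normal_logpdf(t, np.asarray(mu_i, float), np.asarray(sigma_w, float)))
    with np.errstate(divide="ignore"):
        out = np.log(a1 * field + (1.0 - a1) / delay_l)
    return out if out.ndim else float(out)


def lognormal_field_logpdf(t, a1, mu, sigma, delay_l: float):
    """Mixture log density with a log-normal (skewed) field.

    p(t) = a1 * LogNormal(t | mu, sigma^2) + (1 - a1) / delay_l.
    The field's median exp(mu) serves as the peak-location summary.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise ValueError("log-normal field requires t > 0")
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    logt = np.log(t)
    field = np.exp(_normal_logpdf(logt, mu, sigma)) / t
    with np.errstate(divide="ignore"):
        out = np.log(a1 * field + (1.0 - a1) / delay_l)
    return out if out.ndim else float(out)


def lognormal_sd(mu, sigma):
    """Standard deviation of a log-normal field: sqrt((e^{s^2}-1) e^{2m+s^2})."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    s2 = sigma * sigma
    out = np.sqrt((np.exp(s2) - 1.0) * np.exp(2.0 * mu + s2))
    return out if out.ndim else float(out)


def population_logpdf(tau, variant: str, params: dict,
                      peak_min: float | None = None,
                      peak_max: float | None = None):
    """Log density of a time-field peak under an alternative population law.

    variant "exponential_pop": p(tau) = beta * exp(-beta * tau)
    variant "weibull_pop":     p(tau) = (k/lam) (tau/lam)^(k-1) exp(-(tau/lam)^k)

    When (peak_min, peak_max) are given the density is renormalized to that
    interval, matching the bounded support on which peaks are modelled.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0.0):
        raise ValueError("tau must be positive")
    if variant == "exponential_pop":
        beta = float(params["beta"])
        if beta <= 0:
            raise ValueError("beta must be positive")
        dist = stats.expon(scale=1.0 / beta)
    elif variant == "weibull_pop":
        k, lam = float(params["k"]), float(params["lam"])
        if k <= 0 or lam <= 0:
            raise ValueError("k and lam must be positive")
        dist = stats.weibull_min(k, scale=lam)
    else:
        raise ValueError(f"unknown population variant: {variant!r}")
    out = dist.logpdf(tau)
    if peak_min is not None and peak_max is not None:
        mass = dist.cdf(peak_max) - dist.cdf(peak_min)
        out = np.where(
            (tau >= peak_min) & (tau <= peak_max),
            out - np.log(mass),
            -np.inf,
        )
    return out if out.ndim else float(out)
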