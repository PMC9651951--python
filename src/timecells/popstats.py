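"""Population-level statistics on fitted time-field parameters.

Every function is a pure function of posterior summaries (posterior
means, per the reporting convention) plus configuration, so reports are
exactly reproducible from a saved fit.  Frequentist pieces use
statsmodels/scipy; Bayes factors for regressions use the BIC
approximation and t-test Bayes factors use the JZS default Cauchy prior
(scale sqrt(2)/2), so BF magnitudes are comparable to GUI packages only
qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionReport",
    "GroupTestReport",
    "regress_quadratic",
    "sign_split_chi2",
    "alpha_posterior_summary",
    "cdf_log_linearity",
    "early_late_analysis",
    "event_correlation_analysis",
    "bayes_ttest",
    "plot_sorted_heatmap",
]


# ---------------------------------------------------------------------------
# Regression with BIC-approximate Bayes factors


@dataclass
class RegressionReport:
    """OLS fit of y on (1, x, x^2) with nested-model Bayes factors."""

    terms: pd.DataFrame          # index: const/linear/quadratic; coef, se, p
    r2_adj: float
    bayes_factors: dict          # model name -> BF vs null (BIC approximation)
    best_model: str
    bf_m: float                  # posterior-odds BF for the winning model

    def coef(self, name: str) -> float:
        return float(self.terms.loc[name, "coef"])


_CANDIDATES = {
    "null": [],
    "linear": ["x"],
    "quadratic": ["x2"],
    "linear+quadratic": ["x", "x2"],
}


def regress_quadratic(y, x, include_bayes: bool = True) -> RegressionReport:
    """Quadratic OLS of y on x plus a four-model Bayesian comparison.

    Candidate models (all with intercept): null, linear, quadratic,
    linear+quadratic.  BF_i0 = exp((BIC_0 - BIC_i)/2); the winning
    model's BF_M converts its posterior probability to posterior odds
    against equal prior odds.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if len(y) != len(x):
        raise ValueError("y and x must have equal length")
    if len(y) < 4:
        raise ValueError("need at least 4 observations")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite values in y or x")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; design is collinear")

    X = pd.DataFrame({"const": 1.0, "x": x, "x2": x * x})
    full = sm.OLS(y, X).fit()
    terms = pd.DataFrame({
        "coef": full.params, "se": full.bse, "p": full.pvalues,
    }).rename(index={"const": "intercept", "x": "linear", "x2": "quadratic"})

    bfs, best, bf_m = {}, "null", np.nan
    if include_bayes:
        bics = {}
        for name, cols in _CANDIDATES.items():
            Xm = X[["const"] + cols]
            bics[name] = sm.OLS(y, Xm).fit().bic
        b0 = bics["null"]
        # log-space throughout: a perfect fit gives BIC -> -inf
        logbf = np.array([(b0 - b) / 2.0 for b in bics.values()])
        bfs = dict(zip(bics, np.exp(logbf)))
        if np.isinf(logbf.max()):
            # an exact fit (zero residual): most parsimonious exact model wins
            exact = np.isinf(logbf)
            sizes = np.array([len(c) for c in _CANDIDATES.values()])
            post = np.zeros(len(logbf))
            post[np.flatnonzero(exact)[np.argmin(sizes[exact])]] = 1.0
        else:
            w = np.exp(logbf - logbf.max())
            post = w / w.sum()
        i = int(np.argmax(post))
        best = list(bfs)[i]
        k = len(bfs)
        prior_odds = (1 / k) / (1 - 1 / k)
        bf_m = float(post[i] / (1 - post[i]) / prior_odds) \
            if post[i] < 1.0 else np.inf

    return RegressionReport(terms=terms, r2_adj=float(full.rsquared_adj),
                            bayes_factors=bfs, best_model=best, bf_m=bf_m)


# ---------------------------------------------------------------------------
# Simple group statistics


def sign_split_chi2(n_greater: int, n_total: int):
    """Goodness-of-fit chi-square (1 df) against a 50/50 split.

    Uses the Yates continuity correction
    chi2 = 2 * (|k - n/2| - 0.5)^2 / (n/2), clamped at zero when the
    split is within half a count of even.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_greater <= n_total:
        raise ValueError("n_greater must be in [0, n_total]")
    half = n_total / 2.0
    dev = max(abs(n_greater - half) - 0.5, 0.0)
    chi2 = 2.0 * dev * dev / half
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def alpha_posterior_summary(draws) -> dict:
    """Mean, 95% equal-tailed CI, mass in [0.9, 1.1], sd-distance from 0."""
    a = np.asarray(draws, float)
    if len(a) < 100:
        raise ValueError("need at least 100 posterior draws")
    lo, hi = np.percentile(a, [2.5, 97.5])
    sd = a.std(ddof=1)
    return {
        "mean": float(a.mean()),
        "sd": float(sd),
        "ci95": (float(lo), float(hi)),
        "frac_in_0.9_1.1": float(np.mean((a >= 0.9) & (a <= 1.1))),
        "sd_from_zero": float(a.mean() / sd) if sd > 0 else np.inf,
    }


def cdf_log_linearity(peaks):
    """Regress the empirical CDF of peaks on log(peak).

    Under logarithmic compression (peak density ~ 1/t) the CDF is linear
    in log time; returns (slope, intercept, R^2).
    """
    peaks = np.asarray(peaks, float)
    if np.any(peaks <= 0):
        raise ValueError("peaks must be positive")
    x = np.sort(peaks)
    ecdf = np.arange(1, len(x) + 1) / len(x)
    res = stats.linregress(np.log(x), ecdf)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# Bayesian t-tests (JZS default prior)


def jzs_bf10(t: float, n_eff: float, dof: float,
             scale: float = np.sqrt(2) / 2,
             alternative: str = "two-sided") -> float:
    """JZS Bayes factor for a t statistic by numerical quadrature.

    The standardized effect delta carries a Cauchy(0, scale) prior under
    H1 (truncated to delta > 0 for ``alternative="greater"``); the
    marginal likelihood of t is the noncentral-t density averaged over
    that prior, and BF10 is its ratio to the central-t density under H0.
    """
    from scipy import integrate

    def marginal(lo, hi, mult):
        f = lambda d: (stats.nct.pdf(t, dof, d * np.sqrt(n_eff))  # noqa: E731
                       * mult * stats.cauchy.pdf(d, 0.0, scale))
        val, _ = integrate.quad(f, lo, hi, limit=200)
        return val

    if alternative == "two-sided":
        num = marginal(-np.inf, np.inf, 1.0)
    elif alternative == "greater":
        num = marginal(0.0, np.inf, 2.0)
    elif alternative == "less":
        num = marginal(-np.inf, 0.0, 2.0)
    else:
        raise ValueError("alternative must be two-sided, greater or less")
    den = stats.t.pdf(t, dof)
    return float(num / den)


def bayes_ttest(x, y=None, alternative: str = "two-sided") -> dict:
    """One- or two-sample (pooled) t-test with the JZS BF10.

    The default Cauchy prior scale is sqrt(2)/2 on the standardized
    effect; the two-sample effective sample size is nx*ny/(nx+ny).
    """
    x = np.asarray(x, float)
    if y is None:
        res = stats.ttest_1samp(x, 0.0, alternative=alternative)
        n_eff, dof = len(x), len(x) - 1
    else:
        y = np.asarray(y, float)
        res = stats.ttest_ind(x, y, alternative=alternative)
        n_eff = len(x) * len(y) / (len(x) + len(y))
        dof = len(x) + len(y) - 2
    t = float(res.statistic)
    return {"t": t, "dof": float(dof), "p": float(res.pvalue),
            "bf10": jzs_bf10(t, n_eff, dof, alternative=alternative)}


# ---------------------------------------------------------------------------
# Early/late split and event-timing analyses


@dataclass
class GroupTestReport:
    split_threshold: float
    n_early: int
    n_late: int
    early_uniform_ks: dict | None = None      # D, p against uniform on range
    late_uniform_ks: dict | None = None
    normalized_two_sample_ks: dict | None = None
    early_width_regression: RegressionReport | None = None
    late_width_regression: RegressionReport | None = None
    warnings: list = field(default_factory=list)


def _uniform_ks(peaks) -> dict:
    lo, hi = float(np.min(peaks)), float(np.max(peaks))
    res = stats.kstest(peaks, stats.uniform(loc=lo, scale=hi - lo).cdf)
    return {"D": float(res.statistic), "p": float(res.pvalue), "n": len(peaks)}


def _minmax(x):
    x = np.asarray(x, float)
    return (x - x.min()) / (x.max() - x.min())


def early_late_analysis(M, sigma_w, threshold: float = 2.0) -> GroupTestReport:
    """Compression tests within early (< threshold) and late peak groups.

    Per group: KS test of peaks against a uniform distribution over that
    group's observed peak range, and a width-on-peak regression with
    Bayes factors.  Across groups: two-sample KS on min-max normalized
    peaks (tests whether the two groups share a relative peak
    distribution).  Groups with fewer than 5 cells are skipped with a
    warning.
    """
    M = np.asarray(M, float)
    sigma_w = np.asarray(sigma_w, float)
    early = M < threshold
    rep = GroupTestReport(split_threshold=threshold,
                          n_early=int(early.sum()),
                          n_late=int((~early).sum()))
    groups = {"early": early, "late": ~early}
    for name, mask in groups.items():
        if mask.sum() < 5:
            rep.warnings.append(f"{name} group has <5 cells; tests skipped")
            continue
        setattr(rep, f"{name}_uniform_ks", _uniform_ks(M[mask]))
        reg = regress_quadratic(sigma_w[mask], M[mask])
        setattr(rep, f"{name}_width_regression", reg)
    if early.sum() >= 5 and (~early).sum() >= 5:
        res = stats.ks_2samp(_minmax(M[early]), _minmax(M[~early]))
        rep.normalized_two_sample_ks = {
            "D": float(res.statistic), "p": float(res.pvalue),
            "n_early": int(early.sum()), "n_late": int((~early).sum()),
        }
    return rep


def event_correlation_analysis(trial_mu: pd.DataFrame, cell_M: pd.DataFrame,
                               threshold: float = 2.0,
                               min_event_trials: int = 5) -> dict:
    """Correlation between trial-level field location and event timing.

    Parameters
    ----------
    trial_mu : DataFrame with columns (unit_id, trial_id, mu, event_offset_s)
        Posterior-mean field location per trial plus the behavioral
        event offset.
    cell_M : DataFrame with columns (unit_id, M)
        Posterior-mean peak per cell, used for the early/late split.

    Returns per-cell Pearson r, a one-sample JZS Bayes-factor t-test of
    mean r > 0, and a one-sided two-sample test of early r > late r.
    Cells with fewer than ``min_event_trials`` event trials, or constant
    offsets, are excluded with a warning.
    """
    warnings_list = []
    rows = []
    M_of = dict(zip(cell_M["unit_id"], cell_M["M"]))
    for uid, g in trial_mu.groupby("unit_id", sort=False):
        g = g.dropna(subset=["mu", "event_offset_s"])
        if len(g) < min_event_trials:
            warnings_list.append(f"{uid}: <{min_event_trials} event trials; excluded")
            continue
        off = g["event_offset_s"].to_numpy(float)
        if np.ptp(off) == 0:
            warnings_list.append(f"{uid}: constant event offsets; excluded")
            continue
        r = stats.pearsonr(g["mu"].to_numpy(float), off).statistic
        rows.append({"unit_id": uid, "r": float(r), "M": M_of.get(uid, np.nan)})
    per_cell = pd.DataFrame(rows)
    out = {"per_cell": per_cell, "warnings": warnings_list,
           "mean_r": np.nan, "one_sample": None, "early_vs_late": None}
    if len(per_cell) >= 3:
        out["mean_r"] = float(per_cell["r"].mean())
        out["one_sample"] = bayes_ttest(per_cell["r"].to_numpy(),
                                        alternative="greater")
        early = per_cell["M"] < threshold
        if early.sum() >= 3 and (~early).sum() >= 3:
            out["early_vs_late"] = bayes_ttest(
                per_cell.loc[early, "r"].to_numpy(),
                per_cell.loc[~early, "r"].to_numpy(),
                alternative="greater")
    return out


# ---------------------------------------------------------------------------
# Diagnostic plotting


def plot_sorted_heatmap(dataset, unit_ids=None, n_bins: int = 80,
                        log_time: bool = False, ax=None):
    """Trial-averaged, peak-sorted, normalized firing-rate heat map.

    Under logarithmic compression the sorted ridge is curved on a linear
    time axis and straightens on a log axis.
    """
    import matplotlib.pyplot as plt

    unit_ids = unit_ids or dataset.unit_ids
    L = dataset.delay_l
    if log_time:
        edges = np.geomspace(0.05, L, n_bins + 1)
    else:
        edges = np.linspace(0.0, L, n_bins + 1)
    mat, peaks = [], []
    for uid in unit_ids:
        t = dataset.unit_spikes(uid)["spike_time_s"].to_numpy(float)
        h, _ = np.histogram(t, bins=edges)
        rate = h / np.diff(edges)
        m = rate.max()
        mat.append(rate / m if m > 0 else rate)
        peaks.append(edges[np.argmax(rate)])
    order = np.argsort(peaks)
    mat = np.asarray(mat)[order]
    if ax is None:
        _, ax = plt.subplots()
    ax.pcolormesh(edges, np.arange(len(mat) + 1), mat, shading="flat")
    ax.set_xlabel("log time (s)" if log_time else "time (s)")
    ax.set_ylabel("unit (sorted by peak)")
    ax.invert_yaxis()
    if log_time:
        ax.set_xscale("log")
    return ax
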