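"""Synthetic delay-period spike trains with known ground truth.

The generator emulates the statistical structure of a population of
hippocampal CA1 time cells recorded across a fixed delay:

* time-field peaks ``M`` drawn from a bounded power law ``M^-alpha`` on
  ``[peak_min, peak_max]`` (alpha = 1 gives logarithmic compression);
* within-trial field width growing linearly with the peak,
  ``sigma_w = width_intercept + width_slope * M``;
* across-trial jitter of the field location following a quadratic law
  ``sigma_t(M) = c0 + c1*M + c2*M^2`` (clipped below at a small floor);
* per-trial spike times drawn from the mixture
  ``a1 * field(mu_i, sigma_w) + (1 - a1) * Uniform(0, delay_l)``;
* distractor units firing uniformly at low rate and "interneuron" units
  firing uniformly above the 5 Hz screening ceiling;
* optional per-trial behavioral event offsets that shift ``mu_i`` with a
  gain decaying with the peak time, mimicking sensitivity of early time
  cells to delay-onset event timing.

Defaults mirror the study conditions the analysis assumes: 131 time
cells, an 8 s delay, peaks on [0.35 s, 7.2 s] with alpha = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .distributions import sample_bounded_powerlaw
from .spikeio import SpikeTrainDataset

__all__ = [
    "TheoryParams",
    "GeneratorConfig",
    "GroundTruth",
    "logarithmic_peak_sequence",
    "sample_bounded_powerlaw",
    "generate_cell",
    "generate_population",
]

SIGMA_T_FLOOR = 0.05  # seconds; the fitted quadratic goes negative near M=0


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the idealized logarithmic timeline t_n = t0 * b^n."""

    t0: float
    b: float

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if self.b <= 1:
            raise ValueError("logarithm base b must exceed 1")


def logarithmic_peak_sequence(theory: TheoryParams, count: int) -> np.ndarray:
    """Peak times t_n = t0 * b^n for n = 0 .. count-1.

    Consecutive peaks have constant ratio b, so the spacing between
    adjacent fields grows linearly with the peak:
    t_{n+1} - t_n = (b - 1) * t_n.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    n = np.arange(count)
    return theory.t0 * theory.b ** n


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the synthetic population."""

    n_time_cells: int = 131
    n_distractor_cells: int = 20
    n_interneurons: int = 8
    trials_per_cell: int = 40
    delay_l: float = 8.0
    alpha: float = 1.0
    peak_min: float = 0.35
    peak_max: float = 7.2
    width_slope: float = 0.14
    width_intercept: float = 0.11
    trialvar_coeffs: tuple = (-0.33, 0.84, -0.11)
    a1: float = 0.7
    spikes_per_trial_mean: float = 12.0
    event_coupling: float = 0.5
    event_sd: float = 0.3
    field_shape: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.peak_min < self.peak_max <= self.delay_l):
            raise ValueError("require 0 < peak_min < peak_max <= delay_l")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (0 < self.a1 <= 1):
            raise ValueError("a1 must be in (0, 1]")
        if self.field_shape not in ("gaussian", "lognormal"):
            raise ValueError("field_shape must be 'gaussian' or 'lognormal'")
        lo = self.sigma_w(self.peak_min)
        if lo <= 0:
            raise ValueError("width law must be positive over [peak_min, peak_max]")

    def sigma_w(self, M):
        return self.width_intercept + self.width_slope * np.asarray(M, float)

    def sigma_t(self, M):
        c0, c1, c2 = self.trialvar_coeffs
        M = np.asarray(M, float)
        return np.maximum(c0 + c1 * M + c2 * M * M, SIGMA_T_FLOOR)

    def coupling_gain(self, M):
        """Event-coupling gain; decays linearly with peak, reaching 0 at 2 s."""
        return self.event_coupling * np.maximum(0.0, 1.0 - np.asarray(M, float) / 2.0)


@dataclass
class GroundTruth:
    """Generator-side true parameters for recovery tests.

    ``cells``: one row per generated unit (cell_id, kind, M, sigma_w,
    sigma_t, a1).  ``trials``: one row per (cell, trial) with the true
    per-trial field location ``mu_i`` and the event offset.  ``alpha``
    is the population compression exponent.
    """

    alpha: float
    cells: pd.DataFrame
    trials: pd.DataFrame

    def time_cell_ids(self) -> list:
        return list(self.cells.loc[self.cells["kind"] == "time_cell", "cell_id"])


def _truncated_normal(rng, loc, scale, lo, hi, size):
    """Normal(loc, scale) resampled (not clipped) into [lo, hi]."""
    if scale == 0:
        return np.full(size, loc, float)
    out = rng.normal(loc, scale, size)
    bad = (out < lo) | (out > hi)
    tries = 0
    while bad.any():
        out[bad] = rng.normal(loc, scale, bad.sum())
        bad = (out < lo) | (out > hi)
        tries += 1
        if tries > 10000:  # pathological parameters; fall back to clipping
            out = np.clip(out, lo, hi)
            break
    return out


def generate_cell(M: float, sigma_w: float, sigma_t: float, a1: float,
                  spikes_per_trial_mean: float, n_trials: int, delay_l: float,
                  field_shape: str = "gaussian", seed=None,
                  mu_override: np.ndarray | None = None):
    """Spike trains for one time cell.

    Per trial, ``mu_i ~ Normal(M, sigma_t^2)`` resampled into
    [0, delay_l]; the spike count is Poisson; each spike comes from the
    field (probability ``a1``) or the uniform background.  Field spikes
    falling outside the delay are resampled so the within-trial field sd
    stays ``sigma_w``.

    Returns ``(trial_spikes, mu)`` — a list of sorted spike-time arrays
    and the per-trial field locations.
    """
    if a1 < 0 or a1 > 1:
        raise ValueError("a1 must be in [0, 1]")
    if a1 > 0 and sigma_w <= 0:
        raise ValueError("sigma_w must be positive when a1 > 0")
    if sigma_t < 0:
        raise ValueError("sigma_t must be non-negative")
    rng = np.random.default_rng(seed)
    if mu_override is not None:
        mu = np.asarray(mu_override, float)
        if len(mu) != n_trials:
            raise ValueError("mu_override length must equal n_trials")
    else:
        mu = _truncated_normal(rng, M, sigma_t, 0.0, delay_l, n_trials)
    trial_spikes = []
    for i in range(n_trials):
        m = rng.poisson(spikes_per_trial_mean)
        in_field = rng.random(m) < a1
        t = rng.uniform(0.0, delay_l, m)
        k = int(in_field.sum())
        if k:
            if field_shape == "gaussian":
                draw = lambda r, n: r.normal(mu[i], sigma_w, n)  # noqa: E731
            elif field_shape == "lognormal":
                # log-scale shape chosen so the field sd is ~sigma_w at mu_i
                s = math.log1p(sigma_w / max(mu[i], 1e-3))
                draw = lambda r, n: r.lognormal(math.log(max(mu[i], 1e-3)), s, n)  # noqa: E731
            else:
                raise ValueError("field_shape must be 'gaussian' or 'lognormal'")
            f = draw(rng, k)
            bad = (f < 0) | (f > delay_l)
            tries = 0
            while bad.any():
                f[bad] = draw(rng, int(bad.sum()))
                bad = (f < 0) | (f > delay_l)
                tries += 1
                if tries > 10000:
                    f = np.clip(f, 0.0, delay_l)
                    break
            t[in_field] = f
        trial_spikes.append(np.sort(t))
    return trial_spikes, mu


def generate_population(config: GeneratorConfig):
    """Full synthetic population: time cells, distractors and interneurons.

    Returns ``(SpikeTrainDataset, GroundTruth)``; byte-identical output
    for identical config (including seed).
    """
    rng = np.random.default_rng(config.seed)

    peaks = sample_bounded_powerlaw(
        config.alpha, config.peak_min, config.peak_max,
        config.n_time_cells, seed=rng,
    )
    spike_rows = []
    trial_rows = []
    cell_rows = []

    def cell_id(kind, i):
        return f"{kind}{i:04d}"

    for i, M in enumerate(peaks):
        cid = cell_id("tc", i)
        sw = float(config.sigma_w(M))
        st = float(config.sigma_t(M))
        gain = float(config.coupling_gain(M))
        offsets = rng.normal(0.0, config.event_sd, config.trials_per_cell)
        # per-trial field location: Normal centered at M plus event shift,
        # resampled into the delay window
        centers = M + gain * offsets
        mu = np.empty(config.trials_per_cell)
        for j, c in enumerate(centers):
            mu[j] = _truncated_normal(rng, c, st, 0.0, config.delay_l, 1)[0]
        spikes, _ = generate_cell(
            M, sw, st, config.a1, config.spikes_per_trial_mean,
            config.trials_per_cell, config.delay_l,
            field_shape=config.field_shape, seed=rng, mu_override=mu,
        )
        cell_rows.append(dict(cell_id=cid, kind="time_cell", M=M,
                              sigma_w=sw, sigma_t=st, a1=config.a1))
        for j in range(config.trials_per_cell):
            trial_rows.append(dict(cell_id=cid, trial_id=j, mu_i=mu[j],
                                   event_offset=offsets[j]))
            for t in spikes[j]:
                spike_rows.append((cid, j, t))

    # distractors: pure uniform background at a modest pyramidal-cell rate
    for i in range(config.n_distractor_cells):
        cid = cell_id("bg", i)
        cell_rows.append(dict(cell_id=cid, kind="distractor", M=np.nan,
                              sigma_w=np.nan, sigma_t=np.nan, a1=0.0))
        for j in range(config.trials_per_cell):
            offset = rng.normal(0.0, config.event_sd)
            trial_rows.append(dict(cell_id=cid, trial_id=j, mu_i=np.nan,
                                   event_offset=offset))
            m = rng.poisson(config.spikes_per_trial_mean)
            for t in np.sort(rng.uniform(0.0, config.delay_l, m)):
                spike_rows.append((cid, j, t))

    # interneurons: uniform firing at 6-10 Hz, above the 5 Hz screen ceiling
    for i in range(config.n_interneurons):
        cid = cell_id("in", i)
        rate = rng.uniform(6.0, 10.0)
        cell_rows.append(dict(cell_id=cid, kind="interneuron", M=np.nan,
                              sigma_w=np.nan, sigma_t=np.nan, a1=0.0))
        for j in range(config.trials_per_cell):
            offset = rng.normal(0.0, config.event_sd)
            trial_rows.append(dict(cell_id=cid, trial_id=j, mu_i=np.nan,
                                   event_offset=offset))
            m = rng.poisson(rate * config.delay_l)
            for t in np.sort(rng.uniform(0.0, config.delay_l, m)):
                spike_rows.append((cid, j, t))

    spikes_df = pd.DataFrame(spike_rows, columns=["unit_id", "trial_id", "spike_time_s"])
    trials_df = pd.DataFrame(trial_rows)
    events_df = trials_df.rename(
        columns={"cell_id": "unit_id", "event_offset": "event_offset_s"}
    )[["unit_id", "trial_id", "event_offset_s"]]

    dataset = SpikeTrainDataset(
        delay_l=config.delay_l,
        spikes=spikes_df,
        trials=events_df,
        meta={"generator": asdict(config)},
    )
    truth = GroundTruth(alpha=config.alpha,
                        cells=pd.DataFrame(cell_rows),
                        trials=trials_df)
    return dataset, truth
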