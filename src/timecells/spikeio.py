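"""On-disk data model for delay-period spike trains.

A dataset directory holds three plain-text files:

``spikes.csv``
    columns ``unit_id, trial_id, spike_time_s`` — one row per spike.
``events.csv`` (optional)
    columns ``unit_id, trial_id, event_offset_s`` — one row per trial,
    including spikeless trials; the offset is the time from treadmill
    entry to the beam break (beam break defines t = 0) and may be empty.
``meta.yaml``
    at least ``delay_l`` (seconds); free-form provenance (seed, etc.).

All times are seconds.  Spike times must lie in [0, delay_l].  Duplicate
(unit, trial, time) rows are permitted: simultaneous spikes recorded on
different tetrode channels are not merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["SpikeTrainDataset", "read_dataset", "write_dataset", "ValidationError"]

SPIKE_COLUMNS = ["unit_id", "trial_id", "spike_time_s"]
EVENT_COLUMNS = ["unit_id", "trial_id", "event_offset_s"]
_FLOAT_FMT = "%.6f"


class ValidationError(ValueError):
    """A dataset violates the documented layout or bounds."""


@dataclass
class SpikeTrainDataset:
    """Per-unit, per-trial spike times on a fixed delay interval.

    Parameters
    ----------
    delay_l : float
        Length of the delay window in seconds; every spike time lies in
        [0, delay_l].
    spikes : pandas.DataFrame
        Columns ``unit_id, trial_id, spike_time_s``.
    trials : pandas.DataFrame
        Columns ``unit_id, trial_id, event_offset_s`` — the trial index.
        Trials with no spikes are represented here; ``event_offset_s``
        may be NaN when no behavioral event was recorded.
    meta : dict
        Free-form provenance (seed, generator config, ...).
    """

    delay_l: float
    spikes: pd.DataFrame
    trials: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spikes = (
            self.spikes[SPIKE_COLUMNS]
            .sort_values(SPIKE_COLUMNS, kind="mergesort")
            .reset_index(drop=True)
        )
        if self.trials is None:
            self.trials = (
                self.spikes[["unit_id", "trial_id"]]
                .drop_duplicates()
                .assign(event_offset_s=np.nan)
            )
        self.trials = (
            self.trials[EVENT_COLUMNS]
            .sort_values(["unit_id", "trial_id"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.validate()

    # -- integrity ---------------------------------------------------------

    def validate(self) -> None:
        if self.delay_l <= 0:
            raise ValidationError("delay_l must be positive")
        t = self.spikes["spike_time_s"].to_numpy(float)
        if np.isnan(t).any():
            raise ValidationError("NaN spike times are not permitted")
        bad = (t < 0) | (t > self.delay_l)
        if bad.any():
            row = self.spikes[bad].iloc[0]
            raise ValidationError(
                f"spike time {row.spike_time_s} outside [0, {self.delay_l}] "
                f"(unit {row.unit_id}, trial {row.trial_id})"
            )
        if self.trials.duplicated(["unit_id", "trial_id"]).any():
            raise ValidationError("duplicate (unit_id, trial_id) in trials table")
        known = set(map(tuple, self.trials[["unit_id", "trial_id"]].itertuples(index=False)))
        seen = set(map(tuple, self.spikes[["unit_id", "trial_id"]].drop_duplicates().itertuples(index=False)))
        orphan = seen - known
        if orphan:
            raise ValidationError(f"spikes reference unknown trials: {sorted(orphan)[:3]} ...")

    # -- accessors ---------------------------------------------------------

    @property
    def unit_ids(self) -> list:
        return list(pd.unique(self.trials["unit_id"]))

    def unit_spikes(self, unit_id) -> pd.DataFrame:
        return self.spikes[self.spikes["unit_id"] == unit_id]

    def unit_trial_ids(self, unit_id) -> list:
        return list(self.trials.loc[self.trials["unit_id"] == unit_id, "trial_id"])

    def trial_spike_times(self, unit_id, trial_id) -> np.ndarray:
        s = self.spikes
        m = (s["unit_id"] == unit_id) & (s["trial_id"] == trial_id)
        return s.loc[m, "spike_time_s"].to_numpy(float)

    def n_trials(self, unit_id) -> int:
        return int((self.trials["unit_id"] == unit_id).sum())

    def n_trials_with_spikes(self, unit_id) -> int:
        s = self.unit_spikes(unit_id)
        return int(s["trial_id"].nunique())

    def mean_rate(self, unit_id) -> float:
        """Mean firing rate (Hz) over all of the unit's delay intervals."""
        n = self.n_trials(unit_id)
        if n == 0:
            return 0.0
        return len(self.unit_spikes(unit_id)) / (n * self.delay_l)

    def subset(self, unit_ids) -> "SpikeTrainDataset":
        keep = set(unit_ids)
        return SpikeTrainDataset(
            delay_l=self.delay_l,
            spikes=self.spikes[self.spikes["unit_id"].isin(keep)].copy(),
            trials=self.trials[self.trials["unit_id"].isin(keep)].copy(),
            meta=dict(self.meta),
        )


def write_dataset(dataset: SpikeTrainDataset, path) -> None:
    """Write ``spikes.csv``, ``events.csv`` and ``meta.yaml`` under *path*.

    Column order and float formatting (6 decimals) are fixed so rewrites
    are byte-stable and diffs meaningful.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.validate()
    dataset.spikes.to_csv(path / "spikes.csv", index=False, float_format=_FLOAT_FMT)
    dataset.trials.to_csv(path / "events.csv", index=False, float_format=_FLOAT_FMT)
    meta = {"delay_l": float(dataset.delay_l), **dataset.meta}
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_dataset(path, delay_l: float | None = None) -> SpikeTrainDataset:
    """Read and validate a dataset directory.

    ``delay_l`` is taken from ``meta.yaml`` unless given explicitly.
    """
    path = Path(path)
    spike_file = path / "spikes.csv"
    if not spike_file.exists():
        raise FileNotFoundError(spike_file)
    spikes = pd.read_csv(spike_file)
    missing = [c for c in SPIKE_COLUMNS if c not in spikes.columns]
    if missing:
        raise ValidationError(f"spikes.csv missing columns: {missing}")

    meta: dict = {}
    meta_file = path / "meta.yaml"
    if meta_file.exists():
        with open(meta_file) as fh:
            meta = yaml.safe_load(fh) or {}
    if delay_l is None:
        if "delay_l" not in meta:
            raise ValidationError("delay_l not given and absent from meta.yaml")
        delay_l = float(meta.pop("delay_l"))
    else:
        meta.pop("delay_l", None)

    trials = None
    event_file = path / "events.csv"
    if event_file.exists():
        trials = pd.read_csv(event_file)
        missing = [c for c in EVENT_COLUMNS if c not in trials.columns]
        if missing:
            raise ValidationError(f"events.csv missing columns: {missing}")

    return SpikeTrainDataset(delay_l=delay_l, spikes=spikes, trials=trials, meta=meta)
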