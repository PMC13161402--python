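"""Dataset containers, on-disk format, and spike binning.

A :class:`SessionDataset` bundles three tables — trials, spikes, neurons —
plus a metadata dict, and is the interchange object for every analysis
stage.  On disk it is two delimited text tables (``trials.csv``,
``spikes.csv``), a neuron table (``neurons.csv``) and one JSON metadata
file, chosen for diffability and language neutrality.

All spike times are in milliseconds relative to instruction stimulus
onset; fixation-period times are negative.  Bins are half-open
``[a, b)`` with left-edge alignment and 0-based indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "session_id", "trial_id", "numerosity", "format", "stim_condition",
    "arrangement", "produced_count", "outcome",
]
SPIKE_COLUMNS = ["neuron_id", "trial_id", "time_ms"]
NEURON_COLUMNS = ["neuron_id", "session_id"]


class DatasetValidationError(ValueError):
    """Raised when a dataset violates its schema or referential integrity."""


@dataclass
class SessionDataset:
    """Trial table + spike table + neuron metadata for one or more sessions.

    Parameters
    ----------
    trials : DataFrame with TRIAL_COLUMNS. ``produced_count`` is NaN for
        aborted trials; ``outcome`` is one of ``correct|error|aborted``.
    spikes : DataFrame with SPIKE_COLUMNS, one row per spike.
    neurons : DataFrame with NEURON_COLUMNS.
    meta : phase durations (``fixation_ms``, ``instruction_ms``,
        ``planning_ms``, ``execution_ms``) and provenance.
    """

    trials: pd.DataFrame
    spikes: pd.DataFrame
    neurons: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- schema ------------------------------------------------------------
    def validate(self) -> None:
        for col in TRIAL_COLUMNS:
            if col not in self.trials.columns:
                raise DatasetValidationError(f"trials table missing column {col!r}")
        for col in SPIKE_COLUMNS:
            if col not in self.spikes.columns:
                raise DatasetValidationError(f"spikes table missing column {col!r}")
        for col in NEURON_COLUMNS:
            if col not in self.neurons.columns:
                raise DatasetValidationError(f"neurons table missing column {col!r}")
        dup = self.trials.duplicated(["session_id", "trial_id"])
        if dup.any():
            rows = self.trials.index[dup].tolist()
            raise DatasetValidationError(f"duplicate trial ids at rows {rows}")
        known_trials = set(self.trials["trial_id"])
        orphan = ~self.spikes["trial_id"].isin(known_trials)
        if orphan.any():
            row = int(np.flatnonzero(orphan.to_numpy())[0])
            raise DatasetValidationError(
                f"spike row {row} references unknown trial "
                f"{self.spikes['trial_id'].iloc[row]!r}"
            )
        known_neurons = set(self.neurons["neuron_id"])
        orphan = ~self.spikes["neuron_id"].isin(known_neurons)
        if orphan.any():
            row = int(np.flatnonzero(orphan.to_numpy())[0])
            raise DatasetValidationError(
                f"spike row {row} references unknown neuron "
                f"{self.spikes['neuron_id'].iloc[row]!r}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def neuron_ids(self) -> np.ndarray:
        return self.neurons["neuron_id"].to_numpy()

    @property
    def phase_durations(self) -> dict:
        return {k: self.meta[k] for k in
                ("fixation_ms", "instruction_ms", "planning_ms", "execution_ms")
                if k in self.meta}

    def trial_ids(self, mask: pd.Series | None = None) -> np.ndarray:
        t = self.trials if mask is None else self.trials[mask]
        return t["trial_id"].to_numpy()

    def spikes_for(self, neuron_id, trial_id) -> np.ndarray:
        s = self.spikes
        sel = (s["neuron_id"] == neuron_id) & (s["trial_id"] == trial_id)
        return np.sort(s.loc[sel, "time_ms"].to_numpy())

    def equals(self, other: "SessionDataset") -> bool:
        return (
            self.trials.reset_index(drop=True).equals(other.trials.reset_index(drop=True))
            and self.spikes.reset_index(drop=True).equals(other.spikes.reset_index(drop=True))
            and self.neurons.reset_index(drop=True).equals(other.neurons.reset_index(drop=True))
            and self.meta == other.meta
        )


def write_dataset(ds: SessionDataset, path) -> None:
    """Write ``trials.csv``, ``spikes.csv``, ``neurons.csv`` and ``meta.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ds.trials[TRIAL_COLUMNS].to_csv(path / "trials.csv", index=False)
    ds.spikes[SPIKE_COLUMNS].to_csv(path / "spikes.csv", index=False)
    ds.neurons[NEURON_COLUMNS].to_csv(path / "neurons.csv", index=False)
    with open(path / "meta.json", "w") as fh:
        json.dump(ds.meta, fh, indent=1, sort_keys=True)


def read_dataset(path) -> SessionDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    An empty spike table is legal (zero-rate neurons); referential
    violations raise :class:`DatasetValidationError` naming the row.
    """
    path = Path(path)
    trials = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    spikes = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    if spikes.empty:
        spikes = pd.DataFrame(columns=SPIKE_COLUMNS).astype(
            {"neuron_id": "int64", "trial_id": "int64", "time_ms": "float64"})
    neurons = pd.read_csv(path / "neurons.csv")
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    return SessionDataset(trials=trials, spikes=spikes, neurons=neurons, meta=meta)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinScheme:
    """Sliding-window bin layout: half-open windows of ``width_ms`` stepped
    by ``step_ms``, the first starting at ``start_ms``.

    ``n_bins = floor((end - start - width)/step) + 1``; every bin lies
    inside ``[start_ms, end_ms]``.
    """

    start_ms: float
    end_ms: float
    width_ms: float = 200.0
    step_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.width_ms <= 0 or self.step_ms <= 0:
            raise ValueError("width_ms and step_ms must be positive")
        if self.start_ms >= self.end_ms:
            raise ValueError("start_ms must be before end_ms")
        if self.end_ms - self.start_ms < self.width_ms:
            raise ValueError("scheme shorter than one window")

    @property
    def n_bins(self) -> int:
        return int(np.floor((self.end_ms - self.start_ms - self.width_ms)
                            / self.step_ms)) + 1

    @property
    def bin_starts(self) -> np.ndarray:
        return self.start_ms + self.step_ms * np.arange(self.n_bins)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.width_ms / 2.0


@dataclass
class BinnedRates:
    """neurons x trials x bins firing-rate tensor (Hz) with index maps."""

    rates: np.ndarray
    scheme: BinScheme
    neuron_ids: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.rates.shape != (len(self.neuron_ids), len(self.trial_ids),
                                self.scheme.n_bins):
            raise ValueError("rate tensor shape inconsistent with index maps")

    def neuron_index(self, neuron_id) -> int:
        idx = np.flatnonzero(self.neuron_ids == neuron_id)
        if idx.size == 0:
            raise KeyError(f"neuron {neuron_id!r} not in tensor")
        return int(idx[0])


def _counts_in_windows(times: np.ndarray, starts: np.ndarray,
                       width: float) -> np.ndarray:
    """Spike counts per half-open window [s, s+width) via searchsorted."""
    times = np.sort(times)
    lo = np.searchsorted(times, starts, side="left")
    hi = np.searchsorted(times, starts + width, side="left")
    return hi - lo


def bin_rates(ds: SessionDataset, scheme: BinScheme,
              neuron_ids: Sequence | None = None,
              trial_ids: Sequence | None = None) -> BinnedRates:
    """Bin spikes into sliding-window firing rates.

    Bin ``b`` covers ``[start + b*step, start + b*step + width)``; a spike
    exactly on the right edge is excluded.  Rate = count / width.
    """
    neuron_ids = np.asarray(ds.neuron_ids if neuron_ids is None else neuron_ids)
    trial_ids = np.asarray(ds.trials["trial_id"].to_numpy()
                           if trial_ids is None else trial_ids)
    fix = float(ds.meta.get("fixation_ms", np.inf))
    if scheme.start_ms < -fix:
        raise ValueError(
            f"scheme starts at {scheme.start_ms} ms, before trial coverage "
            f"(-{fix} ms)")
    starts = scheme.bin_starts
    width = scheme.width_ms
    rates = np.zeros((len(neuron_ids), len(trial_ids), scheme.n_bins))
    n_pos = {n: i for i, n in enumerate(neuron_ids)}
    t_pos = {t: j for j, t in enumerate(trial_ids)}
    wanted_n = ds.spikes["neuron_id"].map(n_pos).to_numpy()
    wanted_t = ds.spikes["trial_id"].map(t_pos).to_numpy()
    keep = ~(np.isnan(wanted_n) | np.isnan(wanted_t))
    sub = ds.spikes.loc[keep]
    for (ni, tj), grp in sub.groupby(
            [wanted_n[keep].astype(int), wanted_t[keep].astype(int)]):
        rates[ni, tj, :] = _counts_in_windows(
            grp["time_ms"].to_numpy(), starts, width)
    rates /= width / 1000.0
    return BinnedRates(rates=rates, scheme=scheme,
                       neuron_ids=neuron_ids, trial_ids=trial_ids)


def mean_rate_in_window(ds: SessionDataset, neuron_id,
                        trial_ids: Sequence, window: tuple) -> float:
    """Mean firing rate (Hz) of one neuron over a half-open window,
    averaged across the given trials."""
    trial_ids = np.asarray(trial_ids)
    if trial_ids.size == 0:
        raise ValueError("empty trial set")
    a, b = window
    if b <= a:
        raise ValueError("window end must exceed start")
    s = ds.spikes
    sel = (s["neuron_id"] == neuron_id) & s["trial_id"].isin(set(trial_ids))
    t = s.loc[sel, "time_ms"].to_numpy()
    count = int(np.sum((t >= a) & (t < b)))
    return count / trial_ids.size / ((b - a) / 1000.0)
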