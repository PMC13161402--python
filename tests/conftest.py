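import numpy as np
import pandas as pd
import pytest

from numopop import (PopulationPriors, SessionDataset, TaskConfig,
                     generate_experiment)


@pytest.fixture(scope="session")
def small_experiment():
    """One session, 24 trials/condition, 12 neurons (6 tuned, 1
    format-coupled, 5 untuned at default priors); reused read-only."""
    cfg = TaskConfig(n_sessions=1, trials_per_condition=24, rng_seed=7)
    return generate_experiment(cfg, PopulationPriors(n_neurons=12))


@pytest.fixture(scope="session")
def small_ds(small_experiment):
    return small_experiment[0]


@pytest.fixture(scope="session")
def small_truth(small_experiment):
    return small_experiment[1]


@pytest.fixture(scope="session")
def decoding_experiment():
    """Richer dataset for decoding protocols: 30 trials/condition."""
    cfg = TaskConfig(n_sessions=1, trials_per_condition=30, rng_seed=5)
    return generate_experiment(cfg, PopulationPriors(n_neurons=16))


@pytest.fixture(scope="session")
def decoding_ds(decoding_experiment):
    return decoding_experiment[0]


def toy_dataset(spike_times_by_trial, n_trials=2, fixation_ms=500.0,
                outcomes=None, numerosities=None):
    """Hand-built single-neuron dataset for exact-count tests.

    ``spike_times_by_trial``: dict trial_id -> list of times (ms).
    """
    trial_ids = sorted(set(spike_times_by_trial) | set(range(n_trials)))
    trials = pd.DataFrame({
        "session_id": 0,
        "trial_id": trial_ids,
        "numerosity": numerosities if numerosities is not None
        else [1 + (t % 5) for t in trial_ids],
        "format": ["dot" if t % 2 == 0 else "sign" for t in trial_ids],
        "stim_condition": "standard",
        "arrangement": "standard",
        "produced_count": 1.0,
        "outcome": outcomes if outcomes is not None else "correct",
    })
    rows = [(0, t, ms) for t, times in spike_times_by_trial.items()
            for ms in times]
    spikes = pd.DataFrame(rows, columns=["neuron_id", "trial_id", "time_ms"]
                          ) if rows else pd.DataFrame(
        columns=["neuron_id", "trial_id", "time_ms"]).astype(
        {"neuron_id": "int64", "trial_id": "int64", "time_ms": "float64"})
    neurons = pd.DataFrame({"neuron_id": [0], "session_id": [0]})
    meta = dict(fixation_ms=fixation_ms, instruction_ms=500.0,
                planning_ms=1000.0, execution_ms=1000.0)
    return SessionDataset(trials=trials, spikes=spikes, neurons=neurons,
                          meta=meta)
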