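"""Synthetic task trials, behavioral responses, and Poisson spike trains.

The generator emulates a number-production task: a monkey sees an
instruction stimulus (1-5 items, as dot arrays or Arabic numerals, each in
a standard and a visually controlled variant — 20 conditions), holds the
number through a motor-planning delay, then releases a handle that many
times.  Behavioral errors follow an approximate-number-system model: the
internal estimate of the instructed numerosity ``n`` is log-normally
distributed with Weber fraction ``w``, producing the numerical distance
effect (errors cluster near the target) and the size effect (spread grows
with ``n``).

Neurons are inhomogeneous-Poisson units with log-Gaussian numerosity
tuning gated by a per-neuron response window:

    lambda(t) = max(0, baseline + gain * exp(-(ln n - ln pref)^2 / (2 width^2)) * 1[t in window])

``gain < 0`` gives inhibited (below-baseline) tuning.  Static-code neurons
hold one window spanning instruction through planning; dynamic-code
neurons have short (<= 400 ms) windows, so population tuning sweeps
through time.  Format-coupled neurons draw independent preferred values
for the dot and sign formats; untuned neurons fire at baseline only.

Randomness uses one root seed with per-trial and per-(neuron, trial)
streams derived by seed-sequence splitting, so adding neurons does not
perturb existing trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datasets import SessionDataset

ARRANGEMENT_SCHEMES = ("standard", "control1", "control2")
STANDARD_INTERVALS_MS = (200.0, 500.0, 800.0, 1100.0)
# fixed-total-duration control: interval table per numerosity
_CONTROL2_TABLE = {1: [], 2: [2100.0], 3: [800.0, 800.0],
                   4: [400.0, 400.0, 400.0], 5: [200.0] * 4}


@dataclass(frozen=True)
class TaskConfig:
    """Task structure and trial counts.

    ``trials_per_condition`` is the number of non-aborted trials per each
    of the 20 numerosity x format x stimulus-condition cells, per session.
    Phase durations are ms; times elsewhere are relative to instruction
    onset, so fixation spans ``[-fixation_ms, 0)``.
    """

    n_sessions: int = 1
    trials_per_condition: int = 10
    numerosities: tuple = (1, 2, 3, 4, 5)
    formats: tuple = ("dot", "sign")
    stim_conditions: tuple = ("standard", "control")
    fixation_ms: float = 500.0
    instruction_ms: float = 500.0
    planning_ms: float = 1000.0
    execution_ms: float = 1000.0
    abort_fraction: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_condition < 5:
            raise ValueError(
                "trials_per_condition must be >= 5 (the neuron-inclusion "
                "rule requires at least five correct trials per condition)")
        for name in ("fixation_ms", "instruction_ms", "planning_ms",
                     "execution_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.abort_fraction < 1.0:
            raise ValueError("abort_fraction must be in [0, 1)")

    @property
    def conditions(self) -> list:
        return [(n, f, s) for n in self.numerosities
                for f in self.formats for s in self.stim_conditions]

    @property
    def trial_end_ms(self) -> float:
        return self.instruction_ms + self.planning_ms + self.execution_ms


@dataclass(frozen=True)
class PopulationPriors:
    """Composition and parameter ranges of the simulated population.

    Fractions partition neurons into numerosity-tuned, format-coupled
    (independent tuning per format) and untuned nuisance units; among
    tuned neurons a fraction is inhibited (negative gain) and a fraction
    carries a dynamic (short-window) code.
    """

    n_neurons: int = 40
    frac_tuned: float = 0.5
    frac_format_coupled: float = 0.05
    frac_inhibited: float = 0.25
    frac_dynamic: float = 0.3
    gain_hz: tuple = (15.0, 25.0)
    baseline_hz: tuple = (5.0, 15.0)
    tuning_width: float = 0.3
    latency_ms: tuple = (100.0, 300.0)
    dynamic_window_ms: float = 300.0
    weber_fraction: float = 0.2
    log_axis: bool = True

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("population must contain at least one neuron")
        if self.frac_tuned + self.frac_format_coupled > 1.0 + 1e-9:
            raise ValueError("tuned + format-coupled fractions exceed 1")
        if self.weber_fraction < 0:
            raise ValueError("weber_fraction must be nonnegative")


@dataclass
class GroundTruth:
    """Per-neuron generative parameters plus the behavioral Weber fraction.

    ``neurons`` columns: neuron_id, session_id, tuned, format_coupled,
    preferred_value (NaN if untuned), preferred_value_sign (for
    format-coupled neurons, tuning under the sign format), tuning_width,
    gain_hz, baseline_hz, window_onset_ms, window_offset_ms, code_type.
    """

    neurons: pd.DataFrame
    weber_fraction: float
    log_axis: bool = True

    def to_json(self) -> str:
        import json
        return json.dumps({
            "weber_fraction": self.weber_fraction,
            "log_axis": self.log_axis,
            "neurons": self.neurons.to_dict(orient="list"),
        }, indent=1, sort_keys=True, default=float)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        import json
        d = json.loads(text)
        return cls(neurons=pd.DataFrame(d["neurons"]),
                   weber_fraction=d["weber_fraction"],
                   log_axis=d.get("log_axis", True))


# ---------------------------------------------------------------------------
# Behavioral model
# ---------------------------------------------------------------------------

def sample_behavioral_response(numerosity: int, w: float,
                               rng: np.random.Generator) -> int:
    """Draw a produced count from the log-normal internal-estimate model.

    The internal estimate is ``x ~ Normal(log n, w)``; the animal produces
    ``round(exp(x))`` clipped to at least 1.  With ``w = 0`` the response
    is always exact.
    """
    if numerosity not in (1, 2, 3, 4, 5):
        raise ValueError(f"numerosity must be in 1..5, got {numerosity}")
    if w < 0:
        raise ValueError("weber fraction must be nonnegative")
    if w == 0:
        return int(numerosity)
    x = rng.normal(np.log(numerosity), w)
    return int(max(1, np.rint(np.exp(x))))


def temporal_arrangement(scheme: str, numerosity: int,
                         rng: np.random.Generator | None = None) -> list:
    """Inter-response intervals (ms) for the enumeration period.

    ``standard`` draws each interval uniformly from 200/500/800/1100 ms;
    ``control1`` fixes every interval at 200 ms; ``control2`` holds the
    total enumeration time constant via a per-numerosity interval table.
    """
    if numerosity not in (1, 2, 3, 4, 5):
        raise ValueError(f"numerosity must be in 1..5, got {numerosity}")
    if scheme == "standard":
        rng = np.random.default_rng() if rng is None else rng
        return [float(rng.choice(STANDARD_INTERVALS_MS))
                for _ in range(numerosity - 1)]
    if scheme == "control1":
        return [200.0] * (numerosity - 1)
    if scheme == "control2":
        return list(_CONTROL2_TABLE[numerosity])
    raise ValueError(f"unknown arrangement scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Spiking model
# ---------------------------------------------------------------------------

def tuning_drive(preferred: float, width: float, numerosity: float,
                 log_axis: bool = True) -> float:
    """Gaussian tuning profile evaluated at ``numerosity`` (peak = 1)."""
    if log_axis:
        d = np.log(numerosity) - np.log(preferred)
    else:
        d = numerosity - preferred
    return float(np.exp(-d * d / (2.0 * width * width)))


def _rate_segments(neuron: pd.Series, drive_numerosity, fmt: str,
                   config: TaskConfig, log_axis: bool) -> list:
    """Piecewise-constant rate profile [(t0, t1, hz), ...] for one trial."""
    t0, t_end = -config.fixation_ms, config.trial_end_ms
    base = float(neuron["baseline_hz"])
    tuned = bool(neuron["tuned"]) or bool(neuron["format_coupled"])
    if not tuned or drive_numerosity is None or not np.isfinite(drive_numerosity):
        return [(t0, t_end, max(0.0, base))]
    pref = float(neuron["preferred_value_sign"]) if (
        bool(neuron["format_coupled"]) and fmt == "sign"
    ) else float(neuron["preferred_value"])
    amp = float(neuron["gain_hz"]) * tuning_drive(
        pref, float(neuron["tuning_width"]), drive_numerosity, log_axis)
    a, b = float(neuron["window_onset_ms"]), float(neuron["window_offset_ms"])
    return [
        (t0, a, max(0.0, base)),
        (a, b, max(0.0, base + amp)),
        (b, t_end, max(0.0, base)),
    ]


def sample_spike_train(neuron: pd.Series, drive_numerosity, fmt: str,
                       config: TaskConfig, rng: np.random.Generator,
                       log_axis: bool = True) -> np.ndarray:
    """Sample one trial's spike times (ms, sorted) for one neuron.

    The rate is piecewise constant (baseline outside the response window,
    baseline + tuned drive inside, clipped at zero), so each segment is a
    homogeneous Poisson draw with uniform spike placement.
    """
    times = []
    for a, b, hz in _rate_segments(neuron, drive_numerosity, fmt, config,
                                   log_axis):
        if b <= a or hz <= 0:
            continue
        n = rng.poisson(hz * (b - a) / 1000.0)
        if n:
            times.append(rng.uniform(a, b, size=n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


# ---------------------------------------------------------------------------
# Ground-truth population
# ---------------------------------------------------------------------------

def sample_ground_truth(priors: PopulationPriors, config: TaskConfig,
                        rng: np.random.Generator) -> GroundTruth:
    n = priors.n_neurons
    n_tuned = int(round(priors.frac_tuned * n))
    n_fmt = int(round(priors.frac_format_coupled * n))
    roles = (["tuned"] * n_tuned + ["format"] * n_fmt
             + ["untuned"] * (n - n_tuned - n_fmt))
    rows = []
    plan_end = config.instruction_ms + config.planning_ms
    for i, role in enumerate(roles):
        tuned = role == "tuned"
        fmt_coupled = role == "format"
        if tuned or fmt_coupled:
            pref = float(rng.integers(1, 6))
            pref_sign = float(rng.integers(1, 6)) if fmt_coupled else pref
            sign = -1.0 if (tuned and rng.random() < priors.frac_inhibited) else 1.0
            gain = sign * rng.uniform(*priors.gain_hz)
            dynamic = rng.random() < priors.frac_dynamic
            latency = rng.uniform(*priors.latency_ms)
            if dynamic:
                onset = rng.uniform(latency, plan_end - priors.dynamic_window_ms)
                offset = onset + priors.dynamic_window_ms
                code = "dynamic"
            else:
                onset, offset, code = latency, plan_end, "static"
            base = rng.uniform(*priors.baseline_hz)
            if gain < 0:
                # keep inhibited neurons from clipping to silence at the peak
                base = max(base, -gain * 0.8)
        else:
            pref = pref_sign = np.nan
            gain, onset, offset, code = 0.0, 0.0, plan_end, "static"
            base = rng.uniform(*priors.baseline_hz)
        rows.append(dict(
            neuron_id=i, session_id=i % config.n_sessions, tuned=tuned,
            format_coupled=fmt_coupled, preferred_value=pref,
            preferred_value_sign=pref_sign, tuning_width=priors.tuning_width,
            gain_hz=gain, baseline_hz=base, window_onset_ms=onset,
            window_offset_ms=offset, code_type=code))
    return GroundTruth(neurons=pd.DataFrame(rows),
                       weber_fraction=priors.weber_fraction,
                       log_axis=priors.log_axis)


# ---------------------------------------------------------------------------
# Experiment generator
# ---------------------------------------------------------------------------

def _trial_rng(seed: int, session: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, 1, session, index])


def _spike_rng(seed: int, neuron_id: int, trial_id: int) -> np.random.Generator:
    return np.random.default_rng([seed, 2, neuron_id, trial_id])


def generate_experiment(config: TaskConfig,
                        priors: PopulationPriors | None = None,
                        truth: GroundTruth | None = None,
                        error_drive: str = "produced"):
    """Generate a full synthetic experiment.

    Returns ``(SessionDataset, GroundTruth)``.  Behavioral outcomes come
    from the Weber-fraction model; by default (``error_drive="produced"``)
    tuned neurons on error trials are driven by the numerosity the animal
    actually produced (clipped to 1-5), encoding the hypothesis that
    planning activity predicts the action, not the instruction.  Aborted
    trials (a fixed extra fraction) carry baseline-only spiking and no
    produced count.

    Each session pairs the standard temporal arrangement with one of the
    two controls, alternating by session, in a balanced sequence.
    """
    if error_drive not in ("produced", "instructed"):
        raise ValueError("error_drive must be 'produced' or 'instructed'")
    priors = PopulationPriors() if priors is None else priors
    seed = config.rng_seed
    if truth is None:
        truth = sample_ground_truth(priors, config,
                                    np.random.default_rng([seed, 0]))
    if len(truth.neurons) == 0:
        raise ValueError("empty neuron population")
    w = truth.weber_fraction

    trial_rows, spike_frames = [], []
    for sess in range(config.n_sessions):
        control = ARRANGEMENT_SCHEMES[1 + sess % 2]
        grid = []
        for cond in config.conditions:
            for k in range(config.trials_per_condition):
                arr = "standard" if k % 2 == 0 else control
                grid.append((cond, arr, False))
        n_abort = int(round(config.abort_fraction * len(grid)))
        for k in range(n_abort):
            grid.append((config.conditions[k % len(config.conditions)],
                         "standard" if k % 2 else control, True))
        order_rng = np.random.default_rng([seed, 3, sess])
        order = order_rng.permutation(len(grid))
        sess_neurons = truth.neurons[truth.neurons["session_id"] == sess]
        for idx, gi in enumerate(order):
            (numer, fmt, stim), arr, aborted = grid[gi]
            trial_id = sess * 100000 + idx
            t_rng = _trial_rng(seed, sess, idx)
            if aborted:
                produced, outcome = np.nan, "aborted"
            else:
                produced = sample_behavioral_response(numer, w, t_rng)
                outcome = "correct" if produced == numer else "error"
            trial_rows.append(dict(
                session_id=sess, trial_id=trial_id, numerosity=numer,
                format=fmt, stim_condition=stim, arrangement=arr,
                produced_count=produced, outcome=outcome))
            if outcome == "aborted":
                drive = None
            elif outcome == "error" and error_drive == "produced":
                drive = float(np.clip(produced, 1, 5))
            else:
                drive = float(numer)
            for _, nr in sess_neurons.iterrows():
                s_rng = _spike_rng(seed, int(nr["neuron_id"]), trial_id)
                t = sample_spike_train(nr, drive, fmt, config, s_rng,
                                       truth.log_axis)
                if t.size:
                    spike_frames.append(pd.DataFrame({
                        "neuron_id": int(nr["neuron_id"]),
                        "trial_id": trial_id, "time_ms": t}))

    trials = pd.DataFrame(trial_rows)
    if spike_frames:
        spikes = pd.concat(spike_frames, ignore_index=True)
    else:
        spikes = pd.DataFrame(columns=["neuron_id", "trial_id", "time_ms"]
                              ).astype({"neuron_id": "int64",
                                        "trial_id": "int64",
                                        "time_ms": "float64"})
    neurons = truth.neurons[["neuron_id", "session_id"]].copy()
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in asdict(config).items()}  # JSON-stable provenance
    meta = dict(fixation_ms=config.fixation_ms,
                instruction_ms=config.instruction_ms,
                planning_ms=config.planning_ms,
                execution_ms=config.execution_ms,
                provenance=dict(kind="synthetic", seed=seed, config=cfg))
    ds = SessionDataset(trials=trials, spikes=spikes, neurons=neurons,
                        meta=meta)
    return ds, truth
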