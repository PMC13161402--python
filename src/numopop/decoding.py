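"""Resampled linear-SVM population decoding.

All protocols share one scheme: per neuron, a fixed number of trials per
class is drawn without replacement and label-aligned across neurons into
pseudotrials (neurons recorded in different sessions are conjoined by
(label, draw index)); features are trial mean firing rates in an analysis
window, z-scored; a linear one-vs-one multiclass SVM is cross-validated
with stratified folds; the whole procedure repeats over many random trial
subsets.  Chance is estimated by re-running the identical protocol on
shuffled labels.

z-scoring uses training-fold statistics applied to held-out trials by
default (leak-free); ``pooled`` mode standardizes the full matrix before
cross-validation instead, matching protocols that z-score the sampled
trials up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .datasets import SessionDataset


@dataclass(frozen=True)
class DecodingProtocol:
    """Resampling and classifier settings shared by all protocols."""

    trials_per_class: int = 20
    folds: int = 10
    resamples: int = 1000
    z_score: str = "train-fold"      # or "pooled"
    C: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_class % self.folds:
            raise ValueError("trials_per_class must be divisible by folds")
        if self.resamples < 1:
            raise ValueError("resamples must be >= 1")
        if self.z_score not in ("train-fold", "pooled"):
            raise ValueError("z_score must be 'train-fold' or 'pooled'")


@dataclass
class DecodingResult:
    """Confusion matrix (row-normalized), accuracies, and shuffle null."""

    classes: np.ndarray
    confusion: np.ndarray
    accuracy: float
    sem: float
    per_class: np.ndarray
    accuracies: np.ndarray
    null_accuracies: np.ndarray | None = None
    null_95: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def window_rate_table(ds: SessionDataset, neuron_ids, window: tuple
                      ) -> pd.DataFrame:
    """Trial x neuron matrix of firing rates (Hz) in a half-open window."""
    a, b = window
    neuron_ids = list(neuron_ids)
    s = ds.spikes
    sel = s["neuron_id"].isin(neuron_ids) & (s["time_ms"] >= a) \
        & (s["time_ms"] < b)
    counts = (s.loc[sel].groupby(["trial_id", "neuron_id"], observed=True)
              .size().unstack(fill_value=0))
    table = counts.reindex(index=ds.trials["trial_id"].to_numpy(),
                           columns=neuron_ids, fill_value=0).astype(float)
    return table / ((b - a) / 1000.0)


class PseudopopulationSampler:
    """Draws label-aligned pseudotrial feature matrices.

    Parameters
    ----------
    rate_table : trial x neuron rate matrix (e.g. from
        :func:`window_rate_table`; for cross-window protocols pass a dict
        name -> table with identical trial indices via ``extra_tables``).
    class_of : Series mapping trial_id -> class label (NaN = excluded).
    neuron_sessions : Series mapping neuron_id -> session_id.
    trial_sessions : Series mapping trial_id -> session_id.
    min_trials_per_class : neurons whose session lacks this many eligible
        trials in any class are dropped (recorded in ``dropped``).
    """

    def __init__(self, rate_table: pd.DataFrame, class_of: pd.Series,
                 neuron_sessions: pd.Series, trial_sessions: pd.Series,
                 min_trials_per_class: int,
                 extra_tables: dict | None = None):
        self.classes = np.sort(pd.unique(class_of.dropna()))
        self.tables = {"main": rate_table, **(extra_tables or {})}
        self.pools: dict = {}
        self.dropped: list = []
        for nid in rate_table.columns:
            sess = neuron_sessions.loc[nid]
            pools = {}
            ok = True
            for c in self.classes:
                ids = class_of.index[(class_of == c)
                                     & (trial_sessions.loc[class_of.index]
                                        == sess)].to_numpy()
                if len(ids) < min_trials_per_class:
                    ok = False
                    break
                pools[c] = ids
            if ok:
                self.pools[nid] = pools
            else:
                self.dropped.append(nid)
        self.neuron_ids = list(self.pools)

    def sample(self, trials_per_class: int, rng: np.random.Generator,
               table: str = "main"):
        """One pseudopopulation draw -> (X, y, sampled trial ids)."""
        if not self.neuron_ids:
            raise ValueError("no neurons satisfy the trial minimum")
        tab = self.tables[table]
        n_rows = trials_per_class * len(self.classes)
        X = np.empty((n_rows, len(self.neuron_ids)))
        y = np.repeat(self.classes, trials_per_class)
        picks = {}
        for j, nid in enumerate(self.neuron_ids):
            col = []
            chosen = {}
            for c in self.classes:
                ids = rng.choice(self.pools[nid][c], size=trials_per_class,
                                 replace=False)
                chosen[c] = ids
                col.append(tab.loc[ids, nid].to_numpy())
            X[:, j] = np.concatenate(col)
            picks[nid] = chosen
        return X, y, picks

    def matrix_for(self, picks: dict, table: str):
        """Feature matrix for an existing draw under another window."""
        tab = self.tables[table]
        n_rows = sum(len(v) for v in next(iter(picks.values())).values())
        X = np.empty((n_rows, len(self.neuron_ids)))
        for j, nid in enumerate(self.neuron_ids):
            X[:, j] = np.concatenate(
                [tab.loc[picks[nid][c], nid].to_numpy()
                 for c in self.classes])
        return X


def sampler_for(ds: SessionDataset, window: tuple, neuron_ids=None,
                label_col: str = "numerosity",
                trial_mask: pd.Series | None = None,
                min_trials_per_class: int = 20,
                extra_windows: dict | None = None) -> PseudopopulationSampler:
    """Build a sampler from a dataset: correct trials, numerosity labels."""
    neuron_ids = ds.neuron_ids if neuron_ids is None else neuron_ids
    trials = ds.trials
    mask = trials["outcome"] == "correct" if trial_mask is None else trial_mask
    class_of = pd.Series(np.where(mask, trials[label_col], np.nan),
                         index=trials["trial_id"].to_numpy())
    table = window_rate_table(ds, neuron_ids, window)
    extra = {name: window_rate_table(ds, neuron_ids, w)
             for name, w in (extra_windows or {}).items()}
    return PseudopopulationSampler(
        table, class_of,
        ds.neurons.set_index("neuron_id")["session_id"],
        ds.trials.set_index("trial_id")["session_id"],
        min_trials_per_class, extra_tables=extra)


# ---------------------------------------------------------------------------
# Cross-validation core
# ---------------------------------------------------------------------------

def _stratified_folds(y: np.ndarray, folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold index per row; each class spread evenly over folds."""
    assign = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign

_N_DEGENERATE = 0


def _zstats(X: np.ndarray):
    global _N_DEGENERATE
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    degenerate = sd <= 0
    if degenerate.any():
        _N_DEGENERATE += int(degenerate.sum())
        sd = np.where(degenerate, 1.0, sd)
    return mu, sd


def cv_predict(X: np.ndarray, y: np.ndarray, protocol: DecodingProtocol,
               rng: np.random.Generator,
               test_sets: dict | None = None) -> dict:
    """One stratified k-fold pass; optionally test each fold's model on
    alternative feature matrices with the same rows.

    Returns ``{name: (y_true, y_pred)}``; ``"self"`` is the standard CV.
    """
    folds = _stratified_folds(y, protocol.folds, rng)
    if protocol.z_score == "pooled":
        mu, sd = _zstats(X)
        Xz = (X - mu) / sd
    out = {name: ([], []) for name in
           ["self"] + list(test_sets or {})}
    for k in range(protocol.folds):
        tr, te = folds != k, folds == k
        if protocol.z_score == "train-fold":
            mu, sd = _zstats(X[tr])
            Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
        else:
            Xtr, Xte = Xz[tr], Xz[te]
        clf = SVC(kernel="linear", C=protocol.C,
                  decision_function_shape="ovo")
        clf.fit(Xtr, y[tr])
        out["self"][0].extend(y[te])
        out["self"][1].extend(clf.predict(Xte))
        for name, Xalt in (test_sets or {}).items():
            Xa = (Xalt[te] - mu) / sd
            out[name][0].extend(y[te])
            out[name][1].extend(clf.predict(Xa))
    return {name: (np.asarray(t), np.asarray(p))
            for name, (t, p) in out.items()}


def _result_from_counts(classes, counts, accuracies,
                        null=None) -> DecodingResult:
    row = counts.sum(axis=1, keepdims=True)
    confusion = np.divide(counts, row, out=np.zeros_like(counts, dtype=float),
                          where=row > 0)
    per_class = np.diag(confusion)
    accuracies = np.asarray(accuracies, dtype=float)
    sem = accuracies.std(ddof=1) / np.sqrt(len(accuracies)) \
        if len(accuracies) > 1 else 0.0
    res = DecodingResult(classes=np.asarray(classes), confusion=confusion,
                         accuracy=float(np.mean(accuracies)), sem=float(sem),
                         per_class=per_class, accuracies=accuracies)
    if null is not None:
        null = np.asarray(null, dtype=float)
        res.null_accuracies = null
        res.null_95 = float(np.percentile(null, 95))
    return res


def decode(X: np.ndarray, y: np.ndarray, protocol: DecodingProtocol,
           rng: np.random.Generator | None = None,
           n_null: int = 0) -> DecodingResult:
    """Cross-validated decoding of one fixed feature matrix.

    The fold partition is re-randomized every resample; ``n_null``
    additional resamples with permuted labels build the chance
    distribution.
    """
    rng = np.random.default_rng(protocol.rng_seed) if rng is None else rng
    y = np.asarray(y)
    classes = np.unique(y)
    cidx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    accs = []
    for _ in range(protocol.resamples):
        (t, p), = cv_predict(X, y, protocol, rng).values()
        for ti, pi in zip(t, p):
            counts[cidx[ti], cidx[pi]] += 1
        accs.append(np.mean(t == p))
    null = []
    for _ in range(n_null):
        ys = rng.permutation(y)
        (t, p), = cv_predict(X, ys, protocol, rng).values()
        null.append(np.mean(t == p))
    return _result_from_counts(classes, counts, accs,
                               null if n_null else None)


def decode_population(sampler: PseudopopulationSampler,
                      protocol: DecodingProtocol,
                      rng: np.random.Generator | None = None,
                      n_null: int = 0, shuffle: bool = False
                      ) -> DecodingResult:
    """Full resampled protocol: new pseudotrials each resample, one
    stratified CV pass per draw.  ``shuffle=True`` permutes labels in
    every resample (used to *be* the null)."""
    rng = np.random.default_rng(protocol.rng_seed) if rng is None else rng
    classes = sampler.classes
    cidx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    accs, null = [], []
    for _ in range(protocol.resamples):
        X, y, _ = sampler.sample(protocol.trials_per_class, rng)
        if shuffle:
            y = rng.permutation(y)
        (t, p), = cv_predict(X, y, protocol, rng).values()
        for ti, pi in zip(t, p):
            counts[cidx[ti], cidx[pi]] += 1
        accs.append(np.mean(t == p))
    for _ in range(n_null):
        X, y, _ = sampler.sample(protocol.trials_per_class, rng)
        ys = rng.permutation(y)
        (t, p), = cv_predict(X, ys, protocol, rng).values()
        null.append(np.mean(t == p))
    return _result_from_counts(classes, counts, accs,
                               null if n_null else None)


# ---------------------------------------------------------------------------
# Protocol variants
# ---------------------------------------------------------------------------

def decode_cross_format(ds: SessionDataset, window: tuple,
                        protocol: DecodingProtocol,
                        neuron_ids=None, n_null: int = 0) -> dict:
    """Within- and across-format decoding with a shared neuron set.

    Neurons need ``trials_per_class`` correct trials per numerosity *per
    format*.  For each resample the two format matrices share fold
    structure: the model trained on format A's training folds is tested on
    the held-out folds of both formats.  Returns a dict with keys
    ``within_dot``, ``within_sign``, ``dot_to_sign``, ``sign_to_dot``.
    """
    rng = np.random.default_rng(protocol.rng_seed)
    neuron_ids = ds.neuron_ids if neuron_ids is None else neuron_ids
    samplers = {}
    for f in ("dot", "sign"):
        mask = (ds.trials["outcome"] == "correct") & (ds.trials["format"] == f)
        samplers[f] = sampler_for(
            ds, window, neuron_ids, trial_mask=mask,
            min_trials_per_class=protocol.trials_per_class)
    shared = [n for n in samplers["dot"].neuron_ids
              if n in set(samplers["sign"].neuron_ids)]
    for f in ("dot", "sign"):
        samplers[f].neuron_ids = shared
    keys = ["within_dot", "within_sign", "dot_to_sign", "sign_to_dot"]
    classes = samplers["dot"].classes
    cidx = {c: i for i, c in enumerate(classes)}
    counts = {k: np.zeros((len(classes), len(classes))) for k in keys}
    accs = {k: [] for k in keys}
    nulls = {k: [] for k in keys}

    def one_pass(store_counts: bool, shuffle: bool):
        X = {f: samplers[f].sample(protocol.trials_per_class, rng)[0]
             for f in ("dot", "sign")}
        y = np.repeat(classes, protocol.trials_per_class)
        if shuffle:
            y = rng.permutation(y)
        for train_f, test_f, wkey, xkey in (
                ("dot", "sign", "within_dot", "dot_to_sign"),
                ("sign", "dot", "within_sign", "sign_to_dot")):
            preds = cv_predict(X[train_f], y, protocol, rng,
                               test_sets={"cross": X[test_f]})
            for key, (t, p) in zip((wkey, xkey),
                                   (preds["self"], preds["cross"])):
                if store_counts:
                    for ti, pi in zip(t, p):
                        counts[key][cidx[ti], cidx[pi]] += 1
                    accs[key].append(np.mean(t == p))
                else:
                    nulls[key].append(np.mean(t == p))

    for _ in range(protocol.resamples):
        one_pass(True, False)
    for _ in range(n_null):
        one_pass(False, True)
    return {k: _result_from_counts(classes, counts[k], accs[k],
                                   nulls[k] if n_null else None)
            for k in keys}


def decode_cross_phase(ds: SessionDataset, neuron_ids,
                       protocol: DecodingProtocol,
                       instruction_window: tuple = (250.0, 550.0),
                       planning_window: tuple = (700.0, 1600.0),
                       n_null: int = 100) -> dict:
    """Train on one trial phase, test on the other (non-overlapping
    windows: a 300 ms instruction interval starting 250 ms after
    instruction onset, and the 900 ms planning interval starting 700 ms
    after onset).  Returns the four train/test combinations, each with a
    shuffle-null 95th percentile.
    """
    rng = np.random.default_rng(protocol.rng_seed)
    sampler = sampler_for(ds, instruction_window, neuron_ids,
                          min_trials_per_class=protocol.trials_per_class,
                          extra_windows={"planning": planning_window})
    classes = sampler.classes
    cidx = {c: i for i, c in enumerate(classes)}
    keys = ["instr_instr", "instr_plan", "plan_plan", "plan_instr"]
    counts = {k: np.zeros((len(classes), len(classes))) for k in keys}
    accs = {k: [] for k in keys}
    nulls = {k: [] for k in keys}

    def one_pass(store: bool, shuffle: bool):
        Xi, y, picks = sampler.sample(protocol.trials_per_class, rng)
        Xp = sampler.matrix_for(picks, "planning")
        if shuffle:
            y = rng.permutation(y)
        for Xtr, Xte, wkey, xkey in ((Xi, Xp, "instr_instr", "instr_plan"),
                                     (Xp, Xi, "plan_plan", "plan_instr")):
            preds = cv_predict(Xtr, y, protocol, rng,
                               test_sets={"cross": Xte})
            for key, (t, p) in zip((wkey, xkey),
                                   (preds["self"], preds["cross"])):
                if store:
                    for ti, pi in zip(t, p):
                        counts[key][cidx[ti], cidx[pi]] += 1
                    accs[key].append(np.mean(t == p))
                else:
                    nulls[key].append(np.mean(t == p))

    for _ in range(protocol.resamples):
        one_pass(True, False)
    for _ in range(n_null):
        one_pass(False, True)
    return {k: _result_from_counts(classes, counts[k], accs[k],
                                   nulls[k] if n_null else None)
            for k in keys}


def decode_error_trials(ds: SessionDataset, window: tuple,
                        protocol: DecodingProtocol,
                        neuron_ids=None) -> dict:
    """Train on correct trials, test held-out correct and error trials.

    Error test trials are labeled by the *instructed* numerosity; per
    resample one error trial per class is drawn.  Neurons need one error
    trial per class and ``trials_per_class`` correct trials.  Returns
    paired correct/error accuracies and a Wilcoxon signed-rank p across
    resamples.
    """
    rng = np.random.default_rng(protocol.rng_seed)
    neuron_ids = ds.neuron_ids if neuron_ids is None else neuron_ids
    cor = sampler_for(ds, window, neuron_ids,
                      min_trials_per_class=protocol.trials_per_class)
    err_mask = ds.trials["outcome"] == "error"
    err = sampler_for(ds, window, neuron_ids, trial_mask=err_mask,
                      min_trials_per_class=1)
    shared = [n for n in cor.neuron_ids if n in set(err.neuron_ids)]
    if not shared:
        raise ValueError("no neurons with errors in every class")
    cor.neuron_ids = shared
    err.neuron_ids = shared
    acc_c, acc_e = [], []
    for _ in range(protocol.resamples):
        X, y, _ = cor.sample(protocol.trials_per_class, rng)
        Xe, ye, _ = err.sample(1, rng)
        folds = _stratified_folds(y, protocol.folds, rng)
        tc = pc = te = pe = 0
        for k in range(protocol.folds):
            tr = folds != k
            mu, sd = _zstats(X[tr])
            clf = SVC(kernel="linear", C=protocol.C,
                      decision_function_shape="ovo")
            clf.fit((X[tr] - mu) / sd, y[tr])
            pred_c = clf.predict((X[folds == k] - mu) / sd)
            tc += len(pred_c)
            pc += int(np.sum(pred_c == y[folds == k]))
            pred_e = clf.predict((Xe - mu) / sd)
            te += len(pred_e)
            pe += int(np.sum(pred_e == ye))
        acc_c.append(pc / tc)
        acc_e.append(pe / te)
    acc_c, acc_e = np.asarray(acc_c), np.asarray(acc_e)
    if np.allclose(acc_c, acc_e):
        p = 1.0
    else:
        _, p = stats.wilcoxon(acc_c, acc_e)
    return {"accuracy_correct": float(acc_c.mean()),
            "accuracy_error": float(acc_e.mean()),
            "accuracies_correct": acc_c, "accuracies_error": acc_e,
            "wilcoxon_p": float(p), "neurons": shared}


def decode_outcome(ds: SessionDataset, window: tuple,
                   protocol: DecodingProtocol | None = None,
                   neuron_ids=None, n_null: int = 0) -> DecodingResult:
    """Three-class outcome decoding: correct vs -1 error vs +1 error.

    Trials are pooled over numerosities; undershoots produce one fewer
    action than instructed, overshoots one more.  Default protocol uses
    30 trials per class with a 27/3 tenfold split (chance 33.3%).
    """
    if protocol is None:
        protocol = DecodingProtocol(trials_per_class=30)
    neuron_ids = ds.neuron_ids if neuron_ids is None else neuron_ids
    t = ds.trials
    delta = t["produced_count"] - t["numerosity"]
    label = pd.Series(np.where(t["outcome"] == "correct", "correct",
                      np.where((t["outcome"] == "error") & (delta == -1),
                               "minus1",
                      np.where((t["outcome"] == "error") & (delta == 1),
                               "plus1", None))),
                      index=t["trial_id"].to_numpy())
    table = window_rate_table(ds, neuron_ids, window)
    sampler = PseudopopulationSampler(
        table, label.dropna(),
        ds.neurons.set_index("neuron_id")["session_id"],
        t.set_index("trial_id")["session_id"],
        protocol.trials_per_class)
    return decode_population(sampler, protocol, n_null=n_null)
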