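"""Time-resolved population statistics: omega-squared percent explained
variance (PEV), cross-temporal decoding matrices, cluster-based
permutation significance, and confusion-diagonal distance curves.

omega squared converts sliding-window ANOVA sums of squares into a
bias-corrected percentage of variance explained per factor:

    w2 = (SS_TERM - df * MS_ERROR) / (SS_TOTAL + MS_ERROR) * 100

It is near zero in expectation for null factors and may be slightly
negative in small samples; values are reported unclipped by default.

Cross-temporal decoding trains a linear SVM in each time bin and tests it
in every bin, yielding an accuracy matrix whose off-diagonal structure
separates static codes (square, generalizing pattern) from dynamic codes
(accuracy confined to the diagonal).  Significance uses a cluster-based
permutation test: per-cell shuffle-null thresholds, connected components
of supra-threshold cells, and cluster sizes ranked against the null
matrices' cluster sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .anova import AnovaDecomposition, two_factor_anova
from .datasets import BinScheme, SessionDataset, bin_rates
from .decoding import DecodingProtocol, _stratified_folds, _zstats
from sklearn.svm import SVC


# ---------------------------------------------------------------------------
# omega squared
# ---------------------------------------------------------------------------

def omega_squared(dec: AnovaDecomposition, factor: str,
                  clip: bool = False):
    """Percent explained variance for one ANOVA factor (may be negative)."""
    ss = dec.ss[factor]
    denom = dec.ss_total + dec.ms_error
    if np.any(np.asarray(denom) <= 0):
        raise ValueError("SS_TOTAL + MS_ERROR must be positive")
    w2 = (ss - dec.df[factor] * dec.ms_error) / denom * 100.0
    if clip:
        w2 = np.maximum(w2, 0.0)
    return w2


# ---------------------------------------------------------------------------
# PEV time course
# ---------------------------------------------------------------------------

@dataclass
class PEVTrace:
    """Population omega-squared traces with resample SEM and shuffle null."""

    times: np.ndarray
    mean: dict                  # factor -> (n_bins,)
    sem: dict
    per_resample: dict          # factor -> (n_resamples, n_bins)
    null_threshold: dict        # factor -> (n_bins,) 95th pct of null
    null_values: dict           # factor -> (n_resamples*n_shuffles, n_bins)


def _population_omega(rates: np.ndarray, numer: np.ndarray,
                      fmt: np.ndarray) -> dict:
    """Mean-over-neurons omega squared per factor and bin.

    ``rates``: (n_neurons, n_obs, n_bins); all neurons share labels, so
    one ANOVA call handles the full tensor by folding neurons into the
    response columns.
    """
    n_neurons, n_obs, n_bins = rates.shape
    y = np.moveaxis(rates, 0, 2).reshape(n_obs, n_bins * n_neurons)
    dec = two_factor_anova(y, numer, fmt)
    out = {}
    for factor in ("number", "format", "interaction"):
        w2 = omega_squared(dec, factor).reshape(n_bins, n_neurons)
        out[factor] = w2.mean(axis=1)
    return out


def pev_timecourse(ds: SessionDataset, neuron_ids=None,
                   scheme: BinScheme | None = None,
                   n_resamples: int = 50, n_shuffles: int = 20,
                   trials_per_cell: int = 10,
                   rng: np.random.Generator | None = None) -> PEVTrace:
    """Resampled population PEV for number, format, and their interaction.

    Each resample draws ``trials_per_cell`` correct trials per numerosity
    x format cell (neurons below that count are dropped), computes each
    neuron's omega-squared trace, and averages over neurons.  Each
    resample also shuffles trial labels ``n_shuffles`` times, giving
    ``n_resamples * n_shuffles`` null values per bin; their 95th
    percentile is the baseline PEV threshold.  The default window runs
    from 300 ms before instruction onset to 100 ms after planning ends.
    """
    rng = np.random.default_rng() if rng is None else rng
    meta = ds.meta
    if scheme is None:
        scheme = BinScheme(start_ms=-300.0,
                           end_ms=meta["instruction_ms"]
                           + meta["planning_ms"] + 100.0)
    neuron_ids = ds.neuron_ids if neuron_ids is None else np.asarray(neuron_ids)
    factors = ("number", "format", "interaction")
    traces = {f: np.zeros((n_resamples, scheme.n_bins)) for f in factors}
    nulls = {f: np.zeros((n_resamples * n_shuffles, scheme.n_bins))
             for f in factors}

    # bin once per session, resample trial subsets from the cached tensor
    per_session = []
    neuron_meta = ds.neurons.set_index("neuron_id")["session_id"]
    for sess in np.unique(neuron_meta.loc[neuron_ids]):
        nids = [n for n in neuron_ids if neuron_meta.loc[n] == sess]
        trials = ds.trials[(ds.trials["session_id"] == sess)
                           & (ds.trials["outcome"] == "correct")]
        cells = trials.groupby(["numerosity", "format"],
                               observed=True)["trial_id"].apply(list)
        if (cells.apply(len) < trials_per_cell).any():
            raise ValueError(
                f"session {sess}: fewer than {trials_per_cell} correct "
                "trials in some numerosity x format cell")
        binned = bin_rates(ds, scheme, neuron_ids=nids,
                           trial_ids=trials["trial_id"].to_numpy())
        pos = {t: j for j, t in enumerate(binned.trial_ids)}
        per_session.append((binned.rates, cells, pos))

    for r in range(n_resamples):
        sess_w2 = []
        sess_null = [[] for _ in range(n_shuffles)]
        for rates, cells, pos in per_session:
            idx, numer, fmt = [], [], []
            for (nv, fv), ids in cells.items():
                pick = rng.choice(len(ids), size=trials_per_cell,
                                  replace=False)
                idx.extend(pos[ids[k]] for k in pick)
                numer.extend([nv] * trials_per_cell)
                fmt.extend([fv] * trials_per_cell)
            sub = rates[:, idx, :]
            numer, fmt = np.asarray(numer), np.asarray(fmt)
            sess_w2.append(_population_omega(sub, numer, fmt))
            for s in range(n_shuffles):
                perm = rng.permutation(len(numer))
                sess_null[s].append(
                    _population_omega(sub, numer[perm], fmt[perm]))
        for f in factors:
            traces[f][r] = np.mean([d[f] for d in sess_w2], axis=0)
            for s in range(n_shuffles):
                nulls[f][r * n_shuffles + s] = np.mean(
                    [d[f] for d in sess_null[s]], axis=0)

    return PEVTrace(
        times=scheme.bin_centers,
        mean={f: traces[f].mean(axis=0) for f in factors},
        sem={f: traces[f].std(axis=0, ddof=1) / np.sqrt(n_resamples)
             if n_resamples > 1 else np.zeros(scheme.n_bins)
             for f in factors},
        per_resample=traces,
        null_threshold={f: np.percentile(nulls[f], 95, axis=0)
                        for f in factors},
        null_values=nulls)


# ---------------------------------------------------------------------------
# Cross-temporal decoding
# ---------------------------------------------------------------------------

@dataclass
class CrossTemporalMatrix:
    """Train x test accuracy grid with its shuffle-null matrices."""

    times: np.ndarray
    accuracy: np.ndarray                 # (n_bins, n_bins)
    null: np.ndarray | None = None       # (n_perm, n_bins, n_bins)
    confusion: np.ndarray | None = None  # (n_bins, K, K) diagonal-time
    classes: np.ndarray | None = None
    clusters: list = field(default_factory=list)


def _binned_pseudopopulation(ds: SessionDataset, neuron_ids,
                             scheme: BinScheme, trials_per_class: int,
                             rng: np.random.Generator):
    """(trials, neurons, bins) tensor with label-aligned pseudotrials."""
    neuron_meta = ds.neurons.set_index("neuron_id")["session_id"]
    neuron_ids = [n for n in neuron_ids]
    cols, classes_ref = [], None
    for nid in neuron_ids:
        sess = neuron_meta.loc[nid]
        trials = ds.trials[(ds.trials["session_id"] == sess)
                           & (ds.trials["outcome"] == "correct")]
        ids_by_class = trials.groupby("numerosity",
                                      observed=True)["trial_id"].apply(list)
        classes = np.sort(ids_by_class.index.to_numpy())
        if classes_ref is None:
            classes_ref = classes
        chosen = []
        for c in classes:
            ids = ids_by_class.loc[c]
            if len(ids) < trials_per_class:
                raise ValueError(
                    f"neuron {nid}: fewer than {trials_per_class} correct "
                    f"trials for numerosity {c}")
            pick = rng.choice(len(ids), size=trials_per_class, replace=False)
            chosen.extend(ids[k] for k in pick)
        binned = bin_rates(ds, scheme, neuron_ids=[nid], trial_ids=chosen)
        cols.append(binned.rates[0])            # (trials, bins)
    X = np.stack(cols, axis=1)                  # (trials, neurons, bins)
    y = np.repeat(classes_ref, trials_per_class)
    return X, y


def cross_temporal_matrix(ds: SessionDataset, neuron_ids=None,
                          scheme: BinScheme | None = None,
                          protocol: DecodingProtocol | None = None,
                          n_redraws: int = 50, n_shuffles: int = 0,
                          rng: np.random.Generator | None = None
                          ) -> CrossTemporalMatrix:
    """Train-on-one-bin, test-on-all-bins SVM accuracy matrix.

    Per redraw a fresh pseudopopulation is drawn; within each stratified
    fold the model trained at bin ``i`` (z-scored with that bin's
    training-fold statistics) predicts the held-out trials at every bin
    ``j``, so train and test trials stay disjoint off the diagonal too.
    ``n_shuffles`` label permutations per redraw build the null matrices
    used by :func:`cluster_permutation_test`.
    """
    rng = np.random.default_rng() if rng is None else rng
    protocol = protocol or DecodingProtocol(trials_per_class=20, resamples=1)
    if scheme is None:
        meta = ds.meta
        scheme = BinScheme(start_ms=-300.0,
                           end_ms=meta["instruction_ms"]
                           + meta["planning_ms"] + 100.0)
    neuron_ids = ds.neuron_ids if neuron_ids is None else neuron_ids
    B = scheme.n_bins

    def grid_pass(X, y):
        acc = np.zeros((B, B))
        folds = _stratified_folds(y, protocol.folds, rng)
        for k in range(protocol.folds):
            tr, te = folds != k, folds == k
            yte = y[te]
            for bi in range(B):
                mu, sd = _zstats(X[tr, :, bi])
                clf = SVC(kernel="linear", C=protocol.C,
                          decision_function_shape="ovo")
                clf.fit((X[tr, :, bi] - mu) / sd, y[tr])
                for bj in range(B):
                    pred = clf.predict((X[te, :, bj] - mu) / sd)
                    acc[bi, bj] += np.mean(pred == yte)
        return acc / protocol.folds

    acc_sum = np.zeros((B, B))
    null = []
    for _ in range(n_redraws):
        X, y = _binned_pseudopopulation(ds, neuron_ids, scheme,
                                        protocol.trials_per_class, rng)
        acc_sum += grid_pass(X, y)
        for _ in range(n_shuffles):
            null.append(grid_pass(X, rng.permutation(y)))
    return CrossTemporalMatrix(
        times=scheme.bin_centers, accuracy=acc_sum / n_redraws,
        null=np.stack(null) if null else None)


def generalization_index(mat: np.ndarray) -> float:
    """Mean off-diagonal minus mean diagonal accuracy; near zero for a
    static (fully generalizing) code, strongly negative for a dynamic
    one."""
    mat = np.asarray(mat)
    diag = np.diag(mat).mean()
    off = (mat.sum() - np.trace(mat)) / (mat.size - mat.shape[0])
    return float(off - diag)


# ---------------------------------------------------------------------------
# Cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    cells: np.ndarray     # boolean mask over the grid
    size: int
    p: float


def cluster_permutation_test(observed: np.ndarray, null: np.ndarray,
                             alpha_cluster: float = 0.05,
                             alpha_rank: float = 0.05,
                             connectivity: int = 4) -> list:
    """Cluster-based permutation significance on an accuracy grid.

    Cells are supra-threshold when the observed accuracy exceeds the
    per-cell ``1 - alpha_cluster`` quantile of the pooled null-plus-
    observed matrices (pooling keeps observed and null exchangeable, so
    the rank test below is exact).  Contiguous supra-threshold cells
    (4-connectivity by default, 8 by flag) form clusters scored by cell
    count; the null distribution of maximal cluster sizes comes from
    thresholding each null matrix the same way.  Clusters whose
    permutation rank ``p = (1 + #{null >= size}) / (1 + n_perm)`` is at
    most ``alpha_rank`` are returned.
    """
    observed = np.asarray(observed)
    null = np.asarray(null)
    if null.ndim != 3 or null.shape[1:] != observed.shape:
        raise ValueError("null must be (n_perm, *observed.shape)")
    if null.shape[0] < 20:
        raise ValueError("need at least 20 permutations")
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    elif connectivity == 8:
        structure = np.ones((3, 3))
    else:
        raise ValueError("connectivity must be 4 or 8")
    pool = np.concatenate([null, observed[None]], axis=0)
    thresh = np.quantile(pool, 1.0 - alpha_cluster, axis=0)

    def max_cluster(mask):
        lab, n = ndimage.label(mask, structure=structure)
        if n == 0:
            return 0
        return int(np.max(ndimage.sum_labels(np.ones_like(lab), lab,
                                             np.arange(1, n + 1))))

    null_sizes = np.array([max_cluster(m > thresh) for m in null])
    lab, n = ndimage.label(observed > thresh, structure=structure)
    out = []
    for i in range(1, n + 1):
        cells = lab == i
        size = int(cells.sum())
        p = float((np.sum(null_sizes >= size) + 1) / (len(null_sizes) + 1))
        if p <= alpha_rank:
            out.append(Cluster(cells=cells, size=size, p=p))
    return out


# ---------------------------------------------------------------------------
# Distance curves
# ---------------------------------------------------------------------------

def distance_curves(confusions: np.ndarray, atol: float = 1e-8
                    ) -> pd.DataFrame:
    """Classification probability vs numerical distance from the correct
    label, per time bin.

    ``confusions``: (T, K, K) or (K, K) row-normalized matrices (rows =
    instructed, columns = predicted).  Distance ``d`` averages all
    entries with ``|instructed - predicted| = d`` (pooling +d and -d).
    """
    confusions = np.asarray(confusions, dtype=float)
    if confusions.ndim == 2:
        confusions = confusions[None]
    T, K, K2 = confusions.shape
    if K != K2:
        raise ValueError("confusion matrices must be square")
    rows = confusions.sum(axis=2)
    if not np.allclose(rows, 1.0, atol=atol):
        raise ValueError("confusion rows must sum to 1 (row-normalized)")
    i, j = np.meshgrid(np.arange(K), np.arange(K), indexing="ij")
    dist = np.abs(i - j)
    recs = []
    for t in range(T):
        for d in range(K):
            recs.append(dict(time_bin=t, distance=d,
                             probability=float(
                                 confusions[t][dist == d].mean())))
    return pd.DataFrame(recs)
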