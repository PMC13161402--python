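"""Numerosity-selective neurons: sliding-window ANOVA, selective-window
detection, preferred value and response sign, split-half tuning
reliability, population tuning curves, and error-trial contrasts.

A neuron counts as numerosity-selective when the sliding 5 x 2
(numerosity x format) ANOVA shows a significant main effect of number —
without a format main effect or an interaction — in at least ``min_run``
consecutive bins.  With the default 200 ms window and 20 ms step, 11
consecutive bins span 400 ms of data (first-bin start to last-bin end);
the run count is the operative rule.  The analysis interval starts
100 ms after instruction onset (response latency) and extends 100 ms
into motor execution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import two_factor_anova
from .datasets import BinScheme, BinnedRates, SessionDataset, bin_rates, \
    mean_rate_in_window

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_RUN = 11


# ---------------------------------------------------------------------------
# Inclusion
# ---------------------------------------------------------------------------

def include_neuron(ds: SessionDataset, neuron_id, min_rate_hz: float = 0.5,
                   min_trials_per_condition: int = 5,
                   window: tuple | None = None) -> bool:
    """Inclusion filter: mean rate and correct-trial counts.

    The neuron must fire at ``min_rate_hz`` on average over the interval
    from baseline onset to the end of motor planning (2000 ms at the
    default phase durations), and its session must hold at least
    ``min_trials_per_condition`` correct trials in every numerosity x
    format x stimulus-condition cell.
    """
    meta = ds.meta
    if window is None:
        window = (-meta["fixation_ms"],
                  meta["instruction_ms"] + meta["planning_ms"])
    sess = int(ds.neurons.loc[ds.neurons["neuron_id"] == neuron_id,
                              "session_id"].iloc[0])
    trials = ds.trials[(ds.trials["session_id"] == sess)
                       & (ds.trials["outcome"] == "correct")]
    if trials.empty:
        return False
    counts = trials.groupby(["numerosity", "format", "stim_condition"],
                            observed=True).size()
    n_cells = (trials["numerosity"].nunique() * trials["format"].nunique()
               * trials["stim_condition"].nunique())
    if len(counts) < n_cells or (counts < min_trials_per_condition).any():
        return False
    rate = mean_rate_in_window(ds, neuron_id, trials["trial_id"].to_numpy(),
                               window)
    return rate >= min_rate_hz


# ---------------------------------------------------------------------------
# Sliding ANOVA
# ---------------------------------------------------------------------------

@dataclass
class SlidingAnovaResult:
    """p-value surfaces (neurons x bins) for number, format, interaction."""

    scheme: BinScheme
    neuron_ids: np.ndarray
    p: dict          # factor -> (n_neurons, n_bins)
    decompositions: list


def sliding_anova(binned: BinnedRates, numerosity: np.ndarray,
                  fmt: np.ndarray, typ: int = 2) -> SlidingAnovaResult:
    """Per-bin two-factor ANOVA for every neuron in the rate tensor."""
    n_neurons = len(binned.neuron_ids)
    n_bins = binned.scheme.n_bins
    p = {k: np.full((n_neurons, n_bins), np.nan)
         for k in ("number", "format", "interaction")}
    decs = []
    for i in range(n_neurons):
        dec = two_factor_anova(binned.rates[i], numerosity, fmt, typ=typ)
        decs.append(dec)
        for k in p:
            p[k][i] = dec.p[k]
    return SlidingAnovaResult(scheme=binned.scheme,
                              neuron_ids=binned.neuron_ids, p=p,
                              decompositions=decs)


def _runs(mask: np.ndarray) -> list:
    """Maximal runs of True as inclusive (start, stop) index pairs."""
    out, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def detect_selective_window(p_number: np.ndarray, scheme: BinScheme,
                            rates: np.ndarray | None = None,
                            numerosity: np.ndarray | None = None,
                            p_format: np.ndarray | None = None,
                            p_interaction: np.ndarray | None = None,
                            alpha: float = DEFAULT_ALPHA,
                            min_run: int = DEFAULT_MIN_RUN):
    """Find the neuron's selective window, or None.

    Bins qualify when ``p_number < alpha`` and — if the format and
    interaction surfaces are supplied — neither of those is significant.
    Runs of at least ``min_run`` qualifying bins are candidates; among
    several, the run with the largest spread (max - min) of
    numerosity-mean rates within the run wins (ties toward the earlier
    run).  The window is reported as [first-bin start, last-bin end].
    """
    sig = np.asarray(p_number) < alpha
    if p_format is not None:
        sig &= np.asarray(p_format) >= alpha
    if p_interaction is not None:
        sig &= np.asarray(p_interaction) >= alpha
    candidates = [r for r in _runs(sig) if r[1] - r[0] + 1 >= min_run]
    if not candidates:
        return None
    if len(candidates) == 1 or rates is None:
        best = candidates[0]
    else:
        numerosity = np.asarray(numerosity)
        spreads = []
        for lo, hi in candidates:
            seg = rates[:, lo:hi + 1].mean(axis=1)
            means = [seg[numerosity == v].mean()
                     for v in np.unique(numerosity)]
            spreads.append(max(means) - min(means))
        best = candidates[int(np.argmax(spreads))]
    starts = scheme.bin_starts
    return (float(starts[best[0]]), float(starts[best[1]] + scheme.width_ms),
            best)


def classify_selectivity(res: SlidingAnovaResult, neuron_index: int,
                         bins: slice | None = None,
                         alpha: float = DEFAULT_ALPHA,
                         min_run: int = DEFAULT_MIN_RUN) -> str:
    """Selectivity category within a bin range.

    ``exclusively_number`` requires a qualifying number run with no
    format/interaction significance inside it; otherwise the first of
    ``format``, ``interaction``, ``number`` with a qualifying run of its
    own, else ``none``.
    """
    sl = bins if bins is not None else slice(None)
    pn = res.p["number"][neuron_index, sl]
    pf = res.p["format"][neuron_index, sl]
    pi = res.p["interaction"][neuron_index, sl]
    has = {k: any(r[1] - r[0] + 1 >= min_run
                  for r in _runs(res.p[k][neuron_index, sl] < alpha))
           for k in ("number", "format", "interaction")}
    exclusive = any(r[1] - r[0] + 1 >= min_run for r in _runs(
        (pn < alpha) & (pf >= alpha) & (pi >= alpha)))
    if exclusive:
        return "exclusively_number"
    if has["format"]:
        return "format"
    if has["interaction"]:
        return "interaction"
    if has["number"]:
        return "number"
    return "none"


# ---------------------------------------------------------------------------
# Preferred value, sign, tuning curves
# ---------------------------------------------------------------------------

def numerosity_rates(ds: SessionDataset, neuron_id, trial_table: pd.DataFrame,
                     window: tuple) -> pd.Series:
    """Mean rate per numerosity (Hz) within a window, indexed 1..5."""
    out = {}
    for v, grp in trial_table.groupby("numerosity", observed=True):
        out[int(v)] = mean_rate_in_window(
            ds, neuron_id, grp["trial_id"].to_numpy(), window)
    return pd.Series(out).sort_index()


def preferred_and_sign(ds: SessionDataset, neuron_id, window: tuple,
                       baseline_window: tuple | None = None):
    """Preferred numerosity (argmax of window rates, ties toward the
    smaller value) and excited/inhibited label vs fixation baseline."""
    if baseline_window is None:
        baseline_window = (-ds.meta["fixation_ms"], 0.0)
    sess = int(ds.neurons.loc[ds.neurons["neuron_id"] == neuron_id,
                              "session_id"].iloc[0])
    trials = ds.trials[(ds.trials["session_id"] == sess)
                       & (ds.trials["outcome"] == "correct")]
    curve = numerosity_rates(ds, neuron_id, trials, window)
    preferred = int(curve.index[int(np.argmax(curve.to_numpy()))])
    window_mean = mean_rate_in_window(ds, neuron_id,
                                      trials["trial_id"].to_numpy(), window)
    baseline = mean_rate_in_window(ds, neuron_id,
                                   trials["trial_id"].to_numpy(),
                                   baseline_window)
    sign = "excited" if window_mean >= baseline else "inhibited"
    return preferred, sign, curve


def normalize_curve(curve: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; flat curves map to all-zero."""
    curve = np.asarray(curve, dtype=float)
    lo, hi = curve.min(), curve.max()
    if hi - lo <= 0:
        return np.zeros_like(curve)
    return (curve - lo) / (hi - lo)


def population_tuning(curves: pd.DataFrame,
                      values: tuple = (1, 2, 3, 4, 5)) -> dict:
    """Average normalized tuning grouped by preferred value and by distance.

    ``curves`` has one row per neuron with columns ``preferred`` and the
    numerosity values; returns ``{"by_preferred": DataFrame,
    "by_distance": Series}`` where the distance index runs -4..4.
    """
    values = list(values)
    norm = curves.copy()
    norm[values] = np.apply_along_axis(normalize_curve, 1,
                                       curves[values].to_numpy())
    by_pref = norm.groupby("preferred", observed=True)[values].mean()
    dist_sum: dict[int, list] = {}
    for _, row in norm.iterrows():
        for v in values:
            d = int(v - row["preferred"])
            dist_sum.setdefault(d, []).append(row[v])
    by_distance = pd.Series({d: float(np.mean(vals))
                             for d, vals in sorted(dist_sum.items())})
    return {"by_preferred": by_pref, "by_distance": by_distance}


# ---------------------------------------------------------------------------
# Split-half reliability
# ---------------------------------------------------------------------------

def split_half_reliability(ds: SessionDataset, neuron_id, window: tuple,
                           n_perm: int = 10000,
                           rng: np.random.Generator | None = None):
    """Pearson correlation of tuning curves from two balanced trial halves,
    with a label-permutation percentile as the reliability measure.

    Halves are stratified by numerosity x format.  A zero-variance curve
    leaves ``r`` undefined (NaN, flagged).  Returns ``(r, percentile)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    sess = int(ds.neurons.loc[ds.neurons["neuron_id"] == neuron_id,
                              "session_id"].iloc[0])
    trials = ds.trials[(ds.trials["session_id"] == sess)
                       & (ds.trials["outcome"] == "correct")]
    a_ids, b_ids = [], []
    for _, grp in trials.groupby(["numerosity", "format"], observed=True):
        ids = rng.permutation(grp["trial_id"].to_numpy())
        if len(ids) < 4:
            raise ValueError("need >= 2 trials per numerosity per half")
        half = len(ids) // 2
        a_ids.extend(ids[:half])
        b_ids.extend(ids[half:2 * half])
    # one rate per trial in the window, then split by labels
    lookup = trials.set_index("trial_id")["numerosity"]
    rates, numer, half_tag = [], [], []
    for tag, ids in (("a", a_ids), ("b", b_ids)):
        for t in ids:
            rates.append(mean_rate_in_window(ds, neuron_id, [t], window))
            numer.append(int(lookup.loc[t]))
            half_tag.append(tag)
    rates = np.asarray(rates)
    numer = np.asarray(numer)
    half_tag = np.asarray(half_tag)
    vals = np.unique(numer)

    def curves(nlabels):
        ca = [rates[(half_tag == "a") & (nlabels == v)].mean() for v in vals]
        cb = [rates[(half_tag == "b") & (nlabels == v)].mean() for v in vals]
        return np.asarray(ca), np.asarray(cb)

    ca, cb = curves(numer)
    if ca.std() == 0 or cb.std() == 0:
        return np.nan, np.nan
    r = float(stats.pearsonr(ca, cb)[0])
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(numer)
        pa, pb = curves(perm)
        if pa.std() == 0 or pb.std() == 0:
            null[k] = 0.0
        else:
            null[k] = stats.pearsonr(pa, pb)[0]
    percentile = 100.0 * np.mean(null < r)
    return r, percentile


# ---------------------------------------------------------------------------
# Error-trial analysis
# ---------------------------------------------------------------------------

def error_trial_tuning(ds: SessionDataset, selective: pd.DataFrame,
                       min_error_trials: int = 3) -> dict:
    """Correct-vs-error activity at each neuron's preferred numerosity.

    ``selective`` needs columns neuron_id, preferred, window_on, window_off.
    For each neuron with at least ``min_error_trials`` error trials at its
    preferred numerosity, the mean window rate on correct vs error trials
    enters a paired Wilcoxon signed-rank test across neurons.  The
    ``adjacent`` table holds the n-vs-n±1 contrast: error trials where the
    preferred count n was produced instead of instructed n±1, against
    correct n±1 trials (preferred values 2-4 only).
    """
    rows, dropped = [], 0
    for _, nr in selective.iterrows():
        nid, pref = nr["neuron_id"], int(nr["preferred"])
        window = (nr["window_on"], nr["window_off"])
        sess = int(ds.neurons.loc[ds.neurons["neuron_id"] == nid,
                                  "session_id"].iloc[0])
        t = ds.trials[ds.trials["session_id"] == sess]
        at_pref = t[t["numerosity"] == pref]
        cor = at_pref[at_pref["outcome"] == "correct"]
        err = at_pref[at_pref["outcome"] == "error"]
        if len(err) < min_error_trials:
            dropped += 1
            continue
        r_cor = mean_rate_in_window(ds, nid, cor["trial_id"].to_numpy(),
                                    window)
        r_err = mean_rate_in_window(ds, nid, err["trial_id"].to_numpy(),
                                    window)
        rows.append(dict(neuron_id=nid, preferred=pref,
                         rate_correct=r_cor, rate_error=r_err))
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        diffs = table["rate_correct"] - table["rate_error"]
        if np.allclose(diffs, 0):
            w_stat, p = np.nan, 1.0
        else:
            w_stat, p = stats.wilcoxon(table["rate_correct"],
                                       table["rate_error"])
    else:
        w_stat, p = np.nan, np.nan

    adj_rows = []
    for _, nr in selective.iterrows():
        nid, pref = nr["neuron_id"], int(nr["preferred"])
        if pref not in (2, 3, 4):
            continue
        window = (nr["window_on"], nr["window_off"])
        sess = int(ds.neurons.loc[ds.neurons["neuron_id"] == nid,
                                  "session_id"].iloc[0])
        t = ds.trials[ds.trials["session_id"] == sess]
        for delta in (-1, 1):
            instructed = pref + delta
            err_n = t[(t["numerosity"] == instructed)
                      & (t["outcome"] == "error")
                      & (t["produced_count"] == pref)]
            cor_adj = t[(t["numerosity"] == instructed)
                        & (t["outcome"] == "correct")]
            if len(err_n) < min_error_trials or cor_adj.empty:
                continue
            adj_rows.append(dict(
                neuron_id=nid, preferred=pref, delta=delta,
                rate_error_n=mean_rate_in_window(
                    ds, nid, err_n["trial_id"].to_numpy(), window),
                rate_correct_adjacent=mean_rate_in_window(
                    ds, nid, cor_adj["trial_id"].to_numpy(), window)))
    adjacent = pd.DataFrame(adj_rows)
    adj_tests = {}
    for delta in (-1, 1):
        sub = adjacent[adjacent["delta"] == delta] if not adjacent.empty \
            else adjacent
        if len(sub) >= 2 and not np.allclose(
                sub["rate_error_n"] - sub["rate_correct_adjacent"], 0):
            _, ap = stats.wilcoxon(sub["rate_error_n"],
                                   sub["rate_correct_adjacent"])
        else:
            ap = np.nan
        adj_tests[delta] = ap
    return {"table": table, "wilcoxon_stat": w_stat, "p": p,
            "adjacent": adjacent, "adjacent_p": adj_tests,
            "n_dropped": dropped}


# ---------------------------------------------------------------------------
# End-to-end selectivity stage
# ---------------------------------------------------------------------------

def analyze_selectivity(ds: SessionDataset, alpha: float = DEFAULT_ALPHA,
                        min_run: int = DEFAULT_MIN_RUN,
                        width_ms: float = 200.0, step_ms: float = 20.0,
                        typ: int = 2) -> pd.DataFrame:
    """Run the full selectivity stage over all neurons of a dataset.

    Returns one row per neuron: included, selective, window_on/off,
    preferred, sign, category, and the per-numerosity window rates.
    """
    meta = ds.meta
    start = 100.0
    end = meta["instruction_ms"] + meta["planning_ms"] + 100.0
    scheme = BinScheme(start_ms=start, end_ms=end, width_ms=width_ms,
                       step_ms=step_ms)
    rows = []
    for sess, sess_neurons in ds.neurons.groupby("session_id"):
        trials = ds.trials[(ds.trials["session_id"] == sess)
                           & (ds.trials["outcome"] == "correct")]
        trial_ids = trials["trial_id"].to_numpy()
        numer = trials["numerosity"].to_numpy()
        fmt = trials["format"].to_numpy()
        binned = bin_rates(ds, scheme,
                           neuron_ids=sess_neurons["neuron_id"].to_numpy(),
                           trial_ids=trial_ids)
        surf = sliding_anova(binned, numer, fmt, typ=typ)
        for i, nid in enumerate(binned.neuron_ids):
            rec = dict(neuron_id=nid, session_id=sess,
                       included=include_neuron(ds, nid), selective=False,
                       window_on=np.nan, window_off=np.nan,
                       preferred=np.nan, sign="", category="none")
            if rec["included"]:
                win = detect_selective_window(
                    surf.p["number"][i], scheme, rates=binned.rates[i],
                    numerosity=numer, p_format=surf.p["format"][i],
                    p_interaction=surf.p["interaction"][i],
                    alpha=alpha, min_run=min_run)
                rec["category"] = classify_selectivity(
                    surf, i, alpha=alpha, min_run=min_run)
                if win is not None:
                    on, off, _ = win
                    pref, sign, curve = preferred_and_sign(ds, nid, (on, off))
                    rec.update(selective=True, window_on=on, window_off=off,
                               preferred=pref, sign=sign)
                    for v, r in curve.items():
                        rec[f"rate_{v}"] = r
            rows.append(rec)
    return pd.DataFrame(rows)
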