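"""Behavioral performance: percent correct, response functions, chance
level, session exclusion, and above-chance testing.

Percent correct is computed per session as correct / (correct + error);
aborted trials (fixation breaks, premature releases) count toward
neither numerator nor denominator.  The chance level is heuristic but
principled: with responses unconstrained, the reciprocal of the modal
maximum produced count bounds how often guessing hits any one target
(a modal maximum of 8 gives 100/8 = 12.5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class BehaviorSummary:
    """Per-session performance plus per-(numerosity, format) breakdowns."""

    per_session: pd.DataFrame          # session_id, n_correct, n_error, percent_correct
    per_condition: pd.DataFrame        # session_id, numerosity, format, percent_correct
    response_function: pd.DataFrame    # numerosity, format, produced_count, probability
    chance_level: float = 12.5
    included_sessions: list = field(default_factory=list)


def percent_correct(trials: pd.DataFrame,
                    by: list | None = None) -> pd.DataFrame:
    """Percent correct with aborts excluded, optionally per group.

    Raises if any group contains no scored (non-aborted) trial rather
    than silently reporting 0.
    """
    scored = trials[trials["outcome"].isin(["correct", "error"])]
    if by is None:
        by = ["session_id"]
    if scored.empty:
        raise ValueError("no non-aborted trials to score")
    all_groups = trials.groupby(by, observed=True).size()
    out = []
    for key, grp in scored.groupby(by, observed=True):
        n_c = int((grp["outcome"] == "correct").sum())
        n_e = int((grp["outcome"] == "error").sum())
        rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        rec.update(n_correct=n_c, n_error=n_e,
                   percent_correct=100.0 * n_c / (n_c + n_e))
        out.append(rec)
    if len(out) < len(all_groups):
        missing = set(all_groups.index) - {
            tuple(r[k] for k in by) if len(by) > 1 else r[by[0]] for r in out}
        raise ValueError(f"groups with only aborted trials: {sorted(missing)}")
    return pd.DataFrame(out)


def response_functions(trials: pd.DataFrame) -> pd.DataFrame:
    """P(produced = k | instructed = n, format), session-averaged.

    Frequencies are normalized within each (session, numerosity, format)
    cell and then averaged across sessions, so each session contributes
    equally regardless of trial count.  Rows sum to 1 per (numerosity,
    format) up to floating error.
    """
    scored = trials[trials["outcome"].isin(["correct", "error"])].copy()
    if scored.empty:
        raise ValueError("no scored trials")
    scored["produced_count"] = scored["produced_count"].astype(int)
    per_sess = (
        scored.groupby(["session_id", "numerosity", "format",
                        "produced_count"], observed=True)
        .size().rename("n").reset_index())
    totals = per_sess.groupby(["session_id", "numerosity", "format"],
                              observed=True)["n"].transform("sum")
    per_sess["p"] = per_sess["n"] / totals
    out = (per_sess.groupby(["numerosity", "format", "produced_count"],
                            observed=True)["p"].sum().reset_index())
    n_sessions = scored["session_id"].nunique()
    out["probability"] = out["p"] / n_sessions
    return out[["numerosity", "format", "produced_count", "probability"]]


def chance_level(max_count_distribution) -> float:
    """Chance percent from the distribution of unrestricted maximum counts.

    ``max_count_distribution`` is a sequence of per-session maximum
    produced counts; the chance level is ``100 / mode``.  Ties on the
    mode are broken toward the smaller count (conservative: higher
    chance).
    """
    counts = np.asarray(list(max_count_distribution))
    if counts.size == 0:
        raise ValueError("empty count distribution")
    if np.any(counts <= 0):
        raise ValueError("counts must be positive integers")
    values, freq = np.unique(counts, return_counts=True)
    mode = values[np.argmax(freq)]
    return 100.0 / float(mode)


def filter_sessions(per_session: pd.DataFrame,
                    threshold: float = 40.0) -> list:
    """Session ids with overall percent correct >= threshold.

    'Below threshold' is read strictly: a session at exactly 40.0% is
    retained.
    """
    keep = per_session["percent_correct"] >= threshold
    return per_session.loc[keep, "session_id"].tolist()


def test_above_chance(trials: pd.DataFrame, chance: float = 12.5,
                      strata: list | None = None) -> pd.DataFrame:
    """One-sided one-sample t-tests of per-session percent correct vs chance.

    One row per stratum (default numerosity x format x stim_condition x
    arrangement) with t, one-sided p, n_sessions.  Strata with fewer than
    two sessions are flagged (t and p NaN) rather than silently dropped.
    """
    if strata is None:
        strata = ["numerosity", "format", "stim_condition", "arrangement"]
    rows = []
    for key, grp in trials.groupby(strata, observed=True):
        try:
            pc = percent_correct(grp, by=["session_id"])["percent_correct"]
        except ValueError:
            pc = pd.Series(dtype=float)
        rec = dict(zip(strata, key if isinstance(key, tuple) else (key,)))
        rec["n_sessions"] = len(pc)
        if len(pc) < 2:
            rec.update(t=np.nan, p=np.nan, flagged=True)
        else:
            t, p = stats.ttest_1samp(pc, chance, alternative="greater")
            rec.update(t=float(t), p=float(p), flagged=False)
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize_behavior(trials: pd.DataFrame, chance: float = 12.5,
                       exclusion_threshold: float = 40.0) -> BehaviorSummary:
    """End-to-end behavioral summary used by the pipeline stage."""
    per_session = percent_correct(trials, by=["session_id"])
    included = filter_sessions(per_session, exclusion_threshold)
    kept = trials[trials["session_id"].isin(included)]
    per_condition = percent_correct(kept, by=["session_id", "numerosity",
                                              "format"])
    rf = response_functions(kept)
    return BehaviorSummary(per_session=per_session,
                           per_condition=per_condition,
                           response_function=rf,
                           chance_level=chance,
                           included_sessions=included)
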