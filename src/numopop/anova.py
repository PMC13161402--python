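"""Two-factor fixed-effects ANOVA, vectorized across time bins.

Selectivity and explained-variance analyses both run the same 5 x 2
(numerosity x format) ANOVA in every bin of a sliding window.  The trial
labels — and hence the design matrices — are identical across bins, so
the sums of squares for all bins reduce to a handful of projection-matrix
contractions computed once.  Unbalanced cell counts are allowed; sums of
squares are Type II by default (each main effect adjusted for the other,
the interaction adjusted for both), with Type III available.  For
balanced designs the types coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

FACTORS = ("number", "format", "interaction")


@dataclass
class AnovaDecomposition:
    """Per-bin sums of squares, degrees of freedom, F and p values.

    Arrays have one entry per response column (time bin).  ``ss`` maps
    factor name -> SS_TERM; ``df`` maps factor name -> degrees of
    freedom (scalar).  ``ms_error = ss_error / df_error``.
    """

    ss: dict
    df: dict
    ss_error: np.ndarray
    df_error: int
    ss_total: np.ndarray
    f: dict
    p: dict

    @property
    def ms_error(self) -> np.ndarray:
        return self.ss_error / self.df_error


def _effect_columns(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum-to-zero (deviation) coding; returns (columns, level array)."""
    levels, idx = np.unique(labels, return_inverse=True)
    k = len(levels)
    cols = np.zeros((len(labels), k - 1))
    for j in range(k - 1):
        cols[idx == j, j] = 1.0
    cols[idx == k - 1, :] = -1.0
    return cols, levels


def _proj(X: np.ndarray) -> np.ndarray:
    """Orthogonal projection matrix onto the column space of X."""
    Q, R = np.linalg.qr(X)
    rank = np.sum(np.abs(np.diag(R)) > 1e-10 * max(X.shape))
    Q = Q[:, :rank]
    return Q @ Q.T


def two_factor_anova(y: np.ndarray, factor_a: np.ndarray,
                     factor_b: np.ndarray, typ: int = 2) -> AnovaDecomposition:
    """Fixed-effects two-way ANOVA on one or many response columns.

    Parameters
    ----------
    y : (n_obs,) or (n_obs, n_bins) response array.
    factor_a, factor_b : length-n_obs label arrays (numerosity, format).
    typ : 2 (default) or 3; sums-of-squares type for unbalanced cells.

    Every factor needs >= 2 levels and every a x b cell >= 2 observations;
    empty or singleton cells make the per-cell error variance undefined
    and are rejected rather than silently yielding significance.
    """
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    n = y.shape[0]
    if len(factor_a) != n or len(factor_b) != n:
        raise ValueError("label length does not match observations")
    A, lev_a = _effect_columns(factor_a)
    B, lev_b = _effect_columns(factor_b)
    a, b = len(lev_a), len(lev_b)
    if a < 2 or b < 2:
        raise ValueError("each factor needs at least two levels")
    for la in lev_a:
        for lb in lev_b:
            if np.sum((factor_a == la) & (factor_b == lb)) < 2:
                raise ValueError(
                    f"cell ({la!r}, {lb!r}) has fewer than two observations")
    AB = np.einsum("ni,nj->nij", A, B).reshape(n, -1)
    one = np.ones((n, 1))
    P = {
        "a": _proj(np.hstack([one, A])),
        "b": _proj(np.hstack([one, B])),
        "ab": _proj(np.hstack([one, A, B])),
        "full": _proj(np.hstack([one, A, B, AB])),
    }
    if typ == 3:
        P["no_a"] = _proj(np.hstack([one, B, AB]))
        P["no_b"] = _proj(np.hstack([one, A, AB]))
    elif typ != 2:
        raise ValueError("typ must be 2 or 3")

    def rss(key: str) -> np.ndarray:
        resid = y - P[key] @ y
        return np.einsum("nk,nk->k", resid, y)

    rss_full = rss("full")
    rss_ab = rss("ab")
    if typ == 2:
        ss_a = rss("b") - rss_ab
        ss_b = rss("a") - rss_ab
    else:
        ss_a = rss("no_a") - rss_full
        ss_b = rss("no_b") - rss_full
    ss_int = rss_ab - rss_full
    ybar = y.mean(axis=0)
    ss_total = np.einsum("nk,nk->k", y - ybar, y - ybar)
    df = {"number": a - 1, "format": b - 1, "interaction": (a - 1) * (b - 1)}
    df_error = n - a * b
    if df_error <= 0:
        raise ValueError("no error degrees of freedom")
    ms_error = rss_full / df_error
    ss = {"number": np.maximum(ss_a, 0.0), "format": np.maximum(ss_b, 0.0),
          "interaction": np.maximum(ss_int, 0.0)}
    f, p = {}, {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name in FACTORS:
            fval = (ss[name] / df[name]) / ms_error
            fval = np.where(ms_error > 0, fval, np.nan)
            f[name] = fval
            p[name] = stats.f.sf(fval, df[name], df_error)
    if squeeze:
        ss = {k: v[0] for k, v in ss.items()}
        f = {k: float(v[0]) for k, v in f.items()}
        p = {k: float(v[0]) for k, v in p.items()}
        return AnovaDecomposition(ss=ss, df=df, ss_error=rss_full[0],
                                  df_error=df_error, ss_total=ss_total[0],
                                  f=f, p=p)
    return AnovaDecomposition(ss=ss, df=df, ss_error=rss_full,
                              df_error=df_error, ss_total=ss_total, f=f, p=p)
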