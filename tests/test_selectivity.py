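"""Sliding-window ANOVA, selective-window detection, preferred value,
split-half reliability, population tuning, and error-trial contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from numopop import (BinScheme, bin_rates, two_factor_anova,
                     detect_selective_window, include_neuron,
                     population_tuning, preferred_and_sign, sliding_anova,
                     split_half_reliability, error_trial_tuning,
                     analyze_selectivity)
from numopop.selectivity import classify_selectivity, normalize_curve, _runs

from conftest import toy_dataset


# ---------------------------------------------------------------------------
# ANOVA engine
# ---------------------------------------------------------------------------

def _bruteforce_balanced_anova(y, a_lab, b_lab):
    """Textbook sums-of-squares decomposition via explicit group means
    (balanced designs only)."""
    y = np.asarray(y, float)
    A = np.unique(a_lab)
    B = np.unique(b_lab)
    n_cell = len(y) // (len(A) * len(B))
    gm = y.mean()
    ss_a = sum(np.sum(a_lab == a) * (y[a_lab == a].mean() - gm) ** 2
               for a in A)
    ss_b = sum(np.sum(b_lab == b) * (y[b_lab == b].mean() - gm) ** 2
               for b in B)
    ss_cells = sum(
        np.sum((a_lab == a) & (b_lab == b))
        * (y[(a_lab == a) & (b_lab == b)].mean() - gm) ** 2
        for a in A for b in B)
    ss_int = ss_cells - ss_a - ss_b
    ss_tot = np.sum((y - gm) ** 2)
    ss_err = ss_tot - ss_cells
    return dict(number=ss_a, format=ss_b, interaction=ss_int,
                error=ss_err, total=ss_tot)


class TestTwoFactorAnova:
    def test_balanced_matches_bruteforce_sums_of_squares(self):
        rng = np.random.default_rng(0)
        a = np.repeat([1, 2, 3, 4, 5], 8)
        b = np.tile(np.repeat(["dot", "sign"], 4), 5)
        y = rng.normal(10, 3, 40) + a * 0.5
        dec = two_factor_anova(y, a, b)
        ref = _bruteforce_balanced_anova(y, a, b)
        for k in ("number", "format", "interaction"):
            assert dec.ss[k] == pytest.approx(ref[k], abs=1e-10)
        assert dec.ss_error == pytest.approx(ref["error"], abs=1e-10)
        assert dec.ss_total == pytest.approx(ref["total"], abs=1e-10)

    def test_unbalanced_matches_statsmodels_type2(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(1)
        rows = []
        for a in range(1, 6):
            for b in ("dot", "sign"):
                for _ in range(int(rng.integers(3, 9))):
                    rows.append((a, b, rng.normal(5 + a, 2)))
        df = pd.DataFrame(rows, columns=["num", "fmt", "y"])
        dec = two_factor_anova(df["y"], df["num"], df["fmt"])
        fit = ols("y ~ C(num) * C(fmt)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert dec.p["number"] == pytest.approx(
            tab.loc["C(num)", "PR(>F)"], abs=1e-12)
        assert dec.p["format"] == pytest.approx(
            tab.loc["C(fmt)", "PR(>F)"], abs=1e-12)
        assert dec.p["interaction"] == pytest.approx(
            tab.loc["C(num):C(fmt)", "PR(>F)"], abs=1e-12)

    def test_vectorized_equals_columnwise(self):
        rng = np.random.default_rng(2)
        a = np.repeat([1, 2, 3], 6)
        b = np.tile(np.repeat(["x", "y"], 3), 3)
        Y = rng.normal(size=(18, 7))
        dec = two_factor_anova(Y, a, b)
        for j in range(7):
            single = two_factor_anova(Y[:, j], a, b)
            for k in ("number", "format", "interaction"):
                assert dec.p[k][j] == pytest.approx(single.p[k], abs=1e-12)

    def test_rejects_degenerate_layouts(self):
        with pytest.raises(ValueError, match="two levels"):
            two_factor_anova(np.arange(8.0), [1] * 8,
                             ["x", "y"] * 4)
        with pytest.raises(ValueError, match="fewer than two"):
            two_factor_anova(np.arange(8.0), [1, 1, 1, 1, 2, 2, 2, 2],
                             ["x", "y", "x", "y", "x", "x", "x", "y"])

    def test_null_false_positive_rate_near_alpha(self):
        # ~1e4 independent null bins; per-bin FPR should sit near 0.01
        rng = np.random.default_rng(3)
        a = np.repeat([1, 2, 3, 4, 5], 8)
        b = np.tile(np.repeat(["dot", "sign"], 4), 5)
        Y = rng.normal(size=(40, 10_000))
        dec = two_factor_anova(Y, a, b)
        fpr = np.mean(dec.p["number"] < 0.01)
        assert 0.005 < fpr < 0.015


# ---------------------------------------------------------------------------
# Window detection
# ---------------------------------------------------------------------------

SCHEME = BinScheme(start_ms=100, end_ms=1600, width_ms=200, step_ms=20)


class TestWindowDetection:
    def _series(self, sig_idx, n=66):
        p = np.full(n, 0.5)
        p[list(sig_idx)] = 0.001
        return p

    def test_ten_bins_below_criterion(self):
        assert detect_selective_window(
            self._series(range(10)), SCHEME) is None

    def test_eleven_bins_at_boundary(self):
        out = detect_selective_window(self._series(range(5, 16)), SCHEME)
        assert out is not None
        on, off, run = out
        assert run == (5, 15)
        assert on == 100 + 5 * 20
        assert off == 100 + 15 * 20 + 200

    def test_larger_rate_spread_run_selected(self):
        p = self._series(list(range(0, 12)) + list(range(30, 42)))
        n_trials = 50
        rng = np.random.default_rng(4)
        numer = rng.integers(1, 6, n_trials)
        rates = rng.normal(10, 1, (n_trials, 66))
        # plant a big numerosity effect only inside the second run
        rates[:, 30:42] += 5.0 * numer[:, None]
        out = detect_selective_window(p, SCHEME, rates=rates,
                                      numerosity=numer)
        assert out[2] == (30, 41)

    def test_exclusivity_mask_applied(self):
        p_num = self._series(range(20))
        p_fmt = self._series(range(5, 9))      # format significant inside
        out = detect_selective_window(p_num, SCHEME, p_format=p_fmt)
        # bins 5-8 are knocked out, leaving runs 0-4 and 9-19 (11 bins)
        assert out[2] == (9, 19)

    @given(st.lists(st.booleans(), min_size=1, max_size=80))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_run_finder_matches_enumeration(self, mask):
        runs = _runs(np.asarray(mask))
        # brute force: every maximal run of consecutive True indices
        expected = []
        i = 0
        while i < len(mask):
            if mask[i]:
                j = i
                while j + 1 < len(mask) and mask[j + 1]:
                    j += 1
                expected.append((i, j))
                i = j + 1
            else:
                i += 1
        assert runs == expected


# ---------------------------------------------------------------------------
# Inclusion and preferred value
# ---------------------------------------------------------------------------

class TestInclusionAndPreference:
    def _rate_ds(self, hz, duration=2000.0):
        # one neuron, 20 correct trials spanning all conditions,
        # evenly spaced spikes at the requested mean rate
        n_spikes_per_trial = hz * duration / 1000.0
        trials = {}
        for t in range(40):
            k = int(np.floor(n_spikes_per_trial * (t + 1))
                    - np.floor(n_spikes_per_trial * t))
            k = int(round(n_spikes_per_trial)) if hz * 2 == int(hz * 2) \
                else k
            trials[t] = list(np.linspace(-499, 1499, k)) if k else []
        numerосities = [1 + (t // 8) % 5 for t in range(40)]
        ds = toy_dataset(trials, n_trials=40, numerosities=numerосities)
        # make every numerosity x format x stim cell populated 4x
        ds.trials["format"] = ["dot", "sign"] * 20
        ds.trials["stim_condition"] = (["standard"] * 2 + ["control"] * 2) \
            * 10
        return ds

    def test_rate_boundary(self):
        assert not include_neuron(self._rate_ds(0.49), 0,
                                  min_trials_per_condition=1)
        assert include_neuron(self._rate_ds(0.5), 0,
                              min_trials_per_condition=1)

    def test_trial_minimum(self):
        ds = self._rate_ds(5.0)
        assert not include_neuron(ds, 0, min_trials_per_condition=3)
        assert include_neuron(ds, 0, min_trials_per_condition=2)

    def test_bruteforce_verdicts_on_random_dataset(self, small_ds):
        for nid in small_ds.neuron_ids:
            trials = small_ds.trials[small_ds.trials["outcome"] == "correct"]
            counts = trials.groupby(["numerosity", "format",
                                     "stim_condition"]).size()
            s = small_ds.spikes
            sel = (s["neuron_id"] == nid) \
                & (s["time_ms"] >= -500) & (s["time_ms"] < 1500)
            n_sp = int((sel & s["trial_id"].isin(
                trials["trial_id"])).sum())
            rate = n_sp / len(trials) / 2.0
            expected = bool((counts >= 5).all() and len(counts) == 20
                            and rate >= 0.5)
            assert include_neuron(small_ds, nid) == expected

    def test_preferred_is_argmax(self):
        # rates [2,4,9,4,2] Hz by numerosity over a 1 s window
        trials, numerос = {}, []
        hz = {1: 2, 2: 4, 3: 9, 4: 4, 5: 2}
        for t in range(40):
            n = 1 + t % 5
            numerос.append(n)
            trials[t] = list(np.linspace(600, 1599.9, hz[n]))
        ds = toy_dataset(trials, n_trials=40, numerosities=numerос)
        pref, sign, curve = preferred_and_sign(ds, 0, (600, 1600))
        assert pref == 3
        assert curve.loc[3] == pytest.approx(9.0)

    def test_inhibited_when_window_below_baseline(self):
        trials = {}
        for t in range(10):
            # 10 Hz during fixation, ~3 Hz in the window
            trials[t] = list(np.linspace(-499, -1, 5)) \
                + list(np.linspace(600, 1599, 3))
        ds = toy_dataset(trials, n_trials=10,
                         numerosities=[1 + t % 5 for t in range(10)])
        _, sign, _ = preferred_and_sign(ds, 0, (600, 1600))
        assert sign == "inhibited"


# ---------------------------------------------------------------------------
# Tuning curves and reliability
# ---------------------------------------------------------------------------

class TestTuning:
    def test_normalization_idempotent(self):
        rng = np.random.default_rng(5)
        c = rng.uniform(0, 30, 5)
        once = normalize_curve(c)
        assert np.allclose(normalize_curve(once), once)
        assert once.min() == 0.0 and once.max() == 1.0

    def test_single_neuron_population_curve_is_own(self):
        df = pd.DataFrame([{1: 2.0, 2: 4.0, 3: 9.0, 4: 4.0, 5: 2.0,
                            "preferred": 3}])
        out = population_tuning(df)
        np.testing.assert_allclose(out["by_preferred"].loc[3],
                                   normalize_curve([2, 4, 9, 4, 2]))

    def test_flat_neurons_average_flat(self):
        df = pd.DataFrame([{1: 5.0, 2: 5.0, 3: 5.0, 4: 5.0, 5: 5.0,
                            "preferred": 2}] * 3)
        out = population_tuning(df)
        assert np.allclose(out["by_preferred"].loc[2], 0.0)

    def test_distance_curve_peaks_at_zero(self, small_ds, small_truth):
        sel = analyze_selectivity(small_ds)
        sel = sel[sel["selective"]]
        cols = {v: sel[f"rate_{v}"] for v in (1, 2, 3, 4, 5)}
        df = pd.DataFrame({**cols, "preferred": sel["preferred"]})
        out = population_tuning(df)
        d = out["by_distance"]
        assert d.loc[0] == d.max()
        for sign in (1, -1):
            if sign * 1 in d.index and sign * 2 in d.index:
                assert d.loc[0] > d.loc[sign * 1] > d.loc[sign * 2]

    def test_split_half_tuned_neuron_reliable(self, small_ds, small_truth):
        tuned = small_truth.neurons.query("tuned and gain_hz > 15")
        nid = int(tuned["neuron_id"].iloc[0])
        rng = np.random.default_rng(6)
        r, pct = split_half_reliability(small_ds, nid, (600, 1600),
                                        n_perm=300, rng=rng)
        assert r > 0.8
        assert pct > 95

    def test_split_half_untuned_percentile_uniformish(self, small_ds,
                                                      small_truth):
        untuned = small_truth.neurons.query("not tuned and not "
                                            "format_coupled")
        nid = int(untuned["neuron_id"].iloc[0])
        rng = np.random.default_rng(7)
        pcts = [split_half_reliability(small_ds, nid, (600, 1600),
                                       n_perm=100, rng=rng)[1]
                for _ in range(30)]
        assert 25 < np.mean(pcts) < 75


# ---------------------------------------------------------------------------
# Full stage on synthetic ground truth
# ---------------------------------------------------------------------------

class TestSelectivityStage:
    def test_tuned_neurons_significant_inside_truth_window(
            self, small_ds, small_truth):
        sess_trials = small_ds.trials[small_ds.trials["outcome"]
                                      == "correct"]
        scheme = BinScheme(start_ms=100, end_ms=1600)
        strong = small_truth.neurons.query(
            "tuned and gain_hz > 15 and code_type == 'static'")
        binned = bin_rates(small_ds, scheme,
                           neuron_ids=strong["neuron_id"].to_numpy(),
                           trial_ids=sess_trials["trial_id"].to_numpy())
        surf = sliding_anova(binned, sess_trials["numerosity"].to_numpy(),
                             sess_trials["format"].to_numpy())
        for i, (_, nr) in enumerate(strong.iterrows()):
            starts = scheme.bin_starts
            inside = (starts >= nr["window_onset_ms"] + 50) \
                & (starts + 200 <= nr["window_offset_ms"])
            frac_sig = np.mean(surf.p["number"][i, inside] < 0.01)
            assert frac_sig > 0.9

    def test_recovers_ground_truth_preferences(self, small_ds, small_truth):
        sel = analyze_selectivity(small_ds)
        merged = sel.merge(small_truth.neurons, on="neuron_id")
        tuned = merged[merged["tuned"]]
        hit = (tuned.loc[tuned["selective"], "preferred"]
               == tuned.loc[tuned["selective"], "preferred_value"])
        assert hit.mean() >= 0.9
        untuned = merged[~merged["tuned"] & ~merged["format_coupled"]]
        assert untuned["selective"].mean() <= 0.2

    def test_classification_categories(self):
        # synthetic p surfaces exercising each category
        class FakeRes:
            def __init__(self, pn, pf, pi):
                self.p = {"number": pn[None], "format": pf[None],
                          "interaction": pi[None]}
        n = 30
        flat = np.full(n, 0.5)
        sig = np.full(n, 0.001)
        assert classify_selectivity(FakeRes(sig, flat, flat), 0) \
            == "exclusively_number"
        assert classify_selectivity(FakeRes(sig, sig, flat), 0) == "format"
        assert classify_selectivity(FakeRes(flat, flat, sig), 0) \
            == "interaction"
        assert classify_selectivity(FakeRes(flat, flat, flat), 0) == "none"


# ---------------------------------------------------------------------------
# Error-trial analysis
# ---------------------------------------------------------------------------

class TestErrorTrials:
    def test_identical_rates_give_p_one(self):
        # same spike pattern on correct and error trials
        trials, outcomes, numerос = {}, [], []
        for t in range(60):
            trials[t] = list(np.linspace(600, 1599, 10))
            numerос.append(1 + t % 5)
            outcomes.append("correct" if t < 40 else "error")
        ds = toy_dataset(trials, n_trials=60, numerosities=numerос,
                         outcomes=outcomes)
        sel = pd.DataFrame([{"neuron_id": 0, "preferred": 3,
                             "window_on": 600.0, "window_off": 1600.0}])
        # a single neuron cannot carry a population test; duplicate it
        sel = pd.concat([sel] * 3, ignore_index=True)
        out = error_trial_tuning(ds, sel)
        assert out["p"] == 1.0

    def test_signed_rank_matches_bruteforce(self):
        # hand-built 5-neuron paired table vs explicit rank computation
        correct = np.array([14.0, 12.0, 9.0, 16.0, 11.0])
        error = np.array([11.0, 10.5, 9.5, 12.0, 8.0])
        from scipy import stats
        w_impl = stats.wilcoxon(correct, error)[0]
        d = correct - error
        ranks = stats.rankdata(np.abs(d))
        w_pos = ranks[d > 0].sum()
        w_neg = ranks[d < 0].sum()
        assert w_impl == min(w_pos, w_neg)

    def test_produced_drive_reduces_preferred_activity(self, decoding_ds,
                                                       decoding_experiment):
        truth = decoding_experiment[1]
        sel = analyze_selectivity(decoding_ds)
        sel = sel[sel["selective"]].rename(columns={})
        table = pd.DataFrame({
            "neuron_id": sel["neuron_id"],
            "preferred": sel["preferred"],
            "window_on": sel["window_on"],
            "window_off": sel["window_off"]})
        out = error_trial_tuning(decoding_ds, table, min_error_trials=3)
        t = out["table"]
        assert len(t) >= 3
        assert (t["rate_error"] < t["rate_correct"]).mean() > 0.7
        assert out["p"] < 0.05
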