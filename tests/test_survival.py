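"""Survival machinery: KM, log-rank, Cox, ROC/DeLong, cutoffs, kappa."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from petdmax.survival import (
    binary_agreement_kappa,
    cox_ph,
    cox_score_test,
    delong_compare,
    event_by_horizon,
    km_estimate,
    logrank_test,
    maxstat_cutoff,
    optimal_cutoff,
    roc_auc,
    sens_spec,
    youden_cutoff,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def hand_km(time, event):
    """Product-limit by explicit summation over distinct event times."""
    time, event = np.asarray(time, float), np.asarray(event, int)
    s = 1.0
    out = {}
    for t in np.unique(time[event == 1]):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / n
        out[t] = s
    return out

def hand_logrank(time_a, event_a, time_b, event_b):
    """Direct O-E / V summation over pooled distinct event times."""
    time = np.concatenate([time_a, time_b]).astype(float)
    event = np.concatenate([event_a, event_b]).astype(int)
    group = np.concatenate([np.zeros(len(time_a)), np.ones(len(time_b))])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, stats.chi2.sf(chi2, 1)

def hand_partial_loglik(beta, time, event, x):
    """Explicit Cox partial log-likelihood (no ties)."""
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll

def pair_counting_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

class TestKM:
    def test_no_events_flat_at_one(self):
        km = km_estimate([5, 8, 12], [0, 0, 0])
        assert km.at(100.0) == 1.0

    def test_all_events_no_censoring(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(2) == pytest.approx(1 / 3)
        assert km.at(3) == pytest.approx(0.0)

    def test_censored_middle_record(self):
        # times {1, 2+, 3}: S(1)=2/3; at t=3 one at risk, one event -> S=0
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(3) == pytest.approx(0.0)

    def test_matches_hand_product_limit(self, rng):
        time = rng.exponential(20, 40).round(1) + 0.1
        event = rng.integers(0, 2, 40)
        if event.sum() == 0:
            event[0] = 1
        km = km_estimate(time, event)
        for t, s in hand_km(time, event).items():
            assert km.at(t) == pytest.approx(s, abs=1e-12)

    def test_zero_censoring_equals_empirical_survival(self, rng):
        time = rng.exponential(10, 60)
        event = np.ones(60, dtype=int)
        km = km_estimate(time, event)
        for t in np.quantile(time, [0.2, 0.5, 0.9]):
            assert km.at(t) == pytest.approx((time > t).mean(), abs=1e-12)

    def test_ci_brackets_estimate(self, rng):
        time = rng.exponential(20, 50)
        event = rng.integers(0, 2, 50)
        event[:5] = 1
        km = km_estimate(time, event)
        assert np.all(km.ci_lower <= km.survival + 1e-12)
        assert np.all(km.ci_upper >= km.survival - 1e-12)

    def test_non_increasing(self, rng):
        time = rng.exponential(20, 50)
        event = rng.integers(0, 2, 50)
        event[0] = 1
        km = km_estimate(time, event)
        assert np.all(np.diff(km.survival) <= 1e-12)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.array([1, 0, 1, 1, 0])
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_summation_oracle(self, rng):
        # non-overlapping event times, strong separation, n = 20
        ta = rng.uniform(1, 10, 10).round(2)
        tb = rng.uniform(20, 30, 10).round(2)
        ea = np.ones(10, dtype=int)
        eb = np.ones(10, dtype=int)
        chi2, p = logrank_test(ta, ea, tb, eb)
        chi2_ref, p_ref = hand_logrank(ta, ea, tb, eb)
        assert chi2 == pytest.approx(chi2_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_matches_lifelines_with_censoring_and_ties(self, rng):
        ta = rng.integers(1, 15, 30).astype(float)
        tb = rng.integers(1, 20, 25).astype(float)
        ea = rng.integers(0, 2, 30)
        eb = rng.integers(0, 2, 25)
        ea[0] = eb[0] = 1
        from lifelines.statistics import logrank_test as ll_logrank

        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        chi2, p = logrank_test(ta, ea, tb, eb)
        assert chi2 == pytest.approx(float(ref.test_statistic), abs=1e-9)
        assert p == pytest.approx(float(ref.p_value), abs=1e-9)

    def test_symmetric_in_group_labels(self, rng):
        ta, tb = rng.exponential(10, 15), rng.exponential(20, 12)
        ea, eb = np.ones(15, int), np.ones(12, int)
        chi2_ab, _ = logrank_test(ta, ea, tb, eb)
        chi2_ba, _ = logrank_test(tb, eb, ta, ea)
        assert chi2_ab == pytest.approx(chi2_ba, abs=1e-9)

    def test_no_events_anywhere_gives_p_one(self):
        chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert (chi2, p) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [1])


# ---------------------------------------------------------------------------
# Cox PH
# ---------------------------------------------------------------------------

class TestCox:
    def test_identical_groups_null_effect(self):
        t = [1, 2, 3, 4, 5, 6, 7, 8.0]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        df = pd.DataFrame({"time": t + t, "event": e + e, "x": [0] * 8 + [1] * 8})
        fit = cox_ph(df, "time", "event", ["x"])
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-6)
        assert fit.ci_lower[0] < fit.hr[0] < fit.ci_upper[0]

    def test_beta_matches_partial_likelihood_grid(self, rng):
        """12 records, no ties: beta-hat maximizes the explicitly summed
        partial likelihood (grid + golden-section refinement oracle)."""
        time = np.array([1.3, 2.1, 3.4, 4.2, 5.9, 6.1, 7.7, 8.2, 9.9, 11.4, 12.8, 14.1])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1, 1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 0], dtype=float)
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        fit = cox_ph(df, "time", "event", ["x"], ties="breslow")
        grid = np.linspace(-3, 3, 20001)
        ll = [hand_partial_loglik(b, time, event, x) for b in grid]
        beta_ref = grid[int(np.argmax(ll))]
        assert fit.coef[0] == pytest.approx(beta_ref, abs=1e-3)
        # beta-hat is a stationary point of the oracle likelihood
        h = 1e-4
        deriv = (
            hand_partial_loglik(fit.coef[0] + h, time, event, x)
            - hand_partial_loglik(fit.coef[0] - h, time, event, x)
        ) / (2 * h)
        assert deriv == pytest.approx(0.0, abs=1e-4)

    def test_efron_equals_breslow_without_ties(self, rng):
        time = rng.exponential(10, 30) + rng.uniform(0, 1e-3, 30)  # tie-free
        x = rng.integers(0, 2, 30).astype(float)
        event = np.ones(30, int)
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        f1 = cox_ph(df, "time", "event", ["x"], ties="efron")
        f2 = cox_ph(df, "time", "event", ["x"], ties="breslow")
        assert f1.coef[0] == pytest.approx(f2.coef[0], abs=1e-8)

    def test_score_test_at_zero_equals_logrank_on_tie_free_data(self, rng):
        time = np.sort(rng.exponential(10, 40)) + np.arange(40) * 1e-6
        event = rng.integers(0, 2, 40)
        event[:10] = 1
        x = rng.integers(0, 2, 40).astype(float)
        if x.sum() in (0, len(x)):
            x[0] = 1 - x[0]
        chi2_score, _ = cox_score_test(time, event, x)
        chi2_lr, _ = logrank_test(
            time[x == 0], event[x == 0], time[x == 1], event[x == 1]
        )
        assert chi2_score == pytest.approx(chi2_lr, abs=1e-6)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0, 1]})
        with pytest.raises(ValueError, match="no events"):
            cox_ph(df, "time", "event", ["x"])

    def test_complete_separation_flagged(self):
        # x=1 patients all fail first: monotone likelihood
        df = pd.DataFrame(
            {
                "time": [1, 2, 3, 4, 10, 11, 12, 13.0],
                "event": [1, 1, 1, 1, 1, 1, 1, 1],
                "x": [1, 1, 1, 1, 0, 0, 0, 0.0],
            }
        )
        with pytest.warns(UserWarning, match="converge"):
            fit = cox_ph(df, "time", "event", ["x"])
        assert not fit.converged


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------

class TestAUC:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        r = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_exhaustive_pair_counting_examples(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == pytest.approx(1.0)
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == pytest.approx(0.75)

    def test_equals_mann_whitney_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 40))
            scores = rng.integers(0, 10, n).astype(float)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels).auc == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        s = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:5], labels[-5:] = 1, 0
        _, p = delong_compare(s, s, labels)
        assert p == 1.0

    def test_null_p_values_are_uniform(self):
        """Equal-AUC paired scorers: p ~ U(0,1) across replicates (KS test)."""
        ps = []
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = 120
            labels = np.r_[np.ones(60, int), np.zeros(60, int)]
            base = rng.normal(size=n) + labels * 0.8
            a = base + rng.normal(scale=0.8, size=n)
            b = base + rng.normal(scale=0.8, size=n)
            _, p = delong_compare(a, b, labels)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_perfect_vs_random_scorer(self):
        rng = np.random.default_rng(7)
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        perfect = labels + rng.normal(scale=0.01, size=200)
        random_scores = rng.normal(size=200)
        _, p = delong_compare(perfect, random_scores, labels)
        assert p < 0.001


# ---------------------------------------------------------------------------
# Cutoffs / agreement / Se-Sp
# ---------------------------------------------------------------------------

class TestCutoffs:
    def test_youden_perfect_split(self):
        scores = np.arange(1.0, 11.0)
        events = (scores >= 7).astype(int)
        c = youden_cutoff(scores, events)
        assert 6.0 < c <= 7.0

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            youden_cutoff(np.ones(20), np.r_[np.ones(10, int), np.zeros(10, int)])
        with pytest.raises(ValueError, match="degenerate"):
            maxstat_cutoff(np.ones(20), np.arange(20.0) + 1, np.ones(20, int))

    def test_maxstat_recovers_change_point(self):
        """Hazard doubles above the score change-point c: recovered cutoff
        within one decile of c in >= 80% of replicates."""
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 25
        for _ in range(n_rep):
            n = 200
            scores = rng.uniform(0, 1, n)
            c_true = 0.6
            rate = np.where(scores > c_true, 0.10, 0.02)
            t = rng.exponential(1 / rate)
            cens = rng.uniform(0, 40, n)
            time = np.minimum(t, cens)
            event = (t <= cens).astype(int)
            res = maxstat_cutoff(scores, time, event)
            if abs(res.cutoff - c_true) <= 0.1:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_maxstat_naive_p_is_anticonservative_and_permutation_corrects(self):
        """On null data the minimum-p selection inflates type I error; the
        permutation p-value does not reject."""
        rng = np.random.default_rng(5)
        naive = []
        for _ in range(40):
            n = 80
            scores = rng.uniform(0, 1, n)
            t = rng.exponential(10, n)
            cens = rng.uniform(0, 30, n)
            time, event = np.minimum(t, cens), (t <= cens).astype(int)
            res = maxstat_cutoff(scores, time, event)
            naive.append(res.naive_p)
        assert np.mean(np.array(naive) < 0.05) > 0.05  # inflated beyond nominal
        res = maxstat_cutoff(
            scores, time, event, n_permutations=200, rng=np.random.default_rng(0)
        )
        assert res.perm_p > res.naive_p

    def test_optimal_cutoff_needs_ten_records(self):
        with pytest.raises(ValueError, match="10"):
            optimal_cutoff([1, 2, 3], [1, 2, 3], [1, 0, 1], method="youden")


class TestKappa:
    def test_identical_vectors(self):
        a = np.array([0, 1, 1, 0, 1])
        assert binary_agreement_kappa(a, a) == 1.0

    def test_independence_table(self):
        a = np.r_[np.ones(50, int), np.zeros(50, int)]
        b = np.r_[np.ones(25, int), np.zeros(25, int), np.ones(25, int), np.zeros(25, int)]
        assert binary_agreement_kappa(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_calculation_45_5_5_45(self):
        # p_o = 0.9, p_e = 0.5 -> kappa = 0.8
        a = np.r_[np.ones(50, int), np.zeros(50, int)]
        b = np.r_[np.ones(45, int), np.zeros(5, int), np.ones(5, int), np.zeros(45, int)]
        assert binary_agreement_kappa(a, b) == pytest.approx(0.8, abs=1e-12)


class TestSensSpec:
    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 8, 9, 10.0])
        events = np.array([0, 0, 0, 1, 1, 1])
        assert sens_spec(scores, 5.0, events) == (1.0, 1.0)

    def test_cutoff_above_all_scores(self):
        scores = np.array([1, 2, 3, 4.0])
        events = np.array([0, 1, 0, 1])
        assert sens_spec(scores, 10.0, events) == (0.0, 1.0)

    def test_eight_patient_toy_table(self):
        # direct enumeration: events at scores {6,7,9}, non-events {1,2,3,5,8}
        scores = np.array([1, 2, 3, 5, 6, 7, 8, 9.0])
        events = np.array([0, 0, 0, 0, 1, 1, 0, 1])
        se, sp = sens_spec(scores, 5.5, events)
        assert se == pytest.approx(3 / 3)
        assert sp == pytest.approx(4 / 5)
        se, sp = sens_spec(scores, 6.5, events)
        assert se == pytest.approx(2 / 3)
        assert sp == pytest.approx(4 / 5)


def test_event_by_horizon():
    time = np.array([10.0, 50.0, 30.0, 60.0])
    event = np.array([1, 1, 0, 0])
    np.testing.assert_array_equal(event_by_horizon(time, event, 48.0), [1, 0, 0, 0])
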