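import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cadscore.diagnostics import (
    binary_metrics,
    categorical_nri,
    compare_auc_paired,
    continuous_nri,
    idi,
    liu_cutpoint,
    metrics_at_threshold,
    roc_auc,
)
from cadscore.errors import ParameterError
from cadscore.reference_tables import (
    RECLASSIFICATION_EVENTS,
    RECLASSIFICATION_NONEVENTS,
    expand_crosstab,
)


# ---------------------------------------------------------------- oracles

def auc_pair_count_oracle(scores, labels):
    """Exhaustive concordant-pair count with 1/2 credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def liu_oracle(scores, labels):
    """Exhaustive threshold search over adjacent-score midpoints."""
    uniq = sorted(set(scores))
    if len(uniq) < 2:
        return float(uniq[0])
    best_thr, best = None, -1.0
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    for a, b in zip(uniq, uniq[1:]):
        thr = (a + b) / 2
        sens = sum(1 for s, l in zip(scores, labels) if l == 1 and s > thr) / n_pos
        spec = sum(1 for s, l in zip(scores, labels) if l == 0 and s <= thr) / n_neg
        if sens * spec > best + 1e-12:
            best, best_thr = sens * spec, thr
    return best_thr


small_dataset = st.lists(
    st.tuples(st.integers(0, 5), st.integers(0, 1)), min_size=2, max_size=12
).filter(lambda rows: len({l for _, l in rows}) == 2)


# ---------------------------------------------------------------- ROC / AUC

class TestROC:
    def test_worked_example(self):
        assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1]).auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert roc_auc([2, 2, 2, 2], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(small_dataset)
    def test_matches_pair_count_oracle(self, rows):
        scores = [s for s, _ in rows]
        labels = [l for _, l in rows]
        assert roc_auc(scores, labels).auc == pytest.approx(
            auc_pair_count_oracle(scores, labels), abs=1e-12)

    def test_ci_brackets_estimate(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 80), rng.normal(1, 1, 40)])
        labels = np.array([0] * 80 + [1] * 40)
        r = roc_auc(scores, labels)
        assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestPairedComparison:
    def test_identical_scores_p_one(self, rng):
        s = rng.normal(size=50)
        y = (rng.random(50) < 0.4).astype(int)
        y[0], y[1] = 0, 1
        assert compare_auc_paired(s, s.copy(), y) == 1.0

    def test_swap_symmetric(self, rng):
        a = rng.normal(size=100)
        y = np.array([0, 1] * 50)
        b = a + y * 0.5 + rng.normal(0, 0.3, 100)
        assert compare_auc_paired(a, b, y) == pytest.approx(
            compare_auc_paired(b, a, y), abs=1e-12)

    def test_power_against_uninformative_competitor(self, rng):
        # 1-SD effect vs pure noise at n = 400: p < 0.01 nearly always
        hits = 0
        n_sim = 30
        for _ in range(n_sim):
            y = np.array([0] * 200 + [1] * 200)
            informative = rng.standard_normal(400) + y * 1.0
            noise = rng.standard_normal(400)
            if compare_auc_paired(informative, noise, y) < 0.01:
                hits += 1
        assert hits / n_sim >= 0.90


# ---------------------------------------------------------------- Liu cut-point

class TestLiuCutpoint:
    def test_separable_midpoint(self):
        assert liu_cutpoint([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(2.5)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(small_dataset)
    def test_matches_exhaustive_oracle(self, rows):
        scores = [float(s) for s, _ in rows]
        labels = [l for _, l in rows]
        assert liu_cutpoint(scores, labels) == pytest.approx(
            liu_oracle(scores, labels))

    def test_label_inversion_symmetric_optimum(self, rng):
        # inverting the labels and the positivity direction leaves the
        # achievable sensitivity x specificity product unchanged
        scores = np.round(rng.normal(size=20), 1)
        labels = np.array([0, 1] * 10)
        uniq = np.unique(scores)
        mids = (uniq[:-1] + uniq[1:]) / 2

        def best_product(labs, positive_high):
            best = 0.0
            for t in mids:
                pos = scores > t if positive_high else scores <= t
                sens = (pos & (labs == 1)).sum() / (labs == 1).sum()
                spec = (~pos & (labs == 0)).sum() / (labs == 0).sum()
                best = max(best, sens * spec)
            return best

        assert best_product(labels, True) == pytest.approx(
            best_product(1 - labels, False), abs=1e-12)

    def test_youden_alternative(self):
        scores = [1, 2, 3, 4, 5, 6]
        labels = [0, 0, 0, 1, 1, 1]
        assert liu_cutpoint(scores, labels, method="youden") == pytest.approx(3.5)


# ---------------------------------------------------------------- binary metrics

class TestBinaryMetrics:
    def test_reference_npv(self):
        # negative = score <= 20: 62 + 12 healthy and 6 diseased below the cut
        m = binary_metrics(tp=57, fp=91, tn=74, fn=6)
        assert m.npv == pytest.approx(74 / 80)

    def test_reference_ppv(self):
        # high score (> 30): 37 diseased of 85 positives
        m = binary_metrics(tp=37, fp=48, tn=117, fn=26)
        assert m.ppv == pytest.approx(37 / 85)

    def test_perfect_classifier(self):
        m = binary_metrics(tp=10, fp=0, tn=10, fn=0)
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_identities_exact_rationals(self, tp, fp, tn, fn):
        if tp + fn == 0 or tn + fp == 0:
            with pytest.raises(ParameterError):
                binary_metrics(tp, fp, tn, fn)
            return
        m = binary_metrics(tp, fp, tn, fn)
        assert m.sensitivity == float(Fraction(tp, tp + fn))
        assert m.specificity == float(Fraction(tn, tn + fp))
        if tp + fp:
            assert m.ppv == float(Fraction(tp, tp + fp))
        if tn + fn:
            assert m.npv == float(Fraction(tn, tn + fn))
        if m.specificity not in (1.0,):
            assert m.plr == pytest.approx(m.sensitivity / (1 - m.specificity))
        if m.specificity != 0.0:
            assert m.nlr == pytest.approx((1 - m.sensitivity) / m.specificity)

    def test_wilson_ci_contains_point(self):
        m = binary_metrics(tp=74, fp=0, tn=1, fn=6, with_ci=True)
        lo, hi = m.sensitivity_ci
        assert lo <= m.sensitivity <= hi


# ---------------------------------------------------------------- NRI / IDI

class TestCategoricalNRI:
    def test_reference_crosstab(self):
        old, new, ev = expand_crosstab(RECLASSIFICATION_EVENTS, RECLASSIFICATION_NONEVENTS)
        res = categorical_nri(old, new, ev)
        assert res.up_events == 18 and res.down_events == 6
        assert res.up_nonevents == 36 and res.down_nonevents == 55
        assert res.event_component == pytest.approx(12 / 63)
        assert res.nonevent_component == pytest.approx(19 / 165)
        assert res.nri == pytest.approx(12 / 63 + 19 / 165)

    def test_identity_reclassification_zero(self):
        cats = np.array([0, 1, 2, 3] * 10)
        ev = np.array([0, 1] * 20)
        assert categorical_nri(cats, cats.copy(), ev).nri == 0.0

    def test_maximal_value_two(self):
        old = np.array([1] * 10 + [2] * 10)
        new = np.array([2] * 10 + [1] * 10)
        ev = np.array([1] * 10 + [0] * 10)
        assert categorical_nri(old, new, ev).nri == pytest.approx(2.0)


class TestContinuousNRI:
    def test_identity_zero(self):
        p = np.array([0.2, 0.4, 0.6, 0.8])
        ev = np.array([0, 1, 0, 1])
        assert continuous_nri(p, p.copy(), ev).nri == 0.0

    def test_maximal_two(self):
        p = np.array([0.3] * 20)
        ev = np.array([1] * 10 + [0] * 10)
        p_new = p + np.where(ev == 1, 0.01, -0.01)
        assert continuous_nri(p, p_new, ev).nri == pytest.approx(2.0)

    def test_positive_for_informative_added_predictor(self, rng):
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            n = 300
            x1 = rng.standard_normal(n)
            x2 = rng.standard_normal(n)
            eta = x1 + x2
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            p_old = 1 / (1 + np.exp(-x1))
            p_new = 1 / (1 + np.exp(-eta))
            if continuous_nri(p_old, p_new, y).nri > 0:
                hits += 1
        assert hits / n_sim >= 0.95


class TestIDI:
    def test_identity_zero(self):
        p = np.array([0.2, 0.4, 0.6, 0.8])
        ev = np.array([0, 1, 0, 1])
        assert idi(p, p.copy(), ev).idi == 0.0

    def test_two_point_arithmetic(self):
        p_old = np.array([0.2, 0.3])
        p_new = np.array([0.4, 0.2])
        ev = np.array([1, 0])
        assert idi(p_old, p_new, ev).idi == pytest.approx(0.3)

    def test_shift_invariance(self, rng):
        n = 50
        p_old = rng.random(n) * 0.5
        p_new = p_old + rng.normal(0, 0.05, n)
        ev = (rng.random(n) < 0.4).astype(int)
        ev[:2] = [0, 1]
        base = idi(p_old, p_new, ev).idi
        shifted = idi(p_old + 0.1, p_new + 0.1, ev).idi
        assert shifted == pytest.approx(base, abs=1e-12)
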