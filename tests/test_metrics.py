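"""Confusion-matrix metrics and agreement statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungsound.metrics import (
    ClassMetrics,
    ConfusionMatrix3,
    accuracy,
    chi_square,
    class_metrics,
    cohens_kappa,
    confusion,
    evaluation_report,
    f1_score,
    kendalls_w,
    macro_mean,
    round1,
)

CLASSES = ("crackle", "wheeze", "normal")


def labels_series(pairs):
    return pd.Series({f"r{i}": lab for i, lab in enumerate(pairs)})


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        gs = labels_series(["crackle"] * 10 + ["wheeze"] * 20 + ["normal"] * 30)
        cm = confusion(gs, gs)
        assert np.array_equal(cm.counts, np.diag([10, 20, 30]))

    def test_swapped_classes_move_off_diagonal(self):
        gs = labels_series(["crackle"] * 10 + ["wheeze"] * 20 + ["normal"] * 30)
        swap = gs.map({"crackle": "wheeze", "wheeze": "crackle", "normal": "normal"})
        cm = confusion(gs, swap)
        assert cm.counts[0, 0] == cm.counts[1, 1] == 0
        assert cm.counts[0, 1] == 10 and cm.counts[1, 0] == 20

    def test_random_fixture_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        gs = labels_series(rng.choice(CLASSES, 100))
        pred = labels_series(rng.choice(CLASSES, 100))
        cm = confusion(gs, pred)
        assert cm.total == 100
        for i, gi in enumerate(CLASSES):
            for j, pj in enumerate(CLASSES):
                brute = sum((gs[k] == gi) and (pred[k] == pj) for k in gs.index)
                assert cm.counts[i, j] == brute

    def test_id_mismatch_reported(self):
        gs = pd.Series({"a": "normal", "b": "crackle"})
        pred = pd.Series({"a": "normal", "c": "crackle"})
        with pytest.raises(ValueError, match="c"):
            confusion(gs, pred)


class TestClassMetrics:
    def test_one_vs_rest_identity(self):
        cm = ConfusionMatrix3([[50, 5, 10], [4, 60, 6], [8, 12, 80]])
        for cls in CLASSES:
            c = CLASSES.index(cls)
            tp = cm.counts[c, c]
            fn = cm.counts[c].sum() - tp
            fp = cm.counts[:, c].sum() - tp
            tn = cm.total - tp - fn - fp
            assert tp + fn + fp + tn == cm.total
            m = class_metrics(cm, cls)
            assert m.sensitivity == pytest.approx(100 * tp / (tp + fn))
            assert m.specificity == pytest.approx(100 * tn / (tn + fp))

    def test_zero_row_undefined(self):
        cm = ConfusionMatrix3([[0, 0, 0], [0, 10, 0], [0, 0, 10]])
        m = class_metrics(cm, "crackle")
        assert m.sensitivity is None
        assert m.f1 is None

    @given(st.floats(0.1, 100), st.floats(0.1, 100))
    def test_f1_between_min_and_max(self, s, p):
        f1 = f1_score(s, p)
        assert min(s, p) - 1e-9 <= f1 <= max(s, p) + 1e-9
        assert f1_score(s, s) == pytest.approx(s)

    def test_reported_f1_rounding(self):
        assert round1(f1_score(100.0, 46.2)) == 63.2


class TestMacroAndAccuracy:
    def test_macro_mean_over_adventitious_classes(self):
        c = ClassMetrics(81.1, 80.6, 94.1, 80.9)
        w = ClassMetrics(86.4, 76.0, 83.0, 80.9)
        m = macro_mean(c, w)
        assert round1(m.sensitivity) == 83.8
        assert round1(m.specificity) == 88.6

    def test_identical_inputs_fixed_point(self):
        x = ClassMetrics(50.0, 60.0, 70.0, 54.5)
        assert macro_mean(x, x) == x

    def test_undefined_propagates(self):
        x = ClassMetrics(None, 60.0, 70.0, None)
        y = ClassMetrics(50.0, 60.0, 70.0, 54.5)
        m = macro_mean(x, y)
        assert m.sensitivity is None and m.precision == 60.0

    def test_accuracy_perfect_and_uniform(self):
        assert accuracy(ConfusionMatrix3(np.diag([10, 20, 30]))) == 100.0
        assert round1(accuracy(ConfusionMatrix3(np.ones((3, 3))))) == 33.3

    def test_accuracy_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix3(np.zeros((3, 3))))


class TestCohensKappa:
    def test_identical_tables_kappa_one(self):
        gs = labels_series(["crackle"] * 5 + ["wheeze"] * 5 + ["normal"] * 5)
        res = cohens_kappa(gs, gs)
        assert res.kappa == pytest.approx(1.0)

    def test_independence_table_kappa_zero(self):
        # 2x2 contingency [[10,10],[10,10]] realized as paired labels
        a = labels_series(["crackle"] * 20 + ["wheeze"] * 20)
        b = labels_series((["crackle"] * 10 + ["wheeze"] * 10) * 2)
        res = cohens_kappa(a, b)
        assert res.kappa == pytest.approx(0.0)
        assert res.ci_low < 0 < res.ci_high

    def test_matches_hand_po_pe_oracle(self):
        """Unweighted kappa on a fixed 60-item fixture equals the direct
        po/pe computation to 1e-10."""
        rng = np.random.default_rng(42)
        a = labels_series(rng.choice(CLASSES, 60, p=[0.3, 0.3, 0.4]))
        b = a.copy()
        flip = rng.random(60) < 0.35
        b[flip] = rng.choice(CLASSES, flip.sum())
        res = cohens_kappa(a, b)
        n = 60
        po = np.mean(a.values == b.values)
        pe = sum((np.mean(a.values == c)) * (np.mean(b.values == c)) for c in CLASSES)
        expected = (po - pe) / (1 - pe)
        assert res.kappa == pytest.approx(expected, abs=1e-10)
        # CI is kappa +/- 1.96 SE, hence symmetric about kappa
        assert res.ci_low < res.kappa < res.ci_high
        assert (res.kappa - res.ci_low) == pytest.approx(res.ci_high - res.kappa, abs=1e-6)

    def test_quadratic_weighting_matches_hand_oracle(self):
        rng = np.random.default_rng(3)
        a = labels_series(rng.choice(CLASSES, 80))
        b = labels_series(rng.choice(CLASSES, 80))
        res = cohens_kappa(a, b, weighting="quadratic")
        k = len(CLASSES)
        idx = {c: i for i, c in enumerate(CLASSES)}
        w = 1 - (np.subtract.outer(np.arange(k), np.arange(k)) / (k - 1)) ** 2
        table = np.zeros((k, k))
        for x, y in zip(a.values, b.values):
            table[idx[x], idx[y]] += 1
        p = table / table.sum()
        po = (w * p).sum()
        pe = (w * np.outer(p.sum(1), p.sum(0))).sum()
        assert res.kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-10)

    def test_constant_equal_raters_undefined(self):
        a = labels_series(["normal"] * 10)
        res = cohens_kappa(a, a)
        assert res.kappa is None

    def test_unknown_weighting_rejected(self):
        a = labels_series(["crackle", "wheeze"])
        with pytest.raises(ValueError):
            cohens_kappa(a, a, weighting="cubic")


class TestKendallsW:
    def test_identical_rankings_w_one(self):
        ratings = pd.DataFrame([[1, 2, 3, 4]] * 3)
        assert kendalls_w(ratings) == pytest.approx(1.0)

    def test_reversed_rankings_match_hand_formula(self):
        """2 raters, exactly reversed rankings of 3 distinct subjects:
        rank sums are all equal, so S = 0 and W = 0."""
        ratings = pd.DataFrame([[1, 2, 3], [3, 2, 1]])
        m, n = 2, 3
        rank_sums = np.array([4, 4, 4])
        s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
        expected = 12 * s / (m**2 * (n**3 - n))
        assert kendalls_w(ratings) == pytest.approx(expected) == 0.0

    def test_tie_correction_hand_example(self):
        """3 raters, 4 subjects with ties: compare against the 12S formula
        with T = sum(t^3 - t) computed by hand."""
        ratings = pd.DataFrame([
            [1.0, 2.0, 3.0, 4.0],
            [1.0, 1.0, 3.0, 4.0],   # tie on the first two -> mid-ranks 1.5
            [2.0, 1.0, 3.0, 4.0],
        ])
        ranks = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [1.5, 1.5, 3.0, 4.0],
            [2.0, 1.0, 3.0, 4.0],
        ])
        rank_sums = ranks.sum(0)
        s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
        t = (2**3 - 2)  # one group of 2 tied values in rater 2
        m, n = 3, 4
        expected = 12 * s / (m**2 * (n**3 - n) - m * t)
        assert kendalls_w(ratings) == pytest.approx(expected, abs=1e-12)

    def test_label_embedding_and_subject_permutation_invariance(self):
        ratings = pd.DataFrame([
            ["normal", "crackle", "wheeze", "crackle"],
            ["normal", "wheeze", "wheeze", "crackle"],
        ])
        w1 = kendalls_w(ratings)
        w2 = kendalls_w(ratings[[2, 0, 3, 1]])
        assert w1 == pytest.approx(w2)
        assert 0.0 <= w1 <= 1.0

    def test_zero_variance_undefined(self):
        assert kendalls_w(pd.DataFrame([[1, 1, 1], [1, 1, 1]])) is None

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            kendalls_w(pd.DataFrame([[1, 2, 3]]))


class TestChiSquare:
    def test_independence_exact_table(self):
        # outer product of margins: observed == expected everywhere
        table = np.outer([10, 20], [3, 7]) / 10.0
        stat, dof, p = chi_square(table)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        stat, dof, p = chi_square([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3, abs=1e-9)  # sum (O-E)^2/E, E=15
        assert dof == 1

    @pytest.mark.parametrize("k", [2, 5])
    def test_scaling_counts_scales_statistic(self, k):
        base = np.array([[20, 10], [10, 20]])
        s1, _, _ = chi_square(base)
        s2, _, _ = chi_square(k * base)
        assert s2 == pytest.approx(k * s1)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [10, 20]])


class TestEvaluationReport:
    def test_report_tree_structure(self):
        rng = np.random.default_rng(1)
        gs = labels_series(rng.choice(CLASSES, 50))
        pred = labels_series(rng.choice(CLASSES, 50))
        rep = evaluation_report(gs, pred)
        assert rep["n"] == 50
        assert set(rep["per_class"]) == set(CLASSES)
        assert rep["kappa"]["weighting"] == "none"
        total = np.sum(rep["confusion_matrix"])
        assert total == 50

    def test_round1_half_up(self):
        assert round1(83.75) == 83.8
        assert round1(88.55) == 88.6
        assert round1(80.849) == 80.8
        assert round1(None) is None
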