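"""Label mappings and the evaluation suite against independent oracles."""

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import matthews_corrcoef

from protlm.metrics import (
    ConfusionMatrix,
    binary_mcc_and_fpr,
    bootstrap_se,
    confusion_matrix,
    disorder_from_coordinates,
    gorodkin_mcc,
    map_dssp8_to_3,
    map_ss8_string,
    mcc_macro_per_protein,
    q_accuracy,
    se_over_proteins,
)


class TestDsspMapping:
    @pytest.mark.parametrize(
        "eight,three",
        [("G", "H"), ("H", "H"), ("I", "H"),
         ("B", "E"), ("E", "E"),
         ("T", "O"), ("S", "O"), ("C", "O"), ("-", "O")],
    )
    def test_convention(self, eight, three):
        assert map_dssp8_to_3(eight) == three

    def test_total_on_alphabet_and_idempotent_through_ss3(self):
        ss8 = "HGIEBTSC-"
        ss3 = map_ss8_string(ss8)
        assert set(ss3) <= set("HEO")
        # H and E survive a second application; O is not an 8-state letter
        for ch in ss3:
            if ch in "HE":
                assert map_dssp8_to_3(ch) == ch

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            map_dssp8_to_3("Q")


class TestDisorder:
    def test_all_coordinates_present_means_ordered(self):
        assert disorder_from_coordinates([True] * 6).sum() == 0

    def test_missing_coordinates_are_disordered(self):
        mask = [False] * 5 + [True] * 5
        assert disorder_from_coordinates(mask)[:5].all()

    def test_labels_are_negation_of_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = rng.random(50) > 0.5
            assert np.array_equal(disorder_from_coordinates(mask), ~mask)


class TestQAccuracy:
    def test_perfect_prediction_scores_100(self):
        assert q_accuracy(["HHH"], ["HHH"]).value == 100.0

    def test_macro_average_of_50_and_100_is_75(self):
        r = q_accuracy(["HE", "HH"], ["HH", "HH"])
        assert r.value == 75.0
        assert list(r.per_protein) == [50.0, 100.0]

    def test_matches_brute_force_recount_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        states = np.array(list("HEO"))
        pred, true = [], []
        for _ in range(20):
            n = int(rng.integers(5, 60))
            pred.append("".join(rng.choice(states, n)))
            true.append("".join(rng.choice(states, n)))
        got = q_accuracy(pred, true)
        # position-by-position recount
        per = []
        for p, t in zip(pred, true):
            per.append(100.0 * sum(a == b for a, b in zip(p, t)) / len(p))
        assert got.value == pytest.approx(np.mean(per))

    def test_protein_with_no_valid_residue_is_excluded_and_counted(self):
        valid = [np.array([True, True]), np.array([False, False])]
        r = q_accuracy(["HE", "HE"], ["HE", "OO"], valid=valid)
        assert r.value == 100.0 and r.n_excluded == 1

    def test_macro_bounded_by_extremes_and_permutation_invariant(self):
        pred, true = ["HE", "HH", "EO"], ["HH", "HH", "EO"]
        r = q_accuracy(pred, true)
        assert r.per_protein.min() <= r.value <= r.per_protein.max()
        r2 = q_accuracy(pred[::-1], true[::-1])
        assert r2.value == r.value


class TestBinaryMcc:
    def test_perfect_and_inverted(self):
        t = [0, 1, 0, 1, 1]
        assert binary_mcc_and_fpr(t, t).mcc == pytest.approx(1.0)
        assert binary_mcc_and_fpr(t, t).fpr == 0.0
        inv = [1 - x for x in t]
        assert binary_mcc_and_fpr(inv, t).mcc == pytest.approx(-1.0)

    def test_hand_computed_contingency_table(self):
        # TP=4, FP=1, TN=3, FN=2
        true = [1] * 4 + [0] * 1 + [0] * 3 + [1] * 2
        pred = [1] * 4 + [1] * 1 + [0] * 3 + [0] * 2
        s = binary_mcc_and_fpr(pred, true)
        expected = (4 * 3 - 1 * 2) / np.sqrt((4 + 1) * (4 + 2) * (3 + 1) * (3 + 2))
        assert s.mcc == pytest.approx(expected)
        assert s.fpr == pytest.approx(1 / 4)

    def test_degenerate_marginal_flagged_as_zero(self):
        s = binary_mcc_and_fpr([1, 1, 1], [1, 1, 0])
        assert s.mcc == 0.0 and s.degenerate


class TestGorodkin:
    def test_diagonal_matrix_scores_one(self):
        cm = ConfusionMatrix(np.diag([5, 3, 7]), ("a", "b", "c"))
        assert gorodkin_mcc(cm) == pytest.approx(1.0)

    def test_reduces_to_binary_mcc_on_1000_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            counts = rng.integers(0, 30, size=(2, 2))
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(counts, ("0", "1"))
            true = [0] * counts[0].sum() + [1] * counts[1].sum()
            pred = (
                [0] * counts[0, 0] + [1] * counts[0, 1]
                + [0] * counts[1, 0] + [1] * counts[1, 1]
            )
            assert gorodkin_mcc(cm) == pytest.approx(
                binary_mcc_and_fpr(pred, true).mcc, abs=1e-12
            )

    def test_agrees_with_sklearn_multiclass_mcc(self):
        rng = np.random.default_rng(3)
        true = rng.integers(0, 6, size=500)
        pred = np.where(rng.random(500) < 0.6, true, rng.integers(0, 6, size=500))
        classes = [str(i) for i in range(6)]
        cm = confusion_matrix([str(x) for x in true], [str(x) for x in pred],
                              classes)
        assert gorodkin_mcc(cm) == pytest.approx(
            matthews_corrcoef(true, pred), abs=1e-12
        )

    def test_independent_predictions_score_near_zero(self):
        rng = np.random.default_rng(4)
        n = 100_000
        true = rng.integers(0, 10, size=n)
        pred = rng.integers(0, 10, size=n)
        classes = [str(i) for i in range(10)]
        cm = confusion_matrix([str(x) for x in true], [str(x) for x in pred],
                              classes)
        assert abs(gorodkin_mcc(cm)) < 0.01

    def test_degenerate_single_class_returns_zero(self):
        cm = ConfusionMatrix(np.array([[10, 0], [0, 0]]), ("a", "b"))
        assert gorodkin_mcc(cm) == 0.0


class TestBootstrap:
    def test_constant_scores_have_zero_se(self):
        assert bootstrap_se([50.0] * 10, seed=0) == 0.0

    def test_two_point_scores_match_closed_form(self):
        # resample means of {0,100}: 0/50/100 w.p. 1/4,1/2,1/4 -> SD = sqrt(1250)
        se = bootstrap_se([0.0, 100.0], n_boot=20000, seed=1)
        assert se == pytest.approx(np.sqrt(1250.0), rel=0.02)

    def test_same_seed_is_deterministic(self):
        scores = list(np.random.default_rng(5).random(30))
        assert bootstrap_se(scores, seed=7) == bootstrap_se(scores, seed=7)

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_se([1.0])

    def test_se_over_proteins_is_sd_over_sqrt_n(self):
        scores = np.array([10.0, 20.0, 60.0, 30.0])
        assert se_over_proteins(scores) == pytest.approx(
            scores.std(ddof=1) / 2.0
        )


class TestConfusion:
    def test_marginals_equal_label_counts(self):
        rng = np.random.default_rng(6)
        classes = list("abcd")
        true = rng.choice(classes, 300)
        pred = rng.choice(classes, 300)
        cm = confusion_matrix(true, pred, classes)
        assert cm.total == 300
        for i, c in enumerate(classes):
            assert cm.counts[i].sum() == (true == c).sum()
            assert cm.counts[:, i].sum() == (pred == c).sum()
        sk = sk_confusion(true, pred, labels=classes)
        assert np.array_equal(cm.counts, sk)

    def test_macro_mcc_excludes_single_class_proteins(self):
        pred = [[1, 0, 1], [1, 1, 1]]
        true = [[1, 0, 1], [1, 1, 1]]  # second protein has one true class
        value, dist, n_excl = mcc_macro_per_protein(pred, true)
        assert value == pytest.approx(1.0)
        assert n_excl == 1 and len(dist) == 1
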