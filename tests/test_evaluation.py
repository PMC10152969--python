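import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tcrbench.core import records_to_frame
from tcrbench.evaluation import (
    balance,
    baseline_constant,
    baseline_kmer_nn,
    baseline_memory,
    baseline_peptide_frequency,
    crossval_evaluate,
    dataset_balance,
    external_scores,
    pr_auc,
    roc_auc,
)
from conftest import rec


# ------------------------------------------------------------------
# independent metric oracles
# ------------------------------------------------------------------

def roc_auc_bruteforce(scores, labels):
    """P(s+ > s-) + 0.5 P(s+ == s-) over all positive-negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def average_precision_by_enumeration(scores, labels):
    """AP as the sum over descending-score thresholds of precision
    times the recall increment (ties grouped)."""
    order = np.argsort(np.asarray(scores))[::-1]
    y = np.asarray(labels)[order]
    s = np.asarray(scores)[order]
    n_pos = y.sum()
    ap, tp, fp, prev_recall = 0.0, 0, 0, 0.0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += int((1 - y[i:j]).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += precision * (recall - prev_recall)
        prev_recall = recall
        i = j
    return ap


class TestBalance:
    def test_uniform_counts_give_one(self):
        assert balance([10, 10, 10, 10]).balance == pytest.approx(1.0)

    def test_two_class_nine_to_one(self):
        # closed form: -(0.9 ln 0.9 + 0.1 ln 0.1) / ln 2
        assert balance([9, 1]).balance == pytest.approx(0.4690, abs=5e-5)

    def test_monotone_toward_uniformity(self):
        assert balance([10, 10, 10, 10]).balance > balance([37, 1, 1, 1]).balance

    def test_single_peptide_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            rep = balance([42])
        assert rep.balance == 1.0 and rep.k == 1

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            balance([])
        with pytest.raises(ValueError):
            balance([3, 0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=500),
                    min_size=2, max_size=12),
           st.integers(min_value=1, max_value=7),
           st.randoms(use_true_random=False))
    def test_scale_and_permutation_invariance(self, counts, m, rnd):
        b = balance(counts).balance
        assert 0.0 <= b <= 1.0
        assert balance([c * m for c in counts]).balance == pytest.approx(b)
        shuffled = list(counts)
        rnd.shuffle(shuffled)
        assert balance(shuffled).balance == pytest.approx(b)
        assert sum(balance(counts).fractions) == pytest.approx(1.0, abs=1e-9)

    def test_accepts_mapping(self, make_dataset):
        ds = make_dataset([rec(peptide="NLVPMVATV"), rec(peptide="GILGFVFTL"),
                           rec(peptide="GILGFVFTL", cdr3_beta="CASSIRSSYEQYF")])
        rep = dataset_balance(ds)
        assert rep.k == 2
        assert rep.balance == pytest.approx(
            balance([2, 1]).balance)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_bruteforce_exhaustively_small(self):
        grid = [0.0, 0.5, 1.0]
        for n in range(2, 5):
            for labels in itertools.product([0, 1], repeat=n):
                if len(set(labels)) < 2:
                    continue
                for scores in itertools.product(grid, repeat=n):
                    expected = roc_auc_bruteforce(scores, labels)
                    assert roc_auc(scores, labels) == pytest.approx(
                        expected, abs=1e-12)

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_matches_bruteforce_tie_rich(self, n):
        rng = np.random.default_rng(n)
        for labels in itertools.product([0, 1], repeat=n):
            if len(set(labels)) < 2:
                continue
            scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
            assert roc_auc(scores, list(labels)) == pytest.approx(
                roc_auc_bruteforce(scores, labels), abs=1e-12)

    def test_complement_under_score_negation(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)  # ties almost surely absent
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            1.0 - roc_auc(-scores, labels), abs=1e-12)


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_equal_prevalence(self):
        labels = [1, 1, 0, 0, 0, 0, 0, 0]
        assert pr_auc([0.3] * 8, labels) == pytest.approx(0.25)

    def test_six_item_hand_computed(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        labels = [1, 0, 1, 1, 0, 0]
        # thresholds: P at the three positives = 1/1, 2/3, 3/4
        assert pr_auc(scores, labels) == pytest.approx(29 / 36, abs=1e-12)

    def test_no_positive_errors(self):
        with pytest.raises(ValueError):
            pr_auc([0.4, 0.6], [0, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0] = 1
        assert pr_auc(scores, labels) == pytest.approx(
            average_precision_by_enumeration(scores, labels), abs=1e-12)


# ------------------------------------------------------------------
# predictors
# ------------------------------------------------------------------

def labeled_table(rows):
    """rows: (cdr3_beta, peptide, label, fold)."""
    frame = records_to_frame(
        [rec(cdr3_beta=t, peptide=p, label=y) for t, p, y, _ in rows])
    frame["fold"] = [f for *_, f in rows]
    return frame


class TestBaselines:
    def test_kmer_nn_identical_binder_scores_one(self):
        train = labeled_table([
            ("CASSLAPGATNEKLFF", "NLVPMVATV", 1, 0),
            ("CASSIRSSYEQYF", "NLVPMVATV", 1, 0),
            ("CASSIRSSYEQYF", "GILGFVFTL", 0, 0),
        ])
        m = baseline_kmer_nn()
        m.fit(train)
        q = labeled_table([("CASSLAPGATNEKLFF", "NLVPMVATV", 1, 0)])
        assert m.predict(q)[0] == 1.0

    def test_kmer_nn_disjoint_kmers_score_zero(self):
        train = labeled_table([("CASSLAPGF", "NLVPMVATV", 1, 0),
                               ("CAWWYYWWF", "GILGFVFTL", 1, 0)])
        m = baseline_kmer_nn()
        m.fit(train)
        q = labeled_table([("WYWYWYWYWY", "NLVPMVATV", 1, 0)])
        assert m.predict(q)[0] == 0.0

    def test_kmer_nn_unseen_peptide_scores_half(self):
        train = labeled_table([("CASSLAPGF", "NLVPMVATV", 1, 0)])
        m = baseline_kmer_nn()
        m.fit(train)
        q = labeled_table([("CASSLAPGF", "ELAGIGILTV", 1, 0)])
        assert m.predict(q)[0] == 0.5

    def test_peptide_frequency_constant_on_uniform_training(self):
        train = labeled_table(
            [(f"CASS{c}APGF", p, 1, 0)
             for c, p in zip("ACDE", ["NLVPMVATV"] * 2 + ["GILGFVFTL"] * 2)])
        m = baseline_peptide_frequency()
        m.fit(train)
        scores = m.predict(train)
        assert len(set(scores)) == 1

    def test_memory_scores_training_pairs_only(self):
        train = labeled_table([("CASSLAPGF", "NLVPMVATV", 1, 0)])
        m = baseline_memory()
        m.fit(train)
        q = labeled_table([("CASSLAPGF", "NLVPMVATV", 1, 0),
                           ("CASSLAPGF", "GILGFVFTL", 0, 0)])
        assert list(m.predict(q)) == [1.0, 0.0]

    def test_external_scores_reads_column(self):
        q = labeled_table([("CASSLAPGF", "NLVPMVATV", 1, 0)])
        q["score"] = [0.73]
        m = external_scores()
        m.fit(q)
        assert m.predict(q)[0] == 0.73
        del q["score"]
        with pytest.raises(ValueError):
            m.predict(q)

    def test_constant_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            baseline_constant(1.5)


class TestCrossvalEvaluate:
    def two_fold_memory_toy(self):
        # the pair (T1, p1) recurs as a positive in both folds; the
        # memory predictor thus scores it 1.0 in each test fold while
        # every other test row scores 0.0.
        return labeled_table([
            ("CASSLAPGAF", "NLVPMVATV", 1, 0),
            ("CASSWGQDTF", "GILGFVFTL", 1, 0),
            ("CASSLAPGAF", "GILGFVFTL", 0, 0),
            ("CASSWGQDTF", "NLVPMVATV", 0, 0),
            ("CASSLAPGAF", "NLVPMVATV", 1, 1),
            ("CASSYNEQFF", "GILGFVFTL", 1, 1),
            ("CASSLAPGAF", "GILGFVFTL", 0, 1),
            ("CASSYNEQFF", "NLVPMVATV", 0, 1),
        ])

    def test_memory_predictor_hand_traced(self):
        result = crossval_evaluate(self.two_fold_memory_toy(),
                                   baseline_memory, k=2)
        # per fold: scores (1, 0, 0, 0) for labels (1, 1, 0, 0):
        # pairs won 2 of 4, ties 2 of 4 -> AUC 0.75
        assert list(result.per_fold["roc_auc"]) == pytest.approx([0.75, 0.75])
        assert result.summary["roc_auc_mean"] == pytest.approx(0.75)

    def test_constant_predictor_baselines(self):
        table = self.two_fold_memory_toy()
        result = crossval_evaluate(table, baseline_constant, k=2)
        assert result.summary["roc_auc_mean"] == pytest.approx(0.5)
        # 0.5 >= threshold: everything predicted positive
        assert result.summary["accuracy_mean"] == pytest.approx(0.5)

    def test_per_peptide_table_structure(self):
        result = crossval_evaluate(self.two_fold_memory_toy(),
                                   baseline_memory, k=2)
        pp = result.per_peptide
        assert set(pp.columns) >= {"peptide", "n_test", "accuracy",
                                   "train_occurrence"}
        assert pp["n_test"].sum() == 8
        assert ((pp["accuracy"] >= 0) & (pp["accuracy"] <= 1)).all()

    def test_wrong_fold_count_rejected(self):
        with pytest.raises(ValueError):
            crossval_evaluate(self.two_fold_memory_toy(), baseline_memory, k=5)

    def test_missing_column_rejected(self):
        table = self.two_fold_memory_toy().drop(columns=["fold"])
        with pytest.raises(ValueError, match="fold"):
            crossval_evaluate(table, baseline_memory)

    def test_predictor_failure_names_fold(self):
        class Broken:
            def fit(self, train):
                raise RuntimeError("boom")

            def predict(self, records):
                return np.zeros(len(records))

        with pytest.raises(RuntimeError, match="fold 0"):
            crossval_evaluate(self.two_fold_memory_toy(), Broken, k=2)
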