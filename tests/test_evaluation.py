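import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from cpirex.evaluation import (
    ContingencyTable2x2,
    ScoredPair,
    auc,
    baseline_cooccurrence,
    chi_squared_independence,
    combine_and,
    cross_validate,
    document_folds,
    evaluate_pooled,
    matched_precision_threshold,
    metrics,
    nested_cv,
    report_from_predictions,
    round_half_up,
    stratify_by_verb,
    verb_label_table,
)
from cpirex.sl_kernel import SLParams
from cpirex.synthetic import SyntheticConfig, generate_corpus


class TestMetrics:
    def test_perfect_classification(self):
        report = metrics(tp=1, fp=0, tn=1, fn=0)
        assert report.recall == report.specificity == report.precision == 100.0
        assert report.f1 == 100.0

    def test_all_positive_on_benchmark_counts(self):
        report = metrics(tp=2931, fp=2631, tn=0, fn=0)
        rounded = report.rounded()
        assert rounded["precision"] == 52.7
        assert rounded["f1"] == 69.0
        assert rounded["recall"] == 100.0
        assert rounded["specificity"] == 0.0
        assert report.precision == report.accuracy  # no negatives predicted

    def test_balanced_counts(self):
        report = metrics(tp=50, fp=50, tn=50, fn=50)
        assert report.recall == report.precision == report.f1 == 50.0

    def test_undefined_ratios_are_none(self):
        assert metrics(tp=0, fp=0, tn=3, fn=2).precision is None
        assert metrics(tp=0, fp=1, tn=3, fn=0).recall is None

    @given(
        st.integers(0, 500), st.integers(0, 500),
        st.integers(0, 500), st.integers(0, 500),
    )
    @settings(max_examples=50, derandomize=True)
    def test_count_conservation(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        report = metrics(tp, fp, tn, fn)
        assert report.total == tp + fp + tn + fn


@pytest.mark.parametrize(
    "n_pos,n_neg,precision,f1",
    [(2931, 2631, 52.7, 69.0), (1598, 1269, 55.7, 71.6),
     (1333, 1362, 49.5, 66.2), (1, 1, 50.0, 66.7)],
)
def test_cooccurrence_baseline(n_pos, n_neg, precision, f1):
    report = baseline_cooccurrence(n_pos, n_neg)
    rounded = report.rounded()
    assert rounded["recall"] == 100.0
    assert rounded["specificity"] == 0.0
    assert rounded["precision"] == precision
    assert rounded["f1"] == f1


def test_round_half_up():
    assert round_half_up(52.65) == 52.7
    assert round_half_up(52.649) == 52.6


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 1, -1, -1], [0.9, 0.8, 0.2, 0.1]) == 100.0

    def test_all_ties(self):
        assert auc([1, -1, 1], [0.5, 0.5, 0.5]) == 50.0

    def test_hand_enumerated_example(self):
        assert auc([1, 1, -1, -1], [0.9, 0.4, 0.6, 0.1]) == 75.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.1, 0.2])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        labels = rng.choice([-1, 1], n)
        labels[:2] = [1, -1]
        scores = np.round(rng.standard_normal(n), 1)  # force some ties
        wins = total = 0.0
        for (li, si), (lj, sj) in itertools.product(
            zip(labels, scores), repeat=2
        ):
            if li > 0 and lj < 0:
                total += 1
                wins += 1.0 if si > sj else (0.5 if si == sj else 0.0)
        assert auc(labels, scores) == pytest.approx(100.0 * wins / total, abs=1e-12)


class TestDocumentFolds:
    def test_one_document_per_fold(self):
        corpus = generate_corpus(SyntheticConfig(n_docs=10, seed=0))
        split = document_folds(corpus, 10, seed=1)
        counts = [0] * 10
        for fold in split.assignment.values():
            counts[fold] += 1
        assert counts == [1] * 10

    def test_deterministic_for_fixed_seed(self):
        corpus = generate_corpus(SyntheticConfig(n_docs=25, seed=0))
        a = document_folds(corpus, 10, seed=7)
        b = document_folds(corpus, 10, seed=7)
        assert a == b
        c = document_folds(corpus, 10, seed=8)
        assert c != a

    def test_round_robin_balance(self):
        corpus = generate_corpus(SyntheticConfig(n_docs=25, seed=0))
        split = document_folds(corpus, 10, seed=3)
        sizes = [0] * 10
        for fold in split.assignment.values():
            sizes[fold] += 1
        assert set(sizes) <= {2, 3}
        assert max(sizes) - min(sizes) <= 1

    def test_too_few_documents_rejected(self):
        corpus = generate_corpus(SyntheticConfig(n_docs=3, seed=0))
        with pytest.raises(ValueError):
            document_folds(corpus, 5, seed=0)


class TestCrossValidate:
    def test_each_document_scored_by_the_other(self):
        corpus = generate_corpus(
            SyntheticConfig(n_docs=6, sentences_per_doc=3, seed=1)
        )
        split = document_folds(corpus, 2, seed=0)
        scored = cross_validate(corpus, "sl", SLParams(1, 1), split=split)
        assert all(s.score is not None for s in scored)

    def test_test_folds_partition_all_pairs(self):
        corpus = generate_corpus(SyntheticConfig(n_docs=20, seed=4))
        split = document_folds(corpus, 5, seed=2)
        scored = cross_validate(corpus, "sl", SLParams(1, 1), split=split)
        all_ids = [p.pair_id for _, _, p in corpus.iter_pairs()]
        assert sorted(s.pair_id for s in scored) == sorted(all_ids)
        assert len({s.pair_id for s in scored}) == len(all_ids)

def test_unknown_labels_rejected():
    corpus = generate_corpus(SyntheticConfig(n_docs=4, seed=1))
    import dataclasses

    sent = corpus.documents[0].sentences[0]
    from cpirex.corpus import PairLabel

    sent.pairs[0] = dataclasses.replace(sent.pairs[0], label=PairLabel.UNKNOWN)
    split = document_folds(corpus, 2, seed=0)
    with pytest.raises(ValueError, match="unknown"):
        cross_validate(corpus, "sl", SLParams(1, 1), split=split)


class TestNestedCV:
    def test_singleton_grid_equals_plain_cv(self):
        corpus = generate_corpus(SyntheticConfig(n_docs=12, seed=6))
        split = document_folds(corpus, 3, seed=1)
        plain = cross_validate(corpus, "sl", SLParams(2, 1), split=split)
        nested, chosen = nested_cv(corpus, "sl", [SLParams(2, 1)], split)
        assert {s.pair_id: s.score for s in plain} == {
            s.pair_id: s.score for s in nested
        }
        assert set(chosen.values()) == {SLParams(2, 1)}

    def test_chosen_params_recorded_for_every_fold(self):
        corpus = generate_corpus(SyntheticConfig(n_docs=12, seed=6))
        split = document_folds(corpus, 3, seed=1)
        _, chosen = nested_cv(
            corpus, "sl", [SLParams(1, 1), SLParams(1, 2)], split
        )
        assert sorted(chosen) == [0, 1, 2]
        assert all(c in {SLParams(1, 1), SLParams(1, 2)} for c in chosen.values())

    def test_empty_grid_rejected(self):
        corpus = generate_corpus(SyntheticConfig(n_docs=6, seed=6))
        split = document_folds(corpus, 3, seed=1)
        with pytest.raises(ValueError):
            nested_cv(corpus, "sl", [], split)


def _scored(label, score, verb, pid):
    return ScoredPair(
        pair_id=pid, doc_id="d", label=label, score=score, fold=0,
        encloses_verb=verb,
    )


class TestStratifyByVerb:
    def test_all_verb_pairs_means_no_niv_report(self):
        scored = [_scored(1, 0.5, True, "a"), _scored(-1, -0.5, True, "b")]
        iv, niv = stratify_by_verb(scored)
        assert niv is None
        overall = evaluate_pooled(scored)
        assert (iv.tp, iv.fp, iv.tn, iv.fn) == (
            overall.tp, overall.fp, overall.tn, overall.fn
        )

    def test_subset_counts_conserved(self):
        scored = [
            _scored(1, 0.5, True, "a"), _scored(-1, 0.3, False, "b"),
            _scored(1, -0.1, False, "c"), _scored(-1, -0.9, True, "d"),
        ]
        iv, niv = stratify_by_verb(scored)
        assert iv.total + niv.total == 4


class TestChiSquared:
    def test_perfect_independence(self):
        stat, p = chi_squared_independence(ContingencyTable2x2(5, 5, 5, 5))
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        stat, _ = chi_squared_independence(ContingencyTable2x2(10, 0, 0, 10))
        assert stat == pytest.approx(20.0)

    def test_transposition_invariance(self):
        t1 = ContingencyTable2x2(12, 5, 3, 9)
        t2 = ContingencyTable2x2(12, 3, 5, 9)  # transposed table
        assert chi_squared_independence(t1)[0] == pytest.approx(
            chi_squared_independence(t2)[0]
        )

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_independence(ContingencyTable2x2(0, 0, 5, 5))

    @pytest.mark.parametrize("cells", [(12, 5, 3, 9), (100, 40, 60, 80), (1, 2, 3, 4)])
    def test_matches_scipy_contingency(self, cells):
        stat, p = chi_squared_independence(ContingencyTable2x2(*cells))
        a, b, c, d = cells
        expected = chi2_contingency([[a, b], [c, d]], correction=False)
        assert stat == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)


class TestCombineAnd:
    def test_truth_table(self):
        assert combine_and([1, 1, -1, -1], [1, -1, 1, -1]).tolist() == [
            1, -1, -1, -1
        ]

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            combine_and([1], [1, -1])

    @given(st.lists(st.tuples(st.sampled_from([-1, 1]), st.sampled_from([-1, 1]),
                              st.sampled_from([-1, 1])),
                    min_size=4, max_size=30))
    @settings(max_examples=60, derandomize=True)
    def test_recall_and_specificity_bounds(self, rows):
        truth = [r[0] for r in rows]
        preds_a = [r[1] for r in rows]
        preds_b = [r[2] for r in rows]
        if len(set(truth)) < 2:
            return
        combined = combine_and(preds_a, preds_b)
        rep_a = report_from_predictions(truth, preds_a)
        rep_b = report_from_predictions(truth, preds_b)
        rep_c = report_from_predictions(truth, combined)
        assert rep_c.recall <= min(rep_a.recall, rep_b.recall) + 1e-9
        assert rep_c.specificity >= max(rep_a.specificity, rep_b.specificity) - 1e-9


class TestMatchedPrecisionThreshold:
    def test_hand_scanned_example(self):
        scores = [0.9, 0.8, 0.7]
        labels = [1, -1, 1]
        t = matched_precision_threshold(scores, labels, 100.0)
        assert 0.8 < t < 0.9
        preds = np.where(np.asarray(scores) > t, 1, -1)
        rep = report_from_predictions(labels, preds)
        assert rep.precision == 100.0
        assert rep.recall == 50.0

    def test_target_zero_takes_everything(self):
        t = matched_precision_threshold([0.3, -0.2], [1, -1], 0.0)
        assert t == -math.inf

    def test_tie_prefers_largest_prediction_count(self):
        # all-positive precision is exactly 50: -inf must be chosen
        t = matched_precision_threshold([0.9, 0.1], [1, -1], 50.0)
        assert t == -math.inf

    def test_unreachable_target_returns_infinity(self):
        t = matched_precision_threshold([0.5, 0.5], [-1, 1], 100.0)
        assert t == math.inf


def test_verb_label_table_counts():
    scored = [
        _scored(1, 0.1, True, "a"), _scored(1, 0.1, False, "b"),
        _scored(-1, 0.1, True, "c"), _scored(-1, 0.1, False, "d"),
        _scored(1, 0.1, True, "e"),
    ]
    table = verb_label_table(scored)
    assert (table.a, table.b, table.c, table.d) == (2, 1, 1, 1)
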