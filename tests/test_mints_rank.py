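"""Rank conversion, aggregation, redundancy-filtered selection.

The aggregate ordering is validated against a brute-force
reimplementation (explicit sort-based average ranks) on random feature
matrices, and the greedy selection against a literal simulation of the
skip rule.
"""

import numpy as np
import pytest

import mintsum as ms
from mintsum.corpus_io import RawDocument
from mintsum.features import FEATURE_NAMES, HIGHER_IS_BETTER
from mintsum.mints_rank import (
    SelectionConfig,
    aggregate_ranks,
    final_order,
    normalize_scores,
    rank_indicators,
    select_summary,
    summarize,
)


def _rank_brute(values, higher_better):
    """Average-tie ranks by explicit enumeration."""
    keyed = [-v for v in values] if higher_better else list(values)
    out = []
    for x in keyed:
        less = sum(1 for y in keyed if y < x)
        equal = sum(1 for y in keyed if y == x)
        # ranks covered: less+1 .. less+equal
        out.append(less + (equal + 1) / 2)
    return out


class TestRankIndicators:
    def test_higher_is_better(self):
        X = np.zeros((3, 6))
        X[:, 5] = [0.9, 0.1, 0.5]  # ds_global
        R = rank_indicators(X, ("ds_global",))
        assert list(R[:, 0]) == [1, 3, 2]

    def test_average_tie_rule(self):
        X = np.zeros((3, 6))
        X[:, 2] = [7, 7, 1]  # n_relevant
        R = rank_indicators(X, ("n_relevant",))
        assert list(R[:, 0]) == [1.5, 1.5, 3]

    def test_position_lower_is_better(self):
        X = np.zeros((3, 6))
        X[:, 1] = [1, 2, 3]
        R = rank_indicators(X, ("position",))
        assert list(R[:, 0]) == [1, 2, 3]

    def test_unknown_indicator_rejected(self):
        with pytest.raises(ValueError, match="unknown indicator"):
            rank_indicators(np.zeros((2, 6)), ("speed",))

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            X = rng.integers(0, 5, size=(10, 6)).astype(float)
            R = rank_indicators(X, FEATURE_NAMES)
            for k, m in enumerate(FEATURE_NAMES):
                expected = _rank_brute(X[:, k], HIGHER_IS_BETTER[m])
                assert list(R[:, k]) == pytest.approx(expected)


class TestAggregation:
    def test_unanimous_winner(self):
        R = np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0]])
        agg = aggregate_ranks(R)
        assert agg[0] == 1.0
        assert final_order(agg)[0] == 0

    def test_tie_broken_by_earlier_position(self):
        R = np.array([[1.0, 3.0], [3.0, 1.0]])
        agg = aggregate_ranks(R)
        assert agg[0] == agg[1] == 2.0
        assert final_order(agg) == [0, 1]

    def test_ordering_matches_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            X = rng.uniform(0, 1, size=(6, 6))
            R = rank_indicators(X, FEATURE_NAMES)
            agg = aggregate_ranks(R)
            expected_agg = [
                np.mean(
                    [
                        _rank_brute(X[:, k], HIGHER_IS_BETTER[m])[i]
                        for k, m in enumerate(FEATURE_NAMES)
                    ]
                )
                for i in range(6)
            ]
            assert list(agg) == pytest.approx(expected_agg)
            assert final_order(agg) == sorted(
                range(6), key=lambda i: (expected_agg[i], i)
            )

    def test_constant_indicator_never_changes_ordering(self):
        rng = np.random.default_rng(31)
        X = rng.uniform(0, 1, size=(8, 6))
        base = final_order(aggregate_ranks(rank_indicators(X, ("ds_global", "n_relevant"))))
        X2 = X.copy()
        X2[:, 0] = 42.0  # length constant across sentences
        with_const = final_order(
            aggregate_ranks(rank_indicators(X2, ("ds_global", "n_relevant", "length")))
        )
        assert base == with_const


class TestSelection:
    def _sim(self, values):
        v = np.asarray(values, dtype=float)
        return ms.SimilarityMatrix(n=v.shape[0], values=v)

    def test_duplicate_never_co_selected(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 1.0  # exact duplicate pair
        sim = self._sim(v)
        chosen = select_summary([0, 1, 2], sim, SelectionConfig(max_sentences=3))
        assert 0 in chosen and 1 not in chosen and 2 in chosen

    def test_all_orthogonal_takes_top_n(self):
        sim = self._sim(np.eye(6))
        assert select_summary(
            [3, 1, 5, 0, 2, 4], sim, SelectionConfig(max_sentences=3)
        ) == [3, 1, 5]

    def test_threshold_one_disables_filtering(self):
        v = np.ones((4, 4))
        chosen = select_summary(
            [0, 1, 2, 3],
            self._sim(v),
            SelectionConfig(max_sentences=4, redundancy_threshold=1.0),
        )
        assert chosen == [0, 1, 2, 3]

    def test_matches_exhaustive_simulation(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            n = 8
            m = rng.uniform(0, 1, (n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            order = list(rng.permutation(n))
            cfg = SelectionConfig(max_sentences=4, redundancy_threshold=0.4)
            got = select_summary(order, self._sim(m), cfg)
            expected = []
            for i in order:
                if len(expected) == 4:
                    break
                if all(m[i, j] <= 0.4 for j in expected):
                    expected.append(i)
            assert got == expected


class TestNormalizedScores:
    def test_endpoints(self):
        scores = normalize_scores([4, 2, 0, 1, 3])
        assert scores[4] == 1.0
        assert scores[3] == 0.0

    def test_midpoint(self):
        scores = normalize_scores([10, 11, 12, 13, 14])
        assert scores[12] == pytest.approx(0.5)

    def test_single_sentence(self):
        assert normalize_scores([7]) == {7: 1.0}

    def test_strictly_decreasing_along_order(self):
        order = [5, 3, 8, 1]
        scores = normalize_scores(order)
        vals = [scores[i] for i in order]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestSummarize:
    def test_single_sentence_document(self, corpus, idf_index, stopwords):
        doc = ms.preprocess_document(
            RawDocument("one", body="Diabetes is discussed."),
            corpus.vocabulary,
            stopwords,
        )
        ranked, summary = summarize(doc, None, idf_index)
        assert len(ranked) == 1
        assert ranked[0].normalized_score == 1.0
        assert summary == "Diabetes is discussed."

    def test_planted_salient_sentences_selected(
        self, corpus, processed_docs, idf_index, trained_model
    ):
        model, _ = trained_model
        doc = processed_docs[-1]
        planted = set(corpus.salient_indices[doc.doc_id])
        ranked, _ = summarize(doc, model, idf_index)
        selected = {r.index for r in ranked if r.selected}
        assert selected <= planted

    def test_deterministic_across_runs(self, processed_docs, idf_index, trained_model):
        model, _ = trained_model
        a = summarize(processed_docs[0], model, idf_index)
        b = summarize(processed_docs[0], model, idf_index)
        assert a[1] == b[1]
        assert [r.__dict__ for r in a[0]] == [r.__dict__ for r in b[0]]

    def test_all_bad_falls_back_to_ranking_everything(
        self, processed_docs, idf_index
    ):
        class RejectAll:
            feature_names = FEATURE_NAMES
            forest = None

        import mintsum.mints_rank as mr

        doc = processed_docs[2]
        orig = mr.predict_worthiness
        mr.predict_worthiness = lambda model, feats: ["bad"] * len(feats)
        try:
            ranked, summary = summarize(doc, RejectAll(), idf_index)
        finally:
            mr.predict_worthiness = orig
        assert len(ranked) == len(doc.body_sentences)
        assert summary
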