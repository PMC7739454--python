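"""Sentence indicators: Dice, TF-IDF cosine, centrality, feature matrix.

Numeric operations are checked against straight-line brute-force
recomputations that never share code with the implementation.
"""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mintsum as ms
from mintsum.corpus_io import RawDocument
from mintsum.features import (
    build_feature_matrix,
    cosine_matrix,
    degree_centrality,
    dice_coefficient,
    global_term_model,
    tfidf_vector,
)


class TestDice:
    def test_identity(self):
        assert dice_coefficient({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert dice_coefficient({"a"}, {"b"}) == 0.0

    def test_worked_example(self):
        a, b = {"w", "x", "y", "z"}, {"w", "x"}
        assert dice_coefficient(a, b) == pytest.approx(2 * 2 / 6)

    def test_both_empty_defined_as_zero(self):
        assert dice_coefficient(set(), set()) == 0.0

    @given(
        st.sets(st.integers(0, 20), max_size=15),
        st.sets(st.integers(0, 20), max_size=15),
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_and_range(self, a, b):
        d = dice_coefficient(a, b)
        assert d == dice_coefficient(b, a)
        assert 0.0 <= d <= 1.0


def _doc_from_sentences(sentences, vocab, stopwords=frozenset()):
    body = " ".join(s if s.endswith(".") else s + "." for s in sentences)
    return ms.preprocess_document(RawDocument("d", body=body), vocab, set(stopwords))


class TestTfidfVector:
    def test_empty_relevant_stems(self, tiny_vocab):
        doc = _doc_from_sentences(["Nothing relevant"], tiny_vocab)
        idx = ms.IdfIndex(n_docs=1, df={})
        assert tfidf_vector(doc.body_sentences[0], idx) == {}

    def test_count_times_idf(self, tiny_vocab):
        doc = _doc_from_sentences(["Diabetes and diabetes"], tiny_vocab)
        idx = ms.IdfIndex(n_docs=1, df={"diabet": 1})  # idf = 1.0
        assert tfidf_vector(doc.body_sentences[0], idx) == {"diabet": 2.0}

    def test_identical_sentences_identical_vectors(self, tiny_vocab):
        doc = _doc_from_sentences(["Insulin helps", "Insulin helps"], tiny_vocab)
        idx = ms.IdfIndex(n_docs=3, df={"insulin": 2})
        v0 = tfidf_vector(doc.body_sentences[0], idx)
        v1 = tfidf_vector(doc.body_sentences[1], idx)
        assert v0 == v1 and v0


class TestCosineMatrix:
    def test_identical_sentences(self, tiny_vocab):
        doc = _doc_from_sentences(["Diabetes insulin", "Diabetes insulin"], tiny_vocab)
        idx = ms.IdfIndex(n_docs=2, df={"diabet": 1, "insulin": 1})
        sim = cosine_matrix(doc, idx)
        assert sim.values[0, 1] == pytest.approx(1.0)
        assert sim.values[0, 0] == 1.0

    def test_orthogonal_term_sets(self, tiny_vocab):
        doc = _doc_from_sentences(["Diabetes only", "Insulin only"], tiny_vocab)
        idx = ms.IdfIndex(n_docs=2, df={"diabet": 1, "insulin": 1})
        assert cosine_matrix(doc, idx).values[0, 1] == 0.0

    def test_empty_sentence_zero_diagonal(self, tiny_vocab):
        doc = _doc_from_sentences(["Diabetes here", "Nothing at all"], tiny_vocab)
        idx = ms.IdfIndex(n_docs=1, df={})
        sim = cosine_matrix(doc, idx)
        assert sim.values[1, 1] == 0.0

    def test_matches_brute_force_on_random_document(self, corpus, stopwords, idf_index):
        doc = ms.preprocess_document(
            corpus.documents[0], corpus.vocabulary, stopwords
        )
        sim = cosine_matrix(doc, idf_index)
        sents = doc.body_sentences
        for i in range(min(6, len(sents))):
            for j in range(min(6, len(sents))):
                u = {s: c * idf_index.idf(s) for s, c in sents[i].relevant_stems.items()}
                v = {s: c * idf_index.idf(s) for s, c in sents[j].relevant_stems.items()}
                if not u or not v:
                    expected = 0.0
                else:
                    dot = sum(u[k] * v.get(k, 0.0) for k in u)
                    expected = dot / (
                        math.sqrt(sum(x * x for x in u.values()))
                        * math.sqrt(sum(x * x for x in v.values()))
                    )
                assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)


class TestDegreeCentrality:
    def test_identical_sentences(self):
        n = 5
        sim = ms.SimilarityMatrix(n=n, values=np.ones((n, n)))
        cent = degree_centrality(sim, 0.1)
        assert np.allclose(cent, (n - 1) / n)

    def test_orthogonal_sentences(self):
        sim = ms.SimilarityMatrix(n=4, values=np.eye(4))
        assert np.allclose(degree_centrality(sim, 0.1), 0.0)

    def test_single_qualifying_pair(self):
        v = np.eye(4)
        v[0, 1] = v[1, 0] = 0.5
        cent = degree_centrality(ms.SimilarityMatrix(n=4, values=v), 0.1)
        assert list(cent) == [0.25, 0.25, 0.0, 0.0]

    def test_pair_count_is_even(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0, 1, (8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        cent = degree_centrality(ms.SimilarityMatrix(n=8, values=m), 0.5)
        assert int(round(cent.sum() * 8)) % 2 == 0


class TestGlobalTermModel:
    def _doc(self, tiny_vocab):
        return _doc_from_sentences(
            ["Diabetes diabetes diabetes insulin insulin brca1"], tiny_vocab
        )

    def test_all_mode(self, tiny_vocab):
        doc = self._doc(tiny_vocab)
        assert global_term_model(doc, "all") == {"diabet", "insulin", "brca1"}

    def test_top_k_ordering(self, tiny_vocab):
        doc = self._doc(tiny_vocab)
        assert global_term_model(doc, "top_k", k=2) == {"diabet", "insulin"}

    def test_tie_broken_alphabetically(self, tiny_vocab):
        doc = _doc_from_sentences(["Insulin brca1 diabetes"], tiny_vocab)
        # all counts 1: alphabetical order brca1 < diabet < insulin
        assert global_term_model(doc, "top_k", k=2) == {"brca1", "diabet"}

    def test_invalid_k(self, tiny_vocab):
        with pytest.raises(ValueError):
            global_term_model(self._doc(tiny_vocab), "top_k", k=0)


class TestFeatureMatrix:
    def test_sentence_with_all_relevant_stems_has_full_overlap(self, tiny_vocab):
        doc = _doc_from_sentences(
            ["Diabetes insulin brca1 taxonomies", "Diabetes alone"], tiny_vocab
        )
        idx = ms.IdfIndex(n_docs=1, df={})
        feats = build_feature_matrix(doc, idx)
        assert feats[0].ds_global == pytest.approx(1.0)

    def test_sentence_without_relevant_stems(self, tiny_vocab):
        doc = _doc_from_sentences(["Diabetes here", "Nothing here"], tiny_vocab)
        idx = ms.IdfIndex(n_docs=1, df={})
        f = build_feature_matrix(doc, idx)[1]
        assert (f.n_relevant, f.pct_relevant, f.ds_global) == (0, 0.0, 0.0)

    def test_matches_straight_line_recomputation(self, corpus, stopwords, idf_index):
        doc = ms.preprocess_document(
            corpus.documents[1], corpus.vocabulary, stopwords
        )
        tau = 0.1
        feats = build_feature_matrix(doc, idf_index, tau_deg=tau)
        sents = doc.body_sentences
        n = len(sents)
        model = {s for s, c in doc.global_term_counts.items() if c > 0}
        sim = cosine_matrix(doc, idf_index).values
        for i, f in enumerate(feats):
            assert f.length == len(sents[i].tokens)
            assert f.position == i + 1
            assert f.n_relevant == sum(sents[i].relevant_stems.values())
            assert f.pct_relevant == pytest.approx(
                f.n_relevant / f.length if f.length else 0.0
            )
            deg = sum(1 for j in range(n) if j != i and sim[i, j] >= tau)
            assert f.degree_centrality == pytest.approx(deg / n)
            b = set(sents[i].relevant_stems)
            inter = len(model & b)
            expected_ds = 2 * inter / (len(model) + len(b)) if (model or b) else 0.0
            assert f.ds_global == pytest.approx(expected_ds)

    def test_invariant_to_stopword_only_edits_except_length(self, tiny_vocab):
        idx = ms.IdfIndex(n_docs=1, df={})
        a = _doc_from_sentences(["Diabetes insulin", "Insulin alone"], tiny_vocab)
        b = _doc_from_sentences(
            ["The diabetes and the insulin", "Insulin alone"],
            tiny_vocab,
            stopwords={"the", "and"},
        )
        fa = build_feature_matrix(a, idx)
        fb = build_feature_matrix(b, idx)
        for x, y in zip(fa, fb):
            assert x.n_relevant == y.n_relevant
            assert x.ds_global == y.ds_global
            assert x.degree_centrality == y.degree_centrality
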