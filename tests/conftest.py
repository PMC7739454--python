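"""Shared fixtures: a small synthetic corpus, its IDF index, processed
documents and a trained worthiness model (session-scoped: the corpus is
deterministic, so sharing is safe)."""

import pytest

import mintsum as ms

SEED = 11


@pytest.fixture(scope="session")
def synthesis_config():
    return ms.SynthesisConfig(
        n_docs=8, sentences_per_doc=20, vocab_size=120, seed=SEED
    )


@pytest.fixture(scope="session")
def corpus(synthesis_config):
    return ms.generate_corpus(synthesis_config)


@pytest.fixture(scope="session")
def stopwords():
    return ms.default_stopwords()


@pytest.fixture(scope="session")
def idf_index(corpus, stopwords):
    return ms.build_idf_index(corpus.documents, corpus.vocabulary, stopwords)


@pytest.fixture(scope="session")
def processed_docs(corpus, stopwords):
    return [
        ms.preprocess_document(d, corpus.vocabulary, stopwords)
        for d in corpus.documents
    ]


@pytest.fixture(scope="session")
def trained_model(processed_docs, idf_index):
    feats, labels = [], []
    for doc in processed_docs[:6]:
        labels += ms.annotate_by_abstract(doc)
        feats += ms.build_feature_matrix(doc, idf_index)
    model, report = ms.train_worthiness(feats, labels, seed=SEED, n_trees=100)
    return model, report


@pytest.fixture()
def tiny_vocab():
    v = ms.ControlledVocabulary()
    v.add("diabet", "disease")
    v.add("insulin", "chemical")
    v.add("brca1", "gene")
    v.add("taxonomi", "other")
    return v
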