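"""Score a document's terms for an indicative topic cloud.

Each distinct stem t in the body is scored i * Wc * tf * idf(t): terms
in the controlled vocabulary (i = 1) from the clinically salient
categories (disease/chemical/gene/mutation) carry weight Wc = 1000, so
even a rare disease mention outranks frequent generic vocabulary.  The
printed rows are ready for any word-cloud renderer.
"""

import mintsum as ms

stopwords = ms.default_stopwords()
corpus = ms.generate_corpus(ms.SynthesisConfig(n_docs=10, seed=42))
index = ms.build_idf_index(corpus.documents, corpus.vocabulary, stopwords)
doc = ms.preprocess_document(corpus.documents[0], corpus.vocabulary, stopwords)

scores = ms.score_terms(doc, corpus.vocabulary, index)
print(f"{'term':<12} {'category':<10} {'tf':>3} {'idf':>6} {'score':>10}")
for term, score, category in ms.topic_cloud_data(scores, top_m=10):
    ts = next(t for t in scores if t.term == term)
    print(f"{term:<12} {category:<10} {ts.tf:>3} {ts.idf:>6.3f} {score:>10.1f}")
print("\nhighest-scoring terms dominate the topic cloud; weighted")
print("categories outrank 'other' terms at comparable frequency")
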