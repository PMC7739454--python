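"""Summarize one document with the multi-indicator pipeline.

Generates a small synthetic corpus with planted salient sentences,
trains the worthiness forest on most of it, then summarizes a held-out
document and prints the ranked-sentence table.  The normalized score
runs from 1 (most important) to 0; the selected flag marks the
redundancy-filtered top sentences that form the summary.
"""

import mintsum as ms

stopwords = ms.default_stopwords()
corpus = ms.generate_corpus(ms.SynthesisConfig(n_docs=10, seed=42))
index = ms.build_idf_index(corpus.documents, corpus.vocabulary, stopwords)
docs = [
    ms.preprocess_document(d, corpus.vocabulary, stopwords)
    for d in corpus.documents
]

features, labels = [], []
for doc in docs[:8]:
    labels += ms.annotate_by_abstract(doc)
    features += ms.build_feature_matrix(doc, index)
model, report = ms.train_worthiness(features, labels, n_trees=200, seed=42)
print(f"worthiness forest: held-out accuracy {report.test_accuracy:.3f}")

target = docs[-1]
ranked, summary = ms.summarize(target, model, index)
print(f"\n{target.doc_id}: {len(target.body_sentences)} sentences, "
      f"{len(ranked)} predicted summary-worthy")
print(f"{'idx':>4} {'agg_rank':>9} {'score':>6} sel  sentence")
for r in ranked:
    flag = "*" if r.selected else " "
    print(f"{r.index:>4} {r.aggregated_rank:>9.2f} {r.normalized_score:>6.2f}  {flag}   {r.raw[:60]}")
print("\nsummary (document order):")
print(summary)
print(f"\nplanted salient sentences were {corpus.salient_indices[target.doc_id]}")
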