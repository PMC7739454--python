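# mintsum

Multi-indicator extractive summarization and indicative term scoring for
clinical and biomedical text.

Clinicians and biomedical researchers face full-text articles, case
reports and clinical notes far longer than they have time to read.
`mintsum` extracts the most summary-worthy sentences from such a
document and, alongside, produces a weighted term list (topic-cloud
data) that gives an at-a-glance view of what the document is about.

## The method

Summarization runs in three stages over the sentences of a document:

1. **Sentence features.** After segmentation, tokenization and Porter
   stemming, each body sentence *s* gets six relevance indicators:
   token length, position, the number and percentage of controlled-
   vocabulary (clinical/biomedical) terms, degree centrality in the
   TF-IDF cosine-similarity sentence graph (normalized by sentence
   count), and the Sørensen–Dice overlap with the document's global
   term-frequency model:

   DS(s) = 2·|A ∩ B| / (|A| + |B|),

   where A is the document-level relevant-term set and B the
   sentence's.

2. **Worthiness filtering.** A random forest (500 trees grown to
   purity, √m features per split, majority vote) classifies each
   sentence as *good* or *bad* for summarization. Training labels come
   from the article abstract, not manual annotation: a sentence is bad
   iff its Dice overlap with the abstract's relevant-term set is below
   0.01.

3. **Rank aggregation and selection.** Each indicator's scores over
   the good sentences are converted to ranks (average ranks on ties)
   and averaged into an aggregated rank. A greedy scan in aggregated
   order selects up to 5 sentences, skipping any candidate whose
   cosine similarity to an already-selected sentence exceeds 0.4, and
   assigns each sentence a normalized score in [0, 1].

Indicative summarization scores every distinct term *t* of the body as

Score(t) = i · Wc · tf · IDF(t),  IDF(t) = 1 + log(N / n_t),

with i = 1 iff *t* is in the controlled vocabulary, Wc = 1000 for
disease/chemical/gene/mutation terms (1 otherwise), tf the term's
frequency in the document, N the number of indexed abstracts and n_t
the number containing *t*.

The package also ships the comparison baselines (topicDist, LexRank,
position, random), a ROUGE-1/2/SU4 recall evaluation harness with a
one-sided paired Wilcoxon test, and a synthetic-corpus generator with
planted salient sentences so everything is testable offline.

## Worked example

```bash
python examples/benchmark_methods.py
```

generates a 20-document synthetic corpus, trains the worthiness forest
on 12 documents, and benchmarks all five methods over the corpus:

```
method      ROUGE-1  ROUGE-2  ROUGE-SU4  p vs random
mints         0.830    0.031      0.325     4.34e-05
topicdist     0.705    0.031      0.278     4.38e-05
lexrank       0.640    0.025      0.260     5.12e-05
position      0.350    0.019      0.138     6.79e-02
random        0.263    0.004      0.102            -
```

Each row is a method's mean ROUGE recall against the abstracts; the
last column is the one-sided paired Wilcoxon p-value against the
3-repeat random baseline. The multi-indicator summarizer recovers the
most abstract content, the single-indicator term-frequency and
graph-centrality baselines trail it, and position carries no signal
here because the generator plants salient sentences at random
positions. See `examples/summarize_document.py` for a ranked-sentence
table of a single document and `examples/topic_cloud.py` for term
scoring.

A CLI wraps the same pipeline:

```bash
mintsum simulate --n-docs 20 --seed 1 --out-dir data
mintsum train --corpus data/corpus.jsonl --vocab data/vocabulary.tsv \
    --index data/idf_index.tsv --model-out model.joblib
mintsum summarize --input doc.txt --vocab data/vocabulary.tsv \
    --index data/idf_index.tsv --model model.joblib --keyword diabetes
mintsum topiccloud --input doc.txt --vocab data/vocabulary.tsv --index data/idf_index.tsv
mintsum evaluate --corpus data/corpus.jsonl --vocab data/vocabulary.tsv \
    --index data/idf_index.tsv --model model.joblib
```

Real documents need a controlled vocabulary (TSV of term → category,
e.g. assembled from MeSH/SNOMED-CT term lists) and a document-frequency
index built from any abstract collection via `build_idf_index`.

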