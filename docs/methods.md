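# Methods

## Pipeline model and assumptions

The summarizer treats a document as an ordered list of body sentences
plus an optional abstract. All text is lowercased UTF-8; relevance is
decided purely lexically: a token counts as clinically/biologically
relevant iff its Porter stem appears in the controlled vocabulary.
Any token outside the vocabulary is treated like a stop word for
relevance purposes (it still counts toward sentence length and ROUGE
tokens). No syntactic or semantic analysis is performed; the method's
premise is that term overlap statistics suffice to locate
summary-worthy sentences.

### Preprocessing

Sentence segmentation is rule-based: split at `.?!` followed by
whitespace and an uppercase letter or digit, suppressed after a
packaged abbreviation list (Dr., Fig., e.g., i.e., et al., vs.,
approx., No., …) and after single-letter initials. Tokenization takes
maximal runs of letters/digits, keeping internal hyphens
(`psa-screening` is one token). Stemming is the classic Porter (1980)
five-step algorithm, implemented in-package (`mintsum/porter.py`) and
pinned by a test vector of the algorithm's published worked examples.
The stopword check is applied to the raw lowercase token *before*
stemming because the packaged PubMed-style stopword list is unstemmed.

The packaged stopword list has exactly 121 entries. The official
PubMed help table is commonly counted at 133 entries; the packaged
list is a curated 121-entry subset of it (the least function-word-like
entries were dropped) and is a stand-in, not a copy of any specific
release. Supply your own list via `read_stopwords` to override.

### Vocabulary and IDF index

Vocabulary files are TSV (surface term, category ∈ disease/chemical/
gene/mutation/other); terms are stemmed at load with the same stemmer
as document text, and stem collisions resolve in favor of the weighted
categories because the term-scoring weight depends on the category.
The document-frequency index counts stem presence per abstract;
IDF(t) = 1 + log(N/n_t) with natural log by default (the log base only
rescales scores monotonically; it is configurable). Unseen terms are
smoothed with n_t = 1, giving rare terms the maximal finite IDF
without dividing by zero.

### Features

Six per-sentence indicators: length (all tokens, pre-filtering),
1-based position, relevant-term count and percentage, degree
centrality, and Dice overlap with the document-level term model. The
Dice overlap is computed on stem *sets* (presence, not weighted
counts), and Dice of two empty sets is defined as 0 — an empty
sentence carries no summary value. Degree centrality is a thresholded
degree count (cosine ≥ τ_deg, default 0.1) over the TF-IDF cosine
similarity graph, normalized by the total sentence count; a
weighted-sum variant was considered but the thresholded count is the
standard reading in the sentence-graph literature and is kept as the
default. The global term model defaults to *all* relevant stems with
nonzero body frequency; a top-k mode (alphabetical tie-breaks) exists
and drives the topicDist baseline (default k = 20).

### Worthiness classification

Labels are data-driven: bad iff Dice(sentence, abstract) < 0.01,
strictly — a sentence exactly at the threshold is good. The classifier
is a scikit-learn random forest behind the module's own surface:
500 trees, sqrt(m) features per split, trees grown to purity,
bootstrap sampling with the out-of-bag estimate reported. Training
uses a stratified 60/40 split; the report carries OOB, held-out,
per-class and balanced accuracies. The quantity reported as
`balanced_accuracy` is the mean of per-class accuracies (sometimes
loosely called a balanced error rate elsewhere; the naming here states
what is computed). Prediction ties (exact 50/50 vote) go to "good":
the filtering stage should not discard borderline sentences in a
recall-oriented task. No class re-weighting is applied by default.

### Ranking and selection

Indicator scores of the good sentences become ranks (1 = most
favorable; higher-is-better for all indicators except position, where
earlier is better; ties take average ranks), are averaged into the
aggregated rank, and final-order ties break toward the earlier
sentence. The greedy selection skips a candidate iff its cosine to any
already-selected sentence is strictly greater than the redundancy
threshold (default 0.4), so a threshold of 1.0 disables filtering; the
summary caps at 5 sentences by default and is rendered in document
order. Normalized scores map the final ordering linearly onto [0, 1]
(single sentence → 1.0). If the classifier rejects every sentence the
ranker falls back to ranking all sentences and logs the event — a
summarizer must produce output.

### Baselines and evaluation

topicDist scores each sentence by Dice with the top-20 global stems;
LexRank computes the stationary distribution of the damped
(d = 0.85) random walk on the thresholded (0.1) similarity graph by
power iteration to 1e-6, parameters following common LexRank/MEAD
conventions; position scores (N − position + 1)/N; random draws three
uniform summaries and averages their ROUGE. Baselines select top-n
purely by score, without worthiness filtering or redundancy control.

ROUGE-1/2/SU4 are recall-only with clipped multiset counting; bigrams
and skip-bigrams (≤ 4 intervening tokens; unigrams included in the SU
unit inventory) do not cross sentence boundaries; summary tokens are
stemmed before matching and stopwords retained, both configurable.
The Wilcoxon signed-rank test is scipy's, one-sided, zero differences
dropped (exact distribution when sample size and ties permit, normal
approximation otherwise); the degenerate all-equal case reports p = 1.

## Synthetic corpus

The generator emulates the structure the annotation scheme assumes:
an abstract whose term distribution overlaps a planted subset of body
sentences. Each document draws a 10-term theme; the abstract
enumerates the theme; each of 6 planted salient sentences covers a
distinct *aspect* (a round-robin slice of the theme) plus one of two
shared hub terms, padded to at least 3 theme terms — so salient
sentences are related through common terminology (moderate pairwise
cosine, giving them centrality) without being near-duplicates (so the
redundancy filter does not suppress them), which is how abstract-worthy
sentences behave in real articles. Distractors carry 1–2 non-theme
vocabulary terms plus out-of-vocabulary filler, making their abstract
overlap exactly 0 and their relevant-term density visibly lower.
Planted overlaps are verified against the Dice formula at generation
time and generation fails loudly if the configured targets are
unsatisfiable. Synthetic words are consonant-vowel syllables with a
closed final consonant, chosen so the Porter stemmer maps them to
themselves (asserted at generation); generator correctness is thereby
decoupled from stemmer behavior.

Default study conditions: 20 documents, 30 sentences each (6 salient),
300-term vocabulary with category proportions
(disease .25, chemical .20, gene .15, mutation .10, other .30),
10 tokens per sentence, salient Dice target 0.30 against the 0.01
annotation threshold. These sizes keep a full train-and-benchmark
cycle to a few seconds while leaving enough sentences (600 per corpus)
for stable classifier estimates.

What passing on this corpus shows: the formulas, the ranking
machinery, the classifier plumbing and the relative ordering of
methods under planted salience. What it does not show: performance on
natural language — real sentence-length distributions, morphology,
paraphrase, section structure and annotation noise are absent, so
absolute ROUGE values here are far higher than on real articles and
are not comparable to published figures on external corpora. The
separable feature generator (`separable_feature_set`) is a further
abstraction used only for classifier checks: one informative feature,
the rest noise.

## Numerical choices and degenerate inputs

- Cosine of an all-zero TF-IDF vector is 0 against everything,
  including itself (its diagonal entry is 0, not 1).
- LexRank dangling nodes (no edges) receive uniform teleport rows;
  non-convergence raises with the residual rather than returning a
  stale vector.
- Rank conversion uses average ranks on ties (scipy `rankdata`);
  brute-force reimplementations in the tests pin the semantics.
- All seeded randomness goes through `numpy.random.default_rng`;
  the random baseline seeds per (seed, repeat) so repeats are
  independently reproducible.
- Empty documents, empty abstracts (when annotation or evaluation
  needs them), single-class training labels and fewer than 10 training
  sentences are hard errors, not warnings.

## Known limitations

- The segmenter is a deterministic rule set; it will mis-split
  unusual abbreviations not on its list.
- The classifier inherits any bias of the abstract-overlap labels;
  sentences summary-worthy for reasons other than term overlap with
  the abstract are invisible to it.
- Term scores are not mapped to ontology concepts, so synonymous
  surface forms fragment the topic cloud.
- Only English is supported (Porter stemmer, English stopwords).
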