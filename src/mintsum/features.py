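"""Per-sentence relevance indicators (the sentence-feature matrix).

Six indicators are computed for every body sentence:

* ``length`` — token count (before stopword removal);
* ``position`` — 1-based sentence index;
* ``n_relevant`` — occurrences of controlled-vocabulary stems;
* ``pct_relevant`` — n_relevant / length;
* ``degree_centrality`` — thresholded degree in the TF-IDF cosine
  similarity graph, normalized by the total sentence count;
* ``ds_global`` — Sørensen–Dice overlap between the sentence's
  relevant-stem set and the document-level term model.

The same feature matrix feeds both the worthiness classifier and the
rank-aggregation stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import ProcessedDocument, Sentence
from .vocab_index import IdfIndex

FEATURE_NAMES = (
    "length",
    "position",
    "n_relevant",
    "pct_relevant",
    "degree_centrality",
    "ds_global",
)

#: indicators where a larger value means a more summary-worthy sentence;
#: position is the lone lower-is-better indicator (earlier = better).
HIGHER_IS_BETTER = {
    "length": True,
    "position": False,
    "n_relevant": True,
    "pct_relevant": True,
    "degree_centrality": True,
    "ds_global": True,
}

DEFAULT_TAU_DEG = 0.1


@dataclass
class FeatureVector:
    length: int
    position: int
    n_relevant: int
    pct_relevant: float
    degree_centrality: float
    ds_global: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.length,
                self.position,
                self.n_relevant,
                self.pct_relevant,
                self.degree_centrality,
                self.ds_global,
            ],
            dtype=float,
        )


@dataclass
class SimilarityMatrix:
    n: int
    values: np.ndarray  # (n, n) symmetric, entries in [0, 1]


def dice_coefficient(a: frozenset | set, b: frozenset | set) -> float:
    """Sørensen–Dice set overlap 2|A∩B|/(|A|+|B|); two empty sets → 0."""
    total = len(a) + len(b)
    if total == 0:
        return 0.0
    return 2.0 * len(a & b) / total


def tfidf_vector(sent: Sentence, index: IdfIndex) -> dict[str, float]:
    """Sparse TF-IDF over the sentence's relevant stems."""
    return {s: c * index.idf(s) for s, c in sent.relevant_stems.items()}


def _cosine(u: dict[str, float], v: dict[str, float]) -> float:
    if not u or not v:
        return 0.0
    dot = sum(w * v[s] for s, w in u.items() if s in v)
    nu = math.sqrt(sum(w * w for w in u.values()))
    nv = math.sqrt(sum(w * w for w in v.values()))
    return dot / (nu * nv)


def cosine_matrix(doc: ProcessedDocument, index: IdfIndex) -> SimilarityMatrix:
    """TF-IDF cosine similarity between all body-sentence pairs.

    Sentences whose TF-IDF vector is all-zero (no relevant stems) get
    similarity 0 to everything, including themselves.
    """
    sents = doc.body_sentences
    n = len(sents)
    if n < 1:
        raise ValueError("cosine_matrix needs at least one body sentence")
    vecs = [tfidf_vector(s, index) for s in sents]
    sim = np.zeros((n, n))
    for i in range(n):
        if vecs[i]:
            sim[i, i] = 1.0
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = _cosine(vecs[i], vecs[j])
    return SimilarityMatrix(n=n, values=sim)


def degree_centrality(
    sim: SimilarityMatrix, tau_deg: float = DEFAULT_TAU_DEG
) -> np.ndarray:
    """Thresholded-degree centrality normalized by sentence count:
    the fraction of *other* sentences with cosine >= tau_deg."""
    n = sim.n
    above = sim.values >= tau_deg
    np.fill_diagonal(above, False)
    return above.sum(axis=1) / n


def global_term_model(
    doc: ProcessedDocument, mode: str = "all", k: int = 20
) -> frozenset:
    """Stem set of the document-level term model.

    ``all`` (the summarizer default) takes every stem with a nonzero
    body count; ``top_k`` takes the *k* most frequent stems with
    alphabetical tie-breaks (used by the topic-distribution baseline).
    """
    counts = doc.global_term_counts
    if mode == "all":
        return frozenset(s for s, c in counts.items() if c > 0)
    if mode == "top_k":
        if k < 1:
            raise ValueError("top_k mode requires k >= 1")
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return frozenset(s for s, _ in ordered[:k])
    raise ValueError(f"unknown term-model mode: {mode!r}")


def build_feature_matrix(
    doc: ProcessedDocument,
    index: IdfIndex,
    tau_deg: float = DEFAULT_TAU_DEG,
    sim: SimilarityMatrix | None = None,
    term_model_mode: str = "all",
    term_model_k: int = 20,
) -> list[FeatureVector]:
    """One FeatureVector per body sentence."""
    sents = doc.body_sentences
    if not sents:
        raise ValueError("document has no body sentences")
    if sim is None:
        sim = cosine_matrix(doc, index)
    cent = degree_centrality(sim, tau_deg)
    model = global_term_model(doc, mode=term_model_mode, k=term_model_k)
    out = []
    for i, s in enumerate(sents):
        length = len(s.tokens)
        n_rel = s.n_relevant
        out.append(
            FeatureVector(
                length=length,
                position=i + 1,
                n_relevant=n_rel,
                pct_relevant=(n_rel / length) if length else 0.0,
                degree_centrality=float(cent[i]),
                ds_global=dice_coefficient(model, s.relevant_set),
            )
        )
    return out


def feature_array(features: list[FeatureVector]) -> np.ndarray:
    return np.vstack([f.as_array() for f in features])
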