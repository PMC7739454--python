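"""Weighted term scoring for topic clouds and keyword filtering.

Each distinct stem t in a document body is scored

    score(t) = i * Wc * tf * idf(t)

where i is 1 iff t is in the controlled vocabulary, Wc weights the
clinically salient categories (disease/chemical/gene/mutation, default
1000; 1 for "other"), tf is the raw stem frequency over the whole body,
and idf comes from the abstract-corpus document-frequency index.  The
top-scoring terms form the topic-cloud data (rendering is left to the
caller).  Keyword filtering keeps ranked sentences whose stems contain
the stem of the query keyword.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mints_rank import RankedSentence
from .porter import stem as porter_stem
from .preprocess import ProcessedDocument
from .vocab_index import (
    DEFAULT_WC,
    ControlledVocabulary,
    IdfIndex,
    category_weight,
)

DEFAULT_TOP_M = 50


@dataclass
class TermScore:
    term: str
    category: str
    i: int
    wc: float
    tf: int
    idf: float
    score: float


def score_terms(
    doc: ProcessedDocument,
    vocab: ControlledVocabulary,
    index: IdfIndex,
    wc: float = DEFAULT_WC,
    include_zero: bool = False,
) -> list[TermScore]:
    """Score every distinct body stem; sorted by score descending with
    alphabetical tie-breaks.  Out-of-vocabulary stems score 0 and are
    excluded unless *include_zero* is set."""
    tf_counts: dict[str, int] = {}
    for s in doc.body_sentences:
        for t in s.stems:
            tf_counts[t] = tf_counts.get(t, 0) + 1
    scores = []
    for term, tf in tf_counts.items():
        i, weight = category_weight(vocab, term, wc=wc)
        if i == 0 and not include_zero:
            continue
        idf_val = index.idf(term)
        scores.append(
            TermScore(
                term=term,
                category=vocab.category(term) or "",
                i=i,
                wc=weight,
                tf=tf,
                idf=idf_val,
                score=i * weight * tf * idf_val,
            )
        )
    scores.sort(key=lambda t: (-t.score, t.term))
    return scores


def topic_cloud_data(
    scores: list[TermScore], top_m: int = DEFAULT_TOP_M
) -> list[tuple[str, float, str]]:
    """Top-*m* (term, score, category) triples for any cloud renderer."""
    return [(t.term, t.score, t.category) for t in scores[:top_m]]


def filter_sentences_by_keyword(
    ranked: list[RankedSentence],
    doc: ProcessedDocument,
    keyword: str,
    exact_surface: bool = False,
) -> list[RankedSentence]:
    """Keep ranked sentences mentioning *keyword*, in their ranking order.

    Matching is at the stem level by default, so "diabetes" matches a
    sentence containing "diabetic" exactly when their Porter stems
    coincide; *exact_surface* switches to raw lowercase token equality.
    """
    if not keyword.strip():
        raise ValueError("keyword must be non-empty")
    key = keyword.strip().lower()
    key_stem = porter_stem(key)
    out = []
    for r in ranked:
        sent = doc.body_sentences[r.index]
        if exact_surface:
            hit = key in sent.tokens
        else:
            hit = key_stem in sent.stems
        if hit:
            out.append(r)
    return out
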