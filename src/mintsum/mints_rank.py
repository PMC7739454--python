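"""Rank aggregation and redundancy-controlled sentence selection.

The final stage of the multi-indicator summarizer: each indicator's
scores over the worthiness-filtered sentences are converted to ranks
(1 = most favorable, average ranks on ties), the per-sentence ranks
are averaged into an aggregated rank, and a greedy scan in aggregated
order selects up to ``max_sentences`` sentences, skipping any candidate
whose TF-IDF cosine similarity to an already-selected sentence exceeds
the redundancy threshold (default 0.4).  Normalized scores map the
final ordering linearly onto [0, 1] with 1 = most important.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .features import (
    DEFAULT_TAU_DEG,
    FEATURE_NAMES,
    HIGHER_IS_BETTER,
    FeatureVector,
    SimilarityMatrix,
    build_feature_matrix,
    cosine_matrix,
    feature_array,
)
from .preprocess import ProcessedDocument
from .vocab_index import IdfIndex
from .worthiness import GOOD, WorthinessModel, predict_worthiness

logger = logging.getLogger(__name__)

DEFAULT_MAX_SENTENCES = 5
DEFAULT_REDUNDANCY_THRESHOLD = 0.4


@dataclass
class SelectionConfig:
    max_sentences: int = DEFAULT_MAX_SENTENCES
    redundancy_threshold: float = DEFAULT_REDUNDANCY_THRESHOLD
    indicators: tuple[str, ...] = FEATURE_NAMES
    directions: dict[str, bool] = field(default_factory=lambda: dict(HIGHER_IS_BETTER))
    tau_deg: float = DEFAULT_TAU_DEG

    def __post_init__(self) -> None:
        if self.max_sentences < 1:
            raise ValueError("max_sentences must be >= 1")
        if not 0.0 <= self.redundancy_threshold <= 1.0:
            raise ValueError("redundancy_threshold must lie in [0, 1]")


@dataclass
class RankedSentence:
    index: int  # body-sentence index within the document
    raw: str
    indicator_ranks: dict[str, float]
    aggregated_rank: float
    normalized_score: float = 0.0
    selected: bool = False


def rank_indicators(
    features: list[FeatureVector] | np.ndarray,
    indicators: tuple[str, ...] = FEATURE_NAMES,
    directions: dict[str, bool] | None = None,
) -> np.ndarray:
    """Convert indicator scores to ranks, one column per indicator.

    Rank 1 is the most favorable value; ties receive the average of the
    ranks they cover (so two sentences tied at the top both get 1.5).
    """
    directions = directions if directions is not None else HIGHER_IS_BETTER
    X = features if isinstance(features, np.ndarray) else feature_array(features)
    cols = []
    for m in indicators:
        if m not in FEATURE_NAMES:
            raise ValueError(f"unknown indicator: {m!r}")
        values = X[:, FEATURE_NAMES.index(m)]
        higher_better = directions.get(m, True)
        # rankdata ranks ascending; negate for higher-is-better
        cols.append(rankdata(-values if higher_better else values, method="average"))
    return np.column_stack(cols)


def aggregate_ranks(rank_matrix: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the per-indicator ranks for each sentence."""
    return rank_matrix.mean(axis=1)


def final_order(aggregated: np.ndarray) -> list[int]:
    """Sentence indices from best (lowest aggregated rank) to worst;
    ties broken by earlier document position."""
    return sorted(range(len(aggregated)), key=lambda i: (aggregated[i], i))


def select_summary(
    order: list[int],
    sim: SimilarityMatrix,
    cfg: SelectionConfig | None = None,
) -> list[int]:
    """Greedy scan of *order*: take a sentence unless its similarity to
    any already-selected sentence exceeds the redundancy threshold
    (strict >, so a threshold of 1.0 disables the filter).  Returns the
    selected indices in selection (rank) order."""
    cfg = cfg or SelectionConfig()
    selected: list[int] = []
    for i in order:
        if len(selected) >= cfg.max_sentences:
            break
        if any(sim.values[i, j] > cfg.redundancy_threshold for j in selected):
            continue
        selected.append(i)
    return selected


def normalize_scores(order: list[int]) -> dict[int, float]:
    """Linear scores on the final ordering: best 1.0, worst 0.0."""
    n = len(order)
    if n == 1:
        return {order[0]: 1.0}
    return {idx: 1.0 - pos / (n - 1) for pos, idx in enumerate(order)}


def rank_sentences(
    doc: ProcessedDocument,
    features: list[FeatureVector],
    candidate_indices: list[int],
    sim: SimilarityMatrix,
    cfg: SelectionConfig | None = None,
) -> list[RankedSentence]:
    """Rank the candidate sentences and flag the redundancy-filtered
    top selection.  Indices refer to body-sentence positions."""
    cfg = cfg or SelectionConfig()
    if not candidate_indices:
        raise ValueError("no candidate sentences to rank")
    sub = feature_array([features[i] for i in candidate_indices])
    R = rank_indicators(sub, cfg.indicators, cfg.directions)
    agg = aggregate_ranks(R)
    order_local = final_order(agg)
    order_doc = [candidate_indices[i] for i in order_local]
    scores_doc = {
        candidate_indices[i]: s
        for i, s in normalize_scores(order_local).items()
    }
    chosen = set(select_summary(order_doc, sim, cfg))
    ranked = []
    for local, doc_idx in enumerate(candidate_indices):
        ranked.append(
            RankedSentence(
                index=doc_idx,
                raw=doc.body_sentences[doc_idx].raw,
                indicator_ranks={
                    m: float(R[local, k]) for k, m in enumerate(cfg.indicators)
                },
                aggregated_rank=float(agg[local]),
                normalized_score=scores_doc[doc_idx],
                selected=doc_idx in chosen,
            )
        )
    ranked.sort(key=lambda r: (-r.normalized_score, r.index))
    return ranked


def summarize(
    doc: ProcessedDocument,
    model: WorthinessModel | None,
    index: IdfIndex,
    cfg: SelectionConfig | None = None,
) -> tuple[list[RankedSentence], str]:
    """Full pipeline for one document: features → worthiness filter →
    rank aggregation → redundancy-controlled selection.

    If the classifier rejects every sentence (or *model* is None) all
    sentences are ranked — a summarizer must still produce output; the
    fallback is logged.  The summary text joins the selected sentences
    in original document order.
    """
    if not doc.body_sentences:
        raise ValueError(f"document {doc.doc_id!r} has no body sentences")
    cfg = cfg or SelectionConfig()
    sim = cosine_matrix(doc, index)
    features = build_feature_matrix(doc, index, tau_deg=cfg.tau_deg, sim=sim)
    n = len(features)
    if model is not None:
        labels = predict_worthiness(model, features)
        candidates = [i for i, lab in enumerate(labels) if lab == GOOD]
        if not candidates:
            logger.warning(
                "document %s: classifier rejected all %d sentences; "
                "falling back to ranking every sentence",
                doc.doc_id,
                n,
            )
            candidates = list(range(n))
    else:
        candidates = list(range(n))
    ranked = rank_sentences(doc, features, candidates, sim, cfg)
    chosen = sorted(r.index for r in ranked if r.selected)
    summary = " ".join(doc.body_sentences[i].raw for i in chosen)
    return ranked, summary
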