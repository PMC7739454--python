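"""Single-indicator reference summarizers.

* ``topicDist`` — Dice overlap between a sentence and the document's
  most frequent relevant stems (Luhn-style topic distribution);
* ``LexRank`` — eigenvector centrality of the damped random walk on
  the thresholded cosine-similarity sentence graph;
* ``position`` — earlier sentences score higher;
* ``random`` — uniform sentence samples, averaged over repeats.

Each baseline scores every sentence and selects the top *n* purely by
score (no worthiness filter, no redundancy control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import SimilarityMatrix, dice_coefficient, global_term_model
from .preprocess import ProcessedDocument

DEFAULT_TOPIC_K = 20


@dataclass
class LexRankConfig:
    similarity_threshold: float = 0.1
    damping: float = 0.85
    tolerance: float = 1e-6
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must lie in (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def topic_dist_scores(doc: ProcessedDocument, k: int = DEFAULT_TOPIC_K) -> np.ndarray:
    """Dice overlap of each sentence with the top-*k* global stems."""
    if not doc.body_sentences:
        raise ValueError("document has no body sentences")
    top = global_term_model(doc, mode="top_k", k=k)
    return np.array(
        [dice_coefficient(top, s.relevant_set) for s in doc.body_sentences]
    )


def lexrank_scores(sim: SimilarityMatrix, cfg: LexRankConfig | None = None) -> np.ndarray:
    """Stationary distribution of the damped walk on the similarity graph.

    Edges connect sentence pairs with cosine >= the threshold; the walk
    follows edges with probability *damping* and teleports uniformly
    otherwise.  Isolated sentences keep only their teleport mass.
    Scores sum to 1.  Computed by power iteration to the L-infinity
    tolerance; raises on non-convergence.
    """
    cfg = cfg or LexRankConfig()
    n = sim.n
    adj = (sim.values >= cfg.similarity_threshold).astype(float)
    np.fill_diagonal(adj, 0.0)
    deg = adj.sum(axis=1)
    # row-stochastic transition matrix; dangling rows teleport uniformly
    P = np.full((n, n), 1.0 / n)
    nz = deg > 0
    P[nz] = adj[nz] / deg[nz, None]
    d = cfg.damping
    p = np.full(n, 1.0 / n)
    for _ in range(cfg.max_iterations):
        p_next = (1 - d) / n + d * (p @ P)
        residual = np.abs(p_next - p).max()
        p = p_next
        if residual < cfg.tolerance:
            return p
    raise RuntimeError(
        f"LexRank power iteration failed to converge after "
        f"{cfg.max_iterations} iterations (residual {residual:.2e})"
    )


def position_scores(doc: ProcessedDocument) -> np.ndarray:
    """(N - position + 1)/N: first sentence 1.0, last 1/N."""
    n = len(doc.body_sentences)
    if n < 1:
        raise ValueError("document has no body sentences")
    return (n - np.arange(n)) / n


def top_n_by_score(scores: np.ndarray, n_sentences: int) -> list[int]:
    """Indices of the *n* highest-scoring sentences, ties to the earlier
    sentence, returned in document order."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return sorted(order[:n_sentences])


def random_summary(
    doc: ProcessedDocument,
    n_sentences: int,
    seed: int,
    repeats: int = 3,
) -> list[list[int]]:
    """*repeats* uniform without-replacement sentence samples (document
    order within each); deterministic per (seed, repeat index)."""
    n = len(doc.body_sentences)
    if n_sentences > n:
        raise ValueError(f"cannot sample {n_sentences} of {n} sentences")
    out = []
    for r in range(repeats):
        rng = np.random.default_rng((seed, r))
        pick = rng.choice(n, size=n_sentences, replace=False)
        out.append(sorted(int(i) for i in pick))
    return out
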