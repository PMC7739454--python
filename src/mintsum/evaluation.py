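"""Recall-oriented n-gram evaluation (ROUGE-1/2/SU4) and benchmarking.

System summaries are scored against the article abstract, which serves
as the human-written reference.  ROUGE-1 and ROUGE-2 count unigram and
bigram co-occurrence; ROUGE-SU4 counts unigrams plus ordered skip
bigrams with at most four intervening tokens.  All counting is clipped
multiset counting and recall only (matched reference units divided by
total reference units).  Bigrams and skip-bigrams never cross sentence
boundaries; tokens are stemmed before matching and stopwords retained
by default (both configurable).

Significance of per-document score differences between two methods is
assessed with a one-sided paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import wilcoxon

from .mints_rank import SelectionConfig, summarize
from .porter import stem as porter_stem
from .preprocess import ProcessedDocument
from .vocab_index import IdfIndex
from . import baselines

Segments = Sequence[Sequence[str]]


@dataclass
class RougeScores:
    rouge1: float
    rouge2: float
    rouge_su4: float

    def as_dict(self) -> dict[str, float]:
        return {"rouge1": self.rouge1, "rouge2": self.rouge2, "rouge_su4": self.rouge_su4}


@dataclass
class BenchmarkResult:
    per_document: dict[str, list[RougeScores]]  # method -> one entry per doc
    means: dict[str, RougeScores]
    p_values: dict[str, dict[str, float]] = field(default_factory=dict)
    doc_ids: list[str] = field(default_factory=list)


def _as_segments(tokens) -> list[list[str]]:
    if not tokens:
        return []
    if isinstance(tokens[0], (list, tuple)):
        return [list(seg) for seg in tokens]
    return [list(tokens)]


def _ngrams(segments: Segments, n: int) -> Counter:
    grams: Counter = Counter()
    for seg in segments:
        for i in range(len(seg) - n + 1):
            grams[tuple(seg[i : i + n])] += 1
    return grams


def _su_units(segments: Segments, max_skip: int) -> Counter:
    """Unigrams plus ordered skip-bigrams with <= max_skip intervening
    tokens, within each segment."""
    units: Counter = Counter()
    for seg in segments:
        for tok in seg:
            units[(tok,)] += 1
        for i in range(len(seg)):
            for j in range(i + 1, min(i + max_skip + 2, len(seg))):
                units[(seg[i], seg[j])] += 1
    return units


def _clipped_recall(sys_units: Counter, ref_units: Counter) -> float:
    total = sum(ref_units.values())
    if total == 0:
        return 0.0
    matched = sum(min(c, sys_units[g]) for g, c in ref_units.items())
    return matched / total


def rouge_n(system, reference, n: int) -> float:
    """Clipped n-gram recall of *system* against *reference*.

    Both arguments are token lists or lists of per-sentence token lists
    (n-grams do not cross sentence boundaries in the latter form).
    """
    ref_segs = _as_segments(reference)
    ref_grams = _ngrams(ref_segs, n)
    if not ref_grams:
        raise ValueError(f"reference has no {n}-grams")
    return _clipped_recall(_ngrams(_as_segments(system), n), ref_grams)


def rouge_su(system, reference, max_skip: int = 4) -> float:
    """Skip-bigram + unigram recall (ROUGE-SU) with the given maximum
    number of intervening tokens (default 4, i.e. ROUGE-SU4)."""
    ref_units = _su_units(_as_segments(reference), max_skip)
    if not ref_units:
        raise ValueError("reference is empty")
    return _clipped_recall(_su_units(_as_segments(system), max_skip), ref_units)


def score_summary(
    system_segments: Segments, reference_segments: Segments, stem_tokens: bool = True
) -> RougeScores:
    """ROUGE-1/2/SU4 of a system summary against a reference, both given
    as per-sentence token lists."""
    if stem_tokens:
        system_segments = [[porter_stem(t) for t in seg] for seg in system_segments]
        reference_segments = [
            [porter_stem(t) for t in seg] for seg in reference_segments
        ]
    if not any(reference_segments):
        raise ValueError("reference summary is empty")
    r1 = rouge_n(system_segments, reference_segments, 1)
    try:
        r2 = rouge_n(system_segments, reference_segments, 2)
    except ValueError:  # reference shorter than 2 tokens
        r2 = 0.0
    su4 = rouge_su(system_segments, reference_segments, max_skip=4)
    return RougeScores(rouge1=r1, rouge2=r2, rouge_su4=su4)


def _doc_segments(doc: ProcessedDocument, indices: Sequence[int]) -> list[list[str]]:
    return [doc.body_sentences[i].tokens for i in indices]


def _abstract_segments(doc: ProcessedDocument) -> list[list[str]]:
    return [s.tokens for s in doc.abstract_sentences]


def evaluate_method(
    corpus: Sequence[ProcessedDocument],
    summarizer: Callable[[ProcessedDocument], Sequence[int]],
    n_sentences: int = 5,
    stem_tokens: bool = True,
) -> list[RougeScores]:
    """Score *summarizer* (a callable returning selected body-sentence
    indices) over every document, against each document's abstract."""
    out = []
    for doc in corpus:
        if not doc.abstract_sentences:
            raise ValueError(f"document {doc.doc_id!r} lacks an abstract")
        indices = list(summarizer(doc))[:n_sentences]
        out.append(
            score_summary(
                _doc_segments(doc, indices),
                _abstract_segments(doc),
                stem_tokens=stem_tokens,
            )
        )
    return out


def paired_wilcoxon_one_sided(scores_a, scores_b) -> float:
    """One-sided paired Wilcoxon signed-rank p-value for a > b.

    Zero differences are dropped; if every difference is zero the test
    is degenerate and p = 1 (no evidence of superiority).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 paired observations")
    if np.all(a == b):
        return 1.0
    return float(
        wilcoxon(a, b, alternative="greater", zero_method="wilcox").pvalue
    )


def make_summarizers(
    model,
    index: IdfIndex,
    cfg: SelectionConfig | None = None,
    seed: int = 0,
    topic_k: int = baselines.DEFAULT_TOPIC_K,
    lexrank_cfg: baselines.LexRankConfig | None = None,
) -> dict[str, Callable[[ProcessedDocument], list[int]]]:
    """Named summarizer callables sharing one protocol: document in,
    selected body-sentence indices out (document order)."""
    cfg = cfg or SelectionConfig()
    n = cfg.max_sentences

    def mints(doc: ProcessedDocument) -> list[int]:
        ranked, _ = summarize(doc, model, index, cfg)
        return sorted(r.index for r in ranked if r.selected)

    def topicdist(doc: ProcessedDocument) -> list[int]:
        return baselines.top_n_by_score(baselines.topic_dist_scores(doc, k=topic_k), n)

    def lexrank(doc: ProcessedDocument) -> list[int]:
        from .features import cosine_matrix

        sim = cosine_matrix(doc, index)
        return baselines.top_n_by_score(baselines.lexrank_scores(sim, lexrank_cfg), n)

    def position(doc: ProcessedDocument) -> list[int]:
        return baselines.top_n_by_score(baselines.position_scores(doc), n)

    return {
        "mints": mints,
        "topicdist": topicdist,
        "lexrank": lexrank,
        "position": position,
    }


def benchmark_corpus(
    corpus: Sequence[ProcessedDocument],
    model,
    index: IdfIndex,
    methods: Sequence[str] = ("mints", "topicdist", "lexrank", "position", "random"),
    cfg: SelectionConfig | None = None,
    seed: int = 0,
    random_repeats: int = 3,
    stem_tokens: bool = True,
) -> BenchmarkResult:
    """Run every requested method over the corpus, average the random
    baseline over its repeats, and test each method against the random
    baseline with the one-sided paired Wilcoxon on each ROUGE metric."""
    cfg = cfg or SelectionConfig()
    summarizers = make_summarizers(model, index, cfg, seed=seed)
    per_document: dict[str, list[RougeScores]] = {}
    for name in methods:
        if name == "random":
            per_doc = []
            for doc in corpus:
                picks = baselines.random_summary(
                    doc, min(cfg.max_sentences, len(doc.body_sentences)),
                    seed=seed, repeats=random_repeats,
                )
                reps = [
                    score_summary(
                        _doc_segments(doc, p),
                        _abstract_segments(doc),
                        stem_tokens=stem_tokens,
                    )
                    for p in picks
                ]
                per_doc.append(
                    RougeScores(
                        rouge1=float(np.mean([r.rouge1 for r in reps])),
                        rouge2=float(np.mean([r.rouge2 for r in reps])),
                        rouge_su4=float(np.mean([r.rouge_su4 for r in reps])),
                    )
                )
            per_document[name] = per_doc
        else:
            per_document[name] = evaluate_method(
                corpus, summarizers[name], cfg.max_sentences, stem_tokens=stem_tokens
            )

    means = {
        name: RougeScores(
            rouge1=float(np.mean([r.rouge1 for r in rows])),
            rouge2=float(np.mean([r.rouge2 for r in rows])),
            rouge_su4=float(np.mean([r.rouge_su4 for r in rows])),
        )
        for name, rows in per_document.items()
    }
    p_values: dict[str, dict[str, float]] = {}
    if "random" in per_document and len(corpus) >= 5:
        base = per_document["random"]
        for name, rows in per_document.items():
            if name == "random":
                continue
            p_values[name] = {
                metric: paired_wilcoxon_one_sided(
                    [getattr(r, metric) for r in rows],
                    [getattr(r, metric) for r in base],
                )
                for metric in ("rouge1", "rouge2", "rouge_su4")
            }
    return BenchmarkResult(
        per_document=per_document,
        means=means,
        p_values=p_values,
        doc_ids=[d.doc_id for d in corpus],
    )
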