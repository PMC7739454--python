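"""Synthetic documents with planted salience structure.

Real training data for the worthiness classifier comes from full-text
articles whose abstracts define, via term overlap, which body sentences
are summary-worthy.  This module emulates exactly that structure over a
small synthetic vocabulary so the whole pipeline — annotation, feature
computation, classification, ranking, selection and ROUGE evaluation —
is testable without any external corpus:

* each document has a *theme*: a set of controlled-vocabulary terms
  that make up its abstract;
* planted salient sentences each cover a distinct *aspect* of the
  theme (a slice of the theme terms) plus a shared hub term, the way
  abstract-worthy sentences in a real article cover its different
  claims: related through common terminology but not near-duplicates.
  Their Dice overlap with the abstract clears the annotation
  threshold, and their pairwise cosine sits in the moderate range that
  yields centrality edges without tripping the redundancy filter;
* distractor sentences carry one or two non-theme vocabulary terms and
  out-of-vocabulary filler, so their abstract overlap is exactly zero
  and their relevant-term density is visibly lower.

Synthetic vocabulary words are built from consonant-vowel syllables
with a closed final consonant, which makes them fixed points of the
Porter stemmer (verified at generation time); generator correctness is
therefore independent of stemmer behavior.  The generator is
deterministic for a fixed seed.

What this does NOT emulate: natural-language fluency, morphological
variation, section structure, or the long-tailed sentence lengths of
real articles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import CorpusManifest, RawDocument
from .porter import stem as porter_stem
from .vocab_index import CATEGORIES, ControlledVocabulary

# glue tokens drawn from the packaged stopword list: they appear in the
# text but never in relevant-stem sets
_GLUE = ("the", "of", "and", "in", "with", "for")

_ONSETS = "bdfgjklmnprstvz"
_VOWELS = "aeiou"
_FINALS = "bfkmpvxz"  # endings no stemming rule touches

DEFAULT_CATEGORY_PROPORTIONS = (0.25, 0.20, 0.15, 0.10, 0.30)


@dataclass
class SynthesisConfig:
    n_docs: int = 20
    vocab_size: int = 300
    category_proportions: tuple[float, ...] = DEFAULT_CATEGORY_PROPORTIONS
    sentences_per_doc: int = 30
    n_salient_per_doc: int = 6
    theme_terms_per_doc: int = 10
    salient_overlap: float = 0.30
    distractor_overlap: float = 0.0
    annotation_threshold: float = 0.01
    tokens_per_sentence: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 10:
            raise ValueError("vocab_size must be >= 10")
        if len(self.category_proportions) != len(CATEGORIES):
            raise ValueError("need one proportion per category")
        if abs(sum(self.category_proportions) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if self.n_salient_per_doc >= self.sentences_per_doc:
            raise ValueError("n_salient_per_doc must be < sentences_per_doc")
        if not (self.salient_overlap > self.annotation_threshold):
            raise ValueError("salient_overlap must exceed the annotation threshold")
        if not (self.distractor_overlap < self.annotation_threshold):
            raise ValueError("distractor_overlap must fall below the annotation threshold")


@dataclass
class SyntheticCorpus:
    manifest: CorpusManifest
    vocabulary: ControlledVocabulary
    salient_indices: dict[str, list[int]] = field(default_factory=dict)
    config: SynthesisConfig | None = None

    @property
    def documents(self) -> list[RawDocument]:
        return self.manifest.entries


def _make_word(rng: np.random.Generator, n_syllables: int, used: set[str]) -> str:
    """A pronounceable pseudo-term that is its own Porter stem."""
    for _ in range(100):
        w = "".join(
            rng.choice(list(_ONSETS)) + rng.choice(list(_VOWELS))
            for _ in range(n_syllables)
        ) + rng.choice(list(_FINALS))
        if w not in used and porter_stem(w) == w:
            used.add(w)
            return w
    raise RuntimeError("failed to generate a stemmer-stable word")


def generate_vocabulary(
    cfg: SynthesisConfig, rng: np.random.Generator | None = None
) -> ControlledVocabulary:
    """Synthetic controlled vocabulary with categories drawn by the
    configured proportions; deterministic per seed."""
    rng = rng or np.random.default_rng(cfg.seed)
    used: set[str] = set()
    vocab = ControlledVocabulary()
    cats = rng.choice(
        len(CATEGORIES), size=cfg.vocab_size, p=list(cfg.category_proportions)
    )
    for ci in cats:
        vocab.add(_make_word(rng, 2, used), CATEGORIES[int(ci)])
    return vocab


def _min_theme_terms(cfg: SynthesisConfig) -> int:
    # Dice of a sentence with k theme terms vs a T-term abstract is
    # 2k/(T+k); solve for the smallest k meeting the overlap target
    t = cfg.theme_terms_per_doc
    k = math.ceil(cfg.salient_overlap * t / (2.0 - cfg.salient_overlap))
    return max(1, k)


def _sentence_text(tokens: list[str]) -> str:
    text = " ".join(tokens)
    return text[0].upper() + text[1:] + "."


def _compose_sentence(
    rng: np.random.Generator,
    content: list[str],
    fillers: list[str],
    n_tokens: int,
) -> str:
    toks = list(content)
    while len(toks) < n_tokens - 2:
        toks.append(str(rng.choice(fillers)))
    toks.extend(rng.choice(list(_GLUE), size=2).tolist())
    perm = rng.permutation(len(toks))
    toks = [toks[i] for i in perm]
    # last token must be a content/filler word so the trailing period is
    # never mistaken for an abbreviation by the segmenter
    if toks[-1] in _GLUE:
        for i, t in enumerate(toks):
            if t not in _GLUE:
                toks[i], toks[-1] = toks[-1], toks[i]
                break
    return _sentence_text(toks)


def generate_document(
    cfg: SynthesisConfig,
    vocab: ControlledVocabulary,
    doc_id: str = "doc0",
    rng: np.random.Generator | None = None,
) -> tuple[RawDocument, list[int]]:
    """One document plus the planted salient-sentence indices.

    The abstract enumerates the theme terms; salient body sentences
    carry enough theme terms that their relevant-set Dice against the
    abstract meets ``salient_overlap``; distractors carry only
    non-theme vocabulary and filler, giving Dice 0.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    terms = sorted(vocab.entries)
    theme = [str(t) for t in rng.choice(terms, size=cfg.theme_terms_per_doc, replace=False)]
    non_theme = [t for t in terms if t not in theme]

    used: set[str] = set(terms)
    fillers = [_make_word(rng, 3, used) for _ in range(30)]

    # abstract: two sentences jointly covering every theme term
    half = len(theme) // 2
    abstract = " ".join(
        _sentence_text(list(rng.permutation(part)))
        for part in (theme[:half], theme[half:])
        if part
    )
    title = _sentence_text(theme[:3])[:-1]

    k_min = max(3, _min_theme_terms(cfg))
    n = cfg.sentences_per_doc
    n_salient = cfg.n_salient_per_doc
    salient_idx = sorted(
        int(i) for i in rng.choice(n, size=n_salient, replace=False)
    )
    salient_set = set(salient_idx)

    # two hub terms tie the salient sentences together; the rest of the
    # theme is dealt out round-robin as per-sentence aspects
    hubs, pool = theme[:2], theme[2:]
    aspects = [pool[j::n_salient] for j in range(n_salient)]

    sentences = []
    aspect_no = 0
    for i in range(n):
        if i in salient_set:
            content = list(aspects[aspect_no % n_salient])
            content.append(hubs[aspect_no % len(hubs)])
            extra = [t for t in pool if t not in content]
            while len(content) < k_min and extra:
                content.append(
                    extra.pop(int(rng.integers(0, len(extra))))
                )
            aspect_no += 1
            # planted overlap: Dice vs the theme-term abstract
            k = len(set(content))
            if 2 * k / (cfg.theme_terms_per_doc + k) < cfg.salient_overlap:
                raise ValueError(
                    "unsatisfiable salient_overlap for the configured "
                    "theme size and sentence length"
                )
        else:
            d = int(rng.integers(1, 3))
            content = [str(t) for t in rng.choice(non_theme, size=d, replace=False)]
        sentences.append(
            _compose_sentence(rng, content, fillers, cfg.tokens_per_sentence)
        )
    body = " ".join(sentences)
    doc = RawDocument(doc_id=doc_id, title=title, abstract=abstract, body=body)
    return doc, salient_idx


def generate_corpus(cfg: SynthesisConfig) -> SyntheticCorpus:
    """A reproducible corpus whose abstracts double as the input for
    the document-frequency index."""
    if cfg.n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    vocab = generate_vocabulary(cfg, rng)
    docs = []
    salient: dict[str, list[int]] = {}
    for d in range(cfg.n_docs):
        doc, idx = generate_document(cfg, vocab, doc_id=f"doc{d:03d}", rng=rng)
        docs.append(doc)
        salient[doc.doc_id] = idx
    return SyntheticCorpus(
        manifest=CorpusManifest(entries=docs),
        vocabulary=vocab,
        salient_indices=salient,
        config=cfg,
    )


def separable_feature_set(
    n: int = 2000, seed: int = 0
) -> tuple[np.ndarray, list[str]]:
    """A linearly separable sentence-feature sample for classifier
    checks: good sentences draw their global-overlap feature from
    U(0.3, 0.6), bad ones from U(0, 0.005); all other indicators are
    uninformative noise.  Balanced classes, deterministic per seed."""
    rng = np.random.default_rng(seed)
    n_good = n // 2
    labels = ["good"] * n_good + ["bad"] * (n - n_good)
    ds = np.concatenate(
        [rng.uniform(0.3, 0.6, size=n_good), rng.uniform(0.0, 0.005, size=n - n_good)]
    )
    X = np.column_stack(
        [
            rng.integers(5, 40, size=n),  # length
            rng.permutation(n) + 1,  # position
            rng.integers(0, 10, size=n),  # n_relevant
            rng.uniform(0, 1, size=n),  # pct_relevant
            rng.uniform(0, 1, size=n),  # degree_centrality
            ds,  # ds_global
        ]
    ).astype(float)
    return X, labels
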