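"""Sentence segmentation, tokenization, stemming and relevance marking.

A document's title, abstract and body are segmented into sentences,
tokenized into lowercase word tokens, stemmed with the Porter stemmer,
and each stem is marked *relevant* iff it appears in the controlled
vocabulary.  Stopwords (checked on the raw lowercase token, before
stemming, since the PubMed list is unstemmed) and out-of-vocabulary
stems never enter ``relevant_stems``: any word absent from the
controlled dictionary is treated as a stop word for relevance purposes.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator

from .porter import stem
from .vocab_index import ControlledVocabulary

if TYPE_CHECKING:  # pragma: no cover
    from .corpus_io import RawDocument

__all__ = [
    "Sentence",
    "ProcessedDocument",
    "segment_sentences",
    "tokenize",
    "stem",
    "preprocess_document",
    "sentence_stems",
]

# lowercase word: runs of letters/digits, internal hyphens kept
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")

# abbreviations after which a period never ends a sentence
ABBREVIATIONS = (
    "dr", "fig", "figs", "e.g", "i.e", "et al", "al", "vs", "approx",
    "no", "nos", "mr", "mrs", "ms", "prof", "st", "etc", "ref", "eq",
)

_BOUNDARY_RE = re.compile(r"([.?!])\s+(?=[A-Z0-9])")


def _ends_with_abbreviation(chunk: str) -> bool:
    tail = chunk.rstrip(".").lower()
    for abbr in ABBREVIATIONS:
        if tail.endswith(abbr):
            prev = tail[: -len(abbr)]
            if not prev or not prev[-1].isalpha():
                return True
    # single-letter initial, e.g. "J. Smith"
    last = tail.rsplit(None, 1)[-1] if tail.split() else tail
    return len(last) == 1 and last.isalpha()


def segment_sentences(text: str) -> list[str]:
    """Split *text* into sentences on ``. ? !`` followed by whitespace
    and an uppercase letter or digit, suppressing splits after a known
    abbreviation or a single-letter initial.

    The concatenation of the result equals the input up to
    inter-sentence whitespace; empty sentences are never produced.
    """
    text = text.strip()
    if not text:
        return []
    pieces: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        candidate = text[start : m.end(1)]
        if _ends_with_abbreviation(candidate):
            continue
        pieces.append(candidate.strip())
        start = m.end()
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    return [p for p in pieces if p]


def tokenize(sentence: str) -> list[str]:
    """Lowercase word tokens: maximal letter/digit runs, hyphens kept
    inside a word.  Pure punctuation yields no tokens."""
    return _TOKEN_RE.findall(sentence.lower())


@dataclass
class Sentence:
    """One sentence with its token, stem and relevant-stem views."""

    doc_id: str
    index: int  # 0-based position within the body (or abstract)
    raw: str
    tokens: list[str] = field(default_factory=list)
    stems: list[str] = field(default_factory=list)
    relevant_stems: Counter = field(default_factory=Counter)

    @property
    def relevant_set(self) -> frozenset:
        return frozenset(self.relevant_stems)

    @property
    def n_relevant(self) -> int:
        return sum(self.relevant_stems.values())


@dataclass
class ProcessedDocument:
    doc_id: str
    title_sentence: Sentence | None
    abstract_sentences: list[Sentence]
    body_sentences: list[Sentence]
    global_term_counts: Counter = field(default_factory=Counter)

    @property
    def abstract_relevant_set(self) -> frozenset:
        out: set[str] = set()
        for s in self.abstract_sentences:
            out.update(s.relevant_stems)
        return frozenset(out)


def _make_sentence(
    doc_id: str,
    index: int,
    raw: str,
    vocab: ControlledVocabulary,
    stopwords: set[str],
) -> Sentence:
    tokens = tokenize(raw)
    stems = [stem(t) for t in tokens]
    relevant = Counter(
        s for t, s in zip(tokens, stems) if t not in stopwords and s in vocab
    )
    return Sentence(doc_id, index, raw, tokens, stems, relevant)


def _segment_and_build(
    doc_id: str, text: str, vocab: ControlledVocabulary, stopwords: set[str]
) -> list[Sentence]:
    return [
        _make_sentence(doc_id, i, raw, vocab, stopwords)
        for i, raw in enumerate(segment_sentences(text))
    ]


def preprocess_document(
    doc: "RawDocument",
    vocab: ControlledVocabulary,
    stopwords: set[str],
) -> ProcessedDocument:
    """Segment, tokenize, stem and relevance-mark a raw document.

    ``global_term_counts`` is the relevant-stem frequency distribution
    over the whole body — the document-level term model the sentence
    overlap feature is computed against.
    """
    if not doc.body.strip():
        raise ValueError(f"document {doc.doc_id!r} has an empty body")
    title = None
    if doc.title.strip():
        title = _make_sentence(doc.doc_id, 0, doc.title.strip(), vocab, stopwords)
    abstract_sents = _segment_and_build(doc.doc_id, doc.abstract, vocab, stopwords)
    body_sents = _segment_and_build(doc.doc_id, doc.body, vocab, stopwords)
    global_counts: Counter = Counter()
    for s in body_sents:
        global_counts.update(s.relevant_stems)
    return ProcessedDocument(
        doc_id=doc.doc_id,
        title_sentence=title,
        abstract_sentences=abstract_sents,
        body_sentences=body_sents,
        global_term_counts=global_counts,
    )


def sentence_stems(text: str, stopwords: set[str]) -> Iterator[str]:
    """Yield stems of all non-stopword tokens in *text* (all sentences)."""
    for t in tokenize(text):
        if t not in stopwords:
            yield stem(t)
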