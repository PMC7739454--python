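"""Controlled vocabulary and document-frequency (IDF) index.

The controlled vocabulary maps stems to one of five biomedical
categories (disease, chemical, gene, mutation, other); it stands in for
the MeSH/SNOMED-CT/PubTator dictionary that defines which tokens count
as clinically or biologically relevant.  The IDF index is a local
document-frequency table built from an abstract corpus and supplies

    idf(t) = 1 + log(n_docs / df[t])

with natural log by default.  Terms never seen in the index are smoothed
with df = 1 so rare terms get the maximal finite IDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from .corpus_io import RawDocument

CATEGORIES = ("disease", "chemical", "gene", "mutation", "other")

#: categories whose terms carry the heavy topic-cloud weight
PRIORITY_CATEGORIES = frozenset({"disease", "chemical", "gene", "mutation"})

#: default weight for priority-category terms in the term-scoring scheme
DEFAULT_WC = 1000.0


@dataclass
class ControlledVocabulary:
    """Map stem -> category label."""

    entries: dict[str, str] = field(default_factory=dict)

    def __contains__(self, stem: str) -> bool:
        return stem in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def category(self, stem: str) -> str | None:
        return self.entries.get(stem)

    def add(self, stem: str, category: str) -> None:
        """Register *stem*; on collision the priority category wins."""
        if category not in CATEGORIES:
            raise ValueError(f"unknown vocabulary category: {category!r}")
        current = self.entries.get(stem)
        if current is None:
            self.entries[stem] = category
        elif current == "other" and category in PRIORITY_CATEGORIES:
            self.entries[stem] = category


@dataclass
class IdfIndex:
    """Document-frequency table over an abstract corpus."""

    n_docs: int
    df: dict[str, int] = field(default_factory=dict)
    log_base: float | None = None  # None = natural log

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("IdfIndex requires n_docs >= 1")

    def idf(self, stem: str) -> float:
        d = self.df.get(stem, 1)  # unseen-term smoothing
        ratio = self.n_docs / d
        log = math.log(ratio) if self.log_base is None else math.log(ratio, self.log_base)
        return 1.0 + log


def build_idf_index(
    abstracts: Iterable["RawDocument"],
    vocab: ControlledVocabulary | None = None,
    stopwords: set[str] | None = None,
) -> IdfIndex:
    """Count per-stem document frequency (presence, not multiplicity).

    Each abstract contributes at most 1 to every stem it contains.  When
    *vocab* is given only vocabulary stems are indexed; otherwise every
    non-stopword stem is.  The abstract text is used when non-empty,
    falling back to the body (so a plain abstract-only corpus works).
    """
    from .preprocess import sentence_stems  # local import: avoid cycle

    df: dict[str, int] = {}
    n = 0
    for doc in abstracts:
        n += 1
        text = doc.abstract if doc.abstract.strip() else doc.body
        seen: set[str] = set()
        for s in sentence_stems(text, stopwords or set()):
            if vocab is not None and s not in vocab:
                continue
            seen.add(s)
        for s in seen:
            df[s] = df.get(s, 0) + 1
    if n == 0:
        raise ValueError("cannot build an IDF index from an empty corpus")
    return IdfIndex(n_docs=n, df=df)


def idf(index: IdfIndex, stem: str) -> float:
    return index.idf(stem)


def category_weight(
    vocab: ControlledVocabulary, stem: str, wc: float = DEFAULT_WC
) -> tuple[int, float]:
    """Return (i, Wc): vocabulary membership flag and category weight.

    Wc is *wc* (default 1000) for disease/chemical/gene/mutation terms
    and 1 otherwise; i = 0 zeroes the downstream term score entirely.
    """
    cat = vocab.category(stem)
    if cat is None:
        return 0, 1.0
    return 1, (wc if cat in PRIORITY_CATEGORIES else 1.0)


def save_idf_index(index: IdfIndex, path) -> None:
    """Persist as TSV: an ``#n_docs`` header line then (stem, df) rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#n_docs\t{index.n_docs}\n")
        fh.write("stem\tdf\n")
        for stem_, d in sorted(index.df.items()):
            fh.write(f"{stem_}\t{d}\n")


def load_idf_index(path) -> IdfIndex:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#n_docs\t"):
            raise ValueError(f"not an IDF index file: {path}")
        n_docs = int(header.split("\t")[1])
        fh.readline()  # column header
        df: dict[str, int] = {}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            stem_, d = line.split("\t")
            df[stem_] = int(d)
    return IdfIndex(n_docs=n_docs, df=df)
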