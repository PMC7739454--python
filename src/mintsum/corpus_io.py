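"""Readers and writers for documents, corpora, vocabularies and tables.

On-disk conventions:

* plain documents: whole ``.txt`` file becomes the body (no abstract);
* structured corpora: JSON-lines with keys doc_id/title/abstract/body;
* controlled vocabulary: two-column TSV (surface term, category);
* stopwords: one lowercase token per line;
* all result tables: TSV with a header row.

Vocabulary terms are stemmed at load time with the same Porter stemmer
applied to document text, so relevance matching is stem-to-stem.  When
two surface terms collapse to one stem with different categories, the
weighted category (disease/chemical/gene/mutation) wins over "other" —
the term-scoring weights depend on the category, so the weighted
reading must survive the collision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .porter import stem
from .vocab_index import ControlledVocabulary


@dataclass
class RawDocument:
    doc_id: str
    title: str = ""
    abstract: str = ""
    body: str = ""


@dataclass
class CorpusManifest:
    entries: list[RawDocument] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate doc_ids in corpus")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def read_document(path, format: str = "plain", doc_id: str | None = None) -> RawDocument:
    """Read one document.  ``plain`` maps the whole file to the body;
    ``structured`` expects a single JSON object with named fields."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"empty document: {path}")
    if format == "plain":
        return RawDocument(doc_id=doc_id or path.stem, body=text)
    if format == "structured":
        rec = json.loads(text)
        if "body" not in rec or not str(rec["body"]).strip():
            raise ValueError(f"structured document lacks a body field: {path}")
        return RawDocument(
            doc_id=str(rec.get("doc_id", doc_id or path.stem)),
            title=str(rec.get("title", "")),
            abstract=str(rec.get("abstract", "")),
            body=str(rec["body"]),
        )
    raise ValueError(f"unknown document format: {format!r}")


def read_corpus(path) -> CorpusManifest:
    """Read a JSON-lines corpus (one document object per line)."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            docs.append(
                RawDocument(
                    doc_id=str(rec["doc_id"]),
                    title=str(rec.get("title", "")),
                    abstract=str(rec.get("abstract", "")),
                    body=str(rec.get("body", "")),
                )
            )
    return CorpusManifest(entries=docs)


def write_corpus(corpus: CorpusManifest, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus:
            fh.write(
                json.dumps(
                    {
                        "doc_id": d.doc_id,
                        "title": d.title,
                        "abstract": d.abstract,
                        "body": d.body,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_vocabulary(path) -> ControlledVocabulary:
    """Load a two-column TSV (surface term, category) into a stemmed
    controlled vocabulary.  Multi-word terms contribute each word's stem."""
    vocab = ControlledVocabulary()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            term, category = parts[0].strip().lower(), parts[1].strip().lower()
            n_rows += 1
            for word in term.split():
                vocab.add(stem(word), category)
    if n_rows == 0:
        raise ValueError(f"empty vocabulary file: {path}")
    return vocab


def write_vocabulary(vocab: ControlledVocabulary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, cat in sorted(vocab.entries.items()):
            fh.write(f"{term}\t{cat}\n")


def read_stopwords(path) -> set[str]:
    """One token per line, lowercased; duplicates collapse."""
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            tok = line.strip().lower()
            if tok:
                out.add(tok)
    return out


def default_stopwords() -> set[str]:
    """The packaged PubMed-style stopword list (121 entries)."""
    text = resources.files("mintsum.data").joinpath("pubmed_stopwords.txt").read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def write_ranked_sentences(ranked: Sequence, path) -> None:
    """TSV of ranked sentences, ordered by normalized score descending."""
    if not ranked:
        raise ValueError("no ranked sentences to write")
    rows = sorted(ranked, key=lambda r: (-r.normalized_score, r.index))
    indicator_names = list(rows[0].indicator_ranks)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "index\traw\t"
            + "\t".join(f"rank_{m}" for m in indicator_names)
            + "\taggregated_rank\tnormalized_score\tselected\n"
        )
        for r in rows:
            ranks = "\t".join(f"{r.indicator_ranks[m]:.6f}" for m in indicator_names)
            fh.write(
                f"{r.index}\t{r.raw}\t{ranks}\t{r.aggregated_rank:.6f}"
                f"\t{r.normalized_score:.6f}\t{int(r.selected)}\n"
            )


def write_term_scores(scores: Sequence, path) -> None:
    if not scores:
        raise ValueError("no term scores to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tcategory\ti\twc\ttf\tidf\tscore\n")
        for t in scores:
            fh.write(
                f"{t.term}\t{t.category}\t{t.i}\t{t.wc:g}\t{t.tf}"
                f"\t{t.idf:.6f}\t{t.score:.6f}\n"
            )


def write_summary(sentences: Iterable[str], path) -> None:
    """Selected sentences, one per line, in original document order."""
    sentences = list(sentences)
    if not sentences:
        raise ValueError("no sentences selected for summary")
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(s + "\n")
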