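"""Faceted full-text index over annotated abstracts.

Documents arrive with the facet fields the annotation pass produced (genes,
diseases, drugs/chemicals, cell lines, event types).  The index keeps an
inverted token index over title+abstract plus per-field facet postings and
serves:

* conjunctive search — a document must contain every query term (AND
  semantics) and satisfy every facet filter;
* TF-IDF cosine ranking with doc-id tie-break;
* facet counts over the full result set, which is what makes click-through
  consistent: refining by a displayed (field, value) returns exactly that
  many documents;
* tag clouds (top-k facet values, weights relative to the maximum count);
* prefix autocomplete over the text and facet vocabularies.

The index persists as a JSON header plus a JSON-lines document file, with
postings rebuilt deterministically on load — no external search server.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from ._tokenize import word_tokens

logger = logging.getLogger(__name__)

DEFAULT_FACET_FIELDS: tuple[str, ...] = (
    "genes", "diseases", "drugs_chemicals", "cell_lines", "event_types")

PUBMED_URL = "https://pubmed.ncbi.nlm.nih.gov/{pmid}/"


@dataclass(frozen=True)
class IndexedDocument:
    """The shared annotation↔faceting record for one abstract."""

    doc_id: str
    title: str
    abstract: str
    genes: tuple[str, ...] = ()
    diseases: tuple[str, ...] = ()
    drugs_chemicals: tuple[str, ...] = ()
    cell_lines: tuple[str, ...] = ()
    event_types: tuple[str, ...] = ()
    url: str | None = None

    def facet_values(self, fld: str) -> tuple[str, ...]:
        vals = getattr(self, fld)
        return tuple(dict.fromkeys(vals))  # dedup, order-preserving

    @staticmethod
    def pubmed_url(doc_id: str) -> str | None:
        return PUBMED_URL.format(pmid=doc_id) if doc_id.isdigit() else None


@dataclass(frozen=True)
class Query:
    terms: tuple[str, ...] = ()
    filters: tuple[tuple[str, str], ...] = ()


FacetCounts = dict[str, dict[str, int]]


@dataclass
class ResultSet:
    ranked: list[tuple[str, float]]     # (doc_id, score), best first
    total: int
    facet_counts: FacetCounts

    @property
    def doc_ids(self) -> list[str]:
        return [d for d, _ in self.ranked]


# ---------------------------------------------------------------------------
# Index construction
# ---------------------------------------------------------------------------

class Index:
    """Inverted text index plus facet postings; see module docstring."""

    def __init__(self, facet_fields: Sequence[str] = DEFAULT_FACET_FIELDS):
        self.facet_fields = tuple(facet_fields)
        self.docs: dict[str, IndexedDocument] = {}
        self.postings: dict[str, set[str]] = {}
        self.facet_postings: dict[str, dict[str, set[str]]] = {
            f: {} for f in self.facet_fields}
        self.term_freq: dict[str, Counter] = {}   # doc_id -> token counts
        self.collection_freq: Counter = Counter()
        self._doc_norm: dict[str, float] = {}

    # -- building -----------------------------------------------------------

    def add(self, doc: IndexedDocument) -> None:
        if doc.doc_id in self.docs:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        self.docs[doc.doc_id] = doc
        counts = Counter(word_tokens((doc.title + " " + doc.abstract).lower()))
        self.term_freq[doc.doc_id] = counts
        for tok, c in counts.items():
            self.postings.setdefault(tok, set()).add(doc.doc_id)
            self.collection_freq[tok] += c
        for fld in self.facet_fields:
            for val in doc.facet_values(fld):
                self.facet_postings[fld].setdefault(val, set()).add(doc.doc_id)
        self._doc_norm.clear()  # idf changes with N; recompute lazily

    def _idf(self, term: str) -> float:
        df = len(self.postings.get(term, ()))
        return math.log(len(self.docs) / df) if df else 0.0

    def _norm(self, doc_id: str) -> float:
        if not self._doc_norm:
            for did, counts in self.term_freq.items():
                self._doc_norm[did] = math.sqrt(sum(
                    (c * self._idf(t)) ** 2 for t, c in counts.items()))
        return self._doc_norm[doc_id]


def build_index(docs: Iterable[IndexedDocument],
                facet_fields: Sequence[str] = DEFAULT_FACET_FIELDS) -> Index:
    """Build an index; duplicate doc ids raise. Deterministic."""
    index = Index(facet_fields)
    for doc in docs:
        index.add(doc)
    return index


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def _candidates(index: Index, query: Query) -> set[str]:
    ids: set[str] | None = None
    for term in query.terms:
        hits = index.postings.get(term.lower(), set())
        ids = hits.copy() if ids is None else ids & hits
        if not ids:
            return set()
    if ids is None:
        ids = set(index.docs)
    for fld, val in query.filters:
        if fld not in index.facet_postings:
            raise KeyError(f"unknown facet field {fld!r}")
        ids &= index.facet_postings[fld].get(val, set())
        if not ids:
            return set()
    return ids


def facet_counts(index: Index, ids: set[str]) -> FacetCounts:
    out: FacetCounts = {f: {} for f in index.facet_fields}
    for doc_id in ids:
        doc = index.docs[doc_id]
        for fld in index.facet_fields:
            per = out[fld]
            for val in doc.facet_values(fld):
                per[val] = per.get(val, 0) + 1
    return out


def _score(index: Index, query_counts: Counter, doc_id: str) -> float:
    q_weights = {t: c * index._idf(t) for t, c in query_counts.items()}
    q_norm = math.sqrt(sum(w * w for w in q_weights.values()))
    d_norm = index._norm(doc_id)
    if q_norm == 0.0 or d_norm == 0.0:
        return 0.0
    tf = index.term_freq[doc_id]
    dot = sum(w * tf.get(t, 0) * index._idf(t) for t, w in q_weights.items())
    return dot / (q_norm * d_norm)


def search(index: Index, query: Query) -> ResultSet:
    """Conjunctive faceted search with TF-IDF cosine ranking.

    An empty query with no filters is browsing mode and returns the whole
    collection.  Facet counts are computed over the complete candidate set.
    """
    ids = _candidates(index, query)
    q_counts = Counter(t.lower() for t in query.terms)
    scored = [(doc_id, _score(index, q_counts, doc_id)) for doc_id in ids]
    scored.sort(key=lambda pair: (-pair[1], pair[0]))
    return ResultSet(ranked=scored, total=len(ids),
                     facet_counts=facet_counts(index, ids))


# ---------------------------------------------------------------------------
# Query refinement (pure)
# ---------------------------------------------------------------------------

def refine(query: Query, fld: str, value: str) -> Query:
    """Append a facet filter; idempotent on duplicates."""
    f = (fld, value)
    if f in query.filters:
        return query
    return replace(query, filters=query.filters + (f,))


def unrefine(query: Query, fld: str, value: str) -> Query:
    """Remove a facet filter, preserving the order of the rest."""
    f = (fld, value)
    if f not in query.filters:
        logger.warning("unrefine: filter %r not present", f)
        return query
    return replace(query, filters=tuple(x for x in query.filters if x != f))


def clear(query: Query) -> Query:
    """Drop all facet filters, keeping the text terms."""
    return replace(query, filters=())


# ---------------------------------------------------------------------------
# Tag cloud and autocomplete
# ---------------------------------------------------------------------------

def tag_cloud(result: ResultSet, fld: str, k: int) -> list[tuple[str, float]]:
    """Top-k facet values by count; weights are relative to the leader."""
    if k <= 0:
        return []
    counts = result.facet_counts.get(fld, {})
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    if not top:
        return []
    max_count = top[0][1]
    return [(v, c / max_count) for v, c in top]


def autocomplete(index: Index, prefix: str, k: int) -> list[str]:
    """Indexed terms (text + facet vocabularies) starting with the prefix,
    by descending collection frequency then lexicographically."""
    if not prefix:
        raise ValueError("autocomplete requires a non-empty prefix")
    prefix = prefix.lower()
    vocab: Counter = Counter(index.collection_freq)
    for fld in index.facet_fields:
        for val, ids in index.facet_postings[fld].items():
            low = val.lower()
            if low not in vocab:
                vocab[low] = len(ids)
    hits = [(t, c) for t, c in vocab.items() if t.startswith(prefix)]
    hits.sort(key=lambda kv: (-kv[1], kv[0]))
    return [t for t, _ in hits[:k]]


# ---------------------------------------------------------------------------
# Persistence and I/O
# ---------------------------------------------------------------------------

def doc_to_record(doc: IndexedDocument) -> dict:
    rec = {"doc_id": doc.doc_id, "title": doc.title, "abstract": doc.abstract}
    for fld in DEFAULT_FACET_FIELDS:
        rec[fld] = list(getattr(doc, fld))
    if doc.url:
        rec["url"] = doc.url
    return rec


def record_to_doc(rec: dict) -> IndexedDocument:
    return IndexedDocument(
        doc_id=str(rec["doc_id"]), title=rec.get("title", ""),
        abstract=rec.get("abstract", ""),
        genes=tuple(rec.get("genes", ())),
        diseases=tuple(rec.get("diseases", ())),
        drugs_chemicals=tuple(rec.get("drugs_chemicals", ())),
        cell_lines=tuple(rec.get("cell_lines", ())),
        event_types=tuple(rec.get("event_types", ())),
        url=rec.get("url") or IndexedDocument.pubmed_url(str(rec["doc_id"])))


def read_indexed_jsonl(path: str | Path) -> list[IndexedDocument]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(record_to_doc(json.loads(line)))
    return out


def save_index(index: Index, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = {"facet_fields": list(index.facet_fields),
              "n_docs": len(index.docs)}
    (directory / "header.json").write_text(json.dumps(header, indent=2))
    with open(directory / "documents.jsonl", "w", encoding="utf-8") as fh:
        for doc in index.docs.values():
            fh.write(json.dumps(doc_to_record(doc), ensure_ascii=False) + "\n")


def load_index(directory: str | Path) -> Index:
    directory = Path(directory)
    header = json.loads((directory / "header.json").read_text())
    docs = read_indexed_jsonl(directory / "documents.jsonl")
    return build_index(docs, facet_fields=header["facet_fields"])
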