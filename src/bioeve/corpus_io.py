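"""Document ingestion and storage.

Reads Medline-style XML (plain or gzipped) and plain text into
:class:`Document` records, splits abstracts into offset-anchored
:class:`Sentence` objects with a deterministic rule-based splitter, and keeps
a keyword-accessible in-memory :class:`DocumentStore` that can be persisted
as JSON lines.

All text is normalized to Unicode NFC on read; offsets are 0-based,
half-open, counted in code points.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

from ._resources import abbreviations
from ._tokenize import word_tokens

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "Sentence",
    "DocumentStore",
    "ParseError",
    "DocumentNotFoundError",
    "read_medline_xml",
    "read_plaintext",
    "read_jsonl",
    "split_sentences",
]


class ParseError(ValueError):
    """Raised for malformed XML input; the message names the byte offset."""


class DocumentNotFoundError(KeyError):
    """Raised when a doc_id is absent from a :class:`DocumentStore`."""


@dataclass(frozen=True)
class Document:
    """One abstract: a PubMed citation or a synthetic stand-in."""

    doc_id: str
    title: str
    abstract: str = ""
    source_uri: str | None = None


@dataclass(frozen=True)
class Sentence:
    """A sentence of an abstract, anchored by code-point offsets.

    Invariant: ``abstract[char_start:char_end] == text``.
    """

    doc_id: str
    index: int
    text: str
    char_start: int
    char_end: int


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path: str | Path) -> io.BufferedReader:
    raw = open(path, "rb")
    magic = raw.peek(2)[:2]
    if magic == b"\x1f\x8b":
        return gzip.open(raw)  # type: ignore[return-value]
    return raw


def read_medline_xml(path: str | Path) -> Iterator[Document]:
    """Stream :class:`Document` records from a Medline-style XML file.

    Accepts two dialects: citation elements carrying ``PMID`` /
    ``ArticleTitle`` / ``AbstractText`` descendants (MedlineCitation or
    PubmedArticle wrappers), and a minimal fixture dialect of
    ``<doc id=.. title=.. abstract=../>`` elements.  Citations without an
    abstract yield ``abstract=""``; citations without a PMID are skipped
    with a logged warning.  The file may be gzipped.
    """
    path = Path(path)
    with _open_maybe_gzip(path) as fh:
        try:
            tree = etree.parse(fh)
        except etree.XMLSyntaxError as exc:
            line, col = exc.position
            offset = _byte_offset(path, line, col)
            raise ParseError(
                f"{path}: malformed XML at byte offset {offset} "
                f"(line {line}, column {col}): {exc.msg}"
            ) from exc
    root = tree.getroot()
    citations = root.iter("MedlineCitation")
    found = False
    for cit in citations:
        found = True
        yield from _parse_citation(cit, path)
    if not found:
        for el in root.iter("doc"):
            found = True
            yield from _parse_fixture_doc(el, path)
    if not found and root.tag == "doc":
        yield from _parse_fixture_doc(root, path)


def _byte_offset(path: Path, line: int, col: int) -> int:
    offset = 0
    try:
        with _open_maybe_gzip(path) as fh:
            for _ in range(line - 1):
                offset += len(fh.readline())
    except OSError:
        pass
    return offset + max(col - 1, 0)


def _text_of(el: etree._Element | None) -> str:
    if el is None:
        return ""
    return _nfc("".join(el.itertext()))


def _parse_citation(cit: etree._Element, path: Path) -> Iterator[Document]:
    pmid = cit.findtext("PMID")
    if pmid is None or not pmid.strip():
        logger.warning("%s: citation without PMID skipped", path)
        return
    title = _text_of(cit.find(".//ArticleTitle"))
    parts = [_text_of(a) for a in cit.findall(".//AbstractText")]
    abstract = " ".join(p for p in parts if p)
    yield Document(doc_id=pmid.strip(), title=title, abstract=abstract,
                   source_uri=str(path))


def _parse_fixture_doc(el: etree._Element, path: Path) -> Iterator[Document]:
    doc_id = el.get("id")
    if not doc_id:
        logger.warning("%s: <doc> without id skipped", path)
        return
    yield Document(doc_id=doc_id, title=_nfc(el.get("title", "")),
                   abstract=_nfc(el.get("abstract", "")), source_uri=str(path))


def read_plaintext(path: str | Path) -> Iterator[Document]:
    """Read a one-abstract-per-file plain-text document.

    The file stem is the doc_id, the first line the title, the remainder
    the abstract.
    """
    path = Path(path)
    text = _nfc(path.read_text("utf-8"))
    first, _, rest = text.partition("\n")
    yield Document(doc_id=path.stem, title=first.strip(),
                   abstract=rest.strip(), source_uri=str(path))


def read_jsonl(path: str | Path) -> Iterator[Document]:
    """Read a JSON-lines document dump (doc_id, title, abstract)."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            yield Document(doc_id=str(rec["doc_id"]),
                           title=_nfc(rec.get("title", "")),
                           abstract=_nfc(rec.get("abstract", "")),
                           source_uri=rec.get("source_uri"))


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

_TERMINAL_RE = re.compile(r"[.!?]+")
_SINGLE_LETTER_ABBREV = re.compile(r"^\w\.$", re.UNICODE)


def _is_boundary(text: str, end: int) -> bool:
    """Is the terminal-punctuation run ending at ``end`` a sentence break?"""
    if end >= len(text):
        return False  # end of string closes the last sentence anyway
    if not text[end].isspace():
        return False
    rest = text[end:].lstrip()
    if not rest:
        return False
    if not (rest[0].isupper() or rest[0].isdigit()):
        return False
    if text[end - 1] == ".":
        m = re.search(r"\S+$", text[:end])
        token = m.group().lower() if m else ""
        # strip leading punctuation such as an opening parenthesis
        token = token.lstrip("([{\"'")
        if token in abbreviations() or _SINGLE_LETTER_ABBREV.match(token):
            return False
        m2 = re.search(r"(\S+\s+\S+)$", text[:end])
        if m2 and m2.group(1).lower() in abbreviations():
            return False
    return True


def split_sentences(doc: Document) -> list[Sentence]:
    """Split an abstract into sentences.

    Rule-based: a run of ``.!?`` followed by whitespace and an upper-case
    letter or digit ends a sentence, unless the preceding token is a known
    abbreviation (shipped whitelist) or a single letter followed by a period
    ("E. coli").  Deterministic; empty abstracts give an empty list.
    """
    text = doc.abstract
    cuts = [0]
    for m in _TERMINAL_RE.finditer(text):
        if _is_boundary(text, m.end()):
            cuts.append(m.end())
    cuts.append(len(text))
    sentences: list[Sentence] = []
    for raw_start, raw_end in zip(cuts, cuts[1:]):
        s, e = raw_start, raw_end
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s == e:
            continue
        sentences.append(Sentence(doc_id=doc.doc_id, index=len(sentences),
                                  text=text[s:e], char_start=s, char_end=e))
    return sentences


# ---------------------------------------------------------------------------
# Document store
# ---------------------------------------------------------------------------

@dataclass
class DocumentStore:
    """In-memory document store with exact and keyword access.

    Keeps insertion order; maintains an inverted token index over lowercased
    title+abstract so :meth:`keyword_scan` does not rescan the collection.
    """

    _docs: dict[str, Document] = field(default_factory=dict)
    _token_index: dict[str, list[str]] = field(default_factory=dict)

    def add(self, doc: Document) -> None:
        if doc.doc_id in self._docs:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        self._docs[doc.doc_id] = doc
        for tok in set(word_tokens((doc.title + " " + doc.abstract).lower())):
            self._token_index.setdefault(tok, []).append(doc.doc_id)

    def add_many(self, docs: Iterable[Document]) -> None:
        for doc in docs:
            self.add(doc)

    def get(self, doc_id: str) -> Document:
        try:
            return self._docs[doc_id]
        except KeyError:
            raise DocumentNotFoundError(doc_id) from None

    def keyword_scan(self, term: str) -> list[str]:
        """Doc ids whose lowercased title+abstract contains ``term`` as a token."""
        return list(self._token_index.get(term.lower(), []))

    def __len__(self) -> int:
        return len(self._docs)

    def __iter__(self) -> Iterator[Document]:
        return iter(self._docs.values())

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._docs

    @property
    def doc_ids(self) -> list[str]:
        return list(self._docs)

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = directory / "documents.jsonl"
        with open(out, "w", encoding="utf-8") as fh:
            for doc in self:
                fh.write(json.dumps({
                    "doc_id": doc.doc_id, "title": doc.title,
                    "abstract": doc.abstract, "source_uri": doc.source_uri,
                }, ensure_ascii=False) + "\n")
        return out

    @classmethod
    def load(cls, directory: str | Path) -> "DocumentStore":
        store = cls()
        store.add_many(read_jsonl(Path(directory) / "documents.jsonl"))
        return store


def store_documents(docs: Iterable[Document]) -> DocumentStore:
    """Build a :class:`DocumentStore` from an iterable of documents."""
    store = DocumentStore()
    store.add_many(docs)
    return store
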