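"""Dictionary-based entity tagging.

Replaces the roles of statistical NER tools and curated thesauri with
pluggable lexicons: TSV files mapping a surface form to a canonical id, one
per entity class (gene, chemical, disease, ...).  Tagging is greedy
longest-match over token n-grams, left to right, with matched spans consumed
so mentions never overlap.

Case policy: surfaces of four characters or fewer match exactly (protecting
short symbols like "p53" from "P53" collisions); longer surfaces match
case-insensitively.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from ._tokenize import tokenize_with_offsets
from .corpus_io import Document, DocumentStore, Sentence, split_sentences

logger = logging.getLogger(__name__)

MAX_NGRAM = 6  # longest candidate span, in tokens
CASE_SENSITIVE_MAX_LEN = 4


class EntityClass(str, Enum):
    """Entity classes recognised by the annotator, in priority order."""

    GENE = "gene"
    DNA = "dna"
    RNA = "rna"
    CELL_LINE = "cell_line"
    CELL_TYPE = "cell_type"
    CHEMICAL = "chemical"
    DISEASE = "disease"


_PRIORITY = {cls: i for i, cls in enumerate(EntityClass)}


@dataclass
class Lexicon:
    """Surface form → canonical id map for one entity class."""

    entity_class: EntityClass
    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # Lookup keys folded per the case policy, built once.
        self._exact: dict[str, str] = {}
        self._folded: dict[str, str] = {}
        for surface, canonical in self.entries.items():
            if not surface:
                raise ValueError("empty surface form in lexicon")
            if len(surface) <= CASE_SENSITIVE_MAX_LEN:
                self._exact.setdefault(surface, canonical)
            else:
                self._folded.setdefault(surface.lower(), canonical)

    def lookup(self, candidate: str) -> str | None:
        """Canonical id for ``candidate`` under the case policy, else None."""
        if len(candidate) <= CASE_SENSITIVE_MAX_LEN:
            return self._exact.get(candidate)
        return self._folded.get(candidate.lower())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class EntityMention:
    """A typed span in a sentence; offsets are sentence-local, half-open."""

    doc_id: str
    sentence_index: int
    char_start: int
    char_end: int
    entity_class: EntityClass
    surface: str
    canonical: str


def load_lexicon(path: str | Path, entity_class: EntityClass | str) -> Lexicon:
    """Load a TSV lexicon (``surface[\\tcanonical]`` per row).

    Rows starting with ``#`` are comments.  A missing canonical column
    defaults to the surface form.  Duplicate surfaces keep the first
    canonical (warning logged); malformed (empty-surface) rows are skipped
    with a warning.  An empty lexicon is an error.
    """
    entity_class = EntityClass(entity_class)
    entries: dict[str, str] = {}
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            surface = parts[0].strip()
            if not surface:
                logger.warning("%s:%d: malformed row skipped", path, lineno)
                continue
            canonical = parts[1].strip() if len(parts) > 1 and parts[1].strip() else surface
            if surface in entries:
                logger.warning("%s:%d: duplicate surface %r ignored",
                               path, lineno, surface)
                continue
            entries[surface] = canonical
    if not entries:
        raise ValueError(f"{path}: empty lexicon")
    return Lexicon(entity_class=entity_class, entries=entries)


def annotate_sentence(sentence: Sentence,
                      lexicons: Iterable[Lexicon]) -> list[EntityMention]:
    """Tag a sentence with all lexicons.

    Greedy left-to-right over token n-grams up to :data:`MAX_NGRAM` tokens.
    At each position, candidates from all lexicons compete: entity-class
    priority (gene first, disease last) breaks ties first, then the longer
    span wins within a class.  Matched token spans are consumed, so the
    output never overlaps.
    """
    lexicons = list(lexicons)
    tokens = tokenize_with_offsets(sentence.text)
    mentions: list[EntityMention] = []
    i = 0
    while i < len(tokens):
        best: tuple[int, int, Lexicon, str, int, int] | None = None
        for lex in lexicons:
            for n in range(min(MAX_NGRAM, len(tokens) - i), 0, -1):
                start = tokens[i][1]
                end = tokens[i + n - 1][2]
                candidate = sentence.text[start:end]
                canonical = lex.lookup(candidate)
                if canonical is None:
                    continue
                key = (_PRIORITY[lex.entity_class], -n)
                if best is None or key < (best[0], best[1]):
                    best = (key[0], key[1], lex, canonical, start, end)
                break  # longest n for this lexicon found
        if best is None:
            i += 1
            continue
        _, neg_n, lex, canonical, start, end = best
        mentions.append(EntityMention(
            doc_id=sentence.doc_id, sentence_index=sentence.index,
            char_start=start, char_end=end, entity_class=lex.entity_class,
            surface=sentence.text[start:end], canonical=canonical))
        i += -neg_n
    return mentions


def annotate_document(doc: Document,
                      lexicons: Iterable[Lexicon]) -> list[EntityMention]:
    lexicons = list(lexicons)
    out: list[EntityMention] = []
    for sent in split_sentences(doc):
        out.extend(annotate_sentence(sent, lexicons))
    return out


def annotate_corpus(store: DocumentStore,
                    lexicons: Iterable[Lexicon]) -> dict[str, list[EntityMention]]:
    """Annotate every document in a store (deterministic, idempotent)."""
    lexicons = list(lexicons)
    return {doc.doc_id: annotate_document(doc, lexicons) for doc in store}


# ---------------------------------------------------------------------------
# Stand-off JSON-lines output
# ---------------------------------------------------------------------------

def mention_to_record(m: EntityMention) -> dict:
    return {"doc_id": m.doc_id, "sentence_index": m.sentence_index,
            "start": m.char_start, "end": m.char_end,
            "class": m.entity_class.value, "surface": m.surface,
            "canonical": m.canonical}


def write_annotations(annotations: Mapping[str, list[EntityMention]],
                      path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id in annotations:
            for m in annotations[doc_id]:
                fh.write(json.dumps(mention_to_record(m), ensure_ascii=False) + "\n")
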