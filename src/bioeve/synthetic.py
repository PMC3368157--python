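"""Deterministic synthetic corpora with gold annotations.

Generates abstracts of pseudo-word sentences with planted entity mentions,
per-class event-trigger words, and gold labels/spans, so the ingestion,
tagging, classification, CRF, evaluation and faceting modules are all
testable without any external corpus.

The generator controls exactly the properties the classifiers rely on:

* in disjoint-trigger mode, the background vocabulary, the per-class trigger
  vocabularies, and the entity surfaces are drawn from disjoint word pools,
  so each labeled sentence contains at least one class-unique token and the
  classes are separable by construction;
* every planted span is recorded, giving exact ground truth for recall,
  boundary matching, facet counts, and the frequency ordering of a mined
  trigger-word table;
* a single seed fully determines the output.

Sentences are synthetic token strings, not natural language: the models
under test are bag-of-words/feature driven, so linguistic realism is not
required for correctness testing.

The ``genia-like-small`` preset mimics the scale and structure of a
BioNLP'09-style event corpus at one tenth size: 80/15/26
train/dev/test abstracts at roughly 9.4 sentences per abstract, with the
nine event classes imbalanced in proportions like those of that corpus's
test set (Positive_regulation most frequent, Protein_catabolism rarest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping

import numpy as np
from lxml import etree

from .corpus_io import Document
from .entity_annotation import EntityClass, EntityMention, Lexicon
from .event_classification import (EVENT_TYPES, EventType, LabeledSentence,
                                   TriggerAnnotation)
from .facet_index import IndexedDocument
from .trigger_crf import TriggerSpan, encode_labels

# Event-class imbalance mirroring a BioNLP'09-style test set
# (counts 38, 17, 200, 39, 60, 153, 90, 220, 125 in EVENT_TYPES order).
GENIA_LIKE_CLASS_COUNTS: tuple[int, ...] = (38, 17, 200, 39, 60, 153, 90, 220, 125)

_ENTITY_FACET_FIELD = {
    EntityClass.GENE: "genes",
    EntityClass.DISEASE: "diseases",
    EntityClass.CHEMICAL: "drugs_chemicals",
    EntityClass.CELL_LINE: "cell_lines",
}

PRESETS = ("genia-like-small",)


@dataclass(frozen=True)
class CorpusConfig:
    """Study conditions for one synthetic corpus (or one split of it)."""

    n_docs: int = 20
    sentences_per_doc: tuple[int, int] = (7, 12)
    tokens_per_sentence: tuple[int, int] = (8, 14)
    background_vocab_size: int = 300
    trigger_vocab_size: int = 6           # words per event class
    disjoint_triggers: bool = True
    entity_lexicon_sizes: Mapping[str, int] = field(
        default_factory=lambda: MappingProxyType(
            {"gene": 30, "disease": 20, "chemical": 20}))
    mention_rate: float = 0.8             # expected entity mentions / sentence
    label_noise: float = 0.0
    event_count_probs: tuple[float, float, float] = (0.30, 0.50, 0.20)
    class_weights: tuple[float, ...] | None = None   # None = uniform
    seed: int = 17
    splits: Mapping[str, int] | None = None          # split name -> n_docs

    def validate(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        lo, hi = self.sentences_per_doc
        if not (1 <= lo <= hi):
            raise ValueError("invalid sentences_per_doc range")
        lo, hi = self.tokens_per_sentence
        if not (3 <= lo <= hi):
            raise ValueError("tokens_per_sentence must start at >= 3")
        if self.trigger_vocab_size < 1:
            raise ValueError("trigger_vocab_size must be >= 1")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")
        if self.mention_rate < 0:
            raise ValueError("mention_rate must be >= 0")
        if self.class_weights is not None and len(self.class_weights) != len(EVENT_TYPES):
            raise ValueError("class_weights must have one weight per event class")
        if abs(sum(self.event_count_probs) - 1.0) > 1e-9:
            raise ValueError("event_count_probs must sum to 1")


def scale_preset(name: str) -> CorpusConfig:
    """Named study conditions; currently only ``genia-like-small``."""
    if name != "genia-like-small":
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    # The non-count parameters are calibrated so that, with disjoint trigger
    # vocabularies and zero label noise, the planted trigger word carries
    # more evidence than the largest class-prior gap under Laplace-smoothed
    # TF-IDF naive Bayes: background words recur in most sentences (tiny
    # idf, hence tiny weight), trigger words are concentrated on two words
    # per class, and entity mentions — class-independent, high-idf noise —
    # are kept sparse.  This is what makes the classes separable by
    # construction rather than merely in expectation.
    return CorpusConfig(
        n_docs=80 + 15 + 26,
        splits=MappingProxyType({"train": 80, "dev": 15, "test": 26}),
        sentences_per_doc=(7, 12),
        tokens_per_sentence=(8, 14),
        background_vocab_size=15,
        trigger_vocab_size=2,
        entity_lexicon_sizes=MappingProxyType(
            {"gene": 12, "disease": 8, "chemical": 8}),
        mention_rate=0.3,
        event_count_probs=(0.3, 0.6, 0.1),
        class_weights=tuple(float(c) for c in GENIA_LIKE_CLASS_COUNTS),
    )


# ---------------------------------------------------------------------------
# Corpus containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSentence:
    doc_id: str
    index: int
    tokens: tuple[str, ...]
    text: str
    labels: tuple[EventType, ...]                  # possibly noise-corrupted
    triggers: tuple[TriggerAnnotation, ...]        # character spans (true class)
    trigger_token_spans: tuple[TriggerSpan, ...]   # token spans (true class)
    entities: tuple[EntityMention, ...]


@dataclass
class SyntheticCorpus:
    config: CorpusConfig
    documents: list[Document]
    sentences: list[SyntheticSentence]
    lexicons: dict[EntityClass, Lexicon]
    trigger_vocab: dict[EventType, tuple[str, ...]]

    # -- exports in the other modules' input formats ------------------------

    def labeled_sentences(self) -> list[LabeledSentence]:
        """Event-bearing sentences in the classifier training format."""
        out = []
        for s in self.sentences:
            if not s.labels:
                continue
            genes = tuple((m.char_start, m.char_end) for m in s.entities
                          if m.entity_class is EntityClass.GENE)
            out.append(LabeledSentence(text=s.text, labels=s.labels,
                                       triggers=s.triggers, genes=genes))
        return out

    def bio_sequences(self) -> list[tuple[list[str], list[str]]]:
        """All sentences as (tokens, BIO labels) pairs."""
        return [(list(s.tokens),
                 encode_labels(len(s.tokens), s.trigger_token_spans))
                for s in self.sentences]

    def gold_entities(self) -> dict[str, list[EntityMention]]:
        out: dict[str, list[EntityMention]] = {d.doc_id: [] for d in self.documents}
        for s in self.sentences:
            out[s.doc_id].extend(s.entities)
        return out

    def gold_spans_by_sentence(self) -> dict[str, list[TriggerSpan]]:
        return {f"{s.doc_id}:{s.index}": list(s.trigger_token_spans)
                for s in self.sentences}

    def indexed_documents(self) -> list[IndexedDocument]:
        by_doc: dict[str, dict[str, list[str]]] = {
            d.doc_id: {f: [] for f in _ENTITY_FACET_FIELD.values()}
            for d in self.documents}
        events: dict[str, list[str]] = {d.doc_id: [] for d in self.documents}
        for s in self.sentences:
            for m in s.entities:
                fld = _ENTITY_FACET_FIELD.get(m.entity_class)
                if fld:
                    by_doc[s.doc_id][fld].append(m.canonical)
            events[s.doc_id].extend(l.value for l in s.labels)
        out = []
        for d in self.documents:
            facets = by_doc[d.doc_id]
            out.append(IndexedDocument(
                doc_id=d.doc_id, title=d.title, abstract=d.abstract,
                genes=tuple(dict.fromkeys(facets["genes"])),
                diseases=tuple(dict.fromkeys(facets["diseases"])),
                drugs_chemicals=tuple(dict.fromkeys(facets["drugs_chemicals"])),
                cell_lines=tuple(dict.fromkeys(facets["cell_lines"])),
                event_types=tuple(dict.fromkeys(events[d.doc_id])),
                url=IndexedDocument.pubmed_url(d.doc_id)))
        return out

    def to_medline_xml(self) -> str:
        root = etree.Element("MedlineCitationSet")
        for d in self.documents:
            cit = etree.SubElement(root, "MedlineCitation")
            etree.SubElement(cit, "PMID").text = d.doc_id
            art = etree.SubElement(cit, "Article")
            etree.SubElement(art, "ArticleTitle").text = d.title
            abstract = etree.SubElement(art, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = d.abstract
        return etree.tostring(root, pretty_print=True, xml_declaration=True,
                              encoding="UTF-8").decode("utf-8")

    def lexicon_tsv(self, entity_class: EntityClass) -> str:
        lex = self.lexicons[entity_class]
        return "".join(f"{surface}\t{canonical}\n"
                       for surface, canonical in lex.entries.items())


# ---------------------------------------------------------------------------
# Word pools
# ---------------------------------------------------------------------------

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"


def _make_words(rng: np.random.Generator, n: int,
                taken: set[str]) -> list[str]:
    """Distinct pronounceable pseudo-words (2-4 CV syllables)."""
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError(
                f"cannot generate {n} distinct words (vocabulary too large "
                "for the word space)")
        k = int(rng.integers(2, 5))
        word = "".join(_CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
                       + _VOWELS[int(rng.integers(len(_VOWELS)))]
                       for _ in range(k))
        if word not in taken:
            taken.add(word)
            out.append(word)
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

@dataclass
class _WordPools:
    background: list[str]
    trigger_vocab: dict[EventType, tuple[str, ...]]
    lexicons: dict[EntityClass, Lexicon]


def _make_pools(rng: np.random.Generator, config: CorpusConfig) -> _WordPools:
    taken: set[str] = set()
    background = _make_words(rng, config.background_vocab_size, taken)

    trigger_vocab: dict[EventType, tuple[str, ...]] = {}
    if config.disjoint_triggers:
        for et in EVENT_TYPES:
            trigger_vocab[et] = tuple(
                _make_words(rng, config.trigger_vocab_size, taken))
    else:
        for et in EVENT_TYPES:
            idx = rng.choice(len(background), size=config.trigger_vocab_size,
                             replace=False)
            trigger_vocab[et] = tuple(background[i] for i in sorted(idx))

    lexicons: dict[EntityClass, Lexicon] = {}
    for cls_name, size in config.entity_lexicon_sizes.items():
        cls = EntityClass(cls_name)
        words = _make_words(rng, size + size // 3, taken)
        entries: dict[str, str] = {}
        i = 0
        for j in range(size):
            if rng.random() < 0.3 and i + 1 < len(words) - (size - j - 1):
                surface = f"{words[i]} {words[i + 1]}"
                i += 2
            else:
                surface = words[i]
                i += 1
            entries[surface] = f"{cls.value.upper()}:{j:04d}"
        lexicons[cls] = Lexicon(entity_class=cls, entries=entries)
    return _WordPools(background, trigger_vocab, lexicons)


def generate(config: CorpusConfig,
             rng: np.random.Generator | None = None,
             pools: _WordPools | None = None,
             doc_id_start: int = 9_000_000) -> SyntheticCorpus:
    """Generate one corpus; fully determined by ``config`` (and its seed)."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    pools = pools or _make_pools(rng, config)
    background, trigger_vocab, lexicons = (
        pools.background, pools.trigger_vocab, pools.lexicons)

    class_p = None
    if config.class_weights is not None:
        w = np.asarray(config.class_weights, dtype=float)
        class_p = w / w.sum()

    documents: list[Document] = []
    sentences: list[SyntheticSentence] = []
    entity_classes = list(lexicons)
    for d in range(config.n_docs):
        doc_id = str(doc_id_start + d)
        n_sent = int(rng.integers(config.sentences_per_doc[0],
                                  config.sentences_per_doc[1] + 1))
        title = " ".join(
            background[int(rng.integers(len(background)))]
            for _ in range(4)).capitalize()
        sent_records = []
        for si in range(n_sent):
            sent_records.append(_make_sentence(
                rng, config, doc_id, si, background, trigger_vocab,
                lexicons, entity_classes, class_p))
        abstract = " ".join(s.text for s in sent_records)
        # re-anchor nothing: entity/trigger offsets are sentence-local
        documents.append(Document(doc_id=doc_id, title=title,
                                  abstract=abstract))
        sentences.extend(sent_records)
    return SyntheticCorpus(config=config, documents=documents,
                           sentences=sentences, lexicons=lexicons,
                           trigger_vocab=trigger_vocab)


def _make_sentence(rng: np.random.Generator, config: CorpusConfig,
                   doc_id: str, index: int, background: list[str],
                   trigger_vocab: dict[EventType, tuple[str, ...]],
                   lexicons: dict[EntityClass, Lexicon],
                   entity_classes: list[EntityClass],
                   class_p: np.ndarray | None) -> SyntheticSentence:
    n_bg = int(rng.integers(config.tokens_per_sentence[0],
                            config.tokens_per_sentence[1] + 1))
    # cell tags: ("bg", word) / ("trig", EventType, word) / ("ent", cls, [tokens])
    cells: list[tuple] = [("bg", background[int(rng.integers(len(background)))].capitalize())]
    cells += [("bg", background[int(rng.integers(len(background)))])
              for _ in range(n_bg - 1)]

    n_events = int(rng.choice(3, p=np.asarray(config.event_count_probs)))
    chosen = rng.choice(len(EVENT_TYPES), size=n_events, replace=False,
                        p=class_p) if n_events else []
    true_classes = [EVENT_TYPES[int(c)] for c in chosen]
    for et in true_classes:
        vocab = trigger_vocab[et]
        word = vocab[int(rng.integers(len(vocab)))]
        pos = int(rng.integers(1, len(cells) + 1))
        cells.insert(pos, ("trig", et, word))

    n_mentions = min(int(rng.poisson(config.mention_rate)), 3) \
        if entity_classes else 0
    for _ in range(n_mentions):
        cls = entity_classes[int(rng.integers(len(entity_classes)))]
        surfaces = list(lexicons[cls].entries)
        surface = surfaces[int(rng.integers(len(surfaces)))]
        pos = int(rng.integers(1, len(cells) + 1))
        cells.insert(pos, ("ent", cls, surface.split(" ")))

    # lay out tokens and record spans
    tokens: list[str] = []
    char_pos = 0
    trig_char: list[TriggerAnnotation] = []
    trig_tok: list[TriggerSpan] = []
    ents: list[EntityMention] = []
    for cell in cells:
        start_tok = len(tokens)
        start_char = char_pos if not tokens else char_pos + 1
        if cell[0] == "ent":
            cell_tokens = cell[2]
        else:
            cell_tokens = [cell[-1]]
        for t in cell_tokens:
            if tokens:
                char_pos += 1  # joining space
            tokens.append(t)
            char_pos += len(t)
        if cell[0] == "trig":
            trig_char.append(TriggerAnnotation(start_char, char_pos, cell[1]))
            trig_tok.append(TriggerSpan(start_tok, len(tokens), cell[1]))
        elif cell[0] == "ent":
            cls = cell[1]
            surface = " ".join(cell_tokens)
            ents.append(EntityMention(
                doc_id=doc_id, sentence_index=index, char_start=start_char,
                char_end=char_pos, entity_class=cls, surface=surface,
                canonical=lexicons[cls].entries[surface]))
    text = " ".join(tokens) + "."

    labels: list[EventType] = []
    for et in true_classes:
        if config.label_noise > 0 and rng.random() < config.label_noise:
            others = [c for c in EVENT_TYPES if c is not et]
            labels.append(others[int(rng.integers(len(others)))])
        else:
            labels.append(et)
    return SyntheticSentence(
        doc_id=doc_id, index=index, tokens=tuple(tokens), text=text,
        labels=tuple(labels), triggers=tuple(trig_char),
        trigger_token_spans=tuple(trig_tok), entities=tuple(ents))


def generate_splits(config: CorpusConfig) -> dict[str, SyntheticCorpus]:
    """Generate the configured splits from one seed.

    Word pools (background, triggers, lexicons) are shared across splits —
    a model trained on one split sees the same vocabularies at test time —
    while sentences are drawn independently per split.
    """
    if not config.splits:
        raise ValueError("config has no splits; use generate()")
    rng = np.random.default_rng(config.seed)
    pools = _make_pools(rng, config)
    out: dict[str, SyntheticCorpus] = {}
    for k, (name, n) in enumerate(config.splits.items()):
        split_cfg = CorpusConfig(
            **{**_config_dict(config), "n_docs": n, "splits": None})
        out[name] = generate(split_cfg, rng=rng, pools=pools,
                             doc_id_start=9_000_000 + 100_000 * k)
    return out


def _config_dict(config: CorpusConfig) -> dict:
    return {
        "n_docs": config.n_docs,
        "sentences_per_doc": config.sentences_per_doc,
        "tokens_per_sentence": config.tokens_per_sentence,
        "background_vocab_size": config.background_vocab_size,
        "trigger_vocab_size": config.trigger_vocab_size,
        "disjoint_triggers": config.disjoint_triggers,
        "entity_lexicon_sizes": config.entity_lexicon_sizes,
        "mention_rate": config.mention_rate,
        "label_noise": config.label_noise,
        "event_count_probs": config.event_count_probs,
        "class_weights": config.class_weights,
        "seed": config.seed,
        "splits": config.splits,
    }


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_corpus(corpus: SyntheticCorpus, directory: str | Path,
                 prefix: str = "corpus") -> dict[str, Path]:
    """Write every export format to ``directory``; returns the path map."""
    from .event_classification import write_labeled_jsonl
    from .facet_index import doc_to_record
    from .trigger_crf import write_bio_jsonl
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    xml_path = directory / f"{prefix}.xml"
    xml_path.write_text(corpus.to_medline_xml(), encoding="utf-8")
    paths["medline_xml"] = xml_path

    for cls in corpus.lexicons:
        p = directory / f"{prefix}.lexicon.{cls.value}.tsv"
        p.write_text(corpus.lexicon_tsv(cls), encoding="utf-8")
        paths[f"lexicon_{cls.value}"] = p

    p = directory / f"{prefix}.labeled.jsonl"
    write_labeled_jsonl(corpus.labeled_sentences(), p)
    paths["labeled_jsonl"] = p

    p = directory / f"{prefix}.bio.jsonl"
    write_bio_jsonl(corpus.bio_sequences(), p)
    paths["bio_jsonl"] = p

    p = directory / f"{prefix}.annotated.jsonl"
    with open(p, "w", encoding="utf-8") as fh:
        for doc in corpus.indexed_documents():
            fh.write(json.dumps(doc_to_record(doc), ensure_ascii=False) + "\n")
    paths["annotated_jsonl"] = p
    return paths
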