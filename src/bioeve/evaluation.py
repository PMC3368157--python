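"""Scoring of event classifiers and trigger taggers.

Two granularities:

* sentence level, single label — a prediction is correct when it matches the
  modal gold event of the sentence (any of them, when several tie for the
  maximal multiplicity);
* span level — predicted trigger spans are matched one-to-one against gold
  spans, either exactly (identical token interval and event type) or softly
  (same type, both endpoints within one token of the gold endpoints).

Reports carry per-class precision/recall/F1 in percent plus unweighted
(macro) averages.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .event_classification import EVENT_TYPES, EventType
from .trigger_crf import TriggerSpan

__all__ = [
    "GoldSentence", "PRF", "ClassReport", "BoundaryMode",
    "eval_single_label", "match_boundary", "coverage", "span_prf",
    "report_to_json", "format_report_table",
]


class BoundaryMode(str, Enum):
    EXACT = "exact"
    SOFT = "soft"       # 1-token window on either side of the gold phrase


SOFT_WINDOW = 1


@dataclass(frozen=True)
class GoldSentence:
    sentence_id: str
    events: tuple[EventType, ...]            # multiset, multiplicities >= 1
    trigger_spans: tuple[TriggerSpan, ...] = ()


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "PRF":
        p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        return cls(p, r, f)


@dataclass
class ClassReport:
    per_class: dict[EventType, PRF] = field(default_factory=dict)

    @property
    def macro_precision(self) -> float:
        return self._macro("precision")

    @property
    def macro_recall(self) -> float:
        return self._macro("recall")

    @property
    def macro_f1(self) -> float:
        return self._macro("f1")

    def _macro(self, attr: str) -> float:
        if not self.per_class:
            return 0.0
        vals = [getattr(v, attr) for v in self.per_class.values()]
        return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# Sentence-level, single label
# ---------------------------------------------------------------------------

def modal_events(gold: GoldSentence) -> set[EventType]:
    """Event types tying for the maximal multiplicity in the gold multiset."""
    counts = Counter(gold.events)
    if not counts:
        return set()
    top = max(counts.values())
    return {e for e, c in counts.items() if c == top}


def eval_single_label(predictions: Mapping[str, EventType],
                      gold: Sequence[GoldSentence]
                      ) -> tuple[float, ClassReport]:
    """Score single-label predictions against the modal gold events.

    A prediction is correct iff it equals one of the modal gold events.  The
    per-class report is built from the correctness-resolved confusion: a
    correct prediction counts as (pred, pred); an incorrect one pairs the
    prediction with the first modal gold event in declaration order.
    Missing predictions raise with the offending sentence id.
    """
    tp: Counter = Counter()
    fp: Counter = Counter()
    fn: Counter = Counter()
    n_correct = 0
    for gs in gold:
        if gs.sentence_id not in predictions:
            raise KeyError(f"missing prediction for sentence {gs.sentence_id!r}")
        pred = predictions[gs.sentence_id]
        modal = modal_events(gs)
        if pred in modal:
            n_correct += 1
            tp[pred] += 1
        else:
            fp[pred] += 1
            resolved = next(e for e in EVENT_TYPES if e in modal)
            fn[resolved] += 1
    accuracy = n_correct / len(gold) if gold else 0.0
    present = [c for c in EVENT_TYPES if tp[c] or fp[c] or fn[c]]
    report = ClassReport({c: PRF.from_counts(tp[c], fp[c], fn[c])
                          for c in present})
    return accuracy, report


# ---------------------------------------------------------------------------
# Span boundary matching
# ---------------------------------------------------------------------------

def match_boundary(pred: TriggerSpan, gold: TriggerSpan,
                   mode: BoundaryMode = BoundaryMode.EXACT) -> bool:
    """Does a predicted span match a gold span under the given mode?

    Exact: identical token interval and event type.  Soft: identical event
    type with each endpoint within :data:`SOFT_WINDOW` tokens of gold; every
    exact match is also a soft match.
    """
    if pred.event_type is not gold.event_type:
        return False
    if mode is BoundaryMode.EXACT:
        return pred.start == gold.start and pred.end == gold.end
    return (abs(pred.start - gold.start) <= SOFT_WINDOW
            and abs(pred.end - gold.end) <= SOFT_WINDOW)


def _greedy_match(pred: Sequence[TriggerSpan], gold: Sequence[TriggerSpan],
                  mode: BoundaryMode) -> list[tuple[int, int]]:
    """Greedy one-to-one matching: gold spans in order, first unmatched
    matching prediction wins."""
    used: set[int] = set()
    pairs = []
    for gi, g in enumerate(gold):
        for pi, p in enumerate(pred):
            if pi in used:
                continue
            if match_boundary(p, g, mode):
                used.add(pi)
                pairs.append((pi, gi))
                break
    return pairs


def coverage(pred_by_sentence: Mapping[str, Sequence[TriggerSpan]],
             gold_by_sentence: Mapping[str, Sequence[TriggerSpan]],
             mode: BoundaryMode = BoundaryMode.EXACT) -> float:
    """Percent of gold trigger spans matched one-to-one by predictions."""
    matched = 0
    total = 0
    for sid, gold in gold_by_sentence.items():
        gold = list(gold)
        total += len(gold)
        pred = list(pred_by_sentence.get(sid, ()))
        matched += len(_greedy_match(pred, gold, mode))
    return 100.0 * matched / total if total else 0.0


def span_prf(pred_by_sentence: Mapping[str, Sequence[TriggerSpan]],
             gold_by_sentence: Mapping[str, Sequence[TriggerSpan]],
             mode: BoundaryMode = BoundaryMode.EXACT) -> ClassReport:
    """Per-class span precision/recall/F1 from greedy one-to-one matching."""
    tp: Counter = Counter()
    fp: Counter = Counter()
    fn: Counter = Counter()
    sids = set(gold_by_sentence) | set(pred_by_sentence)
    for sid in sids:
        gold = list(gold_by_sentence.get(sid, ()))
        pred = list(pred_by_sentence.get(sid, ()))
        pairs = _greedy_match(pred, gold, mode)
        matched_p = {pi for pi, _ in pairs}
        matched_g = {gi for _, gi in pairs}
        for pi, gi in pairs:
            tp[gold[gi].event_type] += 1
        for pi, p in enumerate(pred):
            if pi not in matched_p:
                fp[p.event_type] += 1
        for gi, g in enumerate(gold):
            if gi not in matched_g:
                fn[g.event_type] += 1
    present = [c for c in EVENT_TYPES if tp[c] or fp[c] or fn[c]]
    return ClassReport({c: PRF.from_counts(tp[c], fp[c], fn[c])
                        for c in present})


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def report_to_json(report: ClassReport) -> str:
    payload = {
        "per_class": {c.value: {"precision": v.precision, "recall": v.recall,
                                "f1": v.f1}
                      for c, v in report.per_class.items()},
        "macro": {"precision": report.macro_precision,
                  "recall": report.macro_recall, "f1": report.macro_f1},
    }
    return json.dumps(payload, indent=2)


def format_report_table(report: ClassReport,
                        counts: Mapping[EventType, int] | None = None) -> str:
    """Aligned plain-text table: one row per event type plus an Average row."""
    rows = []
    header = f"{'Event type':<22}{'N':>6}{'P':>8}{'R':>8}{'F1':>8}"
    rows.append(header)
    rows.append("-" * len(header))
    for c in EVENT_TYPES:
        if c not in report.per_class:
            continue
        v = report.per_class[c]
        n = str(counts.get(c, "")) if counts else ""
        rows.append(f"{c.value.replace('_', ' '):<22}{n:>6}"
                    f"{v.precision:>8.1f}{v.recall:>8.1f}{v.f1:>8.1f}")
    rows.append("-" * len(header))
    rows.append(f"{'Average':<22}{'':>6}{report.macro_precision:>8.1f}"
                f"{report.macro_recall:>8.1f}{report.macro_f1:>8.1f}")
    return "\n".join(rows)
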