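"""End-to-end study runs on the synthetic preset.

Each function generates the ``genia-like-small`` corpus splits for a seed,
runs one component of the pipeline from scratch, and measures it against the
generator's gold record.  These runs back both the acceptance checks and the
reproduction script; nothing here reads any external resource.

The classifier runs use the trigger-boosted bag-of-words features (the
feature set the sentence classifiers are designed around); the CRF run uses
the per-class trigger dictionaries as lexicon-membership features, mirroring
the trigger-phrase-dictionary resource a sequence tagger of this kind is
customarily given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluation as ev
from . import event_classification as ec
from . import facet_index as fx
from . import trigger_crf as tc
from .entity_annotation import annotate_corpus
from .corpus_io import store_documents
from .synthetic import (CorpusConfig, SyntheticCorpus, _config_dict, generate,
                        generate_splits, scale_preset)


def preset_splits(seed: int) -> dict[str, SyntheticCorpus]:
    base = _config_dict(scale_preset("genia-like-small"))
    base["seed"] = int(seed)
    return generate_splits(CorpusConfig(**base))


def _single_label_accuracy(model, test: list[ec.LabeledSentence]) -> float:
    preds = {str(i): ec.predict_nb(model, ls) for i, ls in enumerate(test)}
    gold = [ev.GoldSentence(str(i), ls.labels) for i, ls in enumerate(test)]
    return ev.eval_single_label(preds, gold)[0]


def nb_run(seed: int) -> dict:
    """Train naive Bayes on the train split, score on the test split."""
    splits = preset_splits(seed)
    train = splits["train"].labeled_sentences()
    test = splits["test"].labeled_sentences()
    model = ec.train_nb(train, features=ec.FeatureVariant.BOW_TRIGGER)
    return {"accuracy": _single_label_accuracy(model, test), "n": len(test)}


def maxent_run(seed: int) -> dict:
    """Train MaxEnt on the train split; measure training-set accuracy
    (multi-label prediction must contain a gold label) and test accuracy."""
    splits = preset_splits(seed)
    train = splits["train"].labeled_sentences()
    test = splits["test"].labeled_sentences()
    model = ec.train_maxent(train, features=ec.FeatureVariant.BOW_TRIGGER)
    def hit(ls):
        return bool(set(ls.labels) & ec.predict_multilabel(model, ls))
    return {"train_accuracy": float(np.mean([hit(ls) for ls in train])),
            "test_accuracy": float(np.mean([hit(ls) for ls in test])),
            "n": len(train)}


def nb_em_run(seed: int, labeled_fraction: float = 0.1) -> dict:
    """Semi-supervised run: a fraction of train labeled, the rest unlabeled."""
    splits = preset_splits(seed)
    train = splits["train"].labeled_sentences()
    test = splits["test"].labeled_sentences()
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(train))
    n_lab = max(9, int(len(train) * labeled_fraction))
    labeled = [train[i] for i in idx[:n_lab]]
    unlabeled = [train[i].text for i in idx[n_lab:]]
    nb = ec.train_nb(labeled, features=ec.FeatureVariant.BOW_TRIGGER)
    em = ec.train_nb_em(labeled, unlabeled,
                        features=ec.FeatureVariant.BOW_TRIGGER)
    return {"nb_small_accuracy": _single_label_accuracy(nb, test),
            "em_accuracy": _single_label_accuracy(em, test),
            "monotone": all(b >= a - 1e-9 for a, b in zip(
                em.objective_history, em.objective_history[1:])),
            "n": len(test)}


def crf_run(seed: int) -> dict:
    """Train the trigger CRF on the train split, score spans on test."""
    splits = preset_splits(seed)
    tr, te = splits["train"], splits["test"]
    lexicons = {f"trigger_{et.value}": set(words)
                for et, words in tr.trigger_vocab.items()}
    train_seqs = [(tc.extract_features(tokens, lexicons=lexicons), labels)
                  for tokens, labels in tr.bio_sequences()]
    model = tc.train_crf(train_seqs)
    pred, gold = {}, {}
    for i, (tokens, labels) in enumerate(te.bio_sequences()):
        obs = tc.extract_features(tokens, lexicons=lexicons)
        pred[str(i)] = tc.decode_spans(tokens, tc.viterbi_tag(model, obs))
        gold[str(i)] = tc.decode_spans(tokens, labels)
    report = ev.span_prf(pred, gold, ev.BoundaryMode.EXACT)
    n_gold = sum(len(v) for v in gold.values())
    return {
        "exact_f1": report.macro_f1,
        "exact_coverage": ev.coverage(pred, gold, ev.BoundaryMode.EXACT),
        "soft_coverage": ev.coverage(pred, gold, ev.BoundaryMode.SOFT),
        "n": n_gold,
    }


def entity_run(seed: int) -> dict:
    """Dictionary NER against the generator's planted mentions."""
    corpus = generate(CorpusConfig(n_docs=20, seed=seed))
    store = store_documents(corpus.documents)
    found = annotate_corpus(store, corpus.lexicons.values())
    gold = corpus.gold_entities()
    def key(m):
        return (m.doc_id, m.sentence_index, m.char_start, m.char_end,
                m.entity_class, m.canonical)
    got = {key(m) for ms in found.values() for m in ms}
    want = {key(m) for ms in gold.values() for m in ms}
    recall = len(got & want) / len(want) if want else 1.0
    precision = len(got & want) / len(got) if got else 1.0
    return {"recall": recall, "precision": precision, "n": len(want)}


@dataclass
class WalkthroughResult:
    term: str
    gene: str
    disease: str
    totals: tuple[int, int, int]
    cloud_consistent: bool


def walkthrough_run(seed: int, n_docs: int = 30) -> WalkthroughResult:
    """The query → gene refine → disease refine navigation chain.

    Finds the first (term, gene, disease) chain, in deterministic order,
    whose hit totals strictly decrease to a non-empty final set, and checks
    that every tag-cloud count reproduces itself when clicked.
    """
    corpus = generate(CorpusConfig(n_docs=n_docs, seed=seed))
    index = fx.build_index(corpus.indexed_documents())
    vocab = sorted(index.postings)
    for term in vocab:
        q0 = fx.Query(terms=(term,))
        r0 = fx.search(index, q0)
        if not 0 < r0.total < len(index.docs):
            continue
        for gene, g_count in sorted(r0.facet_counts["genes"].items()):
            if not 0 < g_count < r0.total:
                continue
            q1 = fx.refine(q0, "genes", gene)
            r1 = fx.search(index, q1)
            for disease, d_count in sorted(r1.facet_counts["diseases"].items()):
                if not 0 < d_count < r1.total:
                    continue
                q2 = fx.refine(q1, "diseases", disease)
                r2 = fx.search(index, q2)
                consistent = True
                for result, query in ((r0, q0), (r1, q1), (r2, q2)):
                    for fld, counts in result.facet_counts.items():
                        for value, count in counts.items():
                            clicked = fx.search(
                                index, fx.refine(query, fld, value))
                            if clicked.total != count:
                                consistent = False
                return WalkthroughResult(
                    term=term, gene=gene, disease=disease,
                    totals=(r0.total, r1.total, r2.total),
                    cloud_consistent=consistent)
    raise RuntimeError("no strictly narrowing navigation chain found")
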