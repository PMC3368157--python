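"""Sentence-level biomolecular event-type classification.

Sentences are mapped onto nine event classes (the BioNLP'09 shared-task
scheme: Gene_expression, Transcription, ..., Negative_regulation) from
TF-IDF bag-of-words features, optionally with gene-name and trigger-word
boosting:

* gene tokens are collapsed into a single renamed feature (``"protein"``)
  whose weight is multiplied by a boost factor (default 2.0);
* tokens found in a per-class trigger-word table (mined from training
  triggers, stop words removed, ordered by frequency) are likewise boosted.

Three classifier families are provided: a single-label multinomial naive
Bayes, a semi-supervised naive Bayes trained with EM over unlabeled
sentences (multi-label output), and a MaxEnt (softmax regression) model
optimized by L-BFGS on the L2-penalized conditional log-likelihood.

Conventions fixed here so results are exactly reproducible: tokens are
lowercased and must start with a letter (so "−300" is dropped but "p55"
kept); one sentence is one document for idf purposes, idf(t) = ln(N/df(t));
vectors are L2-normalized; boosting happens after normalization and the
vector is then re-normalized; naive Bayes uses Laplace (+1) smoothing over
the (fractional) TF-IDF class totals.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.special import logsumexp

from ._resources import stopwords as _default_stopwords

logger = logging.getLogger(__name__)

FeatureVector = dict[str, float]


class EventType(Enum):
    """The nine biomolecular event classes.

    Declaration order is the tie-break order used by every classifier.
    """

    Phosphorylation = "Phosphorylation"
    Protein_catabolism = "Protein_catabolism"
    Gene_expression = "Gene_expression"
    Localization = "Localization"
    Transcription = "Transcription"
    Binding = "Binding"
    Regulation = "Regulation"
    Positive_regulation = "Positive_regulation"
    Negative_regulation = "Negative_regulation"


EVENT_TYPES: tuple[EventType, ...] = tuple(EventType)
N_CLASSES = len(EVENT_TYPES)
_CLASS_INDEX = {c: i for i, c in enumerate(EVENT_TYPES)}


class FeatureVariant(str, Enum):
    BOW = "bow"
    BOW_GENE = "bow+gene"
    BOW_TRIGGER = "bow+trigger"
    BOW_GENE_TRIGGER = "bow+gene+trigger"
    #: Part-of-speech tagged bag of words; hook only, no tagger is shipped.
    BOW_POS = "bow+pos"


@dataclass(frozen=True)
class TriggerAnnotation:
    """A gold trigger span (character offsets into the sentence)."""

    start: int
    end: int
    event_type: EventType


@dataclass(frozen=True)
class LabeledSentence:
    """A training sentence with event labels, trigger spans and gene spans."""

    text: str
    labels: tuple[EventType, ...]
    triggers: tuple[TriggerAnnotation, ...] = ()
    genes: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class BoostConfig:
    gene_boost_factor: float = 2.0
    trigger_boost_factor: float = 2.0
    gene_rename: str = "protein"

    def __post_init__(self) -> None:
        if self.gene_boost_factor < 1 or self.trigger_boost_factor < 1:
            raise ValueError("boost factors must be >= 1")


# ---------------------------------------------------------------------------
# Tokenization and TF-IDF
# ---------------------------------------------------------------------------

def tokenize_and_filter(text: str) -> list[str]:
    """Lowercased tokens whose first character is a letter.

    Tokens are whitespace-delimited with surrounding punctuation stripped
    (internal hyphens survive), then filtered so that e.g. "−300" is dropped
    while "p55" is retained.
    """
    out: list[str] = []
    for raw in text.split():
        start, end = 0, len(raw)
        while start < end and not raw[start].isalnum():
            start += 1
        while end > start and not raw[end - 1].isalnum():
            end -= 1
        tok = raw[start:end]
        if tok and tok[0].isalpha():
            out.append(tok.lower())
    return out


@dataclass
class TfidfModel:
    """idf table fit on a training corpus (one sentence = one document)."""

    idf: dict[str, float]
    n_docs: int


def fit_tfidf(corpus: Iterable[str]) -> TfidfModel:
    """Fit idf(t) = ln(N / df(t)) over tokenized-and-filtered sentences."""
    docs = [tokenize_and_filter(s) for s in corpus]
    if not docs:
        raise ValueError("cannot fit TF-IDF on an empty corpus")
    n = len(docs)
    df: dict[str, int] = {}
    for toks in docs:
        for t in set(toks):
            df[t] = df.get(t, 0) + 1
    return TfidfModel(idf={t: float(np.log(n / d)) for t, d in df.items()},
                      n_docs=n)


def _l2_normalize(vec: FeatureVector) -> FeatureVector:
    norm = float(np.sqrt(sum(w * w for w in vec.values())))
    if norm == 0.0:
        return {}
    return {t: w / norm for t, w in vec.items()}


def vectorize(model: TfidfModel, sentence: str) -> FeatureVector:
    """L2-normalized TF-IDF vector; out-of-vocabulary tokens get weight 0."""
    if model is None:
        raise ValueError("vectorize called before fit")
    counts: dict[str, int] = {}
    for t in tokenize_and_filter(sentence):
        counts[t] = counts.get(t, 0) + 1
    vec = {t: c * model.idf[t] for t, c in counts.items()
           if t in model.idf and model.idf[t] > 0.0}
    return _l2_normalize(vec)


# ---------------------------------------------------------------------------
# Trigger lexicon and boosting
# ---------------------------------------------------------------------------

@dataclass
class TriggerLexicon:
    """Per-class trigger words, ordered by descending frequency then lexicographically."""

    by_class: dict[EventType, list[tuple[str, int]]] = field(default_factory=dict)

    def words(self) -> frozenset[str]:
        return frozenset(w for lst in self.by_class.values() for w, _ in lst)

    def class_words(self, event_type: EventType) -> list[str]:
        return [w for w, _ in self.by_class.get(event_type, [])]


def build_trigger_lexicon(training: Iterable[LabeledSentence],
                          stop_words: Iterable[str] | None = None) -> TriggerLexicon:
    """Mine per-class trigger words from gold trigger spans.

    Trigger phrases are tokenized with the classifier tokenizer; stop words
    are removed; within each class words are ordered by descending frequency
    with lexicographic tie-break.
    """
    stop = frozenset(stop_words) if stop_words is not None else _default_stopwords()
    counts: dict[EventType, dict[str, int]] = {}
    empty = True
    for ls in training:
        empty = False
        for trig in ls.triggers:
            for tok in tokenize_and_filter(ls.text[trig.start:trig.end]):
                if tok in stop:
                    continue
                per = counts.setdefault(trig.event_type, {})
                per[tok] = per.get(tok, 0) + 1
    if empty:
        logger.warning("build_trigger_lexicon: empty training data")
    by_class = {
        cls: sorted(per.items(), key=lambda kv: (-kv[1], kv[0]))
        for cls, per in counts.items()
    }
    return TriggerLexicon(by_class=by_class)


def apply_boosting(vec: FeatureVector,
                   gene_tokens: Iterable[str] = (),
                   trigger_words: Iterable[str] = (),
                   cfg: BoostConfig | None = None) -> FeatureVector:
    """Boost gene and trigger features, then re-normalize to unit L2 norm.

    Gene tokens are removed from the vector; their summed weight is added to
    the single renamed feature ``cfg.gene_rename``, which is then multiplied
    by ``gene_boost_factor``.  Tokens in ``trigger_words`` are multiplied by
    ``trigger_boost_factor``.  Gene tokens absent from the vector are
    ignored with a warning.
    """
    cfg = cfg or BoostConfig()
    out = dict(vec)
    gene_sum = 0.0
    seen_gene = False
    for g in {t.lower() for t in gene_tokens}:
        if g in out:
            gene_sum += out.pop(g)
            seen_gene = True
        else:
            logger.warning("apply_boosting: gene token %r not in vector", g)
    if seen_gene:
        out[cfg.gene_rename] = (out.get(cfg.gene_rename, 0.0) + gene_sum) \
            * cfg.gene_boost_factor
    trigger_set = set(trigger_words)
    for t in list(out):
        if t in trigger_set and t != cfg.gene_rename:
            out[t] *= cfg.trigger_boost_factor
    return _l2_normalize(out)


def _gene_tokens_of(ls: LabeledSentence) -> set[str]:
    toks: set[str] = set()
    for start, end in ls.genes:
        toks.update(tokenize_and_filter(ls.text[start:end]))
    return toks


def featurize(tfidf: TfidfModel, sentence: "str | LabeledSentence",
              variant: FeatureVariant = FeatureVariant.BOW,
              trigger_lexicon: TriggerLexicon | None = None,
              boost: BoostConfig | None = None) -> FeatureVector:
    """Full feature pipeline: vectorize, then boost per the feature variant."""
    if variant is FeatureVariant.BOW_POS:
        raise NotImplementedError(
            "part-of-speech features require an external tagger")
    text = sentence if isinstance(sentence, str) else sentence.text
    vec = vectorize(tfidf, text)
    if variant is FeatureVariant.BOW:
        return vec
    genes: Iterable[str] = ()
    triggers: Iterable[str] = ()
    if variant in (FeatureVariant.BOW_GENE, FeatureVariant.BOW_GENE_TRIGGER) \
            and not isinstance(sentence, str):
        genes = {t for t in _gene_tokens_of(sentence) if t in vec}
    if variant in (FeatureVariant.BOW_TRIGGER, FeatureVariant.BOW_GENE_TRIGGER):
        if trigger_lexicon is None:
            raise ValueError(f"variant {variant.value} requires a trigger lexicon")
        triggers = trigger_lexicon.words()
    return apply_boosting(vec, genes, triggers, boost)


# ---------------------------------------------------------------------------
# Shared model plumbing
# ---------------------------------------------------------------------------

@dataclass
class _FeaturePipeline:
    tfidf: TfidfModel
    variant: FeatureVariant
    trigger_lexicon: TriggerLexicon | None
    boost: BoostConfig
    feature_index: dict[str, int]

    def vector(self, sentence: "str | LabeledSentence") -> FeatureVector:
        return featurize(self.tfidf, sentence, self.variant,
                         self.trigger_lexicon, self.boost)

    def row(self, sentence: "str | LabeledSentence") -> tuple[list[int], list[float]]:
        vec = self.vector(sentence)
        idx, val = [], []
        for t, w in vec.items():
            j = self.feature_index.get(t)
            if j is not None:
                idx.append(j)
                val.append(w)
        return idx, val


def _build_pipeline(training: Sequence[LabeledSentence],
                    variant: FeatureVariant,
                    boost: BoostConfig | None,
                    trigger_lexicon: TriggerLexicon | None,
                    extra_corpus: Sequence[str] = ()) -> tuple[_FeaturePipeline, sp.csr_matrix]:
    boost = boost or BoostConfig()
    if trigger_lexicon is None and variant in (
            FeatureVariant.BOW_TRIGGER, FeatureVariant.BOW_GENE_TRIGGER):
        trigger_lexicon = build_trigger_lexicon(training)
    texts = [ls.text for ls in training] + list(extra_corpus)
    tfidf = fit_tfidf(texts)
    vectors = [featurize(tfidf, ls, variant, trigger_lexicon, boost)
               for ls in training]
    vocab = sorted({t for v in vectors for t in v})
    feature_index = {t: j for j, t in enumerate(vocab)}
    pipe = _FeaturePipeline(tfidf, variant, trigger_lexicon, boost, feature_index)
    X = _rows_to_csr(vectors, feature_index)
    return pipe, X


def _rows_to_csr(vectors: Sequence[FeatureVector],
                 feature_index: dict[str, int]) -> sp.csr_matrix:
    data, indices, indptr = [], [], [0]
    for vec in vectors:
        for t, w in sorted(vec.items()):
            j = feature_index.get(t)
            if j is not None:
                indices.append(j)
                data.append(w)
        indptr.append(len(indices))
    return sp.csr_matrix((data, indices, indptr),
                         shape=(len(vectors), len(feature_index)))


def _first_label(ls: LabeledSentence) -> EventType:
    if not ls.labels:
        raise ValueError("training sentence without a label")
    return ls.labels[0]


# ---------------------------------------------------------------------------
# Naive Bayes
# ---------------------------------------------------------------------------

@dataclass
class NBModel:
    """Multinomial naive Bayes over TF-IDF weights with Laplace smoothing."""

    pipeline: _FeaturePipeline
    classes: tuple[EventType, ...]
    log_prior: np.ndarray          # (K,); -inf for classes never seen
    log_theta: np.ndarray          # (K, V)
    objective_history: list[float] = field(default_factory=list)
    loglik_history: list[float] = field(default_factory=list)

    def _scores(self, sentence: "str | LabeledSentence") -> np.ndarray:
        idx, val = self.pipeline.row(sentence)
        scores = self.log_prior.copy()
        if idx:
            scores = scores + self.log_theta[:, idx] @ np.asarray(val)
        return scores

    def posterior(self, sentence: "str | LabeledSentence") -> np.ndarray:
        scores = self._scores(sentence)
        with np.errstate(invalid="ignore"):
            return np.exp(scores - logsumexp(scores))


def _nb_from_responsibilities(pipe: _FeaturePipeline, X: sp.csr_matrix,
                              resp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """M-step: class priors (MLE) and Laplace-smoothed feature log-likelihoods."""
    n, v = X.shape
    class_mass = resp.sum(axis=0)                      # (K,)
    with np.errstate(divide="ignore"):
        log_prior = np.log(class_mass / n)
    counts = np.asarray(resp.T @ X)                    # (K, V) fractional
    theta = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + v)
    return log_prior, np.log(theta)


def _one_hot(labels: Sequence[EventType]) -> np.ndarray:
    resp = np.zeros((len(labels), N_CLASSES))
    for i, lab in enumerate(labels):
        resp[i, _CLASS_INDEX[lab]] = 1.0
    return resp


def train_nb(training: Sequence[LabeledSentence],
             features: FeatureVariant = FeatureVariant.BOW,
             trigger_lexicon: TriggerLexicon | None = None,
             boost: BoostConfig | None = None) -> NBModel:
    """Train the single-label naive Bayes classifier.

    Multi-label sentences contribute their first label only.
    """
    training = list(training)
    pipe, X = _build_pipeline(training, features, boost, trigger_lexicon)
    resp = _one_hot([_first_label(ls) for ls in training])
    log_prior, log_theta = _nb_from_responsibilities(pipe, X, resp)
    return NBModel(pipeline=pipe, classes=EVENT_TYPES,
                   log_prior=log_prior, log_theta=log_theta)


def predict_nb(model: NBModel, sentence: "str | LabeledSentence") -> EventType:
    """Argmax-posterior class; ties go to declaration order."""
    scores = model._scores(sentence)
    return model.classes[int(np.argmax(scores))]


def predict_multilabel(model: "NBModel | MaxEntModel",
                       sentence: "str | LabeledSentence") -> set[EventType]:
    """Classes whose posterior clears max(1/K, half the top posterior)."""
    p = model.posterior(sentence)
    theta = max(1.0 / len(model.classes), float(p.max()) / 2.0)
    return {c for c, pc in zip(model.classes, p) if pc >= theta}


# ---------------------------------------------------------------------------
# Semi-supervised naive Bayes (EM)
# ---------------------------------------------------------------------------

def train_nb_em(labeled: Sequence[LabeledSentence],
                unlabeled: Sequence[str] = (),
                max_iter: int = 50,
                tol: float = 1e-4,
                features: FeatureVariant = FeatureVariant.BOW,
                trigger_lexicon: TriggerLexicon | None = None,
                boost: BoostConfig | None = None) -> NBModel:
    """Semi-supervised naive Bayes.

    Initializes on the labeled sentences, then alternates the E-step
    (posterior responsibilities on the unlabeled set) and M-step
    (re-estimation with fractional counts) until the MAP objective —
    observed-data log-likelihood plus the Dirichlet log-prior implied by
    Laplace smoothing — improves by less than ``tol``.  The objective is
    non-decreasing across iterations; with no unlabeled data the model
    equals :func:`train_nb` on the labeled set.
    """
    labeled = list(labeled)
    if not labeled:
        raise ValueError("train_nb_em requires labeled sentences")
    unlabeled = list(unlabeled)
    pipe, Xl = _build_pipeline(labeled, features, boost, trigger_lexicon,
                               extra_corpus=unlabeled)
    y_l = np.asarray([_CLASS_INDEX[_first_label(ls)] for ls in labeled])
    resp_l = _one_hot([_first_label(ls) for ls in labeled])
    vectors_u = [featurize(pipe.tfidf, s, pipe.variant, pipe.trigger_lexicon,
                           pipe.boost) for s in unlabeled]
    Xu = _rows_to_csr(vectors_u, pipe.feature_index)
    X = sp.vstack([Xl, Xu]).tocsr() if unlabeled else Xl

    log_prior, log_theta = _nb_from_responsibilities(pipe, Xl, resp_l)
    model = NBModel(pipeline=pipe, classes=EVENT_TYPES,
                    log_prior=log_prior, log_theta=log_theta)
    if not unlabeled:
        return model

    def scores_matrix() -> np.ndarray:
        return log_prior[None, :] + X @ log_theta.T  # (N, K) joint log p(x, c)

    prev = -np.inf
    for _ in range(max_iter):
        joint = scores_matrix()
        # E-step on the unlabeled block
        ju = joint[len(labeled):]
        log_z = logsumexp(ju, axis=1)
        resp_u = np.exp(ju - log_z[:, None])
        # Observed-data log-likelihood + Dirichlet(2) log-prior on theta (MAP EM)
        jl = joint[:len(labeled)]
        ll = float(jl[np.arange(len(labeled)), y_l].sum() + log_z.sum())
        objective = ll + float(log_theta.sum())
        if not np.isfinite(objective):
            raise RuntimeError(
                f"EM objective became non-finite ({objective}); "
                "check for empty classes or degenerate features")
        model.loglik_history.append(ll)
        model.objective_history.append(objective)
        if objective - prev < tol and np.isfinite(prev):
            break
        prev = objective
        resp = np.vstack([resp_l, resp_u])
        log_prior, log_theta = _nb_from_responsibilities(pipe, X, resp)
    model.log_prior, model.log_theta = log_prior, log_theta
    return model


# ---------------------------------------------------------------------------
# MaxEnt (softmax regression)
# ---------------------------------------------------------------------------

@dataclass
class MaxEntModel:
    """Multinomial logistic regression with a Gaussian (L2) prior."""

    pipeline: _FeaturePipeline
    classes: tuple[EventType, ...]
    weights: np.ndarray            # (K, V + 1); last column is the bias
    converged: bool = True

    def _scores(self, sentence: "str | LabeledSentence") -> np.ndarray:
        idx, val = self.pipeline.row(sentence)
        scores = self.weights[:, -1].copy()
        if idx:
            scores = scores + self.weights[:, idx] @ np.asarray(val)
        return scores

    def posterior(self, sentence: "str | LabeledSentence") -> np.ndarray:
        s = self._scores(sentence)
        return np.exp(s - logsumexp(s))


def maxent_objective(w_flat: np.ndarray, X: sp.csr_matrix, y: np.ndarray,
                     sigma2: float, n_classes: int = N_CLASSES
                     ) -> tuple[float, np.ndarray]:
    """Penalized negative conditional log-likelihood and its gradient.

    ``X`` must already carry the bias column; the Gaussian prior with
    variance ``sigma2`` penalizes every parameter.
    """
    n, d = X.shape
    W = w_flat.reshape(n_classes, d)
    scores = X @ W.T                                    # (n, K)
    log_z = logsumexp(scores, axis=1)
    nll = float(log_z.sum() - scores[np.arange(n), y].sum())
    p = np.exp(scores - log_z[:, None])
    p[np.arange(n), y] -= 1.0
    grad = np.asarray(p.T @ X)                          # (K, d)
    nll += float((W * W).sum()) / (2.0 * sigma2)
    grad += W / sigma2
    return nll, grad.ravel()


def _with_bias(X: sp.csr_matrix) -> sp.csr_matrix:
    ones = np.ones((X.shape[0], 1))
    return sp.hstack([X, sp.csr_matrix(ones)]).tocsr()


def train_maxent(training: Sequence[LabeledSentence],
                 features: FeatureVariant = FeatureVariant.BOW,
                 trigger_lexicon: TriggerLexicon | None = None,
                 boost: BoostConfig | None = None,
                 sigma2: float = 1.0,
                 max_iter: int = 200,
                 tol: float = 1e-5) -> MaxEntModel:
    """Train the MaxEnt classifier by L-BFGS.

    Multi-label sentences are reduced to one training instance per label.
    If the optimizer does not reach the gradient tolerance within
    ``max_iter`` iterations the best iterate is returned with a warning.
    """
    training = list(training)
    if not training:
        raise ValueError("train_maxent requires training sentences")
    expanded: list[LabeledSentence] = []
    y: list[int] = []
    for ls in training:
        if not ls.labels:
            raise ValueError("training sentence without a label")
        for lab in ls.labels:
            expanded.append(replace(ls, labels=(lab,)))
            y.append(_CLASS_INDEX[lab])
    pipe, X = _build_pipeline(expanded, features, boost, trigger_lexicon)
    Xb = _with_bias(X)
    y_arr = np.asarray(y)
    d = Xb.shape[1]
    res = scipy.optimize.minimize(
        maxent_objective, np.zeros(N_CLASSES * d), jac=True,
        args=(Xb, y_arr, sigma2), method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "maxfun": 10 * max_iter})
    grad_norm = float(np.linalg.norm(res.jac, ord=np.inf))
    converged = grad_norm <= 10 * tol or res.success
    if not converged:
        warnings.warn(f"MaxEnt did not converge (grad inf-norm {grad_norm:.2e})",
                      RuntimeWarning, stacklevel=2)
    return MaxEntModel(pipeline=pipe, classes=EVENT_TYPES,
                       weights=res.x.reshape(N_CLASSES, d), converged=converged)


@dataclass(frozen=True)
class MultiLabelPrediction:
    labels: frozenset[EventType]
    probabilities: dict[EventType, float]


def predict_maxent(model: MaxEntModel,
                   sentence: "str | LabeledSentence") -> MultiLabelPrediction:
    p = model.posterior(sentence)
    probs = {c: float(pc) for c, pc in zip(model.classes, p)}
    return MultiLabelPrediction(labels=frozenset(predict_multilabel(model, sentence)),
                                probabilities=probs)


# ---------------------------------------------------------------------------
# I/O: JSON-lines and standoff training data
# ---------------------------------------------------------------------------

def labeled_to_record(ls: LabeledSentence) -> dict:
    return {"text": ls.text,
            "labels": [l.value for l in ls.labels],
            "triggers": [{"start": t.start, "end": t.end,
                          "type": t.event_type.value} for t in ls.triggers],
            "genes": [list(g) for g in ls.genes]}


def record_to_labeled(rec: dict) -> LabeledSentence:
    return LabeledSentence(
        text=rec["text"],
        labels=tuple(EventType(l) for l in rec.get("labels", [])),
        triggers=tuple(TriggerAnnotation(t["start"], t["end"],
                                         EventType(t["type"]))
                       for t in rec.get("triggers", [])),
        genes=tuple((int(a), int(b)) for a, b in rec.get("genes", [])))


def read_labeled_jsonl(path: str | Path) -> list[LabeledSentence]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(record_to_labeled(json.loads(line)))
    return out


def write_labeled_jsonl(sentences: Iterable[LabeledSentence],
                        path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ls in sentences:
            fh.write(json.dumps(labeled_to_record(ls), ensure_ascii=False) + "\n")


def read_standoff(text_path: str | Path, ann_path: str | Path) -> list[LabeledSentence]:
    """Read paired text + standoff trigger annotations into labeled sentences.

    The annotation file carries tab-separated lines
    ``T<id>\\t<EventType> <start> <end>\\t<surface>`` with character offsets
    into the raw text.  The text is split into sentences; each trigger is
    assigned to the sentence containing it and re-based to sentence-local
    offsets; a sentence's label set is the set of its trigger types.
    Sentences without triggers are omitted.
    """
    from .corpus_io import Document, split_sentences

    text = Path(text_path).read_text("utf-8")
    triggers: list[tuple[int, int, EventType]] = []
    with open(ann_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or not line.startswith("T"):
                continue
            _, meta = line.split("\t", 2)[:2]
            etype, start, end = meta.rsplit(" ", 2)
            triggers.append((int(start), int(end), EventType(etype)))
    doc = Document(doc_id=Path(text_path).stem, title="", abstract=text)
    out: list[LabeledSentence] = []
    for sent in split_sentences(doc):
        local = [TriggerAnnotation(s - sent.char_start, e - sent.char_start, t)
                 for s, e, t in triggers
                 if s >= sent.char_start and e <= sent.char_end]
        if not local:
            continue
        labels = tuple(dict.fromkeys(t.event_type for t in local))
        out.append(LabeledSentence(text=sent.text, labels=labels,
                                   triggers=tuple(local)))
    return out
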