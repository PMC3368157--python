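"""Linear-chain CRF for event-trigger phrase tagging.

Tokens are labeled with a BIO scheme over the nine event classes (19 labels:
``O`` plus ``B-T``/``I-T`` per type).  Each token is described by a set of
indicator features: 17 named orthographic/affix indicators (case shape,
digit shape, hyphen position, punctuation, Roman numerals, spelled-out Greek
letters, and 3/4-gram prefixes and suffixes), the lowercased token itself
(the training-vocabulary feature), optional lexicon-membership features, and
copies of the neighbors' features at offsets −1/+1.

Training maximizes the L2-penalized conditional log-likelihood with exact
forward–backward gradients; invalid BIO transitions are excluded
structurally (−∞ scores), so neither training nor Viterbi decoding can
produce an ill-formed path.  Initialization is at zero, making training
deterministic.  The forward log-partition and Viterbi routines are exposed
on raw score matrices so they can be checked against exhaustive path
enumeration.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection, Iterable, Mapping, Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from ._resources import greek_words
from .event_classification import EVENT_TYPES, EventType

NEG_INF = -np.inf

# ---------------------------------------------------------------------------
# Label scheme
# ---------------------------------------------------------------------------

LABELS: tuple[str, ...] = ("O",) + tuple(
    f"{p}-{t.value}" for t in EVENT_TYPES for p in ("B", "I"))
LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}
N_LABELS = len(LABELS)


def _valid_transitions() -> tuple[np.ndarray, np.ndarray]:
    """Additive masks: 0 where allowed, -inf where the BIO grammar forbids."""
    trans = np.zeros((N_LABELS, N_LABELS))
    init = np.zeros(N_LABELS)
    for j, lab in enumerate(LABELS):
        if not lab.startswith("I-"):
            continue
        t = lab[2:]
        init[j] = NEG_INF
        for i, prev in enumerate(LABELS):
            if prev not in (f"B-{t}", f"I-{t}"):
                trans[i, j] = NEG_INF
    return trans, init


TRANS_MASK, INIT_MASK = _valid_transitions()


def is_valid_path(labels: Sequence[str]) -> bool:
    idx = [LABEL_INDEX[l] for l in labels]
    if not idx:
        return True
    if INIT_MASK[idx[0]] == NEG_INF:
        return False
    return all(TRANS_MASK[a, b] == 0.0 for a, b in zip(idx, idx[1:]))


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

_ORTHO_REGEXES: tuple[tuple[str, re.Pattern], ...] = (
    ("InitCaps", re.compile(r"^[A-Z][a-z]")),
    ("AllCaps", re.compile(r"^[A-Z]+$")),
    ("MixedCase", re.compile(r"[a-z][A-Z]")),
    ("SingleDigit", re.compile(r"^[0-9]$")),
    ("DoubleDigit", re.compile(r"^[0-9][0-9]$")),
    ("NaturalNumber", re.compile(r"^[0-9]+$")),
    ("RealNumber", re.compile(r"^[-+−]?[0-9]+[.,][0-9]+$")),
    ("Hyphen", re.compile(r"-")),
    ("LeadHyphen", re.compile(r"^-")),
    ("TrailHyphen", re.compile(r"-$")),
    ("Punctuation", re.compile(r"^[^\w\s]+$")),
    ("Roman", re.compile(r"^[IVXDLCM]+$")),
)
# The 17 named indicators: the 12 regexes above, the Greek-letter word check,
# and the PRE3/PRE4/SUF3/SUF4 affix features.
ORTHO_FEATURE_NAMES: tuple[str, ...] = tuple(
    n for n, _ in _ORTHO_REGEXES) + ("Greek",)


@dataclass(frozen=True)
class TokenObservation:
    token: str
    features: frozenset[str]


def _base_features(token: str,
                   lexicons: Mapping[str, Collection[str]] | None,
                   include_word: bool) -> set[str]:
    feats: set[str] = set()
    for name, rx in _ORTHO_REGEXES:
        if rx.search(token):
            feats.add(f"ORTH={name}")
    low = token.lower()
    if low in greek_words():
        feats.add("ORTH=Greek")
    if len(low) >= 3:
        feats.add(f"PRE3={low[:3]}")
        feats.add(f"SUF3={low[-3:]}")
    if len(low) >= 4:
        feats.add(f"PRE4={low[:4]}")
        feats.add(f"SUF4={low[-4:]}")
    if include_word:
        feats.add(f"W={low}")
    if lexicons:
        for name, words in lexicons.items():
            if low in words:
                feats.add(f"LEX={name}")
    return feats


def extract_features(tokens: Sequence[str],
                     lexicons: Mapping[str, Collection[str]] | None = None,
                     window: int = 1,
                     include_word: bool = True) -> list[TokenObservation]:
    """Featurize a token sequence, copying neighbor features at ±``window``."""
    if not tokens:
        raise ValueError("extract_features requires a non-empty token sequence")
    base = [_base_features(t, lexicons, include_word) for t in tokens]
    out = []
    for i, tok in enumerate(tokens):
        feats = set(base[i])
        for off in range(-window, window + 1):
            if off == 0:
                continue
            j = i + off
            if 0 <= j < len(tokens):
                feats.update(f"{off:+d}:{f}" for f in base[j])

        out.append(TokenObservation(token=tok, features=frozenset(feats)))
    return out


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CRFHyper:
    sigma2: float = 10.0
    max_iter: int = 300
    tol: float = 1e-5


@dataclass
class CRFModel:
    feature_index: dict[str, int]
    state_weights: np.ndarray      # (F, L)
    trans_weights: np.ndarray      # (L, L)
    init_weights: np.ndarray       # (L,)
    hyper: CRFHyper
    labels: tuple[str, ...] = LABELS
    objective_history: list[float] = field(default_factory=list)

    def emissions(self, observations: Sequence[TokenObservation]) -> np.ndarray:
        emit = np.zeros((len(observations), N_LABELS))
        for t, obs in enumerate(observations):
            for f in obs.features:
                j = self.feature_index.get(f)
                if j is not None:
                    emit[t] += self.state_weights[j]
        return emit


def sequence_scores(model: CRFModel, observations: Sequence[TokenObservation]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Masked ``(emissions, transition, initial)`` score arrays for decoding."""
    emit = model.emissions(observations)
    trans = model.trans_weights + TRANS_MASK
    init = model.init_weights + INIT_MASK
    return emit, trans, init


def _lse(m: np.ndarray, axis: int) -> np.ndarray:
    """logsumexp tolerating -inf blocks without warnings."""
    mx = np.max(m, axis=axis)
    safe_mx = np.where(np.isfinite(mx), mx, 0.0)
    with np.errstate(invalid="ignore"):
        s = np.log(np.sum(np.exp(m - np.expand_dims(safe_mx, axis)), axis=axis))
    return np.where(np.isfinite(mx), s + safe_mx, NEG_INF)


def log_partition(emit: np.ndarray, trans: np.ndarray,
                  init: np.ndarray) -> float:
    """Forward-algorithm log of the sum of exp path scores."""
    alpha = init + emit[0]
    for t in range(1, emit.shape[0]):
        alpha = _lse(alpha[:, None] + trans, axis=0) + emit[t]
    return float(_lse(alpha, axis=0))


def viterbi_decode(emit: np.ndarray, trans: np.ndarray,
                   init: np.ndarray) -> tuple[list[int], float]:
    """Max-score path and its score; ties go to the lower label index."""
    n, L = emit.shape
    delta = init + emit[0]
    back = np.zeros((n, L), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + trans          # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(L)] + emit[t]
    best = int(np.argmax(delta))
    path = [best]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, float(delta[best])


def viterbi_tag(model: CRFModel,
                observations: Sequence[TokenObservation]) -> list[str]:
    """Tag a sequence with the maximum-score valid BIO path."""
    if not observations:
        raise ValueError("viterbi_tag requires a non-empty sequence")
    path, _ = viterbi_decode(*sequence_scores(model, observations))
    return [LABELS[i] for i in path]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _index_dataset(sequences: Sequence[tuple[Sequence[TokenObservation], Sequence[str]]]
                   ) -> tuple[dict[str, int], sp.csr_matrix, list[np.ndarray], list[int]]:
    feature_index: dict[str, int] = {}
    rows: list[list[int]] = []
    y_seqs: list[np.ndarray] = []
    lengths: list[int] = []
    for k, (obs, labels) in enumerate(sequences):
        if len(obs) != len(labels):
            raise ValueError(f"sequence {k}: observation/label length mismatch")
        if not is_valid_path(labels):
            raise ValueError(f"sequence {k}: invalid BIO label path")
        y_seqs.append(np.asarray([LABEL_INDEX[l] for l in labels]))
        lengths.append(len(obs))
        for o in obs:
            row = []
            for f in o.features:
                j = feature_index.setdefault(f, len(feature_index))
                row.append(j)
            rows.append(row)
    data, indices, indptr = [], [], [0]
    for row in rows:
        indices.extend(sorted(row))
        data.extend([1.0] * len(row))
        indptr.append(len(indices))
    X = sp.csr_matrix((data, indices, indptr),
                      shape=(len(rows), len(feature_index)))
    return feature_index, X, y_seqs, lengths


def _crf_objective(params: np.ndarray, X: sp.csr_matrix,
                   y_seqs: list[np.ndarray], lengths: list[int],
                   sigma2: float) -> tuple[float, np.ndarray]:
    """Penalized negative conditional log-likelihood and gradient."""
    F = X.shape[1]
    L = N_LABELS
    Ws = params[:F * L].reshape(F, L)
    Wt = params[F * L:F * L + L * L].reshape(L, L)
    Wi = params[F * L + L * L:]
    trans = Wt + TRANS_MASK
    init = Wi + INIT_MASK

    emit_all = np.asarray(X @ Ws)               # (n_tokens, L)
    post_all = np.zeros_like(emit_all)          # marginal - gold, per token
    grad_t = np.zeros((L, L))
    grad_i = np.zeros(L)
    nll = 0.0
    offset = 0
    for y, T in zip(y_seqs, lengths):
        emit = emit_all[offset:offset + T]
        # forward
        alpha = np.empty((T, L))
        alpha[0] = init + emit[0]
        for t in range(1, T):
            alpha[t] = _lse(alpha[t - 1][:, None] + trans, axis=0) + emit[t]
        log_z = float(_lse(alpha[T - 1], axis=0))
        # backward + pairwise marginals
        beta = np.zeros(L)
        post = np.empty((T, L))
        with np.errstate(invalid="ignore"):
            post[T - 1] = np.exp(alpha[T - 1] - log_z)
            for t in range(T - 1, 0, -1):
                m = trans + (emit[t] + beta)[None, :]
                pair = np.exp(alpha[t - 1][:, None] + m - log_z)
                pair[~np.isfinite(pair)] = 0.0
                grad_t += pair
                beta = _lse(m, axis=1)
                post[t - 1] = np.exp(alpha[t - 1] + beta - log_z)
        post[~np.isfinite(post)] = 0.0
        # gold score and indicator subtraction
        gold = emit[np.arange(T), y].sum() + Wi[y[0]] + Wt[y[:-1], y[1:]].sum()
        nll += log_z - float(gold)
        post[np.arange(T), y] -= 1.0
        grad_i += post[0]                      # marginal minus gold at t = 0
        np.subtract.at(grad_t, (y[:-1], y[1:]), 1.0)
        post_all[offset:offset + T] = post
        offset += T
    grad_s = np.asarray(X.T @ post_all)
    nll += (float((Ws * Ws).sum()) + float((Wt * Wt).sum())
            + float((Wi * Wi).sum())) / (2.0 * sigma2)
    grad_s += Ws / sigma2
    grad_t += Wt / sigma2
    grad_i += Wi / sigma2
    grad = np.concatenate([grad_s.ravel(), grad_t.ravel(), grad_i])
    return nll, grad


def train_crf(sequences: Sequence[tuple[Sequence[TokenObservation], Sequence[str]]],
              hyper: CRFHyper | None = None,
              record_history: bool = False) -> CRFModel:
    """Train the CRF by L-BFGS from a deterministic zero initialization.

    Sequences with mismatched lengths or invalid BIO paths are rejected with
    the offending sequence index.  With ``record_history=True`` the penalized
    objective is recorded at every accepted optimizer iterate (costs one
    extra function evaluation per iteration).
    """
    hyper = hyper or CRFHyper()
    if not sequences:
        raise ValueError("train_crf requires training sequences")
    feature_index, X, y_seqs, lengths = _index_dataset(sequences)
    F, L = X.shape[1], N_LABELS
    n_params = F * L + L * L + L
    history: list[float] = []

    args = (X, y_seqs, lengths, hyper.sigma2)
    callback = None
    if record_history:
        def callback(xk: np.ndarray) -> None:
            history.append(float(_crf_objective(xk, *args)[0]))

    res = scipy.optimize.minimize(
        _crf_objective, np.zeros(n_params), jac=True, args=args,
        method="L-BFGS-B", callback=callback,
        options={"maxiter": hyper.max_iter, "gtol": hyper.tol,
                 "maxfun": 10 * hyper.max_iter})
    params = res.x
    model = CRFModel(
        feature_index=feature_index,
        state_weights=params[:F * L].reshape(F, L),
        trans_weights=params[F * L:F * L + L * L].reshape(L, L),
        init_weights=params[F * L + L * L:],
        hyper=hyper,
        objective_history=history)
    return model


# ---------------------------------------------------------------------------
# Span codec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriggerSpan:
    """A trigger phrase as a half-open token-index interval with its type."""

    start: int
    end: int
    event_type: EventType


def decode_spans(tokens: Sequence[str], labels: Sequence[str]) -> list[TriggerSpan]:
    """Turn a valid BIO label sequence into typed token spans."""
    if len(tokens) != len(labels):
        raise ValueError("tokens and labels differ in length")
    if not is_valid_path(labels):
        raise ValueError("invalid BIO label sequence")
    spans: list[TriggerSpan] = []
    start = None
    current: EventType | None = None
    for i, lab in enumerate(labels):
        if lab.startswith("B-"):
            if current is not None:
                spans.append(TriggerSpan(start, i, current))
            start, current = i, EventType(lab[2:])
        elif lab == "O":
            if current is not None:
                spans.append(TriggerSpan(start, i, current))
            start, current = None, None
    if current is not None:
        spans.append(TriggerSpan(start, len(labels), current))
    return spans


def encode_labels(n_tokens: int, spans: Iterable[TriggerSpan]) -> list[str]:
    """Inverse of :func:`decode_spans` for non-overlapping span sets."""
    labels = ["O"] * n_tokens
    for span in sorted(spans, key=lambda s: s.start):
        if span.start < 0 or span.end > n_tokens or span.start >= span.end:
            raise ValueError(f"span {span} out of range")
        if any(labels[i] != "O" for i in range(span.start, span.end)):
            raise ValueError(f"span {span} overlaps a previous span")
        labels[span.start] = f"B-{span.event_type.value}"
        for i in range(span.start + 1, span.end):
            labels[i] = f"I-{span.event_type.value}"
    return labels


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bio_jsonl(path: str | Path) -> list[tuple[list[str], list[str]]]:
    """Read ``{"tokens": [...], "labels": [...]}`` JSON-lines sequences."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                out.append((list(rec["tokens"]), list(rec.get("labels", []))))
    return out


def write_bio_jsonl(sequences: Iterable[tuple[Sequence[str], Sequence[str]]],
                    path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tokens, labels in sequences:
            fh.write(json.dumps({"tokens": list(tokens),
                                 "labels": list(labels)}) + "\n")


def sequences_from_labeled(sentences: Iterable) -> list[tuple[list[str], list[str]]]:
    """Convert labeled sentences with character-offset triggers to BIO sequences.

    Tokens are the word tokens of the sentence; a trigger span covers the
    tokens lying fully inside its character interval.
    """
    from ._tokenize import tokenize_with_offsets

    out = []
    for ls in sentences:
        toks = tokenize_with_offsets(ls.text)
        tokens = [t for t, _, _ in toks]
        spans = []
        for trig in ls.triggers:
            covered = [i for i, (_, s, e) in enumerate(toks)
                       if s >= trig.start and e <= trig.end]
            if covered:
                spans.append(TriggerSpan(covered[0], covered[-1] + 1,
                                         trig.event_type))
        try:
            labels = encode_labels(len(tokens), spans)
        except ValueError:
            # overlapping gold triggers: keep the first, drop the rest
            labels = ["O"] * len(tokens)
            for span in sorted(spans, key=lambda s: s.start):
                if all(labels[i] == "O" for i in range(span.start, span.end)):
                    labels[span.start] = f"B-{span.event_type.value}"
                    for i in range(span.start + 1, span.end):
                        labels[i] = f"I-{span.event_type.value}"
        out.append((tokens, labels))
    return out
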