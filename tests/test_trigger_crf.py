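"""Orthographic features, CRF inference oracles, training, and the BIO codec."""

import itertools

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings, strategies as st

import bioeve.trigger_crf as tc
from bioeve.event_classification import EventType
from bioeve.trigger_crf import (CRFHyper, CRFModel, INIT_MASK, LABELS,
                                N_LABELS, TRANS_MASK, TriggerSpan,
                                decode_spans, encode_labels, extract_features,
                                is_valid_path, log_partition, train_crf,
                                viterbi_decode, viterbi_tag)


class TestExtractFeatures:
    def test_hyphenated_symbol(self):
        (obs,) = extract_features(["IL-2"], window=0)
        assert {"ORTH=Hyphen", "PRE3=il-", "SUF3=l-2",
                "PRE4=il-2", "SUF4=il-2", "W=il-2"} <= obs.features
        assert "ORTH=InitCaps" not in obs.features
        assert "ORTH=AllCaps" not in obs.features

    def test_greek_letter_word(self):
        (obs,) = extract_features(["alpha"], window=0)
        assert "ORTH=Greek" in obs.features

    def test_custom_lexicon_membership(self):
        (obs,) = extract_features(
            ["alanine"], lexicons={"aminoacid": {"alanine"}}, window=0)
        assert "LEX=aminoacid" in obs.features

    def test_plain_word_has_only_affixes_and_identity(self):
        (obs,) = extract_features(["the"], window=0)
        orth = {f for f in obs.features if f.startswith("ORTH=")}
        assert orth == set()
        assert {"PRE3=the", "SUF3=the", "W=the"} <= obs.features
        assert not any(f.startswith("PRE4") for f in obs.features)

    @pytest.mark.parametrize("token, expected", [
        ("Binding", "ORTH=InitCaps"),
        ("DNA", "ORTH=AllCaps"),
        ("mRna", "ORTH=MixedCase"),
        ("7", "ORTH=SingleDigit"),
        ("42", "ORTH=DoubleDigit"),
        ("1234", "ORTH=NaturalNumber"),
        ("3.14", "ORTH=RealNumber"),
        ("-300", "ORTH=LeadHyphen"),
        ("anti-", "ORTH=TrailHyphen"),
        (";", "ORTH=Punctuation"),
        ("XIV", "ORTH=Roman"),
    ])
    def test_each_orthographic_indicator(self, token, expected):
        (obs,) = extract_features([token], window=0)
        assert expected in obs.features

    def test_neighbor_copies(self):
        obs = extract_features(["IL-2", "binds", "DNA"])
        assert "-1:ORTH=Hyphen" in obs[1].features
        assert "+1:ORTH=AllCaps" in obs[1].features
        assert not any(f.startswith(("-1:", "+1:")) and "-1:" in f
                       for f in extract_features(["solo"])[0].features)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            extract_features([])


def _random_model(rng, features):
    fi = {f: i for i, f in enumerate(features)}
    return CRFModel(
        feature_index=fi,
        state_weights=rng.normal(0, 1, (len(fi), N_LABELS)),
        trans_weights=rng.normal(0, 1, (N_LABELS, N_LABELS)),
        init_weights=rng.normal(0, 1, N_LABELS),
        hyper=CRFHyper())


def _enumerate_paths(emit, trans, init):
    """Brute-force scores of every valid path (independent oracle)."""
    T = emit.shape[0]
    scores = []
    best_path, best_score = None, -np.inf
    for path in itertools.product(range(N_LABELS), repeat=T):
        if INIT_MASK[path[0]] != 0.0:
            continue
        if any(TRANS_MASK[a, b] != 0.0 for a, b in zip(path, path[1:])):
            continue
        s = init[path[0]] + emit[0, path[0]]
        for t in range(1, T):
            s += trans[path[t - 1], path[t]] + emit[t, path[t]]
        scores.append(s)
        if s > best_score:
            best_score, best_path = s, path
    return np.asarray(scores), list(best_path), best_score


class TestInferenceOracles:
    @pytest.mark.parametrize("T", [1, 2, 3, 4])
    def test_viterbi_and_partition_match_enumeration(self, T):
        rng = np.random.default_rng(100 + T)
        model = _random_model(rng, [f"f{i}" for i in range(6)])
        obs = [tc.TokenObservation(f"t{t}", frozenset(
            rng.choice([f"f{i}" for i in range(6)], size=2, replace=False)))
            for t in range(T)]
        emit, trans, init = tc.sequence_scores(model, obs)
        scores, oracle_path, oracle_best = _enumerate_paths(emit, trans, init)

        path, score = viterbi_decode(emit, trans, init)
        assert score == pytest.approx(oracle_best, abs=1e-9)
        assert path == oracle_path

        from scipy.special import logsumexp
        assert log_partition(emit, trans, init) == pytest.approx(
            logsumexp(scores), abs=1e-9)

    def test_all_zero_weights_gives_all_O(self):
        model = CRFModel(feature_index={"f": 0},
                         state_weights=np.zeros((1, N_LABELS)),
                         trans_weights=np.zeros((N_LABELS, N_LABELS)),
                         init_weights=np.zeros(N_LABELS),
                         hyper=CRFHyper())
        obs = extract_features(["a", "b", "c", "d"])
        assert viterbi_tag(model, obs) == ["O"] * 4

    def test_output_structurally_valid(self):
        rng = np.random.default_rng(5)
        model = _random_model(rng, [f"f{i}" for i in range(4)])
        for trial in range(25):
            T = int(rng.integers(1, 8))
            obs = [tc.TokenObservation("x", frozenset(
                rng.choice([f"f{i}" for i in range(4)], size=2, replace=False)))
                for _ in range(T)]
            labels = viterbi_tag(model, obs)
            assert len(labels) == T
            assert is_valid_path(labels)


class TestTraining:
    def test_memorizes_single_sequence(self):
        tokens = ["Stat1", "binds", "to", "the", "promoter"]
        labels = ["O", "B-Binding", "O", "O", "O"]
        obs = extract_features(tokens)
        model = train_crf([(obs, labels)])
        assert viterbi_tag(model, obs) == labels

    def test_gradient_matches_finite_differences(self):
        seqs = [(extract_features(["Abc", "binds"], window=0),
                 ["O", "B-Binding"])]
        fi, X, ys, lens = tc._index_dataset(seqs)
        n = X.shape[1] * N_LABELS + N_LABELS ** 2 + N_LABELS
        rng = np.random.default_rng(0)
        p0 = rng.normal(0, 0.3, n)
        _, g = tc._crf_objective(p0, X, ys, lens, 10.0)
        gfd = scipy.optimize.approx_fprime(
            p0, lambda p: tc._crf_objective(p, X, ys, lens, 10.0)[0], 1e-6)
        assert np.abs(g - gfd).max() < 1e-5

    def test_invalid_bio_path_rejected_with_index(self):
        good = (extract_features(["a"]), ["O"])
        bad = (extract_features(["a", "b"]), ["O", "I-Binding"])
        with pytest.raises(ValueError, match="sequence 1"):
            train_crf([good, bad])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            train_crf([(extract_features(["a", "b"]), ["O"])])

    def test_objective_history_monotone_nonincreasing(self):
        seqs = [(extract_features(t.split()), l.split()) for t, l in [
            ("x binds y", "O B-Binding O"),
            ("z regulates w", "O B-Regulation O"),
            ("x stays here", "O O O")]]
        model = train_crf(seqs, record_history=True)
        h = model.objective_history
        assert len(h) >= 2
        assert all(b <= a + 1e-8 for a, b in zip(h, h[1:]))

    def test_deterministic_feature_rule_is_learned(self):
        """Labels are a function of one feature -> perfect test tagging."""
        rng = np.random.default_rng(11)
        vocab = ["foo", "bar", "baz", "qux"]

        def make(n):
            out = []
            for _ in range(n):
                toks = [str(rng.choice(vocab)) for _ in range(rng.integers(3, 7))]
                pos = int(rng.integers(len(toks)))
                toks[pos] = "binds"
                labels = ["B-Binding" if t == "binds" else "O" for t in toks]
                out.append((extract_features(toks), labels))
            return out

        model = train_crf(make(30))
        correct = total = 0
        for obs, gold in make(15):
            pred = viterbi_tag(model, obs)
            correct += sum(p == g for p, g in zip(pred, gold))
            total += len(gold)
        assert correct == total


span_strategy = st.lists(
    st.tuples(st.integers(0, 10), st.integers(1, 3),
              st.sampled_from(list(EventType))),
    max_size=4)


class TestSpanCodec:
    def test_simple_run(self):
        labels = ["O", "B-Binding", "I-Binding", "O"]
        assert decode_spans(["a", "b", "c", "d"], labels) == [
            TriggerSpan(1, 3, EventType.Binding)]

    def test_all_outside(self):
        assert decode_spans(["a", "b"], ["O", "O"]) == []

    def test_adjacent_spans(self):
        labels = ["B-Binding", "B-Regulation", "I-Regulation"]
        spans = decode_spans(["a", "b", "c"], labels)
        assert spans == [TriggerSpan(0, 1, EventType.Binding),
                         TriggerSpan(1, 3, EventType.Regulation)]

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            decode_spans(["a", "b"], ["O", "I-Binding"])

    @given(span_strategy)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_encode_decode_roundtrip(self, raw):
        # build non-overlapping spans, then encode -> decode must be identity
        spans, cursor = [], 0
        for gap, length, et in raw:
            start = cursor + gap
            spans.append(TriggerSpan(start, start + length, et))
            cursor = start + length
        n = cursor + 2
        labels = encode_labels(n, spans)
        assert is_valid_path(labels)
        assert decode_spans(["t"] * n, labels) == spans


class TestSequenceConversion:
    def test_char_triggers_become_token_spans(self, small_corpus):
        sentences = small_corpus.labeled_sentences()[:40]
        seqs = tc.sequences_from_labeled(sentences)
        for ls, (tokens, labels) in zip(sentences, seqs):
            assert len(tokens) == len(labels)
            assert is_valid_path(labels)
            decoded = decode_spans(tokens, labels)
            assert len(decoded) == len(ls.triggers)
            for span, trig in zip(decoded,
                                  sorted(ls.triggers, key=lambda t: t.start)):
                phrase = " ".join(tokens[span.start:span.end])
                assert phrase == ls.text[trig.start:trig.end]

    def test_bio_jsonl_roundtrip(self, tmp_path):
        seqs = [(["a", "b"], ["O", "B-Binding"]), (["c"], ["O"])]
        p = tmp_path / "bio.jsonl"
        tc.write_bio_jsonl(seqs, p)
        assert tc.read_bio_jsonl(p) == seqs
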