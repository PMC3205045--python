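import itertools
import json
import random

import numpy as np
import pytest

from chemtagger.document import EntityType, NamedEntity
from chemtagger.fixtures import CorpusSpec, generate_corpus, generate_word_lists
from chemtagger.memm import (
    LABELS,
    LABEL_INDEX,
    START,
    AnnotatedDocument,
    MEMMModel,
    SpanAlignmentError,
    TemplateMismatchError,
    corpus_from_json,
    corpus_to_json,
    decode,
    evaluate_entities,
    extract_features,
    labels_to_spans,
    spans_to_labels,
    train,
    word_shape,
)
from chemtagger.ngram import train as ngram_train, build_word_lists

from conftest import make_sequence


@pytest.fixture(scope="module")
def nm():
    return ngram_train(build_word_lists({"benzenol", "tolane"}, {"house", "the"}))


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def test_word_shape():
    assert word_shape("C-H") == "A-A"
    assert word_shape("Benzene") == "Aa"
    assert word_shape("NSC-2648") == "A-0"


def test_feature_vector_contents(nm):
    seq = make_sequence(["benzene"])
    feats = extract_features(seq, 0, nm)
    assert "suf3=ene" in feats
    assert "prev:BOS" in feats
    assert "next:EOS" in feats
    assert "w=benzene" in feats
    assert feats == extract_features(seq, 0, nm)  # deterministic


def test_neighbour_features(nm):
    seq = make_sequence(["the", "C-H", "bond"])
    feats = extract_features(seq, 1, nm)
    assert "shape=A-A" in feats
    assert "prev:w=the" in feats
    assert "next:w=bond" in feats
    with pytest.raises(IndexError):
        extract_features(seq, 3, nm)


# ---------------------------------------------------------------------------
# Label coding
# ---------------------------------------------------------------------------

def test_label_alphabet():
    assert len(LABELS) == 9
    assert set(LABELS) == {"O"} | {
        f"{bi}-{c}" for bi in "BI" for c in ("CM", "RN", "CJ", "ASE")
    }


def test_spans_to_labels_and_back():
    seq = make_sequence(["add", "ethyl", "acetate", "now"])
    gold = NamedEntity(surface="ethyl acetate", type=EntityType.CM, start=4, end=17)
    doc = AnnotatedDocument(seq, (gold,))
    labels = spans_to_labels(doc)
    assert labels == ["O", "B-CM", "I-CM", "O"]
    assert labels_to_spans(labels) == [(1, 2, "CM")]


def test_misaligned_span_is_named_error():
    seq = make_sequence(["benzene", "ring"])
    bad = NamedEntity(surface="enzene", type=EntityType.CM, start=1, end=7)
    with pytest.raises(SpanAlignmentError, match="enzene"):
        spans_to_labels(AnnotatedDocument(seq, (bad,)))


# ---------------------------------------------------------------------------
# Enumeration oracle for decoding
# ---------------------------------------------------------------------------

def valid_transition(prev: str, lab: str) -> bool:
    if lab.startswith("I-"):
        cls = lab[2:]
        return prev in (f"B-{cls}", f"I-{cls}")
    return True


def random_model_and_sequence(rng, length):
    """A random-weight MEMM over the features a random sequence emits."""
    words = ["".join(rng.choice("abxy") for _ in range(rng.randint(1, 4)))
             for _ in range(length)]
    seq = make_sequence(words)
    lists = build_word_lists({"ax", "bx"}, {"yy", "ya"})
    nm_local = ngram_train(lists)
    feats = set()
    for i in range(length):
        feats |= set(extract_features(seq, i, nm_local))
    feats |= {f"__prev__={lab}" for lab in LABELS} | {f"__prev__={START}"}
    index = {f: i for i, f in enumerate(sorted(feats))}
    npr = np.random.default_rng(rng.randint(0, 2**31 - 1))
    weights = npr.normal(scale=1.0, size=(len(index), len(LABELS)))
    return MEMMModel(index, weights), seq, nm_local


def enumerate_paths(log_probs):
    """Log-weight of every label path, as a (9,)*L tensor; invalid = -inf."""
    L, _, n = log_probs.shape
    start_valid = np.array([valid_transition(START, lab) for lab in LABELS])
    T = np.where(start_valid, log_probs[0, n], -np.inf)
    for i in range(1, L):
        step_valid = np.array(
            [[valid_transition(p, lab) for lab in LABELS] for p in LABELS]
        )
        step = np.where(step_valid, log_probs[i, :n], -np.inf)
        T = T[..., :, None] + step  # broadcast over new axis
    return T


def logsumexp_tensor(T):
    m = T.max()
    if not np.isfinite(m):
        return -np.inf
    return m + np.log(np.exp(T - m).sum())


def test_viterbi_and_confidence_match_enumeration(nm):
    rng = random.Random(20)
    for trial in range(30):
        length = rng.randint(1, 5)
        model, seq, nm_local = random_model_and_sequence(rng, length)
        log_probs = model.transition_log_probs(seq, nm_local)
        T = enumerate_paths(log_probs)

        best = np.unravel_index(np.argmax(T), T.shape)
        best_labels = [LABELS[k] for k in best]

        entities = decode(seq, model, nm_local)
        decoded_spans = labels_to_spans(best_labels)
        got_spans = []
        starts = {t.start: i for i, t in enumerate(seq.tokens)}
        ends = {t.end: i for i, t in enumerate(seq.tokens)}
        for e in entities:
            got_spans.append((starts[e.start], ends[e.end], e.type.value))
        assert got_spans == decoded_spans

        log_z = logsumexp_tensor(T)
        for e, (i0, i1, cls) in zip(entities, decoded_spans):
            mask = np.ones(T.shape, dtype=bool)
            axis_allowed = [np.ones(len(LABELS), dtype=bool) for _ in range(length)]
            axis_allowed[i0][:] = False
            axis_allowed[i0][LABEL_INDEX[f"B-{cls}"]] = True
            for k in range(i0 + 1, i1 + 1):
                axis_allowed[k][:] = False
                axis_allowed[k][LABEL_INDEX[f"I-{cls}"]] = True
            if i1 + 1 < length:
                axis_allowed[i1 + 1][LABEL_INDEX[f"I-{cls}"]] = False
            for ax, allowed in enumerate(axis_allowed):
                shape = [1] * length
                shape[ax] = len(LABELS)
                mask &= allowed.reshape(shape)
            log_span = logsumexp_tensor(np.where(mask, T, -np.inf))
            assert e.confidence == pytest.approx(
                np.exp(log_span - log_z), abs=1e-9
            )


def test_decode_empty_sequence(nm):
    from chemtagger.document import TokenSequence

    model, _, nm_local = random_model_and_sequence(random.Random(1), 2)
    empty = TokenSequence(text="", offset=0, tokens=())
    assert decode(empty, model, nm_local) == []


def test_decoded_paths_respect_bi_constraint(nm):
    rng = random.Random(5)
    for _ in range(20):
        model, seq, nm_local = random_model_and_sequence(rng, rng.randint(2, 6))
        entities = decode(seq, model, nm_local)
        for a, b in itertools.combinations(entities, 2):
            assert min(a.end, b.end) <= max(a.start, b.start)  # no overlap
        for e in entities:
            assert 0.0 <= e.confidence <= 1.0


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def small_corpus(seed, n):
    return generate_corpus(CorpusSpec(seed=seed, n_sentences=n))


def test_all_o_corpus_decodes_all_o(nm):
    docs = [
        AnnotatedDocument(make_sequence(["the", "house", "stood"]), ()),
        AnnotatedDocument(make_sequence(["it", "was", "fine"]), ()),
    ]
    model = train(docs, nm, max_iter=50)
    assert decode(docs[0].seq, model, nm) == []


def test_objective_decreases_monotonically(nm):
    spec = CorpusSpec(seed=3, n_sentences=30)
    corpus = generate_corpus(spec)
    nm_fix = ngram_train(generate_word_lists(spec))
    trace: list[float] = []
    train(corpus, nm_fix, max_iter=60, objective_trace=trace)
    assert len(trace) > 3
    assert all(b <= a + 1e-6 for a, b in zip(trace, trace[1:]))


def test_suffix_rule_recovery_small():
    """Tokens with class suffixes are recovered on held-out sentences."""
    spec = CorpusSpec(seed=17, n_sentences=150)
    nm_fix = ngram_train(generate_word_lists(spec))
    model = train(generate_corpus(spec), nm_fix, max_iter=150)
    test = generate_corpus(CorpusSpec(seed=18, n_sentences=40))
    pred = [decode(d.seq, model, nm_fix) for d in test]
    gold = [list(d.entities) for d in test]
    scores = evaluate_entities(gold, pred)
    assert scores["f1"] >= 0.9


def test_model_json_round_trip(nm):
    model = train(small_corpus(2, 20), nm, max_iter=40)
    clone = MEMMModel.from_json(model.to_json())
    doc = small_corpus(9, 3)[0]
    assert decode(doc.seq, clone, nm) == decode(doc.seq, model, nm)


def test_template_mismatch_is_an_error(nm):
    model = train(small_corpus(2, 5), nm, max_iter=10)
    stale = MEMMModel(
        model.feature_index, model.weights, template_version="ancient"
    )
    with pytest.raises(TemplateMismatchError):
        decode(small_corpus(9, 1)[0].seq, stale, nm)


def test_corpus_json_round_trip():
    corpus = small_corpus(4, 10)
    clone = corpus_from_json(corpus_to_json(corpus))
    assert clone == corpus


def test_evaluate_entities_counts():
    e1 = NamedEntity(surface="aa", type=EntityType.CM, start=0, end=2)
    e2 = NamedEntity(surface="bb", type=EntityType.RN, start=3, end=5)
    scores = evaluate_entities([[e1, e2]], [[e1]])
    assert scores["precision"] == 1.0
    assert scores["recall"] == 0.5
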