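"""Maximum Entropy Markov Model sequence tagger for chemical entity classes.

Tokens are labelled with a per-class B/I scheme plus O (9 labels for the four
classes CM, RN, CJ and ASE).  A single conditional maximum-entropy classifier
models P(label | previous label, local features); the previous label enters
as an indicator feature, so the learned weights form a (previous label,
label) conditional table as in a classic MEMM.  Decoding is Viterbi under the
hard constraint that I-t may only follow B-t or I-t; entity confidences are
constrained-forward probability ratios, i.e. the total probability mass of
label paths that realise exactly the emitted span divided by the mass of all
valid paths.

The label-bias property of locally normalised MEMMs is inherited by design
and not mitigated here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse
from scipy.special import logsumexp

from .document import EntityType, NamedEntity, TokenSequence
from .ngram import NGramModel

ENTITY_CLASSES = ("CM", "RN", "CJ", "ASE")
LABELS: tuple[str, ...] = ("O",) + tuple(
    f"{bi}-{c}" for c in ENTITY_CLASSES for bi in ("B", "I")
)
LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}
START = "<s>"  # pseudo previous-label at sequence start
FEATURE_TEMPLATE_VERSION = "ct-memm-v1"

_PREV_FEATURES = tuple(f"__prev__={lab}" for lab in LABELS) + (f"__prev__={START}",)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def word_shape(surface: str) -> str:
    """Compress character classes: upper->A, lower->a, digit->0, runs collapsed."""
    out: list[str] = []
    for ch in surface:
        if ch.isupper():
            mapped = "A"
        elif ch.islower():
            mapped = "a"
        elif ch.isdigit():
            mapped = "0"
        else:
            mapped = ch
        if not out or out[-1] != mapped:
            out.append(mapped)
    return "".join(out)


def _token_features(surface: str, p_chem: float) -> list[str]:
    lc = surface.casefold()
    feats = [
        f"w={surface}",
        f"lc={lc}",
        f"shape={word_shape(surface)}",
        f"pchem={min(9, int(p_chem * 10))}",
    ]
    for k in range(1, 5):
        if k <= len(lc):
            feats.append(f"pre{k}={lc[:k]}")
            feats.append(f"suf{k}={lc[-k:]}")
    padded = "^" + lc + "$"
    for i in range(len(padded) - 2):
        feats.append(f"tg={padded[i:i + 3]}")
    if not any(ch.isalnum() for ch in surface):
        feats.append("punct")
    return feats


def extract_features(
    seq: TokenSequence, i: int, ngram_model: NGramModel
) -> dict[str, float]:
    """Deterministic sparse feature vector for token ``i`` of a sequence.

    Includes the token's own lexical/shape/n-gram/chemical-probability
    features plus the same items for its neighbours under "prev:"/"next:"
    prefixes (pseudo-tokens BOS/EOS at the boundaries).
    """
    if not 0 <= i < len(seq.tokens):
        raise IndexError(f"position {i} out of range for sequence of {len(seq.tokens)}")

    def feats_at(j: int) -> list[str]:
        surf = seq.tokens[j].surface
        return _token_features(surf, ngram_model.p_chemical(surf))

    vec = {f: 1.0 for f in feats_at(i)}
    if i > 0:
        for f in feats_at(i - 1):
            vec[f"prev:{f}"] = 1.0
    else:
        vec["prev:BOS"] = 1.0
    if i < len(seq.tokens) - 1:
        for f in feats_at(i + 1):
            vec[f"next:{f}"] = 1.0
    else:
        vec["next:EOS"] = 1.0
    vec["__bias__"] = 1.0
    return vec


# ---------------------------------------------------------------------------
# Corpus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedDocument:
    """A token sequence with gold entity spans of the four MEMM classes."""

    seq: TokenSequence
    entities: tuple[NamedEntity, ...]


AnnotatedCorpus = list[AnnotatedDocument]


class SpanAlignmentError(ValueError):
    """A gold span does not coincide with token boundaries."""


def spans_to_labels(doc: AnnotatedDocument) -> list[str]:
    """Convert gold spans to the B/I/O labelling; misalignment is an error."""
    labels = ["O"] * len(doc.seq.tokens)
    starts = {t.start: i for i, t in enumerate(doc.seq.tokens)}
    ends = {t.end: i for i, t in enumerate(doc.seq.tokens)}
    for e in doc.entities:
        if e.type.value not in ENTITY_CLASSES:
            raise SpanAlignmentError(f"entity class {e.type.value} is not MEMM-taggable")
        if e.start not in starts or e.end not in ends:
            raise SpanAlignmentError(
                f"gold span [{e.start},{e.end}) {e.surface!r} is not token-aligned"
            )
        i0, i1 = starts[e.start], ends[e.end]
        if any(labels[k] != "O" for k in range(i0, i1 + 1)):
            raise SpanAlignmentError(f"gold span {e.surface!r} overlaps another span")
        labels[i0] = f"B-{e.type.value}"
        for k in range(i0 + 1, i1 + 1):
            labels[k] = f"I-{e.type.value}"
    return labels


def labels_to_spans(labels: list[str]) -> list[tuple[int, int, str]]:
    """Maximal B-t (I-t)* runs -> (start token, end token inclusive, class)."""
    spans = []
    i = 0
    while i < len(labels):
        if labels[i].startswith("B-"):
            cls = labels[i][2:]
            j = i
            while j + 1 < len(labels) and labels[j + 1] == f"I-{cls}":
                j += 1
            spans.append((i, j, cls))
            i = j + 1
        else:
            i += 1
    return spans


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class TemplateMismatchError(ValueError):
    """Model was trained with an incompatible feature-template version."""


class MEMMModel:
    """Maxent weights over (feature, label); previous label as a feature."""

    def __init__(
        self,
        feature_index: dict[str, int],
        weights: np.ndarray,
        template_version: str = FEATURE_TEMPLATE_VERSION,
        l2_strength: float = 1.0,
    ) -> None:
        if weights.shape != (len(feature_index), len(LABELS)):
            raise ValueError("weight matrix shape inconsistent with feature index")
        if not np.all(np.isfinite(weights)):
            raise ValueError("weights must be finite")
        self.feature_index = feature_index
        self.weights = weights
        self.template_version = template_version
        self.l2_strength = l2_strength

    # -- local conditional probabilities -------------------------------------

    def transition_log_probs(
        self, seq: TokenSequence, ngram_model: NGramModel
    ) -> np.ndarray:
        """log P(label | previous label, position) for every position.

        Returns an array of shape (L, n_prev, n_labels) where n_prev indexes
        the 9 labels plus the start pseudo-label (last row).
        """
        n_lab = len(LABELS)
        prev_rows = np.zeros((n_lab + 1, n_lab))
        for p, pf in enumerate(_PREV_FEATURES):
            idx = self.feature_index.get(pf)
            if idx is not None:
                prev_rows[p] = self.weights[idx]

        out = np.empty((len(seq.tokens), n_lab + 1, n_lab))
        for i in range(len(seq.tokens)):
            feats = extract_features(seq, i, ngram_model)
            base = np.zeros(n_lab)
            for f in feats:
                idx = self.feature_index.get(f)
                if idx is not None:
                    base += self.weights[idx]
            scores = base[None, :] + prev_rows  # (n_prev, n_labels)
            out[i] = scores - logsumexp(scores, axis=1, keepdims=True)
        return out

    # -- persistence ----------------------------------------------------------

    def to_json(self) -> str:
        nz = {}
        for feat, idx in self.feature_index.items():
            row = self.weights[idx]
            nzc = np.nonzero(row)[0]
            if len(nzc):
                nz[feat] = {str(int(c)): float(row[c]) for c in nzc}
        return json.dumps(
            {
                "labels": list(LABELS),
                "template_version": self.template_version,
                "l2_strength": self.l2_strength,
                "weights": nz,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "MEMMModel":
        raw = json.loads(payload)
        if tuple(raw["labels"]) != LABELS:
            raise TemplateMismatchError("label alphabet mismatch")
        feats = sorted(raw["weights"])
        index = {f: i for i, f in enumerate(feats)}
        weights = np.zeros((len(feats), len(LABELS)))
        for f, row in raw["weights"].items():
            for c, w in row.items():
                weights[index[f], int(c)] = w
        return cls(
            index,
            weights,
            template_version=raw["template_version"],
            l2_strength=raw["l2_strength"],
        )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(
    corpus: AnnotatedCorpus,
    ngram_model: NGramModel,
    l2_strength: float = 1.0,
    max_iter: int = 200,
    seed: int = 0,
    objective_trace: list[float] | None = None,
) -> MEMMModel:
    """Fit the conditional maxent by L2-regularised maximum likelihood.

    Gold spans become B/I/O labels; each position contributes one training
    instance (features + previous *gold* label indicator) -> label.  The
    convex objective is minimised with L-BFGS; pass ``objective_trace`` to
    record the objective at each accepted iterate.
    """
    if not corpus:
        raise ValueError("training corpus is empty")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))

    feature_index: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    y: list[int] = []

    def fid(f: str) -> int:
        if f not in feature_index:
            feature_index[f] = len(feature_index)
        return feature_index[f]

    inst = 0
    for d in order:
        doc = corpus[d]
        labels = spans_to_labels(doc)
        prev = START
        for i in range(len(doc.seq.tokens)):
            feats = extract_features(doc.seq, i, ngram_model)
            feats[f"__prev__={prev}"] = 1.0
            for f in feats:
                rows.append(inst)
                cols.append(fid(f))
            y.append(LABEL_INDEX[labels[i]])
            prev = labels[i]
            inst += 1

    n_inst, n_feat, n_lab = inst, len(feature_index), len(LABELS)
    X = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_inst, n_feat)
    )
    y_arr = np.asarray(y)
    Y = sparse.csr_matrix(
        (np.ones(n_inst), (np.arange(n_inst), y_arr)), shape=(n_inst, n_lab)
    )

    def objective(w_flat: np.ndarray) -> tuple[float, np.ndarray]:
        W = w_flat.reshape(n_feat, n_lab)
        scores = X @ W
        log_z = logsumexp(scores, axis=1)
        nll = float(np.sum(log_z) - np.sum(scores[np.arange(n_inst), y_arr]))
        nll += 0.5 * l2_strength * float(np.sum(W * W))
        P = np.exp(scores - log_z[:, None])
        grad = (X.T @ (P - Y.toarray())) + l2_strength * W
        return nll, np.asarray(grad).ravel()

    if objective_trace is not None:
        objective_trace.append(objective(np.zeros(n_feat * n_lab))[0])

    def callback(w_flat: np.ndarray) -> None:
        if objective_trace is not None:
            objective_trace.append(objective(w_flat)[0])

    result = optimize.minimize(
        objective,
        np.zeros(n_feat * n_lab),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
        callback=callback,
    )
    return MEMMModel(
        feature_index,
        result.x.reshape(n_feat, n_lab),
        l2_strength=l2_strength,
    )


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def transition_mask() -> np.ndarray:
    """valid[prev, label] over 9+1 previous labels (last row = start)."""
    n = len(LABELS)
    valid = np.ones((n + 1, n), dtype=bool)
    for j, lab in enumerate(LABELS):
        if lab.startswith("I-"):
            cls = lab[2:]
            for p in range(n + 1):
                prev = LABELS[p] if p < n else START
                if prev not in (f"B-{cls}", f"I-{cls}"):
                    valid[p, j] = False
    return valid


_VALID = transition_mask()
_NEG_INF = -np.inf


def _viterbi(log_probs: np.ndarray) -> list[int]:
    """Max-probability valid label path; log_probs is (L, n_prev+1, n_lab)."""
    L, _, n_lab = log_probs.shape
    delta = np.where(_VALID[n_lab], log_probs[0, n_lab], _NEG_INF)
    back = np.zeros((L, n_lab), dtype=int)
    for i in range(1, L):
        step = np.where(_VALID[:n_lab], log_probs[i, :n_lab], _NEG_INF)
        cand = delta[:, None] + step
        back[i] = np.argmax(cand, axis=0)
        delta = np.max(cand, axis=0)
    path = [int(np.argmax(delta))]
    for i in range(L - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    return path[::-1]


def _log_forward(log_probs: np.ndarray, allowed: np.ndarray) -> float:
    """log total weight of valid paths whose labels respect ``allowed`` (L, n_lab)."""
    L, _, n_lab = log_probs.shape
    alpha = np.where(
        _VALID[n_lab] & allowed[0], log_probs[0, n_lab], _NEG_INF
    )
    for i in range(1, L):
        step = np.where(
            _VALID[:n_lab] & allowed[i][None, :], log_probs[i, :n_lab], _NEG_INF
        )
        with np.errstate(invalid="ignore"):
            alpha = logsumexp(alpha[:, None] + step, axis=0)
    return float(logsumexp(alpha))


def decode(
    seq: TokenSequence, model: MEMMModel, ngram_model: NGramModel
) -> list[NamedEntity]:
    """Viterbi-decode one sequence into typed entities with confidences.

    Confidence of a span is the probability, over all valid label paths,
    that the path realises exactly that span (clamped B/I labels inside, and
    no same-class I continuing past the end), computed by constrained
    forward passes.
    """
    if model.template_version != FEATURE_TEMPLATE_VERSION:
        raise TemplateMismatchError(
            f"model templates {model.template_version!r} != {FEATURE_TEMPLATE_VERSION!r}"
        )
    if len(seq.tokens) == 0:
        return []

    log_probs = model.transition_log_probs(seq, ngram_model)
    path = _viterbi(log_probs)
    labels = [LABELS[k] for k in path]

    n_lab = len(LABELS)
    log_z = _log_forward(log_probs, np.ones((len(labels), n_lab), dtype=bool))

    entities = []
    for i0, i1, cls in labels_to_spans(labels):
        allowed = np.ones((len(labels), n_lab), dtype=bool)
        allowed[i0] = False
        allowed[i0, LABEL_INDEX[f"B-{cls}"]] = True
        for k in range(i0 + 1, i1 + 1):
            allowed[k] = False
            allowed[k, LABEL_INDEX[f"I-{cls}"]] = True
        if i1 + 1 < len(labels):
            allowed[i1 + 1, LABEL_INDEX[f"I-{cls}"]] = False
        log_span = _log_forward(log_probs, allowed)
        conf = float(np.exp(min(log_span - log_z, 0.0)))
        toks = seq.tokens[i0 : i1 + 1]
        surface = seq.text[toks[0].start - seq.offset : toks[-1].end - seq.offset]
        entities.append(
            NamedEntity(
                surface=surface,
                type=EntityType(cls),
                start=toks[0].start,
                end=toks[-1].end,
                confidence=conf,
            )
        )
    return entities


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_entities(
    gold: list[list[NamedEntity]], predicted: list[list[NamedEntity]]
) -> dict[str, float]:
    """Entity-level precision/recall/F1 with exact span + class matching."""
    tp = fp = fn = 0
    for g, p in zip(gold, predicted, strict=True):
        gset = {(e.start, e.end, e.type) for e in g}
        pset = {(e.start, e.end, e.type) for e in p}
        tp += len(gset & pset)
        fp += len(pset - gset)
        fn += len(gset - pset)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1}


# ---------------------------------------------------------------------------
# Corpus (de)serialisation: standoff JSON plus token boundaries
# ---------------------------------------------------------------------------

def corpus_to_json(corpus: AnnotatedCorpus) -> str:
    docs = []
    for doc in corpus:
        docs.append(
            {
                "text": doc.seq.text,
                "offset": doc.seq.offset,
                "tokens": [[t.start, t.end] for t in doc.seq.tokens],
                "entities": [
                    {
                        "type": e.type.value,
                        "start": e.start,
                        "end": e.end,
                        "surface": e.surface,
                    }
                    for e in doc.entities
                ],
            }
        )
    return json.dumps(docs, ensure_ascii=False)


def corpus_from_json(payload: str) -> AnnotatedCorpus:
    from .document import Token

    corpus = []
    for raw in json.loads(payload):
        text, off = raw["text"], raw["offset"]
        tokens = tuple(
            Token(surface=text[s - off : e - off], start=s, end=e, index=i)
            for i, (s, e) in enumerate(raw["tokens"])
        )
        seq = TokenSequence(text=text, offset=off, tokens=tokens)
        ents = tuple(
            NamedEntity(
                surface=e["surface"],
                type=EntityType(e["type"]),
                start=e["start"],
                end=e["end"],
            )
            for e in raw["entities"]
        )
        corpus.append(AnnotatedDocument(seq, ents))
    return corpus
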