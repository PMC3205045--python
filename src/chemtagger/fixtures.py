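"""Deterministic synthetic-data generators.

Real chemical NER systems are trained on hand-annotated journal text, which
cannot be bundled.  The generators here produce miniature stand-ins: word
lists of pseudo-chemical words (random syllables plus a chemical suffix),
annotated corpora in which the entity rule is known by construction (tokens
carrying a class-specific suffix are entities of that class), and random NMR
peak lists.  Gold annotations are recorded at insertion time, never by
pattern-matching the rendered text, so they are independent of the
recognisers under test.

What these fixtures do *not* emulate: journal prose style, nested or
ambiguous entity mentions, and vocabulary overlap between entity and
non-entity tokens.  Results on them bound best-case behaviour, not
performance on real text.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .document import EntityType, NamedEntity, Token, TokenSequence
from .memm import AnnotatedCorpus, AnnotatedDocument
from .ngram import WordLists, build_word_lists, default_word_lists
from .dataparser import Peak

_SYLLABLES = [
    c + v
    for c in "bdfglmnprstz"
    for v in "aeiou"
]

# class-specific suffixes; the suffix IS the entity rule
CLASS_SUFFIXES: dict[str, tuple[str, ...]] = {
    "CM": ("ol", "ane", "ate"),
    "RN": ("ation",),
    "CJ": ("ic",),
    "ASE": ("ase",),
}

_MULTIPLICITIES = ("s", "d", "t", "q", "m", "dd", "dt", "td", "br")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of the synthetic annotated corpus.

    ``entity_rate`` is the per-slot probability that a sentence position is
    an entity rather than a plain word; ``multi_token_rate`` the probability
    that an entity spans two tokens; ``class_mix`` the distribution over the
    four entity classes.
    """

    seed: int
    n_sentences: int = 500
    n_chemical_words: int = 120
    n_plain_words: int = 200
    entity_rate: float = 0.2
    multi_token_rate: float = 0.2
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"CM": 0.7, "RN": 0.1, "CJ": 0.1, "ASE": 0.1}
    )
    min_sentence_len: int = 6
    max_sentence_len: int = 12

    def __post_init__(self) -> None:
        if not 0.0 <= self.entity_rate <= 1.0 or not 0.0 <= self.multi_token_rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class mix must sum to 1")
        if set(self.class_mix) - set(CLASS_SUFFIXES):
            raise ValueError("class mix keys must be among CM/RN/CJ/ASE")


def _random_word(rng: random.Random, suffix: str) -> str:
    stem = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(2, 3)))
    return stem + suffix


def _plain_vocabulary(spec: CorpusSpec) -> list[str]:
    """Plain words from the packaged English list, minus any word that would
    trigger the entity rule (no plain word ends in a class suffix)."""
    all_suffixes = tuple(s for group in CLASS_SUFFIXES.values() for s in group)
    words = sorted(
        w
        for w in default_word_lists().nonchemical
        if not w.endswith(all_suffixes)
    )
    return words[: spec.n_plain_words]


def _class_vocabulary(
    rng: random.Random, n_words: int, suffixes: tuple[str, ...]
) -> list[str]:
    vocab: set[str] = set()
    while len(vocab) < n_words:
        vocab.add(_random_word(rng, rng.choice(suffixes)))
    return sorted(vocab)


def generate_word_lists(spec: CorpusSpec) -> WordLists:
    """Chemical pseudo-words (CM suffixes) vs packaged plain words."""
    rng = random.Random(spec.seed)
    chemical = set(_class_vocabulary(rng, spec.n_chemical_words, CLASS_SUFFIXES["CM"]))
    plain = set(_plain_vocabulary(spec))
    return build_word_lists(chemical, plain)


def generate_corpus(spec: CorpusSpec) -> AnnotatedCorpus:
    """Sentences of plain words with entity tokens inserted at a known rate.

    Each sentence becomes one single-paragraph document; gold spans are
    recorded at insertion time.  The rendered text is plain space-joined
    words, so re-tokenising it reproduces the recorded token boundaries.
    """
    rng = random.Random(spec.seed)
    plain = _plain_vocabulary(spec)
    class_vocab = {
        cls: _class_vocabulary(rng, spec.n_chemical_words, suffixes)
        for cls, suffixes in CLASS_SUFFIXES.items()
    }
    classes = sorted(spec.class_mix)
    weights = [spec.class_mix[c] for c in classes]

    corpus: AnnotatedCorpus = []
    for _ in range(spec.n_sentences):
        n_slots = rng.randint(spec.min_sentence_len, spec.max_sentence_len)
        words: list[str] = []
        # (first token index, n tokens, class) per inserted entity
        inserted: list[tuple[int, int, str]] = []
        # entities are never adjacent, so every maximal run of suffix-bearing
        # tokens is exactly one gold entity and spans are unambiguous
        prev_was_entity = False
        for _slot in range(n_slots):
            if not prev_was_entity and rng.random() < spec.entity_rate:
                cls = rng.choices(classes, weights=weights)[0]
                n_tok = 2 if rng.random() < spec.multi_token_rate else 1
                inserted.append((len(words), n_tok, cls))
                for _k in range(n_tok):
                    words.append(rng.choice(class_vocab[cls]))
                prev_was_entity = True
            else:
                words.append(rng.choice(plain))
                prev_was_entity = False

        text = " ".join(words)
        starts: list[int] = []
        pos = 0
        for w in words:
            starts.append(pos)
            pos += len(w) + 1
        tokens = tuple(
            Token(surface=w, start=starts[i], end=starts[i] + len(w), index=i)
            for i, w in enumerate(words)
        )
        seq = TokenSequence(text=text, offset=0, tokens=tokens)
        entities = tuple(
            NamedEntity(
                surface=text[starts[i0] : starts[i0 + n - 1] + len(words[i0 + n - 1])],
                type=EntityType(cls),
                start=starts[i0],
                end=starts[i0 + n - 1] + len(words[i0 + n - 1]),
            )
            for i0, n, cls in inserted
        )
        corpus.append(AnnotatedDocument(seq, entities))
    return corpus


def random_peaks(rng: random.Random, n: int) -> list[Peak]:
    """Random but grammar-renderable NMR peaks (2-d.p. shifts, 1-d.p. J)."""
    peaks = []
    for _ in range(n):
        if rng.random() < 0.2:
            hi = round(rng.uniform(0.5, 12.0), 2)
            lo = round(hi - rng.uniform(0.05, 0.5), 2)
            shift: float | tuple[float, float] = (hi, lo)
        else:
            shift = round(rng.uniform(0.0, 12.0), 2)
        couplings = tuple(
            round(rng.uniform(0.5, 18.0), 1) for _ in range(rng.choice((0, 0, 1, 2)))
        )
        peaks.append(
            Peak(
                shift=shift,
                multiplicity=rng.choice(_MULTIPLICITIES),
                integration=rng.randint(1, 12),
                couplings=couplings,
            )
        )
    return peaks


def write_corpus(spec: CorpusSpec, out_dir: str | Path) -> None:
    """Materialise a corpus: plain text, standoff JSON and word lists."""
    from .memm import corpus_to_json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus = generate_corpus(spec)
    (out / "corpus.json").write_text(corpus_to_json(corpus), encoding="utf-8")
    (out / "corpus.txt").write_text(
        "\n\n".join(doc.seq.text for doc in corpus) + "\n", encoding="utf-8"
    )
    lists = generate_word_lists(spec)
    (out / "chemical_words.txt").write_text(
        "\n".join(sorted(lists.chemical)) + "\n", encoding="utf-8"
    )
    (out / "plain_words.txt").write_text(
        "\n".join(sorted(lists.nonchemical)) + "\n", encoding="utf-8"
    )
    (out / "spec.json").write_text(
        json.dumps(
            {
                "seed": spec.seed,
                "n_sentences": spec.n_sentences,
                "entity_rate": spec.entity_rate,
                "multi_token_rate": spec.multi_token_rate,
                "class_mix": spec.class_mix,
            }
        ),
        encoding="utf-8",
    )
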