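"""Character n-gram naïve Bayes classifier for "chemical" vs "non-chemical" tokens.

Two word lists — chemical names and ordinary English words with the chemical
names removed — are turned into class-conditional character n-gram count
tables.  A token is scored by the log-likelihood ratio of its padded n-gram
windows under the two classes (additive smoothing, shared unseen bucket), and
the ratio is mapped to a probability with a logistic transform offset by the
prior log-odds.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass
from functools import cached_property
from importlib import resources as importlib_resources

from .tokeniser import classifier_surface

PAD_START = "^"
PAD_END = "$"

_DIGITS = re.compile(r"[0-9]")


def normalise_word(word: str) -> str:
    """Case-fold, map subscript digits to ASCII and all digits to "0".

    Digit collapsing makes the model respond to token *shape* ("C2H6O" and
    "C3H8O" share windows) rather than particular numbers.
    """
    return _DIGITS.sub("0", classifier_surface(word).casefold())


@dataclass(frozen=True)
class WordLists:
    """Disjoint chemical / non-chemical training vocabularies."""

    chemical: frozenset[str]
    nonchemical: frozenset[str]

    def __post_init__(self) -> None:
        if not self.chemical or not self.nonchemical:
            raise ValueError("both word lists must be non-empty")
        if self.chemical & self.nonchemical:
            raise ValueError("word lists must be disjoint")


def build_word_lists(
    chemical_lexicon: set[str], english_dictionary: set[str]
) -> WordLists:
    """Lowercase both inputs and remove chemical words from the English side."""
    chemical = frozenset(w.casefold() for w in chemical_lexicon)
    nonchemical = frozenset(w.casefold() for w in english_dictionary) - chemical
    if not chemical:
        raise ValueError("chemical word list is empty")
    if not nonchemical:
        raise ValueError("non-chemical word list is empty after removing chemical words")
    return WordLists(chemical=chemical, nonchemical=nonchemical)


def ngram_windows(word: str, n: int) -> list[str]:
    """All length-n windows of the padded word: (n-1) leading '^', one '$'."""
    padded = PAD_START * (n - 1) + word + PAD_END
    return [padded[i : i + n] for i in range(len(padded) - n + 1)]


class NGramModel:
    """Smoothed class-conditional n-gram tables plus a chemical prior."""

    def __init__(
        self,
        n: int = 4,
        alpha: float = 1.0,
        prior_chem: float = 0.5,
        chem_counts: Counter[str] | None = None,
        nonchem_counts: Counter[str] | None = None,
    ) -> None:
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 < prior_chem < 1.0:
            raise ValueError("prior_chem must lie strictly in (0, 1)")
        self.n = n
        self.alpha = alpha
        self.prior_chem = prior_chem
        self.chem_counts: Counter[str] = chem_counts or Counter()
        self.nonchem_counts: Counter[str] = nonchem_counts or Counter()

    # -- derived quantities (counts are frozen once the model is built) ------

    @cached_property
    def chem_total(self) -> int:
        return sum(self.chem_counts.values())

    @cached_property
    def nonchem_total(self) -> int:
        return sum(self.nonchem_counts.values())

    @cached_property
    def vocab_size(self) -> int:
        """Distinct n-grams seen in either class, plus one unseen bucket."""
        return len(self.chem_counts.keys() | self.nonchem_counts.keys()) + 1

    # -- scoring ------------------------------------------------------------

    def score(self, token: str) -> float:
        """Log-likelihood ratio log P(token|chem) - log P(token|nonchem)."""
        if not token:
            raise ValueError("cannot score an empty token")
        word = normalise_word(token)
        v = self.vocab_size
        denom_c = math.log(self.chem_total + self.alpha * v)
        denom_n = math.log(self.nonchem_total + self.alpha * v)
        total = 0.0
        for g in ngram_windows(word, self.n):
            total += math.log(self.chem_counts.get(g, 0) + self.alpha) - denom_c
            total -= math.log(self.nonchem_counts.get(g, 0) + self.alpha) - denom_n
        return total

    def p_chemical(self, token: str) -> float:
        """Posterior probability that the token is chemical.

        Logistic transform of the log-likelihood ratio offset by the prior
        log-odds; strictly monotone in the score.
        """
        z = self.score(token) + math.log(self.prior_chem / (1.0 - self.prior_chem))
        if z >= 0:
            return 1.0 / (1.0 + math.exp(-z))
        e = math.exp(z)
        return e / (1.0 + e)

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "alpha": self.alpha,
                "prior_chem": self.prior_chem,
                "chem_counts": dict(self.chem_counts),
                "nonchem_counts": dict(self.nonchem_counts),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "NGramModel":
        raw = json.loads(payload)
        return cls(
            n=raw["n"],
            alpha=raw["alpha"],
            prior_chem=raw["prior_chem"],
            chem_counts=Counter(raw["chem_counts"]),
            nonchem_counts=Counter(raw["nonchem_counts"]),
        )


def train(
    lists: WordLists,
    n: int = 4,
    alpha: float = 1.0,
    prior_chem: float = 0.5,
) -> NGramModel:
    """Count every n-gram window of every (normalised) training word."""
    chem: Counter[str] = Counter()
    nonchem: Counter[str] = Counter()
    for word in lists.chemical:
        chem.update(ngram_windows(normalise_word(word), n))
    for word in lists.nonchemical:
        nonchem.update(ngram_windows(normalise_word(word), n))
    return NGramModel(
        n=n, alpha=alpha, prior_chem=prior_chem, chem_counts=chem, nonchem_counts=nonchem
    )


def load_word_list(path: str) -> set[str]:
    """One word per line; blank lines and '#' comments ignored."""
    with open(path, encoding="utf-8") as fh:
        return {
            line.strip()
            for line in fh
            if line.strip() and not line.lstrip().startswith("#")
        }


def default_word_lists() -> WordLists:
    """Packaged fixture vocabularies (small, for defaults and tests)."""
    res = importlib_resources.files("chemtagger.resources")
    chem = {
        w
        for w in res.joinpath("chemical_words.txt").read_text("utf-8").splitlines()
        if w.strip()
    }
    eng = {
        w
        for w in res.joinpath("english_words.txt").read_text("utf-8").splitlines()
        if w.strip()
    }
    return build_word_lists(chem, eng)


def default_model() -> NGramModel:
    """N-gram model trained on the packaged fixture word lists."""
    return train(default_word_lists())
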