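"""Chemistry-aware tokenisation.

Plain whitespace/punctuation tokenisers mangle chemical text: "C-H" must stay
one token, "2,5-dichlorobenzylamine" must keep its locant prefix attached and
"NSC-2648" must not lose its serial number.  The tokeniser here splits on
whitespace, then iteratively peels punctuation off token edges with three
guards:

* a trailing period stays attached when the rest of the unit is a known
  abbreviation ("Fig.", "calcd.") or a single letter;
* an edge bracket is only peeled when the remainder stays bracket-balanced
  (so "(S)-ibuprofen" survives but "(42)" splits into "(", "42", ")");
* internal hyphens are preserved unless the text after the hyphen is a
  generic suffix ("water-based" -> "water", "-", "based"), so hyphenated
  chemical names and serial numbers stay whole.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from importlib import resources as importlib_resources

from .document import Token, TokenSequence

DEFAULT_SPLIT_SUFFIXES = (
    "based",
    "containing",
    "free",
    "rich",
    "dependent",
    "induced",
    "mediated",
    "derived",
    "treated",
)

DEFAULT_STRIP_CHARS = ".,;:!?\"'()[]{}"

_OPENERS = {"(": ")", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _OPENERS.items()}

# Unicode subscript digits -> ASCII, used for classifier-side normalisation
SUBSCRIPT_DIGITS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")


def _load_default_abbreviations() -> frozenset[str]:
    text = (
        importlib_resources.files("chemtagger.resources")
        .joinpath("abbreviations.txt")
        .read_text(encoding="utf-8")
    )
    out = set()
    for line in text.splitlines():
        word = line.strip().rstrip(".")
        if word and not word.startswith("#"):
            out.add(word)
    return frozenset(out)


@dataclass(frozen=True)
class TokeniserConfig:
    """Edge-punctuation and hyphen-splitting policy.

    ``split_suffixes`` are lowercase suffixes that force a hyphen split;
    ``strip_chars`` are characters peeled from token edges; ``abbreviations``
    (stored without the period) protect a trailing period.
    """

    split_suffixes: tuple[str, ...] = DEFAULT_SPLIT_SUFFIXES
    strip_chars: str = DEFAULT_STRIP_CHARS
    abbreviations: frozenset[str] = field(default_factory=_load_default_abbreviations)

    def __post_init__(self) -> None:
        if not self.strip_chars:
            raise ValueError("strip_chars must be non-empty")
        if any(s != s.lower() for s in self.split_suffixes):
            raise ValueError("split_suffixes must be lowercase")

    @classmethod
    def from_json(cls, path: str) -> "TokeniserConfig":
        """Load overrides from a JSON config file."""
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        kwargs = {}
        if "split_suffixes" in raw:
            kwargs["split_suffixes"] = tuple(raw["split_suffixes"])
        if "strip_chars" in raw:
            kwargs["strip_chars"] = raw["strip_chars"]
        if "abbreviations" in raw:
            kwargs["abbreviations"] = frozenset(
                a.rstrip(".") for a in raw["abbreviations"]
            )
        return cls(**kwargs)


def normalise(text: str) -> str:
    """NFC-normalise a document before any offsets are assigned."""
    return unicodedata.normalize("NFC", text)


def classifier_surface(surface: str) -> str:
    """Parallel normalised surface for classifiers: subscripts -> ASCII digits.

    Offsets always refer to the original surface; this form is never used for
    slicing.
    """
    return surface.translate(SUBSCRIPT_DIGITS)


def split_paragraphs(text: str) -> list[tuple[str, int]]:
    """Split a document into (paragraph text, document offset) skeletons.

    Paragraphs are maximal runs separated by one or more blank lines;
    concatenating the paragraphs and separators reconstructs the input.
    """
    paragraphs: list[tuple[str, int]] = []
    pos = 0
    n = len(text)
    while pos < n:
        # skip a separator run: whitespace containing at least the structure
        # of blank lines / leading whitespace
        start = pos
        while start < n and text[start] in "\r\n":
            start += 1
        if start >= n:
            break
        # paragraph runs until a blank line (two consecutive newlines with
        # only horizontal whitespace between them) or end of text
        end = start
        while end < n:
            if text[end] == "\n":
                # look ahead: is the next non-horizontal-space char a newline?
                j = end + 1
                while j < n and text[j] in " \t\r":
                    j += 1
                if j >= n or text[j] == "\n":
                    break
            end += 1
        chunk = text[start:end]
        if chunk.strip():
            paragraphs.append((chunk, start))
        pos = end + 1 if end < n else n
    return paragraphs


def _balanced(s: str) -> bool:
    """True iff every bracket in ``s`` is properly matched."""
    stack: list[str] = []
    for ch in s:
        if ch in _OPENERS:
            stack.append(ch)
        elif ch in _CLOSERS:
            if not stack or stack[-1] != _CLOSERS[ch]:
                return False
            stack.pop()
    return not stack


def _split_unit(surface: str, start: int, config: TokeniserConfig) -> list[tuple[str, int]]:
    """Recursively split one whitespace-delimited unit into (surface, start) parts."""
    if len(surface) <= 1:
        return [(surface, start)]

    first, last = surface[0], surface[-1]

    # trailing punctuation
    if last in config.strip_chars:
        keep = False
        if last == ".":
            head = surface[:-1]
            if head in config.abbreviations or (len(head) == 1 and head.isalpha()):
                keep = True
        if last in _CLOSERS or last in _OPENERS:
            if not _balanced(surface[:-1]):
                keep = True
        if not keep:
            return _split_unit(surface[:-1], start, config) + [
                (last, start + len(surface) - 1)
            ]

    # leading punctuation
    if first in config.strip_chars:
        strip_ok = True
        if first in _OPENERS or first in _CLOSERS:
            strip_ok = _balanced(surface[1:])
        if strip_ok:
            return [(first, start)] + _split_unit(surface[1:], start + 1, config)

    # matched enclosing bracket pair: peel both at once ("(42)" -> "(","42",")")
    if (
        first in _OPENERS
        and last == _OPENERS[first]
        and first in config.strip_chars
        and _balanced(surface[1:-1])
    ):
        return (
            [(first, start)]
            + _split_unit(surface[1:-1], start + 1, config)
            + [(last, start + len(surface) - 1)]
        )

    # hyphen-suffix split: "water-based" -> "water", "-", "based"
    lowered = surface.casefold()
    for suffix in config.split_suffixes:
        probe = "-" + suffix
        if lowered.endswith(probe) and len(surface) > len(probe):
            cut = len(surface) - len(probe)
            return (
                _split_unit(surface[:cut], start, config)
                + [("-", start + cut)]
                + _split_unit(surface[cut + 1 :], start + cut + 1, config)
            )

    return [(surface, start)]


def tokenise(
    paragraph: str,
    offset: int = 0,
    config: TokeniserConfig | None = None,
) -> TokenSequence:
    """Tokenise one paragraph into a :class:`TokenSequence`.

    ``offset`` is the paragraph's document offset; emitted token offsets are
    document-level.  Every token satisfies ``paragraph[s-offset:e-offset] ==
    surface``.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if config is None:
        config = TokeniserConfig()

    pieces: list[tuple[str, int]] = []
    i = 0
    n = len(paragraph)
    while i < n:
        if paragraph[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not paragraph[j].isspace():
            j += 1
        pieces.extend(_split_unit(paragraph[i:j], offset + i, config))
        i = j

    tokens = tuple(
        Token(surface=s, start=p, end=p + len(s), index=k)
        for k, (s, p) in enumerate(pieces)
    )
    return TokenSequence(text=paragraph, offset=offset, tokens=tokens)


def tokenise_document(
    text: str, config: TokeniserConfig | None = None
) -> list[TokenSequence]:
    """Split a (pre-normalised) document into paragraphs and tokenise each."""
    return [
        tokenise(para, off, config)
        for para, off in split_paragraphs(text)
        if para.strip()
    ]
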