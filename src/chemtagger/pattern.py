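"""Pattern-based chemical entity recognition.

Each token is first classified chemical / non-chemical with the n-gram naïve
Bayes model; maximal runs of consecutive chemical tokens are then scanned
left-to-right against glob patterns such as ``*yl *ate`` (matching e.g.
"ethyl acetate") to assemble multi-token entities.  Chemical tokens not
consumed by a pattern become single-token entities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from math import exp, log

from .document import EntityType, NamedEntity, TokenSequence
from .ngram import NGramModel


@dataclass(frozen=True)
class PatternDefinition:
    """An ordered list of per-token globs; ``*`` matches any character run."""

    token_patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.token_patterns:
            raise ValueError("a pattern needs at least one token glob")
        if any(p != p.lower() for p in self.token_patterns):
            raise ValueError("patterns must be lowercase")

    def __len__(self) -> int:
        return len(self.token_patterns)


def _default_patterns() -> tuple[PatternDefinition, ...]:
    text = (
        importlib_resources.files("chemtagger.resources")
        .joinpath("patterns.txt")
        .read_text("utf-8")
    )
    return parse_pattern_file(text)


def parse_pattern_file(text: str) -> tuple[PatternDefinition, ...]:
    """One pattern per line, token globs space-separated; '#' comments."""
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(PatternDefinition(tuple(line.split())))
    return tuple(out)


@dataclass(frozen=True)
class PatternRecogniserConfig:
    threshold: float = 0.5
    patterns: tuple[PatternDefinition, ...] = field(default_factory=_default_patterns)

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")


def glob_matches(pattern: str, surface: str) -> bool:
    """Whole-token glob match, case-folded; ``*`` matches any run (may be empty)."""
    if not pattern:
        raise ValueError("empty glob pattern")
    s = surface.casefold()
    parts = pattern.split("*")
    if len(parts) == 1:
        return s == pattern
    head, *middle, tail = parts
    if not s.startswith(head) or not s.endswith(tail):
        return False
    pos, limit = len(head), len(s) - len(tail)
    for part in middle:
        if part:
            idx = s.find(part, pos, limit)
            if idx < 0:
                return False
            pos = idx + len(part)
    return pos <= limit


def _geometric_mean(ps: list[float]) -> float:
    if any(p == 0.0 for p in ps):
        return 0.0
    return exp(sum(log(p) for p in ps) / len(ps))


def _is_word_like(surface: str) -> bool:
    """Tokens with no letters (numbers, bare punctuation) are never chemical."""
    return any(ch.isalpha() for ch in surface)


def find_entities(
    seq: TokenSequence,
    model: NGramModel,
    config: PatternRecogniserConfig | None = None,
) -> list[NamedEntity]:
    """Emit non-overlapping CM entities from one token sequence.

    Within each maximal run of chemical tokens the longest leftmost pattern
    match wins; leftover chemical tokens are emitted singly.  Entity
    confidence is the geometric mean of its tokens' chemical probabilities.
    """
    if config is None:
        config = PatternRecogniserConfig()

    probs = [
        model.p_chemical(t.surface) if _is_word_like(t.surface) else 0.0
        for t in seq.tokens
    ]
    chemical = [p >= config.threshold for p in probs]

    entities: list[NamedEntity] = []
    i = 0
    n = len(seq.tokens)
    while i < n:
        if not chemical[i]:
            i += 1
            continue
        run_end = i
        while run_end < n and chemical[run_end]:
            run_end += 1
        j = i
        while j < run_end:
            best_len = 0
            for pat in config.patterns:
                k = len(pat)
                if k <= 1 or j + k > run_end or k <= best_len:
                    continue
                if all(
                    glob_matches(g, seq.tokens[j + d].surface)
                    for d, g in enumerate(pat.token_patterns)
                ):
                    best_len = k
            span = max(best_len, 1)
            toks = seq.tokens[j : j + span]
            surface = seq.text[
                toks[0].start - seq.offset : toks[-1].end - seq.offset
            ]
            entities.append(
                NamedEntity(
                    surface=surface,
                    type=EntityType.CM,
                    start=toks[0].start,
                    end=toks[-1].end,
                    confidence=_geometric_mean(probs[j : j + span]),
                )
            )
            j += span
        i = run_end
    return entities
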