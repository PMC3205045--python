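"""Deterministic recognisers: serial-number regexes, ontology-term dictionary
lookup and a finite-automaton matcher for chemical locant prefixes.

The ontology recogniser performs longest-leftmost token-aligned matching of a
term multimap (term -> ontology identifiers), the kind of lookup normally
seeded from ChEBI/FIX/REX term lists.  The prefix automaton accepts locant
prefixes such as "2,5-", "N,N-" or "cis-": one or more components (digit
runs, Greek letters, R/S/E/Z stereo-descriptors, cis/trans, o/m/p, N/O/S
locants) separated by commas and terminated by a hyphen.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources as importlib_resources

from .document import EntityType, NamedEntity, TokenSequence

DEFAULT_SERIAL_PATTERN = r"[A-Z]{2,4}-\d+"


def _normalise_term(term: str) -> str:
    return " ".join(term.casefold().split())


class OntologyTerms:
    """Multimap from normalised (possibly multi-word) term to identifier list."""

    def __init__(self, terms: dict[str, list[str]]) -> None:
        if not terms:
            raise ValueError("ontology term set must be non-empty")
        self._terms: dict[str, tuple[str, ...]] = {}
        for term, ids in terms.items():
            norm = _normalise_term(term)
            if not norm:
                raise ValueError("empty ontology term")
            if not ids:
                raise ValueError(f"term {term!r} has no identifiers")
            self._terms[norm] = self._terms.get(norm, ()) + tuple(ids)
        self.max_tokens = max(len(t.split()) for t in self._terms)

    def __contains__(self, term: str) -> bool:
        return _normalise_term(term) in self._terms

    def ids(self, term: str) -> tuple[str, ...]:
        return self._terms.get(_normalise_term(term), ())

    def __len__(self) -> int:
        return len(self._terms)

    @classmethod
    def from_tsv(cls, text: str) -> "OntologyTerms":
        """Parse "term<TAB>id" lines; repeated term lines accumulate ids."""
        terms: dict[str, list[str]] = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            term, ident = line.rstrip("\n").split("\t")
            terms.setdefault(term, []).append(ident)
        return cls(terms)

    @classmethod
    def default_instance(cls) -> "OntologyTerms":
        text = (
            importlib_resources.files("chemtagger.resources")
            .joinpath("ontology_fixture.tsv")
            .read_text("utf-8")
        )
        return cls.from_tsv(text)


@dataclass(frozen=True)
class RegexRecogniserConfig:
    """Whole-token regular-expression recogniser (compound serial numbers)."""

    pattern: str = DEFAULT_SERIAL_PATTERN
    type: EntityType = EntityType.CM

    def compiled(self) -> re.Pattern:
        try:
            return re.compile(self.pattern)
        except re.error as exc:
            raise ValueError(f"invalid recogniser pattern: {exc}") from exc


def regex_find(seq: TokenSequence, config: RegexRecogniserConfig) -> list[NamedEntity]:
    """Tokens fully matching the pattern become entities with confidence 1."""
    pattern = config.compiled()
    return [
        NamedEntity(
            surface=t.surface,
            type=config.type,
            start=t.start,
            end=t.end,
            confidence=1.0,
        )
        for t in seq.tokens
        if pattern.fullmatch(t.surface)
    ]


def ontology_find(seq: TokenSequence, terms: OntologyTerms) -> list[NamedEntity]:
    """Longest-leftmost token-aligned dictionary matches, typed ONT.

    Matching compares normalised token surfaces joined by single spaces; the
    emitted entity carries every identifier registered for the term.
    """
    surfaces = [t.surface.casefold() for t in seq.tokens]
    entities: list[NamedEntity] = []
    i, n = 0, len(seq.tokens)
    while i < n:
        matched = 0
        for length in range(min(terms.max_tokens, n - i), 0, -1):
            candidate = " ".join(surfaces[i : i + length])
            if candidate in terms:
                matched = length
                break
        if matched:
            toks = seq.tokens[i : i + matched]
            surface = seq.text[toks[0].start - seq.offset : toks[-1].end - seq.offset]
            entities.append(
                NamedEntity(
                    surface=surface,
                    type=EntityType.ONT,
                    start=toks[0].start,
                    end=toks[-1].end,
                    confidence=1.0,
                    ontology_ids=terms.ids(" ".join(surfaces[i : i + matched])),
                )
            )
            i += matched
        else:
            i += 1
    return entities


class PrefixAutomaton:
    """Finite automaton for locant prefixes ending in "-".

    Built from component word classes (plus optional digit runs); matching is
    an online-determinised walk over a shared component trie, so acceptance
    is linear in the token length.
    """

    def __init__(self, components: list[str], digit_runs: bool = True) -> None:
        if not components and not digit_runs:
            raise ValueError("automaton needs at least one component class")
        self._root: dict = {}
        for comp in components:
            if not comp:
                raise ValueError("empty component")
            node = self._root
            for ch in comp:
                node = node.setdefault(ch, {})
            node["\0"] = True  # terminal marker
        self.digit_runs = digit_runs

    @classmethod
    def from_grammar(cls, grammar: dict) -> "PrefixAutomaton":
        comps = [c for group in grammar.get("components", {}).values() for c in group]
        return cls(comps, digit_runs=bool(grammar.get("digit_runs", True)))

    @classmethod
    def default_instance(cls) -> "PrefixAutomaton":
        text = (
            importlib_resources.files("chemtagger.resources")
            .joinpath("prefix_grammar.json")
            .read_text("utf-8")
        )
        return cls.from_grammar(json.loads(text))

    def longest_accepting_prefix(self, s: str) -> int:
        """Length of the longest accepted prefix of ``s`` (0 if none).

        Accepted strings always end in "-"; because the hyphen is the sole
        terminator the first acceptance is also the longest.
        """
        nodes = [self._root]
        digit = False
        complete = False
        for k, ch in enumerate(s):
            if complete and ch == "-":
                return k + 1
            if complete and ch == ",":
                nodes, digit, complete = [self._root], False, False
                continue
            at_start = any(n is self._root for n in nodes)
            new_nodes = [n[ch] for n in nodes if ch in n]
            new_digit = self.digit_runs and ch.isdigit() and (digit or at_start)
            if not new_nodes and not new_digit:
                return 0
            complete = new_digit or any("\0" in n for n in new_nodes)
            nodes, digit = new_nodes, new_digit
        return 0

    def accepts(self, s: str) -> bool:
        return self.longest_accepting_prefix(s) == len(s) and len(s) > 0


def prefix_find(seq: TokenSequence, automaton: PrefixAutomaton) -> list[NamedEntity]:
    """Longest accepting locant prefix of each token becomes a CPR entity."""
    entities = []
    for t in seq.tokens:
        length = automaton.longest_accepting_prefix(t.surface)
        if length:
            entities.append(
                NamedEntity(
                    surface=t.surface[:length],
                    type=EntityType.CPR,
                    start=t.start,
                    end=t.start + length,
                    confidence=1.0,
                )
            )
    return entities
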