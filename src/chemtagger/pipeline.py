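"""Single-object facade: tokenise, recognise, merge, resolve.

A :class:`Pipeline` owns its entire configuration as instance state — there
are no module-level singletons and no workspace directory — so two pipelines
with different components coexist in one process and a pipeline can be safely
shared across threads for distinct documents.  Construction with no arguments
"just works" on the packaged fixture resources (pattern recogniser, fixture
n-gram model, fixture ontology, fixture dictionary).

Candidate entities from the active recogniser, the ontology lookup and the
prefix automaton are merged by a deterministic cascade: longer span wins,
then type priority CM > ONT > CPR > RN > CJ > ASE, then higher confidence.
Prefix (CPR) entities that abut or lie inside a chemical span are dropped as
redundant locants.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

from . import lexicon, memm as memm_mod, pattern, resolution
from .dataparser import DataAnnotation, find_data
from .document import (
    EntityType,
    NamedEntity,
    ResolvedNamedEntity,
    TokenSequence,
    entities_overlap,
)
from .memm import MEMMModel, FEATURE_TEMPLATE_VERSION, TemplateMismatchError
from .ngram import NGramModel, default_model
from .tokeniser import TokeniserConfig, normalise, tokenise_document

logger = logging.getLogger("chemtagger")

_TYPE_PRIORITY = {
    EntityType.CM: 0,
    EntityType.ONT: 1,
    EntityType.CPR: 2,
    EntityType.RN: 3,
    EntityType.CJ: 4,
    EntityType.ASE: 5,
    EntityType.DATA: 6,
}

RECOGNISERS = ("pattern", "memm", "regex")


class ConfigurationError(ValueError):
    """Invalid or incompatible pipeline configuration."""


def merge_entities(candidates: Sequence[NamedEntity]) -> list[NamedEntity]:
    """Resolve overlaps: longer span, then type priority, then confidence.

    Idempotent: merging an already-merged list returns it unchanged (up to
    start-order sorting).
    """
    ranked = sorted(
        candidates,
        key=lambda e: (
            -(e.end - e.start),
            _TYPE_PRIORITY[e.type],
            -(e.confidence if e.confidence is not None else 0.0),
            e.start,
        ),
    )
    kept: list[NamedEntity] = []
    for cand in ranked:
        if not any(entities_overlap(cand, k) for k in kept):
            kept.append(cand)
    cm_spans = [(e.start, e.end) for e in kept if e.type is EntityType.CM]
    result = [
        e
        for e in kept
        if not (
            e.type is EntityType.CPR
            and any(
                (e.start >= s and e.end <= t) or e.end == s or e.start == t
                for s, t in cm_spans
            )
        )
    ]
    return sorted(result, key=lambda e: (e.start, e.end))


class Pipeline:
    """Configurable end-to-end chemical text-mining workflow."""

    def __init__(
        self,
        tokeniser_config: TokeniserConfig | None = None,
        recogniser: str = "pattern",
        ngram_model: NGramModel | None = None,
        memm_model: MEMMModel | None = None,
        pattern_config: pattern.PatternRecogniserConfig | None = None,
        regex_config: lexicon.RegexRecogniserConfig | None = None,
        ontology_terms: lexicon.OntologyTerms | None = None,
        prefix_automaton: lexicon.PrefixAutomaton | None = None,
        registry: resolution.DictionaryRegistry | None = None,
    ) -> None:
        self.tokeniser_config = tokeniser_config or TokeniserConfig()
        self.ngram_model = ngram_model or default_model()
        self.pattern_config = pattern_config or pattern.PatternRecogniserConfig()
        self.regex_config = regex_config or lexicon.RegexRecogniserConfig()
        self.ontology_terms = ontology_terms or lexicon.OntologyTerms.default_instance()
        self.prefix_automaton = (
            prefix_automaton or lexicon.PrefixAutomaton.default_instance()
        )
        self.registry = registry or resolution.DictionaryRegistry.default_instance()
        self.memm_model = None
        if memm_model is not None:
            self.set_memm_model(memm_model)
        self.recogniser: str | Callable = "pattern"
        self.set_recogniser(recogniser)

    # -- component replacement (always local, never global) ------------------

    def set_recogniser(self, recogniser: str | Callable) -> "Pipeline":
        """Select "pattern", "memm", "regex" or a custom callable(seq)->entities."""
        if isinstance(recogniser, str):
            if recogniser not in RECOGNISERS:
                raise ConfigurationError(
                    f"unknown recogniser {recogniser!r}; choose from {RECOGNISERS}"
                )
            if recogniser == "memm" and self.memm_model is None:
                raise ConfigurationError("memm recogniser requires a MEMM model")
        elif not callable(recogniser):
            raise ConfigurationError("recogniser must be a name or a callable")
        self.recogniser = recogniser
        return self

    def set_memm_model(self, model: MEMMModel) -> "Pipeline":
        if model.template_version != FEATURE_TEMPLATE_VERSION:
            raise ConfigurationError(
                f"MEMM model built with feature templates "
                f"{model.template_version!r}, expected {FEATURE_TEMPLATE_VERSION!r}"
            )
        self.memm_model = model
        return self

    def set_ngram_model(self, model: NGramModel) -> "Pipeline":
        self.ngram_model = model
        return self

    def set_dictionary_registry(self, registry: resolution.DictionaryRegistry) -> "Pipeline":
        self.registry = registry
        return self

    def set_ontology_terms(self, terms: lexicon.OntologyTerms) -> "Pipeline":
        self.ontology_terms = terms
        return self

    # -- recognition ----------------------------------------------------------

    def _recognise(self, seq: TokenSequence) -> list[NamedEntity]:
        if callable(self.recogniser):
            return list(self.recogniser(seq))
        if self.recogniser == "pattern":
            return pattern.find_entities(seq, self.ngram_model, self.pattern_config)
        if self.recogniser == "memm":
            if self.memm_model is None:
                raise ConfigurationError("memm recogniser requires a MEMM model")
            return memm_mod.decode(seq, self.memm_model, self.ngram_model)
        return lexicon.regex_find(seq, self.regex_config)

    def find_named_entities(self, text: str) -> list[NamedEntity]:
        """Tokenise, run all recognisers and merge their candidates."""
        text = normalise(text)
        entities: list[NamedEntity] = []
        sequences = tokenise_document(text, self.tokeniser_config)
        for seq in sequences:
            candidates = (
                self._recognise(seq)
                + lexicon.ontology_find(seq, self.ontology_terms)
                + lexicon.prefix_find(seq, self.prefix_automaton)
            )
            entities.extend(merge_entities(candidates))
        logger.debug(
            "found %d entities in %d paragraphs", len(entities), len(sequences)
        )
        return sorted(entities, key=lambda e: (e.start, e.end))

    def find_data(self, text: str) -> list[DataAnnotation]:
        """Locate and parse experimental-data spans."""
        return find_data(normalise(text))

    def find_and_resolve_named_entities(
        self, text: str
    ) -> list[ResolvedNamedEntity | NamedEntity]:
        """All entities, with CM entities resolved to structures where possible.

        Order and spans are identical to :meth:`find_named_entities`;
        unresolvable entities are passed through unresolved.
        """
        out: list[ResolvedNamedEntity | NamedEntity] = []
        for e in self.find_named_entities(text):
            if e.type is EntityType.CM:
                resolved = resolution.resolve(e, self.registry)
                out.append(resolved if resolved is not None else e)
            else:
                out.append(e)
        return out

    def find_resolvable_entities(self, text: str) -> list[ResolvedNamedEntity]:
        """Exactly the resolved subset of :meth:`find_and_resolve_named_entities`."""
        return [
            r
            for r in self.find_and_resolve_named_entities(text)
            if isinstance(r, ResolvedNamedEntity)
        ]
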