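"""Core document model: tokens, token sequences, named entities and structures.

Every annotation produced by the library is anchored to the source document by
0-based, half-open *character* (code point) offsets into the NFC-normalised
text, so that ``text[start:end] == surface`` always holds.  Annotations are
standoff: the source text is never mutated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class EntityType(str, Enum):
    """Closed set of entity classes.

    CM = chemical, ONT = ontology term, RN = reaction, CJ = chemical
    adjective, ASE = enzyme, CPR = chemical (locant) prefix.  DATA is reserved
    for parsed experimental-data spans so they can share the standoff channel.
    """

    CM = "CM"
    ONT = "ONT"
    RN = "RN"
    CJ = "CJ"
    ASE = "ASE"
    CPR = "CPR"
    DATA = "DATA"


class StructureFormat(str, Enum):
    SMILES = "SMILES"
    INCHI = "INCHI"
    CML = "CML"


@dataclass(frozen=True)
class Token:
    """A positioned text unit: a word, number, punctuation mark etc.

    ``start``/``end`` are document-level character offsets; ``index`` is the
    token's position within its :class:`TokenSequence`.
    """

    surface: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")
        if self.end - self.start != len(self.surface):
            raise ValueError(
                f"token span [{self.start},{self.end}) inconsistent with "
                f"surface of length {len(self.surface)}"
            )


@dataclass(frozen=True)
class TokenSequence:
    """An ordered run of tokens covering one paragraph of text.

    ``offset`` is the document offset of the paragraph's first character;
    token offsets are document-level (paragraph offset + local offset).
    """

    text: str
    offset: int
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        prev_end = self.offset
        for tok in self.tokens:
            if tok.start < prev_end:
                raise ValueError("tokens must be ordered and non-overlapping")
            if tok.start < self.offset or tok.end > self.offset + len(self.text):
                raise ValueError("token lies outside its paragraph")
            if self.text[tok.start - self.offset : tok.end - self.offset] != tok.surface:
                raise ValueError(f"token surface {tok.surface!r} does not match slice")
            prev_end = tok.end

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


@dataclass(frozen=True)
class NamedEntity:
    """A typed, offset-anchored text span with an optional confidence."""

    surface: str
    type: EntityType
    start: int
    end: int
    confidence: float | None = None
    ontology_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.surface):
            raise ValueError("entity span length inconsistent with surface")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class ChemicalStructure:
    """A machine-readable structure representation (SMILES, InChI or CML)."""

    format: StructureFormat
    value: str

    def __post_init__(self) -> None:
        if not self.value:
            raise ValueError("structure value must be non-empty")


@dataclass(frozen=True)
class ResolvedNamedEntity:
    """A named entity linked to one or more chemical structures.

    Unresolvable entities are represented by *absence* (no object), never by
    an empty structure list.
    """

    entity: NamedEntity
    structures: tuple[ChemicalStructure, ...]

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("a resolved entity carries at least one structure")

    def get_first_structure(
        self, format: StructureFormat
    ) -> ChemicalStructure | None:
        """First structure of the requested format, in stored order."""
        for s in self.structures:
            if s.format is format:
                return s
        return None


def entities_overlap(a: NamedEntity, b: NamedEntity) -> bool:
    """True iff the two half-open spans share at least one character."""
    return max(a.start, b.start) < min(a.end, b.end)


# ---------------------------------------------------------------------------
# Standoff serialisation
# ---------------------------------------------------------------------------

_STANDOFF_FIELDS = ("type", "start", "end", "surface", "confidence", "ids", "structures")


def to_standoff(entities: Iterable[NamedEntity]) -> list[dict]:
    """Serialise entities (or resolved entities) to standoff records.

    Order is preserved; the mapping is lossless for round-tripping through
    :func:`from_standoff`.
    """
    records = []
    for e in entities:
        structures = None
        if isinstance(e, ResolvedNamedEntity):
            structures = [[s.format.value, s.value] for s in e.structures]
            e = e.entity
        records.append(
            {
                "type": e.type.value,
                "start": e.start,
                "end": e.end,
                "surface": e.surface,
                "confidence": e.confidence,
                "ids": list(e.ontology_ids) or None,
                "structures": structures,
            }
        )
    return records


def from_standoff(records: Iterable[dict]) -> list[NamedEntity | ResolvedNamedEntity]:
    """Inverse of :func:`to_standoff`."""
    out: list[NamedEntity | ResolvedNamedEntity] = []
    for r in records:
        e = NamedEntity(
            surface=r["surface"],
            type=EntityType(r["type"]),
            start=r["start"],
            end=r["end"],
            confidence=r.get("confidence"),
            ontology_ids=tuple(r.get("ids") or ()),
        )
        if r.get("structures"):
            out.append(
                ResolvedNamedEntity(
                    e,
                    tuple(
                        ChemicalStructure(StructureFormat(f), v)
                        for f, v in r["structures"]
                    ),
                )
            )
        else:
            out.append(e)
    return out


def standoff_to_json(entities: Iterable[NamedEntity]) -> str:
    return json.dumps(to_standoff(entities), ensure_ascii=False, indent=1)


def standoff_from_json(payload: str) -> list[NamedEntity | ResolvedNamedEntity]:
    return from_standoff(json.loads(payload))


def standoff_to_tsv(entities: Iterable[NamedEntity]) -> str:
    """TSV variant: same columns as the JSON dialect, one entity per line."""
    lines = ["\t".join(_STANDOFF_FIELDS)]
    for r in to_standoff(entities):
        lines.append(
            "\t".join(
                ""
                if r[f] is None
                else (json.dumps(r[f]) if f in ("ids", "structures") else str(r[f]))
                for f in _STANDOFF_FIELDS
            )
        )
    return "\n".join(lines) + "\n"
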