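"""Name-to-structure resolution through an ordered registry of dictionaries.

Each dictionary maps normalised chemical names to structures (SMILES, InChI
or CML).  A registry consults its dictionaries in order, concatenates their
hits (deduplicated by format+value) and, only when every dictionary misses,
invokes an optional fallback resolver hook — the slot where a systematic-
nomenclature parser such as OPSIN can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Callable, Iterable

from .document import (
    ChemicalStructure,
    EntityType,
    NamedEntity,
    ResolvedNamedEntity,
    StructureFormat,
)


def _normalise_name(name: str) -> str:
    return " ".join(name.casefold().split())


class ChemNameDict:
    """One name -> structures table with a human-readable tag."""

    def __init__(self, name: str, entries: dict[str, list[ChemicalStructure]]) -> None:
        self.name = name
        self._entries: dict[str, tuple[ChemicalStructure, ...]] = {}
        for key, structures in entries.items():
            if not structures:
                raise ValueError(f"name {key!r} has an empty structure list")
            norm = _normalise_name(key)
            self._entries[norm] = self._entries.get(norm, ()) + tuple(structures)

    def lookup(self, name: str) -> tuple[ChemicalStructure, ...]:
        return self._entries.get(_normalise_name(name), ())

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_tsv(cls, name: str, text: str) -> "ChemNameDict":
        """Parse "name<TAB>format<TAB>value" lines (formats SMILES/InChI/CML)."""
        entries: dict[str, list[ChemicalStructure]] = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            key, fmt, value = line.rstrip("\n").split("\t")
            entries.setdefault(key, []).append(
                ChemicalStructure(StructureFormat(fmt.upper()), value)
            )
        return cls(name, entries)

    @classmethod
    def default_instance(cls) -> "ChemNameDict":
        text = (
            importlib_resources.files("chemtagger.resources")
            .joinpath("dictionary_fixture.tsv")
            .read_text("utf-8")
        )
        return cls.from_tsv("fixture", text)


ResolverHook = Callable[[str], Iterable[ChemicalStructure]]


@dataclass
class DictionaryRegistry:
    """Ordered dictionaries plus an optional fallback resolver hook."""

    dictionaries: list[ChemNameDict] = field(default_factory=list)
    fallback: ResolverHook | None = None

    @classmethod
    def default_instance(cls) -> "DictionaryRegistry":
        return cls(dictionaries=[ChemNameDict.default_instance()])

    def lookup(self, name: str) -> tuple[ChemicalStructure, ...]:
        """Structures for a name in registry order, deduplicated by value."""
        seen: set[tuple[StructureFormat, str]] = set()
        out: list[ChemicalStructure] = []
        for d in self.dictionaries:
            for s in d.lookup(name):
                key = (s.format, s.value)
                if key not in seen:
                    seen.add(key)
                    out.append(s)
        if not out and self.fallback is not None:
            for s in self.fallback(name):
                key = (s.format, s.value)
                if key not in seen:
                    seen.add(key)
                    out.append(s)
        return tuple(out)


def resolve(
    entity: NamedEntity, registry: DictionaryRegistry
) -> ResolvedNamedEntity | None:
    """Resolve a CM entity's surface; ``None`` when every source misses."""
    if entity.type is not EntityType.CM:
        raise ValueError("only CM entities are resolvable")
    structures = registry.lookup(entity.surface)
    if not structures:
        return None
    return ResolvedNamedEntity(entity, structures)
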