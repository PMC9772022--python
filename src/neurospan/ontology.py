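"""Hierarchical neuro-ontology of sign/symptom concepts and the phrase lookup table.

Concepts carry UMLS-style CUIs and live in a forest whose roots correspond to
the main elements of the neurological examination (mental status, cranial
nerves, motor, sensory, reflexes, symptoms). The lookup table maps normalized
surface phrases (preferred names and synonyms, plus any user-appended rows)
to CUIs and is the exact-match stage of concept normalization.
"""
from __future__ import annotations

import csv
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "EXAM_CATEGORIES",
    "Concept",
    "NeuroOntology",
    "LookupTable",
    "OntologyError",
    "get_concept",
    "normalize_phrase",
    "load_ontology",
    "write_ontology",
    "build_lookup_table",
    "load_lookup_table",
    "write_lookup_table",
]

#: The six top-level exam categories of the neuro-ontology.
EXAM_CATEGORIES: tuple[str, ...] = (
    "mental status",
    "cranial nerves",
    "motor",
    "sensory",
    "reflexes",
    "symptoms",
)

_EDGE_PUNCT = string.punctuation + string.whitespace


class OntologyError(ValueError):
    """Raised when an ontology or lookup table violates its invariants."""


def normalize_phrase(phrase: str) -> str:
    """Canonical lookup key: case-folded, whitespace-collapsed, edge punctuation stripped."""
    collapsed = " ".join(phrase.casefold().split())
    return collapsed.strip(_EDGE_PUNCT)


@dataclass(frozen=True)
class Concept:
    """One ontology concept: a CUI, names, a parent link, and its exam category."""

    cui: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()
    parent_cui: str | None = None
    exam_category: str = "symptoms"

    def __post_init__(self) -> None:
        if not self.cui:
            raise OntologyError("concept requires a CUI")
        if not self.preferred_name:
            raise OntologyError(f"concept {self.cui}: preferred name must be nonempty")
        if self.exam_category not in EXAM_CATEGORIES:
            raise OntologyError(
                f"concept {self.cui}: unknown exam category {self.exam_category!r}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return (self.preferred_name, *self.synonyms)


class NeuroOntology:
    """Validated concept forest keyed by CUI."""

    def __init__(self, concepts: Iterator[Concept] | list[Concept]):
        self.concepts: dict[str, Concept] = {}
        for concept in concepts:
            if concept.cui in self.concepts:
                raise OntologyError(f"duplicate CUI {concept.cui}")
            self.concepts[concept.cui] = concept
        self._validate()

    def _validate(self) -> None:
        for concept in self.concepts.values():
            parent = concept.parent_cui
            if parent is not None and parent not in self.concepts:
                raise OntologyError(
                    f"concept {concept.cui}: dangling parent {parent!r}"
                )
        # Parent links must form a forest: following parents from any node
        # terminates at a root without revisiting a node.
        for cui in self.concepts:
            seen = set()
            cur: str | None = cui
            while cur is not None:
                if cur in seen:
                    raise OntologyError(f"parent cycle involving {cui}")
                seen.add(cur)
                cur = self.concepts[cur].parent_cui

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, cui: str) -> bool:
        return cui in self.concepts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NeuroOntology):
            return NotImplemented
        return self.concepts == other.concepts

    def get(self, cui: str) -> Concept | None:
        """Return the concept for ``cui``, or None if unknown."""
        return self.concepts.get(cui)

    def roots(self) -> list[Concept]:
        return [c for c in self.concepts.values() if c.parent_cui is None]

    def children(self, cui: str) -> list[Concept]:
        return [c for c in self.concepts.values() if c.parent_cui == cui]


def get_concept(ontology: NeuroOntology, cui: str) -> Concept | None:
    """Functional alias for :meth:`NeuroOntology.get`."""
    return ontology.get(cui)


# ---------------------------------------------------------------------------
# CSV I/O  (columns: cui,name,synonyms,parent_cui,exam_category; synonyms
# pipe-separated within one cell)
# ---------------------------------------------------------------------------

_ONTOLOGY_COLUMNS = ["cui", "name", "synonyms", "parent_cui", "exam_category"]


def load_ontology(path: str | Path) -> NeuroOntology:
    """Load and validate an ontology from its CSV form."""
    concepts: list[Concept] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_ONTOLOGY_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise OntologyError(f"ontology CSV missing columns: {sorted(missing)}")
        for row in reader:
            synonyms = tuple(s for s in (row["synonyms"] or "").split("|") if s)
            concepts.append(
                Concept(
                    cui=row["cui"],
                    preferred_name=row["name"],
                    synonyms=synonyms,
                    parent_cui=row["parent_cui"] or None,
                    exam_category=row["exam_category"],
                )
            )
    return NeuroOntology(concepts)


def write_ontology(ontology: NeuroOntology, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(_ONTOLOGY_COLUMNS)
        for cui in sorted(ontology.concepts):
            c = ontology.concepts[cui]
            writer.writerow(
                [c.cui, c.preferred_name, "|".join(c.synonyms), c.parent_cui or "", c.exam_category]
            )


# ---------------------------------------------------------------------------
# Lookup table
# ---------------------------------------------------------------------------


@dataclass
class LookupTable:
    """Map from normalized phrase to CUI (the exact-match normalization stage)."""

    entries: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, phrase: str) -> bool:
        return normalize_phrase(phrase) in self.entries

    def get(self, phrase: str) -> str | None:
        return self.entries.get(normalize_phrase(phrase))

    def add(self, phrase: str, cui: str) -> None:
        """Add a phrase; collisions keep the lexicographically smaller CUI."""
        key = normalize_phrase(phrase)
        if not key:
            return
        existing = self.entries.get(key)
        if existing is not None and existing != cui:
            keep = min(existing, cui)
            logger.warning(
                "lookup collision for %r: %s vs %s, keeping %s", key, existing, cui, keep
            )
            self.entries[key] = keep
        else:
            self.entries[key] = cui

    def validate_against(self, ontology: NeuroOntology) -> None:
        for phrase, cui in self.entries.items():
            if cui not in ontology:
                raise OntologyError(f"lookup phrase {phrase!r} maps to unknown CUI {cui}")


def build_lookup_table(ontology: NeuroOntology) -> LookupTable:
    """Build the phrase→CUI table from every concept name and synonym.

    Phrases are normalized with :func:`normalize_phrase`; a phrase shared by
    two concepts is kept for the lexicographically smallest CUI and the
    collision is logged as a warning.
    """
    table = LookupTable()
    for cui in sorted(ontology.concepts):
        concept = ontology.concepts[cui]
        for name in concept.names:
            table.add(name, cui)
    return table


def load_lookup_table(path: str | Path, ontology: NeuroOntology | None = None) -> LookupTable:
    table = LookupTable()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if set(reader.fieldnames or []) < {"phrase", "cui"}:
            raise OntologyError("lookup CSV requires columns phrase,cui")
        for row in reader:
            table.add(row["phrase"], row["cui"])
    if ontology is not None:
        table.validate_against(ontology)
    return table


def write_lookup_table(table: LookupTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(["phrase", "cui"])
        for phrase in sorted(table.entries):
            writer.writerow([phrase, table.entries[phrase]])
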