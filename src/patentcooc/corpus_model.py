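"""Data model and I/O for annotated patent corpora.

A corpus is a collection of per-(patent, section, entity-type) sets of
canonical entity identifiers, together with a patent -> patent-family map.
Annotations arrive as raw mention records (one row per mention of an entity
in a section of a patent, carrying a machine-annotation confidence score),
are filtered by confidence, mapped to canonical identifiers (see
:mod:`patentcooc.entity_mapping`) and deduplicated: a given identifier counts
at most once per (patent, section, type), no matter how many times it is
mentioned there. The cardinality of each set is the per-section entity count
that drives the informativeness weights in :mod:`patentcooc.scoring`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional


class EntityType(str, Enum):
    """The three entity categories scored against each other.

    ``GENE`` covers genes, proteins, and enzymes: gene and protein names are
    usually indistinguishable in text, so they are treated as one category.
    """

    CHEMICAL = "chemical"
    DISEASE = "disease"
    GENE = "gene"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Source annotation labels that map onto each entity type.
CHEMICAL_SOURCE_TYPES = frozenset(
    {"chemCompound", "drugs", "inorgmat", "natprod", "polymers", "substances"}
)
DISEASE_SOURCE_TYPES = frozenset({"diseases"})
GENE_SOURCE_TYPES = frozenset({"humangenes", "proteins"})
SOURCE_TYPES = CHEMICAL_SOURCE_TYPES | DISEASE_SOURCE_TYPES | GENE_SOURCE_TYPES

#: The four named patent sections. Anything else is preserved verbatim
#: (lower-cased) and scored with the default per-section capacity.
CANONICAL_SECTIONS = ("title", "abstract", "claims", "description")

ANNOTATION_COLUMNS = (
    "patent_id",
    "section",
    "source_type",
    "inchikey",
    "name",
    "confidence",
)
_REQUIRED_COLUMNS = ("patent_id", "section", "source_type", "confidence")


class SchemaError(ValueError):
    """The input file does not have the documented columns/keys."""


class DataError(ValueError):
    """The input data violates a corpus invariant."""


class TooManyRowErrors(DataError):
    """More than the tolerated fraction of rows were malformed."""


@dataclass(frozen=True)
class RowError:
    """A single malformed input row, reported with its 1-based line number."""

    line: int
    message: str


def normalize_section(label: str) -> str:
    """Normalize a section label to a canonical, case-insensitive form.

    The four named sections (title, abstract, claims, description) match
    case-insensitively; any other non-empty label is preserved lower-cased
    so that unanticipated section vocabularies still round-trip.
    """
    if label is None or not label.strip():
        raise DataError("section label must be non-empty")
    return label.strip().lower()


@dataclass(frozen=True)
class RawAnnotation:
    """One mention of an entity in one section of one patent."""

    patent_id: str
    section: str
    source_type: str
    inchikey: Optional[str] = None
    name: Optional[str] = None
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise DataError(
                f"confidence {self.confidence!r} outside [0, 1] "
                f"for patent {self.patent_id!r}"
            )


def _parse_row(row: Mapping[str, str]) -> RawAnnotation:
    patent_id = (row.get("patent_id") or "").strip()
    if not patent_id:
        raise DataError("empty patent_id")
    section = normalize_section(row.get("section") or "")
    source_type = (row.get("source_type") or "").strip()
    if not source_type:
        raise DataError("empty source_type")
    raw_conf = row.get("confidence")
    try:
        confidence = float(raw_conf)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise DataError(f"confidence {raw_conf!r} is not a real number")
    inchikey = (row.get("inchikey") or "").strip() or None
    name = (row.get("name") or "").strip() or None
    return RawAnnotation(patent_id, section, source_type, inchikey, name, confidence)


def read_annotations(
    path,
    fmt: str = "tsv",
    errors: Optional[list] = None,
    max_error_fraction: float = 0.01,
) -> Iterator[RawAnnotation]:
    """Stream :class:`RawAnnotation` records from a TSV or JSONL file.

    Malformed rows are collected into ``errors`` (as :class:`RowError`, with
    line numbers) rather than aborting the stream; if, at the end of the
    file, more than ``max_error_fraction`` of the rows were malformed, a
    :class:`TooManyRowErrors` is raised. A missing required column is a
    :class:`SchemaError` and aborts immediately.
    """
    if fmt not in ("tsv", "jsonl"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    collected: list = errors if errors is not None else []
    total = 0
    with open(path, "r", encoding="utf-8", newline="") as handle:
        if fmt == "tsv":
            reader = csv.DictReader(handle, delimiter="\t")
            header = reader.fieldnames or []
            missing = [c for c in _REQUIRED_COLUMNS if c not in header]
            if missing:
                raise SchemaError(f"annotation file missing column(s): {missing}")
            rows: Iterable[tuple[int, Mapping[str, str]]] = (
                (reader.line_num, row) for row in reader
            )
        else:
            def _jsonl_rows(h):
                for lineno, line in enumerate(h, start=1):
                    if not line.strip():
                        continue
                    try:
                        obj = json.loads(line)
                    except json.JSONDecodeError as exc:
                        yield lineno, exc
                        continue
                    if not isinstance(obj, dict):
                        yield lineno, DataError("JSONL row is not an object")
                        continue
                    missing = [c for c in _REQUIRED_COLUMNS if c not in obj]
                    if missing:
                        yield lineno, SchemaError(
                            f"JSONL row missing key(s): {missing}"
                        )
                        continue
                    yield lineno, obj

            rows = _jsonl_rows(handle)

        for lineno, row in rows:
            total += 1
            if isinstance(row, SchemaError):
                raise row
            if isinstance(row, Exception):
                collected.append(RowError(lineno, str(row)))
                continue
            try:
                yield _parse_row(row)
            except DataError as exc:
                collected.append(RowError(lineno, str(exc)))
    if total and len(collected) / total > max_error_fraction:
        raise TooManyRowErrors(
            f"{len(collected)}/{total} malformed rows exceeds tolerated "
            f"fraction {max_error_fraction}"
        )


def filter_confidence(
    records: Iterable[RawAnnotation], threshold: float
) -> Iterator[RawAnnotation]:
    """Keep records whose confidence is >= ``threshold`` (boundary included)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"confidence threshold {threshold} outside [0, 1]")
    for rec in records:
        if rec.confidence >= threshold:
            yield rec


@dataclass(frozen=True)
class FamilyMap:
    """Patent id -> patent-family id. Every corpus patent must appear."""

    entries: Mapping[str, str]

    @classmethod
    def from_tsv(cls, path) -> "FamilyMap":
        entries: dict[str, str] = {}
        with open(path, "r", encoding="utf-8", newline="") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            header = reader.fieldnames or []
            if "patent_id" not in header or "family_id" not in header:
                raise SchemaError(
                    "family map must have columns patent_id, family_id"
                )
            for row in reader:
                pid = (row.get("patent_id") or "").strip()
                fid = (row.get("family_id") or "").strip()
                if not pid or not fid:
                    raise DataError(
                        f"family map line {reader.line_num}: empty id"
                    )
                if pid in entries and entries[pid] != fid:
                    raise DataError(
                        f"patent {pid!r} assigned to two families "
                        f"({entries[pid]!r}, {fid!r})"
                    )
                entries[pid] = fid
        return cls(entries=entries)

    def family_of(self, patent_id: str) -> str:
        return self.entries[patent_id]

    def __contains__(self, patent_id: str) -> bool:
        return patent_id in self.entries

    def families(self) -> frozenset[str]:
        return frozenset(self.entries.values())


@dataclass(frozen=True)
class SectionEntitySet:
    """The deduplicated entities of one type in one section of one patent."""

    patent_id: str
    section: str
    entity_type: EntityType
    entities: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.entities)


#: Monotone transform flags; they are added by the pipeline stages and never
#: removed, so downstream code can assert its preconditions.
FLAG_CONFIDENCE_FILTERED = "confidence-filtered"
FLAG_MAPPED = "mapped"
FLAG_DEDUPLICATED = "deduplicated"
FLAG_COLLAPSED = "redundancy-collapsed"
FLAG_EXCLUSION_APPLIED = "exclusion-applied"


@dataclass(frozen=True)
class Corpus:
    """An annotated patent corpus: entity sets keyed by (patent, section, type).

    ``sets`` maps ``(patent_id, section, entity_type)`` to a frozenset of
    canonical ids; empty sets are never materialized. ``flags`` records which
    transforms have been applied (monotone — a flag is never unset).
    """

    sets: Mapping[tuple[str, str, EntityType], frozenset[str]]
    family_map: FamilyMap
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = sorted(
            {pid for (pid, _, _) in self.sets if pid not in self.family_map}
        )
        if missing:
            raise DataError(
                f"patents absent from family map: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )

    def with_flags(self, *flags: str) -> "Corpus":
        return replace(self, flags=self.flags | frozenset(flags))

    def section_sets(self) -> Iterator[SectionEntitySet]:
        for (pid, section, etype), entities in self.sets.items():
            yield SectionEntitySet(pid, section, etype, entities)

    def patents(self) -> frozenset[str]:
        return frozenset(pid for (pid, _, _) in self.sets)

    def families(self) -> frozenset[str]:
        return frozenset(self.family_map.family_of(p) for p in self.patents())

    def entities_of_type(self, etype: EntityType) -> frozenset[str]:
        out: set[str] = set()
        for (_, _, t), entities in self.sets.items():
            if t is etype:
                out.update(entities)
        return frozenset(out)

    def entity_family_counts(self, etype: EntityType) -> dict[str, int]:
        """Number of distinct families in which each entity of ``etype``
        is annotated (in any section, after whatever transforms have been
        applied)."""
        fams: dict[str, set[str]] = {}
        for (pid, _, t), entities in self.sets.items():
            if t is not etype:
                continue
            fam = self.family_map.family_of(pid)
            for ent in entities:
                fams.setdefault(ent, set()).add(fam)
        return {ent: len(f) for ent, f in fams.items()}


def build_section_sets(
    matched: Iterable,
    family_map: FamilyMap,
    flags: frozenset[str] = frozenset(
        {FLAG_CONFIDENCE_FILTERED, FLAG_MAPPED, FLAG_DEDUPLICATED}
    ),
) -> Corpus:
    """Group mapped annotations into per-(patent, section, type) entity sets.

    ``matched`` yields objects with ``patent_id``, ``section``,
    ``entity_type`` and ``canonical_id`` attributes (duck-typed so the
    mapping stage and re-grouping of an existing corpus both work). Duplicate
    mentions of the same canonical id in the same section collapse to one.
    """
    acc: dict[tuple[str, str, EntityType], set[str]] = {}
    missing: set[str] = set()
    for ent in matched:
        pid = ent.patent_id
        if pid not in family_map:
            missing.add(pid)
            continue
        key = (pid, normalize_section(ent.section), EntityType(ent.entity_type))
        acc.setdefault(key, set()).add(ent.canonical_id)
    if missing:
        raise DataError(
            f"patents absent from family map: {sorted(missing)[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    sets = {key: frozenset(v) for key, v in acc.items() if v}
    return Corpus(sets=sets, family_map=family_map, flags=flags)
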