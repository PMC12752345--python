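"""Mapping raw annotation payloads to canonical database identifiers.

Chemicals are matched by InChIKey (exact string equality) to compound ids;
an annotation of a chemical source type without an InChIKey is dropped as
unmatched. Disease and gene/protein names are matched after a light
normalization (Unicode NFC, case-fold, trim, collapse internal whitespace)
against lookup tables supplied as two-column TSVs. The nine source
annotation labels collapse onto the three scored entity types; genes,
proteins, and enzymes are a single category.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

from .corpus_model import (
    CHEMICAL_SOURCE_TYPES,
    DISEASE_SOURCE_TYPES,
    GENE_SOURCE_TYPES,
    SOURCE_TYPES,
    DataError,
    EntityType,
    RawAnnotation,
    SchemaError,
)

_WS = re.compile(r"\s+")


class MappingError(DataError):
    """A mapping table violates its invariants (e.g. ambiguous keys)."""


def normalize_name(name: str) -> str:
    """Normalization applied to disease/gene names before table lookup."""
    return _WS.sub(" ", unicodedata.normalize("NFC", name).casefold().strip())


def load_mapping_table(path, normalize_keys: bool = False) -> dict[str, str]:
    """Load a two-column TSV (key, value) into a one-to-one dict.

    The same key mapped to two different values is ambiguous and fails the
    load; exact duplicate rows are tolerated.
    """
    table: dict[str, str] = {}
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise SchemaError(f"mapping table {path} must have two columns")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise SchemaError(f"{path} line {lineno}: expected two columns")
            key, value = row[0].strip(), row[1].strip()
            if normalize_keys:
                key = normalize_name(key)
            if not key or not value:
                raise MappingError(f"{path} line {lineno}: empty key or value")
            if key in table and table[key] != value:
                raise MappingError(
                    f"{path} line {lineno}: key {key!r} ambiguously mapped "
                    f"to {table[key]!r} and {value!r}"
                )
            table[key] = value
    return table


@dataclass(frozen=True)
class MappingTables:
    """Identifier lookup tables for the three entity types."""

    inchikey_to_cid: Mapping[str, str]
    disease_name_to_mesh: Mapping[str, str]
    gene_name_to_symbol: Mapping[str, str]

    @classmethod
    def from_tsvs(cls, chemical_path, disease_path, gene_path) -> "MappingTables":
        return cls(
            inchikey_to_cid=load_mapping_table(chemical_path),
            disease_name_to_mesh=load_mapping_table(disease_path, normalize_keys=True),
            gene_name_to_symbol=load_mapping_table(gene_path, normalize_keys=True),
        )


@dataclass(frozen=True)
class MatchedEntity:
    """A raw annotation resolved to a canonical identifier."""

    entity_type: EntityType
    canonical_id: str
    patent_id: str
    section: str


def collapse_source_type(
    source_type: str, on_unknown: str = "error"
) -> Optional[EntityType]:
    """Collapse one of the nine source annotation labels to an entity type.

    ``on_unknown`` is ``"error"`` (raise) or ``"skip"`` (return None).
    """
    if source_type in CHEMICAL_SOURCE_TYPES:
        return EntityType.CHEMICAL
    if source_type in DISEASE_SOURCE_TYPES:
        return EntityType.DISEASE
    if source_type in GENE_SOURCE_TYPES:
        return EntityType.GENE
    if on_unknown == "skip":
        return None
    raise DataError(
        f"unknown source annotation type {source_type!r}; "
        f"expected one of {sorted(SOURCE_TYPES)}"
    )


def map_annotation(
    rec: RawAnnotation, tables: MappingTables, on_unknown_type: str = "error"
) -> Optional[MatchedEntity]:
    """Resolve one annotation to a :class:`MatchedEntity`, or None if unmatched.

    Unmatched outcomes (no InChIKey on a chemical annotation, identifier not
    in the tables, missing name) are a counted result, not an error.
    """
    etype = collapse_source_type(rec.source_type, on_unknown=on_unknown_type)
    if etype is None:
        return None
    if etype is EntityType.CHEMICAL:
        if not rec.inchikey:
            return None
        cid = tables.inchikey_to_cid.get(rec.inchikey)
        if cid is None:
            return None
        return MatchedEntity(etype, cid, rec.patent_id, rec.section)
    if not rec.name:
        return None
    key = normalize_name(rec.name)
    table = (
        tables.disease_name_to_mesh
        if etype is EntityType.DISEASE
        else tables.gene_name_to_symbol
    )
    canonical = table.get(key)
    if canonical is None:
        return None
    return MatchedEntity(etype, canonical, rec.patent_id, rec.section)


def map_annotations(
    records: Iterable[RawAnnotation],
    tables: MappingTables,
    on_unknown_type: str = "skip",
) -> Iterator[tuple[RawAnnotation, Optional[MatchedEntity]]]:
    """Map a stream of annotations, yielding (record, outcome) pairs."""
    for rec in records:
        yield rec, map_annotation(rec, tables, on_unknown_type=on_unknown_type)


def matching_report(
    outcomes: Iterable[tuple[RawAnnotation, Optional[MatchedEntity]]]
) -> pd.DataFrame:
    """Summarize mapping outcomes per entity type.

    Columns: patents with annotations of the type, patents with at least one
    matched annotation, the matched percentage, and the number of distinct
    canonical ids matched.
    """
    annotated: dict[EntityType, set[str]] = {t: set() for t in EntityType}
    matched_patents: dict[EntityType, set[str]] = {t: set() for t in EntityType}
    matched_ids: dict[EntityType, set[str]] = {t: set() for t in EntityType}
    for rec, outcome in outcomes:
        etype = collapse_source_type(rec.source_type, on_unknown="skip")
        if etype is None:
            continue
        annotated[etype].add(rec.patent_id)
        if outcome is not None:
            matched_patents[etype].add(rec.patent_id)
            matched_ids[etype].add(outcome.canonical_id)
    rows = []
    for etype in EntityType:
        n_ann = len(annotated[etype])
        n_match = len(matched_patents[etype])
        rows.append(
            {
                "entity_type": etype.value,
                "patents_with_annotations": n_ann,
                "patents_with_matched_annotations": n_match,
                "percent_matched": (100.0 * n_match / n_ann) if n_ann else 0.0,
                "distinct_ids_matched": len(matched_ids[etype]),
            }
        )
    return pd.DataFrame(rows).set_index("entity_type")
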