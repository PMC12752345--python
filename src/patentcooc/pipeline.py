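"""End-to-end orchestration: files (or an in-memory synthetic corpus) in,
scored and ranked neighbor lists out.

The stages, in order: read annotations -> confidence filter -> identifier
mapping -> per-section dedup into a corpus -> redundancy collapse ->
optional exclusion-list build/apply -> scoring -> neighbor ranking.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Optional

from . import exclusion as excl_mod
from .corpus_model import (
    Corpus,
    FamilyMap,
    RawAnnotation,
    build_section_sets,
    filter_confidence,
    read_annotations,
)
from .entity_mapping import MappingTables, map_annotation
from .redundancy import RedundancyGroups, collapse_corpus
from .scoring import ScoreResult, ScoringParams, score_corpus
from .synthetic_corpus import SyntheticCorpus


def build_corpus(
    records: Iterable[RawAnnotation],
    tables: MappingTables,
    family_map: FamilyMap,
    params: Optional[ScoringParams] = None,
) -> Corpus:
    """Confidence-filter, map, and deduplicate a stream of raw annotations."""
    params = params or ScoringParams()
    matched = (
        m
        for rec in filter_confidence(records, params.confidence_threshold)
        if (m := map_annotation(rec, tables, on_unknown_type="skip")) is not None
    )
    return build_section_sets(matched, family_map)


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    corpus: Corpus
    result: ScoreResult
    exclusion: Optional[excl_mod.ExclusionList]
    params: ScoringParams


def run_pipeline(
    records: Iterable[RawAnnotation],
    tables: MappingTables,
    family_map: FamilyMap,
    groups: Optional[RedundancyGroups] = None,
    params: Optional[ScoringParams] = None,
    exclusion: str = "none",
    exclusion_list: Optional[excl_mod.ExclusionList] = None,
    k_freq: int = 250,
    k_disease: int = 150,
) -> PipelineResult:
    """Run the full pipeline.

    ``exclusion`` is ``"none"`` (score the collapsed corpus as-is),
    ``"build"`` (derive the exclusion list from the corpus, then apply it),
    or ``"apply"`` (apply a supplied ``exclusion_list``).
    """
    params = params or ScoringParams()
    corpus = build_corpus(records, tables, family_map, params)
    if groups is not None:
        corpus = collapse_corpus(corpus, groups)
    used_list: Optional[excl_mod.ExclusionList] = None
    if exclusion == "build":
        used_list = excl_mod.build_exclusion_list(
            corpus, k_freq=k_freq, k_disease=k_disease
        )
        corpus = excl_mod.apply_exclusion(corpus, used_list)
    elif exclusion == "apply":
        if exclusion_list is None:
            raise ValueError("exclusion='apply' requires an exclusion_list")
        used_list = exclusion_list
        corpus = excl_mod.apply_exclusion(corpus, used_list)
    elif exclusion != "none":
        raise ValueError(f"unknown exclusion mode {exclusion!r}")
    result = score_corpus(corpus, params)
    return PipelineResult(
        corpus=corpus, result=result, exclusion=used_list, params=params
    )


def synthetic_inputs(
    sim: SyntheticCorpus,
) -> tuple[list[RawAnnotation], MappingTables, FamilyMap, RedundancyGroups]:
    """Adapt an in-memory synthetic corpus to the pipeline's input objects
    without touching the filesystem."""
    from .entity_mapping import normalize_name

    records = [
        RawAnnotation(
            patent_id=row.patent_id,
            section=row.section,
            source_type=row.source_type,
            inchikey=row.inchikey or None,
            name=row.name or None,
            confidence=float(row.confidence),
        )
        for row in sim.annotations.itertuples(index=False)
    ]
    tables = MappingTables(
        inchikey_to_cid=dict(
            zip(sim.chemical_map["inchikey"], sim.chemical_map["cid"])
        ),
        disease_name_to_mesh={
            normalize_name(n): m
            for n, m in zip(sim.disease_map["name"], sim.disease_map["mesh_id"])
        },
        gene_name_to_symbol={
            normalize_name(n): s
            for n, s in zip(sim.gene_map["name"], sim.gene_map["gene_symbol"])
        },
    )
    family_map = FamilyMap(
        entries=dict(
            zip(sim.family_map["patent_id"], sim.family_map["family_id"])
        )
    )
    groups = RedundancyGroups.from_pairs(
        zip(sim.groups["cid"], sim.groups["group_id"])
    )
    return records, tables, family_map, groups


def run_pipeline_from_files(
    annotations_path,
    families_path,
    chemical_map_path,
    disease_map_path,
    gene_map_path,
    groups_path=None,
    params: Optional[ScoringParams] = None,
    annotation_format: str = "tsv",
    **kwargs,
) -> PipelineResult:
    """File-based entry point used by the command-line interface."""
    from .redundancy import load_groups

    tables = MappingTables.from_tsvs(
        chemical_map_path, disease_map_path, gene_map_path
    )
    family_map = FamilyMap.from_tsv(families_path)
    groups = load_groups(groups_path) if groups_path else None
    records = read_annotations(annotations_path, fmt=annotation_format)
    return run_pipeline(
        records, tables, family_map, groups=groups, params=params, **kwargs
    )


def corpus_hash(corpus: Corpus) -> str:
    """Stable content hash of a corpus, for run metadata."""
    digest = hashlib.sha256()
    for key in sorted(
        corpus.sets, key=lambda k: (k[0], k[1], k[2].value)
    ):
        digest.update(repr((key[0], key[1], key[2].value)).encode())
        digest.update(repr(sorted(corpus.sets[key])).encode())
    return digest.hexdigest()
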