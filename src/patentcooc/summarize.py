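"""Ranking neighbors and relevant patent families; diagnostics and export.

Neighbors of a query within one type-pair dataset are ranked by the
IDF-adjusted co-occurrence score (descending, ties broken by neighbor id
ascending) and truncated to the saved cap; the patent families behind each
pair are ranked by relevance (the family pair weight), capped for storage
with a short display slice. Everything is a total deterministic order:
permuting the input never changes the output.

The coverage diagnostic reports, for each threshold, the fraction of
distinct matched compounds appearing in at least one section whose chemical
count does not exceed the threshold — the curve that motivates the choice of
the informativeness cut-off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

from .corpus_model import Corpus, EntityType
from .scoring import PairScore, ScoreResult, ScoringParams


def dataset_label(type_pair: tuple[EntityType, EntityType]) -> str:
    """Dataset label for an ordered type pair, e.g. ``PatentChemicalDisease``."""
    return "Patent" + type_pair[0].value.capitalize() + type_pair[1].value.capitalize()


@dataclass(frozen=True)
class FamilyRelevance:
    family_id: str
    relevance: float


@dataclass(frozen=True)
class NeighborEntry:
    neighbor_id: str
    score: float
    top_families: tuple[FamilyRelevance, ...]


@dataclass(frozen=True)
class NeighborList:
    query_id: str
    query_type: EntityType
    neighbor_type: EntityType
    entries: tuple[NeighborEntry, ...]


def rank_families(
    pair: PairScore, params: Optional[ScoringParams] = None
) -> tuple[FamilyRelevance, ...]:
    """Families behind one pair, by relevance descending then family id
    ascending, truncated to the saved cap."""
    params = params or ScoringParams()
    ranked = sorted(
        pair.per_family_weights.items(), key=lambda kv: (-kv[1], kv[0])
    )
    return tuple(
        FamilyRelevance(fid, w)
        for fid, w in ranked[: params.max_families_saved]
    )


def display_families(
    families: Sequence[FamilyRelevance], params: Optional[ScoringParams] = None
) -> tuple[FamilyRelevance, ...]:
    """The short slice of top families shown on a knowledge panel."""
    params = params or ScoringParams()
    return tuple(families[: params.max_families_shown])


def rank_neighbors(
    scores: Iterable[PairScore], params: Optional[ScoringParams] = None
) -> NeighborList:
    """Rank one query's scored pairs into a truncated neighbor list.

    All pairs must share the same query id and type pair. Score descending,
    neighbor id ascending on ties, truncated to the saved neighbor cap.
    """
    params = params or ScoringParams()
    pairs = list(scores)
    if not pairs:
        raise ValueError("cannot rank an empty score collection")
    queries = {p.query_id for p in pairs}
    type_pairs = {p.type_pair for p in pairs}
    if len(queries) != 1 or len(type_pairs) != 1:
        raise ValueError("rank_neighbors expects one query and one type pair")
    tp = type_pairs.pop()
    ranked = sorted(pairs, key=lambda p: (-p.score, p.neighbor_id))
    entries = tuple(
        NeighborEntry(
            neighbor_id=p.neighbor_id,
            score=p.score,
            top_families=rank_families(p, params),
        )
        for p in ranked[: params.max_neighbors_saved]
    )
    return NeighborList(
        query_id=queries.pop(),
        query_type=tp[0],
        neighbor_type=tp[1],
        entries=entries,
    )


def neighbor_lists(
    result: ScoreResult,
    type_pair: Optional[tuple[EntityType, EntityType]] = None,
) -> Iterator[NeighborList]:
    """All neighbor lists of a scored corpus (one type pair, or all nine),
    in deterministic (type pair, query id) order."""
    type_pairs = [type_pair] if type_pair else sorted(
        result.scores, key=lambda tp: (tp[0].value, tp[1].value)
    )
    for tp in type_pairs:
        pair_scores = result.scores.get(tp, {})
        by_query: dict[str, list[PairScore]] = {}
        for (i1, _), ps in pair_scores.items():
            by_query.setdefault(i1, []).append(ps)
        for query_id in sorted(by_query):
            yield rank_neighbors(by_query[query_id], result.params)


def section_count_coverage(
    corpus: Corpus, thresholds: Sequence[int]
) -> pd.DataFrame:
    """Fraction of matched compounds covered at each section-count threshold.

    A compound is covered at threshold ``T`` when it appears in at least one
    section whose (non-redundant) chemical count is at most ``T``; the
    fraction is over all distinct compounds in the corpus and is monotone
    non-decreasing in ``T``.
    """
    if list(thresholds) != sorted(thresholds) or any(
        t <= 0 for t in thresholds
    ):
        raise ValueError("thresholds must be positive and ascending")
    min_count: dict[str, int] = {}
    for (_, _, etype), entities in corpus.sets.items():
        if etype is not EntityType.CHEMICAL:
            continue
        n = len(entities)
        for cid in entities:
            if n < min_count.get(cid, n + 1):
                min_count[cid] = n
    total = len(min_count)
    rows = []
    for t in thresholds:
        covered = sum(1 for n in min_count.values() if n <= t)
        rows.append(
            {
                "threshold": int(t),
                "fraction": (covered / total) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _list_to_doc(nl: NeighborList) -> dict:
    return {
        "dataset": dataset_label((nl.query_type, nl.neighbor_type)),
        "query_type": nl.query_type.value,
        "query_id": nl.query_id,
        "neighbor_type": nl.neighbor_type.value,
        "neighbors": [
            {
                "id": e.neighbor_id,
                "score": e.score,
                "families": [
                    {"family_id": f.family_id, "relevance": f.relevance}
                    for f in e.top_families
                ],
            }
            for e in nl.entries
        ],
    }


def _doc_to_list(doc: Mapping) -> NeighborList:
    return NeighborList(
        query_id=doc["query_id"],
        query_type=EntityType(doc["query_type"]),
        neighbor_type=EntityType(doc["neighbor_type"]),
        entries=tuple(
            NeighborEntry(
                neighbor_id=n["id"],
                score=n["score"],
                top_families=tuple(
                    FamilyRelevance(f["family_id"], f["relevance"])
                    for f in n["families"]
                ),
            )
            for n in doc["neighbors"]
        ),
    )


def export_neighbor_lists(
    lists: Iterable[NeighborList], path, fmt: str = "json"
) -> None:
    """Write neighbor lists as a JSON array of documents or a flat TSV.

    JSON round-trips losslessly through :func:`read_neighbor_lists`; the TSV
    is one row per (query, neighbor, family).
    """
    lists = list(lists)
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as handle:
            json.dump([_list_to_doc(nl) for nl in lists], handle, indent=1)
            handle.write("\n")
    elif fmt == "tsv":
        rows = []
        for nl in lists:
            label = dataset_label((nl.query_type, nl.neighbor_type))
            for e in nl.entries:
                for rank, f in enumerate(e.top_families, start=1):
                    rows.append(
                        (
                            label,
                            nl.query_type.value,
                            nl.query_id,
                            nl.neighbor_type.value,
                            e.neighbor_id,
                            e.score,
                            rank,
                            f.family_id,
                            f.relevance,
                        )
                    )
        pd.DataFrame(
            rows,
            columns=[
                "dataset",
                "query_type",
                "query_id",
                "neighbor_type",
                "neighbor_id",
                "score",
                "family_rank",
                "family_id",
                "relevance",
            ],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_neighbor_lists(path) -> list[NeighborList]:
    """Read back a JSON export of neighbor lists."""
    with open(path, "r", encoding="utf-8") as handle:
        docs = json.load(handle)
    return [_doc_to_list(doc) for doc in docs]
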