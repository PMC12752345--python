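"""Informativeness-weighted co-occurrence scoring.

The model: an annotation is informative when it sits in a patent section
containing few entities of its type, and worthless when the section is a
laundry list. Each (section, patent, type) gets an informativeness weight

    alpha = N_min / N_s                   if count <= N_s
            N_min / max(N_s, count)       if N_s <= count <= N_cutoff
            0                             if count > N_cutoff

where ``count`` is the number of non-redundant entities of the type in the
section, ``N_s`` is a per-section capacity (default 5, 20 for the
description), ``N_min = min_s N_s`` and ``N_cutoff = 200``. The co-occurrence
weight of a (query, neighbor) pair in a section pair of a patent is the
product of the two alphas; within a patent it is maximized over section
pairs, and within a patent family over patents — giving a family weight
``W`` in [0, 1] that quantifies one family's support for the pair.

The simple co-occurrence score ``S~`` is the sum of family weights over the
corpus. It is discounted by an inverse dataset frequency (IDF) term for the
neighbor,

    r = 1 - log(N_bar) / log(N_DS)    if N_DS > 1 and N_bar >= 1, else 1,

where ``N_DS`` is the number of families in the ordered type-pair dataset and
``N_bar`` is the neighbor's effective count: the sum over families of the
best family weight the neighbor achieves with any admissible partner. The
final ranking score is ``S = S~ * r``. Relevance scores, used to order the
patent families behind one pair, equal the family weights themselves.

Pairs require distinct ids for same-type datasets; cross-type pairs admit
any ids. Zero-weight pairs are never materialized — absence and zero are
equivalent everywhere downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd
import yaml

from .corpus_model import Corpus, DataError, EntityType

#: All nine ordered (query type, neighbor type) datasets.
ORDERED_TYPE_PAIRS: tuple[tuple[EntityType, EntityType], ...] = tuple(
    (t1, t2) for t1 in EntityType for t2 in EntityType
)


@dataclass(frozen=True)
class ScoringParams:
    """The tunable constants of the scoring model.

    ``n_s_default`` applies to every section without an explicit override;
    the stock configuration gives the description section capacity 20 and
    every other section 5.
    """

    n_s_default: int = 5
    n_s_overrides: Mapping[str, int] = field(
        default_factory=lambda: {"description": 20}
    )
    n_cutoff: int = 200
    confidence_threshold: float = 0.4
    max_neighbors_saved: int = 100
    max_families_saved: int = 1000
    max_families_shown: int = 5

    def __post_init__(self) -> None:
        if self.n_s_default < 1 or any(v < 1 for v in self.n_s_overrides.values()):
            raise ValueError("per-section capacities N_s must be positive")
        if self.n_cutoff < max(
            [self.n_s_default, *self.n_s_overrides.values()]
        ):
            raise ValueError("N_cutoff must be >= every N_s")
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValueError("confidence threshold outside [0, 1]")
        if min(
            self.max_neighbors_saved,
            self.max_families_saved,
            self.max_families_shown,
        ) < 1:
            raise ValueError("caps must be positive")

    def n_s(self, section: str) -> int:
        return self.n_s_overrides.get(section, self.n_s_default)

    @property
    def n_min(self) -> int:
        return min(self.n_s_default, *self.n_s_overrides.values()) if (
            self.n_s_overrides
        ) else self.n_s_default

    def to_dict(self) -> dict:
        return {
            "n_s": {"default": self.n_s_default, **dict(self.n_s_overrides)},
            "n_cutoff": self.n_cutoff,
            "confidence_threshold": self.confidence_threshold,
            "max_neighbors_saved": self.max_neighbors_saved,
            "max_families_saved": self.max_families_saved,
            "max_families_shown": self.max_families_shown,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScoringParams":
        kwargs: dict = {}
        n_s = dict(data.get("n_s", {}))
        if n_s:
            kwargs["n_s_default"] = int(n_s.pop("default", 5))
            kwargs["n_s_overrides"] = {k: int(v) for k, v in n_s.items()}
        for key in (
            "n_cutoff",
            "max_neighbors_saved",
            "max_families_saved",
            "max_families_shown",
        ):
            if key in data:
                kwargs[key] = int(data[key])
        if "confidence_threshold" in data:
            kwargs["confidence_threshold"] = float(data["confidence_threshold"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "ScoringParams":
        """Load parameters from a YAML or JSON file (by extension)."""
        text = open(path, "r", encoding="utf-8").read()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls.from_dict(data or {})


def informativeness_weight(
    count: int,
    section: str,
    entity_type: Optional[EntityType] = None,
    params: ScoringParams = ScoringParams(),
) -> float:
    """Informativeness weight alpha for a section with ``count`` entities.

    The weight depends on the section (through its capacity ``N_s``) and the
    non-redundant entity count, not on the entity type itself;
    ``entity_type`` is accepted for interface symmetry. Continuous at
    ``count == N_s`` and identically zero above ``N_cutoff``.
    """
    if count < 0:
        raise ValueError("entity count must be non-negative")
    n_s = params.n_s(section)
    if count > params.n_cutoff:
        return 0.0
    if count <= n_s:
        return params.n_min / n_s
    return params.n_min / count


def section_pair_weight(alpha1: float, alpha2: float) -> float:
    """Co-occurrence weight of a section pair: the product of the alphas."""
    for a in (alpha1, alpha2):
        if not (0.0 <= a <= 1.0):
            raise ValueError(f"informativeness weight {a} outside [0, 1]")
    return alpha1 * alpha2


def patent_pair_weight(
    query_occurrences: Iterable[tuple[str, float]],
    neighbor_occurrences: Iterable[tuple[str, float]],
) -> float:
    """Pair weight within one patent: max over section pairs of alpha1*alpha2.

    Each argument is the (section, alpha) occurrences of one entity in the
    patent. The max over the section-pair grid factorizes into the product
    of the per-entity maxima.
    """
    q = [a for _, a in query_occurrences]
    n = [a for _, a in neighbor_occurrences]
    if not q or not n:
        raise ValueError("both entities must occur in the patent")
    return section_pair_weight(max(q), max(n))


def family_pair_weight(per_patent_weights: Mapping[str, float]) -> float:
    """Pair weight within a family: max over its patents' pair weights."""
    if not per_patent_weights:
        raise DataError("pair absent from family: no per-patent weights")
    return max(per_patent_weights.values())


def simple_score(family_weights: Mapping[str, float]) -> float:
    """Simple co-occurrence score: sum of family pair weights."""
    return float(sum(family_weights.values()))


def idf_term(n_bar: float, n_ds: int) -> float:
    """Inverse dataset frequency term for a neighbor entity.

    ``1 - log(n_bar)/log(n_ds)`` when the dataset has more than one family
    and the effective count is at least 1; otherwise 1 (an effective count
    below 1 marks a neighbor too rare to discount). Base-invariant, in
    [0, 1] because ``n_bar <= n_ds`` always holds.
    """
    if n_bar < 0:
        raise ValueError("effective count must be non-negative")
    if n_ds < 1:
        raise ValueError("dataset family count must be >= 1")
    if n_bar > n_ds * (1.0 + 1e-9):
        raise DataError(
            f"effective count {n_bar} exceeds dataset family count {n_ds}"
        )
    if n_ds > 1 and n_bar >= 1.0:
        return 1.0 - math.log(n_bar) / math.log(n_ds)
    return 1.0


def cooccurrence_score(simple: float, idf: float) -> float:
    """Final ranking score: simple score times the neighbor's IDF term."""
    if simple < 0:
        raise ValueError("simple score must be non-negative")
    if not (0.0 <= idf <= 1.0):
        raise ValueError("IDF term outside [0, 1]")
    return simple * idf


def relevance_score(weight: float) -> float:
    """Relevance of a family to a pair: equal to the family pair weight.

    Proximity of the mentions within the text is deliberately not modelled;
    were it, relevance and co-occurrence weight would differ.
    """
    return weight


@dataclass(frozen=True)
class DatasetStats:
    """Per ordered type pair: family count and per-neighbor effective counts."""

    type_pair: tuple[EntityType, EntityType]
    n_ds: int
    effective_counts: Mapping[str, float]


@dataclass(frozen=True)
class PairScore:
    """Scores for one ordered (query, neighbor) pair."""

    query_id: str
    neighbor_id: str
    type_pair: tuple[EntityType, EntityType]
    simple_score: float
    idf_term: float
    score: float
    per_family_weights: Mapping[str, float]


#: family weights for one ordered type pair: (query, neighbor) -> {family: W}
FamilyWeights = dict[tuple[str, str], dict[str, float]]


def section_alphas(
    corpus: Corpus, params: ScoringParams
) -> dict[tuple[str, str, EntityType], float]:
    """Alpha for every materialized (patent, section, type) set."""
    return {
        key: informativeness_weight(len(ents), key[1], key[2], params)
        for key, ents in corpus.sets.items()
    }


def _entity_alphas(
    corpus: Corpus, params: ScoringParams
) -> dict[EntityType, dict[str, dict[str, float]]]:
    """Per type, per patent: entity -> best (max) alpha over its sections.

    Entities whose every section has alpha 0 are dropped here; they cannot
    contribute to any pair.
    """
    out: dict[EntityType, dict[str, dict[str, float]]] = {
        t: {} for t in EntityType
    }
    for (pid, section, etype), ents in corpus.sets.items():
        alpha = informativeness_weight(len(ents), section, etype, params)
        if alpha <= 0.0:
            continue
        per_patent = out[etype].setdefault(pid, {})
        for ent in ents:
            if alpha > per_patent.get(ent, 0.0):
                per_patent[ent] = alpha
    return out


def compute_family_weights(
    corpus: Corpus, params: ScoringParams
) -> dict[tuple[EntityType, EntityType], FamilyWeights]:
    """Family-level pair weights for all nine ordered type-pair datasets.

    For each family and unordered type combination the per-patent pair
    weights (product of the entities' best alphas in that patent) are
    maximized over the family's patents. The family weight is symmetric
    under swapping query and neighbor, so each unordered pair is computed
    once and the two mirrored keys — ``(i1, i2)`` and ``(i2, i1)``, in both
    ordered datasets of a cross-type combination — share one (read-only)
    inner family->weight mapping.
    """
    ent_alpha = _entity_alphas(corpus, params)
    fam_patents: dict[str, list[str]] = {}
    for pid in corpus.patents():
        fam_patents.setdefault(corpus.family_map.family_of(pid), []).append(pid)

    out: dict[tuple[EntityType, EntityType], FamilyWeights] = {
        tp: {} for tp in ORDERED_TYPE_PAIRS
    }
    types = list(EntityType)
    unordered = [
        (types[i], types[j])
        for i in range(len(types))
        for j in range(i, len(types))
    ]
    for family, patents in fam_patents.items():
        for t1, t2 in unordered:
            best: dict[tuple[str, str], float] = {}
            best_get = best.get
            same = t1 is t2
            for pid in patents:
                d1 = ent_alpha[t1].get(pid)
                if not d1:
                    continue
                if same:
                    # canonical (smaller id, larger id) pairs only
                    items = sorted(d1.items())
                    n = len(items)
                    for x in range(n - 1):
                        i1, a1 = items[x]
                        for y in range(x + 1, n):
                            i2, a2 = items[y]
                            w = a1 * a2
                            key = (i1, i2)
                            if w > best_get(key, 0.0):
                                best[key] = w
                else:
                    d2 = ent_alpha[t2].get(pid)
                    if not d2:
                        continue
                    for i1, a1 in d1.items():
                        for i2, a2 in d2.items():
                            w = a1 * a2
                            key = (i1, i2)
                            if w > best_get(key, 0.0):
                                best[key] = w
            if not best:
                continue
            fw12 = out[(t1, t2)]
            fw21 = out[(t2, t1)]
            for (i1, i2), w in best.items():
                famw = fw12.get((i1, i2))
                if famw is None:
                    famw = {}
                    fw12[(i1, i2)] = famw
                    fw21[(i2, i1)] = famw
                famw[family] = w
    return out


def build_dataset_stats(
    family_weights: FamilyWeights,
    type_pair: tuple[EntityType, EntityType],
) -> DatasetStats:
    """Dataset size and effective counts for one ordered type pair.

    ``n_ds`` counts the distinct families carrying at least one
    positive-weight pair of the ordered types; the effective count of a
    neighbor sums, over families, its best weight with any admissible
    query partner.
    """
    families: set[str] = set()
    best_per_neighbor: dict[str, dict[str, float]] = {}
    for (_, i2), famw in family_weights.items():
        families.update(famw)
        per = best_per_neighbor.get(i2)
        if per is None:
            best_per_neighbor[i2] = dict(famw)
            continue
        per_get = per.get
        for fam, w in famw.items():
            if w > per_get(fam, 0.0):
                per[fam] = w
    if not families:
        raise DataError(
            f"type-pair dataset {type_pair[0].value}-{type_pair[1].value} "
            "is empty: no scores computable"
        )
    effective = {
        i2: float(sum(per.values())) for i2, per in best_per_neighbor.items()
    }
    return DatasetStats(
        type_pair=type_pair, n_ds=len(families), effective_counts=effective
    )


@dataclass(frozen=True)
class ScoreResult:
    """All pair scores and dataset statistics of one scored corpus."""

    params: ScoringParams
    family_weights: Mapping[tuple[EntityType, EntityType], FamilyWeights]
    stats: Mapping[tuple[EntityType, EntityType], DatasetStats]
    scores: Mapping[
        tuple[EntityType, EntityType], Mapping[tuple[str, str], PairScore]
    ]

    def pair(
        self, type_pair: tuple[EntityType, EntityType], query_id: str,
        neighbor_id: str,
    ) -> Optional[PairScore]:
        return self.scores.get(type_pair, {}).get((query_id, neighbor_id))

    def pairs_for_query(
        self, type_pair: tuple[EntityType, EntityType], query_id: str
    ) -> Iterator[PairScore]:
        for (i1, _), ps in self.scores.get(type_pair, {}).items():
            if i1 == query_id:
                yield ps

    def to_frame(self) -> pd.DataFrame:
        """Flat score table: one row per ordered (query, neighbor) pair."""
        rows = []
        for (t1, t2), pair_scores in self.scores.items():
            for ps in pair_scores.values():
                rows.append(
                    (
                        t1.value,
                        ps.query_id,
                        t2.value,
                        ps.neighbor_id,
                        ps.simple_score,
                        ps.idf_term,
                        ps.score,
                    )
                )
        frame = pd.DataFrame(
            rows,
            columns=[
                "query_type",
                "query_id",
                "neighbor_type",
                "neighbor_id",
                "simple_score",
                "idf_term",
                "score",
            ],
        )
        return frame.sort_values(
            ["query_type", "query_id", "neighbor_type", "score", "neighbor_id"],
            ascending=[True, True, True, False, True],
        ).reset_index(drop=True)


def score_corpus(corpus: Corpus, params: Optional[ScoringParams] = None) -> ScoreResult:
    """Run the full scoring pipeline on a prepared corpus.

    Computes family pair weights, dataset statistics (on the full pair set,
    before any neighbor-cap truncation), and the simple / IDF-adjusted
    scores for every ordered type-pair dataset that is non-empty.
    """
    params = params or ScoringParams()
    fam_weights = compute_family_weights(corpus, params)
    stats: dict[tuple[EntityType, EntityType], DatasetStats] = {}
    scores: dict[tuple[EntityType, EntityType], dict[tuple[str, str], PairScore]] = {}
    for tp, fw in fam_weights.items():
        if not fw:
            continue
        ds = build_dataset_stats(fw, tp)
        stats[tp] = ds
        pair_scores: dict[tuple[str, str], PairScore] = {}
        for (i1, i2), famw in fw.items():
            s_simple = simple_score(famw)
            r = idf_term(ds.effective_counts[i2], ds.n_ds)
            pair_scores[(i1, i2)] = PairScore(
                query_id=i1,
                neighbor_id=i2,
                type_pair=tp,
                simple_score=s_simple,
                idf_term=r,
                score=cooccurrence_score(s_simple, r),
                per_family_weights=famw,
            )
        scores[tp] = pair_scores
    return ScoreResult(
        params=params, family_weights=fam_weights, stats=stats, scores=scores
    )
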