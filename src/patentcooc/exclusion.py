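"""The common-chemical exclusion list.

Ubiquitous compounds — solvents, common reagents, atmospheric gases — are
co-mentioned with nearly everything, and even IDF discounting cannot keep
them out of neighbor lists. The exclusion list is the union of two
rule-built criterion lists: (A) the ``k_freq`` compounds annotated in the
most patent families overall, and (B) the ``k_disease`` compounds annotated
in the most families that also carry at least one disease annotation.
Applying the list removes its members from every chemical section set —
as queries and as neighbors — which shrinks the per-section chemical counts
and can therefore only raise informativeness weights. Non-chemical entity
sets, and thus every score with no chemical on either side, are untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

from .corpus_model import (
    Corpus,
    DataError,
    EntityType,
    FLAG_EXCLUSION_APPLIED,
)
from .redundancy import id_sort_key

PROVENANCE_VALUES = ("freq", "disease", "both", "unspecified")


@dataclass(frozen=True)
class ExclusionList:
    """Excluded compound ids, each tagged with the criterion that chose it."""

    members: frozenset[str]
    provenance: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.provenance) != set(self.members):
            raise DataError("provenance must cover exactly the members")
        bad = {v for v in self.provenance.values()} - set(PROVENANCE_VALUES)
        if bad:
            raise DataError(f"unknown provenance value(s): {sorted(bad)}")

    def counts(self) -> dict[str, int]:
        out = {v: 0 for v in PROVENANCE_VALUES}
        for v in self.provenance.values():
            out[v] += 1
        return out

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, cid: str) -> bool:
        return cid in self.members


def top_k_with_ties(counts: Mapping[str, int], k: int) -> set[str]:
    """Ids of the ``k`` largest counts, including all ties with the k-th.

    Ordering for the cut is count descending then id ascending; everything
    tied with the k-th count is kept, so the result may exceed ``k``.
    """
    if k <= 0:
        return set()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], id_sort_key(kv[0])))
    if len(ranked) <= k:
        if len(ranked) < k:
            warnings.warn(
                f"only {len(ranked)} compounds available for a top-{k} list"
            )
        return {cid for cid, _ in ranked}
    cutoff = ranked[k - 1][1]
    return {cid for cid, count in ranked if count >= cutoff}


def chemical_family_counts(corpus: Corpus) -> dict[str, int]:
    """Distinct annotated patent families per compound (criterion A counts)."""
    return corpus.entity_family_counts(EntityType.CHEMICAL)


def chemical_disease_family_counts(corpus: Corpus) -> dict[str, int]:
    """Per compound: distinct families containing the compound and at least
    one disease annotation anywhere in the family (criterion B counts)."""
    disease_fams = {
        corpus.family_map.family_of(pid)
        for (pid, _, t) in corpus.sets
        if t is EntityType.DISEASE
    }
    fams: dict[str, set[str]] = {}
    for (pid, _, t), entities in corpus.sets.items():
        if t is not EntityType.CHEMICAL:
            continue
        fam = corpus.family_map.family_of(pid)
        if fam not in disease_fams:
            continue
        for cid in entities:
            fams.setdefault(cid, set()).add(fam)
    return {cid: len(f) for cid, f in fams.items()}


def build_exclusion_from_counts(
    freq_counts: Mapping[str, int],
    disease_counts: Mapping[str, int],
    k_freq: int = 250,
    k_disease: int = 150,
) -> ExclusionList:
    """Union of the two criterion lists, with per-member provenance."""
    list_a = top_k_with_ties(freq_counts, k_freq)
    list_b = top_k_with_ties(disease_counts, k_disease)
    provenance = {}
    for cid in list_a | list_b:
        if cid in list_a and cid in list_b:
            provenance[cid] = "both"
        elif cid in list_a:
            provenance[cid] = "freq"
        else:
            provenance[cid] = "disease"
    return ExclusionList(members=frozenset(provenance), provenance=provenance)


def build_exclusion_list(
    corpus: Corpus, k_freq: int = 250, k_disease: int = 150
) -> ExclusionList:
    """Build the exclusion list from a mapped, deduplicated, collapsed corpus."""
    return build_exclusion_from_counts(
        chemical_family_counts(corpus),
        chemical_disease_family_counts(corpus),
        k_freq=k_freq,
        k_disease=k_disease,
    )


def apply_exclusion(corpus: Corpus, exclusion: ExclusionList) -> Corpus:
    """Remove excluded compounds from every chemical section set.

    Section sets emptied by the removal disappear entirely; counts, and
    therefore the informativeness weights and everything downstream, must be
    recomputed from the returned corpus. Non-chemical sets are unchanged.
    """
    new_sets = {}
    for key, entities in corpus.sets.items():
        if key[2] is EntityType.CHEMICAL:
            kept = frozenset(cid for cid in entities if cid not in exclusion)
            if kept:
                new_sets[key] = kept
        else:
            new_sets[key] = entities
    return Corpus(
        sets=new_sets,
        family_map=corpus.family_map,
        flags=corpus.flags | frozenset({FLAG_EXCLUSION_APPLIED}),
    )


def write_exclusion_list(exclusion: ExclusionList, path) -> None:
    """One ``cid<TAB>criterion`` line per member, sorted, with a comment header."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# excluded compound ids: cid<TAB>criterion\n")
        for cid in sorted(exclusion.members, key=id_sort_key):
            handle.write(f"{cid}\t{exclusion.provenance[cid]}\n")


def load_exclusion_list(path) -> ExclusionList:
    """Read an exclusion list file; ``#`` comments allowed, duplicates
    deduplicated with a warning, a missing criterion column loads as
    ``unspecified``."""
    provenance: dict[str, str] = {}
    duplicates = []
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            cid = parts[0].strip()
            criterion = parts[1].strip() if len(parts) > 1 else "unspecified"
            if criterion not in PROVENANCE_VALUES:
                raise DataError(f"unknown exclusion criterion {criterion!r}")
            if cid in provenance:
                duplicates.append(cid)
            provenance[cid] = criterion
    if duplicates:
        warnings.warn(
            f"exclusion list contained {len(duplicates)} duplicate id(s); "
            "deduplicated"
        )
    return ExclusionList(members=frozenset(provenance), provenance=provenance)
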