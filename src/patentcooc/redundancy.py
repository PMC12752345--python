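"""Collapsing near-duplicate chemicals to one representative per group.

Patent corpora mention the same substance under many compound records: salt
forms, stereo/charge variants sharing parent connectivity, or records tied
together by a shared name. Counting each variant separately inflates the
per-section chemical counts and clutters neighbor lists with near-duplicates.
Group membership is supplied as data (a two-column ``cid -> group_id`` table);
within every chemical section set all members of a group are replaced by the
group representative — the member annotated in the most patent families, ties
broken by the numerically smallest id. Compounds absent from the table are
implicit singletons. Disease and gene sets are untouched: each of those
entities is counted as itself.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from typing import Mapping, Optional

from .corpus_model import (
    Corpus,
    DataError,
    EntityType,
    FLAG_COLLAPSED,
    SchemaError,
)

_DIGITS = re.compile(r"\d+")


def id_sort_key(entity_id: str):
    """Deterministic 'numerically smallest first' ordering for entity ids.

    Purely numeric ids sort by value; ids with an embedded digit run sort by
    that value then the full string; anything else falls back to lexicographic.
    """
    if entity_id.isdigit():
        return (0, int(entity_id), entity_id)
    m = _DIGITS.search(entity_id)
    if m:
        return (1, int(m.group()), entity_id)
    return (2, 0, entity_id)


@dataclass(frozen=True)
class RedundancyGroups:
    """Bidirectional compound-id <-> redundancy-group mapping."""

    member_to_group: Mapping[str, str]
    group_to_members: Mapping[str, frozenset[str]]

    def group_of(self, cid: str) -> Optional[str]:
        return self.member_to_group.get(cid)

    @classmethod
    def from_pairs(cls, pairs) -> "RedundancyGroups":
        member_to_group: dict[str, str] = {}
        inverse: dict[str, set[str]] = {}
        for cid, gid in pairs:
            if cid in member_to_group and member_to_group[cid] != gid:
                raise DataError(
                    f"compound {cid!r} assigned to groups "
                    f"{member_to_group[cid]!r} and {gid!r}"
                )
            member_to_group[cid] = gid
            inverse.setdefault(gid, set()).add(cid)
        return cls(
            member_to_group=member_to_group,
            group_to_members={g: frozenset(m) for g, m in inverse.items()},
        )


def load_groups(path) -> RedundancyGroups:
    """Load a ``cid<TAB>group_id`` table; conflicting rows fail the load."""
    pairs = []
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is not None and len(header) < 2 and any(h.strip() for h in header):
            raise SchemaError(f"group table {path} must have two columns")
        for lineno, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            if len(row) < 2:
                raise SchemaError(f"{path} line {lineno}: expected two columns")
            pairs.append((row[0].strip(), row[1].strip()))
    return RedundancyGroups.from_pairs(pairs)


def select_representative(
    members: frozenset[str] | set[str], stats: Mapping[str, int]
) -> str:
    """Pick the group representative: largest annotated-family count wins,
    ties broken by the numerically smallest id. ``stats`` maps compound id to
    its family count; absent members count 0."""
    if not members:
        raise DataError("cannot select a representative from an empty group")
    return min(members, key=lambda cid: (-stats.get(cid, 0), id_sort_key(cid)))


def representatives(
    groups: RedundancyGroups, stats: Mapping[str, int]
) -> dict[str, str]:
    """Map every grouped compound id to its group's representative."""
    out: dict[str, str] = {}
    for gid, members in groups.group_to_members.items():
        rep = select_representative(members, stats)
        for cid in members:
            out[cid] = rep
    return out


def collapse_corpus(
    corpus: Corpus,
    groups: RedundancyGroups,
    stats: Optional[Mapping[str, int]] = None,
) -> Corpus:
    """Replace grouped chemicals by their representative in every section set.

    ``stats`` (per-compound annotated-family counts, used to pick
    representatives) defaults to counts computed from the corpus itself.
    The chemical section counts become the non-redundant counts used by the
    informativeness weights; disease and gene sets pass through unchanged.
    Idempotent: representatives map to themselves.
    """
    if stats is None:
        stats = corpus.entity_family_counts(EntityType.CHEMICAL)
    rep = representatives(groups, stats)
    new_sets = {}
    for key, entities in corpus.sets.items():
        if key[2] is EntityType.CHEMICAL:
            new_sets[key] = frozenset(rep.get(cid, cid) for cid in entities)
        else:
            new_sets[key] = entities
    return Corpus(
        sets=new_sets,
        family_map=corpus.family_map,
        flags=corpus.flags | frozenset({FLAG_COLLAPSED}),
    )
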