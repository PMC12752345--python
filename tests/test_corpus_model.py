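import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patentcooc.corpus_model import (
    Corpus,
    DataError,
    EntityType,
    FamilyMap,
    RawAnnotation,
    SchemaError,
    TooManyRowErrors,
    build_section_sets,
    filter_confidence,
    normalize_section,
    read_annotations,
)
from patentcooc.entity_mapping import MatchedEntity

HEADER = "patent_id\tsection\tsource_type\tinchikey\tname\tconfidence\n"


def _write_tsv(tmp_path, rows):
    path = tmp_path / "annotations.tsv"
    path.write_text(HEADER + "".join("\t".join(r) + "\n" for r in rows))
    return path


class TestReadAnnotations:
    def test_valid_rows_pass_through_in_order(self, tmp_path):
        rows = [
            ("p1", "title", "chemCompound", "IK-1", "", "0.9"),
            ("p2", "claims", "diseases", "", "neoplasms", "0.5"),
            ("p1", "description", "proteins", "", "insulin", "0.41"),
        ]
        recs = list(read_annotations(_write_tsv(tmp_path, rows)))
        assert [r.patent_id for r in recs] == ["p1", "p2", "p1"]
        assert recs[0].inchikey == "IK-1" and recs[0].name is None
        assert recs[1].confidence == 0.5

    def test_malformed_confidence_isolated_as_row_error(self, tmp_path):
        rows = [
            ("p1", "title", "drugs", "IK-1", "", "abc"),
            ("p2", "title", "drugs", "IK-2", "", "0.8"),
        ]
        errors = []
        recs = list(
            read_annotations(
                _write_tsv(tmp_path, rows), errors=errors, max_error_fraction=0.9
            )
        )
        assert [r.patent_id for r in recs] == ["p2"]
        assert len(errors) == 1 and errors[0].line == 2

    def test_error_fraction_limit_enforced(self, tmp_path):
        rows = [("p1", "title", "drugs", "IK-1", "", "oops")] * 3 + [
            ("p2", "title", "drugs", "IK-2", "", "0.6")
        ]
        with pytest.raises(TooManyRowErrors):
            list(read_annotations(_write_tsv(tmp_path, rows)))

    def test_header_only_file_yields_empty_stream(self, tmp_path):
        assert list(read_annotations(_write_tsv(tmp_path, []))) == []

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("patent_id\tsection\tconfidence\np1\ttitle\t0.5\n")
        with pytest.raises(SchemaError):
            list(read_annotations(path))

    def test_jsonl_equivalent_to_tsv(self, tmp_path):
        path = tmp_path / "annotations.jsonl"
        rows = [
            {
                "patent_id": "p1",
                "section": "Title",
                "source_type": "natprod",
                "inchikey": "IK-9",
                "name": "",
                "confidence": 0.7,
            }
        ]
        path.write_text("".join(json.dumps(r) + "\n" for r in rows))
        recs = list(read_annotations(path, fmt="jsonl"))
        assert recs == [RawAnnotation("p1", "title", "natprod", "IK-9", None, 0.7)]


class TestFilterConfidence:
    def test_threshold_boundary_is_inclusive(self):
        recs = [
            RawAnnotation("p", "title", "drugs", "IK", None, c)
            for c in (0.39, 0.40, 0.41)
        ]
        kept = [r.confidence for r in filter_confidence(recs, 0.4)]
        assert kept == [0.40, 0.41]

    @pytest.mark.parametrize(
        "threshold,n_kept", [(0.0, 3), (1.0, 0)], ids=["vacuous", "degenerate"]
    )
    def test_extreme_thresholds(self, threshold, n_kept):
        recs = [
            RawAnnotation("p", "title", "drugs", "IK", None, c)
            for c in (0.2, 0.5, 0.9)
        ]
        assert len(list(filter_confidence(recs, threshold))) == n_kept


class TestNormalizeSection:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("DESCRIPTION", "description"),
            ("claims", "claims"),
            (" Title ", "title"),
            ("drawings", "drawings"),
        ],
    )
    def test_total_case_insensitive_mapping(self, label, expected):
        assert normalize_section(label) == expected

    def test_empty_label_rejected(self):
        with pytest.raises(DataError):
            normalize_section("   ")


def _me(pid, section, tname, cid):
    return MatchedEntity(EntityType(tname), cid, pid, section)


class TestBuildSectionSets:
    FAM = FamilyMap(entries={"p1": "F1", "p2": "F1", "p3": "F2"})

    def test_repeated_mention_counted_once(self):
        matched = [_me("p1", "description", "chemical", "5")] * 5
        corpus = build_section_sets(matched, self.FAM)
        [sset] = list(corpus.section_sets())
        assert sset.count == 1 and sset.entities == frozenset({"5"})

    def test_sections_are_independent(self):
        matched = [
            _me("p1", "title", "chemical", "5"),
            _me("p1", "claims", "chemical", "5"),
        ]
        corpus = build_section_sets(matched, self.FAM)
        assert len(corpus.sets) == 2
        for entities in corpus.sets.values():
            assert entities == frozenset({"5"})

    def test_counts_match_hand_enumeration(self):
        matched = [
            _me("p1", "title", "chemical", "a"),
            _me("p1", "title", "chemical", "b"),
            _me("p1", "claims", "disease", "d1"),
            _me("p2", "claims", "chemical", "a"),
            _me("p2", "claims", "chemical", "a"),
            _me("p2", "description", "gene", "g1"),
            _me("p2", "description", "gene", "g2"),
            _me("p2", "description", "gene", "g1"),
        ]
        corpus = build_section_sets(matched, self.FAM)
        counts = {key: len(v) for key, v in corpus.sets.items()}
        assert counts == {
            ("p1", "title", EntityType.CHEMICAL): 2,
            ("p1", "claims", EntityType.DISEASE): 1,
            ("p2", "claims", EntityType.CHEMICAL): 1,
            ("p2", "description", EntityType.GENE): 2,
        }

    def test_unknown_patent_rejected_with_ids(self):
        with pytest.raises(DataError, match="p99"):
            build_section_sets([_me("p99", "title", "chemical", "x")], self.FAM)

    def test_dedup_is_idempotent_fixed_point(self):
        matched = [
            _me("p1", "title", "chemical", "a"),
            _me("p1", "title", "chemical", "a"),
            _me("p3", "claims", "gene", "g"),
        ]
        corpus = build_section_sets(matched, self.FAM)
        flattened = [
            _me(s.patent_id, s.section, s.entity_type.value, cid)
            for s in corpus.section_sets()
            for cid in s.entities
        ]
        again = build_section_sets(flattened, self.FAM)
        assert again.sets == corpus.sets

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.permutations(list(range(8))))
    def test_totals_invariant_to_row_order(self, order):
        base = [
            _me("p1", "title", "chemical", "a"),
            _me("p1", "title", "chemical", "b"),
            _me("p1", "claims", "disease", "d"),
            _me("p2", "description", "gene", "g1"),
            _me("p2", "description", "gene", "g2"),
            _me("p2", "title", "chemical", "a"),
            _me("p3", "abstract", "disease", "d"),
            _me("p3", "abstract", "disease", "d"),
        ]
        shuffled = [base[i] for i in order]
        assert build_section_sets(shuffled, self.FAM).sets == build_section_sets(
            base, self.FAM
        ).sets


class TestFamilyMap:
    def test_conflicting_assignment_rejected(self, tmp_path):
        path = tmp_path / "fam.tsv"
        path.write_text("patent_id\tfamily_id\np1\tF1\np1\tF2\n")
        with pytest.raises(DataError):
            FamilyMap.from_tsv(path)

    def test_roundtrip(self, tmp_path):
        path = tmp_path / "fam.tsv"
        path.write_text("patent_id\tfamily_id\np1\tF1\np2\tF1\n")
        fam = FamilyMap.from_tsv(path)
        assert fam.family_of("p2") == "F1" and fam.families() == {"F1"}


def test_corpus_flags_are_monotone(make_corpus):
    corpus = make_corpus({("p1", "title", "chemical"): ["a"]})
    flagged = corpus.with_flags("mapped").with_flags("deduplicated")
    assert frozenset({"mapped", "deduplicated"}) <= flagged.flags
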