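import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patentcooc.corpus_model import DataError, EntityType
from patentcooc.scoring import (
    ScoringParams,
    build_dataset_stats,
    compute_family_weights,
    cooccurrence_score,
    family_pair_weight,
    idf_term,
    informativeness_weight,
    patent_pair_weight,
    relevance_score,
    score_corpus,
    section_pair_weight,
    simple_score,
)

PARAMS = ScoringParams()


class TestScoringParams:
    def test_stock_values(self):
        assert PARAMS.n_s("title") == 5
        assert PARAMS.n_s("description") == 20
        assert PARAMS.n_s("examples") == 5  # unlisted sections use the default
        assert PARAMS.n_min == 5
        assert PARAMS.n_cutoff == 200
        assert PARAMS.confidence_threshold == 0.4
        assert (
            PARAMS.max_neighbors_saved,
            PARAMS.max_families_saved,
            PARAMS.max_families_shown,
        ) == (100, 1000, 5)

    def test_file_roundtrip(self, tmp_path):
        import yaml

        path = tmp_path / "params.yaml"
        path.write_text(yaml.safe_dump(PARAMS.to_dict()))
        assert ScoringParams.from_file(path) == PARAMS

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            ScoringParams(n_cutoff=10)


class TestInformativenessWeight:
    @pytest.mark.parametrize(
        "count,section,expected",
        [
            (3, "title", 1.0),
            (10, "description", 0.25),
            (100, "claims", 0.05),
            (201, "title", 0.0),
            (201, "description", 0.0),
        ],
    )
    def test_worked_values(self, count, section, expected):
        assert informativeness_weight(count, section, params=PARAMS) == expected

    def test_continuous_at_capacity(self):
        for section in ("title", "description"):
            n_s = PARAMS.n_s(section)
            below = informativeness_weight(n_s, section, params=PARAMS)
            above = informativeness_weight(n_s + 1, section, params=PARAMS)
            assert below == PARAMS.n_min / n_s
            assert above == pytest.approx(PARAMS.n_min / (n_s + 1))

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        count=st.integers(min_value=0, max_value=500),
        section=st.sampled_from(["title", "abstract", "claims", "description", "x"]),
    )
    def test_bounded_and_nonincreasing(self, count, section):
        a = informativeness_weight(count, section, params=PARAMS)
        assert 0.0 <= a <= 1.0
        assert informativeness_weight(count + 1, section, params=PARAMS) <= a
        if count > PARAMS.n_cutoff:
            assert a == 0.0


class TestPairWeights:
    def test_section_pair_weight_is_product(self):
        assert section_pair_weight(1.0, 0.05) == 0.05
        assert section_pair_weight(0.0, 0.7) == 0.0
        assert section_pair_weight(0.25, 0.25) == 0.0625

    def test_patent_pair_weight_is_max_product(self):
        q = [("title", 1.0), ("abstract", 0.5)]
        n = [("description", 0.05)]
        assert patent_pair_weight(q, n) == pytest.approx(0.05)

    def test_patent_pair_weight_zero_sections(self):
        assert patent_pair_weight([("x", 0.0)], [("y", 0.0)]) == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        qa=st.lists(
            st.floats(min_value=0, max_value=1), min_size=1, max_size=3
        ),
        na=st.lists(
            st.floats(min_value=0, max_value=1), min_size=1, max_size=3
        ),
    )
    def test_patent_pair_weight_equals_grid_brute_force(self, qa, na):
        q = [(f"s{i}", a) for i, a in enumerate(qa)]
        n = [(f"t{i}", a) for i, a in enumerate(na)]
        brute = max(a1 * a2 for _, a1 in q for _, a2 in n)
        assert patent_pair_weight(q, n) == pytest.approx(brute)

    def test_family_weight_is_max_over_patents(self):
        assert family_pair_weight({"p1": 0.05, "p2": 1.0}) == 1.0
        assert family_pair_weight({"p1": 0.3}) == 0.3
        five = {f"p{i}": w for i, w in enumerate([0.1, 0.4, 0.2, 0.05, 0.35])}
        assert family_pair_weight(five) == max(five.values())

    def test_family_weight_requires_presence(self):
        with pytest.raises(DataError):
            family_pair_weight({})


class TestScores:
    def test_simple_score_sums_families(self):
        assert simple_score({"F1": 0.05, "F2": 1.0}) == pytest.approx(1.05)
        assert simple_score({}) == 0.0
        assert simple_score({f"F{i}": 1.0 for i in range(10)}) == 10.0

    def test_cooccurrence_score_is_product(self):
        assert cooccurrence_score(1.05, 0.5) == pytest.approx(0.525)
        assert cooccurrence_score(3.2, 1.0) == 3.2
        assert cooccurrence_score(0.0, 0.9) == 0.0

    def test_relevance_equals_family_weight(self):
        assert relevance_score(0.25) == 0.25
        assert relevance_score(1.0) == 1.0


class TestIdfTerm:
    def test_below_one_effective_count_returns_one(self):
        assert idf_term(0.5, 100) == 1.0

    def test_saturated_neighbor_scores_zero(self):
        assert idf_term(1000, 1000) == pytest.approx(0.0)

    def test_single_family_dataset_returns_one(self):
        assert idf_term(1.0, 1) == 1.0

    def test_effective_count_above_dataset_size_rejected(self):
        with pytest.raises(DataError):
            idf_term(101.0, 100)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n_bar=st.floats(min_value=1.0, max_value=1e6),
        n_ds=st.integers(min_value=2, max_value=10**7),
    )
    def test_base_invariance_and_bounds(self, n_bar, n_ds):
        if n_bar > n_ds:
            return
        r = idf_term(n_bar, n_ds)
        assert 0.0 <= r <= 1.0
        base10 = 1.0 - math.log10(n_bar) / math.log10(n_ds)
        assert r == pytest.approx(base10, rel=1e-12, abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        n_bar=st.floats(min_value=1.0, max_value=999.0),
        delta=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_nonincreasing_in_effective_count(self, n_bar, delta):
        assert idf_term(n_bar + delta, 1000) <= idf_term(n_bar, 1000) + 1e-12


class TestCorpusScoring:
    def test_effective_count_is_sum_of_per_family_maxima(self, make_corpus):
        # neighbor "n" meets partners in three families with best weights
        # 1.0 (title-title), 0.25 (desc-desc at 10+10 ... ), handcrafted:
        corpus = make_corpus(
            {
                ("p1", "title", "chemical"): ["n", "q1"],
                ("p2", "abstract", "chemical"): ["n", "q1", "q2", "q3", "q4", "q5", "q6", "q7", "q8", "q9"],
                ("p3", "claims", "chemical"): ["n", "q2"],
            },
            family_map={"p1": "F1", "p2": "F2", "p3": "F3"},
        )
        fw = compute_family_weights(corpus, PARAMS)
        tp = (EntityType.CHEMICAL, EntityType.CHEMICAL)
        stats = build_dataset_stats(fw[tp], tp)
        # F1: both in 2-count title -> 1*1; F2: 10-count abstract -> 0.5*0.5;
        # F3: 2-count claims -> 1.
        assert stats.effective_counts["n"] == pytest.approx(1.0 + 0.25 + 1.0)
        assert stats.n_ds == 3

    def test_empty_dataset_raises(self, make_corpus):
        corpus = make_corpus({("p1", "title", "chemical"): ["solo"]})
        fw = compute_family_weights(corpus, PARAMS)
        tp = (EntityType.CHEMICAL, EntityType.CHEMICAL)
        with pytest.raises(DataError):
            build_dataset_stats(fw[tp], tp)

    def test_same_type_pairs_require_distinct_ids(self, make_corpus):
        corpus = make_corpus({("p1", "title", "chemical"): ["a", "b"]})
        result = score_corpus(corpus, PARAMS)
        tp = (EntityType.CHEMICAL, EntityType.CHEMICAL)
        assert set(result.scores[tp]) == {("a", "b"), ("b", "a")}

    def test_cross_type_simple_score_symmetric_and_idf_ratio(self, make_corpus):
        corpus = make_corpus(
            {
                ("p1", "title", "chemical"): ["c1", "c2"],
                ("p1", "claims", "disease"): ["d1"],
                ("p2", "title", "chemical"): ["c1"],
                ("p2", "title", "disease"): ["d1", "d2"],
            },
            family_map={"p1": "F1", "p2": "F2"},
        )
        result = score_corpus(corpus, PARAMS)
        cd = (EntityType.CHEMICAL, EntityType.DISEASE)
        dc = (EntityType.DISEASE, EntityType.CHEMICAL)
        fwd = result.pair(cd, "c1", "d1")
        rev = result.pair(dc, "d1", "c1")
        assert fwd.simple_score == rev.simple_score
        # S(i1->i2)/S(i2->i1) = r_{i2}/r_{i1} whenever both defined
        assert fwd.score * rev.idf_term == pytest.approx(
            rev.score * fwd.idf_term
        )

    def test_zero_weight_sections_drop_out(self, make_corpus):
        many = [f"c{i}" for i in range(201)]
        corpus = make_corpus(
            {
                ("p1", "title", "chemical"): many,  # 201 > cutoff -> alpha 0
                ("p2", "title", "chemical"): ["c0", "c1"],
            },
            family_map={"p1": "F1", "p2": "F2"},
        )
        result = score_corpus(corpus, PARAMS)
        tp = (EntityType.CHEMICAL, EntityType.CHEMICAL)
        assert result.stats[tp].n_ds == 1  # F1 contributes nothing
        assert set(result.scores[tp]) == {("c0", "c1"), ("c1", "c0")}

    def test_all_weights_one_reduces_to_family_counting(self, make_corpus):
        # every section small and N_s uniform -> all alphas 1, all weights 1,
        # so N_bar is a plain document (family) frequency
        params = ScoringParams(n_s_overrides={})
        corpus = make_corpus(
            {
                ("p1", "title", "chemical"): ["a", "b"],
                ("p2", "claims", "chemical"): ["a", "c"],
                ("p3", "description", "chemical"): ["a", "b", "c"],
            },
            family_map={"p1": "F1", "p2": "F2", "p3": "F3"},
        )
        result = score_corpus(corpus, params)
        tp = (EntityType.CHEMICAL, EntityType.CHEMICAL)
        stats = result.stats[tp]
        df = {"a": 3, "b": 2, "c": 2}  # families mentioning with a partner
        assert stats.n_ds == 3
        for cid, expected in df.items():
            assert stats.effective_counts[cid] == pytest.approx(expected)
            r = result.pair(tp, "a" if cid != "a" else "b", cid).idf_term
            assert r == pytest.approx(1 - math.log(expected) / math.log(3))
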