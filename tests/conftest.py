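import pytest

from patentcooc.corpus_model import Corpus, EntityType, FamilyMap


@pytest.fixture
def make_corpus():
    """Build a corpus from a literal spec.

    ``sets_spec`` maps ``(patent_id, section, type_name)`` to an iterable of
    entity ids; ``family_map`` maps patent -> family (defaults to one family
    per patent).
    """

    def _make(sets_spec, family_map=None):
        patents = {pid for (pid, _, _) in sets_spec}
        if family_map is None:
            family_map = {pid: f"fam-{pid}" for pid in patents}
        sets = {
            (pid, section, EntityType(tname)): frozenset(ids)
            for (pid, section, tname), ids in sets_spec.items()
        }
        return Corpus(sets=sets, family_map=FamilyMap(entries=family_map))

    return _make


@pytest.fixture
def tiny_generator_config():
    """A small generator configuration usable for brute-force comparison."""
    from patentcooc.synthetic_corpus import (
        GeneratorConfig,
        PlantedPair,
        SectionCountSpec,
    )

    def _make(seed, planted=False):
        counts = {
            etype: {
                "title": SectionCountSpec(1.0, 0.4),
                "abstract": SectionCountSpec(1.0, 0.4),
                "claims": SectionCountSpec(2.0, 0.5),
                "description": SectionCountSpec(3.0, 0.6),
            }
            for etype in EntityType
        }
        pairs = ()
        if planted:
            from patentcooc.synthetic_corpus import chemical_id, disease_id

            pairs = (
                PlantedPair(
                    EntityType.CHEMICAL,
                    chemical_id(3),
                    EntityType.DISEASE,
                    disease_id(2),
                    boost=8.0,
                ),
            )
        return GeneratorConfig(
            seed=seed,
            n_families=5,
            patents_per_family_mean=1.2,
            vocab_sizes={
                EntityType.CHEMICAL: 12,
                EntityType.DISEASE: 5,
                EntityType.GENE: 6,
            },
            zipf_exponent=1.1,
            section_counts=counts,
            planted_pairs=pairs,
            base_pair_rate=0.05,
        )

    return _make
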