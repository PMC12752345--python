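# Methods

## Scoring model

The pipeline summarizes per-section entity annotations of patent documents
into ranked query–neighbor relationships between chemicals, diseases, and
genes (the gene category absorbs proteins and enzymes, whose names are
rarely distinguishable in text). Its core assumption: a mention is
informative in proportion to how exclusive its section is. A chemical named
in a five-entity title is probably the subject matter; one of four hundred
in a description is probably a solvent, a reagent, or a Markush fragment.

Stages, in order:

1. **Confidence filter.** Annotations carry a machine-annotation confidence
   in [0, 1]; records with confidence ≥ 0.4 are kept (boundary inclusive).
   The filter applies per mention, before deduplication.
2. **Identifier mapping.** Chemicals match by exact InChIKey lookup (a
   chemical mention without an InChIKey is dropped as unmatched); disease
   and gene names match after NFC normalization, case-folding, trimming,
   and whitespace collapsing. Mapping tables must be one-to-one — an
   ambiguous name fails the load rather than making scoring
   nondeterministic. Unmatched is a counted outcome, not an error.
3. **Deduplication.** A canonical id counts once per (patent, section,
   type), however many times it is mentioned there.
4. **Redundancy collapse.** Near-duplicate chemicals (salt forms, shared
   parent connectivity, shared names) are supplied as precomputed groups
   and collapsed to one representative: the member annotated in the most
   families, ties to the numerically smallest id. The rule is
   deterministic and favors the commonly used form; computing the groups
   from structures is out of scope. Collapse runs before exclusion — the
   order is a design choice; the two transforms commute except through the
   family counts used to pick representatives.
5. **Exclusion list.** Union of two criterion lists: the `k_freq` compounds
   in the most annotated families, and the `k_disease` compounds in the
   most families that also carry a disease annotation anywhere. Ties at the
   k-th count are all included (deterministic, possibly > k members).
   Excluded compounds are removed from chemical sets as queries and
   neighbors alike, and the per-section counts — hence all informativeness
   weights — are recomputed from the reduced sets.
6. **Scoring.** As in the README: α per (patent, section, type) from the
   non-redundant count; pair weight = product of the two entities' best α
   within a patent, maximized over the family's patents; S̃ sums family
   weights; the IDF term r = 1 − log N̄ / log N_DS discounts ubiquitous
   neighbors; S = S̃·r ranks neighbors; family relevance equals the family
   weight (mention proximity within the text is deliberately not modelled).
7. **Ranking and caps.** Score descending, neighbor id ascending on ties;
   100 neighbors saved per query, 1000 families saved per pair, 5 shown.
   Ranking is a total order: input permutation cannot change output.

## Parameters

| parameter | default | meaning |
|---|---|---|
| N_s (all sections but description) | 5 | section capacity below which α is maximal |
| N_s (description) | 20 | larger capacity for the inherently crowded section |
| N_min | min_s N_s = 5 | numerator of α; makes max α = 1 |
| N_cutoff | 200 | counts above this contribute nothing (α = 0) |
| confidence threshold | 0.4 | per-mention annotation confidence floor |
| k_freq / k_disease | 250 / 150 | criterion list sizes for the exclusion list |
| caps | 100 / 1000 / 5 | neighbors saved / families saved / families shown |

Sections outside {title, abstract, claims, description} are preserved
verbatim (lower-cased) and scored with the non-description capacity 5.
N_DS for an ordered type pair counts the distinct families carrying at
least one positive-weight pair of those types; N̄ and N_DS are computed on
the full pair set, before neighbor-cap truncation. Same-type pairs require
distinct ids; cross-type pairs admit any ids. Zero-weight pairs are never
materialized — absence and zero are equivalent downstream. Logs are
natural; the IDF ratio of logs is base-invariant. Sums accumulate in double
precision, and comparisons against published worked values are made at the
three decimals at which they are printed.

## Synthetic corpus generator

The generator emulates the statistical features that exercise the model:

- **Skewed section counts.** Per (patent, section, type), counts are
  rounded log-normals with medians ordered description (20 for chemicals)
  > claims (8) > abstract (3) > title (1) and a heavy description tail
  (σ = 1.0) so that a small fraction of sections exceeds the 200-entity
  cut-off. Disease/gene sections are smaller (medians 6/7 down to 1).
- **Zipf entities.** Entities are drawn without replacement with
  probability ∝ rank^(−1.1) from vocabularies of 400 chemicals, 60
  diseases, 80 genes — a head of ubiquitous compounds and a long tail.
- **Families.** Geometric family sizes with mean 1.5 patents.
- **Planted associations.** A planted (query, neighbor) pair is co-injected
  into the claims of one patent of a family with probability
  boost × base rate (default 5 × 0.01), on top of chance co-mentions. The
  defaults plant one chemical–chemical and one chemical–disease pair among
  mid-frequency entities.
- **Noise.** Duplicate mentions (rate 0.2), sub-threshold confidence
  mentions (rate 0.1, confidence < 0.4), and unmappable chemical mentions
  (rate 0.05, alternating missing and unknown InChIKeys) decorate the
  data; none of them survives the pipeline.
- **Redundancy variants.** Optionally, selected mid-rank compounds get 2–3
  numerically larger variant ids co-annotated in exactly the base
  compound's sections, plus a matching group table, so collapsing
  reproduces the base-only corpus exactly.

Ground truth is exact by construction: the surviving section sets are drawn
first and every member is guaranteed one above-threshold, mappable mention,
so the truth record's family counts equal the pipeline's recounts. The
generator does not emulate real corpora's section-size extremes (thousands
of entities), cross-section containment structure (title entities recurring
in the description), multilingual or OCR noise, or a realistic vocabulary
scale (millions of compounds). Passing tests therefore demonstrate the
correctness and stable behavior of the scoring machinery, not
dataset-scale statistics of any real patent corpus.

## Verification design

- Every scoring operation is checked against its closed-form examples, and
  the full pipeline is checked on ~100 small random corpora against a
  brute-force implementation that evaluates the defining formulas by
  explicit loops over (family, patent, section, section, entity, entity),
  to 1e-12 relative agreement, including rankings.
- Published worked values of the IDF term (selected compounds of the
  chemical–chemical dataset, with and without the exclusion list) are
  reproduced to their printed three decimals from the published effective
  counts and dataset sizes; `scripts/acceptance.py` recomputes them.
- With uniform capacities and all counts at or below them, every weight is
  1 and the IDF term must reduce to 1 − log(df)/log(N_DS) with df a
  directly counted family document frequency; this reduction is asserted
  against an independent counter.
- Planted associations are required to reach their query's top-10 neighbor
  list in ≥ 90% of 20 seeds at default generator settings; the test sizes
  (1000 families, 20 seeds; 100 oracle corpora of ≤ ~20 patents) were
  chosen to make these distributional checks decisive at desk scale.

## Known limitations

- The exclusion list's effect on dataset sizes is direction-ambiguous at
  small scale: removing compounds raises informativeness weights (a
  theorem, asserted as such) and at corpus scale tends to admit more
  families into the chemical datasets, but a small family whose
  positive-weight chemicals are all excluded drops out, so N_DS can shrink
  by a family or two on synthetic corpora. The test suite asserts the
  strict non-decrease and documents the observed small-corpus violations
  rather than weakening the check.
- Name resolution is table lookup by design; synonym mining,
  structure-derived redundancy groups, and human-gene prioritization live
  upstream of this package.
- Scores are not probabilities; they are comparable within one (query
  type, neighbor type) dataset only, and the IDF term makes S asymmetric
  between the two directions of a pair (S̃ is symmetric).
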