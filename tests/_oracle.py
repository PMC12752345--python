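"""Direct, unoptimized reference implementation of the scoring model.

Everything here is computed by explicit loops over (family, patent, section,
section, entity, entity), exactly as the defining formulas read, with no
shared code path with the package's pipeline. Only usable on tiny corpora.
"""

from __future__ import annotations

import math

from patentcooc.corpus_model import Corpus, EntityType
from patentcooc.scoring import ScoringParams


def oracle_alpha(count: int, section: str, params: ScoringParams) -> float:
    n_s = params.n_s_overrides.get(section, params.n_s_default)
    n_min = min([params.n_s_default, *params.n_s_overrides.values()])
    if count > params.n_cutoff:
        return 0.0
    if count <= n_s:
        return n_min / n_s
    return n_min / max(n_s, count)


def oracle_scores(corpus: Corpus, params: ScoringParams) -> dict:
    """All nine ordered type-pair datasets, brute-forced.

    Returns, per ordered type pair with at least one positive pair:
    ``family_weights`` ((i1, i2) -> {family: W}), ``n_ds``, ``nbar``
    (neighbor -> effective count), and ``scores`` ((i1, i2) ->
    (simple, idf, score)).
    """
    sets = corpus.sets
    fam_of = corpus.family_map.entries
    families: dict[str, set[str]] = {}
    for (pid, _, _) in sets:
        families.setdefault(fam_of[pid], set()).add(pid)

    results: dict = {}
    for t1 in EntityType:
        for t2 in EntityType:
            fam_w: dict[tuple[str, str], dict[str, float]] = {}
            for family, patents in families.items():
                cand1: set[str] = set()
                cand2: set[str] = set()
                for (pid, s, t), ents in sets.items():
                    if pid in patents and t is t1:
                        cand1 |= ents
                    if pid in patents and t is t2:
                        cand2 |= ents
                for i1 in cand1:
                    for i2 in cand2:
                        if t1 is t2 and i1 == i2:
                            continue
                        w = 0.0
                        for pid in patents:
                            for (p1, s1, tt1), e1 in sets.items():
                                if p1 != pid or tt1 is not t1 or i1 not in e1:
                                    continue
                                a1 = oracle_alpha(len(e1), s1, params)
                                for (p2, s2, tt2), e2 in sets.items():
                                    if (
                                        p2 != pid
                                        or tt2 is not t2
                                        or i2 not in e2
                                    ):
                                        continue
                                    a2 = oracle_alpha(len(e2), s2, params)
                                    if a1 * a2 > w:
                                        w = a1 * a2
                        if w > 0.0:
                            fam_w.setdefault((i1, i2), {})[family] = w
            if not fam_w:
                continue
            dataset_families = {f for d in fam_w.values() for f in d}
            n_ds = len(dataset_families)
            neighbors = {i2 for (_, i2) in fam_w}
            nbar: dict[str, float] = {}
            for i2 in neighbors:
                total = 0.0
                for family in dataset_families:
                    best = 0.0
                    for (j1, j2), d in fam_w.items():
                        if j2 == i2 and family in d and d[family] > best:
                            best = d[family]
                    total += best
                nbar[i2] = total
            scores = {}
            for (i1, i2), d in fam_w.items():
                simple = sum(d.values())
                nb = nbar[i2]
                if n_ds > 1 and nb >= 1.0:
                    r = 1.0 - math.log(nb) / math.log(n_ds)
                else:
                    r = 1.0
                scores[(i1, i2)] = (simple, r, simple * r)
            results[(t1, t2)] = {
                "family_weights": fam_w,
                "n_ds": n_ds,
                "nbar": nbar,
                "scores": scores,
            }
    return results
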