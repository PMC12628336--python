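"""Overlap, similarity search, diversity and scaffold-gap statistics.

The fast vectorised similarity routines are checked against O(n²) brute-force
double loops on corpora of a few hundred molecules.
"""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from chemcov.descriptors import circular_fingerprint, murcko_scaffold, tanimoto
from chemcov.overlap import (
    exact_overlap,
    mean_pairwise_tanimoto,
    missing_scaffolds,
    scaffold_stats,
    similarity_overlap,
)


@pytest.fixture(scope="module")
def corpus_fps(small_corpus):
    """InChI → fingerprint for ≤500 corpus molecules."""
    items = list(small_corpus.molecules.items())[:500]
    return {
        inchi: circular_fingerprint(Chem.MolFromSmiles(rec.smiles))
        for inchi, rec in items
    }


def test_exact_overlap_identities():
    a = {"x", "y", "z"}
    assert exact_overlap(a, a) == (3, ["x", "y", "z"])
    assert exact_overlap(a, {"p"})[0] == 0
    assert exact_overlap(a, {"y", "q"}) == (1, ["y"])
    assert exact_overlap(a, {"y"}) == exact_overlap({"y"}, a)


def test_similarity_overlap_against_brute_force(corpus_fps):
    keys = sorted(corpus_fps)
    a, b = set(keys[: len(keys) // 2]), set(keys[len(keys) // 3 :])
    threshold = 0.75
    count, members = similarity_overlap(a, b, corpus_fps, threshold)
    # brute force: double loop over every (a, b) pair
    brute = {
        ka
        for ka in a
        if any(tanimoto(corpus_fps[ka], corpus_fps[kb]) >= threshold for kb in b)
    } | (a & b)
    assert set(members) == brute
    assert count == len(brute)
    n_exact, _ = exact_overlap(a, b)
    assert n_exact <= count  # exact match ⇒ similarity 1.0


def test_similarity_overlap_is_directional(corpus_fps):
    # asymmetric fixture: b ⊇ a, so every a-member is covered but not
    # every b-member has an analogue in the small set a
    keys = sorted(corpus_fps)[:300]
    a, b = set(keys[:30]), set(keys)
    ab, _ = similarity_overlap(a, b, corpus_fps)
    ba, _ = similarity_overlap(b, a, corpus_fps)
    assert ab == len(a)  # full coverage in one direction ...
    assert ba < len(b)  # ... partial in the other
    assert ab / len(a) != ba / len(b)


def test_similarity_overlap_bounds(corpus_fps):
    keys = sorted(corpus_fps)[:80]
    a = set(keys[:40])
    b = set(keys)  # b ⊇ a: every member is self-similar
    assert similarity_overlap(a, b, corpus_fps)[0] == len(a)
    assert similarity_overlap(a, b, corpus_fps, threshold=1.01)[0] == len(a & b)


def test_similarity_overlap_missing_fingerprint(corpus_fps):
    with pytest.raises(KeyError):
        similarity_overlap({"nope"}, set(list(corpus_fps)[:3]), corpus_fps)


def test_mean_pairwise_tanimoto_brute_force(corpus_fps):
    members = set(sorted(corpus_fps)[:100])
    fast = mean_pairwise_tanimoto(members, corpus_fps)
    keys = sorted(members)
    sims = [
        tanimoto(corpus_fps[x], corpus_fps[y])
        for i, x in enumerate(keys)
        for y in keys[i + 1 :]
    ]
    assert fast == pytest.approx(np.mean(sims))


def test_mean_pairwise_tanimoto_small_sets(corpus_fps):
    k = sorted(corpus_fps)[0]
    assert np.isnan(mean_pairwise_tanimoto({k}, corpus_fps))
    assert mean_pairwise_tanimoto({"a", "b"}, {"a": corpus_fps[k], "b": corpus_fps[k]}) == 1.0


def test_scaffold_stats_hand_example():
    # toluene + ethylbenzene share the benzene framework; naphthalene is alone
    mols = {"t": "Cc1ccccc1", "e": "CCc1ccccc1", "n": "c1ccc2ccccc2c1"}
    scaffolds = {
        k: murcko_scaffold(Chem.MolFromSmiles(s)).scaffold_smiles
        for k, s in mols.items()
    }
    st = scaffold_stats(set(mols), scaffolds)
    assert st.n_scaffolds == 2
    assert st.mean_per_scaffold == 1.5
    assert st.n_singletons == 1
    assert st.singleton_fraction == 0.5


def test_scaffold_stats_single_class():
    scaffolds = {"a": "c1ccccc1", "b": "c1ccccc1", "c": "c1ccccc1"}
    st = scaffold_stats({"a", "b", "c"}, scaffolds)
    assert st.n_scaffolds == 1
    assert st.singleton_fraction == 0
    assert st.mean_per_scaffold == 3


def test_acyclic_scaffold_convention():
    scaffolds = {"a": "", "b": "", "c": "c1ccccc1"}
    with_empty = scaffold_stats({"a", "b", "c"}, scaffolds, include_acyclic=True)
    without = scaffold_stats({"a", "b", "c"}, scaffolds, include_acyclic=False)
    assert with_empty.n_scaffolds == 2
    assert without.n_scaffolds == 1
    assert without.n_molecules == 1


def test_missing_scaffolds_trivia():
    scaffolds = {"q1": "S1", "q2": "S1", "r1": "S1"}
    # references jointly cover every query scaffold -> no gaps
    assert missing_scaffolds({"q1", "q2"}, scaffolds, {"R": {"r1"}}) == []
    # empty reference -> the lone scaffold is a 100% gap
    gaps = missing_scaffolds({"q1"}, scaffolds, {"R": set()})
    assert len(gaps) == 1
    assert gaps[0].pct_of_query == 100.0


def test_missing_scaffolds_recover_ground_truth(small_corpus, small_result):
    """Pipeline gap ranking equals generator bookkeeping, exactly."""
    gt = small_corpus.ground_truth
    got = [
        (r.scaffold_smiles, r.count_in_query)
        for r in small_result.scaffold_gaps.itertuples()
    ]
    assert got == [tuple(x) for x in gt.uncovered_scaffolds]
    # the deliberately planted query-only scaffolds appear with exact counts
    for smiles, count in gt.planted_uncovered:
        assert (smiles, count) in got


def test_scaffold_count_scales_with_set_size(small_corpus, small_result):
    """Scaffold diversity grows with set size on scaffold-structured libraries."""
    rows = [
        (row["n_curated"], row["n_scaffolds"])
        for t in ("table_1", "table_2")
        for _, row in small_result.tables[t].iterrows()
        if row["dataset"] != "total"
    ]
    sizes, scaffolds = zip(*sorted(rows))
    assert np.corrcoef(sizes, scaffolds)[0, 1] > 0.8
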