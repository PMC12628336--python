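"""Generator self-consistency: determinism, bookkeeping, artifact manifest."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from chemcov.synthetic import (
    GeneratorConfig,
    generate_library,
    ground_truth_report,
    inject_artifacts,
)

TINY = dict(
    n_query_sets=2,
    n_reference_sets=2,
    query_set_sizes=(40, 30),
    reference_set_sizes=(50, 40),
    uncovered_scaffold_counts=(3, 1),
)


def test_seed_determinism():
    a = generate_library(GeneratorConfig(**TINY, seed=3))
    b = generate_library(GeneratorConfig(**TINY, seed=3))
    assert a.ground_truth == b.ground_truth
    for name in a.datasets:
        assert a.datasets[name].equals(b.datasets[name])
    assert a.assays.equals(b.assays)
    assert ground_truth_report(GeneratorConfig(**TINY, seed=3)) == a.ground_truth


def test_different_seed_differs():
    a = generate_library(GeneratorConfig(**TINY, seed=3))
    b = generate_library(GeneratorConfig(**TINY, seed=4))
    assert a.ground_truth != b.ground_truth


def test_zero_overlap_means_disjoint_sets():
    corpus = generate_library(GeneratorConfig(**TINY, overlap_fraction=0.0, seed=5))
    gt = corpus.ground_truth
    total = sum(v["n_curated"] for v in gt.per_set.values())
    assert gt.n_universe == total
    assert gt.exact_overlap_query_reference == 0
    for name, stats in gt.per_set.items():
        assert stats["n_exclusive"] == stats["n_curated"]


def test_full_overlap_between_equal_sets():
    cfg = GeneratorConfig(
        n_query_sets=2,
        n_reference_sets=2,
        query_set_sizes=(50, 50),
        reference_set_sizes=(50, 50),
        overlap_fraction=1.0,
        uncovered_scaffold_counts=(),
        uncovered_scaffold_smiles=(),
        seed=6,
    )
    gt = generate_library(cfg).ground_truth
    # after the first set exists, every later draw reuses an earlier substance
    assert gt.n_universe == 50
    assert gt.exact_overlap_query_reference == 50


def test_membership_sizes_and_set_invariants(small_corpus):
    gt = small_corpus.ground_truth
    for name, members in small_corpus.membership.items():
        assert len(set(members)) == gt.per_set[name]["n_curated"]
        assert len(set(members)) <= gt.per_set[name]["n_initial"]
    union = set().union(*(set(m) for m in small_corpus.membership.values()))
    assert len(union) == gt.n_universe
    assert sum(len(set(m)) for m in small_corpus.membership.values()) >= gt.n_universe


def test_planted_scaffold_keys_are_canonical_murcko(small_corpus):
    for inchi, rec in list(small_corpus.molecules.items())[::19]:
        mol = Chem.MolFromSmiles(rec.smiles)
        key = Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol))
        assert key == rec.scaffold


def test_endpoint_sizes_track_coverage_probability(small_corpus):
    """Endpoint size ≈ n_reference_universe × coverage, within 3 binomial SDs."""
    gt = small_corpus.ground_truth
    cfg = small_corpus.config
    n = gt.n_reference_universe
    for test, p in cfg.per_test_coverage.items():
        sd = np.sqrt(n * p * (1 - p))
        assert abs(gt.endpoint_sizes[test] - n * p) <= 3 * sd + 1


def test_fg_frequencies_match_config_within_binomial_tolerance():
    cfg = GeneratorConfig(
        n_query_sets=1,
        n_reference_sets=1,
        query_set_sizes=(1000,),
        reference_set_sizes=(1000,),
        overlap_fraction=0.0,
        uncovered_scaffold_counts=(),
        uncovered_scaffold_smiles=(),
        seed=9,
    )
    gt = generate_library(cfg).ground_truth
    for domain in ("query", "reference"):
        for group, planted in gt.fg_planted[domain].items():
            p = gt.fg_configured[domain][group]
            sd = np.sqrt(p * (1 - p) / 1000)
            assert planted == pytest.approx(p, abs=3 * sd), (domain, group)


def test_zero_artifact_rates_leave_files_untouched():
    cfg = GeneratorConfig(
        **TINY, salt_rate=0.0, wildcard_rate=0.0, duplicate_row_rate=0.0, seed=8
    )
    corpus = generate_library(cfg)
    assert corpus.manifest.empty
    rng = np.random.default_rng(0)
    again, manifest = inject_artifacts(corpus.datasets, cfg, rng)
    assert manifest.empty
    for name in corpus.datasets:
        assert again[name].equals(corpus.datasets[name])


def test_artifact_manifest_complete(small_corpus):
    manifest = small_corpus.manifest
    assert set(manifest["kind"]) <= {"salt", "wildcard", "duplicate"}
    assert (manifest["kind"] == "salt").sum() > 0
    assert (manifest["kind"] == "wildcard").sum() > 0
    wild = manifest.query("kind == 'wildcard'")["emitted"]
    assert wild.str.contains(r"\*", regex=True).all()


def test_write_files_round_trip(tmp_path, small_corpus):
    small_corpus.write_files(tmp_path)
    assert (tmp_path / "assays.csv").exists()
    assert (tmp_path / "ground_truth.json").exists()
    assert (tmp_path / "dataset_manifest.csv").exists()
    names = {p.stem for p in (tmp_path / "datasets").glob("*.csv")}
    assert names == set(small_corpus.datasets)


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(n_query_sets=2, query_set_sizes=(10,))
    with pytest.raises(ValueError):
        GeneratorConfig(overlap_fraction=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(scaffold_pool=())
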