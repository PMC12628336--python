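"""Shared fixtures: synthetic corpora and their curated/analyzed forms.

Corpora are generated once per session; tests assert against the generator's
ground-truth bookkeeping, so no external data is ever read.
"""

from __future__ import annotations

import pytest

from chemcov.dataset_io import curate_dataset, entries_from_frame
from chemcov.pipeline import RunConfig, analyze
from chemcov.synthetic import GeneratorConfig, generate_library


def corpus_category(corpus, name: str) -> str:
    return "pesticide" if corpus.categories[name] == "query" else "genotoxicity"


def curate_corpus(corpus):
    return [
        curate_dataset(entries_from_frame(df, name), name, corpus_category(corpus, name))
        for name, df in corpus.datasets.items()
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """A few hundred molecules; fast enough for per-module tests."""
    cfg = GeneratorConfig(
        n_query_sets=2,
        n_reference_sets=3,
        query_set_sizes=(60, 40),
        reference_set_sizes=(80, 60, 40),
        uncovered_scaffold_counts=(5, 2, 1),
        seed=7,
    )
    return generate_library(cfg)


@pytest.fixture(scope="session")
def small_curated(small_corpus):
    return curate_corpus(small_corpus)


@pytest.fixture(scope="session")
def small_result(small_corpus, small_curated):
    return analyze(small_curated, small_corpus.assays, RunConfig(run_umap=False))


@pytest.fixture(scope="session")
def study_corpus():
    """The default study-scale corpus (~2,000 molecules, two domains)."""
    return generate_library(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def study_curated(study_corpus):
    return curate_corpus(study_corpus)


@pytest.fixture(scope="session")
def study_result(study_corpus, study_curated):
    return analyze(study_curated, study_corpus.assays, RunConfig(run_umap=False))
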