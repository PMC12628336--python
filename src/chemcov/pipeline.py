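"""End-to-end orchestration: curation → merge → hit calls → coverage report.

The pipeline consumes a run configuration naming the input collections (each
with a category: ``pesticide`` query domain, ``genotoxicity`` reference
domain, or additional ``reference`` sets), an optional assay-result table,
and the analysis thresholds.  It produces the report bundle:

* ``table_1.csv`` — per query-domain set accounting (initial/curated counts,
  exclusivity, scaffold statistics, intra-set diversity);
* ``table_2.csv`` — the same per reference-domain set, plus exact overlap
  with the merged query domain;
* ``table_3.csv`` — per-endpoint summaries (six test types + pooled), exact
  and similarity overlap with the query domain in both orientations, scaffold
  statistics, and aggregated positive/negative readouts;
* ``table_4.csv`` — descriptor means/SDs per endpoint and for the query set;
* ``scaffold_gaps.csv``, ``fg_enrichment.csv``, ``fg_top_k.csv``,
  ``coords_pca.csv``, ``pca_loadings.csv``, ``coords_umap.csv``,
  ``umap_grid_scores.csv``, and ``run_manifest.json`` with versions, seeds,
  thresholds and per-stage row counters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from . import __version__
from .chemspace_viz import (
    DEFAULT_BUTINA_CUTOFF,
    DEFAULT_SEED,
    DEFAULT_UMAP_GRID,
    butina_cluster,
    pca_project,
    umap_grid_search,
)
from .dataset_io import (
    CuratedSet,
    curate_dataset,
    exclusivity,
    load_dataset,
    merge_sets,
    universe_frame,
)
from .descriptors import (
    FINGERPRINT_BITS,
    FINGERPRINT_RADIUS,
    circular_fingerprint,
    descriptor_frame,
    murcko_scaffold,
)
from .fg_enrichment import (
    enrichment_frame,
    filter_patterns,
    load_catalogue,
    match_functional_groups,
    proportion_difference,
    top_k_enrichment,
)
from .hitcall import ALL_GENOTOX, TEST_TYPES, build_endpoint_sets, load_assay_results
from .overlap import (
    DEFAULT_SIMILARITY_THRESHOLD,
    coverage_report,
    mean_pairwise_tanimoto,
    missing_scaffolds,
    scaffold_stats,
)

logger = logging.getLogger(__name__)


@dataclass
class DatasetSpec:
    path: str
    name: str
    category: str


@dataclass
class RunConfig:
    datasets: list[DatasetSpec] = field(default_factory=list)
    assay_path: str | None = None
    output_dir: str = "chemcov_out"
    tanimoto_threshold: float = DEFAULT_SIMILARITY_THRESHOLD
    butina_cutoff: float = DEFAULT_BUTINA_CUTOFF
    top_k: int = 10
    pca_scaling: str = "zscore"
    umap_grid: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_UMAP_GRID))
    umap_scorer: str = "fingerprint"
    seed: int = DEFAULT_SEED
    catalogue_path: str | None = None
    run_umap: bool = True
    umap_max_points: int = 3000
    smiles_column: str = "smiles"

    def __post_init__(self) -> None:
        if not 0.0 <= self.tanimoto_threshold <= 1.0:
            raise ValueError("tanimoto_threshold must be in [0, 1]")
        if not 0.0 <= self.butina_cutoff <= 1.0:
            raise ValueError("butina_cutoff must be in [0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        specs = [DatasetSpec(**d) for d in raw.pop("datasets", [])]
        if "umap_grid" in raw:
            raw["umap_grid"] = {k: tuple(v) for k, v in raw["umap_grid"].items()}
        return cls(datasets=specs, **raw)


@dataclass
class PipelineResult:
    universe: dict
    curated: list[CuratedSet]
    endpoint_sets: dict
    tables: dict[str, pd.DataFrame]
    scaffold_gaps: pd.DataFrame
    fg_enrichment: pd.DataFrame
    fg_top_k: pd.DataFrame
    pca: object
    umap_params: object | None
    umap_coords: pd.DataFrame | None
    umap_scores: pd.DataFrame | None
    counters: dict[str, dict[str, int]]
    n_retained_patterns: int = 0


def _scaffold_row(members: set[str], scaffolds: dict[str, str]) -> dict:
    st = scaffold_stats(members, scaffolds)
    return {
        "n_scaffolds": st.n_scaffolds,
        "mean_per_scaffold": st.mean_per_scaffold,
        "sd_per_scaffold": st.sd_per_scaffold,
        "n_singletons": st.n_singletons,
        "singleton_fraction": st.singleton_fraction,
    }


def analyze(
    curated: list[CuratedSet],
    assays: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run every analysis stage on already-curated sets (in memory)."""
    config = config or RunConfig()
    universe = merge_sets(curated)
    mols = {
        inchi: Chem.MolFromSmiles(rec.canonical_smiles)
        for inchi, rec in universe.items()
    }

    counters: dict[str, dict[str, int]] = {
        cs.name: {
            "rows_in": cs.n_initial,
            "curated": cs.n_curated,
            "rejected": len(cs.rejections),
        }
        for cs in curated
    }

    # representations
    descriptors = descriptor_frame(mols)
    fingerprints = {i: circular_fingerprint(m) for i, m in mols.items()}
    scaffolds = {i: murcko_scaffold(m).scaffold_smiles for i, m in mols.items()}

    by_category: dict[str, set[str]] = {}
    for cs in curated:
        by_category.setdefault(cs.category, set()).update(cs.members)
    query = by_category.get("pesticide", set())

    # endpoint sets from assay results (restricted to the merged universe)
    endpoint_sets = {}
    dropped_unknown = 0
    if assays is not None and len(assays):
        known = assays["inchi"].isin(universe.keys())
        dropped_unknown = int((~known).sum())
        if dropped_unknown:
            logger.warning(
                "dropping %d assay rows for substances outside the universe",
                dropped_unknown,
            )
        results, _ = load_assay_results(assays[known])
        endpoint_sets = build_endpoint_sets(results)
    counters["assays"] = {"rows_in": 0 if assays is None else len(assays),
                          "outside_universe": dropped_unknown}

    # per-set accounting tables (query domain → table_1, reference → table_2)
    tables: dict[str, pd.DataFrame] = {}
    for table_name, category in (("table_1", "pesticide"), ("table_2", "genotoxicity")):
        sets_in_cat = [cs for cs in curated if cs.category == category]
        if not sets_in_cat:
            tables[table_name] = pd.DataFrame()
            continue
        excl = exclusivity([cs.as_substance_set() for cs in sets_in_cat])
        rows = []
        for cs in sets_in_cat:
            row = {
                "dataset": cs.name,
                "n_initial": cs.n_initial,
                "n_curated": cs.n_curated,
                "n_exclusive": excl[cs.name],
                **_scaffold_row(cs.members, scaffolds),
                "mean_pairwise_tanimoto": mean_pairwise_tanimoto(
                    cs.members, fingerprints
                ),
            }
            if category == "genotoxicity" and query:
                cov = coverage_report(
                    cs.name, cs.members, "pesticide", query, fingerprints,
                    config.tanimoto_threshold,
                )
                row["overlap_with_query"] = cov.exact_overlap
                row["overlap_with_query_pct"] = 100 * cov.exact_fraction
            rows.append(row)
        merged = set().union(*(cs.members for cs in sets_in_cat))
        total = {
            "dataset": "total",
            "n_initial": sum(cs.n_initial for cs in sets_in_cat),
            "n_curated": len(merged),
            "n_exclusive": np.nan,
            **_scaffold_row(merged, scaffolds),
            "mean_pairwise_tanimoto": mean_pairwise_tanimoto(merged, fingerprints),
        }
        if category == "genotoxicity" and query:
            cov = coverage_report(
                "total", merged, "pesticide", query, fingerprints,
                config.tanimoto_threshold,
            )
            total["overlap_with_query"] = cov.exact_overlap
            total["overlap_with_query_pct"] = 100 * cov.exact_fraction
        rows.append(total)
        tables[table_name] = pd.DataFrame(rows)

    # endpoint summary (table_3) and descriptor summary (table_4)
    endpoint_rows, desc_rows = [], []
    named_sets: list[tuple[str, set[str]]] = [
        (t, endpoint_sets[t].members) for t in (*TEST_TYPES, ALL_GENOTOX)
        if t in endpoint_sets and endpoint_sets[t].members
    ]
    exclusive_counts = (
        exclusivity(
            [cs.as_substance_set() for cs in curated if cs.category == "genotoxicity"]
        )
        if any(cs.category == "genotoxicity" for cs in curated)
        else {}
    )
    for name, members in (*named_sets, ("pesticides", query)):
        if not members:
            continue
        row = {
            "dataset": name,
            "n_substances": len(members),
            **_scaffold_row(members, scaffolds),
            "mean_pairwise_tanimoto": mean_pairwise_tanimoto(members, fingerprints),
        }
        if query:
            cov = coverage_report(
                name, members, "pesticides", query, fingerprints,
                config.tanimoto_threshold,
            )
            row["overlap_with_query"] = cov.exact_overlap
            row["overlap_with_query_pct"] = 100 * cov.exact_fraction
            row["similarity_overlap_with_query"] = cov.similarity_overlap
            row["similarity_overlap_with_query_pct"] = 100 * cov.similarity_fraction
            # reverse orientation: how much of the query domain this set covers
            rev = coverage_report(
                "pesticides", query, name, members, fingerprints,
                config.tanimoto_threshold,
            )
            row["query_covered_exact"] = rev.exact_overlap
            row["query_covered_similarity"] = rev.similarity_overlap
        if name in endpoint_sets:
            row["n_positive"] = endpoint_sets[name].n_positive
            row["n_negative"] = endpoint_sets[name].n_negative
        endpoint_rows.append(row)
        sub = descriptors.loc[descriptors.index.intersection(members)]
        desc_rows.append(
            {
                "dataset": name,
                **{f"{c}_mean": sub[c].mean() for c in descriptors.columns},
                **{f"{c}_sd": sub[c].std(ddof=0) for c in descriptors.columns},
            }
        )
    if universe:
        all_members = set(universe)
        endpoint_rows.append(
            {
                "dataset": "total",
                "n_substances": len(all_members),
                **_scaffold_row(all_members, scaffolds),
                "mean_pairwise_tanimoto": mean_pairwise_tanimoto(
                    all_members, fingerprints
                ),
            }
        )
    tables["table_3"] = pd.DataFrame(endpoint_rows)
    tables["table_4"] = pd.DataFrame(desc_rows)

    # scaffold gaps: query scaffolds no endpoint set covers
    references = {name: members for name, members in named_sets}
    gaps = (
        missing_scaffolds(query, scaffolds, references) if query and references else []
    )
    gaps_df = pd.DataFrame(
        [
            {
                "scaffold_smiles": g.scaffold_smiles,
                "count_in_query": g.count_in_query,
                "pct_of_query": g.pct_of_query,
            }
            for g in gaps
        ],
        columns=["scaffold_smiles", "count_in_query", "pct_of_query"],
    )

    # functional-group enrichment of query vs each endpoint set
    fg_frames, top_frames = [], []
    n_retained = 0
    if query and references:
        catalogue = load_catalogue(config.catalogue_path)
        presence_all = match_functional_groups(mols, catalogue)
        analysed = [presence_all.loc[sorted(query)]] + [
            presence_all.loc[sorted(m)] for _, m in named_sets
        ]
        retained = filter_patterns(catalogue, analysed)
        n_retained = len(retained)
        keep = [p.name for p in retained]
        qp = presence_all.loc[sorted(query), keep]
        for name, members in named_sets:
            rows = proportion_difference(qp, presence_all.loc[sorted(members), keep])
            fg_frames.append(enrichment_frame(rows, name))
            pos, neg = top_k_enrichment(rows, config.top_k)
            for direction, ranked in (("over_in_query", pos), ("under_in_query", neg)):
                top_frames.append(
                    pd.DataFrame(
                        {
                            "reference_set": name,
                            "direction": direction,
                            "rank": range(1, len(ranked) + 1),
                            "group": [r.group for r in ranked],
                            "difference": [r.difference for r in ranked],
                        }
                    )
                )
    fg_df = pd.concat(fg_frames, ignore_index=True) if fg_frames else pd.DataFrame()
    top_df = pd.concat(top_frames, ignore_index=True) if top_frames else pd.DataFrame()

    # projections
    pca = pca_project(descriptors, config.pca_scaling) if len(descriptors) else None
    umap_params = umap_coords = umap_scores = None
    if config.run_umap and len(mols) >= 10:
        keys = sorted(mols)
        rng = np.random.default_rng(config.seed)
        if len(keys) > config.umap_max_points:
            idx = rng.choice(len(keys), config.umap_max_points, replace=False)
            keys = [keys[i] for i in sorted(idx)]
        fp_matrix = np.stack([fingerprints[k] for k in keys])
        reference = None
        if config.umap_scorer == "cluster":
            reference = butina_cluster(fp_matrix, cutoff=config.butina_cutoff)
        umap_params, proj, umap_scores = umap_grid_search(
            fp_matrix,
            grid=config.umap_grid,
            seed=config.seed,
            scorer=config.umap_scorer,
            reference=reference,
        )
        umap_coords = proj.coords.copy()
        umap_coords.index = keys
        _flag_membership(umap_coords, query, endpoint_sets)

    return PipelineResult(
        universe=universe,
        curated=curated,
        endpoint_sets=endpoint_sets,
        tables=tables,
        scaffold_gaps=gaps_df,
        fg_enrichment=fg_df,
        fg_top_k=top_df,
        pca=pca,
        umap_params=umap_params,
        umap_coords=umap_coords,
        umap_scores=umap_scores,
        counters=counters,
        n_retained_patterns=n_retained,
    )


def _flag_membership(coords: pd.DataFrame, query: set[str], endpoint_sets: dict) -> None:
    coords["is_query"] = [i in query for i in coords.index]
    for t, es in endpoint_sets.items():
        coords[f"in_{t}"] = [i in es.members for i in coords.index]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load inputs per config, run every stage, write the report bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    curated = []
    for spec in config.datasets:
        entries = load_dataset(spec.path, spec.name, spec.category, config.smiles_column)
        curated.append(curate_dataset(entries, spec.name, spec.category))
    assays = None
    if config.assay_path:
        assays = pd.read_csv(config.assay_path, dtype=str)
        if "inchi" not in assays.columns:
            raise ValueError("assay table needs an 'inchi' column")
    result = analyze(curated, assays, config)
    write_report(result, config)
    return result


def write_report(result: PipelineResult, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    universe_frame(result.universe).to_csv(outdir / "universe.csv", index=False)
    for name, df in result.tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    result.scaffold_gaps.to_csv(outdir / "scaffold_gaps.csv", index=False)
    result.fg_enrichment.to_csv(outdir / "fg_enrichment.csv", index=False)
    result.fg_top_k.to_csv(outdir / "fg_top_k.csv", index=False)
    if result.pca is not None:
        result.pca.coords.rename_axis("inchi").to_csv(outdir / "coords_pca.csv")
        result.pca.loadings.rename_axis("descriptor").to_csv(
            outdir / "pca_loadings.csv"
        )
        pd.DataFrame(
            {
                "component": range(1, len(result.pca.explained_variance) + 1),
                "explained_variance_fraction": result.pca.explained_variance,
            }
        ).to_csv(outdir / "pca_explained_variance.csv", index=False)
    if result.umap_coords is not None:
        result.umap_coords.rename_axis("inchi").to_csv(outdir / "coords_umap.csv")
        result.umap_scores.to_csv(outdir / "umap_grid_scores.csv", index=False)
    manifest = {
        "chemcov_version": __version__,
        "seed": config.seed,
        "tanimoto_threshold": config.tanimoto_threshold,
        "butina_cutoff": config.butina_cutoff,
        "top_k": config.top_k,
        "fingerprint": {"radius": FINGERPRINT_RADIUS, "n_bits": FINGERPRINT_BITS},
        "pca_scaling": config.pca_scaling,
        "umap_grid": {k: list(v) for k, v in config.umap_grid.items()},
        "umap_params": None
        if result.umap_params is None
        else asdict(result.umap_params),
        "n_retained_fg_patterns": result.n_retained_patterns,
        "counters": result.counters,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
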