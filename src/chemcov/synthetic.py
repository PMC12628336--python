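"""Synthetic multi-source chemical collections with known ground truth.

The generator emulates the statistical structure the coverage analysis
assumes, without any real dataset: several named *query* collections (the
pesticide-like domain) and *reference* collections (the genotoxicity-like
domain) whose members are built by decorating ring scaffolds with functional
groups drawn at planted frequencies.  Controlled features:

* inter-set duplication (``overlap_fraction``) — sets reuse previously
  generated substances, producing known exact overlaps and exclusivities;
* scaffold structure — a shared base pool plus composite (linked) scaffolds
  driven by ``singleton_rate``, and planted query-only scaffolds that every
  reference set is guaranteed to miss;
* functional-group frequency profiles per domain;
* curation artifacts (salt adducts, wildcard entries, duplicated rows)
  injected with a manifest, so standardizer behaviour is checkable row by
  row;
* per-test assay coverage and positive rates for the hit-call stage.

Every statistic the downstream pipeline recomputes is recorded exactly in a
:class:`GroundTruth` object derived from the generator's own bookkeeping (not
from the pipeline modules), so end-to-end tests can assert equality for
deterministic quantities and binomial tolerance for sampled frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

from .hitcall import TEST_TYPES
from .standardizer import default_rules

RDLogger.DisableLog("rdApp.*")

#: Base ring systems: pesticide- and genotoxicant-typical frameworks, free of
#: the planted functional groups (no halogens, nitro, OH, NH2, C=O).
DEFAULT_SCAFFOLD_POOL: tuple[str, ...] = (
    "c1ccccc1",
    "c1ccncc1",
    "c1ccoc1",
    "c1ccsc1",
    "c1cnccn1",
    "c1ccnnc1",
    "c1ncncn1",
    "c1cscn1",
    "c1cocn1",
    "c1cc[nH]c1",
    "c1cn[nH]c1",
    "c1cnc[nH]1",
    "c1ccc2ccccc2c1",
    "c1ccc2ncccc2c1",
    "c1ccc2cnccc2c1",
    "c1ccc2[nH]ccc2c1",
    "c1ccc2occc2c1",
    "c1ccc2sccc2c1",
    "c1ccc2[nH]cnc2c1",
    "c1ccc2ocnc2c1",
    "c1ccc2scnc2c1",
    "C1CCCCC1",
    "C1CCCC1",
    "C1CCNCC1",
    "C1CCOC1",
    "C1CNCCN1",
    "C1COCCN1",
    "C1CCNC1",
    "C1CCOCC1",
    "C1CCSC1",
)

#: Planted query-only scaffolds (fused tricyclics; composites are always
#: *linked* ring systems, so these can never arise by composition).
DEFAULT_UNCOVERED_SCAFFOLDS: tuple[str, ...] = (
    "c1ccc2c(c1)oc1ccccc12",
    "c1ccc2c(c1)[nH]c1ccccc12",
    "c1ccc2c(c1)sc1ccccc12",
)

#: Functional-group fragments: name → SMILES attached via atom 0.
GROUP_FRAGMENTS: dict[str, tuple[str, ...]] = {
    "halogen": ("Cl", "F", "Br"),
    "nitro": ("[N+](=O)[O-]",),
    "carboxylic_acid": ("C(=O)O",),
    "ester": ("C(=O)OC",),
    "hydroxyl": ("O",),
    "primary_amine": ("N",),
}

#: SMARTS that measure exactly the planted groups (used by fg tests and the
#: report stage of synthetic runs); chosen to be mutually non-cross-matching
#: on generator output.
MEASUREMENT_SMARTS: dict[str, str] = {
    "halogen": "[F,Cl,Br,I]",
    "nitro": "[NX3+](=O)[O-]",
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "ester": "[CX3](=O)[OX2][CX4]",
    "hydroxyl": "[OX2H][CX4,c]",
    "primary_amine": "[NX3;H2][CX4,c]",
}

#: Salt adducts appended by inject_artifacts; all strip back to the parent.
SALT_ADDUCTS: tuple[str, ...] = ("Cl", "Br", "O=S(=O)(O)O", "OC(=O)C(=O)O", "[Na+].[Cl-]")

DEFAULT_FG_FREQUENCIES: dict[str, tuple[float, float]] = {
    # (query domain, reference domain): query halogen/acid-rich, reference
    # amine/nitro-rich — the planted enrichment contrast.
    "halogen": (0.45, 0.15),
    "nitro": (0.05, 0.25),
    "carboxylic_acid": (0.25, 0.10),
    "ester": (0.20, 0.10),
    "hydroxyl": (0.15, 0.15),
    "primary_amine": (0.05, 0.30),
}

DEFAULT_PER_TEST_COVERAGE: dict[str, float] = {
    # scaled from the relative endpoint sizes of public genotoxicity data:
    # Ames near-universal, in vivo CA rare.
    "ames": 0.95,
    "invitro_mcgm": 0.17,
    "invitro_mn": 0.07,
    "invitro_ca": 0.19,
    "invivo_mn": 0.07,
    "invivo_ca": 0.016,
}


@dataclass
class GeneratorConfig:
    n_query_sets: int = 4
    n_reference_sets: int = 5
    query_set_sizes: tuple[int, ...] = (250, 200, 150, 100)
    reference_set_sizes: tuple[int, ...] = (500, 300, 250, 200, 150)
    overlap_fraction: float = 0.2
    scaffold_pool: tuple[str, ...] = DEFAULT_SCAFFOLD_POOL
    singleton_rate: float = 0.25
    uncovered_scaffold_smiles: tuple[str, ...] = DEFAULT_UNCOVERED_SCAFFOLDS
    uncovered_scaffold_counts: tuple[int, ...] = (7, 3, 1)
    fg_frequencies: dict[str, float | tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FG_FREQUENCIES)
    )
    salt_rate: float = 0.05
    wildcard_rate: float = 0.02
    duplicate_row_rate: float = 0.03
    per_test_coverage: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PER_TEST_COVERAGE)
    )
    positive_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.query_set_sizes) != self.n_query_sets:
            raise ValueError("query_set_sizes length must equal n_query_sets")
        if len(self.reference_set_sizes) != self.n_reference_sets:
            raise ValueError("reference_set_sizes length must equal n_reference_sets")
        if not self.scaffold_pool:
            raise ValueError("scaffold_pool must be non-empty")
        for p in (
            self.overlap_fraction,
            self.singleton_rate,
            self.salt_rate,
            self.wildcard_rate,
            self.duplicate_row_rate,
            self.positive_rate,
            *self.per_test_coverage.values(),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of range: {p}")
        if len(self.uncovered_scaffold_counts) > len(self.uncovered_scaffold_smiles):
            raise ValueError("more uncovered counts than uncovered scaffolds")

    def domain_frequency(self, group: str, domain: str) -> float:
        value = self.fg_frequencies[group]
        if isinstance(value, (tuple, list)):
            return value[0] if domain == "query" else value[1]
        return float(value)


@dataclass
class MoleculeRecord:
    inchi: str
    smiles: str
    scaffold: str  # canonical Murcko SMILES
    groups: frozenset[str]
    domain_of_origin: str
    planted_uncovered: bool = False


@dataclass
class GroundTruth:
    """Exact expected statistics from generator bookkeeping."""

    n_universe: int
    n_query_universe: int
    n_reference_universe: int
    #: query ∩ reference-set membership (the merged-table orientation)
    exact_overlap_query_reference: int
    #: query ∩ substances with ≥1 assay result (the pooled-endpoint orientation)
    exact_overlap_query_covered: int
    per_set: dict[str, dict[str, int]]  # name → {n_initial, n_curated, n_exclusive}
    set_categories: dict[str, str]
    uncovered_scaffolds: list[tuple[str, int]]  # ranked (count desc, smiles)
    planted_uncovered: list[tuple[str, int]]
    fg_planted: dict[str, dict[str, float]]  # domain → group → exact fraction
    fg_configured: dict[str, dict[str, float]]
    endpoint_sizes: dict[str, int]
    endpoint_positive: dict[str, int]
    query_scaffold_count: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=list))


@dataclass
class SyntheticCorpus:
    config: GeneratorConfig
    datasets: dict[str, pd.DataFrame]  # name → [smiles, dataset]
    categories: dict[str, str]  # name → query/reference category label
    assays: pd.DataFrame  # [inchi, test_type, call, dataset]
    ground_truth: GroundTruth
    molecules: dict[str, MoleculeRecord]
    membership: dict[str, list[str]]  # set name → member InChIs (clean)
    manifest: pd.DataFrame  # artifact injection log

    def write_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "datasets").mkdir(parents=True, exist_ok=True)
        for name, df in self.datasets.items():
            df.to_csv(outdir / "datasets" / f"{name}.csv", index=False)
        self.assays.to_csv(outdir / "assays.csv", index=False)
        self.manifest.to_csv(outdir / "artifact_manifest.csv", index=False)
        self.ground_truth.to_json(outdir / "ground_truth.json")
        pd.DataFrame(
            {"name": list(self.categories), "category": list(self.categories.values())}
        ).to_csv(outdir / "dataset_manifest.csv", index=False)


class _MoleculeFactory:
    """Assembles unique decorated molecules from scaffolds + group fragments."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.base_scaffolds = [Chem.MolFromSmiles(s) for s in config.scaffold_pool]
        if any(m is None for m in self.base_scaffolds):
            raise ValueError("invalid SMILES in scaffold_pool")
        self.uncovered = {
            s: Chem.MolFromSmiles(s) for s in config.uncovered_scaffold_smiles
        }
        self.seen_inchi: set[str] = set()
        # a generated substance must survive its own curation: bare structures
        # that coincide with the standardizer's salt/solvent lists (e.g. plain
        # tetrahydrofuran, toluene) would be stripped from salted rows
        rules = default_rules()
        self.forbidden: frozenset[str] = rules.salt_smiles | rules.solvent_smiles

    @staticmethod
    def scaffold_key(mol: Chem.Mol) -> str:
        return Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol))

    def _attach(self, mol: Chem.Mol, frag_smiles: str) -> Chem.Mol | None:
        frag = Chem.MolFromSmiles(frag_smiles)
        candidates = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
        ]
        if not candidates:
            return None
        pos = int(self.rng.choice(candidates))
        combined = Chem.RWMol(Chem.CombineMols(mol, frag))
        combined.AddBond(pos, mol.GetNumAtoms(), Chem.BondType.SINGLE)
        out = combined.GetMol()
        try:
            Chem.SanitizeMol(out)
        except Exception:
            return None
        return out

    def _pick_scaffold(self, allow_composite: bool) -> Chem.Mol:
        if allow_composite and self.rng.random() < self.config.singleton_rate:
            # composite = two base scaffolds joined by a short alkyl linker —
            # a fresh, likely-unique ring system (drives singleton counts)
            a = self.base_scaffolds[self.rng.integers(len(self.base_scaffolds))]
            b = self.base_scaffolds[self.rng.integers(len(self.base_scaffolds))]
            linker = "C" * int(self.rng.integers(0, 3))
            joined = self._attach(a, linker + Chem.MolToSmiles(b)) if linker else None
            if joined is None:
                joined = self._attach(a, Chem.MolToSmiles(b))
            if joined is not None:
                return joined
        return self.base_scaffolds[self.rng.integers(len(self.base_scaffolds))]

    def build(
        self,
        domain: str,
        scaffold: Chem.Mol | None = None,
        planted_uncovered: bool = False,
        max_attempts: int = 200,
    ) -> MoleculeRecord:
        cfg = self.config
        # groups are drawn once per molecule, *outside* the retry loop:
        # uniqueness retries must not re-sample them, or acceptance would
        # bias the planted frequencies
        groups = frozenset(
            g
            for g in cfg.fg_frequencies
            if self.rng.random() < cfg.domain_frequency(g, domain)
        )
        for _ in range(max_attempts):
            base = scaffold if scaffold is not None else self._pick_scaffold(True)
            mol: Chem.Mol | None = Chem.Mol(base)
            for g in sorted(groups):
                frags = GROUP_FRAGMENTS[g]
                mol = self._attach(mol, frags[self.rng.integers(len(frags))])
                if mol is None:
                    break
            if mol is None:
                continue
            chain = int(self.rng.integers(0, 7))
            if chain:
                mol = self._attach(mol, "C" * chain)
                if mol is None:
                    continue
            if self.rng.random() < 0.5:  # extra variability against collisions
                mol2 = self._attach(mol, "C" * int(self.rng.integers(1, 4)))
                if mol2 is not None:
                    mol = mol2
            smiles = Chem.MolToSmiles(mol)
            if smiles in self.forbidden:
                continue
            inchi = Chem.MolToInchi(mol)
            if not inchi or inchi in self.seen_inchi:
                continue
            self.seen_inchi.add(inchi)
            return MoleculeRecord(
                inchi=inchi,
                smiles=smiles,
                scaffold=self.scaffold_key(mol),
                groups=groups,
                domain_of_origin=domain,
                planted_uncovered=planted_uncovered,
            )
        raise RuntimeError("could not assemble a unique molecule (exhausted retries)")


def generate_library(config: GeneratorConfig | None = None) -> SyntheticCorpus:
    """Generate the full corpus: set files, assay table, artifacts, ground truth.

    All randomness flows from ``config.seed``; identical configs give
    byte-identical outputs.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    factory = _MoleculeFactory(config, rng)

    query_names = [f"Q{i + 1}" for i in range(config.n_query_sets)]
    reference_names = [f"R{i + 1}" for i in range(config.n_reference_sets)]
    categories = {**{n: "query" for n in query_names},
                  **{n: "reference" for n in reference_names}}

    molecules: dict[str, MoleculeRecord] = {}
    membership: dict[str, list[str]] = {n: [] for n in [*query_names, *reference_names]}

    # 1. plant query-only scaffold molecules, round-robin over query sets
    planted: list[tuple[str, int]] = []
    for scaf_smiles, count in zip(
        config.uncovered_scaffold_smiles, config.uncovered_scaffold_counts
    ):
        scaf = factory.uncovered[scaf_smiles]
        key = factory.scaffold_key(scaf)
        made = 0
        for j in range(count):
            rec = factory.build("query", scaffold=scaf, planted_uncovered=True)
            assert rec.scaffold == key
            molecules[rec.inchi] = rec
            membership[query_names[j % len(query_names)]].append(rec.inchi)
            made += 1
        planted.append((key, made))

    # 2. fill each set; reuse previously generated substances with
    #    probability overlap_fraction (reference sets never reuse planted
    #    query-only molecules)
    def fill(name: str, size: int, domain: str) -> None:
        members = set(membership[name])
        pool = [
            i
            for i, m in molecules.items()
            if not (domain == "reference" and m.planted_uncovered)
        ]
        while len(members) < size:
            reused = None
            if rng.random() < config.overlap_fraction:
                available = [i for i in pool if i not in members]
                if available:
                    reused = available[int(rng.integers(len(available)))]
            if reused is not None:
                members.add(reused)
                membership[name].append(reused)
            else:
                rec = factory.build(domain)
                molecules[rec.inchi] = rec
                members.add(rec.inchi)
                membership[name].append(rec.inchi)
                if not (domain == "reference" and rec.planted_uncovered):
                    pool.append(rec.inchi)

    for name, size in zip(query_names, config.query_set_sizes):
        fill(name, size, "query")
    for name, size in zip(reference_names, config.reference_set_sizes):
        fill(name, size, "reference")

    # 3. assay results over the reference universe
    reference_universe = sorted(
        {i for n in reference_names for i in membership[n]}
    )
    query_universe = sorted({i for n in query_names for i in membership[n]})
    sets_of = {
        i: [n for n in reference_names if i in set(membership[n])]
        for i in reference_universe
    }
    assay_rows = []
    endpoint_members: dict[str, set[str]] = {t: set() for t in TEST_TYPES}
    endpoint_positive: dict[str, set[str]] = {t: set() for t in TEST_TYPES}
    for inchi in reference_universe:
        for test in TEST_TYPES:
            if rng.random() >= config.per_test_coverage[test]:
                continue
            n_results = 1 + int(rng.poisson(0.7))
            endpoint_members[test].add(inchi)
            for _ in range(n_results):
                call = "positive" if rng.random() < config.positive_rate else "negative"
                if call == "positive":
                    endpoint_positive[test].add(inchi)
                assay_rows.append(
                    {
                        "inchi": inchi,
                        "test_type": test,
                        "call": call,
                        "dataset": sets_of[inchi][int(rng.integers(len(sets_of[inchi])))],
                    }
                )
    assays = pd.DataFrame(assay_rows, columns=["inchi", "test_type", "call", "dataset"])

    # 4. clean per-set files
    datasets = {
        name: pd.DataFrame(
            {"smiles": [molecules[i].smiles for i in membership[name]], "dataset": name}
        )
        for name in membership
    }

    # 5. artifacts
    datasets, manifest = inject_artifacts(datasets, config, rng)

    # 6. ground truth bookkeeping
    per_set: dict[str, dict[str, int]] = {}
    for category, names in (("query", query_names), ("reference", reference_names)):
        counts: dict[str, int] = {}
        for n in names:
            for i in membership[n]:
                counts[i] = counts.get(i, 0) + 1
        for n in names:
            per_set[n] = {
                "n_initial": int(datasets[n]["smiles"].str.strip().nunique()),
                "n_curated": len(set(membership[n])),
                "n_exclusive": sum(1 for i in set(membership[n]) if counts[i] == 1),
            }

    # gap analysis is against substances that actually carry assay data
    # (the endpoint-level sets), not mere reference-set membership
    covered_members = set().union(*endpoint_members.values()) if assay_rows else set()
    covered_scaffolds = {molecules[i].scaffold for i in covered_members}
    uncovered_counts: dict[str, int] = {}
    for i in query_universe:
        scaf = molecules[i].scaffold
        if scaf and scaf not in covered_scaffolds:
            uncovered_counts[scaf] = uncovered_counts.get(scaf, 0) + 1
    uncovered = sorted(uncovered_counts.items(), key=lambda kv: (-kv[1], kv[0]))

    fg_planted = {}
    for domain, universe in (("query", query_universe), ("reference", reference_universe)):
        fg_planted[domain] = {
            g: sum(1 for i in universe if g in molecules[i].groups) / len(universe)
            for g in config.fg_frequencies
        }
    fg_configured = {
        domain: {g: config.domain_frequency(g, domain) for g in config.fg_frequencies}
        for domain in ("query", "reference")
    }

    all_members = set().union(*endpoint_members.values()) if assay_rows else set()
    all_positive = set().union(*endpoint_positive.values()) if assay_rows else set()
    endpoint_sizes = {t: len(m) for t, m in endpoint_members.items()}
    endpoint_sizes["all"] = len(all_members)
    endpoint_pos = {t: len(m) for t, m in endpoint_positive.items()}
    endpoint_pos["all"] = len(all_positive)

    ground_truth = GroundTruth(
        n_universe=len(molecules),
        n_query_universe=len(query_universe),
        n_reference_universe=len(reference_universe),
        exact_overlap_query_reference=len(set(query_universe) & set(reference_universe)),
        exact_overlap_query_covered=len(set(query_universe) & covered_members),
        per_set=per_set,
        set_categories=categories,
        uncovered_scaffolds=uncovered,
        planted_uncovered=planted,
        fg_planted=fg_planted,
        fg_configured=fg_configured,
        endpoint_sizes=endpoint_sizes,
        endpoint_positive=endpoint_pos,
        query_scaffold_count=len({molecules[i].scaffold for i in query_universe}),
    )
    return SyntheticCorpus(
        config=config,
        datasets=datasets,
        categories=categories,
        assays=assays,
        ground_truth=ground_truth,
        molecules=molecules,
        membership=membership,
        manifest=manifest,
    )


def inject_artifacts(
    datasets: dict[str, pd.DataFrame],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Corrupt clean set files with curation artifacts; emit a manifest.

    Per row, independently: with ``salt_rate`` the SMILES gains a counterion
    adduct (parent recoverable by desalting); rows are duplicated verbatim
    with ``duplicate_row_rate``.  Additionally ``wildcard_rate`` × n extra
    wildcard (*) rows are appended per set — entries no structure can be
    assigned to, which the standardizer must reject.  With all rates zero the
    frames pass through unchanged.
    """
    out: dict[str, pd.DataFrame] = {}
    manifest_rows = []
    for name, df in datasets.items():
        rows = []
        for _, row in df.iterrows():
            smiles = row["smiles"]
            if rng.random() < config.salt_rate:
                adduct = SALT_ADDUCTS[int(rng.integers(len(SALT_ADDUCTS)))]
                salted = f"{smiles}.{adduct}"
                manifest_rows.append(
                    {"dataset": name, "kind": "salt", "original": smiles, "emitted": salted}
                )
                smiles = salted
            rows.append({"smiles": smiles, "dataset": name})
            if rng.random() < config.duplicate_row_rate:
                rows.append({"smiles": smiles, "dataset": name})
                manifest_rows.append(
                    {"dataset": name, "kind": "duplicate", "original": smiles, "emitted": smiles}
                )
        n_wild = int(rng.binomial(len(df), config.wildcard_rate)) if len(df) else 0
        for j in range(n_wild):
            wild = "*" + "C" * (j + 1) + "O"
            rows.append({"smiles": wild, "dataset": name})
            manifest_rows.append(
                {"dataset": name, "kind": "wildcard", "original": "", "emitted": wild}
            )
        out[name] = pd.DataFrame(rows, columns=["smiles", "dataset"])
    manifest = pd.DataFrame(
        manifest_rows, columns=["dataset", "kind", "original", "emitted"]
    )
    return out, manifest


def ground_truth_report(config: GeneratorConfig | None = None) -> GroundTruth:
    """Deterministic expected statistics for a config (same seed ⇒ identical)."""
    return generate_library(config).ground_truth
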