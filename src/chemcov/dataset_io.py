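"""Loading, merging and per-set accounting of named chemical collections.

A *collection* is a CSV/TSV table with at least a SMILES column and a dataset
name.  After standardization, collections are merged into a single substance
universe keyed by standard InChI; each substance keeps full provenance (every
contributing dataset and row).  Per-set accounting mirrors the summary tables
of multi-source curation studies: unique raw SMILES (n_initial), unique InChI
after curation (n_curated), and exclusivity (substances occurring in no other
set of the comparison universe — by default, sets of the same category).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .standardizer import (
    RawEntry,
    RejectionRecord,
    StandardizationRules,
    StandardizedStructure,
    standardize_entries,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("pesticide", "genotoxicity", "reference", "endpoint")


@dataclass(frozen=True)
class SubstanceRecord:
    inchi: str
    canonical_smiles: str
    sources: frozenset[str]
    category_flags: frozenset[str]


@dataclass
class SubstanceSet:
    name: str
    category: str
    members: set[str] = field(default_factory=set)


@dataclass
class CuratedSet:
    """One collection after standardization, with accounting."""

    name: str
    category: str
    n_initial: int
    members: set[str]
    rejections: list[RejectionRecord]
    structures: dict[str, StandardizedStructure]
    #: provenance: inchi → row ids contributing from this set
    rows: dict[str, list[str]]

    @property
    def n_curated(self) -> int:
        return len(self.members)

    def as_substance_set(self) -> SubstanceSet:
        return SubstanceSet(self.name, self.category, set(self.members))


def load_dataset(
    path: str | Path,
    name: str,
    category: str,
    smiles_column: str = "smiles",
) -> list[RawEntry]:
    """Read one collection file into RawEntry rows.

    Duplicate SMILES strings (exact text after whitespace trim) are collapsed
    so n_initial counts unique raw SMILES.  Wildcard entries pass through —
    rejecting them is the standardizer's job.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if smiles_column not in df.columns:
        raise ValueError(f"{path}: missing required column {smiles_column!r}")
    if df.empty:
        logger.warning("%s: empty dataset file", path)
        return []
    return entries_from_frame(df, name, smiles_column)


def entries_from_frame(
    df: pd.DataFrame, name: str, smiles_column: str = "smiles"
) -> list[RawEntry]:
    seen: set[str] = set()
    entries: list[RawEntry] = []
    for idx, raw in df[smiles_column].items():
        if not isinstance(raw, str):
            continue
        smiles = raw.strip()
        if not smiles or smiles in seen:
            continue
        seen.add(smiles)
        entries.append(RawEntry(source_dataset=name, smiles_text=smiles, row_id=str(idx)))
    return entries


def curate_dataset(
    entries: list[RawEntry],
    name: str,
    category: str,
    rules: StandardizationRules | None = None,
) -> CuratedSet:
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    ok, rejected = standardize_entries(entries, rules)
    structures: dict[str, StandardizedStructure] = {}
    rows: dict[str, list[str]] = {}
    for entry, std in ok:
        structures.setdefault(std.inchi, std)
        rows.setdefault(std.inchi, []).append(entry.row_id)
    return CuratedSet(
        name=name,
        category=category,
        n_initial=len(entries),
        members=set(structures),
        rejections=rejected,
        structures=structures,
        rows=rows,
    )


def merge_sets(curated: list[CuratedSet]) -> dict[str, SubstanceRecord]:
    """Merge curated sets into the deduplicated substance universe.

    One record per unique InChI; sources and category flags are unions over
    every contributing set, so the result is independent of input order.
    """
    sources: dict[str, set[str]] = {}
    categories: dict[str, set[str]] = {}
    smiles: dict[str, str] = {}
    for cs in curated:
        for inchi in cs.members:
            sources.setdefault(inchi, set()).add(cs.name)
            categories.setdefault(inchi, set()).add(cs.category)
            smiles.setdefault(inchi, cs.structures[inchi].canonical_smiles)
    return {
        inchi: SubstanceRecord(
            inchi=inchi,
            canonical_smiles=smiles[inchi],
            sources=frozenset(sources[inchi]),
            category_flags=frozenset(categories[inchi]),
        )
        for inchi in sources
    }


def exclusivity(sets: list[SubstanceSet]) -> dict[str, int]:
    """Per-set count of members appearing in no other set of the comparison.

    The caller chooses the comparison universe by choosing which sets to pass
    (default convention: all sets of one category).
    """
    membership: dict[str, int] = {}
    for s in sets:
        for inchi in s.members:
            membership[inchi] = membership.get(inchi, 0) + 1
    return {
        s.name: sum(1 for inchi in s.members if membership[inchi] == 1) for s in sets
    }


def universe_frame(universe: dict[str, SubstanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "inchi": list(universe),
            "canonical_smiles": [r.canonical_smiles for r in universe.values()],
            "sources": ["|".join(sorted(r.sources)) for r in universe.values()],
            "categories": [
                "|".join(sorted(r.category_flags)) for r in universe.values()
            ],
        }
    ).sort_values("inchi", ignore_index=True)
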