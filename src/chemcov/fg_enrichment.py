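"""SMARTS functional-group matching and proportion-difference enrichment.

A functional-group catalogue (named SMARTS patterns; the shipped default is
the Open Babel functional-group classification list) is matched against each
substance set.  Presence is binary per substance — a molecule with two nitro
groups counts once.  Patterns that match nothing in any analysed set are
filtered out before reporting.  For a query set Q and reference set R, each
group g gets

    difference(g) = p_Q(g) − p_R(g),

the difference of the fractions of substances containing g; negative values
mean the group is overrepresented in the reference set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from rdkit import Chem

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmartsPattern:
    name: str
    smarts: str

    def compile(self) -> Chem.Mol:
        query = Chem.MolFromSmarts(self.smarts)
        if query is None:
            raise ValueError(f"SMARTS pattern {self.name!r} does not compile")
        return query


def load_catalogue(path: str | Path | None = None) -> list[SmartsPattern]:
    """Parse a ``name: SMARTS`` catalogue file ('#' comments allowed).

    With no path, the packaged Open Babel functional-group list is used.
    Every pattern is compiled eagerly so a broken catalogue fails loudly,
    naming the offending pattern.
    """
    if path is None:
        text = (
            resources.files("chemcov.data")
            .joinpath("functional_groups_smarts.txt")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    patterns: list[SmartsPattern] = []
    for line in text.splitlines():
        line = line.strip()
        # full-line comments only: '#' inside a SMARTS is an atomic number
        if not line or line.startswith("#") or ":" not in line:
            continue
        name, smarts = line.split(":", 1)
        pattern = SmartsPattern(name.strip(), smarts.strip())
        pattern.compile()
        patterns.append(pattern)
    # some catalogues list several SMARTS variants under one group name;
    # disambiguate so presence-matrix columns stay unique
    seen: dict[str, int] = {}
    unique: list[SmartsPattern] = []
    for p in patterns:
        seen[p.name] = seen.get(p.name, 0) + 1
        name = p.name if seen[p.name] == 1 else f"{p.name}_{seen[p.name]}"
        unique.append(SmartsPattern(name, p.smarts))
    return unique


def match_functional_groups(
    mols: dict[str, Chem.Mol], catalogue: list[SmartsPattern]
) -> pd.DataFrame:
    """Boolean presence matrix (substance × group)."""
    queries = [(p.name, p.compile()) for p in catalogue]
    data = {
        name: [mol.HasSubstructMatch(q) for mol in mols.values()]
        for name, q in queries
    }
    return pd.DataFrame(data, index=list(mols), dtype=bool)


def filter_patterns(
    catalogue: list[SmartsPattern], presence_matrices: list[pd.DataFrame]
) -> list[SmartsPattern]:
    """Retain patterns matching ≥1 substance in ≥1 analysed set."""
    retained = []
    for p in catalogue:
        if any(m[p.name].any() for m in presence_matrices if p.name in m.columns):
            retained.append(p)
        else:
            logger.info("dropping pattern with no matches: %s", p.name)
    return retained


@dataclass(frozen=True)
class EnrichmentRow:
    group: str
    p_query: float
    p_reference: float

    @property
    def difference(self) -> float:
        return self.p_query - self.p_reference


def proportion_difference(
    query_presence: pd.DataFrame, reference_presence: pd.DataFrame
) -> list[EnrichmentRow]:
    """Per-group p_query − p_reference over curated unique substances."""
    if query_presence.empty or reference_presence.empty:
        raise ValueError("proportions undefined for an empty substance set")
    groups = [g for g in query_presence.columns if g in reference_presence.columns]
    return [
        EnrichmentRow(
            group=g,
            p_query=float(query_presence[g].mean()),
            p_reference=float(reference_presence[g].mean()),
        )
        for g in groups
    ]


def top_k_enrichment(
    rows: list[EnrichmentRow], k: int = 10
) -> tuple[list[EnrichmentRow], list[EnrichmentRow]]:
    """The k most positive and k most negative differences.

    Ties are broken lexicographically by group name; with fewer than k groups
    both lists simply contain everything, ranked.
    """
    if len(rows) < k:
        logger.info("only %d groups available for top-%d ranking", len(rows), k)
    most_positive = sorted(rows, key=lambda r: (-r.difference, r.group))[:k]
    most_negative = sorted(rows, key=lambda r: (r.difference, r.group))[:k]
    return most_positive, most_negative


def enrichment_frame(rows: list[EnrichmentRow], reference_set: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "reference_set": reference_set,
            "group": [r.group for r in rows],
            "p_query": [r.p_query for r in rows],
            "p_reference": [r.p_reference for r in rows],
            "difference": [r.difference for r in rows],
        }
    )
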