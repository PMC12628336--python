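"""Coverage statistics between substance sets.

Coverage of a query domain (e.g. pesticides) by a reference set (e.g. the
substances tested in one genotoxicity assay) is quantified four ways:

* exact overlap — substances with identical standard InChI in both sets;
* similarity overlap — members of one set with a Morgan-2/2048 Tanimoto of at
  least the threshold (default 0.75) to *any* member of the other; note this
  direction matters: similarity_overlap(a, b) counts members of ``a``;
* intra-set diversity — mean pairwise Tanimoto over all unordered pairs;
* scaffold statistics and scaffold gaps — Murcko-scaffold counts, singleton
  rates, and query scaffolds absent from every reference set, ranked by how
  many query molecules carry them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import EMPTY_SCAFFOLD

DEFAULT_SIMILARITY_THRESHOLD = 0.75


def exact_overlap(a: set[str], b: set[str]) -> tuple[int, list[str]]:
    """|A ∩ B| on InChI identity, with the intersecting members (sorted)."""
    inter = sorted(a & b)
    return len(inter), inter


def _tanimoto_block(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix between fingerprint row-blocks (float64)."""
    Af = A.astype(np.float64)
    Bf = B.astype(np.float64)
    inter = Af @ Bf.T
    pop_a = Af.sum(axis=1)[:, None]
    pop_b = Bf.sum(axis=1)[None, :]
    union = pop_a + pop_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def max_tanimoto_to_set(
    A: np.ndarray, B: np.ndarray, block: int = 1024
) -> np.ndarray:
    """For each row of A, its maximum Tanimoto to any row of B (blocked)."""
    if B.shape[0] == 0:
        return np.zeros(A.shape[0])
    out = np.zeros(A.shape[0])
    for i in range(0, A.shape[0], block):
        sims = _tanimoto_block(A[i : i + block], B)
        out[i : i + block] = sims.max(axis=1)
    return out


@dataclass(frozen=True)
class CoverageReport:
    set_a: str
    set_b: str
    exact_overlap: int
    exact_fraction: float
    similarity_overlap: int
    similarity_fraction: float
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD
    exact_members: list[str] = field(default_factory=list, compare=False)
    similar_members: list[str] = field(default_factory=list, compare=False)


def similarity_overlap(
    a: set[str],
    b: set[str],
    fingerprints: dict[str, np.ndarray],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    strict: bool = False,
) -> tuple[int, list[str]]:
    """Members of ``a`` whose best Tanimoto to ``b`` meets the threshold.

    The comparator is ``>=`` by default ("at least 0.75"); ``strict=True``
    switches to ``>``.  Exact InChI matches are always included: an exact
    match has self-similarity 1.0, so exact_overlap ≤ similarity_overlap.
    """
    missing = (a | b) - fingerprints.keys()
    if missing:
        raise KeyError(f"missing fingerprints for {sorted(missing)[:5]} ...")
    a_keys = sorted(a)
    b_keys = sorted(b)
    A = np.stack([fingerprints[k] for k in a_keys]) if a_keys else np.zeros((0, 1))
    B = np.stack([fingerprints[k] for k in b_keys]) if b_keys else np.zeros((0, 1))
    best = max_tanimoto_to_set(A, B)
    hit = best > threshold if strict else best >= threshold
    members = {k for k, h in zip(a_keys, hit) if h}
    members |= a & b  # exact matches always count as covered
    return len(members), sorted(members)


def coverage_report(
    name_a: str,
    a: set[str],
    name_b: str,
    b: set[str],
    fingerprints: dict[str, np.ndarray],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> CoverageReport:
    n_exact, exact_members = exact_overlap(a, b)
    n_sim, sim_members = similarity_overlap(a, b, fingerprints, threshold)
    n_a = len(a)
    return CoverageReport(
        set_a=name_a,
        set_b=name_b,
        exact_overlap=n_exact,
        exact_fraction=n_exact / n_a if n_a else 0.0,
        similarity_overlap=n_sim,
        similarity_fraction=n_sim / n_a if n_a else 0.0,
        threshold=threshold,
        exact_members=exact_members,
        similar_members=sim_members,
    )


def mean_pairwise_tanimoto(
    members: set[str], fingerprints: dict[str, np.ndarray]
) -> float:
    """Mean Tanimoto over all unordered distinct pairs; NaN for |set| < 2."""
    keys = sorted(members)
    n = len(keys)
    if n < 2:
        return float("nan")
    M = np.stack([fingerprints[k] for k in keys])
    total = 0.0
    block = 1024
    for i in range(0, n, block):
        sims = _tanimoto_block(M[i : i + block], M)
        for r, gi in enumerate(range(i, min(i + block, n))):
            total += sims[r, gi + 1 :].sum()
    return total / (n * (n - 1) / 2)


@dataclass(frozen=True)
class ScaffoldStats:
    n_molecules: int
    n_scaffolds: int
    mean_per_scaffold: float
    sd_per_scaffold: float
    n_singletons: int
    singleton_fraction: float


def scaffold_counts(
    members: set[str], scaffolds: dict[str, str], include_acyclic: bool = True
) -> dict[str, int]:
    """Scaffold → member count within a set.

    Acyclic molecules all share the empty scaffold, which by default counts as
    one scaffold class; ``include_acyclic=False`` drops those molecules.
    """
    counts: dict[str, int] = {}
    for inchi in members:
        scaf = scaffolds[inchi]
        if scaf == EMPTY_SCAFFOLD and not include_acyclic:
            continue
        counts[scaf] = counts.get(scaf, 0) + 1
    return counts


def scaffold_stats(
    members: set[str], scaffolds: dict[str, str], include_acyclic: bool = True
) -> ScaffoldStats:
    counts = scaffold_counts(members, scaffolds, include_acyclic)
    n_scaffolds = len(counts)
    if n_scaffolds == 0:
        return ScaffoldStats(0, 0, float("nan"), float("nan"), 0, float("nan"))
    values = np.array(list(counts.values()), dtype=float)
    n_singletons = int((values == 1).sum())
    return ScaffoldStats(
        n_molecules=int(values.sum()),
        n_scaffolds=n_scaffolds,
        mean_per_scaffold=float(values.mean()),
        sd_per_scaffold=float(values.std(ddof=0)),
        n_singletons=n_singletons,
        singleton_fraction=n_singletons / n_scaffolds,
    )


@dataclass(frozen=True)
class ScaffoldGap:
    scaffold_smiles: str
    count_in_query: int
    pct_of_query: float
    absent_from: tuple[str, ...]


def missing_scaffolds(
    query: set[str],
    scaffolds: dict[str, str],
    references: dict[str, set[str]],
    include_acyclic: bool = False,
) -> list[ScaffoldGap]:
    """Query scaffolds absent from every reference set, by descending count.

    The empty (acyclic) scaffold is excluded by default: "no rings" is not a
    chemotype gap.  Ties in count are broken lexicographically by SMILES so
    the ranking is deterministic.
    """
    query_counts = scaffold_counts(query, scaffolds, include_acyclic)
    ref_scaffolds: set[str] = set()
    for ref_members in references.values():
        ref_scaffolds |= {scaffolds[i] for i in ref_members}
    n_query = len(query)
    gaps = [
        ScaffoldGap(
            scaffold_smiles=scaf,
            count_in_query=count,
            pct_of_query=100.0 * count / n_query if n_query else 0.0,
            absent_from=tuple(sorted(references)),
        )
        for scaf, count in query_counts.items()
        if scaf not in ref_scaffolds
    ]
    gaps.sort(key=lambda g: (-g.count_in_query, g.scaffold_smiles))
    assert all(g.scaffold_smiles not in ref_scaffolds for g in gaps)
    return gaps
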