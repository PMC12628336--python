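# Methods

## Problem setting

Regulatory assessment of pesticide genotoxicity leans on non-testing
approaches — read-across and QSAR — whose validity depends on how well
existing assay data cover the chemical space of the substances being
assessed. `chemcov` operationalises that question: standardize every
substance from heterogeneous public sources to a single parent-structure
identity, aggregate assay outcomes to one conservative call per substance
and test type, and measure coverage of the query domain by each per-assay
reference set with overlap, scaffold, functional-group and embedding
statistics.

## Structure standardization and substance identity

Each raw SMILES passes through a fixed sequence:

1. **Wildcard rejection.** Any raw string containing `*` is rejected before
   parsing — such entries denote substances of variable composition and have
   no assignable structure.
2. **Standardization.** Parse; normalize charged substructures to a
   consistent depiction (nitro, N-oxide, azide and related groups);
   neutralize protonation states by simple rules; remove explicit hydrogens.
3. **Parent extraction.** Clear isotope labels; split into fragments; strip
   solvent fragments, then salt fragments, each against a versioned list
   shipped with the package (`src/chemcov/data/solvents.smi`, `salts.smi`),
   skipping any step that would delete every fragment — if all fragments sit
   on the salt list (e.g. sodium acetate), the organic fragments are kept;
   collapse duplicate fragments, keyed by InChI so stereo-distinct fragments
   are not duplicates; neutralize the survivor.
4. **Identity.** The standard InChI of the parent is the substance key
   everywhere; the full string is used, not the hashed key, so the match
   predicate is exact. Tautomeric form and stereochemistry are preserved as
   given: two stereoisomers are two substances, and no tautomer
   canonicalization is applied.

Unparseable SMILES and internal failures produce typed rejection records;
every input row is accounted for as exactly one curated structure or one
rejection. Multi-fragment survivors (true mixtures) are kept and flagged
rather than dropped — the pipeline never silently discards chemistry.

## Hit-call aggregation

Per substance and test type, the call is *negative* only when every result
is negative; one or more positive results give *positive* regardless of the
number of negatives. This deliberately conservative rule reflects the
regulatory context: a single positive finding cannot be averaged away. The
pooled "all genotoxicity" call applies the same rule to the pooled result
list, which under an any-positive rule is equivalent to a positive-dominant
vote over per-test calls. Source labels that are neither positive nor
negative ("equivocal", "inconclusive") are dropped at load with a logged
count; test-type vocabulary is mapped through a configurable alias table,
and an unknown label is a hard error with row provenance.

## Coverage statistics

* **Exact overlap**: |A ∩ B| on InChI identity; symmetric.
* **Similarity overlap**: members of A whose maximum Tanimoto coefficient to
  any member of B reaches the threshold (default 0.75, comparator ≥ with a
  strict-inequality option). Directional by construction. Exact matches are
  always included (self-similarity is 1.0), so exact ≤ similarity overlap
  holds as an invariant. Fingerprints are radius-2, 2048-bit circular
  (Morgan) bit vectors; the search is a blocked matrix computation whose
  results are pinned to an O(n²) brute-force double loop by tests.
* **Diversity**: mean Tanimoto over all unordered distinct pairs (no
  self-pairs); undefined below two members and reported as missing.
* **Scaffold statistics**: Murcko frameworks (ring systems plus linkers,
  side chains removed). Acyclic molecules form one "empty scaffold" class by
  default (configurable to exclude); a singleton is a scaffold with exactly
  one member in the set.
* **Scaffold gaps**: query scaffolds absent from every reference set, ranked
  by query member count, ties broken lexicographically by scaffold SMILES.
  The empty scaffold is excluded from gap ranking — "no rings" is not a
  chemotype. Gap analysis runs against the endpoint-level sets (substances
  that actually carry assay data), not mere source-set membership.

## Functional-group enrichment

The shipped catalogue is the Open Babel functional-group classification
list (307 named SMARTS; one pattern, `Salt`, is rewritten without
component-level grouping, which the chemistry toolkit's SMARTS parser does
not accept — semantics on curated, desalted structures are unchanged;
duplicate group names are suffixed to keep presence-matrix columns unique).
Presence is binary per substance; patterns matching nothing in any analysed
set are removed before reporting. For each group, the statistic is the
difference of presence proportions between the query set and the reference
set, computed over curated unique substances; top-k rankings (default 10)
in each direction break ties lexicographically. No significance testing is
attached — the raw proportion difference is the reported effect.

## Projections

**PCA** operates on the 16-descriptor matrix. Columns are z-scored by
default: the descriptors mix units (g/mol, Å², counts, fractions) and
unscaled PCA is dominated by molecular weight; a raw (centred, unscaled)
mode is available and both explained-variance figures are reported by the
acceptance script. Constant columns are dropped under z-scoring with a
warning. All component variance fractions are returned (they sum to 1);
loadings for the first two components are emitted for plotting.

**UMAP** operates on the fingerprints with the Jaccard metric (consistent
with Tanimoto similarity). `n_neighbors` and `min_dist` are chosen by grid
search — default grid {2, 3, 5, 10, 15, 30} × {0.0, 0.01, 0.1, 0.25, 0.5} —
scored by rank-based trustworthiness (penalising points that intrude into
embedded neighbourhoods without being near in the original space). "Score an
embedding against a clustering" admits two readings, and the scorer is
therefore configurable: (a) default, trustworthiness of the 2D embedding
with respect to the binary-fingerprint space itself; (b) with respect to a
cluster-indicator space derived from a Butina clustering (Jaccard distance 0
within a cluster, 1 across). Neither is asserted to be canonical. The
selected cell is the argmax score; ties prefer smaller `n_neighbors`, then
smaller `min_dist`; a failed cell is scored missing and excluded. A fixed
seed (default 42) makes the embedding reproducible and is recorded in the
run manifest.

**Butina clustering** (sphere exclusion at Tanimoto-distance cutoff,
default 0.5) is implemented with a fully deterministic order: candidate
centroids by descending neighbour count, ties by ascending index; clusters
are the centroid plus its not-yet-assigned neighbours, and unclaimed points
become singletons. The established reference implementation breaks
neighbour-count ties toward the larger index; tests therefore cross-check
against it on tie-insensitive properties and pin our exact semantics with a
hand-traced fixture.

## Synthetic data generator

The generator emulates the statistical structure of multi-source curation
studies so every stage has a checkable ground truth:

* molecules are ring scaffolds (a ~30-framework base pool of
  pesticide-typical and genotoxicant-typical heteroaromatics and saturated
  rings) decorated with functional groups drawn per-domain at planted
  frequencies (query: halogen/acid-rich; reference: amine/nitro-rich) plus
  variable alkyl chains for uniqueness;
* `singleton_rate` (default 0.25) controls how often a molecule receives a
  fresh composite scaffold (two base frameworks joined by a short linker),
  which drives scaffold-singleton counts;
* three fused tricyclic scaffolds are planted as query-only with fixed
  member counts (7, 3, 1 by default), guaranteeing known scaffold gaps —
  composites are always linked systems, so they cannot collide with the
  fused planted gaps;
* sets reuse previously generated substances with probability
  `overlap_fraction` (default 0.2), producing exact known overlaps and
  exclusivities; reference sets never reuse planted query-only molecules;
* assay results are drawn i.i.d. per substance and test with per-test
  coverage probabilities scaled from the relative endpoint sizes seen in
  public genotoxicity data (Ames near-universal at 0.95 down to in vivo CA
  at 0.016) and a per-result positive rate of 0.3, with 1 + Poisson(0.7)
  results per covered substance-test pair;
* curation artifacts are injected with a manifest: salt adducts (5% of
  rows; every adduct desalts back to the parent), verbatim duplicate rows
  (3%), and appended wildcard entries (2%).

Group sampling happens once per molecule *outside* the uniqueness retry
loop; otherwise collision retries would bias the planted frequencies.
Assembled structures that coincide with the standardizer's salt/solvent
lists (bare tetrahydrofuran, toluene, …) are rejected and rebuilt, since a
salted row containing them would not survive curation. Ground truth is the
generator's own bookkeeping over its final assignments — not a rerun of the
pipeline — so end-to-end tests can demand exact equality for deterministic
quantities (universe size, per-set initial/curated/exclusive counts,
endpoint sizes and positives, overlap counts, the full ranked gap list) and
binomial 3-SD tolerance for sampled frequencies.

What the generator does **not** emulate: realistic pesticide property
distributions beyond the planted frequencies, correlated assay outcomes,
equivocal source labels, tautomer/stereo corruption, or InChI edge cases
(organometallics, polymers). Passing tests therefore demonstrate the
pipeline's bookkeeping and statistics are correct, not that real-world
curation is free of chemistry-specific surprises.

## Default parameters

| Parameter | Default | Why |
|---|---|---|
| Similarity threshold | 0.75 (≥) | conservative analogue definition for regulatory read-across |
| Fingerprint | radius 2, 2048 bits | standard circular-fingerprint setting for small molecules |
| Butina cutoff | 0.5 | Tanimoto-distance radius of one structural cluster |
| Top-k enrichment | 10 | reporting convention for over/under-represented groups |
| PCA scaling | z-score | mixed descriptor units; raw mode available |
| UMAP grid | {2,3,5,10,15,30} × {0,0.01,0.1,0.25,0.5} | spans local-to-global structure; includes the commonly selected (3, 0.01) cell |
| Seed | 42 | fixed, recorded in the run manifest |

## Problem sizes

Tests run on generated corpora of a few hundred molecules per module and a
~2,000-molecule (4 query + 5 reference set) corpus for the study-scale
end-to-end check; brute-force oracles are applied up to 500 molecules
(similarity) and 50 points (trustworthiness); the acceptance script runs
the study-scale corpus with a 600-point UMAP subsample and a 2 × 2
parameter grid. These sizes are the package's reference conditions; all
scale linearly in code via `GeneratorConfig` and `RunConfig`.

## Known limitations

* The exact 305-pattern catalogue version used by the published study is
  not pinned publicly; retained-pattern counts depend on the catalogue
  version and are reproducible only with matching inputs.
* Exclusivity is computed within a category (query sets against query sets,
  reference against reference) by default; a source appearing in both
  categories is counted per category. The alternative cross-category
  convention is available by passing a different set selection.
* The similarity search is a dense matrix computation — appropriate up to
  tens of thousands of molecules, not millions; no index structure is
  built.
* Hit calls carry no study-quality weighting (guideline compliance, dose
  selection); every parsed result counts equally.
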