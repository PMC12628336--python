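"""Structure validation, standardization and parent extraction.

Every substance entering the coverage analysis passes through this module
exactly once.  The pipeline mirrors the curation workflow used for regulatory
chemical collections:

1. reject entries whose raw SMILES text contains the wildcard atom ``*``
   (substances of variable composition that cannot be assigned a structure);
2. parse and *standardize* the molecule — normalize charged substructures to a
   consistent depiction (nitro, N-oxides, azides, ...), strip explicit
   hydrogens, neutralize protonation states where simple rules apply;
3. extract the *parent*: clear isotope labels, strip solvent and salt
   fragments (each defined by a versioned list shipped with the package),
   collapse duplicate fragments, and neutralize what remains;
4. emit the standard InChI of the parent, which serves as the substance
   identity key for all deduplication and overlap matching downstream.

Tautomeric form and stereochemistry are deliberately left as given: two
stereoisomers are two substances, and no tautomer canonicalization is applied.

Multi-fragment survivors (true mixtures whose components are neither salts nor
solvents) are retained and flagged rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

# RDKit is chatty on real-world inputs; curation messages are reported through
# RejectionRecords instead.
RDLogger.DisableLog("rdApp.*")


class RejectReason(str, Enum):
    WILDCARD = "wildcard"
    UNPARSEABLE = "unparseable"
    STANDARDIZATION_FAILURE = "standardization_failure"


@dataclass(frozen=True)
class RawEntry:
    """One input row, before any chemistry is attempted."""

    source_dataset: str
    smiles_text: str
    row_id: str

    def __post_init__(self) -> None:
        if not self.smiles_text or not self.smiles_text.strip():
            raise ValueError("smiles_text must be non-empty")


@dataclass(frozen=True)
class StandardizedStructure:
    """A curated parent structure and its identity strings."""

    canonical_smiles: str
    inchi: str
    n_fragments: int = 1

    @property
    def is_mixture(self) -> bool:
        """True when >1 non-salt/non-solvent fragment survived desalting."""
        return self.n_fragments > 1

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.canonical_smiles)


@dataclass(frozen=True)
class RejectionRecord:
    raw: RawEntry
    reason: RejectReason


@dataclass
class StandardizationRules:
    """Fragment lists used by :func:`get_parent`.

    Fragments are matched by canonical SMILES after isotope clearing, so the
    shipped lists carry both neutral and charged forms of each species.
    """

    salt_smiles: frozenset[str] = field(default_factory=frozenset)
    solvent_smiles: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def default(cls) -> "StandardizationRules":
        return cls(
            salt_smiles=_load_fragment_list("salts.smi"),
            solvent_smiles=_load_fragment_list("solvents.smi"),
        )


def _load_fragment_list(name: str) -> frozenset[str]:
    text = resources.files("chemcov.data").joinpath(name).read_text()
    out = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        mol = Chem.MolFromSmiles(line)
        if mol is None:  # pragma: no cover - shipped lists are valid
            raise ValueError(f"invalid SMILES in fragment list {name}: {line}")
        out.add(Chem.MolToSmiles(mol))
    return frozenset(out)


_DEFAULT_RULES: StandardizationRules | None = None


def default_rules() -> StandardizationRules:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = StandardizationRules.default()
    return _DEFAULT_RULES


_NORMALIZER = rdMolStandardize.Normalizer()
_UNCHARGER = rdMolStandardize.Uncharger()


def _normalize(mol: Chem.Mol) -> Chem.Mol:
    """Charged-substructure normalization + neutralization + H removal."""
    mol = _NORMALIZER.normalize(mol)
    mol = _UNCHARGER.uncharge(mol)
    mol = Chem.RemoveHs(mol)
    Chem.SanitizeMol(mol)
    return mol


def _clear_isotopes(mol: Chem.Mol) -> Chem.Mol:
    if any(a.GetIsotope() for a in mol.GetAtoms()):
        mol = Chem.RWMol(mol)
        for atom in mol.GetAtoms():
            atom.SetIsotope(0)
        mol = Chem.RemoveHs(mol.GetMol())
        Chem.SanitizeMol(mol)
    return mol


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def get_parent(mol: Chem.Mol, rules: StandardizationRules | None = None) -> Chem.Mol:
    """Reduce a standardized molecule to its parent.

    Isotopes are cleared, solvent fragments then salt fragments are stripped
    (each step skipped if it would delete every fragment), duplicate fragments
    are collapsed (stereo-distinct fragments are non-duplicates, hence keyed by
    InChI), and the survivor is neutralized where possible.  Never returns an
    empty molecule.
    """
    rules = rules or default_rules()
    mol = _clear_isotopes(mol)
    frags = list(Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True))

    for reject_set in (rules.solvent_smiles, rules.salt_smiles):
        kept = [f for f in frags if Chem.MolToSmiles(f) not in reject_set]
        if not kept:
            # Removal would empty the molecule (e.g. sodium acetate, where both
            # the cation and the acid anion sit on the salt list).  Prefer the
            # organic fragments; a purely inorganic salt is kept whole.
            kept = [f for f in frags if _has_carbon(f)]
        if kept:
            frags = kept

    seen: dict[str, Chem.Mol] = {}
    for f in frags:
        key = Chem.MolToInchi(f)
        if key not in seen:
            seen[key] = f
    frags = list(seen.values())

    parent = frags[0]
    for f in frags[1:]:
        parent = Chem.CombineMols(parent, f)
    parent = _UNCHARGER.uncharge(parent)
    Chem.SanitizeMol(parent)
    return parent


def to_inchi(mol: Chem.Mol) -> str:
    """Standard InChI of a parent structure; raises on generation failure."""
    inchi = Chem.MolToInchi(mol, treatWarningAsError=False)
    if not inchi:
        raise ValueError("InChI generation failed")
    return inchi


def standardize_structure(
    entry: RawEntry, rules: StandardizationRules | None = None
) -> StandardizedStructure | RejectionRecord:
    """Full curation of one raw entry.

    Returns either the curated parent (with its InChI identity) or a
    :class:`RejectionRecord` carrying the reason.  Wildcard detection happens
    on the raw text before any parsing, so variable-composition entries are
    rejected even when their SMILES would parse as a query molecule.
    """
    if "*" in entry.smiles_text:
        return RejectionRecord(entry, RejectReason.WILDCARD)
    mol = Chem.MolFromSmiles(entry.smiles_text.strip())
    if mol is None:
        return RejectionRecord(entry, RejectReason.UNPARSEABLE)
    try:
        mol = _normalize(mol)
        mol = get_parent(mol, rules)
        mol = _normalize(mol)
        inchi = to_inchi(mol)
    except Exception:
        logger.debug("standardization failed for %s", entry.row_id, exc_info=True)
        return RejectionRecord(entry, RejectReason.STANDARDIZATION_FAILURE)
    return StandardizedStructure(
        canonical_smiles=Chem.MolToSmiles(mol),
        inchi=inchi,
        n_fragments=len(Chem.GetMolFrags(mol)),
    )


def standardize_entries(
    entries: Iterable[RawEntry], rules: StandardizationRules | None = None
) -> tuple[list[tuple[RawEntry, StandardizedStructure]], list[RejectionRecord]]:
    """Curate a batch; every input appears exactly once across the two outputs."""
    rules = rules or default_rules()
    ok: list[tuple[RawEntry, StandardizedStructure]] = []
    rejected: list[RejectionRecord] = []
    for entry in entries:
        result = standardize_structure(entry, rules)
        if isinstance(result, RejectionRecord):
            rejected.append(result)
            logger.info(
                "rejected %s/%s: %s", entry.source_dataset, entry.row_id, result.reason.value
            )
        else:
            ok.append((entry, result))
    return ok, rejected
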