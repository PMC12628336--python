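"""Per-substance molecular representations.

Three representations drive the coverage analysis:

* a 16-element physicochemical descriptor vector (size, lipophilicity,
  polarity, topology and composition counts) used for the PCA view;
* the radius-2, 2048-bit Morgan (circular) fingerprint used for Tanimoto
  similarity, Butina clustering and the UMAP view;
* the canonical Murcko scaffold (ring systems + linkers, side chains removed)
  used for scaffold-diversity statistics and gap ranking.

All three are deterministic functions of the standardized parent structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

#: Column order of the descriptor matrix; fixed so downstream PCA loadings are
#: reproducible.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "mw",
    "logp",
    "tpsa",
    "hba",
    "hbd",
    "heavy_atoms",
    "n_count",
    "o_count",
    "s_count",
    "halogen_count",
    "bridgehead_count",
    "chiral_centers",
    "aromatic_atoms",
    "ring_count",
    "frac_sp3_carbon",
    "formal_charge",
)

_HALOGENS = {9, 17, 35, 53}  # F, Cl, Br, I

FINGERPRINT_RADIUS = 2
FINGERPRINT_BITS = 2048

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_BITS
)


def _count_atomic_num(mol: Chem.Mol, z: int) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == z)


def physchem_vector(mol: Chem.Mol) -> dict[str, float]:
    """The 16 physicochemical descriptors of one parent structure.

    logP is the Crippen atomic-contribution estimate; chiral centers count
    both assigned and unassigned potential stereocenters; ring count is the
    SSSR ring count; frac_sp3_carbon is sp3 carbons over total carbons.
    """
    return {
        "mw": Descriptors.MolWt(mol),
        "logp": Crippen.MolLogP(mol),
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
        "hba": float(rdMolDescriptors.CalcNumHBA(mol)),
        "hbd": float(rdMolDescriptors.CalcNumHBD(mol)),
        "heavy_atoms": float(mol.GetNumHeavyAtoms()),
        "n_count": float(_count_atomic_num(mol, 7)),
        "o_count": float(_count_atomic_num(mol, 8)),
        "s_count": float(_count_atomic_num(mol, 16)),
        "halogen_count": float(
            sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in _HALOGENS)
        ),
        "bridgehead_count": float(rdMolDescriptors.CalcNumBridgeheadAtoms(mol)),
        "chiral_centers": float(
            len(
                Chem.FindMolChiralCenters(
                    mol, includeUnassigned=True, useLegacyImplementation=False
                )
            )
        ),
        "aromatic_atoms": float(sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())),
        "ring_count": float(rdMolDescriptors.CalcNumRings(mol)),
        "frac_sp3_carbon": rdMolDescriptors.CalcFractionCSP3(mol),
        "formal_charge": float(Chem.GetFormalCharge(mol)),
    }


def descriptor_frame(mols: dict[str, Chem.Mol]) -> pd.DataFrame:
    """Descriptor matrix for a universe keyed by InChI.

    Substances whose descriptor computation fails are dropped from the frame
    (they are flagged by the caller and excluded from PCA).
    """
    rows, index = [], []
    for inchi, mol in mols.items():
        try:
            rows.append(physchem_vector(mol))
            index.append(inchi)
        except Exception:  # exotic valence; excluded from projection
            continue
    return pd.DataFrame(rows, index=index, columns=list(DESCRIPTOR_NAMES))


def circular_fingerprint(mol: Chem.Mol) -> np.ndarray:
    """Radius-2 2048-bit Morgan fingerprint as a uint8 0/1 vector."""
    return _FP_GEN.GetFingerprintAsNumPy(mol).astype(np.uint8)


def fingerprint_matrix(mols: dict[str, Chem.Mol]) -> tuple[np.ndarray, list[str]]:
    """Stacked fingerprints (n × 2048 uint8) and the matching InChI order."""
    keys = list(mols)
    mat = np.zeros((len(keys), FINGERPRINT_BITS), dtype=np.uint8)
    for i, k in enumerate(keys):
        mat[i] = circular_fingerprint(mols[k])
    return mat, keys


@dataclass(frozen=True)
class Scaffold:
    scaffold_smiles: str
    is_empty: bool


#: Scaffold key used for acyclic molecules (empty framework).
EMPTY_SCAFFOLD = ""


def murcko_scaffold(mol: Chem.Mol) -> Scaffold:
    """Canonical Murcko framework; acyclic molecules yield the empty scaffold."""
    if rdMolDescriptors.CalcNumRings(mol) == 0:
        return Scaffold(EMPTY_SCAFFOLD, True)
    core = MurckoScaffold.GetScaffoldForMol(mol)
    smiles = Chem.MolToSmiles(core)
    return Scaffold(smiles, smiles == EMPTY_SCAFFOLD)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two binary fingerprints.

    Two all-zero fingerprints compare as identical (1.0); an all-zero against
    a non-empty one gives 0.0.  The degenerate case does not occur for parsed
    molecules but the convention keeps the function total.
    """
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return inter / union
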