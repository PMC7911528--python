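"""2D descriptor computation, ion-class assignment, structural outlier rule.

Descriptors computed from structure (via RDKit): log P estimate, aromatic
ring count, topological PSA, ring count, rotatable bonds, HBD/HBA counts,
molecular weight, approximate surface area, and an additive polarizability
estimate.  Quantum-derived quantities (dipole moment mu, its maximum
absolute component mu_max, molecular volume, pKa values) are not computed
here; they are ingested as precomputed table columns.
"""

from __future__ import annotations

import math
from typing import Sequence

from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors
from rdkit.Chem.Descriptors import MolWt

from . import errors

# Descriptor column names in the order models usually see them.
TWO_D_FIELDS = ("log_p", "n_ar", "psa", "n_ring", "n_rot", "hbd", "hba", "mw", "sa", "alpha")
PRECOMPUTED_FIELDS = ("mu", "mu_max", "v_m", "pka_max")

# Atomic polarizabilities (A^3), additive fallback when a computed value is
# not supplied; adequate because alpha tracks MW almost linearly.
_ATOMIC_POLARIZABILITY = {
    "H": 0.667, "C": 1.76, "N": 1.10, "O": 0.802, "F": 0.557,
    "Si": 5.38, "P": 3.63, "S": 2.90, "Cl": 2.18, "Br": 3.05, "I": 5.35,
    "B": 3.03, "Se": 3.77,
}


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise errors.StructureError(smiles)
    # re-parse the canonical SMILES so atom order (hence floating-point
    # summation order in additive descriptors) is writing-invariant
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def additive_polarizability(mol: Chem.Mol) -> float:
    """Sum of atomic polarizability contributions over all atoms incl. H."""
    total = 0.0
    for atom in mol.GetAtoms():
        total += _ATOMIC_POLARIZABILITY.get(atom.GetSymbol(), 1.5)
        total += atom.GetTotalNumHs() * _ATOMIC_POLARIZABILITY["H"]
    return total


def compute_2d_descriptors(smiles: str) -> dict[str, float]:
    """Compute the structure-derived descriptor block for one SMILES.

    Returns log_p (Crippen estimate), n_ar, psa (topological), n_ring,
    n_rot (strict rotatable-bond definition excluding amide C-N), hbd, hba,
    mw, sa (Labute approximate surface area) and the additive alpha estimate.
    mu, mu_max, v_m and pka_max stay unavailable unless supplied externally.
    """
    mol = _mol_from_smiles(smiles)
    return {
        "log_p": float(Crippen.MolLogP(mol)),
        "n_ar": int(rdMolDescriptors.CalcNumAromaticRings(mol)),
        "psa": float(rdMolDescriptors.CalcTPSA(mol)),
        "n_ring": int(rdMolDescriptors.CalcNumRings(mol)),
        "n_rot": int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        "hbd": int(rdMolDescriptors.CalcNumHBD(mol)),
        "hba": int(rdMolDescriptors.CalcNumHBA(mol)),
        "mw": float(MolWt(mol)),
        "sa": float(rdMolDescriptors.CalcLabuteASA(mol)),
        "alpha": additive_polarizability(mol),
    }


def assign_ion_class(pka_values: Sequence[tuple[float, str]], lenient: bool = False) -> str:
    """Assign acid/base/neutral/zwitterion from tagged pKa values.

    Each entry is ``(value, kind)`` with kind "acidic" or "basic".  Rules
    relative to pH ~7: a compound whose ionizable groups all have pKa < 7 is
    an acid; all > 7 a base; a zwitterion has its strongest acidic pKa above
    7 and its strongest basic pKa below 7.  A compound with no pKa in the
    2-12 window, or whose values fire none of those rules, is neutral.
    """
    pka_values = list(pka_values)
    if not pka_values:
        if lenient:
            return "unknown"
        raise errors.ValidationError("cannot assign ion class without pKa values")
    for value, kind in pka_values:
        if kind not in ("acidic", "basic"):
            raise errors.ValidationError(f"pKa kind must be 'acidic' or 'basic', got {kind!r}")
        if not math.isfinite(value):
            raise errors.ValidationError("non-finite pKa value")

    values = [v for v, _ in pka_values]
    acidic = [v for v, k in pka_values if k == "acidic"]
    basic = [v for v, k in pka_values if k == "basic"]

    if not any(2.0 <= v <= 12.0 for v in values):
        return "neutral"
    if all(v < 7.0 for v in values):
        return "acid"
    if all(v > 7.0 for v in values):
        return "base"
    # strongest acid = lowest acidic pKa; strongest base = highest basic pKa
    if acidic and basic and min(acidic) > 7.0 and max(basic) < 7.0:
        return "zwitterion"
    return "neutral"


def flag_structural_outlier(n_ring: float | None, hba: float | None) -> bool:
    """Flag compounds with more than nine rings or more than 12 HBAs."""
    if n_ring is None or hba is None:
        raise errors.ValidationError("n_ring and hba required for the structural outlier rule")
    return bool(n_ring > 9 or hba > 12)
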