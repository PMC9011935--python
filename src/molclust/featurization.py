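"""SMILES parsing and per-molecule raw feature generation.

Each molecule is treated as a graph of heavy atoms: hydrogens stay implicit
and enter only through the "number of bonded hydrogens" atomic attribute.
Three raw representations are produced per molecule:

* an atomic feature matrix (one row per heavy atom, 145 columns),
* a bond feature matrix (one row per bond, 12 columns),
* a global descriptor vector (the RDKit molecular-descriptor collection).

All categorical attributes are one-hot encoded; the only real-valued atomic
entry is the atomic mass divided by 100, which keeps it on the same scale as
the one-hot bits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "AtomFeatureMatrix",
    "BondFeatureMatrix",
    "GlobalDescriptorVector",
    "SmilesParseError",
    "parse_smiles",
    "featurize_atoms",
    "featurize_bonds",
    "compute_global_descriptors",
    "default_descriptor_names",
    "ATOM_BLOCK_LAYOUT",
    "BOND_BLOCK_LAYOUT",
    "ATOM_FEATURE_WIDTH",
    "BOND_FEATURE_WIDTH",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the record id."""


# Fixed block layout of the atomic feature matrix.  Widths are the attribute
# sizes of the featurization scheme; their sum (145) is an invariant checked
# by the test suite.
ATOM_BLOCK_LAYOUT: tuple[tuple[str, int], ...] = (
    ("atom_type", 118),      # one-hot over atomic number 1..118
    ("degree", 6),           # number of bonds: 0..5 (clamped above)
    ("formal_charge", 5),    # bins -2, -1, 0, +1, +2 (clamped outside)
    ("chirality", 4),        # unspecified, tetrahedral CW, CCW, other
    ("num_h", 5),            # bonded hydrogens 0..4 (clamped above)
    ("hybridization", 5),    # sp, sp2, sp3, sp3d, sp3d2 (others clamped)
    ("aromaticity", 1),      # 0/1 flag
    ("mass", 1),             # atomic mass / 100
)

BOND_BLOCK_LAYOUT: tuple[tuple[str, int], ...] = (
    ("bond_type", 4),        # single, double, triple, aromatic
    ("conjugated", 1),       # 0/1 flag
    ("ring", 1),             # 0/1 flag
    ("stereo", 6),           # none, any, Z, E, cis, trans
)

ATOM_FEATURE_WIDTH = sum(w for _, w in ATOM_BLOCK_LAYOUT)
BOND_FEATURE_WIDTH = sum(w for _, w in BOND_BLOCK_LAYOUT)

_CHARGE_BINS = (-2, -1, 0, 1, 2)

_CHIRALITY_ORDER = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)  # anything else -> "other" (last slot)

_HYBRIDIZATION_ORDER = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)  # unknown kinds clamp to the last slot

_BOND_TYPE_ORDER = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

_STEREO_ORDER = (
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
)


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed molecule: canonical SMILES plus heavy-atom graph counts."""

    id: str
    smiles: str
    n_atoms: int
    n_bonds: int
    mol: Chem.Mol = field(repr=False, compare=False)


@dataclass(frozen=True)
class AtomFeatureMatrix:
    values: np.ndarray  # n_atoms x 145
    block_layout: tuple[tuple[str, int], ...] = ATOM_BLOCK_LAYOUT


@dataclass(frozen=True)
class BondFeatureMatrix:
    values: np.ndarray  # n_bonds x 12
    block_layout: tuple[tuple[str, int], ...] = BOND_BLOCK_LAYOUT


@dataclass(frozen=True)
class GlobalDescriptorVector:
    values: np.ndarray
    names: tuple[str, ...]


def parse_smiles(smiles: str, id: str = "") -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    Explicit hydrogens in the input are folded into the heavy atoms'
    hydrogen counts, so ``n_atoms`` counts heavy atoms only.

    Raises
    ------
    ValueError
        If *smiles* is empty.
    SmilesParseError
        If RDKit cannot parse the string; the message names *id*.
    """
    if not smiles or not smiles.strip():
        raise ValueError(f"empty SMILES for record {id!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES for record {id!r}: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    return MoleculeRecord(
        id=id,
        smiles=canonical,
        n_atoms=mol.GetNumAtoms(),
        n_bonds=mol.GetNumBonds(),
        mol=mol,
    )


def _one_hot_index(value, order, clamp: bool = True) -> int:
    try:
        return order.index(value)
    except ValueError:
        if clamp:
            return len(order)  # caller reserves a final slot
        raise


def _atom_row(atom: Chem.Atom) -> np.ndarray:
    row = np.zeros(ATOM_FEATURE_WIDTH)
    offset = 0
    # atom type: one-hot over atomic number (1-based -> index Z-1)
    z = atom.GetAtomicNum()
    row[offset + min(max(z, 1), 118) - 1] = 1.0  # dummy atoms (Z=0) clamp into slot 0
    offset += 118
    # degree, clamped to the last category
    row[offset + min(atom.GetDegree(), 5)] = 1.0
    offset += 6
    # formal charge bins {-2,-1,0,+1,+2}; out-of-range clamps to last slot
    charge = atom.GetFormalCharge()
    if charge in _CHARGE_BINS:
        row[offset + _CHARGE_BINS.index(charge)] = 1.0
    else:
        row[offset + 4] = 1.0
    offset += 5
    # chirality: unspecified / CW / CCW / other
    try:
        ci = _CHIRALITY_ORDER.index(atom.GetChiralTag())
    except ValueError:
        ci = 3
    row[offset + ci] = 1.0
    offset += 4
    # implicit+explicit hydrogen count, clamped at 4
    row[offset + min(atom.GetTotalNumHs(), 4)] = 1.0
    offset += 5
    # hybridization
    try:
        hi = _HYBRIDIZATION_ORDER.index(atom.GetHybridization())
    except ValueError:
        hi = 4
    row[offset + hi] = 1.0
    offset += 5
    row[offset] = 1.0 if atom.GetIsAromatic() else 0.0
    offset += 1
    row[offset] = atom.GetMass() / 100.0
    return row


def featurize_atoms(mol: MoleculeRecord) -> AtomFeatureMatrix:
    """Build the n_atoms x 145 one-hot atomic feature matrix."""
    values = np.stack([_atom_row(a) for a in mol.mol.GetAtoms()])
    return AtomFeatureMatrix(values=values)


def _bond_row(bond: Chem.Bond) -> np.ndarray:
    row = np.zeros(BOND_FEATURE_WIDTH)
    offset = 0
    try:
        bi = _BOND_TYPE_ORDER.index(bond.GetBondType())
    except ValueError:
        bi = 3  # exotic bond orders clamp to the last category
    row[offset + bi] = 1.0
    offset += 4
    row[offset] = 1.0 if bond.GetIsConjugated() else 0.0
    offset += 1
    row[offset] = 1.0 if bond.IsInRing() else 0.0
    offset += 1
    try:
        si = _STEREO_ORDER.index(bond.GetStereo())
    except ValueError:
        si = 5
    row[offset + si] = 1.0
    return row


def featurize_bonds(mol: MoleculeRecord) -> BondFeatureMatrix:
    """Build the n_bonds x 12 bond feature matrix (0 rows for bond-free molecules)."""
    bonds = list(mol.mol.GetBonds())
    if not bonds:
        return BondFeatureMatrix(values=np.zeros((0, BOND_FEATURE_WIDTH)))
    values = np.stack([_bond_row(b) for b in bonds])
    return BondFeatureMatrix(values=values)


def default_descriptor_names() -> tuple[str, ...]:
    """The full RDKit molecular-descriptor collection, in its canonical order."""
    return tuple(name for name, _ in Descriptors.descList)


def compute_global_descriptors(
    mol: MoleculeRecord,
    descriptor_set: tuple[str, ...] | list[str] | None = None,
) -> GlobalDescriptorVector:
    """Compute the whole-molecule descriptor vector.

    Descriptors that come back NaN/Inf (some topochemical descriptors are
    undefined for exotic structures) are logged and imputed to 0 so that
    downstream z-scoring never sees a non-finite value.
    """
    if descriptor_set is None:
        descriptor_set = default_descriptor_names()
    fn_map = dict(Descriptors.descList)
    values = np.empty(len(descriptor_set))
    for i, name in enumerate(descriptor_set):
        try:
            v = float(fn_map[name](mol.mol))
        except Exception:  # pragma: no cover - descriptor-internal failure
            v = math.nan
        if not math.isfinite(v):
            logger.warning(
                "descriptor %s non-finite for molecule %s; imputing 0", name, mol.id
            )
            v = 0.0
        values[i] = v
    return GlobalDescriptorVector(values=values, names=tuple(descriptor_set))
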