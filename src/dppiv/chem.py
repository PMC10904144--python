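"""Residue-level chemistry: SMILES table, molecular graphs and the structural tensor.

Each residue of a peptide is rendered independently as the free amino-acid
molecule (peptide bonds are not modelled), its heavy atoms are featurized
into a 21-slot vector, neighbour information is folded in through the
adjacency matrix, and the per-residue matrices are padded into a fixed-shape
3-D tensor (residues x atoms x features) with validity masks.

Feature layout per atom (21 slots):

====  =========================================================
slot  content
====  =========================================================
0-3   one-hot element (C, N, O, S)
4-6   one-hot heavy-atom degree (1, 2, 3)
7-10  one-hot total H count (0, 1, 2, 3)
11-14 one-hot implicit H count (0, 1, 2, 3)
15    aromatic flag
16-17 one-hot ring membership (in ring, not in ring)
18    hybridization as integer 1-7
19    Gasteiger charge (becomes the neighbour sum after aggregation)
20    Gasteiger charge of the atom itself (bypasses aggregation)
====  =========================================================

Slots 0-19 of the final per-atom vector are the sum of the raw vectors of
the atom's bonded neighbours (adjacency-matrix product, no self-loop);
slot 20 alone carries information about the atom itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdPartialCharges

__all__ = [
    "AMINO_ACID_SMILES",
    "N_FEATURES",
    "MAX_ATOMS",
    "DEFAULT_MAX_RESIDUES",
    "MoleculeGraph",
    "StructTensor",
    "aa_to_smiles",
    "build_molecule",
    "featurize_atom",
    "featurize_molecule",
    "aggregate_neighbors",
    "encode_peptide",
    "max_heavy_atoms",
]

N_FEATURES = 21
#: heavy-atom count of the largest standard amino acid (tryptophan)
MAX_ATOMS = 15
#: longest peptide accepted by default (longest record in the benchmark data)
DEFAULT_MAX_RESIDUES = 90

#: Canonical SMILES of the 20 free (neutral, non-zwitterionic) amino acids.
#: Pinned as literals so tensors are bit-reproducible across rdkit versions.
AMINO_ACID_SMILES: dict[str, str] = {
    "A": "CC(N)C(=O)O",
    "R": "NC(CCCNC(=N)N)C(=O)O",
    "N": "NC(CC(N)=O)C(=O)O",
    "D": "NC(CC(=O)O)C(=O)O",
    "C": "NC(CS)C(=O)O",
    "E": "NC(CCC(=O)O)C(=O)O",
    "Q": "NC(CCC(N)=O)C(=O)O",
    "G": "NCC(=O)O",
    "H": "NC(Cc1cnc[nH]1)C(=O)O",
    "I": "CCC(C)C(N)C(=O)O",
    "L": "CC(C)CC(N)C(=O)O",
    "K": "NCCCCC(N)C(=O)O",
    "M": "CSCCC(N)C(=O)O",
    "F": "NC(Cc1ccccc1)C(=O)O",
    "P": "OC(=O)C1CCCN1",
    "S": "NC(CO)C(=O)O",
    "T": "CC(O)C(N)C(=O)O",
    "V": "CC(C)C(N)C(=O)O",
    "W": "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "Y": "NC(Cc1ccc(O)cc1)C(=O)O",
}

_ELEMENTS = ("C", "N", "O", "S")
_HYBRIDIZATION_CODE = {
    Chem.HybridizationType.S: 1,
    Chem.HybridizationType.SP: 2,
    Chem.HybridizationType.SP2: 3,
    Chem.HybridizationType.SP3: 4,
    Chem.HybridizationType.SP3D: 5,
    Chem.HybridizationType.SP3D2: 6,
}


class EncodingError(ValueError):
    """Raised when a sequence or SMILES cannot be encoded."""


def aa_to_smiles(code: str, position: int | None = None) -> str:
    """Return the pinned SMILES of the free amino acid for a one-letter code.

    Parameters
    ----------
    code
        One-letter residue code (one of the 20 standard residues).
    position
        Optional 0-based position inside a parent sequence, used only to
        make the error message actionable.
    """
    try:
        return AMINO_ACID_SMILES[code]
    except KeyError:
        where = "" if position is None else f" at position {position}"
        raise EncodingError(
            f"unknown residue {code!r}{where}: not one of the 20 standard amino acids"
        ) from None


@dataclass(frozen=True)
class MoleculeGraph:
    """Heavy-atom graph of one free amino acid.

    Atom ordering follows the SMILES string, so a given SMILES always
    produces the same graph. Hydrogens never appear as nodes.
    """

    smiles: str
    elements: tuple[str, ...]
    adjacency: np.ndarray  # (n, n) symmetric 0/1, zero diagonal
    raw_features: np.ndarray  # (n, 21) pre-aggregation per-atom features

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def bonds(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency))
        return list(zip(i.tolist(), j.tolist()))

    @property
    def aromatic_flags(self) -> np.ndarray:
        return self.raw_features[:, 15] > 0

    @property
    def in_ring_flags(self) -> np.ndarray:
        return self.raw_features[:, 16] > 0


def _rdkit_mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise EncodingError(f"unparsable SMILES: {smiles!r}")
    rdPartialCharges.ComputeGasteigerCharges(mol)
    return mol


def featurize_atom(mol: Chem.Mol, atom_index: int) -> np.ndarray:
    """Raw (pre-aggregation) 21-slot feature vector of one heavy atom."""
    atom = mol.GetAtomWithIdx(atom_index)
    v = np.zeros(N_FEATURES, dtype=np.float64)
    symbol = atom.GetSymbol()
    if symbol not in _ELEMENTS:
        raise EncodingError(
            f"element {symbol!r} cannot be one-hot encoded (expected one of {_ELEMENTS})"
        )
    v[_ELEMENTS.index(symbol)] = 1.0
    degree = atom.GetDegree()
    if 1 <= degree <= 3:
        v[3 + degree] = 1.0  # slots 4-6 <-> degrees 1-3; other degrees: all-zero block
    total_h = atom.GetTotalNumHs()
    if 0 <= total_h <= 3:
        v[7 + total_h] = 1.0
    implicit_h = atom.GetNumImplicitHs()
    if 0 <= implicit_h <= 3:
        v[11 + implicit_h] = 1.0
    v[15] = 1.0 if atom.GetIsAromatic() else 0.0
    v[16] = 1.0 if atom.IsInRing() else 0.0
    v[17] = 0.0 if atom.IsInRing() else 1.0
    v[18] = _HYBRIDIZATION_CODE.get(atom.GetHybridization(), 7)
    charge = float(atom.GetDoubleProp("_GasteigerCharge"))
    if not np.isfinite(charge):
        raise EncodingError(f"non-finite Gasteiger charge on atom {atom_index}")
    # slot 19 holds the raw charge; the adjacency product turns it into the
    # neighbour-charge sum.  Slot 20 is the same charge kept for the atom itself.
    v[19] = charge
    v[20] = charge
    return v


def build_molecule(smiles: str) -> MoleculeGraph:
    """Parse a SMILES string into a heavy-atom :class:`MoleculeGraph`."""
    mol = _rdkit_mol(smiles)
    n = mol.GetNumAtoms()
    adjacency = np.zeros((n, n), dtype=np.float64)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i, j] = adjacency[j, i] = 1.0
    raw = np.stack([featurize_atom(mol, i) for i in range(n)])
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    return MoleculeGraph(smiles=smiles, elements=elements, adjacency=adjacency, raw_features=raw)


def featurize_molecule(graph: MoleculeGraph) -> np.ndarray:
    """Aggregated (n_atoms x 21) feature matrix of a molecule graph."""
    return aggregate_neighbors(graph.raw_features, graph.adjacency)


def aggregate_neighbors(raw_features: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Fold neighbour information into each atom's feature vector.

    Slots 0-19 of atom *i* become the sum of the raw slots 0-19 over the
    atoms bonded to *i* (adjacency-matrix product, no self-loop); slot 20 is
    copied unchanged from the atom's own raw vector.
    """
    raw_features = np.asarray(raw_features, dtype=np.float64)
    adjacency = np.asarray(adjacency, dtype=np.float64)
    n = raw_features.shape[0]
    if raw_features.ndim != 2 or raw_features.shape[1] != N_FEATURES:
        raise ValueError(f"raw_features must have shape (n, {N_FEATURES})")
    if adjacency.shape != (n, n):
        raise ValueError(f"adjacency shape {adjacency.shape} incompatible with {n} atoms")
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    out = np.empty_like(raw_features)
    out[:, :20] = adjacency @ raw_features[:, :20]
    out[:, 20] = raw_features[:, 20]
    return out


@dataclass
class StructTensor:
    """Residue-major structural tensor with validity masks.

    ``values`` has shape ``(max_residues, MAX_ATOMS, N_FEATURES)``;
    every entry whose mask is false is exactly zero.
    """

    values: np.ndarray
    residue_mask: np.ndarray  # (max_residues,) bool
    atom_mask: np.ndarray  # (max_residues, MAX_ATOMS) bool
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != (*self.atom_mask.shape, N_FEATURES):
            raise ValueError("values / atom_mask shape mismatch")
        if self.residue_mask.shape[0] != self.values.shape[0]:
            raise ValueError("residue_mask length mismatch")

    @property
    def max_residues(self) -> int:
        return self.values.shape[0]

    @property
    def n_residues(self) -> int:
        return int(self.residue_mask.sum())


_MOLECULE_CACHE: dict[str, tuple[MoleculeGraph, np.ndarray]] = {}


def _residue_matrix(code: str) -> tuple[MoleculeGraph, np.ndarray]:
    """Aggregated feature matrix of one residue, memoised (encoding is context-free)."""
    hit = _MOLECULE_CACHE.get(code)
    if hit is None:
        graph = build_molecule(AMINO_ACID_SMILES[code])
        hit = (graph, featurize_molecule(graph))
        _MOLECULE_CACHE[code] = hit
    return hit


def encode_peptide(sequence: str, max_residues: int = DEFAULT_MAX_RESIDUES) -> StructTensor:
    """Encode a peptide into the padded structural tensor.

    Each residue is encoded independently of its context; rows beyond a
    molecule's atom count and residues beyond the sequence length are zero.
    Sequences longer than ``max_residues`` are rejected rather than truncated.
    """
    if not isinstance(sequence, str):
        raise EncodingError("sequence must be a string")
    if len(sequence) < 2:
        raise EncodingError(f"sequence too short ({len(sequence)} residues; minimum is 2)")
    if len(sequence) > max_residues:
        raise EncodingError(
            f"sequence too long ({len(sequence)} residues; maximum is {max_residues})"
        )
    bad = [(i, c) for i, c in enumerate(sequence) if c not in AMINO_ACID_SMILES]
    if bad:
        detail = ", ".join(f"{c!r} at position {i}" for i, c in bad)
        raise EncodingError(f"invalid residue(s): {detail}")

    values = np.zeros((max_residues, MAX_ATOMS, N_FEATURES), dtype=np.float64)
    residue_mask = np.zeros(max_residues, dtype=bool)
    atom_mask = np.zeros((max_residues, MAX_ATOMS), dtype=bool)
    for i, code in enumerate(sequence):
        _, matrix = _residue_matrix(code)
        n = matrix.shape[0]
        values[i, :n] = matrix
        residue_mask[i] = True
        atom_mask[i, :n] = True
    return StructTensor(values=values, residue_mask=residue_mask, atom_mask=atom_mask, sequence=sequence)


def max_heavy_atoms() -> int:
    """Largest heavy-atom count over the 20 standard amino acids."""
    return max(build_molecule(s).n_atoms for s in AMINO_ACID_SMILES.values())
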