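"""SMILES to featurized atom-level molecular graphs.

Atoms are heavy atoms only (hydrogens stay implicit and enter the features
as a count). Each atom feature vector is the concatenation of eight
attribute-group encodings, each bond feature vector of four — the
convention used by directed message-passing property predictors:

atom groups
    1. element one-hot (over a fixed symbol list, with an "other" slot)
    2. total degree one-hot (0-5, "other")
    3. formal charge one-hot (-2..+2, "other")
    4. chirality tag one-hot
    5. attached-hydrogen count one-hot (0-4, "other")
    6. hybridization one-hot
    7. aromaticity flag (single bit)
    8. atomic mass / 100 (single scaled channel)

bond groups
    1. bond type one-hot (single/double/triple/aromatic)
    2. conjugation flag
    3. ring-membership flag
    4. stereo tag one-hot

Every undirected bond is stored as two directed entries (u->v and v->u),
the form the directed-edge message-passing encoder consumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = ["FeatureConfig", "AtomGraph", "SmilesParseError", "smiles_to_atom_graph", "parse_mol"]


class SmilesParseError(ValueError):
    """Raised for SMILES that RDKit cannot parse, carrying the offending string."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


_CHIRAL_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.ChiralType.CHI_OTHER,
]
_HYBRIDIZATIONS = [
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
_BOND_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
]


def _one_hot(value, choices, with_other: bool = True) -> list[float]:
    vec = [0.0] * (len(choices) + (1 if with_other else 0))
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        if with_other:
            vec[-1] = 1.0
    return vec


@dataclass(frozen=True)
class FeatureConfig:
    """Atom/bond attribute vocabulary; fixes feature dimensionality."""

    elements: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se")
    max_degree: int = 5
    charges: tuple[int, ...] = (-2, -1, 0, 1, 2)
    max_num_h: int = 4
    mass_scale: float = 100.0

    #: number of atom / bond attribute groups in the encoding
    n_atom_groups: int = field(default=8, init=False)
    n_bond_groups: int = field(default=4, init=False)

    @property
    def atom_dim(self) -> int:
        return (
            len(self.elements) + 1          # element
            + self.max_degree + 2           # degree
            + len(self.charges) + 1         # formal charge
            + len(_CHIRAL_TAGS)             # chirality
            + self.max_num_h + 2            # attached hydrogens
            + len(_HYBRIDIZATIONS) + 1      # hybridization
            + 1                             # aromaticity
            + 1                             # scaled mass
        )

    @property
    def bond_dim(self) -> int:
        return len(_BOND_TYPES) + 1 + 1 + 1 + len(_BOND_STEREO) + 1

    def atom_features(self, atom: Chem.Atom) -> np.ndarray:
        vec = (
            _one_hot(atom.GetSymbol(), list(self.elements))
            + _one_hot(atom.GetTotalDegree(), list(range(self.max_degree + 1)))
            + _one_hot(atom.GetFormalCharge(), list(self.charges))
            + _one_hot(atom.GetChiralTag(), _CHIRAL_TAGS, with_other=False)
            + _one_hot(atom.GetTotalNumHs(), list(range(self.max_num_h + 1)))
            + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
            + [1.0 if atom.GetIsAromatic() else 0.0]
            + [atom.GetMass() / self.mass_scale]
        )
        return np.asarray(vec)

    def bond_features(self, bond: Chem.Bond) -> np.ndarray:
        vec = (
            _one_hot(bond.GetBondType(), _BOND_TYPES)
            + [1.0 if bond.GetIsConjugated() else 0.0]
            + [1.0 if bond.IsInRing() else 0.0]
            + _one_hot(bond.GetStereo(), _BOND_STEREO)
        )
        return np.asarray(vec)

    def digest(self) -> str:
        """Stable hash of the vocabulary; stored in checkpoints so that a
        model trained under one featurization refuses to load under another."""
        payload = json.dumps(
            {
                "elements": self.elements,
                "max_degree": self.max_degree,
                "charges": self.charges,
                "max_num_h": self.max_num_h,
                "mass_scale": self.mass_scale,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AtomGraph:
    """Featurized molecular graph G = (V, E) with directed bond entries."""

    atoms: np.ndarray                 # (n_atoms, atom_dim)
    bond_src: np.ndarray              # (2 * n_bonds,) directed source indices
    bond_dst: np.ndarray              # (2 * n_bonds,) directed target indices
    bond_features: np.ndarray         # (2 * n_bonds, bond_dim)
    rev_index: np.ndarray             # index of the reverse directed entry
    smiles_canonical: str

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_bonds(self) -> int:
        """Undirected bond count."""
        return self.bond_src.shape[0] // 2

    @property
    def directed_bonds(self):
        """Iterate (src, dst, feature vector) over directed entries."""
        for i in range(self.bond_src.shape[0]):
            yield int(self.bond_src[i]), int(self.bond_dst[i]), self.bond_features[i]


def parse_mol(smiles: str) -> Chem.Mol:
    """Parse SMILES, raising :class:`SmilesParseError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(smiles, "molecule has no heavy atoms")
    return mol


def smiles_to_atom_graph(smiles: str, config: FeatureConfig | None = None) -> AtomGraph:
    """Convert a SMILES string to a featurized :class:`AtomGraph`."""
    config = config or FeatureConfig()
    mol = parse_mol(smiles)

    atoms = np.stack([config.atom_features(a) for a in mol.GetAtoms()]) \
        if mol.GetNumAtoms() else np.zeros((0, config.atom_dim))

    src, dst, feats = [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = config.bond_features(bond)
        src += [u, v]
        dst += [v, u]
        feats += [f, f]
    n_dir = len(src)
    rev = np.arange(n_dir, dtype=np.intp)
    rev[0::2] += 1
    rev[1::2] -= 1
    return AtomGraph(
        atoms=atoms,
        bond_src=np.asarray(src, dtype=np.intp),
        bond_dst=np.asarray(dst, dtype=np.intp),
        bond_features=(
            np.stack(feats) if feats else np.zeros((0, config.bond_dim))
        ),
        rev_index=rev,
        smiles_canonical=Chem.MolToSmiles(mol),
    )
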