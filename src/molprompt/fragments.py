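"""BRICS-augmented molecular view: fragment nodes joined by reaction-typed edges.

The augmented graph keeps the original molecule intact and adds a second,
coarser view: every BRICS-cleavable bond is (virtually) cut, each resulting
connected component becomes a fragment node, and each cut bond becomes a
reaction edge labeled with its unordered pair of BRICS link types (L1..L16,
encoded as two concatenated one-hot blocks sorted by label index). BRICS
never cuts ring bonds, so fragments keep their rings intact; attachment
points are implicitly saturated with hydrogens before featurization, and
fragment membership sets reference only parent heavy atoms.

Molecules with no cleavable bond fall back to a single-fragment graph so a
pretraining corpus never crashes on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem import MACCSkeys

from .featurization import AtomGraph, FeatureConfig, parse_mol, smiles_to_atom_graph

__all__ = [
    "FragmentGraph",
    "N_BRICS_LABELS",
    "REACTION_DIM",
    "FRAGMENT_FEATURE_GROUPS",
    "brics_decompose",
    "featurize_fragment",
    "build_augmented_pair",
    "fragment_feature_dim",
]

N_BRICS_LABELS = 16
REACTION_DIM = 2 * N_BRICS_LABELS

#: the seven fragment attribute groups, in concatenation order
FRAGMENT_FEATURE_GROUPS = (
    "maccs_keys",            # 167 bits
    "element_counts",        # C, N, O, S, P, halogen, other (7 channels)
    "tpsa",                  # topological polar surface area (scaled /100)
    "heavy_atom_count",      # scaled /10
    "ring_count",            # scaled /10
    "h_bond_donors",         # scaled /10
    "h_bond_acceptors",      # scaled /10
)

_HALOGENS = {"F", "Cl", "Br", "I"}


def fragment_feature_dim() -> int:
    return 167 + 7 + 1 + 1 + 1 + 1 + 1


@dataclass
class FragmentGraph:
    """Fragment-level view of a molecule (the augmented graph)."""

    atom_sets: list[frozenset[int]]    # heavy-atom indices in the parent, one set per fragment
    features: np.ndarray               # (n_fragments, fragment_feature_dim)
    edge_src: np.ndarray               # (n_edges,) fragment indices (undirected, stored once)
    edge_dst: np.ndarray
    edge_features: np.ndarray          # (n_edges, REACTION_DIM) sorted label-pair one-hots
    parent_smiles: str

    @property
    def n_fragments(self) -> int:
        return len(self.atom_sets)

    @property
    def n_edges(self) -> int:
        return self.edge_src.shape[0]

    @property
    def fragments(self):
        """Iterate (atom index set, feature vector)."""
        return list(zip(self.atom_sets, self.features))

    @property
    def reaction_edges(self):
        """Iterate (u, v, reaction one-hot)."""
        return [
            (int(self.edge_src[i]), int(self.edge_dst[i]), self.edge_features[i])
            for i in range(self.n_edges)
        ]


def _brics_label(raw: str) -> int:
    """Normalize an RDKit BRICS label ('1'..'16', '7a'/'7b') to 1..16."""
    return int(raw.rstrip("ab"))


def _connected_components(n_atoms: int, bonds: list[tuple[int, int]]) -> list[int]:
    """Union-find component label per atom."""
    parent = list(range(n_atoms))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in bonds:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    roots = [find(i) for i in range(n_atoms)]
    relabel = {r: i for i, r in enumerate(dict.fromkeys(roots))}
    return [relabel[r] for r in roots]


def _fragment_mol(parent: Chem.Mol, atom_set: frozenset[int]) -> Chem.Mol:
    """The fragment as its own molecule, attachment points saturated with H."""
    smi = Chem.MolFragmentToSmiles(parent, atomsToUse=sorted(atom_set), canonical=True)
    frag = Chem.MolFromSmiles(smi)
    if frag is None:  # rare valence edge case: retry without sanitization
        frag = Chem.MolFromSmiles(smi, sanitize=False)
        Chem.SanitizeMol(frag, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
    return frag


def featurize_fragment(atom_set: frozenset[int], parent: Chem.Mol) -> np.ndarray:
    """Seven-attribute fragment feature vector, computed on the fragment as
    its own molecule (attachment points replaced by hydrogens)."""
    frag = _fragment_mol(parent, atom_set)
    maccs = np.asarray(MACCSkeys.GenMACCSKeys(frag).ToList(), dtype=float)  # 167 bits

    counts = dict.fromkeys(("C", "N", "O", "S", "P", "halogen", "other"), 0.0)
    for atom in frag.GetAtoms():
        sym = atom.GetSymbol()
        if sym in counts:
            counts[sym] += 1.0
        elif sym in _HALOGENS:
            counts["halogen"] += 1.0
        else:
            counts["other"] += 1.0
    elem = np.asarray([counts[k] for k in ("C", "N", "O", "S", "P", "halogen", "other")])

    scalars = np.asarray(
        [
            Descriptors.TPSA(frag) / 100.0,
            frag.GetNumHeavyAtoms() / 10.0,
            rdMolDescriptors.CalcNumRings(frag) / 10.0,
            Lipinski.NumHDonors(frag) / 10.0,
            Lipinski.NumHAcceptors(frag) / 10.0,
        ]
    )
    return np.concatenate([maccs, elem / 10.0, scalars])


def brics_decompose(graph: AtomGraph | str) -> FragmentGraph:
    """Cut every BRICS-matching bond and return the fragment-level graph.

    Accepts an :class:`AtomGraph` or a SMILES string. The fragment atom
    sets always partition the parent's heavy atoms; a molecule with no
    BRICS-cleavable bond yields one fragment and no reaction edges.
    """
    smiles = graph.smiles_canonical if isinstance(graph, AtomGraph) else graph
    mol = parse_mol(smiles)
    n = mol.GetNumAtoms()

    brics_bonds = []
    for (u, v), (lu, lv) in BRICS.FindBRICSBonds(mol):
        brics_bonds.append((u, v, _brics_label(lu), _brics_label(lv)))
    cut = {frozenset((u, v)) for u, v, *_ in brics_bonds}

    kept = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        for b in mol.GetBonds()
        if frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())) not in cut
    ]
    comp = _connected_components(n, kept)
    n_frag = max(comp) + 1 if n else 0
    atom_sets = [frozenset(i for i in range(n) if comp[i] == c) for c in range(n_frag)]

    src, dst, feats = [], [], []
    for u, v, lu, lv in brics_bonds:
        cu, cv = comp[u], comp[v]
        if cu == cv:  # defensive: BRICS should never cut ring bonds
            continue
        onehot = np.zeros(REACTION_DIM)
        lo, hi = sorted((lu, lv))
        onehot[lo - 1] = 1.0
        onehot[N_BRICS_LABELS + hi - 1] = 1.0
        src.append(cu)
        dst.append(cv)
        feats.append(onehot)

    features = np.stack([featurize_fragment(s, mol) for s in atom_sets]) \
        if atom_sets else np.zeros((0, fragment_feature_dim()))
    return FragmentGraph(
        atom_sets=atom_sets,
        features=features,
        edge_src=np.asarray(src, dtype=np.intp),
        edge_dst=np.asarray(dst, dtype=np.intp),
        edge_features=np.stack(feats) if feats else np.zeros((0, REACTION_DIM)),
        parent_smiles=Chem.MolToSmiles(mol),
    )


def build_augmented_pair(smiles: str, config: FeatureConfig | None = None) -> tuple[AtomGraph, FragmentGraph]:
    """The positive pair for contrastive training: the untouched atom graph
    and its fragment-level augmented view."""
    atom_graph = smiles_to_atom_graph(smiles, config)
    return atom_graph, brics_decompose(atom_graph)


def fragment_report(smiles: str) -> list[dict]:
    """Per-fragment debug rows (parent smiles, fragment smiles, members, edges)."""
    mol = parse_mol(smiles)
    fg = brics_decompose(smiles)
    rows = []
    for i, atom_set in enumerate(fg.atom_sets):
        rows.append(
            {
                "parent_smiles": fg.parent_smiles,
                "fragment_index": i,
                "fragment_smiles": Chem.MolToSmiles(_fragment_mol(mol, atom_set)),
                "member_atoms": ";".join(str(a) for a in sorted(atom_set)),
                "reaction_edges": ";".join(
                    f"{u}-{v}" for u, v, _ in fg.reaction_edges if i in (u, v)
                ),
            }
        )
    return rows
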