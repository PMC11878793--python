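"""Labeled molecule datasets, CSV ingestion and Bemis-Murcko scaffold splitting."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .featurization import parse_mol

__all__ = ["PropertyDataset", "ScaffoldSplit", "scaffold_split", "murcko_scaffold"]

TASK_KINDS = ("binary_classification", "regression")


@dataclass
class PropertyDataset:
    """Molecules with (possibly multi-task, possibly partially missing) labels.

    ``labels`` is (n, n_tasks); ``mask`` is a boolean array of the same shape,
    True where a label is observed. Missing cells in the input CSV become
    masked-out entries, excluded from both losses and metrics.
    """

    smiles: list[str]
    labels: np.ndarray
    mask: np.ndarray
    task_kind: str
    task_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"task_kind must be one of {TASK_KINDS}, got {self.task_kind!r}")
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype=float))
        if self.labels.shape[0] != len(self.smiles):
            self.labels = self.labels.T
        self.mask = np.asarray(self.mask, dtype=bool).reshape(self.labels.shape)
        if not self.task_names:
            self.task_names = [f"task_{i}" for i in range(self.n_tasks)]

    @property
    def n_tasks(self) -> int:
        return self.labels.shape[1]

    def __len__(self) -> int:
        return len(self.smiles)

    def subset(self, idx) -> "PropertyDataset":
        idx = np.asarray(idx, dtype=int)
        return PropertyDataset(
            smiles=[self.smiles[i] for i in idx],
            labels=self.labels[idx],
            mask=self.mask[idx],
            task_kind=self.task_kind,
            task_names=list(self.task_names),
        )

    @classmethod
    def from_csv(cls, path, task_kind: str) -> "PropertyDataset":
        """Load the standard input CSV: a `smiles` column plus label columns."""
        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise ValueError(f"{path}: required column 'smiles' is missing")
        label_cols = [c for c in df.columns if c != "smiles"]
        labels = df[label_cols].to_numpy(dtype=float) if label_cols else np.zeros((len(df), 0))
        mask = ~np.isnan(labels)
        return cls(
            smiles=df["smiles"].astype(str).tolist(),
            labels=np.nan_to_num(labels),
            mask=mask,
            task_kind=task_kind,
            task_names=label_cols,
        )

    def to_csv(self, path):
        df = pd.DataFrame({"smiles": self.smiles})
        for j, name in enumerate(self.task_names):
            col = self.labels[:, j].astype(object)
            col[~self.mask[:, j]] = np.nan
            df[name] = col
        df.to_csv(path, index=False)


@dataclass
class ScaffoldSplit:
    train_idx: np.ndarray
    valid_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple[float, float, float]

    def as_frame(self, smiles: list[str]) -> pd.DataFrame:
        """Split manifest with columns (index, smiles, split)."""
        rows = []
        for name, idx in (("train", self.train_idx), ("valid", self.valid_idx), ("test", self.test_idx)):
            rows += [(int(i), smiles[int(i)], name) for i in idx]
        return pd.DataFrame(sorted(rows), columns=["index", "smiles", "split"])


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES (empty string for acyclic molecules)."""
    mol = parse_mol(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold) if scaffold is not None else ""


def scaffold_split(
    dataset: PropertyDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    deterministic: bool = True,
    seed: int = 0,
) -> ScaffoldSplit:
    """Partition a dataset so each Bemis-Murcko scaffold lands in one fold.

    Scaffold groups are assigned largest-first (ties broken by scaffold
    string, lexicographically) to train until its share is reached, then to
    valid, then to test; a group that would overflow train falls through to
    the next fold, which keeps valid and test populated even when a few
    scaffolds dominate. With ``deterministic=False`` group order is shuffled
    with ``seed`` instead of sorted.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    n = len(dataset)
    if n < 3:
        raise ValueError(f"dataset must contain at least 3 molecules, got {n}")

    groups: dict[str, list[int]] = {}
    for i, smi in enumerate(dataset.smiles):
        groups.setdefault(murcko_scaffold(smi), []).append(i)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    if not deterministic:
        rng = np.random.default_rng(seed)
        ordered = [ordered[i] for i in rng.permutation(len(ordered))]

    n_train, n_valid = fractions[0] * n, fractions[1] * n
    train, valid, test = [], [], []
    for _, idx in ordered:
        if len(train) + len(idx) <= n_train or not train:
            train += idx
        elif len(valid) + len(idx) <= n_valid or not valid:
            valid += idx
        else:
            test += idx
    return ScaffoldSplit(
        train_idx=np.asarray(sorted(train), dtype=int),
        valid_idx=np.asarray(sorted(valid), dtype=int),
        test_idx=np.asarray(sorted(test), dtype=int),
        fractions=fractions,
    )
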