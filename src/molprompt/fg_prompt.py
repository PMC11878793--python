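"""Functional-group detection and the prompt generator.

A packaged table of 82 named SMARTS patterns defines the functional-group
vocabulary. For a molecule, every substructure match of every pattern
becomes one group occurrence V_i (the same pattern can fire several
times). Each occurrence is embedded by fusing its learnable table row
with the sum and elementwise max of its member atoms' encoder embeddings,

    fg_hat_i = sigma(W . Concat(fg_i, Msum(V_i), Mmax(V_i))),

a learnable task token fg0 is prepended, and single-head self-attention
over {fg0, fg_hat_1..m} followed by an output projection and layer
normalization yields the prompt vector (row 0 of the result). The fg0
attention row doubles as the per-group importance weights reported by
``explain``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem

from ._autodiff import Tensor, concat, segment_max, segment_sum
from ._nn import glorot, layer_norm_rows, softmax_rows, zeros_param
from .encoders import _Module
from .featurization import parse_mol

__all__ = [
    "FunctionalGroupTable",
    "FunctionalGroupAssignment",
    "PromptGenerator",
    "detect_functional_groups",
]


@dataclass(frozen=True)
class FunctionalGroupEntry:
    index: int
    name: str
    smarts: str


class FunctionalGroupTable:
    """Named SMARTS vocabulary (82 entries in the packaged default)."""

    def __init__(self, entries: list[tuple[str, str]]):
        names = [n for n, _ in entries]
        if len(set(names)) != len(names):
            raise ValueError("functional group names must be unique")
        self.entries: list[FunctionalGroupEntry] = []
        self._patterns: list[Chem.Mol] = []
        for i, (name, smarts) in enumerate(entries):
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"SMARTS for {name!r} does not compile: {smarts}")
            self.entries.append(FunctionalGroupEntry(i, name, smarts))
            self._patterns.append(patt)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def index_of(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.index
        raise KeyError(f"no functional group named {name!r} in the table")

    @classmethod
    def from_file(cls, path_or_buffer) -> "FunctionalGroupTable":
        entries = []
        if hasattr(path_or_buffer, "read"):
            lines = path_or_buffer.read().splitlines()
        else:
            with open(path_or_buffer, encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, smarts = line.split("\t")
            entries.append((name, smarts))
        return cls(entries)

    _default = None

    @classmethod
    def default(cls) -> "FunctionalGroupTable":
        """The packaged 82-entry table (cached)."""
        if cls._default is None:
            ref = resources.files("molprompt.data") / "functional_groups.tsv"
            with ref.open("r", encoding="utf-8") as fh:
                cls._default = cls.from_file(fh)
        return cls._default

    def detect(self, molecule: str | Chem.Mol) -> "FunctionalGroupAssignment":
        """All pattern matches, ordered by table index then sorted atom set."""
        mol = parse_mol(molecule) if isinstance(molecule, str) else molecule
        group_ids: list[int] = []
        atom_sets: list[tuple[int, ...]] = []
        for entry, patt in zip(self.entries, self._patterns):
            matches = sorted(
                {tuple(sorted(m)) for m in mol.GetSubstructMatches(patt, uniquify=True)}
            )
            for match in matches:
                group_ids.append(entry.index)
                atom_sets.append(match)
        return FunctionalGroupAssignment(group_ids=group_ids, atom_sets=atom_sets)


@dataclass
class FunctionalGroupAssignment:
    """Per-molecule matches: S = {V_1..V_m} with their table entries."""

    group_ids: list[int]
    atom_sets: list[tuple[int, ...]]

    @property
    def m(self) -> int:
        return len(self.atom_sets)

    def __post_init__(self):
        if len(self.group_ids) != len(self.atom_sets):
            raise ValueError("group_ids and atom_sets must align")
        if any(len(s) == 0 for s in self.atom_sets):
            raise ValueError("every functional-group match must cover at least one atom")


def detect_functional_groups(molecule, table: FunctionalGroupTable | None = None) -> FunctionalGroupAssignment:
    return (table or FunctionalGroupTable.default()).detect(molecule)


@dataclass
class PromptState:
    """Result of the prompt generator for one molecule."""

    fgprompt: Tensor                   # (d_f,) — row 0 of the normalized output
    attention: np.ndarray              # fg0's attention row over {fg0, matches}, sums to 1
    assignment: FunctionalGroupAssignment


class PromptGenerator(_Module):
    """Learnable prompt module: Ftable + fg0 + fusion + self-attention."""

    def __init__(self, table: FunctionalGroupTable | None = None,
                 embed_size: int = 300, atom_hidden_size: int = 300,
                 seed: int = 3, tie_value_to_query: bool = False):
        super().__init__()
        self.table = table or FunctionalGroupTable.default()
        self.embed_size = int(embed_size)
        self.atom_hidden_size = int(atom_hidden_size)
        self.seed = int(seed)
        self.tie_value_to_query = bool(tie_value_to_query)
        d, dh = self.embed_size, self.atom_hidden_size
        rng = np.random.default_rng(seed)
        self._add("Ftable", glorot(rng, len(self.table), d))
        self._add("fg0", glorot(rng, d, d, shape=(d,)))
        self._add("W_fuse", glorot(rng, d + 2 * dh, d))
        self._add("b_fuse", zeros_param(d))
        self._add("W_q", glorot(rng, d, d))
        self._add("W_k", glorot(rng, d, d))
        self._add("W_v", glorot(rng, d, d))
        self._add("W_out", glorot(rng, d, d))
        self._add("ln_gamma", Tensor(np.ones(d), requires_grad=True))
        self._add("ln_beta", zeros_param(d))

    # ------------------------------------------------------------------ fusion
    def fuse_atom_signals(self, assignments: list[FunctionalGroupAssignment],
                          h_atoms: Tensor, atom_offsets: np.ndarray,
                          no_atom_message: bool = False) -> tuple[Tensor, list[np.ndarray]]:
        """Batched fg_hat rows for all matches of all molecules.

        Returns the (n_matches_total, d) fused matrix and, per molecule,
        the row indices of its matches within it.
        """
        p = self.params
        group_ids, flat_atoms, flat_rows, per_mol_rows = [], [], [], []
        row = 0
        for mol_i, asg in enumerate(assignments):
            rows_i = np.arange(row, row + asg.m, dtype=np.intp)
            per_mol_rows.append(rows_i)
            for gid, atoms in zip(asg.group_ids, asg.atom_sets):
                group_ids.append(gid)
                flat_atoms += [a + atom_offsets[mol_i] for a in atoms]
                flat_rows += [row] * len(atoms)
                row += 1
        n_matches = row
        if n_matches == 0:
            return Tensor(np.zeros((0, self.embed_size))), per_mol_rows

        fg_rows = p["Ftable"].gather(np.asarray(group_ids, dtype=np.intp))
        if no_atom_message:
            zeros = Tensor(np.zeros((n_matches, self.atom_hidden_size)))
            m_sum, m_max = zeros, zeros
        else:
            member = h_atoms.gather(np.asarray(flat_atoms, dtype=np.intp))
            m_sum = segment_sum(member, flat_rows, n_matches)
            m_max = segment_max(member, flat_rows, n_matches)
        fused = concat([fg_rows, m_sum, m_max], axis=1) @ p["W_fuse"] + p["b_fuse"]
        return fused.relu(), per_mol_rows

    # --------------------------------------------------------------- attention
    def prompt_attention(self, fg_hat_rows: Tensor | None) -> tuple[Tensor, np.ndarray]:
        """Self-attention over {fg0, fg_hat_1..m}; returns (fgprompt, fg0 row)."""
        p = self.params
        fg0 = p["fg0"].reshape(1, self.embed_size)
        rows = fg0 if fg_hat_rows is None or fg_hat_rows.shape[0] == 0 \
            else concat([fg0, fg_hat_rows], axis=0)
        q = rows @ p["W_q"]
        k = rows @ p["W_k"]
        v = rows @ (p["W_q"] if self.tie_value_to_query else p["W_v"])
        attn = softmax_rows((q @ k.T) * (1.0 / np.sqrt(self.embed_size)))
        out = layer_norm_rows((attn @ v) @ p["W_out"], p["ln_gamma"], p["ln_beta"])
        return out.gather(np.asarray([0], dtype=np.intp)).reshape(self.embed_size), attn.data[0].copy()

    def forward(self, assignments: list[FunctionalGroupAssignment],
                h_atoms: Tensor, atom_offsets: np.ndarray,
                no_atom_message: bool = False) -> tuple[Tensor, list[PromptState]]:
        """Prompts for a batch; returns stacked (n_mols, d) tensor and states."""
        fused, per_mol_rows = self.fuse_atom_signals(
            assignments, h_atoms, atom_offsets, no_atom_message=no_atom_message
        )
        prompts, states = [], []
        for asg, rows_i in zip(assignments, per_mol_rows):
            fg_hat = fused.gather(rows_i) if len(rows_i) else None
            prompt, attn = self.prompt_attention(fg_hat)
            prompts.append(prompt.reshape(1, self.embed_size))
            states.append(PromptState(fgprompt=prompt, attention=attn, assignment=asg))
        return concat(prompts, axis=0), states
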