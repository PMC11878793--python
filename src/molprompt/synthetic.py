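"""Synthetic labeled datasets and the packaged fixture corpus.

The fixture corpus is a curated list of ~200 diverse, parseable molecules
shipped with the package; it stands in for a large unlabeled pretraining
corpus in tests and examples. Synthetic property datasets derive their
labels from functional-group match counts over the same SMARTS table the
model's prompt module uses — deliberately, so recovery experiments isolate
the learning machinery from featurization disagreements. When more
molecules are requested than the corpus holds, the pool is expanded by
recombining the corpus' own BRICS fragments (joins only at compatible
link-type pairs, which the BRICS builder enforces), so every generated
molecule is valence-valid by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import BRICS

from .datasets import PropertyDataset
from .fg_prompt import FunctionalGroupTable

__all__ = ["SyntheticTaskSpec", "load_fixture_corpus", "generate_dataset"]

_corpus_cache: list[str] | None = None


def load_fixture_corpus() -> list[str]:
    """The packaged curated SMILES corpus (canonicalized, deduplicated)."""
    global _corpus_cache
    if _corpus_cache is None:
        ref = resources.files("molprompt.data") / "fixture_corpus.smi"
        seen: dict[str, None] = {}
        with ref.open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                mol = Chem.MolFromSmiles(line)
                if mol is None:
                    raise ValueError(f"fixture corpus contains unparseable SMILES: {line}")
                seen.setdefault(Chem.MolToSmiles(mol), None)
        _corpus_cache = list(seen)
    return list(_corpus_cache)


@dataclass
class SyntheticTaskSpec:
    """Label rule over functional-group match counts.

    Classification rules: ``presence`` of the first group, or ``xor`` /
    ``and`` of the first two. Regression: ``sum_j coefficients[j] *
    count(group_j) + N(0, noise_sigma)``.
    """

    kind: str = "classification"                    # or "regression"
    groups: tuple[str, ...] = ("hydroxyl",)
    combine: str = "presence"                       # presence | xor | and
    coefficients: tuple[float, ...] = (1.0,)
    noise_sigma: float = 0.0
    n_molecules: int = 800
    seed: int = 0
    positive_range: tuple[float, float] = (0.3, 0.7)

    def validate(self, table: FunctionalGroupTable):
        for g in self.groups:
            table.index_of(g)  # raises KeyError when absent
        if self.kind not in ("classification", "regression"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.kind == "classification" and self.combine not in ("presence", "xor", "and"):
            raise ValueError(f"unknown combine rule {self.combine!r}")
        if self.kind == "regression" and len(self.coefficients) != len(self.groups):
            raise ValueError("coefficients must align with groups")


def _group_counts(smiles: str, groups, table: FunctionalGroupTable) -> list[int]:
    """Match counts of just the rule's patterns (consistent with full detection)."""
    mol = Chem.MolFromSmiles(smiles)
    out = []
    for g in groups:
        patt = Chem.MolFromSmarts(table.entries[table.index_of(g)].smarts)
        out.append(len({tuple(sorted(m)) for m in mol.GetSubstructMatches(patt, uniquify=True)}))
    return out


def _corpus_fragments(base: list[str], rng: np.random.Generator) -> list[str]:
    frag_smiles = set()
    for smi in base:
        frag_smiles.update(BRICS.BRICSDecompose(Chem.MolFromSmiles(smi)))
    frags = sorted(frag_smiles)
    rng.shuffle(frags)
    return frags


def _recombinant_stream(fragments: list[str], seen: set[str],
                        max_heavy: int = 60, budget: int = 30_000):
    """Yield novel valence-valid SMILES recombined from BRICS fragments
    (the builder joins only compatible link-type pairs)."""
    RDLogger.DisableLog("rdApp.*")
    frag_mols = [Chem.MolFromSmiles(f) for f in fragments]
    builder = BRICS.BRICSBuild(frag_mols, scrambleReagents=False, maxDepth=2)
    for mol in itertools.islice(builder, budget):
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        if mol.GetNumHeavyAtoms() > max_heavy:
            continue
        smi = Chem.MolToSmiles(mol)
        if smi in seen:
            continue
        seen.add(smi)
        yield smi


def generate_dataset(spec: SyntheticTaskSpec,
                     table: FunctionalGroupTable | None = None) -> PropertyDataset:
    """Deterministically build a labeled dataset from the fixture corpus.

    Classification datasets are rebalanced into the configured positive
    range (default 30-70%) by stratified subsampling of the expanded pool.
    """
    table = table or FunctionalGroupTable.default()
    spec.validate(table)
    rng = np.random.default_rng(spec.seed)

    pool = load_fixture_corpus()
    counts = [_group_counts(s, spec.groups, table) for s in pool]

    if spec.kind == "regression":
        if spec.n_molecules > len(pool):
            frags = _corpus_fragments(pool, rng)
            for smi in _recombinant_stream(frags, seen=set(pool)):
                pool.append(smi)
                counts.append(_group_counts(smi, spec.groups, table))
                if len(pool) >= spec.n_molecules:
                    break
        counts_arr = np.asarray(counts)
        idx = rng.choice(len(pool), size=min(spec.n_molecules, len(pool)), replace=False)
        labels = counts_arr[idx] @ np.asarray(spec.coefficients, dtype=float)
        if spec.noise_sigma > 0:
            labels = labels + rng.normal(0.0, spec.noise_sigma, size=len(idx))
        smiles = [pool[i] for i in idx]
        return PropertyDataset(
            smiles=smiles, labels=labels.reshape(-1, 1),
            mask=np.ones((len(idx), 1), dtype=bool),
            task_kind="regression", task_names=["synthetic_value"],
        )

    def rule(c) -> bool:
        present = [ci > 0 for ci in c]
        if spec.combine == "presence":
            return present[0]
        if spec.combine == "xor":
            return present[0] ^ present[1]
        return present[0] & present[1]

    y = np.asarray([rule(c) for c in counts], dtype=bool)
    lo, hi = spec.positive_range
    # target positive share: the corpus' natural rate, clipped into range
    frac = float(np.clip(y.mean(), lo, hi))
    n = spec.n_molecules
    need_pos, need_neg = int(round(frac * n)), n - int(round(frac * n))
    if need_pos > y.sum() or need_neg > (~y).sum():
        # Class-aware expansion. The generic recombinant stream is heavily
        # biased toward the corpus' common groups, so the negative quota is
        # filled from a stream built only from fragments that do not match
        # the rule's patterns themselves; every product's label is still
        # verified on the assembled molecule.
        frags = _corpus_fragments(pool, rng)
        seen = set(pool)
        y_list = list(y)

        def top_up(stream, want_label: bool, quota: int):
            for smi in stream:
                if sum(1 for v in y_list if v == want_label) >= quota:
                    break
                c = _group_counts(smi, spec.groups, table)
                if rule(c) != want_label:
                    continue
                pool.append(smi)
                counts.append(c)
                y_list.append(want_label)

        top_up(_recombinant_stream(frags, seen), True, need_pos)
        neg_frags = [f for f in frags if all(
            c == 0 for c in _group_counts(f, spec.groups, table))]
        top_up(_recombinant_stream(neg_frags, seen), False, need_neg)
        y = np.asarray(y_list, dtype=bool)

    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    n_pos = min(need_pos, len(pos))
    n_neg = min(n - n_pos, len(neg))
    n_pos = min(n - n_neg, len(pos))
    take = np.concatenate([
        rng.choice(pos, size=n_pos, replace=False),
        rng.choice(neg, size=n_neg, replace=False),
    ])
    rng.shuffle(take)
    smiles = [pool[i] for i in take]
    return PropertyDataset(
        smiles=smiles,
        labels=y[take].astype(float).reshape(-1, 1),
        mask=np.ones((len(take), 1), dtype=bool),
        task_kind="binary_classification",
        task_names=["synthetic_label"],
    )
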