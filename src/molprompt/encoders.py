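"""Graph encoders for the two molecular views, plus projection heads.

``AtomGraphEncoder`` is a communicative directed-edge message-passing
network (CMPNN-style): messages live on directed bonds, node states are
refreshed from the sum of incoming messages boosted by their elementwise
maximum, and the reverse-edge message is subtracted so information does
not bounce straight back. ``FragmentGraphEncoder`` passes messages over
fragment nodes with reaction-edge features folded in through attention-
weighted aggregation. Both read out graph embeddings by summing node
states, which makes them invariant to node reindexing and sensitive to
molecule size.

Graphs are encoded in batches as one disjoint union, so a whole training
batch costs a handful of matrix multiplies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, segment_max, segment_sum
from ._nn import glorot, zeros_param
from .featurization import AtomGraph, FeatureConfig
from .fragments import REACTION_DIM, FragmentGraph, fragment_feature_dim

__all__ = [
    "AtomGraphEncoder",
    "FragmentGraphEncoder",
    "ProjectionHead",
    "collate_atom_graphs",
    "collate_fragment_graphs",
]


# --------------------------------------------------------------------- collate
@dataclass
class AtomBatch:
    x: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    edge_x: np.ndarray
    rev: np.ndarray
    graph_ids: np.ndarray          # per-atom graph membership
    n_graphs: int
    atom_offsets: np.ndarray       # first atom index of each graph


def collate_atom_graphs(graphs: list[AtomGraph]) -> AtomBatch:
    """Disjoint-union batch of atom graphs with index offsets applied."""
    xs, srcs, dsts, exs, revs, gids, offsets = [], [], [], [], [], [], []
    a_off = e_off = 0
    for gi, g in enumerate(graphs):
        offsets.append(a_off)
        xs.append(g.atoms)
        srcs.append(g.bond_src + a_off)
        dsts.append(g.bond_dst + a_off)
        exs.append(g.bond_features)
        revs.append(g.rev_index + e_off)
        gids.append(np.full(g.n_atoms, gi, dtype=np.intp))
        a_off += g.n_atoms
        e_off += g.bond_src.shape[0]
    return AtomBatch(
        x=np.concatenate(xs, axis=0),
        src=np.concatenate(srcs),
        dst=np.concatenate(dsts),
        edge_x=np.concatenate(exs, axis=0),
        rev=np.concatenate(revs),
        graph_ids=np.concatenate(gids),
        n_graphs=len(graphs),
        atom_offsets=np.asarray(offsets, dtype=np.intp),
    )


@dataclass
class FragmentBatch:
    x: np.ndarray
    src: np.ndarray                # directed (both directions per reaction edge)
    dst: np.ndarray
    edge_x: np.ndarray
    graph_ids: np.ndarray
    n_graphs: int


def collate_fragment_graphs(graphs: list[FragmentGraph]) -> FragmentBatch:
    xs, srcs, dsts, exs, gids = [], [], [], [], []
    off = 0
    for gi, g in enumerate(graphs):
        xs.append(g.features)
        srcs += [g.edge_src + off, g.edge_dst + off]
        dsts += [g.edge_dst + off, g.edge_src + off]
        exs += [g.edge_features, g.edge_features]
        gids.append(np.full(g.n_fragments, gi, dtype=np.intp))
        off += g.n_fragments
    return FragmentBatch(
        x=np.concatenate(xs, axis=0),
        src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.intp),
        dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.intp),
        edge_x=np.concatenate(exs, axis=0) if exs else np.zeros((0, REACTION_DIM)),
        graph_ids=np.concatenate(gids),
        n_graphs=len(graphs),
    )


# -------------------------------------------------------------------- encoders
class _Module:
    """Tiny parameter-container base: named tensors, seeded construction."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}

    def _add(self, name: str, tensor: Tensor) -> Tensor:
        self.params[name] = tensor
        return tensor

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray], prefix: str = ""):
        for k, p in self.params.items():
            src = arrays[prefix + k]
            if src.shape != p.data.shape:
                raise ValueError(f"parameter {k}: shape {src.shape} != {p.data.shape}")
            p.data = np.array(src, dtype=np.float64)


class AtomGraphEncoder(_Module):
    """Directed-edge communicative message passing over the original graph."""

    def __init__(self, feature_config: FeatureConfig | None = None,
                 hidden_size: int = 300, depth: int = 3, seed: int = 0):
        super().__init__()
        self.feature_config = feature_config or FeatureConfig()
        self.hidden_size = int(hidden_size)
        self.depth = int(depth)
        self.seed = int(seed)
        d, da, db = self.hidden_size, self.feature_config.atom_dim, self.feature_config.bond_dim
        rng = np.random.default_rng(seed)
        self._add("W_in", glorot(rng, da + db, d))
        self._add("b_in", zeros_param(d))
        self._add("W_comm", glorot(rng, 2 * d, d))
        self._add("b_comm", zeros_param(d))
        self._add("W_h", glorot(rng, d, d))
        self._add("W_out", glorot(rng, da + d, d))
        self._add("b_out", zeros_param(d))

    def forward(self, batch: AtomBatch) -> tuple[Tensor, Tensor]:
        """Return (per-atom embeddings H_K, per-graph embeddings h_G)."""
        p = self.params
        x = Tensor(batch.x)
        n_atoms = batch.x.shape[0]
        if batch.src.shape[0]:
            e_in = concat([x.gather(batch.src), Tensor(batch.edge_x)], axis=1)
            h0 = (e_in @ p["W_in"] + p["b_in"]).relu()
            h = h0
            for _ in range(self.depth):
                m = segment_sum(h, batch.dst, n_atoms)
                b = segment_max(h, batch.dst, n_atoms)
                q = (concat([m, b], axis=1) @ p["W_comm"] + p["b_comm"]).relu()
                h = (h0 + (q.gather(batch.src) - h.gather(batch.rev)) @ p["W_h"]).relu()
            m_final = segment_sum(h, batch.dst, n_atoms)
        else:
            m_final = Tensor(np.zeros((n_atoms, self.hidden_size)))
        h_atom = (concat([x, m_final], axis=1) @ p["W_out"] + p["b_out"]).relu()
        h_graph = segment_sum(h_atom, batch.graph_ids, batch.n_graphs)
        return h_atom, h_graph

    def encode(self, graph: AtomGraph) -> tuple[np.ndarray, np.ndarray]:
        """Single-molecule convenience wrapper returning numpy arrays."""
        h_atom, h_graph = self.forward(collate_atom_graphs([graph]))
        return h_atom.data, h_graph.data[0]


class FragmentGraphEncoder(_Module):
    """Attention message passing over fragment nodes with reaction-edge features."""

    def __init__(self, hidden_size: int = 300, depth: int = 2, seed: int = 1):
        super().__init__()
        self.hidden_size = int(hidden_size)
        self.depth = int(depth)
        self.seed = int(seed)
        d, df, de = self.hidden_size, fragment_feature_dim(), REACTION_DIM
        rng = np.random.default_rng(seed)
        self._add("W_in", glorot(rng, df, d))
        self._add("b_in", zeros_param(d))
        self._add("w_att", glorot(rng, 2 * d + de, 1))
        self._add("W_msg", glorot(rng, d + de, d))
        self._add("W_upd", glorot(rng, 2 * d, d))
        self._add("b_upd", zeros_param(d))

    def forward(self, batch: FragmentBatch) -> tuple[Tensor, Tensor]:
        p = self.params
        n_frag = batch.x.shape[0]
        h = (Tensor(batch.x) @ p["W_in"] + p["b_in"]).relu()
        if batch.src.shape[0]:
            e = Tensor(batch.edge_x)
            for _ in range(self.depth):
                h_src, h_dst = h.gather(batch.src), h.gather(batch.dst)
                score = concat([h_src, h_dst, e], axis=1) @ p["w_att"]
                # per-destination softmax over incoming edges
                shift = np.full((n_frag, 1), -np.inf)
                np.maximum.at(shift, batch.dst, score.data)
                ez = (score - Tensor(shift[batch.dst])).exp()
                denom = segment_sum(ez, batch.dst, n_frag)
                alpha = ez / denom.gather(batch.dst)
                msg = concat([h_src, e], axis=1) @ p["W_msg"]
                agg = segment_sum(alpha * msg, batch.dst, n_frag)
                h = (concat([h, agg], axis=1) @ p["W_upd"] + p["b_upd"]).relu()
        h_graph = segment_sum(h, batch.graph_ids, batch.n_graphs)
        return h, h_graph

    def encode(self, graph: FragmentGraph) -> np.ndarray:
        _, h_graph = self.forward(collate_fragment_graphs([graph]))
        return h_graph.data[0]


class ProjectionHead(_Module):
    """Two-layer MLP with a rectifier between the affine maps."""

    def __init__(self, in_size: int, out_size: int = 128, seed: int = 2):
        super().__init__()
        self.in_size, self.out_size, self.seed = int(in_size), int(out_size), int(seed)
        rng = np.random.default_rng(seed)
        self._add("W1", glorot(rng, in_size, in_size))
        self._add("b1", zeros_param(in_size))
        self._add("W2", glorot(rng, in_size, out_size))
        self._add("b2", zeros_param(out_size))

    def forward(self, h: Tensor) -> Tensor:
        p = self.params
        if h.data.shape[-1] != self.in_size:
            raise ValueError(f"projection head expects size {self.in_size}, got {h.data.shape[-1]}")
        return (h @ p["W1"] + p["b1"]).relu() @ p["W2"] + p["b2"]


# ------------------------------------------------------------------ checkpoint
def save_checkpoint(path, modules: dict[str, _Module], config: dict,
                    feature_config: FeatureConfig):
    """Versioned npz checkpoint: config JSON + named parameter arrays.

    Records the featurization digest so a checkpoint trained under one
    atom/bond vocabulary refuses to load under another.
    """
    arrays = {}
    for prefix, mod in modules.items():
        for k, v in mod.state_arrays().items():
            arrays[f"{prefix}.{k}"] = v
    meta = dict(config, format_version=1, feature_digest=feature_config.digest())
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


class CheckpointError(RuntimeError):
    pass


def load_checkpoint(path, feature_config: FeatureConfig | None = None):
    """Return (meta dict, {prefixed name: array}); verifies the feature digest."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    if feature_config is not None and meta.get("feature_digest") != feature_config.digest():
        raise CheckpointError(
            "checkpoint was trained under a different atom/bond featurization "
            f"(digest {meta.get('feature_digest')} != {feature_config.digest()})"
        )
    return meta, arrays
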