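"""Encoder contracts: permutation invariance, determinism, gradient flow."""

import numpy as np
import pytest
from rdkit import Chem

from molprompt._autodiff import Tensor
from molprompt.encoders import (
    AtomGraphEncoder,
    FragmentGraphEncoder,
    ProjectionHead,
    collate_atom_graphs,
    collate_fragment_graphs,
    load_checkpoint,
    save_checkpoint,
)
from molprompt.featurization import FeatureConfig, smiles_to_atom_graph
from molprompt.fragments import brics_decompose


def _permuted_graph(smiles, seed):
    mol = Chem.MolFromSmiles(smiles)
    perm = np.random.default_rng(seed).permutation(mol.GetNumAtoms())
    renumbered = Chem.RenumberAtoms(mol, [int(p) for p in perm])
    return smiles_to_atom_graph(Chem.MolToSmiles(renumbered, canonical=False))


def test_single_atom_molecule_is_transformed_feature_readout():
    enc = AtomGraphEncoder(hidden_size=8, seed=0)
    g = smiles_to_atom_graph("C")
    h_atom, h_graph = enc.forward(collate_atom_graphs([g]))
    x = np.concatenate([g.atoms[0], np.zeros(8)])
    expected = np.maximum(x @ enc.params["W_out"].data + enc.params["b_out"].data, 0)
    np.testing.assert_allclose(h_atom.data[0], expected)
    np.testing.assert_allclose(h_graph.data[0], expected)


def test_atom_encoder_output_width_is_hidden_size():
    enc = AtomGraphEncoder(hidden_size=17, seed=0)
    _, h = enc.forward(collate_atom_graphs([smiles_to_atom_graph("CCO")]))
    assert h.data.shape == (1, 17)


def test_atom_encoder_permutation_invariance(corpus):
    enc = AtomGraphEncoder(hidden_size=32, seed=0)
    for i, smiles in enumerate(corpus[:20]):
        g1 = smiles_to_atom_graph(smiles)
        g2 = _permuted_graph(smiles, seed=i)
        _, h1 = enc.forward(collate_atom_graphs([g1]))
        _, h2 = enc.forward(collate_atom_graphs([g2]))
        np.testing.assert_allclose(h1.data, h2.data, atol=1e-5)


def test_fragment_encoder_permutation_invariance(corpus):
    enc = FragmentGraphEncoder(hidden_size=32, seed=1)
    multi = [s for s in corpus if brics_decompose(s).n_fragments > 1][:20]
    for i, smiles in enumerate(multi):
        fg = brics_decompose(smiles)
        perm = np.random.default_rng(i).permutation(fg.n_fragments)
        inv = np.argsort(perm)
        from molprompt.fragments import FragmentGraph

        shuffled = FragmentGraph(
            atom_sets=[fg.atom_sets[j] for j in perm],
            features=fg.features[perm],
            edge_src=inv[fg.edge_src],
            edge_dst=inv[fg.edge_dst],
            edge_features=fg.edge_features,
            parent_smiles=fg.parent_smiles,
        )
        _, h1 = enc.forward(collate_fragment_graphs([fg]))
        _, h2 = enc.forward(collate_fragment_graphs([shuffled]))
        np.testing.assert_allclose(h1.data, h2.data, atol=1e-5)


def test_single_fragment_graph_is_transformed_feature():
    enc = FragmentGraphEncoder(hidden_size=8, seed=0)
    fg = brics_decompose("CC")
    _, h = enc.forward(collate_fragment_graphs([fg]))
    expected = np.maximum(fg.features[0] @ enc.params["W_in"].data + enc.params["b_in"].data, 0)
    np.testing.assert_allclose(h.data[0], expected)


def test_batched_and_single_encoding_agree(corpus):
    enc = AtomGraphEncoder(hidden_size=16, seed=3)
    graphs = [smiles_to_atom_graph(s) for s in corpus[:5]]
    _, h_batch = enc.forward(collate_atom_graphs(graphs))
    for i, g in enumerate(graphs):
        _, h_one = enc.forward(collate_atom_graphs([g]))
        np.testing.assert_allclose(h_batch.data[i], h_one.data[0], atol=1e-10)


def test_same_seed_gives_bit_identical_parameters():
    e1 = AtomGraphEncoder(hidden_size=16, seed=42)
    e2 = AtomGraphEncoder(hidden_size=16, seed=42)
    for k in e1.params:
        np.testing.assert_array_equal(e1.params[k].data, e2.params[k].data)
    e3 = AtomGraphEncoder(hidden_size=16, seed=43)
    assert any(not np.array_equal(e1.params[k].data, e3.params[k].data) for k in e1.params)


def test_every_encoder_parameter_receives_gradient():
    enc = AtomGraphEncoder(hidden_size=8, seed=0)
    g = smiles_to_atom_graph("CC(=O)Oc1ccccc1C(=O)O")
    _, h = enc.forward(collate_atom_graphs([g]))
    (h * h).sum().backward()
    for k, p in enc.params.items():
        assert p.grad is not None and np.abs(p.grad).max() > 0, f"dead parameter {k}"

    fenc = FragmentGraphEncoder(hidden_size=8, seed=1)
    fg = brics_decompose("CC(=O)Oc1ccccc1C(=O)O")
    _, hf = fenc.forward(collate_fragment_graphs([fg]))
    (hf * hf).sum().backward()
    for k, p in fenc.params.items():
        assert p.grad is not None and np.abs(p.grad).max() > 0, f"dead parameter {k}"


def test_projection_head_matches_manual_arithmetic():
    head = ProjectionHead(2, 2, seed=0)
    head.params["W1"].data = np.array([[1.0, 2.0], [0.0, 1.0]])
    head.params["b1"].data = np.array([0.5, -4.0])
    head.params["W2"].data = np.array([[1.0, 0.0], [1.0, 1.0]])
    head.params["b2"].data = np.array([0.0, 1.0])
    x = np.array([[1.0, 1.0]])
    # hidden = relu([1,1]@W1 + b1) = relu([1.5, -1.0]) = [1.5, 0]
    # out = [1.5, 0]@W2 + b2 = [1.5, 1.0]
    out = head.forward(Tensor(x))
    np.testing.assert_allclose(out.data, [[1.5, 1.0]])


def test_projection_zero_input_zero_biases_gives_zero():
    head = ProjectionHead(4, 3, seed=0)  # biases initialize to zero
    out = head.forward(Tensor(np.zeros((2, 4))))
    np.testing.assert_allclose(out.data, 0.0)


def test_projection_rejects_wrong_width():
    with pytest.raises(ValueError):
        ProjectionHead(4, 3, seed=0).forward(Tensor(np.zeros((1, 5))))


def test_checkpoint_round_trip_is_bit_identical(tmp_path):
    cfg = FeatureConfig()
    enc = AtomGraphEncoder(cfg, hidden_size=8, seed=5)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, {"encoder": enc}, {"hidden_size": 8, "depth": 3}, cfg)
    meta, arrays = load_checkpoint(path, cfg)
    assert meta["hidden_size"] == 8
    enc2 = AtomGraphEncoder(cfg, hidden_size=8, seed=99)
    enc2.load_state_arrays(arrays, prefix="encoder.")
    for k in enc.params:
        np.testing.assert_array_equal(enc.params[k].data, enc2.params[k].data)


def test_checkpoint_refuses_mismatched_featurization(tmp_path):
    from molprompt.encoders import CheckpointError

    cfg = FeatureConfig()
    enc = AtomGraphEncoder(cfg, hidden_size=8, seed=5)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, {"encoder": enc}, {}, cfg)
    with pytest.raises(CheckpointError):
        load_checkpoint(path, FeatureConfig(max_degree=6))
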