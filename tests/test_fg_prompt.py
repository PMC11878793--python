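"""Functional-group table, detection, atom-signal fusion, prompt attention."""

import numpy as np
import pytest
from rdkit import Chem

from molprompt._autodiff import Tensor
from molprompt.fg_prompt import (
    FunctionalGroupAssignment,
    FunctionalGroupTable,
    PromptGenerator,
    detect_functional_groups,
)


def test_packaged_table_has_82_unique_compiling_entries(fg_table):
    assert len(fg_table) == 82
    assert len(set(fg_table.names)) == 82
    for e in fg_table.entries:
        assert Chem.MolFromSmarts(e.smarts) is not None


def test_duplicate_names_rejected():
    with pytest.raises(ValueError, match="unique"):
        FunctionalGroupTable([("a", "[OX2H]"), ("a", "[NX3]")])


def test_bad_smarts_rejected():
    with pytest.raises(ValueError, match="compile"):
        FunctionalGroupTable([("broken", "[[")])


def test_ethanol_hydroxyl_match_contains_oxygen(fg_table):
    asg = fg_table.detect("CCO")
    hyd = fg_table.index_of("hydroxyl")
    matches = [s for g, s in zip(asg.group_ids, asg.atom_sets) if g == hyd]
    assert matches == [(2,)]  # the oxygen atom of C-C-O


def test_molecule_without_matches_yields_m_zero():
    table = FunctionalGroupTable([("nitrile", "[CX2]#[NX1]")])
    assert table.detect("C").m == 0


def test_detection_matches_direct_smarts_oracle(fg_table):
    """Full detection on phenol equals pattern-by-pattern substructure
    matching done directly with the toolkit."""
    smiles = "Oc1ccccc1"
    mol = Chem.MolFromSmiles(smiles)
    expected = []
    for e in fg_table.entries:
        patt = Chem.MolFromSmarts(e.smarts)
        for match in sorted({tuple(sorted(m)) for m in mol.GetSubstructMatches(patt)}):
            expected.append((e.index, match))
    asg = fg_table.detect(smiles)
    assert list(zip(asg.group_ids, asg.atom_sets)) == expected


def test_detection_order_is_deterministic(fg_table):
    a1 = fg_table.detect("CC(=O)Oc1ccccc1C(=O)O")
    a2 = fg_table.detect("CC(=O)Oc1ccccc1C(=O)O")
    assert a1.group_ids == a2.group_ids
    assert a1.atom_sets == a2.atom_sets


def test_empty_match_set_rejected():
    with pytest.raises(ValueError):
        FunctionalGroupAssignment(group_ids=[0], atom_sets=[()])


# -------------------------------------------------------------------- fusion
def _tiny_prompt(d=4, dh=3):
    return PromptGenerator(
        FunctionalGroupTable([("hydroxyl", "[OX2H]"), ("amine", "[NX3]")]),
        embed_size=d, atom_hidden_size=dh, seed=0,
    )


def test_single_atom_fusion_sum_equals_max():
    gen = _tiny_prompt()
    hk = Tensor(np.arange(12.0).reshape(4, 3))
    asg = FunctionalGroupAssignment(group_ids=[0], atom_sets=[(2,)])
    # with |Vi| = 1, Msum and Mmax both equal that atom's embedding row
    fused, rows = gen.fuse_atom_signals([asg], hk, np.array([0]))
    w, b = gen.params["W_fuse"].data, gen.params["b_fuse"].data
    fg_row = gen.params["Ftable"].data[0]
    manual = np.maximum(np.concatenate([fg_row, hk.data[2], hk.data[2]]) @ w + b, 0)
    np.testing.assert_allclose(fused.data[0], manual)


def test_sum_pool_is_linear_and_max_pool_is_elementwise():
    gen = _tiny_prompt()
    hk_data = np.array([[1.0, -2.0, 3.0], [4.0, 0.0, -1.0], [0.5, 5.0, 2.0]])
    hk = Tensor(hk_data)
    asg = FunctionalGroupAssignment(
        group_ids=[0, 0, 0], atom_sets=[(0,), (1,), (0, 1, 2)]
    )
    # probe the pooled values through a W_fuse set to read them out directly
    d, dh = gen.embed_size, gen.atom_hidden_size
    gen.params["W_fuse"].data = np.zeros((d + 2 * dh, d))
    gen.params["W_fuse"].data[d:d + dh, :dh] = np.eye(dh)  # expose Msum
    gen.params["b_fuse"].data[:] = 100.0  # keep relu inactive
    fused, _ = gen.fuse_atom_signals([asg], hk, np.array([0]))
    np.testing.assert_allclose(
        fused.data[2, :dh] - 100.0,
        (fused.data[0, :dh] - 100.0) + (fused.data[1, :dh] - 100.0) + hk_data[2],
    )
    gen.params["W_fuse"].data[:] = 0.0
    gen.params["W_fuse"].data[d + dh:, :dh] = np.eye(dh)  # expose Mmax
    fused, _ = gen.fuse_atom_signals([asg], hk, np.array([0]))
    np.testing.assert_allclose(fused.data[2, :dh] - 100.0, hk_data.max(axis=0))


def test_no_atom_message_zeroes_the_pooled_signals():
    gen = _tiny_prompt()
    hk = Tensor(np.ones((3, 3)) * 7.0)
    asg = FunctionalGroupAssignment(group_ids=[0], atom_sets=[(0, 1)])
    fused_off, _ = gen.fuse_atom_signals([asg], hk, np.array([0]), no_atom_message=True)
    zeros = Tensor(np.zeros((3, 3)))
    fused_ref, _ = gen.fuse_atom_signals([asg], zeros, np.array([0]))
    np.testing.assert_allclose(fused_off.data, fused_ref.data)


# ----------------------------------------------------------------- attention
def test_attention_rows_are_probability_vectors(fg_table):
    gen = PromptGenerator(fg_table, embed_size=8, atom_hidden_size=8, seed=1)
    rng = np.random.default_rng(0)
    fg_hat = Tensor(rng.normal(size=(5, 8)))
    _, attn_row = gen.prompt_attention(fg_hat)
    assert attn_row.shape == (6,)
    assert attn_row.sum() == pytest.approx(1.0, abs=1e-6)
    assert (attn_row >= 0).all()


def test_empty_molecule_prompt_depends_on_fg0_alone(fg_table):
    gen = PromptGenerator(fg_table, embed_size=8, atom_hidden_size=8, seed=2)
    prompt, attn = gen.prompt_attention(None)
    assert attn.shape == (1,)
    assert attn[0] == pytest.approx(1.0)
    # perturbing the table must not change the m=0 prompt
    before = prompt.data.copy()
    gen.params["Ftable"].data += 5.0
    after, _ = gen.prompt_attention(None)
    np.testing.assert_array_equal(before, after.data)


def test_prompt_invariant_to_functional_group_ordering(fg_table):
    gen = PromptGenerator(fg_table, embed_size=8, atom_hidden_size=8, seed=3)
    rng = np.random.default_rng(4)
    fg_hat = rng.normal(size=(6, 8))
    base, base_attn = gen.prompt_attention(Tensor(fg_hat))
    for trial in range(10):
        perm = np.random.default_rng(trial).permutation(6)
        prompt, attn = gen.prompt_attention(Tensor(fg_hat[perm]))
        np.testing.assert_allclose(prompt.data, base.data, atol=1e-6)
        # fg0's weights follow the permutation of the rows beneath it
        np.testing.assert_allclose(attn[1:], base_attn[1:][perm], atol=1e-6)


def test_reported_weights_are_the_forward_attention_row(fg_table):
    """The explain weights must be the very distribution used to mix the
    value rows — recompute the softmax by hand and compare."""
    gen = PromptGenerator(fg_table, embed_size=4, atom_hidden_size=4, seed=5)
    rng = np.random.default_rng(6)
    fg_hat = rng.normal(size=(3, 4))
    _, attn = gen.prompt_attention(Tensor(fg_hat))
    rows = np.vstack([gen.params["fg0"].data, fg_hat])
    q = rows @ gen.params["W_q"].data
    k = rows @ gen.params["W_k"].data
    scores = (q @ k.T)[0] / np.sqrt(4)
    manual = np.exp(scores - scores.max())
    manual /= manual.sum()
    np.testing.assert_allclose(attn, manual, atol=1e-12)


def test_tied_value_projection_flag_changes_output(fg_table):
    rng = np.random.default_rng(7)
    fg_hat = Tensor(rng.normal(size=(3, 8)))
    g_tied = PromptGenerator(fg_table, embed_size=8, atom_hidden_size=8,
                             seed=8, tie_value_to_query=True)
    g_free = PromptGenerator(fg_table, embed_size=8, atom_hidden_size=8,
                             seed=8, tie_value_to_query=False)
    p_tied, _ = g_tied.prompt_attention(fg_hat)
    p_free, _ = g_free.prompt_attention(fg_hat)
    assert not np.allclose(p_tied.data, p_free.data)


def test_detect_functional_groups_uses_default_table():
    asg = detect_functional_groups("CCO")
    assert asg.m > 0
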