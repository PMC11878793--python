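"""Fine-tuning head, objective, ablations and model persistence."""

import numpy as np
import pytest

from molprompt._autodiff import Tensor
from molprompt.models import (
    PromptedMoleculeClassifier,
    PromptedMoleculeRegressor,
    finetune_objective,
)

SMILES = ["CCO", "CCN", "CCC", "CCCO", "c1ccccc1O", "c1ccccc1", "CC(=O)O", "CCCC"]
LABELS = [1, 0, 0, 1, 1, 0, 1, 0]  # hydroxyl-ish rule by hand

FAST = dict(hidden_size=12, epochs=2, batch_size=4, seed=0)


def test_objective_without_penalty_is_plain_task_loss():
    preds = np.array([[0.3], [-0.2]])
    labels = np.array([[1.0], [0.0]])
    with_pen = finetune_objective(preds, labels, None, np.ones((2, 2)), 0.0, "binary_classification")
    manual = np.mean(np.log1p(np.exp(-np.abs(preds))) + np.maximum(preds, 0) - preds * labels)
    assert with_pen.item() == pytest.approx(manual)


def test_penalty_term_is_gamma_times_sum_of_squares():
    ftable = np.array([[1.0, 2.0], [3.0, 4.0]])
    preds = labels = np.array([[1.0]])
    base = finetune_objective(preds, labels, None, ftable, 0.0, "regression").item()
    with_pen = finetune_objective(preds, labels, None, ftable, 0.5, "regression").item()
    assert with_pen - base == pytest.approx(0.5 * 30.0)  # 1+4+9+16 = 30


def test_perfect_regression_with_zero_gamma_is_zero():
    y = np.array([[1.5], [-2.0]])
    assert finetune_objective(y, y, None, None, 0.0, "regression").item() == 0.0


def test_masked_entries_do_not_contribute():
    preds = np.array([[0.0, 100.0]])
    labels = np.array([[0.0, 0.0]])
    mask = np.array([[True, False]])
    full = finetune_objective(preds, labels, mask, None, 0.0, "regression").item()
    assert full == 0.0  # the wildly wrong masked entry is ignored


def test_fully_masked_labels_rejected():
    with pytest.raises(ValueError):
        finetune_objective(np.ones((1, 1)), np.ones((1, 1)), np.zeros((1, 1)), None, 0.0, "regression")


def test_prediction_head_matches_manual_arithmetic():
    model = PromptedMoleculeRegressor(hidden_size=2, prompt_size=2, mlp_hidden=2, seed=0)
    model._build(n_tasks=1)
    model.head_["W1"].data = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.0, 0.0]])
    model.head_["b1"].data = np.zeros(2)
    model.head_["W2"].data = np.array([[2.0], [1.0]])
    model.head_["b2"].data = np.array([0.5])
    h_g = Tensor(np.array([[1.0, 2.0]]))
    prompt = Tensor(np.array([[3.0, 0.0]]))
    model.alpha_.data = np.array([1.0])
    h_hat = np.concatenate([h_g.data, prompt.data], axis=1)  # [1, 2, 3, 0]
    hidden = np.maximum(h_hat @ model.head_["W1"].data, 0)   # [4, 5]
    expected = hidden @ model.head_["W2"].data + 0.5          # 2*4 + 5 + 0.5
    assert expected[0, 0] == pytest.approx(13.5)
    from molprompt._autodiff import concat

    logits = (concat([h_g, prompt * model.alpha_], axis=1) @ model.head_["W1"]
              + model.head_["b1"]).relu() @ model.head_["W2"] + model.head_["b2"]
    assert logits.data[0, 0] == pytest.approx(13.5)


def test_alpha_zero_makes_predictions_prompt_invariant():
    model = PromptedMoleculeClassifier(alpha_init=0.0, learning_rate=0.0, **FAST)
    model.fit(SMILES, LABELS)
    base = model.decision_function(SMILES)
    model.prompt_.params["Ftable"].data += 10.0  # arbitrary prompt change
    model.prompt_.params["fg0"].data -= 3.0
    np.testing.assert_allclose(model.decision_function(SMILES), base, atol=1e-12)


def test_concatenated_embedding_width():
    model = PromptedMoleculeClassifier(hidden_size=6, prompt_size=5, epochs=1,
                                       batch_size=4, seed=0)
    model.fit(SMILES, LABELS)
    assert model.head_["W1"].data.shape[0] == 6 + 5


def test_training_decreases_objective():
    model = PromptedMoleculeClassifier(hidden_size=16, epochs=10, batch_size=8, seed=1)
    model.fit(SMILES, LABELS)
    assert model.objective_history_[-1] < model.objective_history_[0]


def test_same_seed_reproduces_metrics_exactly():
    m1 = PromptedMoleculeClassifier(**FAST).fit(SMILES, LABELS)
    m2 = PromptedMoleculeClassifier(**FAST).fit(SMILES, LABELS)
    np.testing.assert_array_equal(m1.decision_function(SMILES), m2.decision_function(SMILES))


def test_no_fg_prompt_ablation_trains_and_blocks_explain():
    model = PromptedMoleculeClassifier(no_fg_prompt=True, **FAST).fit(SMILES, LABELS)
    assert model.predict(SMILES).shape == (len(SMILES),)
    with pytest.raises(RuntimeError):
        model.explain(SMILES)


def test_no_atom_message_ablation_trains():
    model = PromptedMoleculeClassifier(no_atom_message=True, **FAST).fit(SMILES, LABELS)
    assert np.isfinite(model.decision_function(SMILES)).all()


def test_explain_respects_threshold_and_sorting():
    model = PromptedMoleculeClassifier(**FAST).fit(SMILES, LABELS)
    reports = model.explain(SMILES, weight_threshold=0.05)
    assert len(reports) == len(SMILES)
    for rows in reports:
        weights = [r["weight"] for r in rows]
        assert all(w >= 0.05 for w in weights)
        assert weights == sorted(weights, reverse=True)


def test_explain_weights_sum_to_one_before_filtering():
    model = PromptedMoleculeClassifier(**FAST).fit(SMILES, LABELS)
    reports = model.explain(["CCO"], weight_threshold=0.0)
    asg = model.prompt_.table.detect("CCO")
    total = sum(r["weight"] for r in reports[0])
    # the missing mass is exactly fg0's own weight
    assert 0.0 < total < 1.0
    assert len(reports[0]) == asg.m


def test_early_stopping_restores_best_parameters():
    model = PromptedMoleculeClassifier(hidden_size=12, epochs=30, batch_size=4,
                                       patience=3, seed=0)
    model.fit(SMILES[:6], LABELS[:6], validation=(SMILES[6:], LABELS[6:]))
    assert len(model.validation_history_) <= 30
    assert model.best_validation_metric_ is not None


def test_model_checkpoint_round_trips_bit_identically(tmp_path):
    model = PromptedMoleculeClassifier(**FAST).fit(SMILES, LABELS)
    p1 = tmp_path / "m1.npz"
    model.save(p1)
    loaded = PromptedMoleculeClassifier.load(p1)
    np.testing.assert_array_equal(
        model.decision_function(SMILES), loaded.decision_function(SMILES)
    )
    p2 = tmp_path / "m2.npz"
    loaded.save(p2)
    with np.load(p1) as z1, np.load(p2) as z2:
        assert set(z1.files) == set(z2.files)
        for k in z1.files:
            if k != "__meta__":
                np.testing.assert_array_equal(z1[k], z2[k])


def test_incompatible_pretrained_encoder_rejected(small_corpus):
    from molprompt.contrastive import ContrastivePretrainer

    pre = ContrastivePretrainer(hidden_size=8, projection_size=8, epochs=1,
                                batch_size=8, seed=0).fit(small_corpus[:10])
    model = PromptedMoleculeClassifier(hidden_size=16, pretrained=pre, epochs=1, seed=0)
    with pytest.raises(ValueError, match="does not match"):
        model.fit(SMILES, LABELS)


def test_regressor_predicts_real_values():
    y = [0.0, 1.0, 2.0, 0.0, 3.0, 1.0, 2.0, 0.0]
    model = PromptedMoleculeRegressor(**FAST).fit(SMILES, y)
    pred = model.predict(SMILES)
    assert pred.shape == (len(SMILES),)
    assert np.isfinite(pred).all()
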