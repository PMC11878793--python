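"""Downstream property prediction with functional-group prompts.

The predictor concatenates the graph embedding h_G with the prompt vector
scaled by a learnable factor alpha,

    h_hat = Concat(h_G, alpha * fgprompt),    y_hat = MLP(h_hat),

and minimizes the task loss (binary cross entropy with logits for
classification, mean squared error for regression; missing labels are
masked out) plus an L2 penalty gamma * ||Ftable||^2 on the functional-
group embedding table. The molecular encoder is initialized from a
contrastive-pretraining checkpoint and fine-tuned jointly with the prompt
module, the prediction head and alpha.

Ablation flags reproduce the variant models: ``no_pretrain`` starts the
encoder from scratch, ``no_atom_message`` removes the atom-signal fusion
inside the prompt, ``no_fg_prompt`` replaces the prompt slot with zeros.

Estimators follow sklearn conventions (``fit``/``predict``/``get_params``,
fitted attributes with a trailing underscore) and compose with sklearn
model selection.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from ._autodiff import Adam, Tensor, concat
from ._nn import glorot, zeros_param
from .contrastive import ContrastivePretrainer
from .encoders import AtomGraphEncoder, collate_atom_graphs, load_checkpoint
from .featurization import FeatureConfig, smiles_to_atom_graph
from .fg_prompt import FunctionalGroupTable, PromptGenerator
from .metrics import compute_metrics

logger = logging.getLogger(__name__)

__all__ = [
    "PromptedMoleculeClassifier",
    "PromptedMoleculeRegressor",
    "finetune_objective",
    "finetune",
    "PAPER_FINETUNE_PRESET",
]

#: training schedule of the original benchmark runs
PAPER_FINETUNE_PRESET = dict(epochs=100, batch_size=256, patience=15)


def _bce_with_logits(logits: Tensor, labels: Tensor) -> Tensor:
    """Elementwise stable binary cross entropy on raw scores."""
    return logits.relu() - logits * labels + ((-(logits.abs())).exp() + 1.0).log()


def finetune_objective(predictions, labels, mask, ftable, gamma: float,
                       task_kind: str) -> Tensor:
    """Masked task loss plus gamma times the squared Frobenius norm of Ftable."""
    predictions = predictions if isinstance(predictions, Tensor) else Tensor(predictions)
    labels = Tensor(np.atleast_2d(np.asarray(labels, dtype=float)))
    mask = np.atleast_2d(np.asarray(mask, dtype=float)) if mask is not None \
        else np.ones(labels.shape)
    n_obs = mask.sum()
    if n_obs == 0:
        raise ValueError("all labels are masked; objective undefined")
    if task_kind == "binary_classification":
        per_entry = _bce_with_logits(predictions, labels)
    elif task_kind == "regression":
        diff = predictions - labels
        per_entry = diff * diff
    else:
        raise ValueError(f"unknown task_kind {task_kind!r}")
    task_loss = (per_entry * Tensor(mask)).sum() * (1.0 / n_obs)
    if gamma and ftable is not None:
        ftable = ftable if isinstance(ftable, Tensor) else Tensor(ftable)
        task_loss = task_loss + gamma * (ftable * ftable).sum()
    return task_loss


class _PromptedModel(BaseEstimator):
    """Shared machinery of the prompted classifier and regressor."""

    _task_kind: str = ""

    def __init__(self, hidden_size: int = 64, depth: int = 3,
                 prompt_size: int | None = None, mlp_hidden: int | None = None,
                 epochs: int = 30, batch_size: int = 64,
                 learning_rate: float = 1e-3, gamma: float = 1e-4,
                 alpha_init: float = 1.0, patience: int = 10,
                 pretrained=None, no_pretrain: bool = False,
                 no_atom_message: bool = False, no_fg_prompt: bool = False,
                 tie_value_to_query: bool = False, seed: int = 0):
        self.hidden_size = hidden_size
        self.depth = depth
        self.prompt_size = prompt_size
        self.mlp_hidden = mlp_hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.gamma = gamma
        self.alpha_init = alpha_init
        self.patience = patience
        self.pretrained = pretrained
        self.no_pretrain = no_pretrain
        self.no_atom_message = no_atom_message
        self.no_fg_prompt = no_fg_prompt
        self.tie_value_to_query = tie_value_to_query
        self.seed = seed

    # -------------------------------------------------------------- components
    def _build(self, n_tasks: int):
        cfg = FeatureConfig()
        d_h = self.hidden_size
        d_f = self.prompt_size or d_h
        d_m = self.mlp_hidden or d_h
        ss = np.random.SeedSequence(self.seed)
        s_enc, s_prompt, s_head = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))

        self.feature_config_ = cfg
        self.encoder_ = AtomGraphEncoder(cfg, d_h, self.depth, seed=s_enc)
        if self.pretrained is not None and not self.no_pretrain:
            self._load_pretrained(cfg)
        self.prompt_ = PromptGenerator(
            FunctionalGroupTable.default(), embed_size=d_f, atom_hidden_size=d_h,
            seed=s_prompt, tie_value_to_query=self.tie_value_to_query,
        )
        rng = np.random.default_rng(s_head)
        self.head_ = {
            "W1": glorot(rng, d_h + d_f, d_m),
            "b1": zeros_param(d_m),
            "W2": glorot(rng, d_m, n_tasks),
            "b2": zeros_param(n_tasks),
        }
        self.alpha_ = Tensor(np.asarray([float(self.alpha_init)]), requires_grad=True)
        self.n_tasks_ = n_tasks
        self._d_f = d_f

    def _load_pretrained(self, cfg: FeatureConfig):
        src = self.pretrained
        if isinstance(src, ContrastivePretrainer):
            arrays = {f"encoder.{k}": v for k, v in src.encoder_.state_arrays().items()}
            if src.hidden_size != self.hidden_size or src.depth != self.depth:
                raise ValueError(
                    "pretrained encoder size "
                    f"({src.hidden_size}, depth {src.depth}) does not match "
                    f"({self.hidden_size}, depth {self.depth})"
                )
        else:
            meta, arrays = load_checkpoint(src, feature_config=cfg)
            if meta["hidden_size"] != self.hidden_size or meta["depth"] != self.depth:
                raise ValueError(
                    f"checkpoint hidden_size/depth {meta['hidden_size']}/{meta['depth']} "
                    f"incompatible with model {self.hidden_size}/{self.depth}"
                )
        self.encoder_.load_state_arrays(arrays, prefix="encoder.")

    def _trainable(self) -> dict[str, Tensor]:
        params = {f"encoder.{k}": v for k, v in self.encoder_.params.items()}
        if not self.no_fg_prompt:
            params.update({f"prompt.{k}": v for k, v in self.prompt_.params.items()})
        params.update({f"head.{k}": v for k, v in self.head_.items()})
        params["alpha"] = self.alpha_
        return params

    # ----------------------------------------------------------------- forward
    def _prepare(self, smiles: list[str]):
        graphs = [smiles_to_atom_graph(s, self.feature_config_) for s in smiles]
        if self.no_fg_prompt:
            assignments = [None] * len(smiles)
        else:
            assignments = [self.prompt_.table.detect(s) for s in smiles]
        return graphs, assignments

    def _forward(self, graphs, assignments, return_states: bool = False):
        batch = collate_atom_graphs(graphs)
        h_atoms, h_graph = self.encoder_.forward(batch)
        states = None
        if self.no_fg_prompt:
            prompts = Tensor(np.zeros((len(graphs), self._d_f)))
        else:
            prompts, states = self.prompt_.forward(
                assignments, h_atoms, batch.atom_offsets,
                no_atom_message=self.no_atom_message,
            )
        h_hat = concat([h_graph, prompts * self.alpha_], axis=1)
        hd = self.head_
        logits = (h_hat @ hd["W1"] + hd["b1"]).relu() @ hd["W2"] + hd["b2"]
        return (logits, states) if return_states else (logits, None)

    # ----------------------------------------------------------------- fitting
    def fit(self, X, y, mask=None, validation=None):
        """Fit on SMILES ``X`` and labels ``y``.

        ``mask`` marks observed labels in multi-task settings (True =
        observed). ``validation`` is an optional ``(X_valid, y_valid)`` or
        ``(X_valid, y_valid, mask_valid)`` tuple used for early stopping
        with the configured patience; without it the model trains for the
        full epoch budget.
        """
        smiles = list(X)
        y = np.asarray(y, dtype=float)
        y = y.reshape(len(smiles), -1)
        mask = np.ones(y.shape, dtype=bool) if mask is None \
            else np.asarray(mask, dtype=bool).reshape(y.shape)
        self._build(n_tasks=y.shape[1])
        graphs, assignments = self._prepare(smiles)

        params = self._trainable()
        opt = Adam(params, lr=self.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 977)).generate_state(1)[0] % (2**31))

        val = None
        if validation is not None:
            xv, yv = validation[0], np.asarray(validation[1], dtype=float).reshape(len(validation[0]), -1)
            mv = np.asarray(validation[2], dtype=bool).reshape(yv.shape) if len(validation) > 2 \
                else np.ones(yv.shape, dtype=bool)
            val = (self._prepare(list(xv)), yv, mv)

        best_metric, best_state, stall = None, None, 0
        self.objective_history_ = []
        self.validation_history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(len(smiles))
            losses = []
            for start in range(0, len(smiles), self.batch_size):
                idx = order[start:start + self.batch_size]
                if not mask[idx].any():
                    continue
                logits, _ = self._forward([graphs[i] for i in idx], [assignments[i] for i in idx])
                ftable = None if self.no_fg_prompt else self.prompt_.params["Ftable"]
                loss = finetune_objective(logits, y[idx], mask[idx], ftable, self.gamma, self._task_kind)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            self.objective_history_.append(float(np.mean(losses)))

            if val is not None:
                (vg, va), yv, mv = val
                scores, _ = self._forward(vg, va)
                metric, better = self._validation_metric(scores.data, yv, mv)
                self.validation_history_.append(metric)
                if best_metric is None or better(metric, best_metric):
                    best_metric, stall = metric, 0
                    best_state = {k: p.data.copy() for k, p in params.items()}
                else:
                    stall += 1
                    if stall >= self.patience:
                        logger.info("early stop at epoch %d (best %.4f)", epoch + 1, best_metric)
                        break
        if best_state is not None:
            for k, p in params.items():
                p.data = best_state[k]
        self.best_validation_metric_ = best_metric
        return self

    def _validation_metric(self, scores, y, m):
        if self._task_kind == "binary_classification":
            auc = compute_metrics(scores, y, m, self._task_kind)["roc_auc"]
            return auc, lambda a, b: a > b
        rmse = compute_metrics(scores, y, m, self._task_kind)["rmse"]
        return rmse, lambda a, b: a < b

    # --------------------------------------------------------------- inference
    def decision_function(self, X) -> np.ndarray:
        out = []
        smiles = list(X)
        for start in range(0, len(smiles), 256):
            graphs, assignments = self._prepare(smiles[start:start + 256])
            logits, _ = self._forward(graphs, assignments)
            out.append(logits.data)
        scores = np.concatenate(out, axis=0)
        return scores[:, 0] if self.n_tasks_ == 1 else scores

    def explain(self, X, weight_threshold: float = 0.1) -> list[list[dict]]:
        """Per-molecule functional-group importance report.

        For each molecule: rows ``{name, atom_indices, weight}`` for every
        functional-group match whose fg0-row attention weight passes
        ``weight_threshold``, sorted by weight, descending. The weights
        are exactly the attention distribution used in the forward pass
        (fg0 itself included in the softmax), so across {fg0, matches}
        they sum to one before filtering.
        """
        if self.no_fg_prompt:
            raise RuntimeError("explain is unavailable when the prompt is ablated")
        reports = []
        smiles = list(X)
        for start in range(0, len(smiles), 256):
            graphs, assignments = self._prepare(smiles[start:start + 256])
            _, states = self._forward(graphs, assignments, return_states=True)
            for st in states:
                rows = []
                for j, (gid, atoms) in enumerate(
                    zip(st.assignment.group_ids, st.assignment.atom_sets)
                ):
                    w = float(st.attention[j + 1])  # position 0 is fg0
                    if w >= weight_threshold:
                        rows.append(
                            {
                                "name": self.prompt_.table.entries[gid].name,
                                "atom_indices": atoms,
                                "weight": w,
                            }
                        )
                rows.sort(key=lambda r: -r["weight"])
                reports.append(rows)
        return reports

    # -------------------------------------------------------------- checkpoint
    def save(self, path):
        from .encoders import save_checkpoint, _Module

        head = _Module()
        head.params = dict(self.head_, alpha=self.alpha_)
        save_checkpoint(
            path,
            {"encoder": self.encoder_, "prompt": self.prompt_, "head": head},
            config=dict(
                hidden_size=self.hidden_size, depth=self.depth,
                prompt_size=self._d_f, task_kind=self._task_kind,
                n_tasks=self.n_tasks_, params=self.get_params(deep=False) | {"pretrained": None},
            ),
            feature_config=self.feature_config_,
        )

    @classmethod
    def load(cls, path) -> "_PromptedModel":
        meta, arrays = load_checkpoint(path, feature_config=FeatureConfig())
        model = cls(**{k: v for k, v in meta["params"].items()})
        model._build(n_tasks=meta["n_tasks"])
        model.encoder_.load_state_arrays(arrays, prefix="encoder.")
        model.prompt_.load_state_arrays(arrays, prefix="prompt.")
        for k in model.head_:
            model.head_[k].data = np.asarray(arrays[f"head.{k}"], dtype=np.float64)
        model.alpha_.data = np.asarray(arrays["head.alpha"], dtype=np.float64)
        return model


class PromptedMoleculeClassifier(_PromptedModel, ClassifierMixin):
    """Binary (possibly multi-task) molecular property classifier."""

    _task_kind = "binary_classification"

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-scores))
        return np.column_stack([1 - p, p]) if p.ndim == 1 else p

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return (scores > 0).astype(int)


class PromptedMoleculeRegressor(_PromptedModel, RegressorMixin):
    """Molecular property regressor (MSE objective, RMSE/MAE metrics)."""

    _task_kind = "regression"

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X)


def finetune(dataset, split, pretrained=None, seeds=(0, 1, 2), **params) -> dict:
    """Fine-tune on a scaffold-split dataset over several seeds.

    Returns per-seed test metrics, their mean/std aggregates, and the
    fitted models. ``dataset`` is a :class:`~molprompt.datasets.PropertyDataset`,
    ``split`` a :class:`~molprompt.datasets.ScaffoldSplit`.
    """
    cls = PromptedMoleculeClassifier if dataset.task_kind == "binary_classification" \
        else PromptedMoleculeRegressor
    train = dataset.subset(split.train_idx)
    valid = dataset.subset(split.valid_idx)
    test = dataset.subset(split.test_idx)

    per_seed, models = {}, {}
    for seed in seeds:
        model = cls(pretrained=pretrained, seed=seed, **params)
        model.fit(
            train.smiles, train.labels, mask=train.mask,
            validation=(valid.smiles, valid.labels, valid.mask) if len(valid) else None,
        )
        scores = model.decision_function(test.smiles).reshape(len(test), -1)
        per_seed[seed] = compute_metrics(scores, test.labels, test.mask, dataset.task_kind)
        models[seed] = model
        logger.info("seed %d test metrics: %s", seed, per_seed[seed])

    keys = [k for k in next(iter(per_seed.values())) if not k.startswith("per_task")]
    aggregate = {}
    for k in keys:
        vals = [m[k] for m in per_seed.values()]
        aggregate[k] = {"mean": float(np.mean(vals)), "std": float(np.std(vals)),
                        "median": float(np.median(vals))}
    return {"per_seed": per_seed, "aggregate": aggregate, "models": models}
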