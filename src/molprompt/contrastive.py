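"""NT-Xent contrastive objective and pretraining over dual molecular views.

Each molecule contributes a positive pair: its original atom graph and its
fragment-level augmented view. Within a batch of N molecules all 2N
projected embeddings share one anchor pool — for every anchor the positive
is its counterpart view and the denominator ranges over the other 2N - 1
embeddings (cross-view and within-view negatives alike), scored by cosine
similarity scaled by a temperature tau.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._autodiff import Adam, Tensor, concat
from .encoders import (
    AtomGraphEncoder,
    FragmentGraphEncoder,
    ProjectionHead,
    collate_atom_graphs,
    collate_fragment_graphs,
)
from .featurization import FeatureConfig
from .fragments import build_augmented_pair

logger = logging.getLogger(__name__)

__all__ = ["nt_xent_loss", "ContrastivePretrainer", "pretrain"]

#: the hyperparameters used in the original large-scale training run
PAPER_PRETRAIN_PRESET = dict(batch_size=1024, epochs=50, learning_rate=3e-5, temperature=0.1)


def nt_xent_loss(z: Tensor | np.ndarray, z_aug: Tensor | np.ndarray,
                 temperature: float = 0.1) -> Tensor:
    """Normalized temperature-scaled cross entropy over 2N paired embeddings.

    ``z[i]`` and ``z_aug[i]`` are the two views of molecule i. Every one of
    the 2N embeddings serves as an anchor; its per-anchor loss is

        l_i = -log exp(sim(z_i, z_i+) / tau) / sum_{k != i} exp(sim(z_i, z_k) / tau)

    with cosine similarity ``sim``. The mean over the 2N anchors is
    returned. For N = 1 the denominator holds only the positive, so the
    loss is exactly zero; the loss is invariant to rescaling all
    embeddings by any positive constant.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = z if isinstance(z, Tensor) else Tensor(z)
    z_aug = z_aug if isinstance(z_aug, Tensor) else Tensor(z_aug)
    if z.shape != z_aug.shape:
        raise ValueError(f"view shapes differ: {z.shape} vs {z_aug.shape}")
    n = z.shape[0]

    stacked = concat([z, z_aug], axis=0)                      # (2N, d)
    sq_norms = (stacked * stacked).sum(axis=1, keepdims=True)
    if np.any(sq_norms.data <= 0):
        raise ValueError("zero-norm embedding: cosine similarity undefined")
    unit = stacked / sq_norms.sqrt()
    sim = (unit @ unit.T) * (1.0 / temperature)               # (2N, 2N)

    self_mask = Tensor(np.where(np.eye(2 * n, dtype=bool), -np.inf, 0.0))
    masked = sim + self_mask
    shift = Tensor(masked.data.max(axis=1, keepdims=True))
    logsumexp = ((masked - shift).exp().sum(axis=1, keepdims=True)).log() + shift

    pos = (sim * Tensor(_pair_mask(n))).sum(axis=1, keepdims=True)
    return (logsumexp - pos).mean()


def _pair_mask(n: int) -> np.ndarray:
    mask = np.zeros((2 * n, 2 * n))
    mask[np.arange(n), np.arange(n) + n] = 1.0
    mask[np.arange(n) + n, np.arange(n)] = 1.0
    return mask


class ContrastivePretrainer(BaseEstimator, TransformerMixin):
    """Self-supervised pretrainer over (original, fragment-augmented) pairs.

    sklearn-style: ``fit`` takes a sequence of SMILES strings (no labels),
    ``transform`` maps SMILES to graph embeddings from the fitted original-
    graph encoder. Defaults are desk-scale; ``PAPER_PRETRAIN_PRESET`` holds
    the settings of the original large-corpus run.

    Parameters
    ----------
    hidden_size : embedding width d_h of both encoders.
    depth : message-passing rounds of the atom-graph encoder.
    projection_size : output width of the projection heads.
    temperature : NT-Xent temperature tau.
    batch_size, epochs, learning_rate : Adam training schedule.
    seed : fixes initialization and batch shuffling exactly.
    """

    def __init__(self, hidden_size: int = 64, depth: int = 3,
                 projection_size: int = 64, temperature: float = 0.1,
                 batch_size: int = 32, epochs: int = 20,
                 learning_rate: float = 1e-3, seed: int = 0):
        self.hidden_size = hidden_size
        self.depth = depth
        self.projection_size = projection_size
        self.temperature = temperature
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed

    # ----------------------------------------------------------------- fitting
    def fit(self, X, y=None):
        smiles = list(X)
        if not smiles:
            raise ValueError("pretraining corpus is empty")
        pairs = [build_augmented_pair(s) for s in smiles]

        cfg = FeatureConfig()
        ss = np.random.SeedSequence(self.seed)
        s_enc, s_frag, s_proj, s_fproj, s_shuffle = (
            int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
        )
        self.feature_config_ = cfg
        self.encoder_ = AtomGraphEncoder(cfg, self.hidden_size, self.depth, seed=s_enc)
        self.fragment_encoder_ = FragmentGraphEncoder(self.hidden_size, seed=s_frag)
        self.projection_head_ = ProjectionHead(self.hidden_size, self.projection_size, seed=s_proj)
        self.fragment_projection_head_ = ProjectionHead(self.hidden_size, self.projection_size, seed=s_fproj)

        batch_size = self.batch_size
        if batch_size > len(smiles):
            warnings.warn(
                f"batch size {batch_size} exceeds corpus size {len(smiles)}; clamped",
                stacklevel=2,
            )
            batch_size = len(smiles)

        params = {}
        for prefix, mod in self._modules().items():
            params.update({f"{prefix}.{k}": v for k, v in mod.params.items()})
        opt = Adam(params, lr=self.learning_rate)
        rng = np.random.default_rng(s_shuffle)

        self.loss_history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(len(pairs))
            losses = []
            for start in range(0, len(pairs), batch_size):
                batch = [pairs[i] for i in order[start:start + batch_size]]
                if len(batch) < 2:
                    continue  # a single pair carries no contrastive signal
                loss = self._batch_loss(batch)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            self.loss_history_.append(float(np.mean(losses)))
            logger.info("pretrain epoch %d/%d loss %.4f", epoch + 1, self.epochs, self.loss_history_[-1])
        self.n_molecules_ = len(smiles)
        return self

    def _batch_loss(self, batch) -> Tensor:
        z, z_aug = self._project_batch(batch)
        return nt_xent_loss(z, z_aug, self.temperature)

    def _project_batch(self, batch) -> tuple[Tensor, Tensor]:
        atom_batch = collate_atom_graphs([a for a, _ in batch])
        frag_batch = collate_fragment_graphs([f for _, f in batch])
        _, h_graph = self.encoder_.forward(atom_batch)
        _, h_frag = self.fragment_encoder_.forward(frag_batch)
        return self.projection_head_.forward(h_graph), self.fragment_projection_head_.forward(h_frag)

    def _modules(self):
        return {
            "encoder": self.encoder_,
            "fragment_encoder": self.fragment_encoder_,
            "projection_head": self.projection_head_,
            "fragment_projection_head": self.fragment_projection_head_,
        }

    # --------------------------------------------------------------- inference
    def transform(self, X) -> np.ndarray:
        """Graph embeddings h_G of the fitted original-graph encoder."""
        pairs = [build_augmented_pair(s) for s in X]
        _, h_graph = self.encoder_.forward(collate_atom_graphs([a for a, _ in pairs]))
        return h_graph.data

    def pair_projections(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Projected latent vectors (z, z_augmented) for each molecule."""
        pairs = [build_augmented_pair(s) for s in X]
        z, z_aug = self._project_batch(pairs)
        return z.data, z_aug.data

    # -------------------------------------------------------------- checkpoint
    def save(self, path):
        from .encoders import save_checkpoint

        save_checkpoint(
            path,
            self._modules(),
            config=dict(
                hidden_size=self.hidden_size,
                depth=self.depth,
                projection_size=self.projection_size,
                temperature=self.temperature,
            ),
            feature_config=self.feature_config_,
        )


def pretrain(corpus, checkpoint_path=None, **params) -> ContrastivePretrainer:
    """Fit a :class:`ContrastivePretrainer` on a SMILES corpus."""
    model = ContrastivePretrainer(**params).fit(corpus)
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    return model
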