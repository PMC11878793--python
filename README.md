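# molprompt

Molecular property prediction from SMILES via **fragment-contrastive
pretraining** and **functional-group prompt fine-tuning**, with
interpretable per-functional-group attention weights.

Predicting ADMET endpoints, solubility or bioactivity from structure
alone is label-starved: most assay datasets hold a few hundred to a few
thousand molecules. `molprompt` addresses this in two stages, both built
around chemistry that practitioners already trust:

1. **Self-supervised pretraining.** Each molecule is viewed twice: as its
   ordinary atom–bond graph *G*, and as an augmented graph *G̃* obtained
   by cutting every BRICS-cleavable bond — fragment nodes joined by
   reaction-typed edges (the unordered pair of BRICS link labels
   L1…L16). Unlike atom-masking or bond-deletion augmentations, the
   BRICS view never perturbs the chemical environment; it only coarsens
   it. Two encoders — a communicative directed-edge message-passing
   network *f* for *G* and an attention message-passing network *f̃* over
   fragments for *G̃* — are trained with the NT-Xent objective

   ```
   l_i = −log [ exp(sim(z_Gi, z_G̃i)/τ) / Σ_{k≠i} exp(sim(z_Gi, z_k)/τ) ],
   sim(a,b) = aᵀb / (‖a‖‖b‖),   τ = 0.1,
   ```

   where the 2N projected embeddings of a batch of N molecules share one
   anchor pool (cross-view and within-view negatives alike).

2. **Prompted fine-tuning.** A packaged table of 82 named SMARTS
   functional groups is matched against each molecule; every occurrence
   V_i fuses its learnable table embedding fg_i with the sum and
   elementwise max of its member atoms' encoder embeddings,
   `fĝ_i = σ(W·Concat(fg_i, Σ_{v∈V_i} h_v, max_{v∈V_i} h_v))`. A
   learnable task token fg₀ attends over {fg₀, fĝ₁…fĝ_m} by single-head
   self-attention; row 0 of the layer-normalized output is the prompt.
   The predictor scores `ŷ = MLP(Concat(h_G, α·fg_prompt))` with a
   learnable scale α, minimizing the masked task loss plus
   γ‖F_table‖² (binary cross entropy for classification, MSE for
   regression). The fg₀ attention row is reported directly as per-group
   importance weights, so every prediction comes with a ranked list of
   the functional groups it leaned on.

The trainable stack (encoders, attention, training loops) runs on a
compact numpy reverse-mode autodiff module inside the package; RDKit
does all chemistry (parsing, BRICS, SMARTS, MACCS/TPSA descriptors), and
scikit-learn supplies metrics and the estimator conventions.

## Worked example

```python
from molprompt import (ContrastivePretrainer, PromptedMoleculeClassifier,
                       SyntheticTaskSpec, generate_dataset, load_fixture_corpus,
                       scaffold_split)

corpus = load_fixture_corpus()                      # 218 curated molecules
pre = ContrastivePretrainer(seed=0).fit(corpus)     # d_h=64, 20 epochs
print(f"loss {pre.loss_history_[0]:.2f} -> {pre.loss_history_[-1]:.2f}")

spec = SyntheticTaskSpec(kind="classification", groups=("hydroxyl",),
                         n_molecules=800, seed=0)
ds = generate_dataset(spec)                          # labels = hydroxyl presence
split = scaffold_split(ds)
train, valid, test = (ds.subset(i) for i in
                      (split.train_idx, split.valid_idx, split.test_idx))

clf = PromptedMoleculeClassifier(pretrained=pre, seed=0)
clf.fit(train.smiles, train.labels, validation=(valid.smiles, valid.labels))

from molprompt import compute_metrics
auc = compute_metrics(clf.decision_function(test.smiles),
                      test.labels, test.mask, ds.task_kind)["roc_auc"]
print(f"test ROC-AUC {auc:.3f}")
for row in clf.explain(["OCC(O)c1ccccc1"], weight_threshold=0.1)[0][:2]:
    print(row["name"], row["atom_indices"], f"{row['weight']:.2f}")
```

Typical output:

```
loss 7.23 -> 1.62
test ROC-AUC 1.000
hydroxyl (3,) 0.26
hydroxyl (0,) 0.25
```

The pretraining loss falls as positive pairs align; the fine-tuned model
separates held-out scaffolds perfectly on this synthetic rule; and the
explanation assigns the highest attention weights to the hydroxyl
occurrences that actually generate the label — the interpretability
behavior the prompt module is designed for.

The same workflow is available from the shell:

```bash
molprompt pretrain --out ckpt.npz --seed 0
molprompt make-fixtures --out task.csv --n-molecules 800
molprompt finetune --data task.csv --checkpoint ckpt.npz \
    --task classification --out run/
molprompt explain --model run/model_seed0.npz --data task.csv \
    --threshold 0.1 --out explain.csv
```

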