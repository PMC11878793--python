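# Methods

This note documents the models implemented in `molprompt`, the
parameters that matter, what the synthetic data does and does not
emulate, and the design decisions taken where the design was genuinely
open.

## Dual-view augmentation

A molecule's original graph keeps heavy atoms as nodes (hydrogens are
implicit, encoded as an attached-H count) and stores every bond as two
directed entries. Atom features concatenate eight attribute groups —
element one-hot, total degree, formal charge, chirality tag,
attached-hydrogen count, hybridization, aromaticity flag, and atomic
mass scaled by 1/100 — and bond features four groups: bond type,
conjugation flag, ring membership, stereo tag. The exact vocabularies
are configuration (`FeatureConfig`), and a hash of them travels with
every checkpoint so that a model never silently loads under a different
featurization.

The augmented view cuts every BRICS-matching bond. BRICS rules never
cut ring bonds, so each resulting connected component keeps its rings;
components become fragment nodes and each cut bond becomes one reaction
edge carrying the unordered pair of BRICS link labels (L1…L16) as two
concatenated one-hot blocks sorted by label index — preserving the
chemistry of both cut ends. RDKit's `7a`/`7b` sub-labels are folded
into L7. Fragments are featurized as stand-alone molecules (attachment
points hydrogen-saturated) with seven attribute groups: the 167-bit
MACCS keys, heavy-atom counts per element class (C, N, O, S, P,
halogen, other), topological polar surface area, heavy-atom count, ring
count, H-bond donors and acceptors; count-valued channels are scaled by
1/10 and TPSA by 1/100 to keep magnitudes comparable with the bit
channels. A molecule with no cleavable bond yields one fragment and no
edges — the pipeline treats this fallback as a normal case, since a
pretraining corpus must not crash on small or rule-free molecules.

Fragment atom-membership sets always partition the parent's heavy
atoms; this invariant is asserted across the entire packaged corpus in
the tests.

## Encoders

Both encoders meet one contract: a permutation-invariant graph
embedding of width `d_h` (default 300 at full scale; 64 in the
desk-scale study configuration used by the tests and the acceptance
script), plus per-node embeddings for the prompt module.

The original-graph encoder passes messages on directed edges for K
rounds (default 3). Edge states initialize from the source atom and
bond features; each round refreshes node states from the **sum** of
incoming edge messages concatenated with their elementwise **max** (the
communicative booster), and updates each directed edge from its source
node state minus the reverse edge's message, with a residual to the
initial edge state. Atom embeddings combine the raw features with the
final incoming message sum; the graph embedding is the sum over atoms.
Sum readout is deliberate: size sensitivity is informative for property
tasks.

The fragment-graph encoder embeds fragment features, then for two
rounds aggregates neighbor messages — each message built from the
neighbor state and the reaction-edge one-hot — with attention weights
softmax-normalized per receiving fragment, followed by a gated update.
It is a single-head attention message-passing network; it stands behind
the same encoder interface, so a different fragment encoder can be
swapped in without touching the contrastive framework or the prompt
module, which are encoder-agnostic.

Projection heads are two-layer MLPs with a rectifier. All weights use
Glorot-uniform initialization; two constructions from the same seed are
bit-identical, which the tests assert.

Because no GPU tensor framework is part of the package's dependency
set, the trainable stack runs on a small reverse-mode autodiff engine
(`molprompt._autodiff`) over float64 numpy arrays: broadcasting
arithmetic, matmul, reductions, row gathering and segment sum/max (the
scatter aggregations message passing needs), with an Adam optimizer.
Graphs are batched as disjoint unions, so a batch costs a handful of
matrix multiplies regardless of molecule count. Gradients of every
operation are verified against central finite differences in the test
suite.

## Contrastive objective

For a batch of N molecules the 2N projected embeddings form one anchor
pool. Each anchor's positive is its counterpart view; the denominator
sums over the other 2N−1 embeddings (cross-view and within-view
negatives), with cosine similarity at temperature τ = 0.1. The loss is
the arithmetic mean of the 2N per-anchor terms. Two consequences are
useful as exact checks: with N = 1 the loss is identically zero, and
rescaling every embedding by any positive constant leaves the loss
unchanged. The implementation is verified against a direct enumeration
of the loss formula to 1e-6 over hundreds of random draws.

Pretraining presets: the desk-scale defaults (`hidden 64, 20 epochs,
batch 32, Adam lr 1e-3`) fit the packaged ~200-molecule corpus in
seconds and are what the tests and the acceptance study use; a
large-corpus preset (`batch 1024, 50 epochs, lr 3e-5`) is retained in
`PAPER_PRETRAIN_PRESET` for runs at hundreds of thousands of molecules,
where the smaller learning rate and large batch are appropriate. The
learning rate for the small corpus was chosen once so that the loss
moves visibly within 20 epochs; it is not tuned per task.

## Functional-group prompt

The packaged table holds 82 named SMARTS patterns (hydroxyl, carbonyl,
carboxyl, esters, amines by substitution, aromatic heterocycles,
halogens, sulfur and phosphorus groups, generic alkyl/alkene/alkyne,
…). The table is data, not code: a TSV with `name \t smarts` rows, so a
different vocabulary can be supplied. Every pattern match is one group
occurrence — a molecule with three hydroxyls contributes three rows —
ordered deterministically by table index, then by sorted atom indices.

Each occurrence fuses its learnable table row with the sum and
elementwise max of its member atoms' encoder embeddings through a
linear map and rectifier (the σ of the fusion equation is a rectifier;
the choice is documented here because the nonlinearity is otherwise
unspecified). A learnable task token fg₀ is prepended and single-head
self-attention with separate W_Q, W_K, W_V runs over the m+1 rows; the
value projection is independent of the query projection by default,
with a `tie_value_to_query` flag preserving the tied variant for
fidelity experiments. The output is projected and layer-normalized; row
0 is the prompt. With m = 0 the prompt is a deterministic function of
fg₀ alone. The prompt is invariant to the ordering of the group rows,
and the attention row reported by `explain` is byte-for-byte the
distribution used in the forward pass — both properties are asserted by
recomputation in the tests.

The prompt width d_f defaults to d_h so the concatenation
`Concat(h_G, α·fg_prompt)` is balanced. α initializes to 1.0 and is
learnable. The prediction head is a two-layer Xavier-initialized MLP.
The fine-tuning objective adds γ‖F_table‖² (squared Frobenius norm)
with γ = 1e-4 by default; γ is exposed because the appropriate penalty
scales with table size and task count. Missing labels in multi-task
datasets are masked out of both the loss and the metrics; a
classification task left single-class after masking is skipped with a
warning rather than silently producing NaN.

Fine-tuning defaults (desk scale): 30 epochs, batch 64, Adam lr 1e-3,
early stopping on the validation metric with patience 10 and
restoration of the best parameters. `PAPER_FINETUNE_PRESET` records the
benchmark-scale schedule (100 epochs, batch 256, patience 15). Ablation
flags: `no_pretrain` (seed-initialized encoder), `no_atom_message`
(zero vectors in place of the pooled atom signals), `no_fg_prompt`
(zero vector in the prompt slot; prompt parameters excluded from the
optimizer). Multi-seed reporting runs seeds 0, 1, 2 by default and
reports mean ± std; the table and fg₀ receive no pretraining signal —
they are fine-tune-only parameters.

## Scaffold split and metrics

Datasets are split by Bemis–Murcko scaffold: all molecules sharing a
scaffold land in one fold. Groups are assigned largest-first (ties
broken lexicographically by scaffold string) to train until its share
is reached, then valid, then test; a group that would overflow train
falls through to the next fold, which keeps valid and test populated
even when a few scaffolds dominate — a strict "fill train first" rule
could leave later folds empty. Classification is scored by ROC-AUC
(averaged over tasks), regression by RMSE and MAE, all via
scikit-learn, with masked entries excluded. The test suite also checks
ROC-AUC against a brute-force pairwise-comparison count.

## Synthetic data: what it shows and what it does not

`SyntheticTaskSpec` defines label rules over functional-group match
counts: presence of a named group (optionally XOR/AND of two) for
classification, or a linear combination of counts plus Gaussian noise
for regression. Labels are derived from the same SMARTS table the
model's prompt uses — deliberately, so that recovery experiments
measure the learning machinery (can the model find and exploit the
generative rule? does the attention concentrate on the right group?)
rather than disagreements between two chemistry toolkits.

When a request exceeds the corpus, the pool grows by recombining the
corpus' own BRICS fragments; the builder joins fragments only at
compatible link-type pairs, so every product is valence-valid, and
each product is canonicalized and deduplicated. Because common groups
dominate generic recombinants, the negative class quota is filled from
a stream built only from fragments that do not themselves match the
rule's patterns — every product's label is still verified on the
assembled molecule. Classification datasets are rebalanced into a
30–70% positive share (the corpus' natural rate, clipped) by stratified
subsampling. Generation is exactly reproducible from the spec's seed.

Passing the recovery study shows that pretraining, prompt fusion,
attention and the head optimize and interact correctly, and that the
attention weights identify the generative substructure. It does **not**
show real-data performance: synthetic labels are noiseless functions of
substructure presence, the molecule pool is small and recombinant, and
assay labels (ADMET, solubility) depend on global physicochemistry that
no single SMARTS rule captures.

## Study configuration and numerical choices

The tests and `scripts/acceptance.py` run a desk-scale study chosen to
exercise every component in minutes on one CPU: pretraining on the full
packaged corpus (d_h = 64, 20 epochs, batch 32), then fine-tuning on an
800-molecule hydroxyl-presence task under scaffold splitting, five
seeds for the full model and five for the prompt-free ablation.
Reported quantities: oracle deviation of the loss, the partition
invariant's coverage, encoder permutation deviation, the
positive-versus-negative cosine margin after pretraining, median test
ROC-AUC, the rate at which `explain` ranks hydroxyl first among
positive test molecules, and the full-versus-ablated AUC ordering.

Numerical details: float64 throughout; softmax rows are shifted by
their (constant) row maximum before exponentiation; layer norm uses
eps = 1e-5; the segment-max used in message passing and match pooling
treats empty buckets as zero and routes gradients to every row
attaining the bucket maximum; cosine similarity raises on zero-norm
embeddings rather than returning NaN. Batch shuffling, initialization
and recombination sampling all derive from explicit seeds; two runs
with the same seed on one machine are bit-identical.

## Known limitations

- The fragment encoder is a stand-in meeting the augmented-encoder
  contract, not a reimplementation of any specific published
  heterogeneous-graph architecture.
- Pure-numpy training is CPU-bound and single-device; the paper-scale
  presets are documented but impractical without a GPU framework.
- The 82-group SMARTS vocabulary is a curated convention; SMARTS
  matching counts overlapping generic groups (alkyl, methylene) which
  inflate m for large aliphatic molecules.
- Attention is single-head; a head-count knob would require splitting
  d_f and was not needed for the contract properties asserted here.
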