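# Methods

## Model

**Featurization.** RDKit perceives each SMILES into a heavy-atom graph
(hydrogens implicit, the standard molecular-GNN convention). Nodes carry
the atomic number (1–118) and a four-way chirality tag (UNSPECIFIED /
TETRAHEDRAL_CW / TETRAHEDRAL_CCW / OTHER); edges carry a four-way bond
type (SINGLE / DOUBLE / TRIPLE / AROMATIC) and a three-way bond direction
(NONE / ENDUPRIGHT / ENDDOWNRIGHT). Each undirected bond is stored as two
directed arcs sharing one feature vector. These category sets are the
conventional AN/CT/BT/BD vocabularies for this featurization.

**Encoder.** Initial node and edge representations are concatenations of
two learned attribute embeddings of width d/2 each (hence d must be even).
Each of the L layers aggregates, for every node, the unweighted sum of
neighbor embeddings plus incident-edge embeddings — sum aggregation is
what gives the GIN family its discriminative power, and the aggregation
takes both node and edge sets. The update applies a two-layer perceptron
(2d → d → d) with a rectifier to the concatenation of the previous node
state and the aggregate; a single-linear update is available via
`EncoderConfig(update="linear")` since the update map can also be read as
one matrix. Edge embeddings stay at layer 0 and are re-used at every
layer. Dropout is applied to node states after each layer's activation,
training mode only. Batch normalization is off by default and available
behind `batch_norm=True`. Defaults: L = 5, d = 300, dropout 0.5.

**Pooling and heads.** The graph embedding is the arithmetic mean of the
*un-normalized* final-layer node rows; the L2-normalized rows feed the
bond-reconstruction decoder. Both conventions are defensible — the
normalized form defines per-node representations while pooling is written
over raw final-layer states — so pooling normalized rows is available via
`pool_normalized=True`, with un-normalized as the documented default. The
classifier concatenates h_G with a learned organism tag (default
dimension 16; one-hot tags via `tag_mode="onehot"`, ablation via
`"none"`) and maps through a 128-unit rectified hidden layer with dropout
0.5 to a logistic output, strictly inside (0, 1).

**Auxiliary losses.** Bond reconstruction scores a pair (u, v) by the
logistic of ⟨h_u, h_v⟩ on normalized embeddings — the simplest decoder
for bond presence; an MLP-on-concatenation decoder sits behind
`bond_decoder="mlp"`. Negatives are non-bonded, non-self pairs sampled
1:1 with the positives per graph (balanced sampling, the standard default
when a ratio is not otherwise fixed); molecules too small to supply that
many negatives contribute what they have. Atom-type prediction is
realized as masked-attribute recovery: a seeded ⌈0.15·|V|⌉-node subset
(minimum one) has its atom-number embedding replaced by a dedicated mask
token, the encoder re-runs, and a linear 118-way head over the masked
nodes' final embeddings is scored by cross-entropy — the context-based
formulation conventional for this pretext task. Default loss weights are
(1.0, 0.1, 0.1): the auxiliary terms act as mild structural regularizers
and are exposed in config. Both auxiliary losses remain active during
fine-tuning by default (flag to disable); nothing in the training
procedure requires turning them off.

## Training procedure

Splits are fixed once before training: validation and test receive
⌊f·n⌋ records each (defaults 0.1/0.1) and all remainders go to train.
Stratified splitting apportions by (organism, label) stratum with
largest-remainder rounding, preserving stratum proportions within one
record while hitting the global sizes exactly. A scaffold strategy
(Murcko ring frameworks kept intact, groups placed by descending size)
is provided because permeability benchmarks are conventionally
scaffold-split; random-stratified is the default.

The curriculum orders organisms by a supplied complexity rank (rat = 1,
human = 2 by default) and is cumulative: stage k trains on the union of
stages 1..k, reading "progressively introducing data" as accumulation;
exclusive stages are available behind `cumulative=False`. The total epoch
budget divides equally among stages (remainder to the last stage) unless
per-organism budgets are given. Validation AUC is always computed on the
full validation split, not per stage, so checkpoint selection is
comparable across stages; ties in the argmax go to the earliest epoch.
Optimization uses Adam with default moments and learning rate 0.001,
batch size 32 (optimizer and batch size are recorded in checkpoints).
Minibatches are encoded as disjoint unions, which is mathematically
identical to per-graph encoding (asserted by a test) and keeps the numpy
matmuls large.

Fine-tuning continues *all* parameters — classifier included — for 20
epochs on a single-organism permeability table with the same best-AUC
checkpoint rule; there is no evidence that reinitializing the classifier
helps, so continuation is the default. An unseen organism raises a
vocabulary error unless `allow_new_organism=True` initializes a fresh
tag. `init_from_pretrained` replaces encoder tensors whose shapes match
an archived checkpoint, leaves heads and tags freshly initialized, and
reports the loaded/fresh disposition per tensor; any dimension mismatch
is a hard shape error.

**Numerical core.** No GPU tensor framework is used: the package ships a
small reverse-mode autodiff engine (`bbbgnn/_tensor.py`) implementing
exactly the operations the model needs, with numerically fused
binary/categorical cross-entropies (log-sum-exp / softplus forms) and an
exact batch-norm backward. Every operation and a full end-to-end model
path are checked against central finite differences. Evaluation-mode
computation is bitwise deterministic; all stochasticity (shuffling,
dropout, negative sampling, masking) flows from explicit numpy
generators seeded from the run config, so identical configs reproduce
identical histories and artifacts byte-for-byte.

## Synthetic data

The generator emulates multi-organism activity tables: molecules are
assembled from a fragment grammar (alkyl chains C1–C6, benzene, pyridine,
aliphatic amines, ether/ester linkers) in four feature categories defined
by (nitrogen present, aromatic ring present). The planted rule makes rats
respond to nitrogen and humans to nitrogen XOR aromatic ring. Both
features are detectable within one or two message-passing hops, so
parameter recovery is fast at desk scale, and the XOR guarantees that a
tag-blind model cannot fit both organisms simultaneously — the designed
probe of the organism tag and curriculum. Category probabilities
(t/2, t/2, t/2, 1 − 3t/2) hit an active-fraction target t for *both*
organisms simultaneously, which bounds t ≤ 2/3. Labels flip independently
with probability 0.05 by default (kept strictly below 0.5). An
imbalance preset reproduces the ≈3.92:1 inactive:active ratio
characteristic of rat brain activity data, noise-free so the ratio
reflects composition alone.

What the generator does *not* emulate: realistic chemistry (no rings
beyond benzene/pyridine, no stereocenters, no charged species), realistic
property distributions, correlated label noise, or inter-organism sample
imbalance. Passing tests therefore demonstrate that the architecture,
losses, curriculum and selection machinery work and that the organism
conditioning carries real signal — not that the model attains any
particular accuracy on real activity or permeability data.

## Problem sizes and defaults used by tests

Training tests and the acceptance script run a reduced encoder — 3
layers, d = 64, dropout 0.2 — chosen because the planted signals live
within a 2-hop receptive field; 60 curriculum epochs on 400 molecules ×
2 organisms (5% label noise) recover the planted signal to validation
AUC ≈ 0.95–0.98 versus ≈ 0.5 for a label-permuted control. The
organism-tag comparison uses 200 molecules and 30 epochs per model over
three seeds. The production default (5 × 300, dropout 0.5, 1000 epochs)
remains the package default configuration.

## Known limitations

* AUC uses exact pair enumeration up to ~10⁷ pair products and the
  tied-rank Mann–Whitney statistic beyond; both routes are tested equal.
* The atom-type head spans the full 118-element vocabulary although the
  grammar emits only C/N/O; real tables exercise more of it.
* Single-process CPU training only; no early stopping beyond
  argmax-checkpoint selection; no probability calibration.
* Checkpoints store raw float64 tensors in a zip archive with a JSON
  manifest; archives are not portable across architecture changes by
  design (shape loading is strict).
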