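# Methods

## Model

`pepclip` couples two modality encoders through a shared latent space.

**Text encoder.** Peptide sequences over the canonical 20-letter alphabet
are tokenized one residue per token, wrapped in `[CLS]`/`[SEP]` specials,
right-padded, and fed to a standard transformer encoder (learned token and
position embeddings, multi-head self-attention with an additive −1e9 mask
on padded keys, GELU feed-forward blocks, post-block layer norm). Pooling
is the first-token state by default, with mask-weighted mean pooling as a
config alternative; both ignore padding, so appending extra padding leaves
the embedding unchanged (asserted to 1e-5 in the tests). A minimal built-in
vocabulary (20 residues + 4 specials) ships with the package; any JSON
token map with the same specials can be plugged in, so external pretrained
vocabularies are an option, never a requirement.

**Graph encoder.** A structure is parsed from PDB ATOM records into a
ten-feature node table per atom: x, y, z (Å), atomic number, standard
atomic mass (u), covalent radius (Å), a side-chain indicator
(backbone = {N, CA, C, O, OXT}), a global 0-based residue ordinal, the
atom count of the owning residue, and the printed residue sequence
number. The element table is a single bundled snapshot (validated against
rdkit's periodic table in the test suite). Edges join atom pairs within a
configurable Euclidean cutoff, default 6.0 Å — the scale of atomic
contacts; the construction is checked against a brute-force O(n²) oracle.
Each convolution layer computes, per node, a learned affine map of the
node's own features plus a learned affine map of the arithmetic **mean**
of its neighbors' features (the sampling-and-aggregation family), then a
rectifier; an isolated node contributes a zero neighbor term. After the
conv stack: mean readout over nodes, a fully connected network with
rectifier activations, and a final sigmoid-bounded layer. Coordinates are
centered at the structure centroid before encoding (translation-invariant
embeddings; a config switch disables this, and the tests assert the
sensitivity that results). Heterogeneous feature scales are divided by
fixed per-feature constants so all inputs are O(1). One published
description counts eleven node features while enumerating ten; the ten
enumerated are implemented, and `graph_append_bias_feature` appends a
constant 1 column for width-11 compatibility.

**Projection heads and classifiers.** Each modality has a projection head
(linear → GELU → linear → dropout → residual add of the first linear's
output → layer normalization; dropout active only when an RNG is passed,
i.e. in training) mapping into a shared latent width, and a classification
head (affine + sigmoid) used in stage 1 and at inference.

**Contrastive objective.** For N row-aligned pairs, logits
S[i][j] = cos(g_i, t_j)/τ; the loss is the mean of the row-wise and
column-wise cross-entropies of S against the diagonal, averaged with
factor 1/2. Targets are hard one-to-one match indices (the canonical
variant); soft targets are not used. Two closed forms anchor the
implementation: two perfectly aligned orthonormal pairs at τ = 1 give
log(1 + e⁻¹), and N identical latents give log N. The autodiff gradient is
checked against central finite differences to 1e-4 on a 3×8 batch. An
optional auxiliary binary-cross-entropy term during alignment is exposed
through the config (weight 0 by default); pure contrastive alignment is
the default behavior.

## Training procedure

Stage 1 trains each encoder + head on binary labels with binary
cross-entropy and AdamW (decoupled weight decay 0.01). Stage 2 freezes
the graph **encoder** — excluded from the optimizer and from gradient
tracking, so its parameters are bit-identical before and after — and
updates the text encoder and **both** projection heads: the graph
projection head is part of the alignment machinery, and only the graph
model's pretrained weights are what the freeze protects. Classification
heads are untouched during alignment. A reduce-on-plateau scheduler
multiplies the learning rate by factor 0.4 after 5 consecutive epochs
without improvement of the monitored quantity (the training loss of the
stage; epoch-mean). Alignment defaults: 100 epochs, lr 6.0e-5, batch 20,
τ = 0.07 (fixed, not learnable, config-exposed). Stage-1 defaults: 50
epochs, batch 20, lr 1e-3 — the stage-1 rate is a package choice suited to
training compact encoders from random initialization; fine-tuning a large
pretrained sequence model would use a much smaller rate. Batches for
alignment never contain the same sequence twice (duplicates can survive
oversampling and would make the one-to-one contrastive targets
ill-posed). All randomness — batch order, oversampling, dropout — derives
from the config seed; the per-stage seeds of the pipeline come from the
run seed by fixed offsets.

**Inference** uses the aligned text encoder with its unchanged stage-1
classification head on sequences alone, at decision threshold 0.5; the
test suite asserts that the prediction path touches no graph-side code.
Whether a refit head would serve better post-alignment is an open design
point; keeping the stage-1 head matches the "updated weights used
directly" reading and is the package default.

## Data preparation

Two deduplication modes: `conflict_drop` removes every copy of a sequence
recorded with both labels (appropriate for assay-variable hemolysis
data); `same_label_collapse` keeps one representative of identical
(sequence, label) pairs. Class imbalance is corrected by duplicating
minority records with replacement (seeded) until counts are equal —
originals always retained. The train/test split (default 80/20) is a
seeded shuffle-partition, stratified by label by default for stable test
composition at small n. Described replication pipelines oversample before
splitting, which leaks duplicated minority records across the split; the
default here splits first and oversamples the training portion only, and
a `paper_order` flag restores the oversample-then-split sequence for
faithful replication.

## Synthetic fixtures

The generator emulates the study conditions of real peptide benchmark
corpora: variable-length sequences, minority-positive imbalance
(hemolysis-like 15/85 by default; the composition arithmetic reproduces
845/4764 → 15.065%/84.935% and 3596/13579 → 20.937%/79.063%), and one
structure per peptide whose atom count scales with length. The label rule
is deterministic in the sequence — positive iff the hydrophobic-residue
fraction ({A,F,I,L,M,V,W,Y}) exceeds 1/2 — so the signal is learnable
from the sequence, and from the structure only insofar as structure is
derived from sequence. Positive and negative draws use class-conditional
residue compositions (hydrophobic probability 0.7 vs 0.3, every draw
re-checked against the rule), emulating the real separation between
hemolytic and benign peptides rather than concentrating all mass at the
decision boundary. Structures are ideal α-helices (rise 1.5 Å, 100° per
residue, CA radius 2.3 Å → adjacent-CA distance ≈ 3.83 Å): deterministic,
parseable, sequence-dependent through glycine's missing CB pseudo
side-chain atom. Synthetic per-atom confidences are uniform on [50, 95]
so selection logic sees both sides of the conventional 70 threshold.

What the fixtures do **not** emulate: real side-chain chemistry and
rotamers (all non-glycine residues look structurally identical apart from
the label-irrelevant backbone geometry), secondary-structure variety,
folding noise, or label noise. Consequently the structure modality
carries only a weak independent signal (glycine content), and passing
tests demonstrate the mechanics — freeze semantics, loss geometry,
optimization, reproducibility — not real-data predictive performance.
The headline accuracies published for the real hemolysis/nonfouling
corpora require those corpora, folded structures and a large pretrained
sequence model, and are out of scope here by design.

## Problem sizes and numerical choices

Desk-scale defaults: text encoder 2 layers / 4 heads / width 128, graph
encoder 2 conv layers / width 64, latent width 128 — all config-overridable.
The acceptance script and heavy tests use reduced sizes chosen as the
package's reference desk-scale experiment: 500 peptides of length 8–32 at
15% positives, text width 64 (2 layers, 4 heads, mean pooling — the
natural readout for a composition-threshold rule), graph width 32, 8/3/6
epochs for text/graph/alignment, median over 3 seeds; a full alignment
run for the freeze check uses a 100-peptide corpus. All arithmetic is
float64. Probabilities are clamped by 1e-12 inside the cross-entropy;
softmax and logsumexp use detached max-shifts; layer norm uses eps 1e-5.
Ties in best-model selection break to the lowest index. Degenerate
inputs — empty graphs, zero vectors in cosine similarity, single-class
oversampling, batches of one in the contrastive loss — raise explicit
errors rather than propagating NaNs.

## Known limitations

- The autodiff core implements exactly the operator set the models need;
  it is single-threaded NumPy and not a general deep-learning runtime.
- Checkpoints store the full optimizer state but assume the same package
  version (a version tag is checked on load).
- t-SNE export (2D/3D, seeded, perplexity 30 default) is for qualitative
  inspection only; coordinates are exported as CSV rather than plotted.
- mmCIF input, bond-order perception, residue-level coarse graphs,
  learnable temperature, and multi-device training are out of scope.
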