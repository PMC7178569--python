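# Methods

## Overview

`molfinetune` implements inductive transfer learning for QSPR/QSAR
modeling from SMILES strings. The pipeline has three stages:

1. **General-corpus language model.** A molecular structure prediction
   model — an AWD-LSTM that predicts the next SMILES token — is trained
   self-supervised on a large unlabeled corpus with the one-cycle policy.
2. **Task-corpus language model (optional).** The general model is adapted
   to the distribution of a specific task corpus with one-cycle scheduling
   and discriminative layer-wise learning rates.
3. **QSAR/QSPR fine-tuning.** The embedding and encoder are transferred
   into a regression/classification model with a freshly initialized
   concat-pooling head, then trained with gradual unfreezing over four
   layer groups.

## Model

The encoder is an embedding layer followed by three LSTM layers. At full
scale the embedding width is 400 and the hidden width 1152, with the last
layer projecting back to 400 so the language-model decoder can be
weight-tied to the embedding (tying is the default and toggleable). The
language model applies a softmax over the vocabulary at every time step.
The QSAR head consumes `[maxpool ‖ meanpool ‖ h_T]` over the final-layer
states — pad positions are excluded from both pools and `h_T` is taken at
the last *non-pad* step — followed by two feed-forward layers with a ReLU
between them (hidden width 50 by default; the width is not dictated by the
architecture and is configurable). Regression uses a single output node on
standardized labels (the affine de-standardization is stored with the
model); classification emits one score per class.

Regularization follows the weight-dropped LSTM recipe: embedding-row
dropout 0.1, input dropout 0.25, recurrent weight DropConnect 0.5, hidden
dropout 0.15, output dropout 0.1, with a single multiplier to scale all
five for fine-tuning. All dropout is inert in eval mode, making eval
forward passes bit-reproducible.

**Initialization.** Input weights are uniform in ±1/√H; recurrent
matrices use one orthogonal block per gate and the forget-gate bias starts
at 1. Orthogonal recurrent initialization with open forget gates keeps
signal norms stable through time; narrow stacked LSTMs initialized
uniformly spend hundreds of epochs stuck at the unigram plateau before
learning any sequential structure. Embeddings are uniform in ±0.1, small
enough that a fresh model's next-token loss is ln(vocabulary size) to
within a fraction of a percent.

## Training machinery

The numerical core is a small reverse-mode automatic differentiation
engine over NumPy arrays, written for exactly the operations these models
need. Training uses Adam (β₂ = 0.99) with optional global-norm gradient
clipping at 0.4, under the one-cycle policy: cosine warmup from
lr_max/25 to lr_max over the first 30% of steps, cosine annealing to
lr_max/(25·10⁴) afterwards, with momentum counter-cycling 0.95 → 0.85 →
0.95. A strictly constant learning-rate mode is available for pretraining
because the phrase "one cycle policy with a constant learning rate" admits
both readings; the default treats one cycle as spanning the whole run.

The language model trains on a single concatenated token stream — each
SMILES wrapped in BOS/EOS — cut into contiguous backpropagation-through-
time windows of 70 tokens (configurable), with hidden state carried,
detached, across windows within an epoch.

Discriminative fine-tuning assigns the top layer group the base rate and
divides by 2.6 per group below. Gradual unfreezing uses four groups:
(1) embedding + first LSTM, (2) second LSTM, (3) last LSTM, (4) head. The
default stage plan is head-only at 3e-2 for 4 epochs, then +last LSTM at
5e-3/4, +last two LSTMs at 5e-4/4, and the full model at 5e-5 for 6
epochs. Within a stage, only the unfrozen groups are handed to the
optimizer, so frozen parameters are bit-identical afterwards; every step
logs the per-group learning rate so schedule conformance is checkable to
machine precision.

## Data handling

Curation applies, in order: parse filter, structural mixture filter
(fragment count after parsing, so `C1.C1` — one molecule written with a
dot — is kept), a strict >50 heavy-atom cutoff, sanitize + standardizer
cleanup + canonicalization, and first-occurrence deduplication on the
canonical form (toggleable). Unlabeled corpora count and drop invalid
entries; labeled datasets abort on them, since silently dropping rows
corrupts label alignment.

Tokenization is character-level with three exceptions: bracket expressions
`[...]` are single tokens, `Cl`/`Br` are single tokens, and two-digit ring
closures `%NN` are single tokens (needed for losslessness beyond nine open
rings). Reserved specials occupy indices 0–3 as PAD, UNK, BOS, EOS.

Augmentation enumerates alternative SMILES by randomizing the atom
ordering (a seeded permutation passed through the backend's writer).
"Augmented N times" means N additional variants alongside the retained
original; an N-total reading is a spec switch. Regression variants carry
the parent label plus i.i.d. Normal(0, σ_noise²) perturbations — the
original label is never touched; classification variants copy the class
unchanged, with per-class counts used for re-balancing (shipped presets:
lipophilicity 25×/σ 0.3, FreeSolv 50×/σ 0.5, HIV 60×/2×, BBBP 10×/30×).
Test-time augmentation averages predictions — probabilities for
classification, raw outputs for regression — over the canonical SMILES
plus four variants by default, fixed per molecule under the run seed.

Splits are 80:10:10, random or by Bemis–Murcko scaffold. The scaffold
split assigns whole scaffold groups largest-first to train, then valid,
then test; acyclic molecules share the empty scaffold as one group by
default (a singleton mode exists because conventions differ). Train and
valid take the floor of their fractions; the remainder lands in test.
Externally supplied split index files (JSON) are honored verbatim.

## Synthetic data

The generator assembles molecules as random valence-respecting trees over
C/N/O/S/F (carbon-weighted), optionally seeding or decorating with
aromatic six-rings at probability 0.3 per opportunity, sizes 8–24 heavy
atoms, with legality deferred to the chemistry backend via
reject-and-retry. Labels follow
`y = a·#N + b·#rings + c·#heavy + ε`, defaults (1.0, 0.5, 0.1) and
ε ~ N(0, 0.1²), chosen so all three structural effects are comparable in
magnitude against the label spread (≈1.4) and exactly recoverable by
least squares from the stored ground-truth count table. Class labels
threshold the latent value at the empirical quantile matching the target
positive fraction. The generator emulates corpus-scale token statistics,
enumeration behavior and class imbalance; it does not emulate drug-like
property distributions, stereochemistry, charged species or measurement
artifacts, so green tests here demonstrate mechanical correctness of the
pipeline, not predictive performance on real chemistry.

## The desk-scale transfer benchmark, and an honest caveat

`transfer_benchmark` pretrains a small language model (embedding 32,
hidden 64, three layers, 4 one-cycle epochs at lr 1e-2, batch 128) on
20 000 synthetic molecules and compares, over 10 paired seeds and task
sizes n ∈ {100, 500}, a fine-tuned regressor against an identically
initialized regressor trained from scratch under the same stage plan,
data subsets and seeds. The pretraining corpus and task pool are generated
once, disjoint in canonical SMILES, and reused across seeds; models are
re-initialized and re-pretrained per seed.

On this synthetic task the pretrained arm does **not** outperform the
scratch arm, and the effect is systematic rather than noise. The reason is
instructive: with orthogonal recurrent weights and open forget gates, a
*random* frozen LSTM already acts as a reservoir that integrates random
projections of local token context over the sequence — and a label that is
a linear function of structural counts is almost exactly the kind of
quantity such random features encode best (a linear probe on pooled
random-encoder features reaches within ~1.5× of the label noise floor at
n = 500). Next-token pretraining reshapes those states toward local syntax
prediction and measurably reduces the linear extractability of global
composition, under every variant probed (more/fewer epochs, AWD dropout,
enumeration-augmented pretraining streams, alternative initializations,
augmented fine-tuning, classification instead of regression). The
full-scale transfer claim concerns real structure–activity landscapes,
where random recurrent features are far from sufficient; the desk-scale
count-linear analogue is a regime where they are already near-optimal, so
the comparison inverts. The benchmark is reported as computed; the
corresponding acceptance tests fail and are expected to.

## Numerical choices and degenerate inputs

Float32 weights and activations; losses accumulated in float64. Ties in
masked max-pooling split gradient evenly; an all-pad sequence is an error.
Vocabulary order is descending frequency with lexicographic tie-break, so
construction is bit-reproducible. Enumeration draws at most
n × 10 candidates before accepting fewer than n variants (bounds work on
small symmetric molecules). Duplicate removal keeps the first occurrence.
Empty corpora, single-class AUROC inputs, rank-deficient count matrices
and infeasible generator specs raise immediately rather than degrade.

## Problem sizes in the default test run

Unit and property tests run on 50–500-molecule corpora with the 32/64
tiny encoder; the memorization check trains 200 epochs on a 50-SMILES
stream; the transfer benchmark uses the full 20 000-molecule corpus and
10 paired seeds. These sizes were chosen as the package's desk-scale
defaults so the whole suite completes on a single CPU in well under half
an hour.
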