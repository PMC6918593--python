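# Methods

## Overview

`protlm` implements a transfer-learning pipeline for protein sequences:
an unsupervised bidirectional language model (biLM) over amino-acid
"sentences", per-residue contextual embeddings extracted from its internal
layers, and two small supervised networks that consume those embeddings (or
any of four baseline encodings) to predict per-residue structure and
per-protein localization. This note records the modeling choices, the
parameters that matter, and what the desk-scale experiments do and do not
show.

## The bidirectional language model

**Tokenization.** Sequences are canonicalized to a 25-letter alphabet (20
standard residues; U and O for selenocysteine/pyrrolysine; B and Z for
ambiguity; X for unknown, which also absorbs any other character), then
bracketed by `<S>`/`</S>` and padded with `<MASK>`: 28 tokens.

**Architecture.** A character-CNN word encoder (each "word" is one amino
acid spelled as begin-of-word + symbol + end-of-word) with a convolution
bank, max-pooling over character positions, highway layers and a linear
projection; then two LSTM layers with hidden-state projection and a
residual connection between them; finally a softmax over the 28 tokens.
The word encoder and the softmax are shared between the forward and
backward directions; the recurrent layers are direction-specific. A
`share_recurrent` flag exists for the memory-saving variant that reuses one
set of recurrent weights for both directions; it is off by default because
the full-preset free-parameter total (~93.6 M) corresponds to the unshared
convention. Presets:

| | char emb | conv bank | highway | proj | hidden | params |
|---|---|---|---|---|---|---|
| `paper` | 16 | (1,32)(2,32)(3,64)(4,128)(5,256)(6,512)(7,1024) | 2 | 512 | 4096 | 93,611,532 |
| `mini` | 8 | (1,16)(2,16)(3,16) | 1 | 32 | 64 | 83,012 |

**Training objective.** Each direction is a next-token predictor over its
own reading order, so the forward loss at position *t* conditions only on
tokens < *t* and the backward loss only on tokens > *t* (verified by
perturbation tests). Losses of the two directions are averaged per step.
Training uses a sampled softmax: the target plus 20 negatives drawn without
replacement from a log-uniform proposal over vocabulary ranks, with the
standard log-proposal correction and masking of accidental hits. With a
28-token vocabulary this is close to the full softmax, which is what
evaluation uses. Sequences are processed in length-sorted padded batches,
split into truncated-backpropagation windows of `unroll_steps` (default
100) tokens with recurrent state carried, detached, across windows within a
protein and reset between batches. Dropout (10%) is applied to the
recurrent inputs during training only.

**Optimizer.** Adam with learning rate 0.01 by default. The classic
large-corpus recipe (Adagrad, lr 0.2) is available via
`optimizer="adagrad"`, but at desk scale (10³–10⁴ update steps rather than
10⁶) Adagrad's monotonically growing accumulators shrink the effective
step long before the loss has converged, so Adam is the default here.
Training is bit-reproducible given (config, corpus, seed) on one device.

**Perplexity.** exp of the mean per-token negative log-likelihood under
the full softmax. Per direction, the scored targets are the residues plus
that direction's terminal token (`</S>` forward, `<S>` backward); padding
is never scored. The `mean` direction averages the two per-token NLLs
before exponentiation. A model forced to a uniform output distribution
scores exactly 28 (the vocabulary size) on any corpus.

## Embedding extraction

Three layers per residue: layer 0 is the context-independent word-encoder
output duplicated across both direction halves (so all layers share one
width); layers 1–2 concatenate forward and backward recurrent states at
that residue's position. Default combination is the unweighted element-wise
**sum** (width = 2 × projection = 1024 in the full preset); `concat` yields
3× the width (3072). No fine-tuning, no learned layer weighting — the
embeddings are a frozen feature extractor. Embeddings are computed in
inference mode (no dropout), in float32, and are independent of how
proteins are packed into batches (tested). Batches for inference are formed
by sorting proteins by length and greedily packing up to a 15,000-token
cap, oversized proteins going alone. Stores are HDF5, one dataset per
protein, with the combination mode and the producing checkpoint hash as
attributes; consumers refuse stores from a mismatched checkpoint.

## Baseline encodings

* **one-hot (20)** — unit vectors for the standard residues; U/O/B/Z/X are
  all-zero rows.
* **BLOSUM65 (23)** — the raw integer substitution-score row over the 23
  symbols (standard + B, Z, X), loaded from biotite's matrix database; an
  NCBI-format text reader/writer supports user-supplied matrices. U and O,
  absent from BLOSUM tables, are looked up as C and K respectively (their
  closest biochemical parents); this aliasing is deliberate and recorded
  here rather than in metadata of every matrix.
* **profile (50)** — [one-hot 20 | substitution profile 20 | alignment-HMM
  transition features 7 | diversity 3], read from HDF5 or TSV; synthetic
  profile fixtures with the same layout are generated for testing.
* **3-mer skip-gram (100)** — overlapping 3-mers (stride 1) embedded by
  skip-gram with negative sampling (window 2, 5 negatives, unigram^0.75
  noise, linearly decaying learning rate). One vector per distinct 3-mer,
  context-free by construction; unseen 3-mers map to zero. At residue
  level, residue *i* takes the vector of the 3-mer centered on it, with the
  terminal residues reusing the first/last 3-mer (the assignment from
  overlapping 3-mers to single residues is otherwise underdetermined); at
  protein level, the mean over all 3-mer vectors.

## Downstream predictors

**Per-residue CNN**: conv(X→32, window 7, same-padding with zero borders)
→ ReLU → dropout 25% → conv(32→13, window 7), the 13 outputs split into
softmax heads of 3 (SS3), 8 (SS8) and 2 (disorder). One shared trunk for
the three tasks; losses are unweighted sums of masked mean cross-entropies.
The receptive field is 13 residues (tested by perturbation). Free
parameters: X·7·32+32 + 32·7·13+13.

**Per-protein net**: linear(d→32) → dropout 25% → batch normalization
(learned scale+shift; running statistics frozen at inference) → ReLU → two
softmax heads (10-class localization, 2-class membrane). Proteins with
membrane status "unknown" are kept for localization training but masked
out of the membrane loss. Free parameters: d·32+32+64+330+66.

Both trainers use Adam (lr 0.001), batch sizes 128/64 (proteins), a random
held-out fraction (5%/10%) for early stopping on the summed held-out loss
(patience 5/10), and restore the best parameters.

## Evaluation measures

Q3/Q8 are computed per protein (percentage of correctly labeled residues)
and macro-averaged over proteins; their standard errors come from the
per-protein score distribution. Q2/Q10 treat each protein as one item, with
1000-resample bootstrap standard errors. Disorder is scored with the binary
Matthews correlation (per protein, macro-averaged; proteins whose true
labels contain a single class are excluded and counted — a pooled
micro-MCC is also available) and the false-positive rate. Localization
additionally reports the Gorodkin K-category correlation RK, computed from
the confusion matrix in covariance form

RK = (N·tr C − t·p) / sqrt((N² − p·p)(N² − t·t)),

which reduces exactly to the binary MCC at K=2 (tested on random tables
and against an independent implementation) and is defined as 0 with a
degeneracy flag when a variance term vanishes.

## The synthetic-data generator

Sequences are emitted by a 10-state hidden Markov grammar whose states
correspond to local structural environments (helix, 3₁₀-helix, π-helix,
strand, bridge, turn, bend, coil, disordered segment, hydrophobic membrane
segment), each with a DSSP letter and a peaked emission distribution over
the 20 standard residues (~86% of mass on 5–7 preferred residues).
Self-transition probabilities (0.5–0.94) set realistic segment lengths;
lengths are log-normal (median ≈ 90, clipped to [30, 2000] — desk scale
rather than the full natural range). Residue labels are the generating
hidden path: SS8 from the state letters, SS3 via the [G,H,I]→H, [B,E]→E,
rest→O convention, disorder flagged for residues emitted by the disordered
state (mirroring "residues without coordinates" rather than a DSSP
letter). Ten localization-class variants re-weight which states are visited
(e.g. the cell-membrane class strongly prefers the membrane state, the
nucleus class the disordered state) and mildly tilt emissions (e.g. K/R
enrichment in nuclear proteins); the class is stored as provenance. A
protein is labeled membrane-bound exactly when its hidden path contains ≥15
consecutive membrane-state residues; 10% of membrane annotations are
masked to "unknown" to exercise the loss masking.

What this emulates: local context predicting structural class, and global
composition/state usage predicting compartment — the statistical structure
the transfer-learning claim rests on. What it does not emulate: real
evolutionary families, domain architecture, long-range contacts, class
imbalance of real annotation databases, or real profile generation (the
profile fixtures are synthetic, with the documented layout and a peak at
the true residue). Passing tests therefore demonstrate correctness of the
machinery and the direction of the embedding-vs-baseline comparisons under
controlled conditions, not absolute performance on real proteins.

## Study conditions and expected numbers

The fixed desk-scale conditions used by the test suite and the acceptance
script: mini LM preset; 200 grammar proteins, 20 epochs for the structured
corpus; 300 i.i.d. uniform proteins, 15 epochs for the entropy-floor
experiment; 250 proteins (200 train / 50 test) for the residue task at 25
epochs; 400 proteins (320/80) for the protein task at 80 epochs; 3-mer
skip-gram trained 3 epochs on the LM corpus.

On the i.i.d. uniform 20-letter corpus, per-residue entropy is exactly
log 20, so perplexity 20 is an analytic floor. A trained model always sits
somewhat above it, for two structural reasons: it must reserve probability
mass for the end-of-sequence token at every position (the sequence-length
hazard is only weakly learnable), and it fits finite-sample noise in the
empirical distribution. The tests therefore assert the floor strictly
(never below 20) and convergence into [20, 25], a band wide enough for
those two overheads at the fixed corpus size. On the grammar corpus the
same model must fall well below 20 (asserted below 18): only a model that
exploits context can beat the uniform-residue floor, and the suite
additionally checks that the same training budget on a residue-shuffled
copy of the corpus ends at strictly higher perplexity.

## Numerical and design notes

* The whole stack runs on a small reverse-mode autodiff engine over NumPy
  (`protlm.nn`), gradient-checked against central finite differences.
  Working precision is float32; optimizer accumulators are float64.
* Softmax cross-entropy uses the log-sum-exp stabilization with the fused
  `softmax − onehot` backward.
* LSTM forget-gate biases initialize to 1; other biases to 0; weights
  uniform in ±sqrt(1/fan-in). Highway transform gates start at −2 (near
  identity).
* Ties in max-pooling route the gradient to the first maximum.
* Binary MCC is defined as 0 (flagged) when a marginal is zero; FPR is NaN
  when no true negatives exist.
* The concatenated three-layer embedding width is 3 × 1024 = 3072.
* The per-residue CNN's borders use zero padding; predictions are
  invariant to trailing padding (tested).
* t-SNE projection delegates to scikit-learn with the configured metric
  (cosine), iteration count (3000) and perplexity (20 for raw embeddings,
  15 for hidden-layer views), seeded for reproducibility.

## Known limitations

* The `paper` biLM preset is buildable (and its arithmetic is tested) but
  not trainable in reasonable time without accelerators; all training
  claims are made at the mini scale.
* Grammar-generated proteins are far easier than real ones; absolute
  accuracies here (Q3 ≈ 90+) say nothing about real-data performance, only
  the relative ordering of input encodings under matched budgets does.
* The skip-gram and LM corpora are small enough that embedding quality is
  noise-limited; rankings are stable under the fixed seeds but individual
  numbers move by a few points across seeds.
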