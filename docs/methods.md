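# Methods

This note documents the model implemented by `lncdap`, the choices made
where the design was genuinely open, the synthetic data the tests run on,
and the limits of what those tests demonstrate.

## Problem setting

Input is a binary disease × lncRNA matrix **A** (1 = curated association,
0 = unknown), a disease ontology as a child→parent DAG, and one nucleotide
sequence per lncRNA. The task is positive–unlabeled link prediction:
score every (disease, lncRNA) cell, treating the zeros as *unlabeled*
rather than negative.

## Similarity views

**DSS (disease semantic similarity).** Each disease contributes 1 to its
own semantics; an ancestor reached through k DAG edges contributes
`Δ^k` along the best path (semantic contribution, SC), with decay
**Δ = 0.5** per edge — the conventional value for this family of
ontology similarities; the similarity of two diseases is the summed shared
contribution normalised by the two semantic values,
`Σ_{d∈D_i∩D_j}(SC_i(d)+SC_j(d)) / (SV_i + SV_j)`. Multiple parents are
resolved by the maximal contribution (best path).

**DCS.** Cosine similarity between association profile rows. Entities with
an all-zero profile get 0 off-diagonal and 1 on the diagonal rather than
NaN; the same convention applies wherever a profile or disease set is
empty.

**DGS / LGS (GIP kernel).** `exp(−γ‖p_i − p_j‖²)` over profile
rows/columns with `γ = γ′ / mean_k ‖p_k‖²` and `γ′ = 1`. This is the
standard "normalised bandwidth" construction: the kernel width adapts to
the average profile density. All profiles zero is a degenerate input and
raises.

**LFS.** Best-match averaging of DSS across the two lncRNAs' disease
sets: `[Σ_{d∈D_i} max_{d′∈D_j} DSS(d,d′) + symmetric] / (|D_i|+|D_j|)`.

**LSES.** Weighted edit distance with insertion/deletion cost 1 and
substitution cost 2 (computed by dynamic programming in a numba kernel;
with these costs the optimum equals `len_1 + len_2 − 2·LCS`). The
normalised cost `cost/(len_i+len_j)` is a distance, 0 for identical
sequences; we report `1 −` that value so the view is a similarity with
unit diagonal, consistent with the other five. `raw_distance=True`
preserves the plain normalised cost for anyone who wants the literal
distance form. T and U are normalised to one alphabet on read.

All six views are symmetric matrices in [0, 1] with unit diagonal, indexed
by the association matrix's canonical (sorted) entity order.

## Multi-view encoder

Each view is converted to a weighted edge list (all off-diagonal entries
above a sparsification threshold, default 0, plus mandatory unit
self-loops) and passed through its own stack of **three single-head GAT
layers**, widths input → 256 → 128 → **64**. Attention per edge (i ← j)
is `softmax_j( LeakyReLU(a_s·h_iW + a_d·h_jW) + log w_ij )`: the edge
weight enters as an additive log-term, i.e. it multiplies the
unnormalised attention, so the softmax respects the graph's weights while
remaining learnable. Activations are LeakyReLU (negative slope 0.2).
Initial node features are each node's row of its view's similarity matrix
(a self-describing profile; the model is silent on initialisation, and
this choice needs no extra parameters).

Per-node features are aggregated across views by **element-wise mean**;
during training a dropout mask (rate 0.5) is applied to the aggregated
feature as a stochastic regulariser, and never at inference. Training
minimises the masked inner-product reconstruction loss

    loss = (1/n²) Σ_j ‖ b_j ⊙ (F Fᵀ − A_j) ⊙ b_jᵀ ‖²_F

with the raw inner product as reconstruction (no sigmoid/clamp), node
masks `b_j` defaulting to all-ones (every view covers the full entity
set; the mask mechanics are implemented and tested for generality), Adam
at learning rate 1e-3, full batch, **200 epochs**, best-iterate
checkpointing on the dropout-free loss (so the returned F never scores
worse than the initialisation). Disease views and lncRNA views train as
two independent encoder stacks. All parameters are initialised from a
seeded generator; runs are bit-reproducible per seed.

The backward pass runs on a small reverse-mode autodiff engine written
for exactly the operations this architecture needs (matmul, broadcast
add/mul, LeakyReLU, masked row-softmax, square/sum); its gradients are
validated against central finite differences in the test suite.

## Negative-sample denoising

Every cell of **A** becomes a sample: feature = concat(disease embedding,
lncRNA embedding), disease first (128 dims); label positive iff A = 1.
K is selected by maximal mean silhouette over candidates 2..10 (ties to
the smallest K; one seeded K-means fit per candidate). The silhouette is
computed on the full sample set up to 20 000 samples and on a seeded
subsample beyond that (the statistic is quadratic in n).

Denoising then runs one initial clustering whose per-cluster positive
proportions are recorded for diagnostics only (they do not influence the
result), followed by **10 rounds** of K-means with seeds
`base_seed + t`. Each round selects the cluster with the highest positive
proportion — ties broken toward the larger cluster, then the lower index
— and records its unknown members; `U_noise` is the intersection across
all 10 rounds (the strict printed intersection, not a majority vote), and
`U_reliable = U − U_noise`. Distances are Euclidean on the raw 128-dim
features; K-means uses k-means++ with 10 restarts per round, and a round
that produces an empty cluster is re-seeded (logged).

## Stacking ensemble

Training data are balanced 1:1 — all positives against an equal number of
negatives drawn uniformly without replacement from `U_reliable` (if fewer
are available, all are used with a warning). A stratified 80/20 split
separates the model-selection pool from the held-out set. Five tree-based
base learners at library defaults (XGBoost, LightGBM, sklearn
HistGradientBoosting, ExtraTrees, RandomForest — three boosted flavours,
randomised trees and bagged forests) produce out-of-fold probabilities
under stratified 5-fold CV inside the pool; the logistic-regression
meta-learner is fit on those 5 OOF columns only (no raw features pass
through), and the base learners are refit on the full pool. When the
minority class is smaller than the fold count, the fold count shrinks to
match (degenerate-input guard). Model selection compares the stacked
model and each base learner on the held-out split by AUC, ties broken by
AUPR, and exports the winner.

## Evaluation

ACC, MCC, F1, precision and recall come from the confusion matrix at a
hard-label threshold of 0.5, with MCC = 0 (and precision/recall/F1 = 0)
when a denominator vanishes. AUC uses the midrank tie convention; AUPR is
step-wise precision–recall integration. Cross-validation reports each
metric's per-fold values with the mean and the **population variance**
over the five folds (variance, not SEM — labelled as such in all
outputs). Per-disease ranking (`leave_disease_out`) removes every pair of
the target disease from the balanced training set, retrains the
classifier (embeddings and denoising are reused by default — a full
upstream retrain is substantially more expensive and changes nothing in
the leakage guarantee, since the downstream model is what sees labels),
scores all lncRNAs for that disease and returns the top 30. View
ablations rerun encoder and downstream stages per view subset with shared
seeds.

## Synthetic data

The generator plants the structure the method assumes, at a scale where
the full pipeline runs in a few minutes on one CPU (defaults: 80
diseases × 120 lncRNAs, latent rank 4, density 0.1, 10% hidden
positives, master seed 42):

* every entity gets an **activity** flag (a fixed-size random third of
  each entity set; exact counts rather than Bernoulli draws keep the
  planted block size controlled at every fixture scale) and a latent
  **family** (one of 4). Association scores are inner products of the
  latent vectors — activity dominating (scale 2.0), family alignment
  modulating (scale 0.7) — plus Gaussian noise (σ 0.5), thresholded at
  the exact target density. This mimics the hub-dominated degree
  distributions of curated association databases;
* a fraction of the true positives ("hidden positives") is relabelled
  unknown in the observed matrix — the planted noise the denoiser should
  recover;
* the disease DAG hangs per-family internal chains (depth 3) under a
  common root, so semantic similarity correlates with family;
* sequences evolve from per-family ancestor strings (length 200–400 nt)
  by point substitution at family-specific rates spanning 0.05–0.3, so
  sequence similarity carries family signal at several strengths;
* the generator also exposes the latent 64-dim "oracle" embeddings (the
  ideal encoder output), which the denoiser unit tests use to exercise
  that stage in isolation.

Everything is deterministic per master seed, including FASTA/TSV output
bytes.

**What passing tests show — and do not.** The planted signal is strong and
low-rank by construction, so end-to-end metrics near 1.0 demonstrate that
the pipeline's stages compose correctly and recover planted structure,
not that comparable numbers would be reached on curated databases, whose
label noise, synonymy artifacts, literature bias and much weaker latent
structure the generator deliberately does not emulate. The permutation
control (shuffled pool labels → held-out AUC ≈ 0.5) guards against
leakage rather than inflating the headline numbers.

## Numerical choices and degenerate inputs

* Similarity matrices are symmetrised (`(M+Mᵀ)/2`) and clipped to [0, 1]
  against floating-point drift; symmetry is enforced to 1e-12.
* Zero profiles / empty disease sets: similarity 0 off-diagonal, 1 on the
  diagonal. All profiles zero: GIP raises a degenerate-input error.
* Non-finite encoder loss raises with the epoch index; isolated nodes
  without self-loops are rejected.
* Ties in K selection go to the smallest K; ties in cluster selection to
  the larger cluster, then the lower index; ranking sorts are stable.
* Every stochastic stage derives its seed from the single pipeline seed
  (recorded in the run manifest), so reruns are byte-identical.

## Known limitations

* Single-head attention and one aggregation scheme (mean); no multi-head
  or contrastive variants.
* The dense attention implementation is comfortable to ~1000 nodes per
  entity type; larger graphs would want sparse edge-indexed attention.
* No hyperparameter search or probability calibration; base learners run
  at library defaults by design.
* Real-database identifier harmonisation (synonyms, cross-database
  merging) is out of scope; inputs are assumed already curated.
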