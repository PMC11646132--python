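# Methods

## Problem and model

`m6afuse` classifies variable-length nucleotide sequences (20–800 nt
peak regions, as produced by m⁶A-seq enrichment in rice) as containing an
m⁶A site or not. Sequences are normalized to the DNA alphabet (U→T),
left-padded with a padding symbol P to a common maximum length
L_max = 800, and label-encoded with the fixed map P/A/T/G/C → 0/1/2/3/4.

The network has four parts.

**Embedding and projection.** Codes are embedded (width `embed_dim`,
default 64); the padding row of the table is fixed at zero and excluded
from gradient updates so the padded prefix carries no learnable signal.
A point-wise convolution projects to `out_channel` = C channels (default
128), giving O_embed of shape C × L_max.

**Multi-kernel feature fusion (MKFF).** Four parallel paths read
O_embed: a point-wise convolution (k1); point-wise bottlenecks followed
by kernel-3 and kernel-5 convolutions (k2, k3); and a stride-1,
length-preserving kernel-3 max-pool followed by a point-wise convolution
(k4). Each path emits C/4 channels; every feature-producing convolution
is followed by ReLU. The concatenated paths are fused point-wise to
MK_Fea. Two attention branches then weight MK_Fea:

* *global channel gate* — average-pool over positions, a single-channel
  convolution sliding across the channel axis with adaptive kernel size
  k_adp, then sigmoid; k_adp is the largest odd integer ≤
  |log₂(C)/γ + b/γ| with γ = 2, b = 1 (so k_adp = 3 at C = 128);
* *local spatial map* — squeeze (C → C/r) and excitation (C/r → C)
  convolutions of width k_adp along positions (reduction ratio r = 4),
  followed by softmax over positions independently per channel. No ReLU
  is used inside the weight-producing branches.

The two weighted maps are concatenated, fused point-wise (ReLU), and
added residually to O_embed, giving O_MKFF. Ablation variants are pure
configuration: `fusion_mode` ∈ {gldf, cat, add, global, local} (cat
passes MK_Fea straight through; all variants keep the residual) and
`kernel_combo` ⊆ {k1..k4}.

**Downsampling residual feature embedding (DRFE).** A stem of two
equal-length kernel-5 convolutions, then three downsampling-residual
blocks: max-pool (kernel 3, stride 2, pad 1) followed by a residual
equal-length double convolution. Positions go 800 → 400 → 200 → 100, an
eightfold compression of the padded feature space before the head. The
pooling stride is not dictated by the architecture's description; stride
2 is the package default and is configurable.

**Output.** The flattened embedding feeds a single-logit fully connected
layer with sigmoid. A probability below the threshold (default 0.5) is
classified negative; the boundary value is positive.

## Objective

Training minimizes L_total = L_cl + L_bce (unweighted).

* L_bce is mean binary cross-entropy with probabilities clipped to
  [1e−7, 1−1e−7].
* L_cl is the margin contrastive loss
  ½[(1−K)·D² + K·max(0, M−D)²] on flattened DRFE embeddings, with K = 0
  for a same-class pair, K = 1 otherwise, D the Euclidean distance, and
  margin M = 2. Pairs are formed by a seeded random disjoint pairing
  within each minibatch (N/2 pairs, odd leftover dropped) and the loss is
  averaged over pairs; an all-pairs mode is available
  (`pair_mode="all"`). The gradient of D at D = 0 uses the subgradient 0
  so coincident embeddings are handled exactly.

Optimization uses Adam at 1e−3 (batch size 128, up to 50 epochs, early
stopping on validation AUC with patience 5, best weights restored).
These training-loop settings are package defaults, not values fixed by
the architecture.

## Numerical substrate

The network runs on a compact reverse-mode automatic differentiation
engine over NumPy (`m6afuse.autodiff`): stride-1 convolution via im2col
and a single GEMM, strided max-pooling with −inf padding (padding can
never win the max; ties resolve to the first maximum), an embedding
lookup with frozen rows, and the usual elementwise ops and reductions.
Graphs are cycle-free so memory frees promptly; `no_grad()` gives an
inference mode. Parameters are float32 by default; float64 is available
and used in the oracle-equivalence tests, which compare every operation
against explicit-loop reference implementations at 1e−6.

## Evaluation

ACC and MCC are computed at the decision threshold (MCC defined as 0
when its denominator vanishes), AUC from the ROC curve (equivalent to
the pairwise rank statistic), and AUPR by the average-precision
convention. Cross-validation is stratified k-fold (default k = 5):
each fold trains on the other four and is evaluated — and used for early
stopping — as the held-out 20%, matching an 80/20 train/validation
protocol. Reports give per-fold values and mean ± sample standard
deviation at four decimals.

## Synthetic data

The generator emulates the structure of the rice benchmark rather than
its sequence content (the real peaks are not redistributable): uniform
lengths in [20, 800] nt, a 1:2 positive:negative ratio, uniform
background composition (configurable), and positives distinguished by
planted motifs (default the RRACH-consensus-style 5-mer GGACT; IUPAC
degenerate motifs are resolved per position). The default copy count is
length-scaled — 1 + length//160, about one occurrence per 160 nt,
placed without overlap — reflecting that real peaks carry consensus-class
occurrences at roughly constant density, so longer peaks contain more.
With the default `decoy_policy="none"`, negatives are resampled until
they contain no match to any motif pattern, so a simple motif scan
separates the classes perfectly: the learning task is solvable by
construction and learning-based checks are meaningful. Ground-truth
motif intervals (0-based, half-open) are kept per record.

What the generator does **not** emulate: realistic base composition and
k-mer background statistics, sequence homology structure, read-coverage
or peak-calling artifacts, and label noise. Passing the learning checks
therefore demonstrates that the architecture, objective, and training
loop can extract a planted sequence signal at desk scale — not that the
printed benchmark performance on real rice data is reproduced.

## Interpretation

Saliency is the L2 norm over embedding dimensions (absolute-sum
optional) of the gradient of the predicted probability with respect to
the embedding vectors, reported only for non-padding positions. A
fixed-width sliding window (stride 1; defaults width 10, top-3) scores
regions by summed saliency; top-k non-overlapping windows are chosen
greedily with ties to the leftmost. Window subsequences export as FASTA
for external motif-alignment tools; windows as BED (0-based, half-open).
Feature vectors can be exported at four stages (MP — the padded code
vector; MKC — concatenated multi-kernel features entering the fusion
function; GLDF — the fused module output including the residual; DRFE —
the compressed embedding), and class separation is quantified with the
silhouette score. Localization quality is tested by a one-sided
permutation test comparing top-1 window overlap with planted motif
intervals against uniformly placed windows of the same width.

## Scaled-down benchmark protocol

`scripts/acceptance.py` (and the corresponding end-to-end tests) run
`m6afuse.protocols.reduced_study`: 2000 synthetic sequences (667
positive, 1333 negative), an 80/20 split, and a reduced model —
out_channel 32, embed_dim 32, batch size 128, at most 10 epochs — sized
so the full study runs in minutes on one CPU. The study trains the
dynamic-fusion model and the plain-concatenation (`fusion_mode="cat"`)
variant under identical seeds, reports validation ACC/MCC/AUC/AUPR,
compares DRFE-stage silhouette scores between the two, and runs the
saliency permutation test (60 positive validation records, window 10,
500 permutations). The claims at this scale are direction-of-effect
only (e.g. saliency localizes planted motifs above a random baseline);
magnitudes from the full-size rice study are not claimed, and the
silhouette comparison has a known negative outcome at desk scale (see
limitations).

## Known limitations

* At the scaled-down benchmark's conditions, the dynamic-fusion model's
  DRFE silhouette does **not** exceed the concatenation variant's (both
  variants reach ceiling AUC on the fully separable planted-motif task,
  and concatenation passes unattenuated path features to the embedding
  with fewer layers to train in the 10-epoch budget). The embedding-
  separation advantage of fusion concerns noisy, non-separable real peak
  data, which the generator does not emulate; the corresponding
  end-to-end test records this as a failing expectation rather than
  hiding it.
* Within the fixed 10-epoch budget the reduced protocol sits at the edge
  of the training transition: some seeds reach validation AUC 1.0 by
  epoch 7, others are still climbing at epoch 10.

* The contrastive term acts on raw flattened embeddings; early in
  training its same-class pull dominates the objective until embedding
  norms shrink, which can slow the first epochs. The w/o-CL variant
  (`use_cl=False`) avoids this.
* No normalization layers are used anywhere (none are part of the
  architecture); very deep configurations may need smaller learning
  rates.
* The softmax axis of the local attention and the pooling stride of the
  DR blocks are configurable because the architecture description leaves
  them open; defaults are positions and 2 respectively.
* Training is CPU-only and single-threaded BLAS-bound; wall time scales
  linearly with L_max × out_channel² × dataset size.
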