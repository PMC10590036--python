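# Methods

## Data model and preprocessing

A dataset is a list of samples (batches) `d = 1..D`, each with raw UMI
counts (spots × genes), 2-D Euclidean coordinates, and identifiers. Model
input is `x_i ∈ [0,1]^M`: genes are restricted to the intersection across
samples, the top `M` genes by dispersion (variance/mean of the concatenated
library-size-normalised log1p matrix) are kept (`M = 3000` by default for
real platforms, 500 for the simulator, which only generates 500), each spot
is normalised to the global median library size, log1p-transformed, and
each gene min-max scaled. Scaling is fit on the concatenated matrix, not
per sample: per-sample scaling would re-inject each batch's dynamic range
into the very signal the model is meant to clean. Constant genes map to 0
(the 0/0 case of min-max). The [0,1] range is what makes a
binary-cross-entropy decoder meaningful.

Quality control keeps spots with total UMI ≥ 3000 and ≥ 15 detected genes
by default (tuned to bead-level platforms; both thresholds are arguments).
Sub-cellular platforms are binned on a square grid (default 50 units) by
flooring shifted coordinates; bin centres become spot coordinates and UMIs
are summed, so total counts are conserved exactly.

Spatial graphs are per-sample and symmetric, with no self-loops. kNN uses
union symmetrisation (an edge exists if either endpoint ranks the other in
its top k), guaranteeing minimum degree ≥ k; ties at equal distance go to
the lower index so graphs are reproducible. Defaults: k = 6 for
Visium-like lattices, 8 for bead/bin platforms, 10 for the simulator. A
`radius` mode thresholds Euclidean distance, and a `feature` mode builds
kNN on a 50-component PCA of expression — the graph used when projecting
dissociated scRNA-seq through a trained model.

## Integration model

Four networks share one objective.

* **Encoder** (GraphSAGE, K = 2, mean aggregator, widths M→512→32, no
  biases): `h_i^1 = ReLU(W^1 [x_i, mean_N(i) x])`,
  `z_i = W^2 [h_i^1, mean_N(i) h^1]` with the final layer linear. Isolated
  nodes aggregate their own features. Full neighbour sets are used (degrees
  here are ≤ ~2k, so fan-out subsampling would only add variance).
* **Decoder** (32→512→M, ReLU then logistic) reconstructs `x` under
  gene-summed binary cross-entropy `l_de`.
* **Discriminator** (28→32→16→out) reads the biology columns through a
  gradient reversal layer (identity forward, gradient × −1 backward) and
  predicts the batch (logistic for D = 2, softmax otherwise).
* **Classifier** (4→out, a single linear map on the noise columns)
  predicts the batch without reversal.

The split `z = [z_noise (4), z_bio (28)]` resolves the head widths
consistently: the classifier's "4" is its input dimension, the
discriminator's "32–16" its hidden widths. The random-walk loss

    l_gs = Σ_pos −log σ(z_i·z_j) + Σ_neg −log(1 − σ(z_i·z_n))

is applied to `z_bio` (the part that should carry spatial structure), with
positives from `n_walks = k` one-step uniform walks per spot and uniform
negatives drawn from same-sample minibatch spots excluding each spot's walk
co-occurrence set, ≈1:1 with positives. All log-sigmoids are computed via
`logaddexp`, so saturated pairs cannot overflow.

Total loss per minibatch: `l_gs + l_de·M + λ·l_disc + γ·l_class` with
λ = γ = 1. `l_de` enters as the per-spot per-gene *mean* BCE so that
`l_de·M` equals the gene-summed decoder loss exactly once. λ controls the
aggressiveness of batch mixing; lowering it is advisable when samples
contain genuinely batch-specific populations that must not be forced
together.

**Training.** Adam, lr 1e-3, weight decay 5e-4, 100 epochs, Glorot-uniform
initialisation, all driven by one seeded generator (two runs with the same
seed are bitwise identical). Each optimisation step draws one shuffled
minibatch from *every* sample (shorter queues wrap around), computes the
encoder forward per sample, and evaluates the adversarial heads on the
mixed-label concatenation — a discriminator that only ever saw one batch
label per step would receive no useful adversarial signal. Walk pairs are
regenerated every step. The default minibatch size is 64 per sample,
chosen so that a few-thousand-spot dataset still takes several hundred
gradient steps per training run; it is configurable from 16 to 512.
Backpropagation is hand-written (the model is four small dense networks
plus two sparse aggregation matmuls), and gradient correctness is pinned by
finite-difference tests.

**Outputs.** Batch-corrected expression is `decode([0, z_bio])` — the
classifier's presence during training is what makes zeroing the noise
columns meaningful. Unseen samples are embedded inductively (one forward
pass over their own graph) and labelled by the nearest training-cluster
centroid in `z_bio` space.

## Clustering and refinement

Joint clustering runs on `z_bio` of all spots. `graph_community` builds a
k = 15 SNN graph (Jaccard weights on kNN sets, pruned below 1/15) and runs
Louvain at a given resolution; resolution is a granularity dial — ~1.0
resolves fine structure with some over-segmentation (harmless for ARI and
for alignment, which operates per cluster), ~0.1 yields macroscopic
domains. `gaussian_mixture` fits EM with the component count given and the
covariance model (full/tied/diag/spherical) selected by BIC; it plays the
role the mclust R package plays in comparable pipelines, with behavioural
rather than bitwise equivalence. Optional spatial refinement does one
synchronous pass in which a spot adopts its neighbourhood's label only on a
strict majority (> half of neighbours); ties leave it unchanged, so a
spatially perfect labelling is a fixed point and no new label can appear.

## Coordinate alignment

The reference is the sample with the largest convex-hull area (spot count
breaks degenerate cases; a user override is accepted). Shared clusters are
joint labels with ≥ 10 spots in both samples — below that, the
Gromov-Wasserstein problem is too small to be meaningful.

Per shared cluster, the fused GW objective combines the Euclidean distance
between biology embeddings, weighted (1−α), with the squared distortion of
within-sample coordinate distances, weighted α (α defaults to 0.6; 0.5–0.8
is the sensible range — more weight on expression compensates for noisy
clustering, more on geometry preserves local structure). Marginals are
uniform on both sides. The solver is conditional gradient from the product
coupling: the linearised subproblem is solved *exactly* (Hungarian
assignment when the two sides have equal size and uniform weights — an
optimal transport vertex is then a permutation — otherwise HiGHS linear
programming), followed by a closed-form line search on the quadratic
objective, so the objective is non-increasing by construction. Tolerance
1e-9 on the relative objective change, at most 1000 outer iterations;
non-convergence returns the last iterate with a warning flag. Iterates stay
exactly feasible, so coupling marginals hold to floating-point precision.

Each query spot's new coordinate is the *unweighted* mean of reference
coordinates with coupling mass above 1e-8 (strict positivity is not
implementable in floating point; an all-below-threshold column falls back
to its argmax row). A π-weighted mean is available but off by default.
Sample-specific spots are placed by least-squares Procrustes
(SVD of the cross-covariance, rotation constrained to det +1, uniform
scale on by default, translation from centroids) fitted on the
shared-cluster spots as landmarks; the transform is fitted once per sample,
not per cluster, since it represents a single change of frame. Clusters
are aligned independently, so their images may overlap in the reference
frame; no de-conflicting is attempted. Because the GW term sees only
within-sample distances, the output is invariant to rigid motions and
uniform scalings of the query's input coordinates.

## Metrics

* **LISI**: per spot, Gaussian kernel weights over the 3×perplexity nearest
  neighbours are calibrated by bisection to a fixed perplexity (default
  30); the score is the inverse Simpson index of the weighted label
  frequencies, in [1, #labels]. Batch-LISI over the whole dataset is the
  mixing metric (iLISI).
* **LISI-CoM** `= 2·((1/d)·b)/((1/d)+b)` on normalised values
  `b, d = (median LISI − 1)/(#labels − 1)`, floored at 1e-3 because the
  combination diverges as the domain term approaches 0. The normalisation
  constants are a documented choice; alternatives can be substituted.
* **SCS**: entropy of unordered label-pair frequencies over graph edges,
  z-scaled against label permutations (default 1000) as
  `(mean(H_perm) − H_obs)/sd(H_perm)` — the sign convention makes larger
  mean more spatially coherent. Single-label inputs return H = 0 with z
  = +inf, flagged rather than erroring.
* **Moran's I / Geary's C** with binary graph weights (textbook formulas);
  Geary is reported as 1 − C so that, like I, larger means more
  autocorrelated. Constant inputs are rejected.
* **ARI** via the standard contingency-table computation; an independent
  hand-computed oracle pins it in the tests.
* **Batch probe**: balanced accuracy of a fresh logistic regression
  predicting batch from an embedding (50/50 stratified split). Balanced
  accuracy keeps chance at 1/D even when batch sizes differ.

## Simulator

Counts follow a Splatter-style gamma-Poisson hierarchy: per-gene base means
Gamma(0.6, rate 0.3); per-group DE factors exp(±N(0.3, 0.2)) on 10% of
genes; per-batch factors exp(±N(0.12, 0.08)) on all genes; library sizes
logN(log 5000, 0.2); Poisson sampling (a negative-binomial option is not
included — Poisson is the variance floor and suffices for the designs
here). Group2 reuses 80% of Group1's DE genes with factors perturbed by
exp(N(0, 0.05)), making the pair transcriptionally adjacent; their spatial
strips sit at opposite ends of the unit square, making them physically
distant. That pair is the simulator's point: expression-only clustering
cannot separate it, spatial context can.

Scenarios: simulate1–3 have four groups with identical compositions in two
batches (1: identical layouts; 2: reversed strip order in batch 2; 3:
additionally rotated 60° and scaled ×1.5); simulate4 has Group1–4 shared
plus Group5/Group6 specific to batch 1/2; simulate5 has three batches with
compositions {G1,G2,G3}, {G1,G3,G4}, {G2,G3,G5,G6}. Shared groups always
keep identical layouts across batches. Placement is grid-jittered uniform
within axis-aligned rectangles (an error is raised if rectangles overlap);
geometry operations are stored as exact matrices and hence invertible.

What the simulator does *not* emulate: spot-level cell mixtures, platform
lattice geometry (hex grids), spatially smooth within-domain expression
gradients, zero-inflation beyond Poisson sampling, and mean-variance trends
(common BCV). Passing tests therefore demonstrate correct mechanics and
recovery under the stated generative model, not performance on any real
tissue.

## Numerical choices and limitations

* BCE clamps predictions to [1e-7, 1 − 1e-7]; contrastive and head losses
  use log-sigmoid / shifted softmax throughout.
* Non-finite losses abort training with the epoch reported.
* kNN ties: lower index; duplicate points are handled the same way.
* Study-scale runs in the tests and the acceptance script use two batches
  of 250 cells/group (simulate1/3), 500 genes, 100 training epochs,
  minibatch 64, and a stratified half of batch 2 held out for the
  inductive-prediction check; the batch-shift experiment uses 100
  cells/group and 60 epochs.
* The GW objective is non-convex; conditional gradient finds a stationary
  point, not a certified global optimum. For the cluster-level problems
  here (hundreds of spots, strong feature term) it converges in a handful
  of iterations.
* With D = 2 the adversarial heads are logistic; a single-sample dataset
  trains but its adversarial losses are vacuous (warned).
* LISI-CoM's normalisation and floor are package choices where the metric's
  published description leaves them open; comparisons across tools should
  use the same normalisation.
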