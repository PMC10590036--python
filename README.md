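# spiral-srt

Spatially aware integration and alignment of multi-sample spatially resolved
transcriptomics (SRT) data.

When several SRT slices are measured — replicates, adjacent sections,
different protocols or platforms — two obstacles block joint analysis: batch
effects contaminate the expression space, and each slice lives in its own
coordinate frame. Expression-only integration methods (Harmony, Seurat CCA)
cannot separate cell populations that are transcriptionally similar but
occupy different tissue regions; purely geometric slice alignment breaks
down when slices are rotated, scaled, or have different region compositions.

This package addresses both with two consecutive modules:

**Integration.** A two-layer GraphSAGE encoder embeds each spot by
aggregating the min-max-scaled expression `x_i ∈ [0,1]^M` over its spatial
k-nearest-neighbour graph (graphs never cross samples):

    h_i^k = ReLU(W^k · [h_i^{k-1}, mean_{j∈N(i)} h_j^{k-1}]),   z_i = h_i^K (linear)

The 32-dimensional embedding is split column-wise into a 4-dim *noise* part
and a 28-dim *biology* part, disentangled by two adversaries: a batch
classifier on `z_noise` (keeps batch identity there) and a batch
discriminator on `z_bio` behind a gradient reversal layer (removes batch
identity from the biology part). A decoder reconstructs `x` from the full
`z` under binary cross-entropy, and a random-walk contrastive loss on
`z_bio` keeps spatial neighbours close in embedding space. The total loss is

    l_total = l_gs(z_bio) + l_de·M + λ·l_disc + γ·l_class,   λ = γ = 1

optimised with Adam (lr 1e-3, weight decay 5e-4, 100 epochs). Batch-free
expression is obtained by decoding with `z_noise = 0`. The encoder is
inductive: unseen samples are embedded with a single forward pass over their
own spatial (or expression-similarity) graph.

**Alignment.** After joint clustering of `z_bio` (SNN-Louvain or Gaussian
mixture), each query sample is mapped into a reference sample's coordinate
frame. Per shared cluster `c`, a fused Gromov-Wasserstein coupling Π
minimises

    F_c = (1−α)·Σ_ij e(z_i, z_j)·π_ij + α·Σ_ijkl (d_ik − d_jl)²·π_ij·π_kl

(`e` = embedding distance, `d` = within-sample coordinate distances,
α ∈ [0.5, 0.8]); each query spot moves to the mean of its coupled reference
spots. Spots of sample-specific clusters are carried over by a least-squares
Procrustes similarity transform fitted on the shared-cluster spots. Because
the spatial term uses only within-sample distances, the alignment absorbs
arbitrary rotations and scalings between slices.

Also included: LISI / LISI-CoM, the z-scaled spatial coherence score (SCS),
Moran's I and converted Geary's C, ARI, and a Splatter-style gamma-Poisson
simulator producing the five multi-batch spatial study designs
(`simulate1`–`simulate5`) used throughout the test suite.

## Worked example

```python
import numpy as np
from spiral import (make_scenario, preprocess_expression, build_graph,
                    fit, TrainingConfig, cluster_embeddings, align_samples,
                    ari, metrics)

# two batches, four groups; Group1/Group2 are transcriptionally similar
# but spatially distant — expression-only clustering confuses them
samples, groups, batches, _ = make_scenario("simulate1", seed=0,
                                            cells_per_group=250)
samples = preprocess_expression(samples, n_genes=500)
graphs = [build_graph(s.coords, "knn", 10) for s in samples]

model, emb = fit(samples, graphs, TrainingConfig(epochs=100, batch_size=64,
                                                 seed=0))
labels = cluster_embeddings(emb.z_bio, "graph_community", 1.0, seed=0)
print("ARI vs ground truth:", round(ari(groups, labels.labels), 3))
print("batch probe on z_noise:",
      round(metrics.batch_probe_accuracy(emb.z_noise, batches), 3))
print("batch probe on z_bio:",
      round(metrics.batch_probe_accuracy(emb.z_bio, batches), 3))
```

```
ARI vs ground truth: 0.894
batch probe on z_noise: 1.0
batch probe on z_bio: 0.463
```

The biology embedding recovers the simulated groups (ARI 0.89) while a
fresh logistic probe can no longer tell batches apart on it (balanced
accuracy ≈ 0.5 = chance); batch identity is fully concentrated in the noise
columns (probe accuracy 1.0). Coordinate alignment then maps, e.g., the
rotated-and-scaled second batch of `simulate3` back onto batch 1:

```python
samples3, groups3, _, _ = make_scenario("simulate3", seed=0, cells_per_group=250)
# ... preprocess, embed (or use PCA features), cluster ...
results = align_samples(samples3, groups3, emb3, reference_id="batch1", alpha=0.6)
```

after which per-group centroids of the query land on their reference
regions to numerical precision and the spatial coherence score of the
overlay rises (see `scripts/acceptance.py` output).

A command-line pipeline wraps the same steps:

```bash
spiral simulate --scenario simulate1 --out data/
spiral integrate --config config.yaml --out run/
spiral cluster --embeddings run/embeddings.csv --method louvain --out labels.csv
spiral align --embeddings run/embeddings.csv --labels labels.csv --out aligned/
spiral evaluate --embeddings run/embeddings.csv --labels labels.csv --out report.json
```

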