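"""Shared fixtures: simulated datasets and session-scoped trained models."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split

from spiral import integration as integ
from spiral import io_graph as iog
from spiral.synthetic import make_scenario


@pytest.fixture(scope="session")
def tiny_pre():
    """Small two-batch dataset for fast unit tests (preprocessed, with graphs)."""
    samples, glab, blab, _ = make_scenario("simulate1", seed=3, cells_per_group=30)
    pre = iog.preprocess_expression(samples, n_genes=120)
    graphs = [iog.build_graph(s.coords, "knn", 10) for s in pre]
    return {"samples": pre, "graphs": graphs, "groups": glab, "batches": blab}


@pytest.fixture(scope="session")
def sim1_bundle():
    """The integration study dataset: two batches, 250 cells per group.

    Batch 2 is split in half (stratified by group); one half joins training,
    the other is the held-out set for inductive prediction.
    """
    samples, _, _, scen = make_scenario("simulate1", seed=0, cells_per_group=250)
    b2 = samples[1]
    idx_a, idx_b = train_test_split(
        np.arange(b2.n_spots), test_size=0.5, random_state=0,
        stratify=b2.group_labels,
    )
    idx_a.sort()
    idx_b.sort()
    pre = iog.preprocess_expression(
        [samples[0], b2.subset_spots(idx_a), b2.subset_spots(idx_b)], n_genes=500
    )
    train_pre, held_pre = pre[:2], pre[2]
    graphs = [iog.build_graph(s.coords, "knn", 10) for s in train_pre]
    truth = np.concatenate([s.group_labels for s in train_pre])
    batch = np.concatenate(
        [np.full(s.n_spots, d) for d, s in enumerate(train_pre)]
    )
    return {
        "train": train_pre,
        "held": held_pre,
        "graphs": graphs,
        "truth": truth,
        "batch": batch,
        "scenario": scen,
    }


@pytest.fixture(scope="session")
def sim1_trained(sim1_bundle):
    """Model trained for 100 epochs on the simulate1 training samples."""
    config = integ.TrainingConfig(epochs=100, batch_size=64, seed=0)
    model, emb = integ.fit(sim1_bundle["train"], sim1_bundle["graphs"], config)
    return {"model": model, "embeddings": emb, **sim1_bundle}


@pytest.fixture(scope="session")
def shift_trained():
    """Two-batch fixture with one injected pure batch-shift gene, briefly trained.

    Gene 0 of batch 2 is multiplied by 4 in every spot regardless of group —
    a batch artefact with no biological counterpart.
    """
    samples, _, _, _ = make_scenario("simulate1", seed=1, cells_per_group=100)
    shifted = samples[1]
    counts = shifted.counts.copy()
    counts[:, 0] = counts[:, 0] * 4
    shifted.counts = counts
    pre = iog.preprocess_expression(samples, n_genes=500)
    graphs = [iog.build_graph(s.coords, "knn", 10) for s in pre]
    config = integ.TrainingConfig(epochs=60, batch_size=64, seed=1)
    model, emb = integ.fit(pre, graphs, config)
    gene_idx = pre[0].gene_names.index("gene0")
    batch = np.concatenate([np.full(s.n_spots, d) for d, s in enumerate(pre)])
    return {
        "samples": pre,
        "model": model,
        "embeddings": emb,
        "gene_idx": gene_idx,
        "batch": batch,
    }


@pytest.fixture(scope="session")
def sim3_aligned():
    """simulate3 (rotated + scaled batch 2) aligned with ground-truth clusters.

    The feature term uses a PCA embedding of the preprocessed expression, so
    the alignment result does not depend on a model training run.
    """
    from spiral import alignment as al

    samples, glab, _, scen = make_scenario("simulate3", seed=0, cells_per_group=250)
    pre = iog.preprocess_expression(samples, n_genes=500)
    X = np.vstack([s.expr for s in pre])
    zb = PCA(n_components=20, random_state=0).fit_transform(X)
    emb = integ.EmbeddingSet(
        z=np.hstack([np.zeros((len(zb), 4)), zb]),
        noise_dim=4,
        sample_idx=np.concatenate([np.full(s.n_spots, d) for d, s in enumerate(pre)]),
    )
    results = al.align_samples(pre, glab, emb, reference_id="batch1", alpha=0.6)
    return {
        "samples": pre,
        "groups": glab,
        "scenario": scen,
        "result": results["batch2"],
    }
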