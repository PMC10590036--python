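"""Evaluation statistics: LISI and its combined form, spatial coherence, autocorrelation, ARI.

LISI (local inverse Simpson index) measures how many label categories mix in
each spot's embedding neighbourhood: 1 means a pure neighbourhood, the
number of categories means perfect mixing. Batch-LISI should be high after
integration (batches mix) while domain-LISI should stay low (domains remain
separated); the combined score harmonically couples the two after
normalising each to (0, 1].

The spatial coherence score (SCS) is the z-scaled entropy of the label-pair
frequencies over graph edges against a label-permutation null; larger means
spatially more coherent. Moran's I and Geary's C (reported as 1 - C so
larger = more autocorrelated) quantify per-gene spatial autocorrelation with
binary graph weights.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .io_graph import SpatialGraph

__all__ = [
    "lisi",
    "normalize_lisi",
    "lisi_com",
    "spatial_coherence_score",
    "spatial_autocorrelation",
    "ari",
    "batch_probe_accuracy",
]

_NORM_FLOOR = 1e-3


def lisi(points: np.ndarray, labels: np.ndarray, perplexity: int = 30) -> np.ndarray:
    """Per-point local inverse Simpson index of ``labels`` in ``points`` space.

    Neighbourhood weights are Gaussian, calibrated per point to the given
    perplexity over its 3 * perplexity nearest neighbours (t-SNE style
    bisection on the kernel entropy); the index is 1 / sum_l p_l^2 over the
    weighted label frequencies. Values lie in [1, #labels].
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < n = {n}")
    k = min(3 * perplexity, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, idx = nn.kneighbors(points)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    uniq, lab_codes = np.unique(labels, return_inverse=True)
    target = np.log(perplexity)
    out = np.empty(n)
    d2 = dist**2
    for i in range(n):
        lo, hi = 0.0, np.inf
        beta = 1.0
        row = d2[i] - d2[i].min()
        for _ in range(64):
            w = np.exp(-beta * row)
            sw = w.sum()
            p = w / sw
            h = -np.sum(p * np.log(np.clip(p, 1e-300, None)))
            if abs(h - target) < 1e-5:
                break
            if h > target:  # too flat -> sharpen
                lo = beta
                beta = beta * 2 if np.isinf(hi) else (beta + hi) / 2
            else:
                hi = beta
                beta = (beta + lo) / 2
        freq = np.bincount(lab_codes[idx[i]], weights=p, minlength=len(uniq))
        out[i] = 1.0 / np.sum(freq**2)
    return out


def normalize_lisi(lisi_values: np.ndarray, n_labels: int) -> float:
    """Median LISI mapped to (0, 1]: (median - 1)/(#labels - 1), floored."""
    if n_labels < 2:
        raise ValueError("need at least 2 label categories")
    val = (float(np.median(lisi_values)) - 1.0) / (n_labels - 1)
    return max(val, _NORM_FLOOR)


def lisi_com(lisi_batch_norm: float, lisi_domain_norm: float) -> float:
    """Combined integration score 2 * ((1/d) * b) / ((1/d) + b).

    ``b`` is the normalised batch-LISI (high = batches mix) and ``d`` the
    normalised domain-LISI (low = domains separate); the score rewards both
    at once, harmonic-mean style.
    """
    if lisi_batch_norm <= 0 or lisi_domain_norm <= 0:
        raise ValueError("normalized LISI inputs must be positive")
    inv_d = 1.0 / lisi_domain_norm
    return 2.0 * (inv_d * lisi_batch_norm) / (inv_d + lisi_batch_norm)


def _edge_pair_entropy(edges: np.ndarray, labels: np.ndarray) -> float:
    """Entropy of unordered endpoint-label pair frequencies over the edges."""
    a = labels[edges[:, 0]]
    b = labels[edges[:, 1]]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    _, counts = np.unique(lo.astype(np.int64) * (labels.max() + 1) + hi, return_counts=True)
    p = counts / len(edges)
    return float(-(p * np.log(p)).sum())


def spatial_coherence_score(
    graph: SpatialGraph,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """z-scaled spatial coherence of a labelling on a spatial graph.

    Returns ``(z, H_obs)`` where H is the entropy of edge label-pair
    frequencies and z = (mean(H_perm) - H_obs) / sd(H_perm) over ``n_perm``
    label permutations, so larger z means spatially more coherent than
    random. A single-label input has zero entropy and an undefined z,
    returned as +inf.
    """
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    edges = graph.edges()
    if len(edges) == 0:
        raise ValueError("graph has no edges")
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    H_obs = _edge_pair_entropy(edges, codes)
    if codes.max() == 0:
        return np.inf, H_obs
    rng = np.random.default_rng(seed)
    H_perm = np.empty(n_perm)
    for t in range(n_perm):
        H_perm[t] = _edge_pair_entropy(edges, rng.permutation(codes))
    sd = H_perm.std(ddof=1)
    if sd == 0:
        return np.inf if H_perm.mean() > H_obs else 0.0, H_obs
    return float((H_perm.mean() - H_obs) / sd), H_obs


def spatial_autocorrelation(
    values: np.ndarray, graph: SpatialGraph
) -> tuple[float, float]:
    """Moran's I and converted Geary's C (1 - C) with binary graph weights."""
    x = np.asarray(values, dtype=float)
    if x.std() == 0:
        raise ValueError("values are constant: autocorrelation undefined")
    edges = graph.edges()
    if len(edges) == 0:
        raise ValueError("graph has no edges")
    n = graph.n_nodes
    xc = x - x.mean()
    denom = (xc**2).sum()
    i, j = edges.T
    # each unordered edge contributes twice to the symmetric weight sums
    s0 = 2.0 * len(edges)
    cross = 2.0 * (xc[i] * xc[j]).sum()
    sqdiff = 2.0 * ((x[i] - x[j]) ** 2).sum()
    morans_i = (n / s0) * cross / denom
    geary_c = ((n - 1) / (2.0 * s0)) * sqdiff / denom
    return float(morans_i), float(1.0 - geary_c)


def batch_probe_accuracy(embedding: np.ndarray, batches: np.ndarray, seed: int = 0) -> float:
    """Balanced accuracy of a fresh logistic probe predicting batch from an embedding.

    Chance level is 1/#batches regardless of batch-size imbalance. Used to
    quantify residual batch information in an embedding: near-chance on the
    biology part and near-perfect on the noise part indicates successful
    disentanglement.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import balanced_accuracy_score
    from sklearn.model_selection import train_test_split

    X_tr, X_te, y_tr, y_te = train_test_split(
        embedding, batches, test_size=0.5, random_state=seed, stratify=batches
    )
    probe = LogisticRegression(max_iter=2000, class_weight="balanced").fit(X_tr, y_tr)
    return float(balanced_accuracy_score(y_te, probe.predict(X_te)))


def ari(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index between two partitions."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(labels_a, labels_b))
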