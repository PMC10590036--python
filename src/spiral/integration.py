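"""Batch-effect removal by adversarial disentanglement on a spatial graph.

The model couples four networks. A two-layer GraphSAGE encoder aggregates
each spot's expression with the mean of its spatial neighbours and maps it to
a 32-dimensional embedding ``z``, split column-wise into a ``noise`` part
(batch identity) and a ``bio`` part (batch-invariant biology). A decoder
reconstructs the [0,1]-scaled expression from ``z`` under binary
cross-entropy. A batch discriminator reads the bio part through a gradient
reversal layer, so that minimising its cross-entropy trains the encoder to
*remove* batch information from ``z_bio``; a batch classifier reads the
noise part directly, concentrating batch information there. A random-walk
contrastive loss on ``z_bio`` keeps spatial neighbours close in embedding
space. Batch-corrected expression is obtained by decoding with the noise
columns zeroed.

The encoder is inductive: a trained model can embed spots of an unseen
sample given only its expression and a neighbourhood graph (spatial, or
expression-similarity for dissociated data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_graph import SpatialGraph, SRTSample
from .nn import Adam, GradientReversal, glorot_uniform, log_sigmoid, relu, sigmoid, softmax

__all__ = [
    "ModelDims",
    "TrainingConfig",
    "SpiralModel",
    "EmbeddingSet",
    "WalkPairSet",
    "init_model",
    "encode",
    "sample_walk_pairs",
    "graphsage_loss",
    "decode",
    "reconstruction_loss",
    "batch_head_losses",
    "batch_head_input_gradients",
    "total_loss",
    "fit",
    "corrected_expression",
    "predict_unseen",
    "save_model",
    "load_model",
]


@dataclass
class ModelDims:
    n_genes: int
    hidden: int = 512
    embed: int = 32
    noise_dim: int = 4
    disc_hidden: tuple[int, int] = (32, 16)

    @property
    def bio_dim(self) -> int:
        return self.embed - self.noise_dim


@dataclass
class TrainingConfig:
    hidden: int = 512
    embed: int = 32
    noise_dim: int = 4
    disc_hidden: tuple[int, int] = (32, 16)
    lambda_: float = 1.0
    gamma: float = 1.0
    lr: float = 1e-3
    weight_decay: float = 5e-4
    epochs: int = 100
    batch_size: int = 64
    n_walks: int | None = None  # default: the graph's knn parameter
    walk_len: int = 1
    seed: int = 0


@dataclass
class SpiralModel:
    """Trainable parameters plus dimensions and loss weights."""

    params: dict[str, np.ndarray]
    dims: ModelDims
    n_batches: int
    lambda_: float = 1.0
    gamma: float = 1.0
    gene_names: list[str] | None = None
    history: list[dict] = field(default_factory=list)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


@dataclass
class EmbeddingSet:
    """Per-spot embeddings with their column split and sample assignment."""

    z: np.ndarray
    noise_dim: int
    sample_idx: np.ndarray
    spot_ids: list[str] | None = None

    @property
    def z_noise(self) -> np.ndarray:
        return self.z[:, : self.noise_dim]

    @property
    def z_bio(self) -> np.ndarray:
        return self.z[:, self.noise_dim:]

    @property
    def n_spots(self) -> int:
        return self.z.shape[0]


@dataclass
class WalkPairSet:
    """Contrastive pairs from short random walks on one sample's graph."""

    positive_pairs: np.ndarray  # (n_pos, 2) node indices
    negative_pairs: np.ndarray  # (n_neg, 2)


# ---------------------------------------------------------------------------
# initialisation / encoder


def init_model(
    n_genes: int,
    n_batches: int,
    config: TrainingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SpiralModel:
    """Glorot-uniform initialised model; biases start at zero."""
    config = config or TrainingConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    dims = ModelDims(
        n_genes=n_genes,
        hidden=config.hidden,
        embed=config.embed,
        noise_dim=config.noise_dim,
        disc_hidden=tuple(config.disc_hidden),
    )
    if dims.noise_dim <= 0 or dims.noise_dim >= dims.embed:
        raise ValueError("noise_dim must be in (0, embed)")
    if config.lambda_ < 0 or config.gamma < 0:
        raise ValueError("loss weights must be non-negative")
    M, H, Z = dims.n_genes, dims.hidden, dims.embed
    d_out = 1 if n_batches == 2 else n_batches
    h1, h2 = dims.disc_hidden
    params = {
        "enc_W1": glorot_uniform(rng, 2 * M, H),
        "enc_W2": glorot_uniform(rng, 2 * H, Z),
        "dec_W1": glorot_uniform(rng, Z, H),
        "dec_b1": np.zeros(H),
        "dec_W2": glorot_uniform(rng, H, M),
        "dec_b2": np.zeros(M),
        "disc_W1": glorot_uniform(rng, dims.bio_dim, h1),
        "disc_b1": np.zeros(h1),
        "disc_W2": glorot_uniform(rng, h1, h2),
        "disc_b2": np.zeros(h2),
        "disc_W3": glorot_uniform(rng, h2, d_out),
        "disc_b3": np.zeros(d_out),
        "clf_W": glorot_uniform(rng, dims.noise_dim, d_out),
        "clf_b": np.zeros(d_out),
    }
    return SpiralModel(
        params=params,
        dims=dims,
        n_batches=n_batches,
        lambda_=config.lambda_,
        gamma=config.gamma,
    )


def _encoder_forward(params: dict, X: np.ndarray, A: sp.csr_matrix) -> dict:
    """Two-layer mean-aggregate / concat / transform forward pass with cache.

    h0 = x; h1_i = ReLU(W1 [h0_i, mean_{j in N(i)} h0_j]);
    z_i = W2 [h1_i, mean_{j in N(i)} h1_j]  (final layer linear).
    Isolated nodes aggregate their own features (handled in the mean
    operator).
    """
    agg0 = A @ X
    c0 = np.hstack([X, agg0])
    pre1 = c0 @ params["enc_W1"]
    h1 = relu(pre1)
    agg1 = A @ h1
    c1 = np.hstack([h1, agg1])
    z = c1 @ params["enc_W2"]
    return {"A": A, "c0": c0, "pre1": pre1, "c1": c1, "z": z}


def _encoder_backward(params: dict, cache: dict, dz: np.ndarray) -> dict:
    H = params["enc_W1"].shape[1]
    A, c0, pre1, c1 = cache["A"], cache["c0"], cache["pre1"], cache["c1"]
    dW2 = c1.T @ dz
    dc1 = dz @ params["enc_W2"].T
    dh1 = dc1[:, :H] + A.T @ dc1[:, H:]
    dpre1 = dh1 * (pre1 > 0)
    dW1 = c0.T @ dpre1
    return {"enc_W1": dW1, "enc_W2": dW2}


def encode(
    model: SpiralModel,
    exprs: list[np.ndarray],
    graphs: list[SpatialGraph],
    spot_ids: list[list[str]] | None = None,
) -> EmbeddingSet:
    """Embed every spot of every sample; neighbours never cross samples."""
    if len(exprs) != len(graphs):
        raise ValueError("exprs and graphs must align")
    zs, sidx = [], []
    for d, (X, g) in enumerate(zip(exprs, graphs)):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != model.dims.n_genes:
            raise ValueError(
                f"sample {d}: expression has {X.shape[1]} genes, model expects "
                f"{model.dims.n_genes}"
            )
        if X.shape[0] != g.n_nodes:
            raise ValueError(f"sample {d}: graph has {g.n_nodes} nodes, expression {X.shape[0]} rows")
        zs.append(_encoder_forward(model.params, X, g.mean_operator())["z"])
        sidx.append(np.full(X.shape[0], d))
    ids = None if spot_ids is None else [s for sub in spot_ids for s in sub]
    return EmbeddingSet(
        z=np.vstack(zs),
        noise_dim=model.dims.noise_dim,
        sample_idx=np.concatenate(sidx),
        spot_ids=ids,
    )


# ---------------------------------------------------------------------------
# walk pairs and losses


def sample_walk_pairs(
    graph: SpatialGraph,
    n_walks: int,
    walk_len: int = 1,
    seed: int | np.random.Generator = 0,
    start_nodes: np.ndarray | None = None,
    negative_pool: np.ndarray | None = None,
) -> WalkPairSet:
    """Positive pairs from random walks; uniform negatives outside each walk set.

    From each start node, ``n_walks`` independent walks of ``walk_len``
    uniform-neighbour steps are taken; every visited node forms a positive
    pair with the start. Negatives are drawn uniformly from
    ``negative_pool`` (default: all nodes of the graph, i.e. the same
    sample) excluding the start's walk co-occurrence set, approximately one
    per positive. Isolated start nodes emit no pairs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = np.arange(graph.n_nodes) if start_nodes is None else np.asarray(start_nodes)
    pool = np.arange(graph.n_nodes) if negative_pool is None else np.asarray(negative_pool)
    pos, neg = [], []
    for i in starts:
        nbrs = graph.neighbor_lists[i]
        if len(nbrs) == 0:
            continue
        visited = []
        for _ in range(n_walks):
            cur = i
            for _ in range(walk_len):
                cands = graph.neighbor_lists[cur]
                if len(cands) == 0:
                    break
                cur = cands[rng.integers(len(cands))]
                visited.append(cur)
        if not visited:
            continue
        for j in visited:
            pos.append((i, j))
        cooc = set(visited) | {i}
        cands = pool[~np.isin(pool, list(cooc))]
        if len(cands) == 0:
            continue
        for j in rng.choice(cands, size=len(visited), replace=True):
            neg.append((i, j))
    return WalkPairSet(
        positive_pairs=np.asarray(pos, dtype=int).reshape(-1, 2),
        negative_pairs=np.asarray(neg, dtype=int).reshape(-1, 2),
    )


def graphsage_loss(z_bio: np.ndarray, pairs: WalkPairSet) -> float:
    """Random-walk contrastive loss, summed over the listed pairs.

    sum_pos -log sigma(z_i . z_j) + sum_neg -log(1 - sigma(z_i . z_n)),
    evaluated through log-sigmoid for overflow safety.
    """
    if len(pairs.positive_pairs) + len(pairs.negative_pairs) == 0:
        raise ValueError("pair set is empty")
    loss = 0.0
    if len(pairs.positive_pairs):
        i, j = pairs.positive_pairs.T
        s = np.einsum("ij,ij->i", z_bio[i], z_bio[j])
        loss += float(-log_sigmoid(s).sum())
    if len(pairs.negative_pairs):
        i, j = pairs.negative_pairs.T
        s = np.einsum("ij,ij->i", z_bio[i], z_bio[j])
        loss += float(-log_sigmoid(-s).sum())  # -log(1 - sigma(s))
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite contrastive loss")
    return loss


def _decoder_forward(params: dict, z: np.ndarray) -> dict:
    pre1 = z @ params["dec_W1"] + params["dec_b1"]
    a1 = relu(pre1)
    logits = a1 @ params["dec_W2"] + params["dec_b2"]
    return {"z": z, "pre1": pre1, "a1": a1, "logits": logits, "x_hat": sigmoid(logits)}


def decode(model: SpiralModel, z: np.ndarray | EmbeddingSet) -> np.ndarray:
    """Reconstruct [0,1] expression: ReLU hidden layer, logistic output."""
    if isinstance(z, EmbeddingSet):
        z = z.z
    z = np.asarray(z, dtype=float)
    if z.shape[1] != model.dims.embed:
        raise ValueError(f"z has {z.shape[1]} columns, model embeds {model.dims.embed}")
    return _decoder_forward(model.params, z)["x_hat"]


_EPS = 1e-7


def reconstruction_loss(x_hat: np.ndarray, x: np.ndarray) -> float:
    """Binary cross-entropy summed over genes, averaged over spots."""
    x_hat = np.clip(np.asarray(x_hat, dtype=float), _EPS, 1 - _EPS)
    x = np.asarray(x, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError("shape mismatch between x and x_hat")
    per_spot = -(x * np.log(x_hat) + (1 - x) * np.log(1 - x_hat)).sum(axis=1)
    return float(per_spot.mean())


def _one_hot(y: np.ndarray, n_batches: int) -> np.ndarray:
    out = np.zeros((len(y), n_batches))
    out[np.arange(len(y)), y] = 1.0
    return out


def _disc_forward(params: dict, z_bio: np.ndarray) -> dict:
    pre1 = z_bio @ params["disc_W1"] + params["disc_b1"]
    a1 = relu(pre1)
    pre2 = a1 @ params["disc_W2"] + params["disc_b2"]
    a2 = relu(pre2)
    logits = a2 @ params["disc_W3"] + params["disc_b3"]
    return {"in": z_bio, "pre1": pre1, "a1": a1, "pre2": pre2, "a2": a2, "logits": logits}


def _head_ce(logits: np.ndarray, y: np.ndarray, n_batches: int) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient wrt logits (already divided by n)."""
    n = len(y)
    if n_batches == 2:
        s = logits.ravel()
        ce = float(np.mean(-(y * log_sigmoid(s) + (1 - y) * log_sigmoid(-s))))
        dlogits = ((sigmoid(s) - y) / n)[:, None]
    else:
        p = softmax(logits)
        ce = float(np.mean(-np.log(np.clip(p[np.arange(n), y], _EPS, None))))
        dlogits = (p - _one_hot(y, n_batches)) / n
    return ce, dlogits


def batch_head_losses(
    model: SpiralModel, z: EmbeddingSet, y: np.ndarray
) -> tuple[float, float]:
    """Mean cross-entropies of the batch discriminator and noise classifier.

    The discriminator consumes the bio columns (through the GRL — identity
    in this forward pass); the classifier consumes the noise columns. With
    two batches both heads are logistic, otherwise softmax.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        import warnings

        warnings.warn("single-batch input: adversarial losses are uninformative")
    grl = GradientReversal()
    disc = _disc_forward(model.params, grl(z.z_bio))
    l_disc, _ = _head_ce(disc["logits"], y, model.n_batches)
    clf_logits = z.z_noise @ model.params["clf_W"] + model.params["clf_b"]
    l_class, _ = _head_ce(clf_logits, y, model.n_batches)
    return l_disc, l_class


def _disc_backward(params: dict, cache: dict, dlogits: np.ndarray) -> tuple[dict, np.ndarray]:
    grads = {}
    grads["disc_W3"] = cache["a2"].T @ dlogits
    grads["disc_b3"] = dlogits.sum(axis=0)
    da2 = dlogits @ params["disc_W3"].T
    dpre2 = da2 * (cache["pre2"] > 0)
    grads["disc_W2"] = cache["a1"].T @ dpre2
    grads["disc_b2"] = dpre2.sum(axis=0)
    da1 = dpre2 @ params["disc_W2"].T
    dpre1 = da1 * (cache["pre1"] > 0)
    grads["disc_W1"] = cache["in"].T @ dpre1
    grads["disc_b1"] = dpre1.sum(axis=0)
    din = dpre1 @ params["disc_W1"].T
    return grads, din


def batch_head_input_gradients(
    model: SpiralModel, z: EmbeddingSet, y: np.ndarray, through_grl: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the head losses wrt their embedding inputs.

    Returns ``(d l_disc / d z_bio, d l_class / d z_noise)``. With
    ``through_grl`` the discriminator gradient is propagated through the
    gradient reversal layer, i.e. negated — the gradient the encoder
    actually receives.
    """
    y = np.asarray(y, dtype=int)
    grl = GradientReversal()
    cache = _disc_forward(model.params, grl(z.z_bio))
    _, dlogits = _head_ce(cache["logits"], y, model.n_batches)
    _, d_bio = _disc_backward(model.params, cache, dlogits)
    if through_grl:
        d_bio = grl.backward(d_bio)
    _, dlogits_c = _head_ce(
        z.z_noise @ model.params["clf_W"] + model.params["clf_b"], y, model.n_batches
    )
    d_noise = dlogits_c @ model.params["clf_W"].T
    return d_bio, d_noise


def total_loss(
    l_gs: float, l_de: float, l_disc: float, l_class: float,
    M: int, lambda_: float = 1.0, gamma: float = 1.0,
) -> float:
    """Weighted sum of the four components.

    ``l_de`` is the per-spot per-gene mean BCE; multiplying by the gene count
    M recovers the gene-summed decoder loss, weighted once.
    """
    if lambda_ < 0 or gamma < 0:
        raise ValueError("loss weights must be non-negative")
    parts = np.array([l_gs, l_de, l_disc, l_class], dtype=float)
    if not np.isfinite(parts).all():
        raise FloatingPointError(f"non-finite loss components: {parts}")
    return float(l_gs + l_de * M + l_disc * lambda_ + l_class * gamma)


# ---------------------------------------------------------------------------
# training


def _accumulate(grads: dict, new: dict) -> None:
    for k, v in new.items():
        if k in grads:
            grads[k] = grads[k] + v
        else:
            grads[k] = v


def _training_step(
    model: SpiralModel,
    opt: Adam,
    exprs: list[np.ndarray],
    ops: list[sp.csr_matrix],
    graphs: list[SpatialGraph],
    mbs: list[np.ndarray],
    rng: np.random.Generator,
    n_walks: int,
    walk_len: int,
) -> dict:
    """One update over one minibatch per sample (so the heads see mixed labels)."""
    p = model.params
    nd = model.dims.noise_dim
    B = sum(len(mb) for mb in mbs)
    grads: dict[str, np.ndarray] = {}
    l_gs_sum = 0.0
    l_de_sum = 0.0
    z_mb_parts, y_parts = [], []
    caches, dzs = [], []

    for d, (X, A, graph, mb) in enumerate(zip(exprs, ops, graphs, mbs)):
        cache = _encoder_forward(p, X, A)
        z = cache["z"]
        z_bio = z[:, nd:]
        dz = np.zeros_like(z)

        # random-walk contrastive loss on the bio columns, within this sample
        pairs = sample_walk_pairs(
            graph, n_walks, walk_len, seed=rng, start_nodes=mb, negative_pool=mb
        )
        dzb = dz[:, nd:]
        for pair_arr, positive in ((pairs.positive_pairs, True), (pairs.negative_pairs, False)):
            if len(pair_arr) == 0:
                continue
            i, j = pair_arr.T
            s = np.einsum("ij,ij->i", z_bio[i], z_bio[j])
            if positive:
                l_gs_sum += float(-log_sigmoid(s).sum())
                coef = (sigmoid(s) - 1.0) / B
            else:
                l_gs_sum += float(-log_sigmoid(-s).sum())
                coef = sigmoid(s) / B
            np.add.at(dzb, i, coef[:, None] * z_bio[j])
            np.add.at(dzb, j, coef[:, None] * z_bio[i])

        # decoder on the minibatch rows (gene-summed BCE)
        dec = _decoder_forward(p, z[mb])
        x_hat = np.clip(dec["x_hat"], _EPS, 1 - _EPS)
        x_mb = X[mb]
        l_de_sum += float(-(x_mb * np.log(x_hat) + (1 - x_mb) * np.log(1 - x_hat)).sum())
        d_logits = (dec["x_hat"] - x_mb) / B
        _accumulate(grads, {"dec_W2": dec["a1"].T @ d_logits, "dec_b2": d_logits.sum(axis=0)})
        da1 = d_logits @ p["dec_W2"].T
        dpre1 = da1 * (dec["pre1"] > 0)
        _accumulate(grads, {"dec_W1": dec["z"].T @ dpre1, "dec_b1": dpre1.sum(axis=0)})
        dz[mb] += dpre1 @ p["dec_W1"].T

        z_mb_parts.append(z[mb])
        y_parts.append(np.full(len(mb), d))
        caches.append(cache)
        dzs.append(dz)

    # adversarial heads on the concatenated minibatch (mixed batch labels)
    z_mb = np.vstack(z_mb_parts)
    y_mb = np.concatenate(y_parts)
    grl = GradientReversal()
    disc_cache = _disc_forward(p, grl(z_mb[:, nd:]))
    l_disc, d_disc_logits = _head_ce(disc_cache["logits"], y_mb, model.n_batches)
    disc_grads, d_bio_in = _disc_backward(p, disc_cache, d_disc_logits * model.lambda_)
    _accumulate(grads, disc_grads)
    d_bio_in = grl.backward(d_bio_in)

    clf_logits = z_mb[:, :nd] @ p["clf_W"] + p["clf_b"]
    l_class, d_clf_logits = _head_ce(clf_logits, y_mb, model.n_batches)
    d_clf_logits = d_clf_logits * model.gamma
    _accumulate(
        grads, {"clf_W": z_mb[:, :nd].T @ d_clf_logits, "clf_b": d_clf_logits.sum(axis=0)}
    )
    d_noise_in = d_clf_logits @ p["clf_W"].T

    start = 0
    for d, (cache, dz, mb) in enumerate(zip(caches, dzs, mbs)):
        stop = start + len(mb)
        dz[np.ix_(mb, np.arange(nd, model.dims.embed))] += d_bio_in[start:stop]
        dz[np.ix_(mb, np.arange(nd))] += d_noise_in[start:stop]
        _accumulate(grads, _encoder_backward(p, cache, dz))
        start = stop
    opt.step(grads)
    return {
        "l_gs": l_gs_sum / B,
        "l_de": l_de_sum / (B * model.dims.n_genes),
        "l_disc": l_disc,
        "l_class": l_class,
    }


def fit(
    samples: list[SRTSample],
    graphs: list[SpatialGraph],
    config: TrainingConfig | None = None,
    seed: int | None = None,
) -> tuple[SpiralModel, EmbeddingSet]:
    """Train the integration model; fully reproducible given the seed.

    Minibatches are drawn per sample and interleaved round-robin so the
    adversarial heads see every batch each epoch. Walk pairs are regenerated
    for every minibatch. Returns the trained model and the embeddings of all
    spots.
    """
    config = config or TrainingConfig()
    if seed is not None:
        config = TrainingConfig(**{**config.__dict__, "seed": seed})
    if not samples:
        raise ValueError("need at least one sample")
    gene_names = samples[0].gene_names
    for s in samples[1:]:
        if s.gene_names != gene_names:
            raise ValueError("all samples must share the identical ordered gene list")
    exprs = []
    for s in samples:
        if s.expr is None:
            raise ValueError(f"sample {s.sample_id} has no expr; run preprocess_expression first")
        exprs.append(np.asarray(s.expr, dtype=float))
    rng = np.random.default_rng(config.seed)
    model = init_model(exprs[0].shape[1], len(samples), config, rng)
    model.gene_names = list(gene_names)
    opt = Adam(model.params, lr=config.lr, weight_decay=config.weight_decay)
    ops = [g.mean_operator() for g in graphs]
    n_walks = config.n_walks
    if n_walks is None:
        n_walks = max(1, int(graphs[0].param)) if graphs[0].mode in ("knn", "feature") else 6

    for epoch in range(config.epochs):
        queues = []
        for d, X in enumerate(exprs):
            perm = rng.permutation(X.shape[0])
            queues.append([perm[i:i + config.batch_size]
                           for i in range(0, len(perm), config.batch_size)])
        comp_sums: dict[str, float] = {"l_gs": 0.0, "l_de": 0.0, "l_disc": 0.0, "l_class": 0.0}
        n_steps = 0
        # one minibatch per sample per step; shorter queues wrap around so the
        # heads always see every batch label
        for step in range(max(len(q) for q in queues)):
            mbs = [queues[d][step % len(queues[d])] for d in range(len(samples))]
            losses = _training_step(
                model, opt, exprs, ops, graphs, mbs,
                rng=rng, n_walks=n_walks, walk_len=config.walk_len,
            )
            for k, v in losses.items():
                comp_sums[k] += v
            n_steps += 1
        comp = {k: v / n_steps for k, v in comp_sums.items()}
        comp["l_total"] = total_loss(
            comp["l_gs"], comp["l_de"], comp["l_disc"], comp["l_class"],
            model.dims.n_genes, model.lambda_, model.gamma,
        )
        if not np.isfinite(comp["l_total"]):
            raise FloatingPointError(f"non-finite total loss at epoch {epoch}")
        model.history.append({"epoch": epoch, **comp})

    embeddings = encode(model, exprs, graphs, spot_ids=[s.spot_ids for s in samples])
    return model, embeddings


# ---------------------------------------------------------------------------
# downstream


def corrected_expression(model: SpiralModel, z: EmbeddingSet) -> np.ndarray:
    """Decode with the noise columns zeroed: batch-effect-free expression."""
    z_corr = z.z.copy()
    z_corr[:, : z.noise_dim] = 0.0
    return decode(model, z_corr)


def predict_unseen(
    model: SpiralModel,
    new_sample: SRTSample,
    graph: SpatialGraph,
    train_embeddings: EmbeddingSet | None = None,
    train_labels: np.ndarray | None = None,
) -> tuple[EmbeddingSet, np.ndarray | None]:
    """Inductive forward pass on unseen data; no retraining.

    The new sample's expression is reordered to the model's gene list. If
    training embeddings and cluster labels are supplied, each new spot is
    assigned the label of the nearest training-cluster centroid in bio
    space; otherwise the label array is None.
    """
    if new_sample.expr is None:
        raise ValueError("new sample has no expr; preprocess it to the model's gene set first")
    X = np.asarray(new_sample.expr, dtype=float)
    if model.gene_names is not None and new_sample.gene_names != model.gene_names:
        pos = {g: i for i, g in enumerate(new_sample.gene_names)}
        missing = [g for g in model.gene_names if g not in pos]
        if missing:
            raise ValueError(
                f"new sample lacks {len(missing)} model genes, e.g. {missing[:5]}"
            )
        X = X[:, [pos[g] for g in model.gene_names]]
    emb = EmbeddingSet(
        z=_encoder_forward(model.params, X, graph.mean_operator())["z"],
        noise_dim=model.dims.noise_dim,
        sample_idx=np.zeros(X.shape[0], dtype=int),
        spot_ids=list(new_sample.spot_ids),
    )
    labels = None
    if train_embeddings is not None and train_labels is not None:
        train_labels = np.asarray(train_labels)
        cents, ids = [], []
        for lab in np.unique(train_labels):
            cents.append(train_embeddings.z_bio[train_labels == lab].mean(axis=0))
            ids.append(lab)
        cents = np.vstack(cents)
        d = np.linalg.norm(emb.z_bio[:, None, :] - cents[None, :, :], axis=-1)
        labels = np.asarray(ids)[d.argmin(axis=1)]
    return emb, labels


def save_model(model: SpiralModel, path) -> None:
    meta = {
        "n_genes": model.dims.n_genes,
        "hidden": model.dims.hidden,
        "embed": model.dims.embed,
        "noise_dim": model.dims.noise_dim,
        "disc_hidden": np.asarray(model.dims.disc_hidden),
        "n_batches": model.n_batches,
        "lambda_": model.lambda_,
        "gamma": model.gamma,
        "gene_names": np.asarray(model.gene_names or [], dtype=object),
    }
    np.savez(path, **model.params, **{f"meta_{k}": v for k, v in meta.items()})


def load_model(path) -> SpiralModel:
    data = np.load(path, allow_pickle=True)
    params = {k: data[k] for k in data.files if not k.startswith("meta_")}
    dims = ModelDims(
        n_genes=int(data["meta_n_genes"]),
        hidden=int(data["meta_hidden"]),
        embed=int(data["meta_embed"]),
        noise_dim=int(data["meta_noise_dim"]),
        disc_hidden=tuple(int(x) for x in data["meta_disc_hidden"]),
    )
    genes = list(data["meta_gene_names"])
    return SpiralModel(
        params=params,
        dims=dims,
        n_batches=int(data["meta_n_batches"]),
        lambda_=float(data["meta_lambda_"]),
        gamma=float(data["meta_gamma"]),
        gene_names=genes or None,
    )
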