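"""Cluster-aware coordinate alignment into a reference coordinate system.

Each query sample is mapped into the coordinate frame of a reference sample
(chosen as the one with the largest convex-hull area). For every cluster
shared between the two samples, a fused Gromov-Wasserstein (FGW) coupling is
computed between the reference and query spots of that cluster: the
objective mixes a feature term — distances between biology embeddings —
weighted (1 - alpha) with a spatial-distortion term — squared differences of
within-sample coordinate distances — weighted alpha. A query spot's new
coordinate is the unweighted mean of the reference coordinates it is coupled
to. Spots of sample-specific clusters are then carried over by a similarity
transform (rotation + translation, optionally uniform scale) fitted by
least-squares Procrustes on the shared-cluster spots used as landmarks.

Because the FGW spatial term uses only within-sample distances, the whole
pipeline is invariant to rigid motions of the query's input coordinates —
which is what lets it absorb rotations and scalings between slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist

from .clustering import ClusterAssignment
from .integration import EmbeddingSet
from .io_graph import SRTSample

__all__ = [
    "ClusterCoupling",
    "RigidTransform",
    "AlignmentResult",
    "select_reference",
    "fused_gw_coupling",
    "transfer_shared_coordinates",
    "fit_rigid_transform",
    "align_samples",
]

SUPPORT_EPS = 1e-8  # numerical threshold for "pi_ij > 0"


@dataclass
class ClusterCoupling:
    pi: np.ndarray  # (n_ref, n_query), non-negative, uniform marginals
    alpha: float
    feature_metric: str = "euclidean"
    cluster_id: int | None = None
    cost: float = np.nan
    converged: bool = True
    n_iter: int = 0


@dataclass
class RigidTransform:
    """Similarity map x -> scale * x @ rotation + translation (row vectors)."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(coords, dtype=float) @ self.rotation + self.translation

    @property
    def angle_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.rotation[0, 1], self.rotation[0, 0])))


@dataclass
class AlignmentResult:
    sample_id: str
    reference_id: str
    new_coords: np.ndarray  # (n_query_spots, 2) in the reference frame
    transform: RigidTransform | None
    shared_clusters: list[int] = field(default_factory=list)
    couplings: dict[int, ClusterCoupling] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def select_reference(samples: list[SRTSample]) -> str:
    """Sample with the largest convex-hull area; spot count breaks degeneracy."""
    if not samples:
        raise ValueError("no samples")
    best_id, best_area = None, -np.inf
    for s in samples:
        try:
            area = ConvexHull(s.coords).volume  # 2-D: volume is the area
        except (QhullError, ValueError):
            area = -1.0
        if area > best_area:
            best_id, best_area = s.sample_id, area
    if best_area <= 0:  # all degenerate: fall back to spot count
        best_id = max(samples, key=lambda s: s.n_spots).sample_id
    return best_id


def _exact_ot_direction(G: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Minimiser of <G, Gamma> over couplings with marginals (p, q)."""
    n, m = G.shape
    if n == m and np.allclose(p, p[0]) and np.allclose(q, q[0]):
        rows, cols = linear_sum_assignment(G)
        gamma = np.zeros_like(G)
        gamma[rows, cols] = 1.0 / n
        return gamma
    row_con = sp.kron(sp.eye(n), np.ones((1, m)), format="csr")
    col_con = sp.kron(np.ones((1, n)), sp.eye(m), format="csr")
    A_eq = sp.vstack([row_con, col_con[:-1]], format="csr")  # drop redundant row
    b_eq = np.concatenate([p, q[:-1]])
    res = linprog(G.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"linear OT subproblem failed: {res.message}")
    return res.x.reshape(n, m)


def fused_gw_coupling(
    ref_spots: tuple[np.ndarray, np.ndarray],
    query_spots: tuple[np.ndarray, np.ndarray],
    alpha: float = 0.6,
    feature_metric: str = "euclidean",
    max_iter: int = 1000,
    tol: float = 1e-9,
    cluster_id: int | None = None,
) -> ClusterCoupling:
    """Fused Gromov-Wasserstein coupling between two spot sets.

    ``ref_spots`` and ``query_spots`` are ``(embedding, coords)`` pairs. The
    objective

        F = (1 - alpha) * sum_ij e(z_i, z_j) pi_ij
            + alpha * sum_ijkl (d_ik - d_jl)^2 pi_ij pi_kl

    is minimised over couplings with uniform marginals by conditional
    gradient: product-coupling initialisation, exact linear-OT direction,
    closed-form line search. The objective is non-increasing across
    iterations; on non-convergence the last iterate is returned with
    ``converged=False``.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    z_r, xy_r = (np.asarray(a, dtype=float) for a in ref_spots)
    z_q, xy_q = (np.asarray(a, dtype=float) for a in query_spots)
    n, m = z_r.shape[0], z_q.shape[0]
    if n == 0 or m == 0:
        raise ValueError("both spot sets must be non-empty")
    E = cdist(z_r, z_q)
    if feature_metric == "sq_euclidean":
        E = E**2
    elif feature_metric != "euclidean":
        raise ValueError(f"unknown feature metric {feature_metric!r}")
    C1 = cdist(xy_r, xy_r)
    C2 = cdist(xy_q, xy_q)
    p = np.full(n, 1.0 / n)
    q = np.full(m, 1.0 / m)
    # GW terms in d_ik^2 and d_jl^2 are constant over the feasible polytope
    cst = float((C1**2 @ p) @ p + (C2**2 @ q) @ q)

    def objective(pi: np.ndarray, cross: np.ndarray) -> float:
        return float((1 - alpha) * (E * pi).sum() + alpha * (cst - 2 * (cross * pi).sum()))

    pi = np.outer(p, q)
    cross = C1 @ pi @ C2  # C1, C2 symmetric
    J = objective(pi, cross)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = (1 - alpha) * E - 4 * alpha * cross
        gamma = _exact_ot_direction(grad, p, q)
        delta = gamma - pi
        cross_delta = C1 @ delta @ C2
        b = float((1 - alpha) * (E * delta).sum() - 4 * alpha * (cross * delta).sum())
        a2 = float(-2 * alpha * (cross_delta * delta).sum())
        if a2 > 0:
            t = float(np.clip(-b / (2 * a2), 0.0, 1.0))
        else:
            t = 1.0 if a2 + b < 0 else 0.0
        if t == 0.0:
            converged = True
            break
        pi = pi + t * delta
        cross = cross + t * cross_delta
        J_new = objective(pi, cross)
        if abs(J - J_new) <= tol * max(1.0, abs(J)):
            J = J_new
            converged = True
            break
        J = J_new
    if not converged:
        warnings.warn(
            f"fused GW did not converge within {max_iter} iterations; returning last iterate"
        )
    return ClusterCoupling(
        pi=pi, alpha=alpha, feature_metric=feature_metric,
        cluster_id=cluster_id, cost=J, converged=converged, n_iter=it,
    )


def transfer_shared_coordinates(
    coupling: ClusterCoupling | np.ndarray, ref_coords: np.ndarray
) -> np.ndarray:
    """New query coordinates: per-column unweighted mean over the coupling support.

    For query spot j the new coordinate is the arithmetic mean of reference
    coordinates with pi_ij above a numerical threshold; if no entry exceeds
    it, the argmax row is used.
    """
    pi = coupling.pi if isinstance(coupling, ClusterCoupling) else np.asarray(coupling)
    ref_coords = np.asarray(ref_coords, dtype=float)
    out = np.empty((pi.shape[1], ref_coords.shape[1]))
    for j in range(pi.shape[1]):
        support = np.flatnonzero(pi[:, j] > SUPPORT_EPS)
        if support.size == 0:
            support = np.array([pi[:, j].argmax()])
        out[j] = ref_coords[support].mean(axis=0)
    return out


def fit_rigid_transform(
    landmarks_query: np.ndarray,
    landmarks_ref: np.ndarray,
    allow_scale: bool = True,
) -> RigidTransform:
    """Least-squares orthogonal Procrustes fit mapping query onto reference.

    Both configurations are centred, the rotation comes from the SVD of the
    cross-covariance with the determinant constrained to +1, the optional
    uniform scale from the trace ratio, and the translation from the
    centroids. Landmark sets related by an exact similarity transform are
    recovered with zero residual.
    """
    X = np.asarray(landmarks_query, dtype=float)
    Y = np.asarray(landmarks_ref, dtype=float)
    if X.shape != Y.shape or X.shape[0] < 2:
        raise ValueError("need >= 2 landmark pairs of matching shape")
    mu_x, mu_y = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mu_x, Y - mu_y
    M = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(M)
    if S[1] <= 1e-12 * max(S[0], 1e-30):
        raise ValueError("rank-deficient cross-covariance: landmarks are degenerate")
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    denom = (Xc**2).sum()
    scale = float((S * np.diag(D)).sum() / denom) if allow_scale else 1.0
    t = mu_y - scale * mu_x @ R
    return RigidTransform(rotation=R, translation=t, scale=scale)


def align_samples(
    samples: list[SRTSample],
    labels: ClusterAssignment | np.ndarray,
    embeddings: EmbeddingSet,
    reference_id: str | None = None,
    alpha: float = 0.6,
    min_cluster_size: int = 10,
    allow_scale: bool = True,
    max_iter: int = 1000,
) -> dict[str, AlignmentResult]:
    """Map every non-reference sample into the reference coordinate system.

    Shared clusters (joint labels with at least ``min_cluster_size`` spots in
    both the reference and the query) are aligned by per-cluster FGW
    couplings and coordinate transfer; spots of all remaining clusters are
    placed by the Procrustes transform fitted on the shared-cluster spots.
    Clusters are aligned independently, so their images may overlap in the
    reference frame.
    """
    lab = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels)
    if len(lab) != embeddings.n_spots:
        raise ValueError("labels and embeddings cover different spot sets")
    if reference_id is None:
        reference_id = select_reference(samples)
    ids = [s.sample_id for s in samples]
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not among samples {ids}")
    r = ids.index(reference_id)
    slices = {}
    start = 0
    for d, s in enumerate(samples):
        if not np.all(embeddings.sample_idx[start:start + s.n_spots] == d):
            raise ValueError("embeddings rows are not ordered by sample")
        slices[d] = np.arange(start, start + s.n_spots)
        start += s.n_spots
    zb = embeddings.z_bio
    ref_rows = slices[r]
    ref_lab = lab[ref_rows]
    results: dict[str, AlignmentResult] = {}
    for d, sample in enumerate(samples):
        if d == r:
            continue
        q_rows = slices[d]
        q_lab = lab[q_rows]
        shared = []
        for c in np.unique(q_lab):
            if (ref_lab == c).sum() >= min_cluster_size and (q_lab == c).sum() >= min_cluster_size:
                shared.append(int(c))
        if not shared:
            raise ValueError(
                f"no shared clusters between reference {reference_id!r} "
                f"(clusters {sorted(set(ref_lab.tolist()))}) and {sample.sample_id!r} "
                f"(clusters {sorted(set(q_lab.tolist()))})"
            )
        new_coords = np.full((sample.n_spots, 2), np.nan)
        couplings: dict[int, ClusterCoupling] = {}
        for c in shared:
            ri = ref_rows[ref_lab == c]
            qi = np.flatnonzero(q_lab == c)
            coupling = fused_gw_coupling(
                (zb[ri], samples[r].coords[ref_lab == c]),
                (zb[q_rows[qi]], sample.coords[qi]),
                alpha=alpha,
                cluster_id=c,
                max_iter=max_iter,
            )
            couplings[c] = coupling
            new_coords[qi] = transfer_shared_coordinates(
                coupling, samples[r].coords[ref_lab == c]
            )
        shared_mask = np.isin(q_lab, shared)
        transform = None
        if shared_mask.sum() >= 3:
            transform = fit_rigid_transform(
                sample.coords[shared_mask], new_coords[shared_mask],
                allow_scale=allow_scale,
            )
        if (~shared_mask).any():
            if transform is None:
                raise ValueError(
                    f"cannot place sample-specific clusters of {sample.sample_id!r}: "
                    "too few shared-cluster landmarks"
                )
            new_coords[~shared_mask] = transform.apply(sample.coords[~shared_mask])
        results[sample.sample_id] = AlignmentResult(
            sample_id=sample.sample_id,
            reference_id=reference_id,
            new_coords=new_coords,
            transform=transform,
            shared_clusters=shared,
            couplings=couplings,
        )
    return results
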