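"""Splatter-style multi-batch spatial simulator.

Counts follow a gamma-Poisson hierarchy: gamma base means per gene,
log-normal differential-expression factors on a fraction of genes per group,
log-normal batch factors on all genes, log-normal library sizes, Poisson
sampling. Two groups (Group1/Group2) are constructed to be adjacent in
feature space — Group2 reuses most of Group1's DE genes with nearly
identical factors — while their spatial regions are placed at opposite ends
of the tissue, so expression alone cannot separate them but spatial context
can.

Five scenarios mirror common multi-sample designs:

* ``simulate1`` — two batches, identical group compositions and layouts.
* ``simulate2`` — as 1, but the spatial ordering of groups is reversed in
  batch 2.
* ``simulate3`` — as 2, plus batch 2's coordinates rotated by 60 degrees and
  scaled by 1.5.
* ``simulate4`` — Group1-4 shared, Group5 only in batch 1, Group6 only in
  batch 2; shared groups keep identical layouts.
* ``simulate5`` — three batches with compositions {G1,G2,G3}, {G1,G3,G4},
  {G2,G3,G5,G6}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_graph import SRTSample

__all__ = [
    "SimulationScenario",
    "get_scenario",
    "simulate_counts",
    "assign_spatial_coordinates",
    "make_scenario",
    "SCENARIO_IDS",
]

SCENARIO_IDS = ("simulate1", "simulate2", "simulate3", "simulate4", "simulate5")

#: group composition per batch for each scenario (groups are 1-based ids)
_COMPOSITIONS: dict[str, list[list[int]]] = {
    "simulate1": [[1, 2, 3, 4], [1, 2, 3, 4]],
    "simulate2": [[1, 2, 3, 4], [1, 2, 3, 4]],
    "simulate3": [[1, 2, 3, 4], [1, 2, 3, 4]],
    "simulate4": [[1, 2, 3, 4, 5], [1, 2, 3, 4, 6]],
    "simulate5": [[1, 2, 3], [1, 3, 4], [2, 3, 5, 6]],
}


@dataclass
class SimulationScenario:
    """Parameters of one simulation design.

    Distribution parameters are on the log scale for the log-normal factors
    (location = mean of log, scale = sd of log). ``group_order`` fixes the
    left-to-right strip layout of groups on the unit square; Group1 and
    Group2 sit at opposite ends so they are spatially distant.
    """

    scenario_id: str
    n_genes: int = 500
    compositions: list[list[int]] = field(default_factory=list)
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    de_prob: float = 0.1
    de_factor_location: float = 0.3
    de_factor_scale: float = 0.2
    batch_factor_location: float = 0.12
    batch_factor_scale: float = 0.08
    library_location: float = float(np.log(5000))
    library_scale: float = 0.2
    group2_shared_de_fraction: float = 0.8
    rotation_deg: float = 60.0
    scale_factor: float = 1.5
    seed: int = 0

    @property
    def n_batches(self) -> int:
        return len(self.compositions)

    @property
    def all_groups(self) -> list[int]:
        out: list[int] = []
        for comp in self.compositions:
            for g in comp:
                if g not in out:
                    out.append(g)
        return sorted(out)

    @property
    def group_order(self) -> list[int]:
        """Strip order: Group1 first, Group2 last, others between."""
        groups = self.all_groups
        middle = [g for g in groups if g not in (1, 2)]
        order = []
        if 1 in groups:
            order.append(1)
        order += middle
        if 2 in groups:
            order.append(2)
        return order

    def geometry_op(self, batch_index: int) -> str:
        if self.scenario_id in ("simulate2", "simulate3") and batch_index == 1:
            return "reverse_order" if self.scenario_id == "simulate2" else "reverse_rotate_scale"
        return "none"

    def group_rectangles(self, batch_index: int) -> dict[int, tuple[float, float, float, float]]:
        """Axis-aligned (x0, x1, y0, y1) rectangle per group, pre-geometry-op."""
        order = self.group_order
        reverse = self.geometry_op(batch_index) != "none"
        if reverse:
            order = order[::-1]
        width = 1.0 / len(order)
        rects = {}
        for pos, g in enumerate(order):
            rects[g] = (pos * width, (pos + 1) * width, 0.0, 1.0)
        present = self.compositions[batch_index]
        return {g: r for g, r in rects.items() if g in present}


def get_scenario(scenario_id: str, seed: int = 0, **overrides) -> SimulationScenario:
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; valid ids: {', '.join(SCENARIO_IDS)}"
        )
    return SimulationScenario(
        scenario_id=scenario_id,
        compositions=[list(c) for c in _COMPOSITIONS[scenario_id]],
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------


def _lognormal_factors(rng: np.random.Generator, n: int, loc: float, scale: float,
                       signed: bool = True) -> np.ndarray:
    """Multiplicative factors exp(+-N(loc, scale)); sign flips direction."""
    logf = rng.normal(loc, scale, size=n)
    if signed:
        sign = rng.choice([-1.0, 1.0], size=n)
        logf = logf * sign
    return np.exp(logf)


def _group_de_factors(scenario: SimulationScenario, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Per-group per-gene DE factor vectors (1.0 for non-DE genes)."""
    G = scenario.n_genes
    n_de = max(1, int(round(scenario.de_prob * G)))
    factors: dict[int, np.ndarray] = {}
    loc, sc = scenario.de_factor_location, scenario.de_factor_scale

    de1 = rng.choice(G, size=n_de, replace=False)
    f1 = np.ones(G)
    f1[de1] = _lognormal_factors(rng, n_de, loc, sc)
    factors[1] = f1

    # Group2: mostly Group1's DE genes with slightly perturbed factors
    n_shared = int(round(scenario.group2_shared_de_fraction * n_de))
    shared = rng.choice(de1, size=n_shared, replace=False)
    rest_pool = np.setdiff1d(np.arange(G), de1)
    swapped = rng.choice(rest_pool, size=n_de - n_shared, replace=False)
    f2 = np.ones(G)
    f2[shared] = f1[shared] * np.exp(rng.normal(0.0, 0.05, size=n_shared))
    f2[swapped] = _lognormal_factors(rng, n_de - n_shared, loc, sc)
    factors[2] = f2

    for g in scenario.all_groups:
        if g in (1, 2):
            continue
        de = rng.choice(G, size=n_de, replace=False)
        f = np.ones(G)
        f[de] = _lognormal_factors(rng, n_de, loc, sc)
        factors[g] = f
    return factors


def simulate_counts(
    scenario: SimulationScenario, cells_per_group: int = 250
) -> tuple[list[SRTSample], dict]:
    """Simulate gamma-Poisson counts for every batch of a scenario.

    Returns the samples (coords zeroed until
    :func:`assign_spatial_coordinates`) and a dict of the sampled factors
    (``base_means``, ``de_factors``, ``batch_factors``) for diagnostics.
    """
    if cells_per_group < 1:
        raise ValueError("cells_per_group must be >= 1")
    for name in ("mean_shape", "mean_rate", "de_prob", "library_scale"):
        if getattr(scenario, name) <= 0 and name != "de_prob":
            raise ValueError(f"scenario parameter {name} must be positive")
    if not (0 < scenario.de_prob <= 1):
        raise ValueError("de_prob must be in (0, 1]")
    rng = np.random.default_rng(scenario.seed)
    G = scenario.n_genes
    base = rng.gamma(scenario.mean_shape, 1.0 / scenario.mean_rate, size=G)
    de = _group_de_factors(scenario, rng)
    batch_factors = {
        d: _lognormal_factors(
            rng, G, scenario.batch_factor_location, scenario.batch_factor_scale
        )
        for d in range(scenario.n_batches)
    }
    samples = []
    for d, comp in enumerate(scenario.compositions):
        n_cells = cells_per_group * len(comp)
        groups = np.repeat(comp, cells_per_group)
        lam = base[None, :] * np.vstack([de[g] for g in groups])
        lam = lam * batch_factors[d][None, :]
        lib = np.exp(rng.normal(scenario.library_location, scenario.library_scale, size=n_cells))
        lam = lam / lam.sum(axis=1, keepdims=True) * lib[:, None]
        counts = rng.poisson(lam)
        sample = SRTSample(
            sample_id=f"batch{d + 1}",
            counts=counts,
            coords=np.zeros((n_cells, 2)),
            gene_names=[f"gene{j}" for j in range(G)],
            spot_ids=[f"batch{d + 1}_spot{i}" for i in range(n_cells)],
            group_labels=groups.copy(),
        )
        samples.append(sample)
    factors = {"base_means": base, "de_factors": de, "batch_factors": batch_factors}
    return samples, factors


def _rotation_matrix(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, s], [-s, c]])  # row-vector convention: p @ R


def assign_spatial_coordinates(
    samples: list[SRTSample], scenario: SimulationScenario
) -> list[SRTSample]:
    """Place each group's cells uniformly in its rectangle; apply geometry ops.

    Placement is grid-jittered uniform within the group rectangle so spots
    cover the region evenly. simulate2 reverses the left-to-right group
    ordering for batch 2; simulate3 additionally rotates batch 2 by the
    scenario angle and multiplies coordinates by the scale factor.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    out = []
    for d, sample in enumerate(samples):
        rects = scenario.group_rectangles(d)
        vals = list(rects.values())
        for a in range(len(vals)):
            for b in range(a + 1, len(vals)):
                ax0, ax1, ay0, ay1 = vals[a]
                bx0, bx1, by0, by1 = vals[b]
                if ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1:
                    raise ValueError("overlapping group rectangles in layout")
        coords = np.zeros((sample.n_spots, 2))
        for g, (x0, x1, y0, y1) in rects.items():
            idx = np.flatnonzero(sample.group_labels == g)
            n = len(idx)
            if n == 0:
                continue
            # jittered grid: ceil-sqrt grid cells, uniform jitter inside each
            nx = max(1, int(np.ceil(np.sqrt(n * (x1 - x0) / (y1 - y0)))))
            ny = int(np.ceil(n / nx))
            cells = [(i, j) for j in range(ny) for i in range(nx)][:n]
            cells = np.asarray(cells, dtype=float)
            u = rng.uniform(size=(n, 2))
            coords[idx, 0] = x0 + (cells[:, 0] + u[:, 0]) * (x1 - x0) / nx
            coords[idx, 1] = y0 + (cells[:, 1] + u[:, 1]) * (y1 - y0) / ny
        op = scenario.geometry_op(d)
        if op == "reverse_rotate_scale":
            coords = coords @ _rotation_matrix(scenario.rotation_deg) * scenario.scale_factor
        new = sample.subset_spots(np.arange(sample.n_spots))
        new.coords = coords
        out.append(new)
    return out


def make_scenario(
    scenario_id: str, seed: int = 0, cells_per_group: int = 250, **overrides
) -> tuple[list[SRTSample], np.ndarray, np.ndarray, SimulationScenario]:
    """One-call fixture: counts + coordinates + ground-truth labels.

    Returns ``(samples, group_labels, batch_labels, scenario)`` where the
    label arrays are concatenated over batches in sample order.
    """
    scenario = get_scenario(scenario_id, seed=seed, **overrides)
    samples, _ = simulate_counts(scenario, cells_per_group=cells_per_group)
    samples = assign_spatial_coordinates(samples, scenario)
    group_labels = np.concatenate([s.group_labels for s in samples])
    batch_labels = np.concatenate(
        [np.full(s.n_spots, d) for d, s in enumerate(samples)]
    )
    return samples, group_labels, batch_labels, scenario
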