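"""Reading, QC, preprocessing and graph construction for spatial transcriptomics samples.

A dataset is a list of :class:`SRTSample` objects, one per slice/batch. Raw
counts are kept alongside the model-ready ``expr`` matrix (library-size
normalised, log1p, min-max scaled to [0, 1] jointly across samples). Spatial
neighbourhood structure is a per-sample :class:`SpatialGraph`; edges never
cross samples.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SRTSample",
    "SpatialGraph",
    "TranscriptTable",
    "load_sample",
    "save_sample",
    "qc_filter_spots",
    "bin_transcripts",
    "preprocess_expression",
    "build_graph",
]


@dataclass
class SRTSample:
    """One batch of spatial transcriptomics data.

    Attributes
    ----------
    sample_id : str
        Batch identifier.
    counts : ndarray, shape (n_spots, n_genes)
        Raw non-negative integer UMI counts.
    coords : ndarray, shape (n_spots, 2)
        Euclidean spot positions (pixels or micrometres).
    gene_names, spot_ids : list of str
    expr : ndarray or None
        Model-ready expression in [0, 1]; set by
        :func:`preprocess_expression`.
    """

    sample_id: str
    counts: np.ndarray
    coords: np.ndarray
    gene_names: list[str]
    spot_ids: list[str]
    expr: np.ndarray | None = None
    group_labels: np.ndarray | None = None  # optional per-spot annotation

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n_spots, 2) matrix")
        if self.counts.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"counts has {self.counts.shape[0]} spots but coords has "
                f"{self.coords.shape[0]}"
            )
        if len(self.gene_names) != self.counts.shape[1]:
            raise ValueError("gene_names length does not match counts columns")
        if len(self.spot_ids) != self.counts.shape[0]:
            raise ValueError("spot_ids length does not match counts rows")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, idx: np.ndarray) -> "SRTSample":
        return replace(
            self,
            counts=self.counts[idx],
            coords=self.coords[idx],
            spot_ids=[self.spot_ids[i] for i in np.atleast_1d(idx)],
            expr=None if self.expr is None else self.expr[idx],
            group_labels=None if self.group_labels is None else self.group_labels[idx],
        )


@dataclass
class SpatialGraph:
    """Undirected neighbourhood graph over one sample's spots.

    ``neighbor_lists[i]`` is the sorted array of neighbours of node ``i``;
    symmetry (j in N(i) iff i in N(j)) and absence of self-loops are enforced
    at construction.
    """

    n_nodes: int
    neighbor_lists: list[np.ndarray]
    mode: str
    param: float

    def edges(self) -> np.ndarray:
        """Array of unordered edges (i < j), shape (n_edges, 2)."""
        out = [
            (i, j)
            for i, nbrs in enumerate(self.neighbor_lists)
            for j in nbrs
            if i < j
        ]
        return np.asarray(out, dtype=int).reshape(-1, 2)

    def adjacency(self) -> sp.csr_matrix:
        rows = np.repeat(
            np.arange(self.n_nodes),
            [len(n) for n in self.neighbor_lists],
        )
        cols = np.concatenate([np.asarray(n, dtype=int) for n in self.neighbor_lists]) \
            if self.n_nodes else np.empty(0, dtype=int)
        data = np.ones(len(cols))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n_nodes, self.n_nodes))

    def mean_operator(self) -> sp.csr_matrix:
        """Row-stochastic neighbour-mean matrix; isolated nodes fall back to self."""
        adj = self.adjacency().tolil()
        for i, nbrs in enumerate(self.neighbor_lists):
            if len(nbrs) == 0:
                adj[i, i] = 1.0
        adj = adj.tocsr()
        deg = np.asarray(adj.sum(axis=1)).ravel()
        inv = sp.diags(1.0 / deg)
        return (inv @ adj).tocsr()

    def degree(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighbor_lists])


@dataclass
class TranscriptTable:
    """Per-molecule records from sub-cellular resolution platforms."""

    gene: np.ndarray
    x: np.ndarray
    y: np.ndarray
    umi_count: np.ndarray

    def __post_init__(self) -> None:
        self.gene = np.asarray(self.gene)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.umi_count = np.asarray(self.umi_count, dtype=int)
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("transcript coordinates must be finite")
        if (self.umi_count < 1).any():
            raise ValueError("umi_count must be >= 1")

    def __len__(self) -> int:
        return len(self.gene)


# ---------------------------------------------------------------------------
# loading / saving


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find(dirpath: Path, stem: str) -> Path:
    for cand in (dirpath / stem, dirpath / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"expected {stem}[.gz] in {dirpath}")


def _load_mtx_dir(path: Path) -> SRTSample:
    mat = scipy.io.mmread(str(_find(path, "matrix.mtx")))
    counts = np.asarray(sp.csr_matrix(mat).todense())
    with _open_maybe_gz(_find(path, "barcodes.tsv")) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gz(_find(path, "features.tsv")) as fh:
        genes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    # CellRanger stores genes x spots; transpose to spots x genes
    if counts.shape == (len(genes), len(barcodes)):
        counts = counts.T
    elif counts.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix shape {counts.shape} matches neither (genes, spots)="
            f"({len(genes)}, {len(barcodes)}) nor its transpose"
        )
    coord_file = None
    for stem in ("coordinates.csv", "tissue_positions.csv", "tissue_positions_list.csv"):
        try:
            coord_file = _find(path, stem)
            break
        except FileNotFoundError:
            continue
    if coord_file is None:
        raise FileNotFoundError(
            f"no coordinate file in {path}; expected coordinates.csv or "
            "tissue_positions.csv with columns spot_id,x,y"
        )
    cdf = pd.read_csv(coord_file)
    cdf = cdf.set_index(cdf.columns[0])
    missing = [b for b in barcodes if b not in cdf.index]
    if missing:
        raise ValueError(f"coordinates missing for {len(missing)} spots, e.g. {missing[:3]}")
    coords = cdf.loc[barcodes].iloc[:, :2].to_numpy(dtype=float)
    return SRTSample(path.name, counts, coords, genes, barcodes)


def _load_h5ad(path: Path) -> SRTSample:
    import anndata

    adata = anndata.read_h5ad(path)
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    counts = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    if "spatial" not in adata.obsm:
        raise ValueError(f"{path}: no obsm['spatial'] coordinate slot")
    coords = np.asarray(adata.obsm["spatial"], dtype=float)[:, :2]
    sample = SRTSample(
        path.stem,
        counts,
        coords,
        list(adata.var_names),
        list(adata.obs_names),
    )
    if "group" in adata.obs:
        sample.group_labels = adata.obs["group"].to_numpy()
    return sample


def _load_csv_pair(path: Path) -> SRTSample:
    expr_file = _find(path, "expression.csv")
    try:
        coord_file = _find(path, "coordinates.csv")
    except FileNotFoundError as err:
        raise FileNotFoundError(
            f"no coordinates.csv next to {expr_file}; expected columns spot_id,x,y"
        ) from err
    edf = pd.read_csv(expr_file, index_col=0)
    cdf = pd.read_csv(coord_file)
    cdf = cdf.set_index(cdf.columns[0])
    missing = edf.index.difference(cdf.index)
    if len(missing):
        raise ValueError(f"coordinates missing for spots {list(missing[:3])} ...")
    cdf = cdf.loc[edf.index]  # join on spot_id: coord rows follow expression order
    return SRTSample(
        path.name,
        edf.to_numpy(),
        cdf.iloc[:, :2].to_numpy(dtype=float),
        list(edf.columns),
        list(edf.index.astype(str)),
    )


_LOADERS = {"mtx_dir": _load_mtx_dir, "h5ad": _load_h5ad, "csv_pair": _load_csv_pair}


def load_sample(path, format: str) -> SRTSample:
    """Load one sample from disk.

    ``mtx_dir``: directory with matrix.mtx[.gz], barcodes.tsv[.gz],
    features.tsv[.gz] and a spot_id,x,y coordinate CSV. ``h5ad``: counts in X
    (or layer "counts"), coordinates in obsm["spatial"]. ``csv_pair``:
    directory with expression.csv (spots x genes, spot_id index) and
    coordinates.csv (spot_id,x,y); coordinate rows are joined on spot_id.
    """
    path = Path(path)
    if format not in _LOADERS:
        raise ValueError(f"unknown format {format!r}; use one of {sorted(_LOADERS)}")
    if not path.exists():
        raise FileNotFoundError(path)
    return _LOADERS[format](path)


def save_sample(sample: SRTSample, path, format: str = "h5ad") -> None:
    """Write a sample as h5ad or as an MTX directory with coordinates.csv."""
    path = Path(path)
    if format == "h5ad":
        import anndata

        adata = anndata.AnnData(
            X=sp.csr_matrix(np.asarray(sample.counts, dtype=np.float64)),
            obs=pd.DataFrame(index=sample.spot_ids),
            var=pd.DataFrame(index=sample.gene_names),
        )
        adata.obsm["spatial"] = np.asarray(sample.coords, dtype=float)
        if sample.group_labels is not None:
            adata.obs["group"] = pd.Categorical(sample.group_labels)
        adata.write_h5ad(path)
    elif format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            str(path / "matrix.mtx"),
            sp.coo_matrix(np.asarray(sample.counts).T),  # genes x spots
        )
        (path / "barcodes.tsv").write_text("\n".join(sample.spot_ids) + "\n")
        (path / "features.tsv").write_text("\n".join(sample.gene_names) + "\n")
        pd.DataFrame(
            {"spot_id": sample.spot_ids,
             "x": sample.coords[:, 0],
             "y": sample.coords[:, 1]}
        ).to_csv(path / "coordinates.csv", index=False)
        if sample.group_labels is not None:
            pd.DataFrame(
                {"spot_id": sample.spot_ids, "group": sample.group_labels}
            ).to_csv(path / "labels.csv", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# QC / binning / preprocessing


def qc_filter_spots(
    sample: SRTSample, min_umi: int = 3000, min_genes: int = 15
) -> SRTSample:
    """Drop low-quality spots: keep total UMI >= min_umi and detected genes >= min_genes."""
    totals = np.asarray(sample.counts).sum(axis=1)
    detected = (np.asarray(sample.counts) > 0).sum(axis=1)
    keep = np.flatnonzero((totals >= min_umi) & (detected >= min_genes))
    if keep.size == 0:
        raise ValueError(
            f"qc_filter_spots removed all {sample.n_spots} spots "
            f"(min_umi={min_umi}, min_genes={min_genes}); lower the thresholds"
        )
    return sample.subset_spots(keep)


def bin_transcripts(tt: TranscriptTable, bin_size: int = 50) -> SRTSample:
    """Aggregate sub-cellular transcripts into square bins of side ``bin_size``.

    Bin id of a molecule is (floor((x - x_min)/bin_size), floor((y - y_min)/bin_size));
    UMI counts are summed per (bin, gene) and the bin centre (original units)
    becomes the spot coordinate.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if len(tt) == 0:
        raise ValueError("empty transcript table")
    x0, y0 = tt.x.min(), tt.y.min()
    bx = np.floor((tt.x - x0) / bin_size).astype(int)
    by = np.floor((tt.y - y0) / bin_size).astype(int)
    df = pd.DataFrame({"bx": bx, "by": by, "gene": tt.gene, "umi": tt.umi_count})
    genes = sorted(pd.unique(df["gene"]))
    gene_idx = {g: i for i, g in enumerate(genes)}
    bins = df[["bx", "by"]].drop_duplicates().sort_values(["bx", "by"])
    bin_idx = {(r.bx, r.by): i for i, r in enumerate(bins.itertuples())}
    counts = np.zeros((len(bins), len(genes)), dtype=int)
    for r in df.itertuples():
        counts[bin_idx[(r.bx, r.by)], gene_idx[r.gene]] += r.umi
    coords = np.column_stack(
        [
            x0 + (bins["bx"].to_numpy() + 0.5) * bin_size,
            y0 + (bins["by"].to_numpy() + 0.5) * bin_size,
        ]
    )
    spot_ids = [f"bin_{r.bx}_{r.by}" for r in bins.itertuples()]
    return SRTSample("binned", counts, coords, genes, spot_ids)


def _dispersion(mat: np.ndarray) -> np.ndarray:
    """Per-gene dispersion (variance / mean) of log-normalised expression."""
    mean = mat.mean(axis=0)
    var = mat.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return disp


def lognormalize(counts: np.ndarray, target: float | None = None) -> np.ndarray:
    """Library-size normalisation to the median total (or ``target``) + log1p."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    if target is None:
        target = float(np.median(totals))
    totals = np.where(totals == 0, 1.0, totals)
    return np.log1p(counts / totals[:, None] * target)


def preprocess_expression(
    samples: list[SRTSample], n_genes: int = 3000
) -> list[SRTSample]:
    """Select shared highly dispersed genes and scale expression to [0, 1].

    Genes are restricted to the intersection across samples, then the top
    ``n_genes`` by dispersion of the concatenated log-normalised matrix are
    kept. Each spot is library-size normalised (to the global median total)
    and log1p-transformed; per-gene min-max scaling is fit on the
    concatenated matrix so values are comparable across samples. Constant
    genes map to 0.
    """
    if not samples:
        raise ValueError("need at least one sample")
    shared = set(samples[0].gene_names)
    for s in samples[1:]:
        shared &= set(s.gene_names)
    if not shared:
        raise ValueError("gene intersection across samples is empty")
    # keep the first sample's ordering for determinism
    shared_ordered = [g for g in samples[0].gene_names if g in shared]
    if n_genes > len(shared_ordered):
        raise ValueError(
            f"n_genes={n_genes} exceeds the {len(shared_ordered)}-gene "
            "intersection across samples"
        )
    sub_counts = []
    for s in samples:
        pos = {g: i for i, g in enumerate(s.gene_names)}
        cols = [pos[g] for g in shared_ordered]
        sub_counts.append(np.asarray(s.counts)[:, cols])
    concat = np.vstack(sub_counts)
    target = float(np.median(concat.sum(axis=1)))
    logn = lognormalize(concat, target=target)
    order = np.argsort(-_dispersion(logn), kind="stable")[:n_genes]
    order = np.sort(order)  # preserve stored gene order among the selected
    sel_genes = [shared_ordered[i] for i in order]
    logn_sel = logn[:, order]
    gmin = logn_sel.min(axis=0)
    gmax = logn_sel.max(axis=0)
    rng = gmax - gmin
    safe = np.where(rng > 0, rng, 1.0)
    scaled = np.where(rng > 0, (logn_sel - gmin) / safe, 0.0)
    out = []
    start = 0
    for s, sub in zip(samples, sub_counts):
        stop = start + s.n_spots
        out.append(
            replace(
                s,
                counts=sub[:, order],
                gene_names=sel_genes,
                expr=scaled[start:stop],
            )
        )
        start = stop
    return out


# ---------------------------------------------------------------------------
# graph construction

#: knn defaults by platform flavour
KNN_DEFAULTS = {"visium": 6, "slide_seq": 8, "stereo_seq": 8, "synthetic": 10}


def _knn_candidates(points: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbours of each point, ties broken toward lower index."""
    n = points.shape[0]
    if n <= 4096:
        d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        # lexsort: primary key distance, secondary key index (stable)
        return np.argsort(d, axis=1, kind="stable")[:, :k]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    idx = nn.kneighbors(points, return_distance=False)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        row = idx[i][idx[i] != i][:k]
        out[i] = row
    return out


def build_graph(points: np.ndarray, mode: str = "knn", param: float = 6) -> SpatialGraph:
    """Build a symmetric neighbourhood graph over points.

    ``knn``: edge i-j if j is among the ``param`` nearest of i or vice versa
    (union symmetrisation, so minimum degree >= param). ``radius``: edge if
    the Euclidean distance is <= param. ``feature``: knn on a 50-component
    PCA of the rows — used for expression-similarity graphs, e.g. when
    projecting dissociated scRNA-seq through a trained model.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if param <= 0:
        raise ValueError("param must be positive")
    if mode in ("knn", "feature"):
        k = int(param)
        if k >= n:
            raise ValueError(f"knn param {k} must be < number of points {n}")
        coords = points
        if mode == "feature" and points.shape[1] > 50:
            coords = PCA(n_components=50, random_state=0).fit_transform(points)
        nbr = _knn_candidates(coords, k)
        pairs = {(i, j) if i < j else (j, i) for i in range(n) for j in nbr[i]}
    elif mode == "radius":
        d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
        ii, jj = np.nonzero(np.triu(d <= param, k=1))
        pairs = set(zip(ii.tolist(), jj.tolist()))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lists: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        lists[i].append(j)
        lists[j].append(i)
    return SpatialGraph(
        n_nodes=n,
        neighbor_lists=[np.array(sorted(l), dtype=int) for l in lists],
        mode=mode,
        param=param,
    )
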