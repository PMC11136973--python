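"""Metacell clustering: feature selection, balanced KNN graph, bootstrap
co-clustering, and partition derivation.

The pipeline partitions single cells into small, transcriptionally
homogeneous clusters (metacells):

1. per-cell downsampling to a common depth;
2. informative-gene selection (total UMI, prevalence, size correlation,
   niche concentration filters);
3. a balanced K-nearest-neighbor cell graph built from Pearson
   correlations of log-transformed downsampled counts (K = 100), where
   an undirected edge survives only if the product of the two directed
   ranks is at most K^2 and each node keeps at most 2K edges;
4. bootstrap co-clustering: repeated community detection on induced
   subgraphs of 75% of the cells (1,000 iterations by default),
   accumulating how often each cell pair is co-sampled and co-assigned;
5. a partition of the co-clustering frequency graph (K_cc = 30 partners
   per cell, alpha = 2 weak-edge filter, minimum metacell size 15), with
   undersized clusters dissolved into their best-matching neighbors;
6. removal of low-information metacells (> 50 cells with median UMI/cell
   below 500).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import child_seed, substream
from .matrix import UMICountMatrix

__all__ = [
    "FeatureSet",
    "CellGraph",
    "CoClustering",
    "MetacellPartition",
    "downsample_cells",
    "select_features",
    "build_balanced_knn",
    "bootstrap_cocluster",
    "derive_metacells",
    "filter_low_quality_metacells",
    "layout_2d",
    "cluster_cells",
]


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def downsample_cells(
    matrix: UMICountMatrix,
    target_depth: int | str = "auto",
    seed: int = 0,
) -> UMICountMatrix:
    """Subsample cells above ``target_depth`` to exactly that depth.

    Sampling is without replacement within each cell (multivariate
    hypergeometric), so no gene can gain counts. Cells at or below the
    target are kept unchanged. ``"auto"`` uses the 5th percentile of
    per-cell totals.
    """
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise ValueError("empty matrix")
    totals = matrix.cell_totals()
    if target_depth == "auto":
        target = int(np.percentile(totals, 5))
    else:
        target = int(target_depth)
    if target < 1:
        raise ValueError("target_depth must be >= 1")

    rng = substream(seed, "downsample")
    counts = matrix.counts.tocsc()
    indptr, indices, data = counts.indptr, counts.indices, counts.data
    new_data = data.copy()
    for c in range(matrix.n_cells):
        if totals[c] <= target:
            continue
        lo, hi = indptr[c], indptr[c + 1]
        colors = data[lo:hi].astype(np.int64)
        new_data[lo:hi] = rng.multivariate_hypergeometric(colors, target)
    out = sp.csc_matrix((new_data, indices.copy(), indptr.copy()), shape=counts.shape)
    out.eliminate_zeros()
    return UMICountMatrix(out, matrix.gene_ids, matrix.cell_ids)


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Selected feature genes plus the per-gene statistics behind them."""

    gene_ids: np.ndarray
    stats: pd.DataFrame  # per gene: total_umi, prevalence, size_correlation, niche_score, selected
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)


def select_features(
    matrix: UMICountMatrix,
    downsampled: UMICountMatrix | None = None,
    t_tot: int = 30,
    t_prev_cells: int = 3,
    t_prev_umi: int = 2,
    t_szcor: float = -0.1,
    t_niche: float = 0.01,
    use_szcor: bool = True,
    use_niche: bool = True,
    seed: int = 0,
) -> FeatureSet:
    """Select informative genes for clustering.

    A gene passes when its total UMI count exceeds ``t_tot``, it has more
    than ``t_prev_umi`` UMIs in at least ``t_prev_cells`` cells, its size
    correlation (Pearson correlation of downsampled counts with
    pre-downsampling cell totals) is below ``t_szcor``, and its niche
    score is above ``t_niche``. The niche score is the fraction of the
    gene's downsampled UMIs concentrated in its top-5%-expressing cells,
    in excess of the uniform expectation (k/n for the top k of n cells);
    it is 0 for a perfectly even gene and approaches 0.95 for a gene
    confined to a niche. The size-correlation and niche filters can each
    be disabled; statistics are reported for every gene regardless.
    """
    if matrix.n_cells == 0:
        raise ValueError("empty matrix")
    if downsampled is None:
        downsampled = downsample_cells(matrix, "auto", seed=seed)

    totals_raw = matrix.gene_totals()
    prevalence = np.asarray((matrix.counts > t_prev_umi).sum(axis=1)).ravel()

    ds = np.asarray(downsampled.counts.todense(), dtype=float)
    cell_tot = matrix.cell_totals().astype(float)

    # Pearson correlation of each gene's downsampled counts vs raw totals.
    x = ds - ds.mean(axis=1, keepdims=True)
    y = cell_tot - cell_tot.mean()
    denom = np.sqrt((x**2).sum(axis=1) * (y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        szcor = (x @ y) / denom
    szcor = np.where(np.isfinite(szcor), szcor, 0.0)

    n = matrix.n_cells
    k = max(1, int(np.ceil(0.05 * n)))
    part = np.partition(ds, n - k, axis=1)[:, n - k :]
    gene_ds_tot = ds.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        top_frac = part.sum(axis=1) / gene_ds_tot
    top_frac = np.where(gene_ds_tot > 0, top_frac, k / n)
    niche = top_frac - k / n

    selected = (totals_raw > t_tot) & (prevalence >= t_prev_cells)
    if use_szcor:
        selected &= szcor < t_szcor
    if use_niche:
        selected &= niche > t_niche

    stats = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "total_umi": totals_raw,
            "prevalence": prevalence,
            "size_correlation": szcor,
            "niche_score": niche,
            "selected": selected,
        }
    ).set_index("gene_id")
    params = {
        "t_tot": t_tot,
        "t_prev_cells": t_prev_cells,
        "t_prev_umi": t_prev_umi,
        "t_szcor": t_szcor,
        "t_niche": t_niche,
        "use_szcor": use_szcor,
        "use_niche": use_niche,
    }
    return FeatureSet(matrix.gene_ids[selected], stats, params)


# ---------------------------------------------------------------------------
# Balanced KNN graph
# ---------------------------------------------------------------------------

@dataclass
class CellGraph:
    """Weighted undirected cell graph (no self-edges, positive weights)."""

    cell_ids: np.ndarray
    edges: np.ndarray  # (m, 2) int array, i < j
    weights: np.ndarray  # (m,) positive floats
    K: int

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=self.n_cells, edges=[tuple(e) for e in self.edges])
        g.es["weight"] = self.weights.tolist()
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_a": self.cell_ids[self.edges[:, 0]],
                "cell_b": self.cell_ids[self.edges[:, 1]],
                "weight": self.weights,
            }
        )


def build_balanced_knn(
    matrix: UMICountMatrix,
    features: FeatureSet | np.ndarray,
    K: int = 100,
) -> CellGraph:
    """Build the balanced K-nearest-neighbor cell graph.

    Similarity is the Pearson correlation of log2(1 + counts) over the
    feature genes (``matrix`` should already be depth-downsampled).
    Each cell ranks its 3K most similar cells; the undirected edge (i, j)
    is kept iff the rank product r_ij * r_ji <= K^2, with weight
    1 / (1 + sqrt(r_ij * r_ji)). Finally each node retains at most 2K
    incident edges, strongest first. Rank ties are broken by cell order.
    """
    feat_ids = features.gene_ids if isinstance(features, FeatureSet) else np.asarray(features)
    if len(feat_ids) < 2:
        raise ValueError("need at least 2 feature genes")
    n = matrix.n_cells
    if n < K + 1:
        raise ValueError(
            f"need at least K+1={K + 1} cells for K={K}; lower K for small datasets"
        )
    rows = matrix.gene_index(feat_ids)
    X = np.log2(1.0 + np.asarray(matrix.counts[rows, :].todense(), dtype=float)).T

    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    norms[norms == 0] = 1.0
    Xn = Xc / norms[:, None]
    S = Xn @ Xn.T
    np.fill_diagonal(S, -np.inf)

    L = min(3 * K, n - 1)
    # Stable argsort on -S: ties resolved by ascending cell index.
    order = np.argsort(-S, axis=1, kind="stable")[:, :L]
    ranks = np.full((n, n), np.inf)
    row_idx = np.repeat(np.arange(n), L)
    ranks[row_idx, order.ravel()] = np.tile(np.arange(1, L + 1), n)

    prod = ranks * ranks.T
    ii, jj = np.nonzero(np.triu(prod <= K * K, k=1))
    w = 1.0 / (1.0 + np.sqrt(prod[ii, jj]))

    # Cap incident edges at 2K per node, strongest first (ties by index).
    order_e = np.lexsort((jj, ii, -w))
    deg = np.zeros(n, dtype=int)
    keep = np.zeros(len(ii), dtype=bool)
    cap = 2 * K
    for e in order_e:
        a, b = ii[e], jj[e]
        if deg[a] < cap and deg[b] < cap:
            keep[e] = True
            deg[a] += 1
            deg[b] += 1
    edges = np.column_stack([ii[keep], jj[keep]])
    return CellGraph(matrix.cell_ids, edges, w[keep], K)


# ---------------------------------------------------------------------------
# Bootstrap co-clustering
# ---------------------------------------------------------------------------

@dataclass
class CoClustering:
    """Pairwise co-cluster and co-sample counts over bootstrap iterations."""

    cell_ids: np.ndarray
    co_count: np.ndarray  # (n, n) int
    co_sample: np.ndarray  # (n, n) int
    n_iter: int
    sample_fraction: float

    def frequency(self) -> np.ndarray:
        """Co-clustering frequency f_ij = co_count / co_sample (0 where never co-sampled)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.co_count / self.co_sample
        f = np.where(self.co_sample > 0, f, 0.0)
        np.fill_diagonal(f, 0.0)
        return f


def _leiden_membership(graph: ig.Graph, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        graph,
        leidenalg.ModularityVertexPartition,
        weights="weight" if "weight" in graph.es.attributes() else None,
        seed=seed,
    )
    return np.asarray(part.membership)


def bootstrap_cocluster(
    graph: CellGraph,
    n_iter: int = 1000,
    fraction: float = 0.75,
    seed: int = 0,
) -> CoClustering:
    """Bootstrap resampling of the cell graph with community detection.

    Each iteration samples ``ceil(fraction * n)`` cells without
    replacement, partitions the induced subgraph by seeded modularity
    community detection, and increments co-cluster counts for co-assigned
    pairs and co-sample counts for co-sampled pairs.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n = graph.n_cells
    m = int(np.ceil(fraction * n))
    rng = substream(seed, "bootstrap-cocluster")
    g = graph.to_igraph()

    co = np.zeros((n, n), dtype=np.int32)
    samp = np.zeros((n, n), dtype=np.int32)
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = g.induced_subgraph(idx.tolist())
        membership = _leiden_membership(sub, child_seed(rng))
        same = membership[:, None] == membership[None, :]
        block = np.ix_(idx, idx)
        co[block] += same
        samp[block] += 1
    return CoClustering(graph.cell_ids, co, samp, n_iter, fraction)


# ---------------------------------------------------------------------------
# Partition derivation
# ---------------------------------------------------------------------------

@dataclass
class MetacellPartition:
    """Cell -> metacell assignment; -1 marks outliers."""

    cell_ids: np.ndarray
    assignment: np.ndarray  # int array, -1 = outlier
    min_size: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_metacells(self) -> int:
        labels = self.assignment[self.assignment >= 0]
        return len(np.unique(labels))

    def metacell_ids(self) -> np.ndarray:
        return np.unique(self.assignment[self.assignment >= 0])

    def members(self, metacell: int) -> np.ndarray:
        return np.nonzero(self.assignment == metacell)[0]

    def sizes(self) -> pd.Series:
        labels = self.assignment[self.assignment >= 0]
        return pd.Series(labels).value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        label = np.where(self.assignment >= 0, self.assignment.astype(object), "outlier")
        return pd.DataFrame({"cell_id": self.cell_ids, "metacell_id": label})

    def relabelled(self, new_assignment: np.ndarray, **extra) -> "MetacellPartition":
        prov = dict(self.provenance)
        prov.update(extra)
        return MetacellPartition(self.cell_ids, new_assignment, self.min_size, prov)


def derive_metacells(
    cocluster: CoClustering,
    K_cc: int = 30,
    alpha: float = 2.0,
    min_size: int = 15,
    seed: int = 0,
) -> MetacellPartition:
    """Partition cells from the bootstrap co-clustering frequencies.

    Builds a graph on frequencies f_ij = co_count / co_sample keeping per
    cell its ``K_cc`` strongest partners, drops edges with
    f_ij < f_max / alpha for *both* endpoints (f_max being each cell's
    strongest frequency), partitions by seeded modularity community
    detection, and dissolves clusters smaller than ``min_size`` by
    reassigning each member to the surviving cluster with the largest
    summed frequency (outlier if none).
    """
    if (cocluster.co_sample.sum() - np.trace(cocluster.co_sample)) == 0:
        raise ValueError("degenerate co-clustering: no pair was ever co-sampled")
    f = cocluster.frequency()
    n = f.shape[0]

    # Per-cell K_cc strongest partners (union over endpoints).
    kth = min(K_cc, max(1, n - 1))
    thresh = -np.sort(-f, axis=1)[:, kth - 1]
    topk = f >= np.maximum(thresh, np.finfo(float).tiny)[:, None]
    topk |= topk.T

    fmax = f.max(axis=1)
    with np.errstate(invalid="ignore"):
        weak_i = f < (fmax[:, None] / alpha) if np.isfinite(alpha) else np.zeros_like(f, bool)
    weak = weak_i & weak_i.T
    adj = topk & ~weak & (f > 0)
    adj &= adj.T

    ii, jj = np.nonzero(np.triu(adj, k=1))
    if len(ii) == 0:
        warnings.warn("all co-clustering edges removed; every cell is an outlier")
        return MetacellPartition(
            cocluster.cell_ids, np.full(n, -1, dtype=int), min_size,
            {"K_cc": K_cc, "alpha": alpha},
        )
    g = ig.Graph(n=n, edges=list(zip(ii.tolist(), jj.tolist())))
    g.es["weight"] = f[ii, jj].tolist()
    membership = _leiden_membership(g, seed=child_seed(substream(seed, "derive-metacells")))

    labels = membership.copy()
    sizes = np.bincount(labels)
    big = np.nonzero(sizes >= min_size)[0]
    if len(big) == 0:
        warnings.warn(f"no cluster reaches min_size={min_size}; all cells are outliers")
        assignment = np.full(n, -1, dtype=int)
    else:
        assignment = np.full(n, -1, dtype=int)
        big_members = {b: np.nonzero(labels == b)[0] for b in big}
        remap = {b: i for i, b in enumerate(sorted(big, key=lambda b: big_members[b][0]))}
        for b in big:
            assignment[labels == b] = remap[b]
        small_cells = np.nonzero(~np.isin(labels, big))[0]
        for c in small_cells:
            scores = np.array([f[c, big_members[b]].sum() for b in big])
            if scores.max() > 0:
                assignment[c] = remap[big[int(np.argmax(scores))]]
    return MetacellPartition(
        cocluster.cell_ids, assignment, min_size,
        {"K_cc": K_cc, "alpha": alpha, "n_iter": cocluster.n_iter,
         "sample_fraction": cocluster.sample_fraction},
    )


def filter_low_quality_metacells(
    partition: MetacellPartition,
    matrix: UMICountMatrix,
    min_cells: int = 50,
    min_median_umi: int = 500,
) -> MetacellPartition:
    """Mark metacells with low transcriptomic information as outliers.

    A metacell is removed when it has more than ``min_cells`` cells AND a
    median per-cell total UMI strictly below ``min_median_umi``.
    """
    if not np.array_equal(partition.cell_ids, matrix.cell_ids):
        raise ValueError("partition and matrix cell ids differ")
    totals = matrix.cell_totals()
    assignment = partition.assignment.copy()
    for mc in partition.metacell_ids():
        members = partition.members(mc)
        if len(members) > min_cells and np.median(totals[members]) < min_median_umi:
            assignment[members] = -1
    return partition.relabelled(
        assignment, low_quality_filter={"min_cells": min_cells, "min_median_umi": min_median_umi}
    )


# ---------------------------------------------------------------------------
# 2D layout
# ---------------------------------------------------------------------------

def layout_2d(
    cocluster: CoClustering,
    partition: MetacellPartition,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Force-directed layout of the metacell co-clustering graph.

    Metacells are spring-embedded using mean between-metacell
    co-clustering frequency as edge weight; cells are scattered around
    their metacell centroid with seeded jitter. Outlier cells get NaN
    coordinates. Returns (metacell coords, cell coords) tables.
    """
    mcs = partition.metacell_ids()
    if len(mcs) == 0:
        raise ValueError("no metacells to lay out")
    f = cocluster.frequency()
    G = nx.Graph()
    G.add_nodes_from(int(m) for m in mcs)
    for a_i, a in enumerate(mcs):
        ma = partition.members(a)
        for b in mcs[a_i + 1 :]:
            mb = partition.members(b)
            w = float(f[np.ix_(ma, mb)].mean())
            if w > 0:
                G.add_edge(int(a), int(b), weight=w)
    if len(mcs) == 1:
        pos = {int(mcs[0]): np.zeros(2)}
    else:
        pos = nx.spring_layout(G, seed=seed % (2**32), weight="weight")

    mc_coords = pd.DataFrame(
        {"metacell_id": [int(m) for m in mcs],
         "x": [pos[int(m)][0] for m in mcs],
         "y": [pos[int(m)][1] for m in mcs]}
    )
    span = max(
        float(np.ptp(mc_coords[["x", "y"]].to_numpy())) if len(mcs) > 1 else 1.0, 1e-6
    )
    rng = substream(seed, "layout-jitter")
    xy = np.full((len(partition.cell_ids), 2), np.nan)
    for m in mcs:
        members = partition.members(m)
        center = pos[int(m)]
        xy[members] = center + rng.normal(0, 0.02 * span, size=(len(members), 2))
    cell_coords = pd.DataFrame(
        {"cell_id": partition.cell_ids, "x": xy[:, 0], "y": xy[:, 1],
         "metacell_id": [int(a) if a >= 0 else None for a in partition.assignment]}
    )
    return mc_coords, cell_coords


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------

def cluster_cells(
    matrix: UMICountMatrix,
    K: int = 100,
    K_cc: int = 30,
    n_boot: int = 1000,
    fraction: float = 0.75,
    alpha: float = 2.0,
    min_size: int = 15,
    use_szcor: bool = False,
    seed: int = 0,
    feature_kwargs: dict | None = None,
) -> tuple[MetacellPartition, CoClustering, FeatureSet]:
    """Full clustering pass: downsample, select features, graph, bootstrap,
    derive metacells, drop low-quality ones.

    The size-correlation feature filter is off by default here (the
    statistic excludes essentially no gene on depth-normalized data and
    its published semantics are underdetermined); it can be re-enabled
    via ``use_szcor``.
    """
    ds = downsample_cells(matrix, "auto", seed=seed)
    features = select_features(
        matrix, downsampled=ds, use_szcor=use_szcor, seed=seed, **(feature_kwargs or {})
    )
    if len(features) < 2:
        raise ValueError("feature selection returned fewer than 2 genes")
    graph = build_balanced_knn(ds, features, K=K)
    coclust = bootstrap_cocluster(graph, n_iter=n_boot, fraction=fraction, seed=seed)
    partition = derive_metacells(coclust, K_cc=K_cc, alpha=alpha, min_size=min_size, seed=seed)
    partition = filter_low_quality_metacells(partition, matrix)
    return partition, coclust, features
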