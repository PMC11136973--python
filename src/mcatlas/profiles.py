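"""Normalized fold-change expression profiles, marker selection, and
cell-type annotation of clusters.

Expression of a gene in a cluster is summarized as a regularized
geometric mean of its (depth-downsampled) counts, and normalized by the
median of that statistic across clusters; the resulting ratio is the
cluster-level fold change (FC). Markers are the top genes per cluster by
FC; cell-type annotation scores clusters against user-supplied marker
signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import UMICountMatrix
from .metacell import MetacellPartition, downsample_cells

__all__ = [
    "FoldChangeProfile",
    "MarkerTable",
    "CellTypeAnnotation",
    "compute_fc",
    "select_markers",
    "annotate_cell_types",
]


@dataclass
class FoldChangeProfile:
    """Genes x clusters fold-change matrix with its geometric means.

    ``fc`` and ``geomean`` are DataFrames indexed by gene id with one
    column per cluster. ``eps`` is the regularization constant applied to
    both numerator and denominator of the ratio.
    """

    fc: pd.DataFrame
    geomean: pd.DataFrame
    eps: float
    median_mode: str = "lower"

    @property
    def clusters(self) -> list:
        return list(self.fc.columns)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.fc.index.to_numpy()


def _lower_median(values: np.ndarray) -> np.ndarray:
    """Row-wise lower median: element at sorted position ceil(n/2)."""
    s = np.sort(values, axis=1)
    n = values.shape[1]
    return s[:, (n + 1) // 2 - 1]


def compute_fc(
    matrix: UMICountMatrix,
    clusters: MetacellPartition | np.ndarray | Sequence,
    eps: float = 0.1,
    median_mode: str = "lower",
    downsample: bool = True,
    seed: int = 0,
) -> FoldChangeProfile:
    """Regularized geometric-mean fold change per gene per cluster.

    ``geomean(g, m) = exp(mean over cells in m of ln(1 + u_gc)) - 1`` on
    depth-downsampled counts, and
    ``fc(g, m) = (geomean(g, m) + eps) / (median_m' geomean(g, m') + eps)``.

    ``clusters`` is a MetacellPartition or a per-cell label vector
    (labels of None/NaN/-1/"outlier" are excluded). ``median_mode`` is
    ``"lower"`` (the median is an actual cluster's value, so with an odd
    or even number of clusters fc = 1 is attained) or ``"midpoint"``
    (average of central order statistics for an even cluster count).
    """
    if median_mode not in ("lower", "midpoint"):
        raise ValueError("median_mode must be 'lower' or 'midpoint'")
    if eps <= 0:
        raise ValueError("eps must be positive")

    if isinstance(clusters, MetacellPartition):
        labels = np.array(
            [a if a >= 0 else None for a in clusters.assignment], dtype=object
        )
    else:
        labels = np.asarray(clusters, dtype=object)
    if len(labels) != matrix.n_cells:
        raise ValueError("cluster labels do not match number of cells")
    valid = np.array(
        [l is not None and l != "outlier" and l == l and l != -1 for l in labels]
    )
    uniq = sorted(set(labels[valid]), key=str)
    if not uniq:
        raise ValueError("no non-outlier clusters")

    data = downsample_cells(matrix, "auto", seed=seed) if downsample else matrix
    log_counts = data.counts.copy().astype(float)
    log_counts.data = np.log1p(log_counts.data)

    gm = np.empty((matrix.n_genes, len(uniq)))
    kept = []
    for k, cl in enumerate(uniq):
        members = np.nonzero(valid & (labels == cl))[0]
        if len(members) == 0:
            warnings.warn(f"cluster {cl!r} has no cells; excluded")
            continue
        mean_log = np.asarray(log_counts[:, members].mean(axis=1)).ravel()
        gm[:, len(kept)] = np.expm1(mean_log)
        kept.append(cl)
    gm = gm[:, : len(kept)]

    if gm.shape[1] == 1:
        med = gm[:, 0]
    elif median_mode == "lower":
        med = _lower_median(gm)
    else:
        med = np.median(gm, axis=1)
    fc = (gm + eps) / (med[:, None] + eps)

    index = pd.Index(matrix.gene_ids, name="gene_id")
    return FoldChangeProfile(
        fc=pd.DataFrame(fc, index=index, columns=kept),
        geomean=pd.DataFrame(gm, index=index, columns=kept),
        eps=eps,
        median_mode=median_mode,
    )


@dataclass
class MarkerTable:
    """Per-cluster ranked marker genes with fold changes."""

    per_cluster: dict  # cluster -> DataFrame(gene_id, fc) sorted desc
    gene_order: list  # heatmap row order: genes ordered by argmax cluster
    max_per_cluster: int
    min_fc: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cl, df in self.per_cluster.items():
            for rank, rec in enumerate(df.itertuples(index=False), start=1):
                rows.append({"cluster": cl, "rank": rank, "gene_id": rec.gene_id, "fc": rec.fc})
        return pd.DataFrame(rows, columns=["cluster", "rank", "gene_id", "fc"])

    def genes(self, cluster) -> list:
        return self.per_cluster[cluster]["gene_id"].tolist()


def select_markers(
    profile: FoldChangeProfile,
    max_per_cluster: int = 30,
    min_fc: float = 2.0,
) -> MarkerTable:
    """Up to ``max_per_cluster`` genes per cluster with fc >= ``min_fc``.

    Genes are ranked by descending fold change within each cluster
    (ties by gene id). The global display order follows each selected
    gene's argmax cluster, matching the heatmap convention of ordering
    rows by the cluster of highest fold change.
    """
    per_cluster: dict = {}
    chosen: set = set()
    for cl in profile.clusters:
        col = profile.fc[cl]
        hits = col[col >= min_fc].sort_values(ascending=False, kind="stable")
        hits = hits.iloc[:max_per_cluster]
        per_cluster[cl] = pd.DataFrame({"gene_id": hits.index.to_numpy(), "fc": hits.to_numpy()})
        chosen.update(hits.index)

    if chosen:
        sub = profile.fc.loc[sorted(chosen, key=str)]
        argmax = sub.to_numpy().argmax(axis=1)
        order = np.lexsort((np.arange(len(sub)), argmax))
        gene_order = sub.index.to_numpy()[order].tolist()
    else:
        gene_order = []
    return MarkerTable(per_cluster, gene_order, max_per_cluster, min_fc)


@dataclass
class CellTypeAnnotation:
    """Cluster -> cell-type assignment from marker signature scores."""

    table: pd.DataFrame  # cluster, cell_type, score, tie
    scores: pd.DataFrame  # clusters x types mean log2 fc
    signatures: dict = field(default_factory=dict)


def annotate_cell_types(
    profile: FoldChangeProfile,
    signatures: Mapping[str, Sequence[str]],
    floor: float = 0.0,
) -> CellTypeAnnotation:
    """Assign each cluster the signature type with highest mean log2 FC.

    ``score(m, t)`` is the mean of log2 fc over type t's signature genes
    (genes missing from the profile are warned about and skipped). A
    cluster is unassigned when its best score is below ``floor``; exact
    ties go to the lexicographically first type label and are flagged.
    """
    if not signatures or any(len(g) == 0 for g in signatures.values()):
        raise ValueError("signatures must be non-empty gene sets")
    types = sorted(signatures)
    log_fc = np.log2(profile.fc)
    scores = pd.DataFrame(index=pd.Index(profile.clusters, name="cluster"), columns=types, dtype=float)
    used: dict[str, list[str]] = {}
    for t in types:
        present = [g for g in signatures[t] if g in log_fc.index]
        missing = set(signatures[t]) - set(present)
        if missing:
            warnings.warn(f"signature {t!r}: {len(missing)} gene(s) absent from profile")
        if not present:
            raise ValueError(f"signature {t!r} has no genes present in the profile")
        used[t] = present
        scores[t] = log_fc.loc[present].mean(axis=0).to_numpy()

    rows = []
    for cl in profile.clusters:
        s = scores.loc[cl]
        best = float(s.max())
        winners = [t for t in types if s[t] == best]
        assigned = winners[0] if best >= floor else None
        rows.append(
            {"cluster": cl, "cell_type": assigned, "score": best, "tie": len(winners) > 1}
        )
    return CellTypeAnnotation(pd.DataFrame(rows), scores, dict(used))
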