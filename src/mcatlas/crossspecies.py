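"""Cross-species cell-type comparison through orthology groups.

Per-species marker statistics come from one-sided Wilcoxon rank-sum
tests (cells of a type vs all others) with Benjamini-Hochberg
adjustment per type; cell types are linked across species by listing
orthology groups whose members pass the fold-change and significance
thresholds in both species, and by Pearson correlation of cell-type
fold-change profiles over orthology-linked genes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .matrix import UMICountMatrix
from .profiles import FoldChangeProfile

__all__ = [
    "OrthologyMap",
    "MarkerStats",
    "SharedMarkerGraph",
    "CellTypeCorrelation",
    "rank_markers",
    "shared_features",
    "celltype_correlation",
    "wilcoxon_rank_sum",
]


@dataclass
class OrthologyMap:
    """Orthology groups: group id -> {species -> gene id set}."""

    groups: dict[str, dict[str, set]]
    tf_flags: set = field(default_factory=set)

    @classmethod
    def from_table(cls, table: pd.DataFrame, tf_flags: Sequence[str] = ()) -> "OrthologyMap":
        seen: dict[str, str] = {}
        groups: dict[str, dict[str, set]] = {}
        for rec in table.itertuples(index=False):
            if rec.gene_id in seen and seen[rec.gene_id] != rec.group_id:
                raise ValueError(f"gene {rec.gene_id} appears in more than one group")
            seen[rec.gene_id] = rec.group_id
            groups.setdefault(rec.group_id, {}).setdefault(rec.species, set()).add(rec.gene_id)
        return cls(groups, set(tf_flags))

    def genes(self, group_id: str, species: str) -> set:
        return self.groups.get(group_id, {}).get(species, set())

    def gene_to_group(self, species: str) -> dict[str, str]:
        return {
            g: gid for gid, sp in self.groups.items() for g in sp.get(species, set())
        }


@dataclass
class MarkerStats:
    """Per (gene, cell type) fold change and overexpression significance."""

    table: pd.DataFrame  # gene_id, cell_type, fc, p_value, p_adj
    eps: float
    small_types: list = field(default_factory=list)

    def passing(self, fc_min: float, p_max: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[(t.fc >= fc_min) & (t.p_adj < p_max)]


@dataclass
class SharedMarkerGraph:
    """Edges between cell types of two species with shared orthogroups."""

    edges: pd.DataFrame  # type_a, type_b, group_id, genes_a, genes_b
    thresholds: dict = field(default_factory=dict)

    def edge_list(self) -> pd.DataFrame:
        return (
            self.edges.groupby(["type_a", "type_b"])["group_id"]
            .apply(sorted)
            .reset_index()
            .rename(columns={"group_id": "shared_groups"})
        )


@dataclass
class CellTypeCorrelation:
    """A-types x B-types Pearson matrix plus row-wise best matches."""

    matrix: pd.DataFrame
    best_match: pd.Series
    n_genes: pd.DataFrame  # usable orthogroup count per pair
    fc_floor: float


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "greater",
    exact_max_n: int = 10,
) -> float:
    """One-sided rank-sum p-value that ``x`` is shifted relative to ``y``.

    Uses exact enumeration of rank assignments when both groups have at
    most ``exact_max_n`` observations and values are tie-free, and the
    tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        return 1.0
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = ranks[:n1].sum()  # rank sum of x

    ties = len(np.unique(pooled)) < n1 + n2
    if n1 <= exact_max_n and n2 <= exact_max_n and not ties:
        # Exact: enumerate all C(n1+n2, n1) placements of x's ranks.
        total = comb(n1 + n2, n1)
        if alternative == "greater":
            extreme = sum(
                1 for c in itertools.combinations(range(1, n1 + n2 + 1), n1) if sum(c) >= w
            )
        elif alternative == "less":
            extreme = sum(
                1 for c in itertools.combinations(range(1, n1 + n2 + 1), n1) if sum(c) <= w
            )
        else:
            raise ValueError("alternative must be 'greater' or 'less'")
        return extreme / total

    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / ((n) * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    from scipy.stats import norm

    if alternative == "greater":
        z = (w - mean - 0.5) / np.sqrt(var)
        return float(norm.sf(z))
    z = (w - mean + 0.5) / np.sqrt(var)
    return float(norm.cdf(z))


def rank_markers(
    matrix: UMICountMatrix,
    labels: Sequence,
    eps: float = 0.1,
    scale: float = 1e4,
    exact_max_n: int = 10,
) -> MarkerStats:
    """Per-type marker statistics: fold change and rank-sum significance.

    Expression is normalized per cell to ``scale`` total (counts per
    10,000 by default). For each gene and type, the one-sided rank-sum
    test asks whether the type's cells overexpress the gene relative to
    all other cells, and FC = (mean in type + eps) / (mean in rest +
    eps). BH adjustment runs across genes within each type. Types with
    fewer than 3 cells are flagged but still tested.
    """
    labels = np.asarray(labels, dtype=object)
    types = sorted(set(labels), key=str)
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    totals = matrix.cell_totals().astype(float)
    totals[totals == 0] = 1.0
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    norm_expr = dense / totals[None, :] * scale

    small = [t for t in types if (labels == t).sum() < 3]
    if small:
        warnings.warn(f"cell types with < 3 cells: {small}")

    rows = []
    for t in types:
        in_t = labels == t
        x = norm_expr[:, in_t]
        y = norm_expr[:, ~in_t]
        mean_t = x.mean(axis=1)
        mean_rest = y.mean(axis=1)
        fc = (mean_t + eps) / (mean_rest + eps)

        n1, n2 = x.shape[1], y.shape[1]
        if n1 <= exact_max_n and n2 <= exact_max_n:
            pvals = np.array(
                [wilcoxon_rank_sum(x[g], y[g], "greater", exact_max_n) for g in range(len(fc))]
            )
        else:
            # Vectorized tie-corrected normal approximation across genes.
            ranks = rankdata(norm_expr, axis=1)
            w = ranks[:, in_t].sum(axis=1)
            n = n1 + n2
            mean = n1 * (n + 1) / 2.0
            tie_term = np.empty(len(fc))
            for g in range(len(fc)):
                _, counts = np.unique(norm_expr[g], return_counts=True)
                tie_term[g] = (counts**3 - counts).sum() / (n * (n - 1))
            var = n1 * n2 / 12.0 * (n + 1 - tie_term)
            from scipy.stats import norm as normal

            with np.errstate(invalid="ignore", divide="ignore"):
                z = (w - mean - 0.5) / np.sqrt(var)
            pvals = np.where(var > 0, normal.sf(z), 1.0)
        padj = multipletests(pvals, method="fdr_bh")[1]
        for g in range(len(fc)):
            rows.append(
                {"gene_id": matrix.gene_ids[g], "cell_type": t, "fc": float(fc[g]),
                 "p_value": float(pvals[g]), "p_adj": float(padj[g])}
            )
    return MarkerStats(
        pd.DataFrame(rows, columns=["gene_id", "cell_type", "fc", "p_value", "p_adj"]),
        eps, small,
    )


# ---------------------------------------------------------------------------
# Shared features
# ---------------------------------------------------------------------------

def shared_features(
    a: MarkerStats,
    b: MarkerStats,
    orthology: OrthologyMap,
    fc_min: float = 1.0,
    p_max: float = 0.05,
    tf_only: bool = False,
    species_a: str = "A",
    species_b: str = "B",
) -> SharedMarkerGraph:
    """Orthogroups significantly overexpressed in a cell type of each species.

    For each (type_a, type_b) pair, lists orthology groups with at least
    one gene passing (p_adj < ``p_max``, FC >= ``fc_min``) in type_a of
    species A and one in type_b of species B. ``tf_only`` restricts to
    genes carrying the TF flag.
    """
    if not orthology.groups:
        warnings.warn("empty orthology map; no shared features")
        return SharedMarkerGraph(
            pd.DataFrame(columns=["type_a", "type_b", "group_id", "genes_a", "genes_b"]),
            {"fc_min": fc_min, "p_max": p_max, "tf_only": tf_only},
        )
    g2g_a = orthology.gene_to_group(species_a)
    g2g_b = orthology.gene_to_group(species_b)

    def passing_by_type(stats: MarkerStats, g2g: dict) -> dict:
        out: dict[str, dict[str, list]] = {}
        hits = stats.passing(fc_min, p_max)
        for rec in hits.itertuples(index=False):
            if tf_only and rec.gene_id not in orthology.tf_flags:
                continue
            gid = g2g.get(rec.gene_id)
            if gid is None:
                continue
            out.setdefault(rec.cell_type, {}).setdefault(gid, []).append(rec.gene_id)
        return out

    pass_a = passing_by_type(a, g2g_a)
    pass_b = passing_by_type(b, g2g_b)
    rows = []
    for ta, groups_a in sorted(pass_a.items()):
        for tb, groups_b in sorted(pass_b.items()):
            for gid in sorted(set(groups_a) & set(groups_b)):
                rows.append(
                    {"type_a": ta, "type_b": tb, "group_id": gid,
                     "genes_a": sorted(groups_a[gid]), "genes_b": sorted(groups_b[gid])}
                )
    return SharedMarkerGraph(
        pd.DataFrame(rows, columns=["type_a", "type_b", "group_id", "genes_a", "genes_b"]),
        {"fc_min": fc_min, "p_max": p_max, "tf_only": tf_only},
    )


# ---------------------------------------------------------------------------
# Cell-type correlation
# ---------------------------------------------------------------------------

def celltype_correlation(
    fc_a: FoldChangeProfile | pd.DataFrame,
    fc_b: FoldChangeProfile | pd.DataFrame,
    orthology: OrthologyMap,
    fc_floor: float = 1.05,
    min_genes: int = 3,
    species_a: str = "A",
    species_b: str = "B",
) -> CellTypeCorrelation:
    """Pearson correlation of cell-type fold-change profiles across species.

    Orthology groups are collapsed to one meta-gene per species (mean FC
    over member genes, avoiding double-counting of expanded families).
    Groups enter the computation when their FC exceeds ``fc_floor`` in at
    least one cell type of either species. Pairs with fewer than
    ``min_genes`` usable groups get a missing coefficient. The best match
    per A type is the row-wise argmax.
    """
    A = fc_a.fc if isinstance(fc_a, FoldChangeProfile) else fc_a
    B = fc_b.fc if isinstance(fc_b, FoldChangeProfile) else fc_b
    g2g_a = orthology.gene_to_group(species_a)
    g2g_b = orthology.gene_to_group(species_b)

    def collapse(fc: pd.DataFrame, g2g: dict) -> pd.DataFrame:
        keep = fc.loc[[g for g in fc.index if g in g2g]]
        if keep.empty:
            return pd.DataFrame(columns=fc.columns)
        groups = [g2g[g] for g in keep.index]
        return keep.groupby(groups).mean()

    meta_a = collapse(A, g2g_a)
    meta_b = collapse(B, g2g_b)
    common = meta_a.index.intersection(meta_b.index)
    meta_a, meta_b = meta_a.loc[common], meta_b.loc[common]

    informative = (meta_a > fc_floor).any(axis=1) | (meta_b > fc_floor).any(axis=1)
    ma, mb = meta_a[informative], meta_b[informative]

    corr = pd.DataFrame(index=A.columns, columns=B.columns, dtype=float)
    n_used = pd.DataFrame(0, index=A.columns, columns=B.columns)
    n = int(informative.sum())
    n_used.loc[:, :] = n
    if n >= min_genes:
        va = ma.to_numpy()
        vb = mb.to_numpy()
        va = va - va.mean(axis=0, keepdims=True)
        vb = vb - vb.mean(axis=0, keepdims=True)
        sa = np.sqrt((va**2).sum(axis=0))
        sb = np.sqrt((vb**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            c = (va.T @ vb) / np.outer(sa, sb)
        corr.loc[:, :] = c
    vals = corr.to_numpy(dtype=float)
    best = pd.Series(
        [corr.columns[int(np.nanargmax(row))] if not np.all(np.isnan(row)) else None
         for row in vals],
        index=corr.index,
    )
    return CellTypeCorrelation(corr, best, n_used, fc_floor)
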