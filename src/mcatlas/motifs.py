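"""Motif library curation, sequence scanning, and enrichment testing.

A motif is a position probability matrix (PPM) over A,C,G,T. The
curation path filters motifs on contiguous information content (IC),
clusters near-identical motifs by weighted-Pearson PPM similarity
(reverse-complement aware, average linkage, 0.95 threshold, minimum
alignment overlap 6 bp), and keeps the highest-IC representative per
cluster. Scanning scores sequences with log2-odds against a uniform
background (probability floor 1e-3) on both strands, calling hits above
80% of each motif's maximum achievable score. Enrichment of cell-type
region sets is assessed per GC bin against GC/length-matched background
regions with a one-sided binomial test and Benjamini-Hochberg
adjustment; per-region empirical hit p-values come from score ranks
within GC-matched backgrounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .synth import SyntheticGenome

__all__ = [
    "MotifPPM",
    "MotifLibrary",
    "MotifHit",
    "column_ic",
    "contiguous_ic_filter",
    "motif_similarity",
    "dedupe_library",
    "scan_regions",
    "sample_matched_background",
    "binned_enrichment",
    "empirical_hit_pvalue",
    "gc_bin_edges",
    "gc_content",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MotifPPM:
    """Position probability matrix: width x 4 probabilities over A,C,G,T."""

    id: str
    matrix: np.ndarray
    source: str = "known"  # "de_novo" | "known"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError(f"motif {self.id}: matrix must be width x 4")
        if (self.matrix < 0).any():
            raise ValueError(f"motif {self.id}: negative probabilities")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"motif {self.id}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "MotifPPM":
        return MotifPPM(self.id, self.matrix[::-1, ::-1], self.source)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def total_ic(self) -> float:
        return float(column_ic(self).sum())


@dataclass
class MotifLibrary:
    """A set of PPMs with IC annotations and (post-dedupe) cluster map."""

    motifs: list[MotifPPM]
    clusters: dict[str, list[str]] = field(default_factory=dict)  # representative -> members

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def ids(self) -> list[str]:
        return [m.id for m in self.motifs]

    def get(self, motif_id: str) -> MotifPPM:
        for m in self.motifs:
            if m.id == motif_id:
                return m
        raise KeyError(motif_id)

    def ic_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"motif_id": self.ids(),
             "width": [m.width for m in self.motifs],
             "total_ic": [m.total_ic() for m in self.motifs]}
        )


# ---------------------------------------------------------------------------
# Information content
# ---------------------------------------------------------------------------

def column_ic(ppm: MotifPPM) -> np.ndarray:
    """Per-column information content in bits vs uniform background.

    ``IC_j = 2 + sum_b p_jb log2 p_jb`` with 0*log(0) = 0; in [0, 2].
    """
    p = ppm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + terms.sum(axis=1)


def _ic_runs(ic: np.ndarray, ic_min: float) -> list[int]:
    """Lengths of maximal runs of columns with IC >= ic_min."""
    runs, cur = [], 0
    for v in ic:
        if v >= ic_min:
            cur += 1
        elif cur:
            runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return runs


def contiguous_ic_filter(
    library: MotifLibrary | Sequence[MotifPPM],
    ic_min: float = 0.5,
    run_len: int = 4,
    block_len: int = 3,
    n_blocks: int = 2,
) -> MotifLibrary:
    """Keep motifs with high contiguous information content.

    A motif is retained when it has at least one run of ``run_len``
    consecutive columns at IC >= ``ic_min``, or at least ``n_blocks``
    disjoint runs each of at least ``block_len`` such columns.
    """
    motifs = list(library)
    kept = []
    for m in motifs:
        runs = _ic_runs(column_ic(m), ic_min)
        if any(r >= run_len for r in runs) or sum(r >= block_len for r in runs) >= n_blocks:
            kept.append(m)
    return MotifLibrary(kept)


# ---------------------------------------------------------------------------
# Similarity and redundancy reduction
# ---------------------------------------------------------------------------

def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    if wsum <= 0:
        return 0.0
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def motif_similarity(a: MotifPPM, b: MotifPPM, min_overlap: int = 6) -> float:
    """Best weighted-Pearson correlation of two PPMs over alignments.

    Maximized over all relative offsets with overlap >= ``min_overlap``
    and over b's reverse complement. Aligned probability columns are
    flattened; each column pair is weighted by the mean IC of the two
    columns. Returns -1 when no alignment reaches the minimum overlap
    (such pairs are never merged).
    """
    best = -1.0
    ic_a = column_ic(a)
    for cand in (b, b.reverse_complement()):
        ic_b = column_ic(cand)
        wa, wb = a.width, cand.width
        for off in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a = max(0, off)
            hi_a = min(wa, off + wb)
            if hi_a - lo_a < min_overlap:
                continue
            cols_a = a.matrix[lo_a:hi_a]
            cols_b = cand.matrix[lo_a - off : hi_a - off]
            w_cols = 0.5 * (ic_a[lo_a:hi_a] + ic_b[lo_a - off : hi_a - off])
            w = np.repeat(w_cols, 4)
            sim = _weighted_pearson(cols_a.ravel(), cols_b.ravel(), w)
            best = max(best, sim)
    return best


def dedupe_library(
    library: MotifLibrary | Sequence[MotifPPM],
    threshold: float = 0.95,
    min_overlap: int = 6,
) -> MotifLibrary:
    """Collapse redundant motifs by average-linkage similarity clustering.

    Motifs are clustered on distance 1 - similarity; clusters are cut so
    that merged groups have average similarity >= ``threshold``. The
    member with the highest total IC represents each cluster (ties by
    lexicographic id). Cluster membership is reported on the result.
    """
    motifs = list(library)
    if len(motifs) <= 1:
        return MotifLibrary(list(motifs), {m.id: [m.id] for m in motifs})
    n = len(motifs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - motif_similarity(motifs[i], motifs[j], min_overlap)
            dist[i, j] = dist[j, i] = d
    linkage = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    labels = sch.fcluster(linkage, t=1.0 - threshold, criterion="distance")

    kept: list[MotifPPM] = []
    clusters: dict[str, list[str]] = {}
    for lab in np.unique(labels):
        members = [motifs[i] for i in np.nonzero(labels == lab)[0]]
        best_ic = max(m.total_ic() for m in members)
        rep = sorted([m for m in members if m.total_ic() == best_ic], key=lambda m: m.id)[0]
        kept.append(rep)
        clusters[rep.id] = sorted(m.id for m in members)
    kept.sort(key=lambda m: m.id)
    return MotifLibrary(kept, clusters)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass
class MotifHit:
    region_id: str
    motif_id: str
    offset: int
    strand: str
    score: float
    score_fraction: float
    empirical_p: float | None = None


def _encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(seq), 4, dtype=np.int8)  # 4 = N / unknown
    for b, i in _BASE_INDEX.items():
        out[raw == ord(b)] = i
    return out


def _logodds(ppm: MotifPPM, floor: float = 1e-3) -> np.ndarray:
    """log2-odds matrix vs uniform background, with an N penalty column."""
    p = np.maximum(ppm.matrix, floor)
    lo = np.log2(p / 0.25)
    return np.hstack([lo, np.full((ppm.width, 1), -1e9)])  # column 4 = N


def _best_scores(seq_idx: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Scores of all windows of width lo.shape[0] (empty if too short)."""
    w = lo.shape[0]
    n = len(seq_idx) - w + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(seq_idx, w)
    return lo[np.arange(w), windows].sum(axis=1)


def scan_regions(
    regions: Mapping[str, str],
    library: MotifLibrary | Sequence[MotifPPM],
    score_fraction_min: float = 0.8,
    best_only: bool = False,
    floor: float = 1e-3,
) -> list[MotifHit]:
    """Scan sequences for motif occurrences on both strands.

    The score of a window is the sum of log2-odds of the PPM (probability
    floor ``floor``) against a uniform background; windows containing N
    never score. Hits require score > ``score_fraction_min`` times the
    motif's maximum achievable score. With ``best_only`` a single best
    hit per region per motif is kept (ties: leftmost, then + strand).
    """
    motifs = list(library)
    hits: list[MotifHit] = []
    encoded = {rid: _encode(seq) for rid, seq in regions.items()}
    for m in motifs:
        lo = _logodds(m, floor)
        max_score = float(lo[:, :4].max(axis=1).sum())
        if max_score <= 0:
            warnings.warn(f"motif {m.id}: non-positive max score; skipped")
            continue
        lo_rc = lo[::-1][:, [3, 2, 1, 0, 4]]
        for rid, idx in encoded.items():
            fwd = _best_scores(idx, lo)
            rev = _best_scores(idx, lo_rc)
            region_hits: list[MotifHit] = []
            for strand, scores in (("+", fwd), ("-", rev)):
                above = np.nonzero(scores > score_fraction_min * max_score)[0]
                for pos in above:
                    region_hits.append(
                        MotifHit(rid, m.id, int(pos), strand,
                                 float(scores[pos]), float(scores[pos] / max_score))
                    )
            if best_only and region_hits:
                region_hits = [
                    max(region_hits, key=lambda h: (h.score, -h.offset, h.strand == "+"))
                ]
            hits.extend(region_hits)
    return hits


# ---------------------------------------------------------------------------
# GC-matched backgrounds
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    return (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0


def gc_bin_edges(gc_values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile edges splitting regions into equal-size GC bins."""
    qs = np.linspace(0, 1, n_bins + 1)
    return np.quantile(np.asarray(gc_values, dtype=float), qs)


def assign_gc_bins(gc_values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    bins = np.searchsorted(edges, gc_values, side="right") - 1
    return np.clip(bins, 0, len(edges) - 2)


def sample_matched_background(
    foreground: Mapping[str, tuple[str, int, int]],
    genome: SyntheticGenome | Mapping[str, str],
    multiple: int = 2,
    n_gc_bins: int = 10,
    seed: int = 0,
    max_tries: int = 200,
) -> dict[str, tuple[str, int, int]]:
    """Sample GC/length-matched background regions from the genome.

    ``foreground`` maps region id -> (chrom, start, end). Foreground
    regions are split into ``n_gc_bins`` equal-size GC bins; per bin,
    ``multiple`` times as many genomic regions of equal length are drawn
    whose GC falls in the bin's range, excluding any overlap with
    foreground regions or previously drawn backgrounds. If a bin is
    unsatisfiable after bounded retries its GC range is relaxed stepwise
    with a warning. Deterministic given ``seed``.
    """
    chroms = genome.chromosomes if isinstance(genome, SyntheticGenome) else dict(genome)
    rng = substream(seed, "matched-background")
    fg_items = sorted(foreground.items())
    if not fg_items:
        return {}
    fg_gc = np.array([gc_content(chroms[c][s:e]) for _, (c, s, e) in fg_items])
    lengths = np.array([e - s for _, (c, s, e) in fg_items])
    n_bins = min(n_gc_bins, len(fg_items))
    edges = gc_bin_edges(fg_gc, n_bins)
    bins = assign_gc_bins(fg_gc, edges)

    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for _, (c, s, e) in fg_items:
        taken[c].append((s, e))

    def overlaps(c: str, s: int, e: int) -> bool:
        return any(s < e2 and s2 < e for s2, e2 in taken[c])

    chrom_names = sorted(chroms)
    chrom_lens = {c: len(chroms[c]) for c in chrom_names}
    background: dict[str, tuple[str, int, int]] = {}
    k = 0
    for b in range(n_bins):
        members = np.nonzero(bins == b)[0]
        if len(members) == 0:
            continue
        want = multiple * len(members)
        length = int(np.round(lengths[members].mean()))
        lo, hi = edges[b], edges[b + 1]
        got = 0
        relax = 0.0
        tries = 0
        while got < want:
            tries += 1
            if tries > max_tries * want:
                relax += 0.02
                tries = 0
                warnings.warn(
                    f"GC bin {b}: relaxing GC range by ±{relax:.2f} to find backgrounds"
                )
                if relax > 0.5:
                    raise RuntimeError(f"GC bin {b}: cannot sample matched backgrounds")
            c = chrom_names[rng.integers(len(chrom_names))]
            if chrom_lens[c] <= length:
                continue
            s = int(rng.integers(0, chrom_lens[c] - length))
            e = s + length
            if overlaps(c, s, e):
                continue
            gc = gc_content(chroms[c][s:e])
            if lo - relax <= gc <= hi + relax:
                background[f"bg{k:05d}"] = (c, s, e)
                taken[c].append((s, e))
                k += 1
                got += 1
    return background


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def binned_enrichment(
    fg_sets: Mapping[tuple[str, str], Sequence[str]],
    bg_regions: Sequence[str],
    hits: Sequence[MotifHit],
    motif_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binomial motif enrichment of foreground sets vs background regions.

    ``fg_sets`` maps (cell type, bin label) -> foreground region ids;
    ``bg_regions`` are the matched background region ids; ``hits`` are
    scan results covering both (same threshold). Per (cell type, bin,
    motif): k = foreground regions with >= 1 hit out of n;
    p0 = (background regions with a hit + 0.5) / (n_bg + 1); one-sided
    binomial tail P(X >= k); log2FC = log2(((k+0.5)/(n+1)) / p0).
    Benjamini-Hochberg adjustment runs across motifs within each
    (cell type, bin).
    """
    if motif_ids is None:
        motif_ids = sorted({h.motif_id for h in hits})
    hit_regions: dict[str, set[str]] = {m: set() for m in motif_ids}
    for h in hits:
        if h.motif_id in hit_regions:
            hit_regions[h.motif_id].add(h.region_id)
    bg_set = set(bg_regions)
    n_bg = len(bg_set)

    rows = []
    for (cell_type, bin_label), regions in sorted(fg_sets.items()):
        regions = list(regions)
        n = len(regions)
        if n == 0:
            warnings.warn(f"({cell_type}, {bin_label}): empty foreground; skipped")
            continue
        pvals = []
        recs = []
        for m in motif_ids:
            k = sum(1 for r in regions if r in hit_regions[m])
            bg_k = len(hit_regions[m] & bg_set)
            p0 = (bg_k + 0.5) / (n_bg + 1)
            p = float(binom.sf(k - 1, n, p0))
            log2fc = float(np.log2(((k + 0.5) / (n + 1)) / p0))
            pvals.append(p)
            recs.append(
                {"cell_type": cell_type, "bin": bin_label, "motif_id": m,
                 "k": k, "n": n, "bg_k": bg_k, "n_bg": n_bg, "p0": p0,
                 "log2fc": log2fc, "p_value": p}
            )
        adj = multipletests(pvals, method="fdr_bh")[1]
        for rec, a in zip(recs, adj):
            rec["p_adj"] = float(a)
            rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=["cell_type", "bin", "motif_id", "k", "n", "bg_k", "n_bg",
                 "p0", "log2fc", "p_value", "p_adj"],
    )


def empirical_hit_pvalue(
    best_scores: Mapping[str, float],
    background_best_scores: Mapping[str, float],
    fg_gc: Mapping[str, float],
    bg_gc: Mapping[str, float],
    n_gc_bins: int = 10,
) -> pd.DataFrame:
    """Rank-based empirical p-value of each region's best motif score.

    Foreground regions are split into ``n_gc_bins`` equal-size GC bins;
    backgrounds are binned on the same edges. Within a region's bin,
    ``p = (1 + #background best scores >= observed) / (1 + n_background)``.
    Regions whose bin has no background get p = NaN with an undefined
    flag.
    """
    fg_ids = sorted(best_scores)
    gc = np.array([fg_gc[r] for r in fg_ids])
    n_bins = min(n_gc_bins, len(fg_ids))
    edges = gc_bin_edges(gc, n_bins)
    fg_bins = assign_gc_bins(gc, edges)
    bg_ids = sorted(background_best_scores)
    bg_bins = assign_gc_bins(np.array([bg_gc[r] for r in bg_ids]), edges)
    bg_scores_by_bin: dict[int, np.ndarray] = {
        b: np.sort(np.array([background_best_scores[bg_ids[i]]
                             for i in np.nonzero(bg_bins == b)[0]]))
        for b in range(n_bins)
    }
    rows = []
    for i, rid in enumerate(fg_ids):
        b = int(fg_bins[i])
        bg = bg_scores_by_bin.get(b, np.empty(0))
        if len(bg) == 0:
            rows.append({"region_id": rid, "gc_bin": b, "empirical_p": np.nan,
                         "undefined": True})
            continue
        n_ge = len(bg) - np.searchsorted(bg, best_scores[rid], side="left")
        p = (1 + n_ge) / (1 + len(bg))
        rows.append({"region_id": rid, "gc_bin": b, "empirical_p": float(p),
                     "undefined": False})
    return pd.DataFrame(rows, columns=["region_id", "gc_bin", "empirical_p", "undefined"])
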