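"""ATAC peak standardization, promoter definition, and rule-based
peak-to-gene assignment.

Peaks (MACS2 narrowPeak) are filtered on q-value support, standardized
to a fixed length around their summit (250 bp by default), reduced to a
non-overlapping set, and linked to genes by summit-to-TSS distance:
a peak overlapping a promoter window is assigned exclusively to that
gene; otherwise it links to every gene within 20 kbp of its summit
whose TSS is not screened by a more proximal gene's TSS on the same
side. Cell-type-specific region sets are then derived from expression
fold changes of the linked genes.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as mio
from .profiles import FoldChangeProfile

__all__ = [
    "PeakSet",
    "PromoterSet",
    "PeakGeneAssignment",
    "CellTypePeakSets",
    "load_and_filter_peaks",
    "standardize_peaks",
    "reduce_overlaps",
    "define_promoters",
    "assign_peaks",
    "celltype_peak_sets",
]


@dataclass
class PeakSet:
    """Peak records (narrowPeak columns; summit is an offset from start)."""

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = self.records
        if len(r):
            if (r.start >= r.end).any():
                raise ValueError("peak with start >= end")
            if ((r.summit < 0) | (r.summit >= r.end - r.start)).any():
                raise ValueError("summit outside [start, end)")
            if (r.q_value < 0).any():
                raise ValueError("negative -log10 q-value")

    def __len__(self) -> int:
        return len(self.records)

    def summit_abs(self) -> np.ndarray:
        return (self.records.start + self.records.summit).to_numpy()

    def to_bed6(self) -> pd.DataFrame:
        r = self.records
        return pd.DataFrame(
            {"chrom": r.chrom, "start": r.start, "end": r.end,
             "name": r.name if "name" in r else "", "score": r.score, "strand": "."}
        )

    def write_narrowpeak(self, path: str) -> None:
        mio.write_narrowpeak(self.records, path)


@dataclass
class PromoterSet:
    """Strand-aware promoter intervals per gene (plus any external ones)."""

    intervals: pd.DataFrame  # gene_id, chrom, start, end, source

    def for_gene(self, gene_id: str) -> pd.DataFrame:
        return self.intervals[self.intervals.gene_id == gene_id]


@dataclass
class PeakGeneAssignment:
    """Peak -> gene links with signed summit-to-TSS distance."""

    links: pd.DataFrame  # peak_id, gene_id, distance, is_promoter, ambiguous
    max_distance: int

    def peaks_per_gene(self) -> pd.Series:
        return self.links.groupby("gene_id").size()

    def genes_of(self, peak_id: str) -> list[str]:
        return self.links.loc[self.links.peak_id == peak_id, "gene_id"].tolist()


@dataclass
class CellTypePeakSets:
    """High / mild / background region sets per cell type (disjoint)."""

    high: dict[str, list[str]]
    mild: dict[str, list[str]]
    background: dict[str, list[str]]
    thresholds: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------

def load_and_filter_peaks(path: str, min_neglog10_q: float = 6.0) -> PeakSet:
    """Read a narrowPeak file, keeping well-supported records.

    Records with -log10(q) below ``min_neglog10_q`` are dropped;
    malformed lines are rejected and reported (with line numbers) via a
    warning.
    """
    records, bad = mio.read_narrowpeak(path)
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:10])
        warnings.warn(f"rejected {len(bad)} malformed narrowPeak line(s): {detail}")
    if (records["summit"] < 0).any():
        raise ValueError("narrowPeak summit column missing or negative")
    kept = records[records.q_value >= min_neglog10_q].reset_index(drop=True)
    if len(kept) == 0:
        warnings.warn(f"no peaks pass -log10(q) >= {min_neglog10_q} in {path}")
    return PeakSet(kept, {"path": path, "min_neglog10_q": min_neglog10_q})


def standardize_peaks(
    peaks: PeakSet,
    half_width: int = 125,
    chrom_sizes: dict[str, int] | None = None,
) -> PeakSet:
    """Standardize each peak to ``[summit - hw, summit + hw)``.

    Intervals are truncated at chromosome bounds (flagged in a
    ``truncated`` column); records whose summit falls outside the
    original interval are rejected with a warning.
    """
    r = peaks.records
    rows = []
    for rec in r.itertuples(index=False):
        summit = rec.start + rec.summit
        if not (rec.start <= summit < rec.end):
            warnings.warn(f"peak {rec.name}: summit outside interval; rejected")
            continue
        start = summit - half_width
        end = summit + half_width
        truncated = False
        if start < 0:
            start, truncated = 0, True
        if chrom_sizes is not None and end > chrom_sizes.get(rec.chrom, np.inf):
            end, truncated = chrom_sizes[rec.chrom], True
        rows.append(
            {"chrom": rec.chrom, "start": start, "end": end, "name": rec.name,
             "score": rec.score, "strand": rec.strand, "signal": rec.signal,
             "p_value": rec.p_value, "q_value": rec.q_value,
             "summit": summit - start, "truncated": truncated}
        )
    out = pd.DataFrame(rows, columns=mio.NARROWPEAK_COLUMNS + ["truncated"])
    prov = dict(peaks.provenance)
    prov["half_width"] = half_width
    return PeakSet(out, prov)


def reduce_overlaps(peaks: PeakSet) -> PeakSet:
    """Merge overlapping records into a non-overlapping set.

    A chain of mutually overlapping records becomes one record spanning
    their union; the merged record keeps the summit (and statistics) of
    the member with the highest -log10(q).
    """
    r = peaks.records
    if len(r) == 0:
        return PeakSet(r.copy(), dict(peaks.provenance))
    r = r.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    rows = []
    cur = None  # [chrom, start, end, best_row]
    for rec in r.itertuples(index=False):
        if cur is not None and rec.chrom == cur[0] and rec.start < cur[2]:
            cur[2] = max(cur[2], rec.end)
            if rec.q_value > cur[3].q_value:
                cur[3] = rec
        else:
            if cur is not None:
                rows.append(cur)
            cur = [rec.chrom, rec.start, rec.end, rec]
    rows.append(cur)
    out = []
    for chrom, start, end, best in rows:
        out.append(
            {"chrom": chrom, "start": start, "end": end, "name": best.name,
             "score": best.score, "strand": best.strand, "signal": best.signal,
             "p_value": best.p_value, "q_value": best.q_value,
             "summit": best.start + best.summit - start}
        )
    return PeakSet(pd.DataFrame(out, columns=mio.NARROWPEAK_COLUMNS), dict(peaks.provenance))


def define_promoters(
    genes: pd.DataFrame,
    upstream: int = 50,
    downstream: int = 200,
    external: PeakSet | None = None,
    swap_orientation: bool = False,
) -> PromoterSet:
    """Strand-aware promoter windows around each TSS.

    On the + strand the window is ``[TSS - upstream, TSS + downstream)``
    (mirrored on -). ``swap_orientation`` flips the two distances, i.e.
    reads the window as downstream/upstream instead. External intervals
    (e.g. H3K4me3 peaks) overlapping a gene's window are unioned in and
    attributed to that gene. Genes without a known strand are treated as
    + with a warning.
    """
    up, down = (downstream, upstream) if swap_orientation else (upstream, downstream)
    rows = []
    for rec in genes.itertuples(index=False):
        strand = rec.strand
        if strand not in ("+", "-"):
            warnings.warn(f"gene {rec.gene_id}: unknown strand, treating as +")
            strand = "+"
        if strand == "+":
            start, end = rec.tss - up, rec.tss + down
        else:
            start, end = rec.tss - down, rec.tss + up
        rows.append(
            {"gene_id": rec.gene_id, "chrom": rec.chrom,
             "start": max(0, int(start)), "end": int(end), "source": "tss_window"}
        )
    windows = pd.DataFrame(rows)
    if external is not None and len(external):
        extra = []
        er = external.records
        for w in windows.itertuples(index=False):
            hits = er[(er.chrom == w.chrom) & (er.start < w.end) & (er.end > w.start)]
            for h in hits.itertuples(index=False):
                extra.append(
                    {"gene_id": w.gene_id, "chrom": h.chrom,
                     "start": int(h.start), "end": int(h.end), "source": "external"}
                )
        if extra:
            windows = pd.concat([windows, pd.DataFrame(extra)], ignore_index=True)
    return PromoterSet(windows)


def assign_peaks(
    peaks: PeakSet,
    genes: pd.DataFrame,
    promoters: PromoterSet | None = None,
    max_distance: int = 20000,
) -> PeakGeneAssignment:
    """Assign peaks to genes by summit-to-TSS distance rules.

    Per peak: (1) if it overlaps exactly one gene's promoter it gets a
    single promoter-flagged link to that gene and nothing else; if it
    overlaps several promoters it links to the one with nearest TSS
    (ties to the smaller gene id) and is flagged ambiguous. (2) Otherwise
    it links to every gene with |summit - TSS| <= ``max_distance`` whose
    TSS is not separated from the summit by another gene's TSS strictly
    in between (genes beyond a more proximal gene are excluded; both
    sides of the peak may link). Peaks on chromosomes absent from the
    gene table are left unassigned with a warning.
    """
    gene_chroms = set(genes.chrom)
    by_chrom = {c: g.reset_index(drop=True) for c, g in genes.groupby("chrom")}
    prom = promoters.intervals if promoters is not None else pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end", "source"]
    )
    links = []
    missing_chrom = 0
    for rec in peaks.records.itertuples(index=False):
        if rec.chrom not in gene_chroms:
            missing_chrom += 1
            continue
        summit = rec.start + rec.summit
        g = by_chrom[rec.chrom]

        ph = prom[(prom.chrom == rec.chrom) & (prom.start < rec.end) & (prom.end > rec.start)]
        pgenes = sorted(set(ph.gene_id))
        if pgenes:
            if len(pgenes) == 1:
                gene_id = pgenes[0]
                ambiguous = False
            else:
                tss = {gr.gene_id: gr.tss for gr in g.itertuples(index=False)}
                gene_id = min(pgenes, key=lambda x: (abs(tss.get(x, np.inf) - summit), x))
                ambiguous = True
            row = g[g.gene_id == gene_id]
            dist = int(summit - int(row.tss.iloc[0])) if len(row) else 0
            links.append(
                {"peak_id": rec.name, "gene_id": gene_id, "distance": dist,
                 "is_promoter": True, "ambiguous": ambiguous}
            )
            continue

        tss = g.tss.to_numpy()
        dist = summit - tss
        in_range = np.abs(dist) <= max_distance
        for i in np.nonzero(in_range)[0]:
            t = tss[i]
            lo, hi = min(summit, t), max(summit, t)
            blocked = np.any((tss > lo) & (tss < hi))
            if not blocked:
                links.append(
                    {"peak_id": rec.name, "gene_id": g.gene_id.iloc[i],
                     "distance": int(dist[i]), "is_promoter": False, "ambiguous": False}
                )
    if missing_chrom:
        warnings.warn(f"{missing_chrom} peak(s) on chromosomes absent from the gene table")
    df = pd.DataFrame(links, columns=["peak_id", "gene_id", "distance", "is_promoter", "ambiguous"])
    return PeakGeneAssignment(df, max_distance)


def celltype_peak_sets(
    assignment: PeakGeneAssignment,
    fc_by_type: FoldChangeProfile | pd.DataFrame,
    hi: float = 1.5,
    mid: float = 1.1,
    bg: float = 1.0,
) -> CellTypePeakSets:
    """Split regions into high / mild / background sets per cell type.

    A region's level in a cell type is the maximum fold change among its
    assigned genes there: >= ``hi`` -> high set; in [``mid``, ``hi``) ->
    mild set; <= ``bg`` -> background set; in (``bg``, ``mid``) -> none.
    Precedence high > mild > background keeps the sets disjoint. Regions
    with no assigned gene are excluded from all sets.
    """
    fc = fc_by_type.fc if isinstance(fc_by_type, FoldChangeProfile) else fc_by_type
    high: dict[str, list[str]] = {t: [] for t in fc.columns}
    mild: dict[str, list[str]] = {t: [] for t in fc.columns}
    background: dict[str, list[str]] = {t: [] for t in fc.columns}
    linked = assignment.links[assignment.links.gene_id.isin(fc.index)]
    for peak_id, group in linked.groupby("peak_id", sort=True):
        level = fc.loc[group.gene_id].max(axis=0)
        for t in fc.columns:
            v = float(level[t])
            if v >= hi:
                high[t].append(peak_id)
            elif v >= mid:
                mild[t].append(peak_id)
            elif v <= bg:
                background[t].append(peak_id)
    return CellTypePeakSets(high, mild, background, {"hi": hi, "mid": mid, "bg": bg})
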