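"""Simulated inputs with planted ground truth.

Generates every input the pipeline consumes — a UMI matrix with planted
cell types and marker programs, a toy genome with genes/TSSs/peaks,
motif occurrences inserted at controlled foreground/background rates,
and a second "species" related through an orthology table — so each
downstream stage can be tested against a known answer.

Coordinates are 0-based half-open throughout. All operations are
deterministic given their integer seed; each draws from a named
substream so components reproduce independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as mio
from ._rng import substream
from .matrix import UMICountMatrix

__all__ = [
    "TruthAtlas",
    "SyntheticGenome",
    "TruthRegulome",
    "SpeciesPairTruth",
    "constant_depth",
    "lognormal_depth",
    "make_expression_truth",
    "sample_umi_matrix",
    "make_genome",
    "make_peaks",
    "plant_motifs",
    "make_orthology_pair",
    "make_motif_ppms",
]

BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Depth laws
# ---------------------------------------------------------------------------

def constant_depth(depth: int) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Every cell sequenced to exactly ``depth`` UMIs."""
    if depth < 1:
        raise ValueError("depth must be >= 1")

    def law(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, int(depth), dtype=np.int64)

    return law


def lognormal_depth(
    median: float = 1000.0,
    sigma: float = 0.6,
    lo: int = 200,
    hi: int = 20000,
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Log-normal per-cell depths, truncated to ``[lo, hi]``.

    The default (median 1,000 UMIs/cell, truncated to [200, 20,000])
    emulates shallow plate-based scRNA-seq library depths.
    """

    def law(rng: np.random.Generator, n: int) -> np.ndarray:
        d = np.exp(rng.normal(np.log(median), sigma, size=n))
        return np.clip(np.round(d), lo, hi).astype(np.int64)

    return law


# ---------------------------------------------------------------------------
# Expression truth
# ---------------------------------------------------------------------------

@dataclass
class TruthAtlas:
    """Planted cell-type expression programs.

    ``program_matrix`` is genes x types; each column is a probability
    vector (sums to 1). ``marker_map`` records, per type, the planted
    marker genes and their fold level over the shared baseline; a
    marker's program value in its own type exceeds its value in every
    other type by exactly that factor.
    """

    type_names: list[str]
    gene_ids: np.ndarray
    program_matrix: np.ndarray
    marker_map: dict[str, list[tuple[str, float]]]

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def marker_genes(self, type_name: str) -> list[str]:
        return [g for g, _ in self.marker_map[type_name]]


def make_expression_truth(
    n_types: int,
    n_genes: int,
    markers_per_type: int,
    fold_levels: Sequence[float],
    seed: int,
) -> TruthAtlas:
    """Plant ``markers_per_type`` marker genes per type over a shared baseline.

    The baseline is a symmetric Dirichlet (concentration 1) draw over
    genes, shared by all types. Marker genes are disjoint across types;
    marker ``i`` of a type is raised by ``fold_levels[i % len(fold_levels)]``
    in that type only. Non-marker genes are rescaled per column so every
    column sums to one while marker between-type ratios stay exactly at
    the planted fold.
    """
    if n_types < 2:
        raise ValueError("n_types must be >= 2")
    if markers_per_type < 1:
        raise ValueError("markers_per_type must be >= 1")
    if n_genes <= n_types * markers_per_type:
        raise ValueError("n_genes must exceed total number of planted markers")
    fold_levels = [float(f) for f in fold_levels]
    if not fold_levels or any(f < 1.0 for f in fold_levels):
        raise ValueError("fold_levels must be non-empty and all >= 1")

    rng = substream(seed, "expression-truth")
    base = rng.dirichlet(np.ones(n_genes))
    base = np.maximum(base, 1e-12)  # guard exact zeros from the Dirichlet draw
    gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)], dtype=object)
    type_names = [f"t{i}" for i in range(n_types)]

    marker_idx = rng.choice(n_genes, size=n_types * markers_per_type, replace=False)
    w = np.tile(base[:, None], (1, n_types))
    marker_map: dict[str, list[tuple[str, float]]] = {}
    for t, tname in enumerate(type_names):
        rows = marker_idx[t * markers_per_type : (t + 1) * markers_per_type]
        entries = []
        for i, g in enumerate(rows):
            fold = fold_levels[i % len(fold_levels)]
            w[g, t] = base[g] * fold
            entries.append((str(gene_ids[g]), fold))
        marker_map[tname] = entries

    # Equalise column sums by rescaling non-marker genes only, so the
    # planted marker ratios survive the final normalisation exactly.
    is_marker = np.zeros(n_genes, dtype=bool)
    is_marker[marker_idx] = True
    marker_mass = w[is_marker, :].sum(axis=0)
    nonmarker_mass = base[~is_marker].sum()
    target = marker_mass.max() + nonmarker_mass
    scale = (target - marker_mass) / nonmarker_mass
    w[~is_marker, :] *= scale[None, :]
    program = w / w.sum(axis=0, keepdims=True)

    return TruthAtlas(type_names, gene_ids, program, marker_map)


def sample_umi_matrix(
    truth: TruthAtlas,
    cells_per_type: int,
    depth_law: Callable[[np.random.Generator, int], np.ndarray] | int | None = None,
    seed: int = 0,
    cell_prefix: str = "c",
) -> tuple[UMICountMatrix, np.ndarray]:
    """Draw a UMI matrix: each cell multinomial from its type's program.

    Returns the matrix together with the per-cell true type labels.
    """
    if truth.n_genes == 0 or truth.n_types == 0:
        raise ValueError("empty truth atlas")
    if cells_per_type < 1:
        raise ValueError("cells_per_type must be >= 1")
    if depth_law is None:
        depth_law = lognormal_depth()
    elif isinstance(depth_law, (int, np.integer)):
        depth_law = constant_depth(int(depth_law))

    rng = substream(seed, "umi-sampling")
    n_cells = cells_per_type * truth.n_types
    depths = depth_law(rng, n_cells)
    if np.any(depths < 1):
        raise ValueError("depth law must yield positive integers")
    labels = np.repeat(np.array(truth.type_names, dtype=object), cells_per_type)

    cols = []
    for c in range(n_cells):
        t = truth.type_names.index(labels[c])
        counts = rng.multinomial(int(depths[c]), truth.program_matrix[:, t])
        cols.append(sp.csc_matrix(counts[:, None]))
    counts = sp.hstack(cols, format="csc").astype(np.int64)
    cell_ids = np.array([f"{cell_prefix}{i:05d}" for i in range(n_cells)], dtype=object)
    return UMICountMatrix(counts, truth.gene_ids, cell_ids), labels


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    """Random genome with gene TSS annotations.

    ``chromosomes`` maps name -> base string; ``genes`` is a table with
    columns gene_id, chrom, tss (0-based), strand.
    """

    chromosomes: dict[str, str]
    genes: pd.DataFrame
    gc_target: float

    def gc_content(self) -> float:
        gc = total = 0
        for seq in self.chromosomes.values():
            gc += seq.count("G") + seq.count("C")
            total += len(seq)
        return gc / total if total else 0.0

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chromosomes[chrom][start:end]

    def write_fasta(self, path: str) -> None:
        mio.write_fasta(self.chromosomes, path)

    def write_gene_table(self, path: str) -> None:
        mio.write_gene_table(self.genes, path)


def make_genome(
    n_genes: int,
    chrom_length: int,
    gc_target: float = 0.4,
    min_spacing: int = 5000,
    seed: int = 0,
    chrom_name: str = "chr1",
    gene_free_tail: int = 60000,
) -> SyntheticGenome:
    """Random base string at ``gc_target`` with TSSs spaced >= ``min_spacing``.

    When the chromosome is long enough, the last ``gene_free_tail`` bases
    are kept free of TSSs so that gene-distal (orphan) regions exist.
    """
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target must be in [0, 1]")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes * min_spacing >= chrom_length:
        raise ValueError(
            f"cannot place {n_genes} TSSs with spacing {min_spacing} "
            f"on a {chrom_length} bp chromosome"
        )
    rng = substream(seed, "genome")
    p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2])
    seq = "".join(BASES[rng.choice(4, size=chrom_length, p=p)])

    usable = chrom_length - gene_free_tail
    if usable <= n_genes * min_spacing:
        usable = chrom_length  # too short for a tail; use the whole chromosome
    slack = usable - n_genes * min_spacing
    offsets = np.sort(rng.uniform(0, slack, size=n_genes))
    tss = (offsets + np.arange(n_genes) * min_spacing).astype(np.int64)
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "chrom": chrom_name,
            "tss": tss,
            "strand": strands,
        }
    )
    return SyntheticGenome({chrom_name: seq}, genes, gc_target)


# ---------------------------------------------------------------------------
# Regulome (peaks + planted motifs)
# ---------------------------------------------------------------------------

@dataclass
class TruthRegulome:
    """Peaks with their true gene assignments and planted motif insertions.

    ``peaks`` follows the narrowPeak column layout (q_value column holds
    -log10 q). ``true_assignment`` maps peak name -> list of gene ids
    (empty for orphan peaks). ``planted_motifs`` maps motif id -> list of
    ``(peak_name, offset_within_peak, strand)`` insertions.
    """

    peaks: pd.DataFrame
    true_assignment: dict[str, list[str]]
    planted_motifs: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    fg_rate: float = 0.0
    bg_rate: float = 0.0

    def write_narrowpeak(self, path: str) -> None:
        mio.write_narrowpeak(self.peaks, path)

    def truth_json(self) -> str:
        return json.dumps(
            {
                "true_assignment": self.true_assignment,
                "planted_motifs": self.planted_motifs,
                "fg_rate": self.fg_rate,
                "bg_rate": self.bg_rate,
            },
            indent=1,
        )


def make_peaks(
    genome: SyntheticGenome,
    peaks_per_gene: int = 2,
    offset_law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    extra_orphans: int = 0,
    peak_width: int = 250,
    orphan_min_distance: int = 20000,
    seed: int = 0,
) -> TruthRegulome:
    """Place ``peaks_per_gene`` peaks per gene at sampled TSS offsets.

    Orphan peaks are placed at least ``orphan_min_distance`` from every
    TSS and carry an empty true assignment. Summits sit at peak
    midpoints; intervals are clipped so peaks never leave the chromosome.
    """
    if offset_law is None:
        def offset_law(rng, n):  # noqa: ANN001 - local default
            return rng.integers(-2000, 2001, size=n)

    rng = substream(seed, "peaks")
    half = peak_width // 2
    sizes = genome.chrom_sizes()
    rows = []
    assignment: dict[str, list[str]] = {}
    k = 0
    for _, gene in genome.genes.iterrows():
        length = sizes[gene.chrom]
        offs = np.asarray(offset_law(rng, peaks_per_gene))
        for off in offs:
            summit = int(np.clip(gene.tss + int(off), half, length - half))
            name = f"peak{k:05d}"
            rows.append(
                {
                    "chrom": gene.chrom,
                    "start": summit - half,
                    "end": summit + half,
                    "name": name,
                    "score": 100.0,
                    "strand": ".",
                    "signal": float(rng.uniform(2, 20)),
                    "p_value": float(rng.uniform(8, 60)),
                    "q_value": float(rng.uniform(6.5, 50)),
                    "summit": half,
                }
            )
            assignment[name] = [gene.gene_id]
            k += 1

    # Orphans: rejection-sample positions far from every TSS.
    tss_by_chrom = {c: g.tss.to_numpy() for c, g in genome.genes.groupby("chrom")}
    chroms = list(sizes)
    placed = 0
    attempts = 0
    while placed < extra_orphans and attempts < 10000 * max(1, extra_orphans):
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        length = sizes[chrom]
        summit = int(rng.integers(half, length - half))
        tss = tss_by_chrom.get(chrom, np.array([]))
        if tss.size and np.min(np.abs(tss - summit)) < orphan_min_distance:
            continue
        name = f"peak{k:05d}"
        rows.append(
            {
                "chrom": chrom,
                "start": summit - half,
                "end": summit + half,
                "name": name,
                "score": 100.0,
                "strand": ".",
                "signal": float(rng.uniform(2, 20)),
                "p_value": float(rng.uniform(8, 60)),
                "q_value": float(rng.uniform(6.5, 50)),
                "summit": half,
            }
        )
        assignment[name] = []
        k += 1
        placed += 1
    if placed < extra_orphans:
        raise ValueError(
            f"could not place {extra_orphans} orphan peaks at distance "
            f">= {orphan_min_distance} from all TSSs"
        )
    peaks = pd.DataFrame(rows, columns=mio.NARROWPEAK_COLUMNS)
    return TruthRegulome(peaks, assignment)


def plant_motifs(
    regulome: TruthRegulome,
    genome: SyntheticGenome,
    motifs: Sequence,
    celltype_map: Mapping[str, str],
    gene_to_type: Mapping[str, str],
    fg_rate: float,
    bg_rate: float,
    seed: int = 0,
) -> tuple[SyntheticGenome, TruthRegulome]:
    """Insert motif instances into peak sequences at controlled rates.

    For each motif with a target cell type (``celltype_map``), a
    consensus-free instance is sampled column-wise from the PPM and
    written into each peak whose (truth-)assigned gene belongs to that
    type with probability ``fg_rate``, and into every other peak with
    probability ``bg_rate``. Insertions overwrite reference bases, so
    peak and TSS coordinates are untouched. All insertions are logged.
    """
    if not 0.0 <= fg_rate <= 1.0 or not 0.0 <= bg_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    rng = substream(seed, "plant-motifs")
    chrom_arrays = {name: np.array(list(seq)) for name, seq in genome.chromosomes.items()}

    peak_type: dict[str, str | None] = {}
    for name, gene_list in regulome.true_assignment.items():
        types = {gene_to_type[g] for g in gene_list if g in gene_to_type}
        peak_type[name] = next(iter(types)) if len(types) == 1 else None

    planted = dict(regulome.planted_motifs)
    for motif in motifs:
        width = motif.width
        target = celltype_map.get(motif.id)
        log: list[tuple[str, int, str]] = []
        for _, peak in regulome.peaks.iterrows():
            if width > peak.end - peak.start:
                raise ValueError(f"motif {motif.id} wider than peak {peak['name']}")
            rate = fg_rate if (target is not None and peak_type.get(peak["name"]) == target) else bg_rate
            if rng.random() >= rate:
                continue
            inst = np.array(
                [BASES[rng.choice(4, p=row / row.sum())] for row in motif.matrix]
            )
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                inst = np.array([comp[b] for b in inst[::-1]])
            offset = int(rng.integers(0, peak.end - peak.start - width + 1))
            pos = peak.start + offset
            chrom_arrays[peak.chrom][pos : pos + width] = inst
            log.append((str(peak["name"]), offset, strand))
        planted[motif.id] = planted.get(motif.id, []) + log

    mutated = SyntheticGenome(
        {name: "".join(arr) for name, arr in chrom_arrays.items()},
        genome.genes.copy(),
        genome.gc_target,
    )
    out = TruthRegulome(
        regulome.peaks.copy(), dict(regulome.true_assignment), planted, fg_rate, bg_rate
    )
    return mutated, out


def make_motif_ppms(
    n_motifs: int,
    width: int = 8,
    dominance: float = 0.92,
    seed: int = 0,
    prefix: str = "M",
):
    """Random informative position probability matrices.

    Each column puts probability near ``dominance`` (jittered per column)
    on one random base and spreads the remainder unevenly over the other
    three, giving sharp, high-IC motifs with realistic, non-degenerate
    log-odds scores.
    """
    from .motifs import MotifPPM  # local import to avoid a cycle

    if not 0.25 < dominance <= 1.0:
        raise ValueError("dominance must be in (0.25, 1]")
    rng = substream(seed, "motif-ppms")
    out = []
    for k in range(n_motifs):
        out.append(
            MotifPPM(id=f"{prefix}{k:03d}", matrix=_random_ppm(rng, width, dominance),
                     source="de_novo")
        )
    return out


def _random_ppm(rng: np.random.Generator, width: int, dominance: float) -> np.ndarray:
    mat = np.empty((width, 4))
    for j in range(width):
        d = rng.uniform(max(0.30, dominance - 0.05), min(0.99, dominance + 0.05))
        rest = rng.dirichlet(np.ones(3)) * (1.0 - d)
        row = np.empty(4)
        b = rng.integers(0, 4)
        row[b] = d
        row[[i for i in range(4) if i != b]] = rest
        mat[j] = row
    return mat


def _shares_kmer(a: str, b: str, k: int) -> bool:
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(b))
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1)) or any(
        rc[i : i + k] in kmers for i in range(len(rc) - k + 1)
    )


def make_motif_families(
    n_families: int,
    copies_per_family: int,
    width: int = 10,
    dominance: float = 0.92,
    perturbation: float = 0.03,
    seed: int = 0,
):
    """Distinct motif families with perturbed/shifted/reverse-complement copies.

    Family founders are drawn with mutually distinct consensi (no shared
    6-mer on either strand, so families are genuinely separate signals).
    Each family then gets ``copies_per_family`` variants: probability
    perturbation (renormalized additive noise of scale ``perturbation``),
    a one-column shift (trim one end, pad the other with a uniform
    column), and reverse complementation, applied cyclically. Returns a
    list of lists (one inner list per family).
    """
    from .motifs import MotifPPM

    rng = substream(seed, "motif-families")
    founders: list[np.ndarray] = []
    tries = 0
    while len(founders) < n_families:
        tries += 1
        if tries > 1000 * n_families:
            raise RuntimeError("could not draw mutually distinct motif families")
        mat = _random_ppm(rng, width, dominance)
        cons = "".join("ACGT"[i] for i in mat.argmax(axis=1))
        if any(_shares_kmer(cons, "".join("ACGT"[i] for i in f.argmax(axis=1)), 6)
               for f in founders):
            continue
        founders.append(mat)

    families = []
    uniform = np.full((1, 4), 0.25)
    for fam, mat in enumerate(founders):
        members = []
        for c in range(copies_per_family):
            m = mat.copy()
            if c > 0:
                m = m + rng.uniform(0, perturbation, size=m.shape)
                m = m / m.sum(axis=1, keepdims=True)
            if c % 3 == 1:  # shift by one column
                m = np.vstack([m[1:], uniform])
            if c % 3 == 2:  # reverse complement
                m = m[::-1, ::-1]
            members.append(MotifPPM(id=f"F{fam:02d}_c{c}", matrix=m, source="de_novo"))
        families.append(members)
    return families


# ---------------------------------------------------------------------------
# Species pair
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPairTruth:
    """Orthology structure linking species A to a derived species B.

    ``orthology_table`` has columns group_id/species/gene_id; every gene
    appears in at most one group. ``conserved_types`` lists the (A type,
    B type) pairs that share a program.
    """

    orthology_table: pd.DataFrame
    conserved_types: list[tuple[str, str]]
    divergence_noise: float
    truth_b: TruthAtlas

    def write_orthology_table(self, path: str) -> None:
        mio.write_orthology_table(self.orthology_table, path)


def make_orthology_pair(
    truth: TruthAtlas,
    one2one_frac: float = 0.8,
    dup_frac: float = 0.1,
    divergence_noise: float = 0.1,
    conserved_types: Sequence[str] | None = None,
    cells_per_type: int = 100,
    depth_law: Callable[[np.random.Generator, int], np.ndarray] | int | None = None,
    seed: int = 0,
) -> tuple[SpeciesPairTruth, UMICountMatrix, np.ndarray]:
    """Derive a second species through orthology groups.

    Each species-A gene is, independently: duplicated in B (probability
    ``dup_frac``; 2 B co-orthologs), mapped 1:1 (probability
    ``one2one_frac``), or lost in B. For conserved types, B's program is
    A's program pushed through the orthology map (split equally among
    duplicates) with multiplicative log-normal noise of scale
    ``divergence_noise``; non-conserved B types get fresh baseline
    programs sharing no planted markers. B's UMI matrix is sampled
    multinomially like species A's.
    """
    if not 0 <= one2one_frac <= 1 or not 0 <= dup_frac <= 1:
        raise ValueError("fractions must be in [0, 1]")
    if one2one_frac + dup_frac > 1 + 1e-12:
        raise ValueError("one2one_frac + dup_frac must be <= 1")
    if divergence_noise < 0:
        raise ValueError("divergence_noise must be >= 0")
    if conserved_types is None:
        conserved_types = list(truth.type_names)

    rng = substream(seed, "orthology-pair")
    u = rng.random(truth.n_genes)
    n_copies = np.where(u < dup_frac, 2, np.where(u < dup_frac + one2one_frac, 1, 0))

    rows = []
    b_gene_ids: list[str] = []
    a_index_of_b: list[int] = []
    copies_of_b: list[int] = []
    group = 0
    for i, gene in enumerate(truth.gene_ids):
        if n_copies[i] == 0:
            continue
        gid = f"og{group:05d}"
        rows.append({"group_id": gid, "species": "A", "gene_id": gene})
        for c in range(n_copies[i]):
            b_gene = f"B_{gene}_{c}" if n_copies[i] > 1 else f"B_{gene}"
            rows.append({"group_id": gid, "species": "B", "gene_id": b_gene})
            b_gene_ids.append(b_gene)
            a_index_of_b.append(i)
            copies_of_b.append(int(n_copies[i]))
        group += 1
    table = pd.DataFrame(rows, columns=["group_id", "species", "gene_id"])

    a_index_of_b = np.array(a_index_of_b, dtype=int)
    copies_of_b = np.array(copies_of_b, dtype=int)
    n_b = len(b_gene_ids)
    b_types = [f"B_{t}" for t in truth.type_names]
    program_b = np.empty((n_b, truth.n_types))
    pairs: list[tuple[str, str]] = []
    for t, tname in enumerate(truth.type_names):
        if tname in conserved_types:
            col = truth.program_matrix[a_index_of_b, t] / copies_of_b
            if divergence_noise > 0:
                col = col * np.exp(rng.normal(0.0, divergence_noise, size=n_b))
            pairs.append((tname, b_types[t]))
        else:
            col = rng.dirichlet(np.ones(n_b))
            col = np.maximum(col, 1e-12)
        program_b[:, t] = col / col.sum()

    marker_map_b: dict[str, list[tuple[str, float]]] = {}
    a_markers = {t: dict(v) for t, v in truth.marker_map.items()}
    for t, tname in enumerate(truth.type_names):
        entries = []
        if tname in conserved_types:
            for j, a_i in enumerate(a_index_of_b):
                a_gene = str(truth.gene_ids[a_i])
                if a_gene in a_markers[tname]:
                    entries.append((b_gene_ids[j], a_markers[tname][a_gene]))
        marker_map_b[b_types[t]] = entries

    truth_b = TruthAtlas(b_types, np.array(b_gene_ids, dtype=object), program_b, marker_map_b)
    matrix_b, labels_b = sample_umi_matrix(
        truth_b, cells_per_type, depth_law, seed=seed + 1, cell_prefix="bc"
    )
    pair = SpeciesPairTruth(table, pairs, divergence_noise, truth_b)
    return pair, matrix_b, labels_b
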