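"""Planted-truth evaluation experiments.

Each function builds a synthetic dataset with known ground truth, runs
the relevant pipeline stage(s) end to end, and measures how well the
truth is recovered. These experiments back the package's recovery and
calibration checks; they are ordinary library code and can be used to
re-validate the pipeline under different conditions.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import metacell, motifs as mo, profiles, synth
from .crossspecies import OrthologyMap, celltype_correlation

__all__ = [
    "clustering_recovery",
    "motif_family_dedupe",
    "enrichment_experiment",
    "null_empirical_p_fraction",
    "crossspecies_recovery",
]


def clustering_recovery(
    seed: int,
    n_types: int = 8,
    cells_per_type: int = 375,
    n_genes: int = 2000,
    markers_per_type: int = 20,
    fold: float = 8.0,
    K: int = 100,
    n_boot: int = 30,
) -> dict:
    """Cluster a planted-type matrix and score metacell-majority recovery.

    Generates ``n_types`` cell types with ``markers_per_type`` markers at
    the given fold over baseline and a log-normal depth law with median
    1,000 UMIs/cell, runs the full metacell pipeline, relabels each cell
    by the majority true type of its metacell, and returns the adjusted
    Rand index of that labeling against the truth.
    """
    truth = synth.make_expression_truth(n_types, n_genes, markers_per_type, [fold], seed)
    matrix, labels = synth.sample_umi_matrix(truth, cells_per_type, None, seed)
    partition, _, _ = metacell.cluster_cells(matrix, K=K, n_boot=n_boot, seed=seed)
    majority = np.array(["outlier"] * matrix.n_cells, dtype=object)
    for mc in partition.metacell_ids():
        members = partition.members(mc)
        vals, counts = np.unique(labels[members], return_counts=True)
        majority[members] = vals[np.argmax(counts)]
    return {
        "ari": float(adjusted_rand_score(labels, majority)),
        "n_metacells": int(partition.n_metacells),
        "n_cells": int(matrix.n_cells),
    }


def motif_family_dedupe(
    seed: int,
    n_families: int = 6,
    copies_per_family: int = 5,
    width: int = 10,
) -> dict:
    """Collapse planted motif families and report the retained count.

    Plants ``n_families`` mutually distinct families with perturbed,
    shifted, and reverse-complement copies, runs redundancy reduction at
    similarity 0.95, and reports the number of representatives plus the
    maximum pairwise similarity among them.
    """
    families = synth.make_motif_families(n_families, copies_per_family, width, seed=seed)
    flat = [m for fam in families for m in fam]
    lib = mo.dedupe_library(flat, threshold=0.95, min_overlap=6)
    kept = lib.motifs
    max_sim = -1.0
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            max_sim = max(max_sim, mo.motif_similarity(kept[i], kept[j]))
    return {"n_retained": len(lib), "max_pairwise_similarity": float(max_sim)}


def enrichment_experiment(
    seed: int,
    n_regions: int = 200,
    fg_rate: float = 0.4,
    bg_rate: float = 0.05,
    chrom_length: int = 3_000_000,
    score_fraction_min: float = 0.8,
) -> dict:
    """Plant one motif in cell-type regions and test its enrichment.

    Builds ``n_regions`` single-gene peaks all belonging to one cell
    type, plants a target motif at ``fg_rate`` in those peaks (and at
    ``bg_rate`` elsewhere in the genome background set through matched
    sampling), scans a planted and a non-planted control motif, and runs
    the binomial enrichment test against 2x GC/length-matched
    backgrounds. Returns enrichment statistics for both motifs.
    """
    genome = synth.make_genome(
        n_regions, chrom_length, 0.4, max(1000, (chrom_length - 100000) // (n_regions + 2)) // 2,
        seed=seed,
    )
    regulome = synth.make_peaks(genome, 1, extra_orphans=0, seed=seed)
    gene_to_type = {g: "tA" for g in genome.genes.gene_id}
    planted, control = synth.make_motif_ppms(2, 10, 0.9, seed=100000 + seed)
    # keep the control genuinely non-planted: resample it until it is
    # dissimilar from the planted motif
    k = 0
    while mo.motif_similarity(planted, control) > 0.5:
        k += 1
        control = synth.make_motif_ppms(1, 10, 0.9, seed=200000 + 1000 * k + seed)[0]
        control = mo.MotifPPM(planted.id[:-3] + "X", control.matrix, control.source)
    genome, regulome = synth.plant_motifs(
        regulome, genome, [planted], {planted.id: "tA"}, gene_to_type,
        fg_rate, bg_rate, seed=seed,
    )
    chroms = genome.chromosomes
    fg = {
        rec.name: (rec.chrom, int(rec.start), int(rec.end))
        for rec in regulome.peaks.itertuples(index=False)
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bg = mo.sample_matched_background(fg, chroms, multiple=2, n_gc_bins=10, seed=seed)
    seqs = {rid: chroms[c][s:e] for rid, (c, s, e) in {**fg, **bg}.items()}
    hits = mo.scan_regions(seqs, [planted, control], score_fraction_min, best_only=True)
    table = mo.binned_enrichment(
        {("tA", "high"): list(fg)}, list(bg), hits, [planted.id, control.id]
    ).set_index("motif_id")
    return {
        "planted_log2fc": float(table.loc[planted.id, "log2fc"]),
        "planted_p_adj": float(table.loc[planted.id, "p_adj"]),
        "control_p_adj": float(table.loc[control.id, "p_adj"]),
    }


def null_empirical_p_fraction(
    seed: int,
    n_regions: int = 1000,
    chrom_length: int = 4_000_000,
) -> float:
    """Empirical-p calibration under a null where foreground = background.

    Draws ``n_regions`` random 250 bp regions and 2x GC-matched
    backgrounds from the same unplanted genome, computes per-region best
    motif scores and rank-based empirical p-values within 10 GC bins,
    and returns the fraction of p-values below 0.05 (nominally ~0.05).
    """
    genome = synth.make_genome(5, chrom_length, 0.42, 10000, seed=seed)
    chroms = genome.chromosomes
    rng = np.random.default_rng(seed)
    L = chrom_length
    fg = {}
    for i in range(n_regions):
        s = int(rng.integers(0, L - 250))
        fg[f"fg{i:05d}"] = ("chr1", s, s + 250)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bg = mo.sample_matched_background(fg, chroms, multiple=2, n_gc_bins=10, seed=seed)
    motif = synth.make_motif_ppms(1, 10, 0.9, seed=300000 + seed)[0]
    hits_fg = mo.scan_regions(
        {r: chroms[c][s:e] for r, (c, s, e) in fg.items()}, [motif], 0.0, best_only=True
    )
    hits_bg = mo.scan_regions(
        {r: chroms[c][s:e] for r, (c, s, e) in bg.items()}, [motif], 0.0, best_only=True
    )
    best_fg = {h.region_id: h.score for h in hits_fg}
    best_bg = {h.region_id: h.score for h in hits_bg}
    fg_gc = {r: mo.gc_content(chroms[c][s:e]) for r, (c, s, e) in fg.items()}
    bg_gc = {r: mo.gc_content(chroms[c][s:e]) for r, (c, s, e) in bg.items()}
    table = mo.empirical_hit_pvalue(best_fg, best_bg, fg_gc, bg_gc, n_gc_bins=10)
    return float((table.empirical_p < 0.05).mean())


def crossspecies_recovery(
    seed: int,
    n_types: int = 6,
    n_genes: int = 800,
    markers_per_type: int = 12,
    cells_per_type: int = 60,
    divergence_noise: float = 0.1,
) -> dict:
    """Best-match recovery of planted conserved type pairs across species.

    Samples species A from a planted atlas, derives species B through an
    orthology map with multiplicative log-normal divergence noise,
    computes cell-type fold-change profiles for both, and checks that
    every conserved pair is the best-correlated match.
    """
    truth = synth.make_expression_truth(n_types, n_genes, markers_per_type, [8.0], seed)
    matrix, labels = synth.sample_umi_matrix(truth, cells_per_type, None, seed)
    pair, matrix_b, labels_b = synth.make_orthology_pair(
        truth, 0.8, 0.1, divergence_noise, cells_per_type=cells_per_type, seed=seed
    )
    orthology = OrthologyMap.from_table(pair.orthology_table)
    fc_a = profiles.compute_fc(matrix, labels, seed=seed)
    fc_b = profiles.compute_fc(matrix_b, labels_b, seed=seed)
    corr = celltype_correlation(fc_a, fc_b, orthology, fc_floor=1.05)
    recovered = sum(corr.best_match[ta] == tb for ta, tb in pair.conserved_types)
    return {
        "n_pairs": len(pair.conserved_types),
        "n_recovered": int(recovered),
        "mean_diag_corr": float(
            np.mean([corr.matrix.loc[ta, tb] for ta, tb in pair.conserved_types])
        ),
    }
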