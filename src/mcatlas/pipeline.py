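"""End-to-end pipeline orchestration on simulated data.

``run_pipeline`` executes the enabled stages in dependency order
(simulate -> cluster -> profile -> regmap -> motifs -> xspecies),
writes every stage's outputs as tab-separated/JSON/standard-format text
files under an output directory, and finishes with a run manifest
(resolved config, input checksums, stage timings, output inventory,
software version). Stages run on the synthetic inputs produced by the
``simulate`` stage; a stage whose upstream outputs are missing fails
with an error naming the stage to run first.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from . import metacell, motifs as mo, profiles, regulatory, synth
from .config import ALL_STAGES, RunConfig
from .crossspecies import OrthologyMap, celltype_correlation, rank_markers, shared_features

__all__ = ["run_pipeline", "DependencyError"]

log = logging.getLogger("mcatlas")


class DependencyError(RuntimeError):
    pass


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _need(state: dict, key: str, stage: str):
    if key not in state:
        raise DependencyError(
            f"missing upstream result {key!r}: run the {stage!r} stage first"
        )
    return state[key]


def _stage_simulate(cfg: RunConfig, outdir: str, state: dict) -> None:
    p = cfg["simulate"]
    seed = cfg.seed
    truth = synth.make_expression_truth(
        p["n_types"], p["n_genes"], p["markers_per_type"], p["fold_levels"], seed
    )
    law = synth.lognormal_depth(p["depth_median"], p["depth_sigma"], p["depth_min"], p["depth_max"])
    matrix, labels = synth.sample_umi_matrix(truth, p["cells_per_type"], law, seed)
    genome = synth.make_genome(
        p["genome_genes"], p["chrom_length"], p["gc_target"], p["min_spacing"], seed
    )
    regulome = synth.make_peaks(
        genome, p["peaks_per_gene"], extra_orphans=p["extra_orphans"], seed=seed
    )
    ppms = synth.make_motif_ppms(p["n_motifs"], p["motif_width"], p["motif_dominance"], seed)
    # Map each genome gene cyclically onto an expression cell type and give
    # every motif one target type.
    gene_to_type = {
        g: truth.type_names[i % truth.n_types]
        for i, g in enumerate(genome.genes.gene_id)
    }
    celltype_map = {m.id: truth.type_names[i % truth.n_types] for i, m in enumerate(ppms)}
    genome, regulome = synth.plant_motifs(
        regulome, genome, ppms, celltype_map, gene_to_type,
        p["fg_rate"], p["bg_rate"], seed,
    )

    mio.write_mtx(matrix, os.path.join(outdir, "umi"))
    pd.DataFrame({"cell_id": matrix.cell_ids, "cell_type": labels}).to_csv(
        os.path.join(outdir, "cell_labels.tsv"), sep="\t", index=False
    )
    genome.write_fasta(os.path.join(outdir, "genome.fa"))
    genome.write_gene_table(os.path.join(outdir, "genes.tsv"))
    regulome.write_narrowpeak(os.path.join(outdir, "peaks.narrowPeak"))
    mio.write_meme(ppms, os.path.join(outdir, "motifs.meme"))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(regulome.truth_json())

    state.update(
        truth=truth, matrix=matrix, labels=labels, genome=genome,
        regulome=regulome, ppms=ppms, gene_to_type=gene_to_type,
        celltype_map=celltype_map,
    )


def _load_simulated(outdir: str, state: dict) -> None:
    """Reload simulate-stage artifacts from disk for stage-wise runs."""
    umi_dir = os.path.join(outdir, "umi")
    if "matrix" in state or not os.path.isdir(umi_dir):
        return
    state["matrix"] = mio.read_mtx(umi_dir)
    labels = pd.read_csv(os.path.join(outdir, "cell_labels.tsv"), sep="\t")
    state["labels"] = labels.cell_type.to_numpy(dtype=object)


def _stage_cluster(cfg: RunConfig, outdir: str, state: dict) -> None:
    p = cfg["cluster"]
    matrix = _need(state, "matrix", "simulate")
    partition, coclust, features = metacell.cluster_cells(
        matrix,
        K=p["K"], K_cc=p["K_cc"], n_boot=p["n_boot"], fraction=p["fraction"],
        alpha=p["alpha"], min_size=p["min_size"], use_szcor=p["use_szcor"],
        seed=cfg.seed,
        feature_kwargs={
            "t_tot": p["t_tot"], "t_prev_cells": p["t_prev_cells"],
            "t_prev_umi": p["t_prev_umi"], "t_szcor": p["t_szcor"],
            "t_niche": p["t_niche"], "use_niche": p["use_niche"],
        },
    )
    partition = metacell.filter_low_quality_metacells(
        partition, matrix, p["low_quality_min_cells"], p["low_quality_min_median_umi"]
    )
    partition.to_frame().to_csv(os.path.join(outdir, "partition.tsv"), sep="\t", index=False)
    features.stats.to_csv(os.path.join(outdir, "feature_stats.tsv"), sep="\t")
    graph_df = pd.DataFrame(
        {"cell_a": coclust.cell_ids[np.nonzero(np.triu(coclust.co_count, 1))[0]],
         "cell_b": coclust.cell_ids[np.nonzero(np.triu(coclust.co_count, 1))[1]]}
    )
    graph_df.to_csv(os.path.join(outdir, "cocluster_edges.tsv"), sep="\t", index=False)
    mc_coords, cell_coords = metacell.layout_2d(coclust, partition, seed=cfg.seed)
    mc_coords.to_csv(os.path.join(outdir, "layout_metacells.tsv"), sep="\t", index=False)
    cell_coords.to_csv(os.path.join(outdir, "layout_cells.tsv"), sep="\t", index=False)
    state.update(partition=partition, coclust=coclust, features=features)


def _stage_profile(cfg: RunConfig, outdir: str, state: dict) -> None:
    p = cfg["profile"]
    matrix = _need(state, "matrix", "simulate")
    partition = _need(state, "partition", "cluster")
    fc = profiles.compute_fc(
        matrix, partition, eps=p["eps"], median_mode=p["median_mode"], seed=cfg.seed
    )
    markers = profiles.select_markers(fc, p["max_markers_per_cluster"], p["min_marker_fc"])
    fc.fc.to_csv(os.path.join(outdir, "fc_metacells.tsv"), sep="\t")
    markers.to_frame().to_csv(os.path.join(outdir, "markers.tsv"), sep="\t", index=False)

    annotation = None
    if "truth" in state:
        signatures = {t: state["truth"].marker_genes(t) for t in state["truth"].type_names}
        annotation = profiles.annotate_cell_types(fc, signatures, p["annotation_floor"])
        annotation.table.to_csv(os.path.join(outdir, "annotation.tsv"), sep="\t", index=False)

    # Cell-type level profile, used by regmap and xspecies.
    labels = _need(state, "labels", "simulate")
    fc_types = profiles.compute_fc(
        matrix, labels, eps=p["eps"], median_mode=p["median_mode"], seed=cfg.seed
    )
    fc_types.fc.to_csv(os.path.join(outdir, "fc_celltypes.tsv"), sep="\t")
    state.update(fc=fc, markers=markers, annotation=annotation, fc_types=fc_types)


def _stage_regmap(cfg: RunConfig, outdir: str, state: dict) -> None:
    p = cfg["regmap"]
    peak_path = os.path.join(outdir, "peaks.narrowPeak")
    if not os.path.exists(peak_path):
        raise DependencyError("missing peaks.narrowPeak: run the 'simulate' stage first")
    genes = mio.read_gene_table(os.path.join(outdir, "genes.tsv"))
    chrom_sizes = (
        state["genome"].chrom_sizes()
        if "genome" in state
        else {c: len(s) for c, s in mio.read_fasta(os.path.join(outdir, "genome.fa")).items()}
    )
    peaks = regulatory.load_and_filter_peaks(peak_path, p["min_neglog10_q"])
    std = regulatory.standardize_peaks(peaks, p["half_width"], chrom_sizes)
    reduced = regulatory.reduce_overlaps(std)
    promoters = regulatory.define_promoters(
        genes, p["promoter_upstream"], p["promoter_downstream"],
        swap_orientation=p["swap_promoter_orientation"],
    )
    assignment = regulatory.assign_peaks(reduced, genes, promoters, p["max_distance"])
    reduced.to_bed6().to_csv(
        os.path.join(outdir, "regions.bed"), sep="\t", header=False, index=False
    )
    assignment.links.to_csv(os.path.join(outdir, "peak_gene_links.tsv"), sep="\t", index=False)

    sets = None
    if "fc_types" in state:
        # The synthetic genome genes map onto expression cell types through
        # gene_to_type; project the cell-type FC onto genome gene ids.
        fc_types = state["fc_types"]
        g2t = state.get("gene_to_type")
        if g2t:
            truth = state["truth"]
            rows = []
            for i, g in enumerate(genes.gene_id):
                markers = truth.marker_genes(g2t[g])
                rep = markers[i % len(markers)]
                rows.append(fc_types.fc.loc[rep])
            proj = pd.DataFrame(rows, index=genes.gene_id.to_numpy())
            sets = regulatory.celltype_peak_sets(
                assignment, proj, p["fc_high"], p["fc_mild"], p["fc_background"]
            )
            with open(os.path.join(outdir, "celltype_peak_sets.json"), "w") as fh:
                json.dump({"high": sets.high, "mild": sets.mild,
                           "background": sets.background}, fh, indent=1)
    state.update(peaks=reduced, assignment=assignment, peak_sets=sets, genes_table=genes)


def _stage_motifs(cfg: RunConfig, outdir: str, state: dict) -> None:
    p = cfg["motifs"]
    meme_path = os.path.join(outdir, "motifs.meme")
    if not os.path.exists(meme_path):
        raise DependencyError("missing motifs.meme: run the 'simulate' stage first")
    library = mo.MotifLibrary(mio.read_meme(meme_path))
    library = mo.contiguous_ic_filter(
        library, p["ic_min"], p["ic_run_len"], p["ic_block_len"], p["ic_n_blocks"]
    )
    library = mo.dedupe_library(library, p["similarity_threshold"], p["min_overlap"])

    peaks = _need(state, "peaks", "regmap")
    genome = state.get("genome")
    chroms = genome.chromosomes if genome else mio.read_fasta(os.path.join(outdir, "genome.fa"))
    r = peaks.records
    fg = {rec.name: (rec.chrom, int(rec.start), int(rec.end)) for rec in r.itertuples(index=False)}
    bg = mo.sample_matched_background(
        fg, chroms, p["background_multiple"], p["n_gc_bins"], seed=cfg.seed
    )
    seqs = {rid: chroms[c][s:e] for rid, (c, s, e) in {**fg, **bg}.items()}
    hits = mo.scan_regions(seqs, library, p["score_fraction_min"], best_only=True)
    hits_df = pd.DataFrame(
        [{"region_id": h.region_id, "motif_id": h.motif_id, "offset": h.offset,
          "strand": h.strand, "score": h.score, "score_fraction": h.score_fraction}
         for h in hits]
    )
    hits_df.to_csv(os.path.join(outdir, "motif_hits.tsv"), sep="\t", index=False)

    sets = state.get("peak_sets")
    if sets is not None:
        fg_sets = {}
        for t, ids in sets.high.items():
            fg_sets[(t, "high")] = ids
        for t, ids in sets.mild.items():
            fg_sets[(t, "mild")] = ids
        enrich = mo.binned_enrichment(fg_sets, list(bg), hits, library.ids())
        enrich.to_csv(os.path.join(outdir, "motif_enrichment.tsv"), sep="\t", index=False)
        state["enrichment"] = enrich
    state.update(library=library, hits=hits, background=bg)


def _stage_xspecies(cfg: RunConfig, outdir: str, state: dict) -> None:
    p = cfg["xspecies"]
    truth = _need(state, "truth", "simulate")
    matrix = _need(state, "matrix", "simulate")
    labels = _need(state, "labels", "simulate")
    pair, matrix_b, labels_b = synth.make_orthology_pair(
        truth, p["one2one_frac"], p["dup_frac"], p["divergence_noise"],
        cells_per_type=p["cells_per_type"], seed=cfg.seed,
    )
    pair.write_orthology_table(os.path.join(outdir, "orthology.tsv"))
    orthology = OrthologyMap.from_table(pair.orthology_table)

    stats_a = rank_markers(matrix, labels)
    stats_b = rank_markers(matrix_b, labels_b)
    stats_a.table.to_csv(os.path.join(outdir, "markers_speciesA.tsv"), sep="\t", index=False)
    stats_b.table.to_csv(os.path.join(outdir, "markers_speciesB.tsv"), sep="\t", index=False)
    graph = shared_features(
        stats_a, stats_b, orthology, p["marker_fc_min"], p["marker_p_max"]
    )
    graph.edge_list().to_csv(os.path.join(outdir, "shared_markers.tsv"), sep="\t", index=False)

    fc_a = profiles.compute_fc(matrix, labels, seed=cfg.seed)
    fc_b = profiles.compute_fc(matrix_b, labels_b, seed=cfg.seed)
    corr = celltype_correlation(fc_a, fc_b, orthology, p["corr_fc_floor"])
    corr.matrix.to_csv(os.path.join(outdir, "celltype_correlation.tsv"), sep="\t")
    corr.best_match.rename("best_match").to_csv(
        os.path.join(outdir, "best_matches.tsv"), sep="\t"
    )
    state.update(pair=pair, corr=corr, shared=graph)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cluster": _stage_cluster,
    "profile": _stage_profile,
    "regmap": _stage_regmap,
    "motifs": _stage_motifs,
    "xspecies": _stage_xspecies,
}

_INPUT_FILES = [
    "umi/matrix.mtx", "umi/genes.tsv", "umi/barcodes.tsv", "cell_labels.tsv",
    "genome.fa", "genes.tsv", "peaks.narrowPeak", "motifs.meme",
]


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    os.makedirs(outdir, exist_ok=True)
    state: dict = {}
    timings: dict[str, float] = {}
    stages = [s for s in ALL_STAGES if s in config.stages]
    if "simulate" not in stages:
        _load_simulated(outdir, state)
    for stage in stages:
        t0 = time.perf_counter()
        log.info("stage %s: start", stage)
        try:
            _STAGE_FUNCS[stage](config, outdir, state)
        except DependencyError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.2fs", stage, timings[stage])

    checksums = {
        f: _sha256(os.path.join(outdir, f))
        for f in _INPUT_FILES
        if os.path.exists(os.path.join(outdir, f))
    }
    outputs = sorted(
        os.path.relpath(os.path.join(root, f), outdir)
        for root, _, files in os.walk(outdir)
        for f in files
        if f != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "config": config.resolved(),
        "stages_run": stages,
        "timings_s": timings,
        "input_checksums": checksums,
        "outputs": outputs,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
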