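"""Peak filtering/standardization and distance-rule assignment, checked
against an exhaustive brute-force implementation of the rules."""

import numpy as np
import pandas as pd
import pytest

from mcatlas import regulatory
from mcatlas.io import NARROWPEAK_COLUMNS


def _peakset(rows):
    recs = []
    for i, row in enumerate(rows):
        rec = {"chrom": "chr1", "name": f"p{i}", "score": 0.0, "strand": ".",
               "signal": 1.0, "p_value": 10.0, "q_value": 10.0}
        rec.update(row)
        rec.setdefault("summit", (rec["end"] - rec["start"]) // 2)
        recs.append(rec)
    return regulatory.PeakSet(pd.DataFrame(recs, columns=NARROWPEAK_COLUMNS))


def _genes(tss_list, strands=None, chrom="chr1"):
    return pd.DataFrame(
        {"gene_id": [f"g{chr(65 + i)}" for i in range(len(tss_list))],
         "chrom": chrom, "tss": tss_list,
         "strand": strands or ["+"] * len(tss_list)}
    )


class TestLoadAndFilter:
    def test_q_threshold(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text(
            "chr1\t100\t350\ta\t0\t.\t1\t9\t6.5\t125\n"
            "chr1\t500\t750\tb\t0\t.\t1\t9\t5.9\t125\n"
        )
        ps = regulatory.load_and_filter_peaks(str(path), 6.0)
        assert list(ps.records["name"]) == ["a"]

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.narrowPeak"
        path.write_text("")
        with pytest.warns(UserWarning, match="no peaks"):
            ps = regulatory.load_and_filter_peaks(str(path), 6.0)
        assert len(ps) == 0


class TestStandardize:
    def test_250bp_window_around_summit(self):
        ps = _peakset([{"start": 400, "end": 700, "summit": 100}])  # summit abs 500
        std = regulatory.standardize_peaks(ps, 125, {"chr1": 10000})
        rec = std.records.iloc[0]
        assert (rec.start, rec.end) == (375, 625)
        assert rec.end - rec.start == 250
        assert not rec.truncated

    def test_truncated_at_chromosome_start(self):
        ps = _peakset([{"start": 0, "end": 200, "summit": 50}])
        std = regulatory.standardize_peaks(ps, 125, {"chr1": 10000})
        rec = std.records.iloc[0]
        assert (rec.start, rec.end) == (0, 175)
        assert rec.truncated

    def test_all_untruncated_records_are_250bp(self, toy_regulome, toy_genome):
        ps = regulatory.PeakSet(toy_regulome.peaks)
        std = regulatory.standardize_peaks(ps, 125, toy_genome.chrom_sizes())
        ok = ~std.records.truncated
        lengths = (std.records.end - std.records.start)[ok]
        assert (lengths == 250).all()


class TestReduceOverlaps:
    def test_disjoint_unchanged(self):
        ps = _peakset([{"start": 0, "end": 100}, {"start": 200, "end": 300}])
        out = regulatory.reduce_overlaps(ps)
        assert len(out) == 2

    def test_identical_collapse_to_one(self):
        ps = _peakset([{"start": 0, "end": 100}, {"start": 0, "end": 100}])
        out = regulatory.reduce_overlaps(ps)
        assert len(out) == 1

    def test_transitive_chain_merges_to_span(self):
        ps = _peakset(
            [{"start": 0, "end": 100}, {"start": 80, "end": 200}, {"start": 180, "end": 260}]
        )
        out = regulatory.reduce_overlaps(ps)
        assert len(out) == 1
        rec = out.records.iloc[0]
        assert (rec.start, rec.end) == (0, 260)

    def test_keeps_summit_of_best_supported_member(self):
        ps = _peakset(
            [{"start": 0, "end": 100, "summit": 10, "q_value": 8.0},
             {"start": 50, "end": 150, "summit": 50, "q_value": 20.0}]
        )
        out = regulatory.reduce_overlaps(ps)
        rec = out.records.iloc[0]
        assert rec.start + rec.summit == 100  # summit of the higher-q member

    def test_output_is_pairwise_disjoint(self, toy_regulome):
        ps = regulatory.PeakSet(toy_regulome.peaks)
        out = regulatory.reduce_overlaps(ps)
        r = out.records.sort_values(["chrom", "start"])
        same = r.chrom.to_numpy()[1:] == r.chrom.to_numpy()[:-1]
        assert np.all(~same | (r.start.to_numpy()[1:] >= r.end.to_numpy()[:-1]))


class TestPromoters:
    def test_plus_strand_window(self):
        prom = regulatory.define_promoters(_genes([1000]), 50, 200)
        rec = prom.intervals.iloc[0]
        assert (rec.start, rec.end) == (950, 1200)

    def test_minus_strand_window_mirrored(self):
        prom = regulatory.define_promoters(_genes([1000], ["-"]), 50, 200)
        rec = prom.intervals.iloc[0]
        assert (rec.start, rec.end) == (800, 1050)

    def test_external_intervals_attributed_to_overlapping_gene(self):
        ext = _peakset([{"start": 900, "end": 1000}])
        prom = regulatory.define_promoters(_genes([1000]), 50, 200, external=ext)
        sources = set(prom.intervals.source)
        assert sources == {"tss_window", "external"}

    def test_unknown_strand_warns_and_defaults_to_plus(self):
        genes = _genes([1000], ["."])
        with pytest.warns(UserWarning, match="strand"):
            prom = regulatory.define_promoters(genes, 50, 200)
        rec = prom.intervals.iloc[0]
        assert (rec.start, rec.end) == (950, 1200)


def brute_force_assign(peaks: pd.DataFrame, genes: pd.DataFrame, promoters, max_dist):
    """Naive re-implementation of the three assignment rules."""
    links = []
    prom = promoters.intervals if promoters is not None else pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end"]
    )
    for _, pk in peaks.iterrows():
        summit = pk.start + pk.summit
        over = []
        for _, pr in prom.iterrows():
            if pr.chrom == pk.chrom and pr.start < pk.end and pr.end > pk.start:
                over.append(pr.gene_id)
        over = sorted(set(over))
        if over:
            tss_of = dict(zip(genes.gene_id, genes.tss))
            best = min(over, key=lambda g: (abs(summit - tss_of[g]), g))
            links.append((pk["name"], best, True))
            continue
        for _, gn in genes.iterrows():
            if gn.chrom != pk.chrom or abs(summit - gn.tss) > max_dist:
                continue
            lo, hi = min(summit, gn.tss), max(summit, gn.tss)
            blocked = any(
                (other.chrom == pk.chrom and lo < other.tss < hi)
                for _, other in genes.iterrows()
            )
            if not blocked:
                links.append((pk["name"], gn.gene_id, False))
    return sorted(links)


class TestAssignPeaks:
    def test_summit_between_two_genes_links_both(self):
        ps = _peakset([{"start": 2875, "end": 3125}])  # summit 3000
        asn = regulatory.assign_peaks(ps, _genes([1000, 5000]), None, 20000)
        assert sorted(asn.links.gene_id) == ["gA", "gB"]

    def test_gene_beyond_more_proximal_gene_excluded(self):
        ps = _peakset([{"start": 11875, "end": 12125}])  # summit 12000
        asn = regulatory.assign_peaks(ps, _genes([10000, 1000]), None, 20000)
        assert list(asn.links.gene_id) == ["gA"]  # the TSS-10000 gene

    def test_distance_cap_at_20kb(self):
        ps = _peakset([{"start": 34875, "end": 35125}])  # summit 35000
        asn = regulatory.assign_peaks(ps, _genes([10000]), None, 20000)
        assert len(asn.links) == 0

    def test_promoter_peak_assigned_exclusively(self):
        ps = _peakset([{"start": 950, "end": 1200}])
        genes = _genes([1000, 1100])
        prom = regulatory.define_promoters(genes, 50, 200)
        asn = regulatory.assign_peaks(ps, genes, prom, 20000)
        # overlaps both promoters -> nearest TSS (summit 1075 -> gB), ambiguous
        assert len(asn.links) == 1
        assert asn.links.iloc[0].is_promoter
        assert asn.links.iloc[0].gene_id == "gB"
        assert asn.links.iloc[0].ambiguous

    def test_missing_chromosome_leaves_peak_unassigned(self):
        ps = _peakset([{"start": 100, "end": 350, "chrom": "chrX"}])
        with pytest.warns(UserWarning, match="absent"):
            asn = regulatory.assign_peaks(ps, _genes([1000]), None, 20000)
        assert len(asn.links) == 0

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            n_genes = int(rng.integers(1, 10))
            n_peaks = int(rng.integers(1, 25))
            tss = sorted(rng.choice(100000, size=n_genes, replace=False).tolist())
            genes = _genes(tss, list(rng.choice(["+", "-"], size=n_genes)))
            rows = []
            for _ in range(n_peaks):
                s = int(rng.integers(0, 100000))
                rows.append({"start": s, "end": s + 250, "summit": int(rng.integers(0, 250))})
            ps = _peakset(rows)
            use_prom = rng.random() < 0.5
            prom = regulatory.define_promoters(genes, 50, 200) if use_prom else None
            got = regulatory.assign_peaks(ps, genes, prom, 20000)
            got_set = sorted(
                (r.peak_id, r.gene_id, bool(r.is_promoter))
                for r in got.links.itertuples(index=False)
            )
            assert got_set == brute_force_assign(ps.records, genes, prom, 20000)


class TestCellTypePeakSets:
    def _assignment(self, mapping):
        rows = [
            {"peak_id": p, "gene_id": g, "distance": 0, "is_promoter": False,
             "ambiguous": False}
            for p, g in mapping
        ]
        return regulatory.PeakGeneAssignment(pd.DataFrame(rows), 20000)

    def _fc(self, values, genes, types):
        return pd.DataFrame(values, index=genes, columns=types)

    @pytest.mark.parametrize(
        "fc_value,expected", [(1.6, "high"), (1.3, "mild"), (1.0, "background"), (1.05, None)]
    )
    def test_threshold_routing(self, fc_value, expected):
        asn = self._assignment([("p0", "gA")])
        fc = self._fc([[fc_value]], ["gA"], ["t0"])
        sets = regulatory.celltype_peak_sets(asn, fc)
        where = {
            "high": sets.high["t0"], "mild": sets.mild["t0"],
            "background": sets.background["t0"],
        }
        for name, ids in where.items():
            assert ("p0" in ids) == (name == expected)

    def test_sets_are_disjoint_and_max_rule_applies(self):
        asn = self._assignment([("p0", "gA"), ("p0", "gB")])
        fc = self._fc([[1.6], [0.5]], ["gA", "gB"], ["t0"])
        sets = regulatory.celltype_peak_sets(asn, fc)
        assert sets.high["t0"] == ["p0"]
        assert sets.background["t0"] == []

    def test_unassigned_region_excluded(self):
        asn = self._assignment([("p0", "gZ")])  # gene not in fc table
        fc = self._fc([[2.0]], ["gA"], ["t0"])
        sets = regulatory.celltype_peak_sets(asn, fc)
        assert sets.high["t0"] == [] and sets.background["t0"] == []


def test_coordinate_convention_round_trip(toy_regulome):
    """0-based half-open -> 1-based closed -> back is the identity."""
    r = toy_regulome.peaks
    one_based = r.assign(start=r.start + 1, end=r.end)  # 1-based closed
    back = one_based.assign(start=one_based.start - 1, end=one_based.end)
    pd.testing.assert_frame_equal(back, r)


def test_median_peaks_per_gene_matches_construction(toy_genome, toy_regulome):
    ps = regulatory.PeakSet(toy_regulome.peaks)
    std = regulatory.standardize_peaks(ps, 125, toy_genome.chrom_sizes())
    prom = regulatory.define_promoters(toy_genome.genes)
    asn = regulatory.assign_peaks(std, toy_genome.genes, prom, 20000)
    per_gene = asn.peaks_per_gene()
    assert per_gene.median() == 2  # built with peaks_per_gene=2
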