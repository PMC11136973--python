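"""Motif IC, similarity clustering, scanning, backgrounds, enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcatlas import motifs as mo
from mcatlas import synth
from mcatlas.motifs import MotifPPM


def _ppm_from_ic_pattern(pattern):
    """Columns with IC 0 (uniform), 1 ((.5,.5,0,0)) or 2 (one-hot)."""
    rows = {0: [0.25] * 4, 1: [0.5, 0.5, 0.0, 0.0], 2: [1.0, 0.0, 0.0, 0.0]}
    return MotifPPM("pat", np.array([rows[p] for p in pattern]))


def _one_hot(consensus, mid="onehot"):
    mat = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = 1.0
    return MotifPPM(mid, mat)


class TestColumnIc:
    @pytest.mark.parametrize(
        "row,expected",
        [([0.25, 0.25, 0.25, 0.25], 0.0), ([1, 0, 0, 0], 2.0), ([0.5, 0.5, 0, 0], 1.0)],
    )
    def test_closed_forms(self, row, expected):
        ppm = MotifPPM("x", np.array([row], dtype=float))
        assert mo.column_ic(ppm)[0] == pytest.approx(expected)

    def test_bounds_and_additivity(self):
        ppms = synth.make_motif_ppms(5, 9, seed=0)
        for p in ppms:
            ic = mo.column_ic(p)
            assert np.all((ic >= 0) & (ic <= 2))
            assert p.total_ic() == pytest.approx(ic.sum())

    def test_invalid_ppm_rejected(self):
        with pytest.raises(ValueError):
            MotifPPM("bad", np.array([[0.5, 0.2, 0.2, 0.2]]))


class TestContiguousIcFilter:
    def test_uniform_motif_rejected(self):
        lib = mo.contiguous_ic_filter([_ppm_from_ic_pattern([0] * 8)])
        assert len(lib) == 0

    def test_run_of_four_retained(self):
        lib = mo.contiguous_ic_filter([_ppm_from_ic_pattern([2, 2, 2, 2])])
        assert len(lib) == 1

    def test_two_blocks_of_three_retained(self):
        lib = mo.contiguous_ic_filter([_ppm_from_ic_pattern([1, 1, 1, 0, 1, 1, 1])])
        assert len(lib) == 1

    def test_single_block_of_three_rejected(self):
        lib = mo.contiguous_ic_filter([_ppm_from_ic_pattern([1, 1, 1, 0, 0, 1])])
        assert len(lib) == 0


class TestSimilarity:
    def test_self_similarity_is_one(self):
        m = synth.make_motif_ppms(1, 8, seed=1)[0]
        assert mo.motif_similarity(m, m) == pytest.approx(1.0)

    def test_reverse_complement_similarity_is_one(self):
        m = synth.make_motif_ppms(1, 8, seed=2)[0]
        assert mo.motif_similarity(m, m.reverse_complement()) == pytest.approx(1.0)

    def test_min_overlap_sentinel(self):
        a = _one_hot("ACGT", "a")
        b = _one_hot("ACGT", "b")
        assert mo.motif_similarity(a, b, min_overlap=6) == -1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(6, 12), st.integers(6, 12))
    def test_symmetry(self, seed, wa, wb):
        a = MotifPPM("a", synth._random_ppm(np.random.default_rng(seed), wa, 0.9))
        b = MotifPPM("b", synth._random_ppm(np.random.default_rng(seed + 1), wb, 0.9))
        assert mo.motif_similarity(a, b) == pytest.approx(mo.motif_similarity(b, a))


class TestDedupe:
    def test_single_motif_unchanged(self):
        m = synth.make_motif_ppms(1, 8, seed=3)
        lib = mo.dedupe_library(m)
        assert lib.ids() == [m[0].id]

    def test_copies_plus_outsider_collapse_to_two(self):
        fam = synth.make_motif_families(2, 5, seed=4)
        copies = fam[0]           # 5 variants of one family
        outsider = fam[1][0]      # one dissimilar motif
        lib = mo.dedupe_library(copies + [outsider])
        assert len(lib) == 2
        assert outsider.id in lib.ids()

    def test_retained_pairwise_similarity_below_threshold(self):
        fams = synth.make_motif_families(4, 4, seed=5)
        lib = mo.dedupe_library([m for f in fams for m in f])
        kept = lib.motifs
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert mo.motif_similarity(kept[i], kept[j]) < 0.95

    def test_representative_has_highest_ic(self):
        fams = synth.make_motif_families(3, 5, seed=6)
        flat = [m for f in fams for m in f]
        lib = mo.dedupe_library(flat)
        by_id = {m.id: m for m in flat}
        for rep, members in lib.clusters.items():
            rep_ic = by_id[rep].total_ic()
            assert all(rep_ic >= by_id[m].total_ic() - 1e-12 for m in members)


class TestScan:
    def test_planted_consensus_found_at_offset_with_fraction_one(self):
        m = _one_hot("ACGTACGTAA")
        region = "T" * 17 + "ACGTACGTAA" + "G" * 13
        hits = mo.scan_regions({"r": region}, [m], 0.8)
        exact = [h for h in hits if h.score_fraction == pytest.approx(1.0)]
        assert any(h.offset == 17 and h.strand == "+" for h in exact)

    def test_fraction_one_keeps_only_exact_consensus(self):
        m = _one_hot("ACGTACGTAA")
        near = "T" * 5 + "ACGTACGTAT" + "G" * 5  # one mismatch
        hits = mo.scan_regions({"r": near}, [m], score_fraction_min=1.0)
        assert hits == []

    def test_region_of_ns_has_no_hits(self):
        m = _one_hot("ACGTACGT")
        assert mo.scan_regions({"r": "N" * 50}, [m], 0.5) == []

    def test_region_shorter_than_motif_is_not_an_error(self):
        m = _one_hot("ACGTACGT")
        assert mo.scan_regions({"r": "ACG"}, [m], 0.5) == []

    def test_lowering_threshold_never_removes_hits(self):
        rng = np.random.default_rng(7)
        region = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        m = synth.make_motif_ppms(1, 8, seed=8)[0]
        strict = {(h.offset, h.strand) for h in mo.scan_regions({"r": region}, [m], 0.8)}
        loose = {(h.offset, h.strand) for h in mo.scan_regions({"r": region}, [m], 0.6)}
        assert strict <= loose

    def test_best_only_keeps_single_top_hit(self):
        m = _one_hot("ACGT" * 2)
        region = "ACGTACGT" + "TT" + "ACGTACGT"
        hits = mo.scan_regions({"r": region}, [m], 0.5, best_only=True)
        assert len(hits) == 1
        assert hits[0].offset == 0  # leftmost on tie


@pytest.fixture(scope="module")
def setup():
    genome = synth.make_genome(5, 1_500_000, 0.42, 10000, seed=9)
    rng = np.random.default_rng(9)
    fg = {}
    for i in range(100):
        s = int(rng.integers(0, 1_500_000 - 250))
        fg[f"fg{i}"] = ("chr1", s, s + 250)
    bg = mo.sample_matched_background(fg, genome, multiple=2, n_gc_bins=10, seed=10)
    return genome, fg, bg


class TestMatchedBackground:
    def test_twice_as_many_background_regions(self, setup):
        _, fg, bg = setup
        assert len(bg) == 2 * len(fg)

    def test_background_lengths_match(self, setup):
        _, _, bg = setup
        assert all(e - s == 250 for _, s, e in bg.values())

    def test_no_overlap_with_foreground(self, setup):
        _, fg, bg = setup
        for _, (c1, s1, e1) in bg.items():
            for _, (c2, s2, e2) in fg.items():
                assert not (c1 == c2 and s1 < e2 and s2 < e1)

    def test_gc_matched_per_bin(self, setup):
        genome, fg, bg = setup
        fg_gc = np.array([mo.gc_content(genome.fetch(c, s, e)) for c, s, e in fg.values()])
        bg_gc = np.array([mo.gc_content(genome.fetch(c, s, e)) for c, s, e in bg.values()])
        assert abs(fg_gc.mean() - bg_gc.mean()) < 0.02


def exact_binom_sf(k, n, p):
    """Independent exact tail sum P(X >= k)."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


class TestEnrichment:
    def _hits(self, region_motif_pairs):
        return [mo.MotifHit(r, m, 0, "+", 1.0, 1.0) for r, m in region_motif_pairs]

    def test_equal_rates_give_near_zero_log2fc(self):
        fg = [f"f{i}" for i in range(20)]
        bg = [f"b{i}" for i in range(40)]
        hits = self._hits([(r, "m") for r in fg[:10]] + [(r, "m") for r in bg[:20]])
        out = mo.binned_enrichment({("t", "high"): fg}, bg, hits, ["m"])
        row = out.iloc[0]
        assert abs(row.log2fc) < 0.1
        assert row.p_adj > 0.1

    def test_extreme_enrichment_matches_closed_form(self):
        fg = [f"f{i}" for i in range(10)]
        bg = [f"b{i}" for i in range(20)]
        hits = self._hits([(r, "m") for r in fg])  # 10/10 fg, 0/20 bg
        out = mo.binned_enrichment({("t", "high"): fg}, bg, hits, ["m"])
        p0 = 0.5 / 21
        assert out.iloc[0].p_value == pytest.approx(exact_binom_sf(10, 10, p0), abs=1e-15)

    def test_binomial_tail_matches_exact_summation(self):
        from scipy.stats import binom

        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            assert binom.sf(k - 1, n, p) == pytest.approx(exact_binom_sf(k, n, p), abs=1e-12)

    def test_bh_of_three_pvalues(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_adjusted_never_below_raw(self):
        fg = [f"f{i}" for i in range(15)]
        bg = [f"b{i}" for i in range(30)]
        rng = np.random.default_rng(12)
        pairs = [(r, m) for m in "abc" for r in fg if rng.random() < 0.4]
        pairs += [(r, m) for m in "abc" for r in bg if rng.random() < 0.3]
        out = mo.binned_enrichment({("t", "high"): fg}, bg, self._hits(pairs), list("abc"))
        assert (out.p_adj >= out.p_value - 1e-15).all()
        assert (out.p_adj <= 1.0).all()

    def test_empty_foreground_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty foreground"):
            out = mo.binned_enrichment({("t", "high"): []}, ["b0"], [], ["m"])
        assert len(out) == 0


class TestEmpiricalP:
    def test_score_above_all_backgrounds(self):
        fg = {"r0": 10.0}
        bg = {f"b{i}": float(i) / 100 for i in range(100)}
        gc = {k: 0.5 for k in list(fg) + list(bg)}
        out = mo.empirical_hit_pvalue(fg, bg, gc, gc, n_gc_bins=1)
        assert out.iloc[0].empirical_p == pytest.approx(1 / 101)

    def test_score_below_all_backgrounds(self):
        fg = {"r0": -5.0}
        bg = {f"b{i}": float(i) for i in range(50)}
        gc = {k: 0.5 for k in list(fg) + list(bg)}
        out = mo.empirical_hit_pvalue(fg, bg, gc, gc, n_gc_bins=1)
        assert out.iloc[0].empirical_p == pytest.approx(1.0)

    def test_empty_bin_flagged_undefined(self):
        fg = {"r0": 1.0}
        out = mo.empirical_hit_pvalue(fg, {}, {"r0": 0.5}, {}, n_gc_bins=1)
        assert out.iloc[0].undefined
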