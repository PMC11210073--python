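import math
from math import comb

import numpy as np
import pytest
from scipy import stats

from tadhub.boundary_levels import extract_boundaries
from tadhub.enrichment import (
    ContingencyTable,
    assign_gene_boundary_levels,
    bin_group_summary,
    classify_genome_bins,
    compartment_fraction_by_level,
    enrichment_vs_background,
    fisher_exact,
    fraction_overlapping,
    gene_set_boundary_enrichment,
    overlap_fraction_by_level,
    profile_matrix,
    random_level0_control,
)
from tadhub.genome_io import GeneRecord, GenomicInterval, SignalTrack
from tests.conftest import RES, make_tads


def fisher_oracle(a, b, c, d):
    """Exact-rational enumeration of the two-sided Fisher p-value."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, r1)
    k_lo, k_hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: comb(c1, k) * comb(n - c1, r1 - k) for k in range(k_lo, k_hi + 1)}
    p_obs = probs[a]
    return sum(v for v in probs.values() if v <= p_obs) / denom


class TestFisher:
    def test_symmetric_table_p_one(self):
        r = fisher_exact(ContingencyTable(5, 5, 5, 5))
        assert r.p_two_sided == pytest.approx(1.0, abs=1e-12)
        assert r.odds_ratio == pytest.approx(1.0)

    def test_small_table_enumeration(self):
        # margins (4,4)/(4,4): five possible tables, direct enumeration
        r = fisher_exact(ContingencyTable(3, 1, 1, 3))
        assert r.p_two_sided == pytest.approx(fisher_oracle(3, 1, 1, 3), abs=1e-12)
        assert r.p_two_sided == pytest.approx(0.48571428571428565, abs=1e-9)

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if a + b + c + d == 0:
                continue
            r = fisher_exact(ContingencyTable(a, b, c, d))
            assert r.p_two_sided == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12
            ), (a, b, c, d)

    def test_cross_check_against_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if a + b + c + d == 0:
                continue
            ours = fisher_exact(ContingencyTable(a, b, c, d)).p_two_sided
            ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_odds_ratio_conventions(self):
        assert math.isinf(fisher_exact(ContingencyTable(5, 0, 0, 5)).odds_ratio)
        assert math.isnan(fisher_exact(ContingencyTable(0, 5, 0, 5)).odds_ratio)
        assert fisher_exact(ContingencyTable(6, 2, 3, 4)).odds_ratio == pytest.approx(4.0)

    def test_degenerate_margin_p_one(self):
        assert fisher_exact(ContingencyTable(0, 0, 5, 5)).p_two_sided == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


def _two_level_set():
    # level-1 boundaries at bins 10..90, a level-4 anchor at bin 200
    spans = [("chr1", b * RES, (b + 5) * RES) for b in range(10, 90, 10)]
    spans += [("chr1", 200 * RES, (200 + k) * RES) for k in (5, 8, 11, 14)]
    return extract_boundaries(make_tads(spans), RES)


class TestOverlapFractions:
    def test_full_coverage_all_one(self):
        bset = _two_level_set()
        genome = [GenomicInterval("chr1", 0, 10_000_000)]
        frac = overlap_fraction_by_level(bset, genome)
        assert all(v == 1.0 for v in frac.values())

    def test_no_features_all_zero(self):
        frac = overlap_fraction_by_level(_two_level_set(), [])
        assert all(v == 0.0 for v in frac.values())

    def test_invariant_to_order_split_duplicates(self):
        bset = _two_level_set()
        base = [GenomicInterval("chr1", 95_000, 130_000),
                GenomicInterval("chr1", 2_000_000, 2_010_000)]
        split = [GenomicInterval("chr1", 95_000, 100_000),
                 GenomicInterval("chr1", 100_000, 130_000),
                 GenomicInterval("chr1", 2_000_000, 2_010_000)]
        dup = base + base
        f0 = overlap_fraction_by_level(bset, base)
        assert overlap_fraction_by_level(bset, split) == f0
        assert overlap_fraction_by_level(bset, dup) == f0
        assert overlap_fraction_by_level(bset, base[::-1]) == f0

    def test_padding_widens_hits(self):
        bset = _two_level_set()
        feature = [GenomicInterval("chr1", 115_000, 116_000)]  # bin 11
        assert overlap_fraction_by_level(bset, feature, pad_bins=0)[1] == 0.0
        assert overlap_fraction_by_level(bset, feature, pad_bins=1)[1] > 0.0


class TestRandomControl:
    SIZES = {"chr1": 5_000_000}

    def test_matches_count_and_avoids_boundaries(self):
        bset = _two_level_set()
        ctrl = random_level0_control(bset, self.SIZES, seed=9)
        assert len(ctrl) == len(bset)
        bad = bset.bin_keys()
        assert all((iv.chrom, iv.start // RES) not in bad for iv in ctrl)
        assert len({(iv.chrom, iv.start) for iv in ctrl}) == len(ctrl)

    def test_same_seed_identical(self):
        bset = _two_level_set()
        a = random_level0_control(bset, self.SIZES, seed=5)
        b = random_level0_control(bset, self.SIZES, seed=5)
        assert [(i.chrom, i.start) for i in a] == [(i.chrom, i.start) for i in b]

    def test_not_enough_bins_rejected(self):
        bset = _two_level_set()
        with pytest.raises(ValueError):
            random_level0_control(bset, {"chr1": 20 * RES}, seed=0)

    def test_control_fraction_matches_coverage_expectation(self):
        bset = _two_level_set()
        rng = np.random.default_rng(2)
        # scatter features covering ~30% of bins uniformly
        nbins = self.SIZES["chr1"] // RES
        chosen = rng.choice(nbins, size=int(0.3 * nbins), replace=False)
        feats = [GenomicInterval("chr1", int(b) * RES, (int(b) + 1) * RES) for b in chosen]
        fracs = [
            fraction_overlapping(random_level0_control(bset, self.SIZES, seed=s), feats)
            for s in range(30)
        ]
        p = len(chosen) / nbins
        sd = math.sqrt(p * (1 - p) / len(bset))
        assert abs(np.mean(fracs) - p) < 3 * sd


class TestEnrichmentVsBackground:
    def test_perfect_separation(self):
        group = [GenomicInterval("chr1", i * RES, (i + 1) * RES) for i in range(10)]
        bg = [GenomicInterval("chr1", i * RES, (i + 1) * RES) for i in range(100, 110)]
        feats = [GenomicInterval("chr1", 0, 10 * RES)]
        r = enrichment_vs_background(group, bg, feats)
        assert math.isinf(r.odds_ratio)
        assert r.p_two_sided < 1e-4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            enrichment_vs_background([], [GenomicInterval("chr1", 0, 10)], [])

    def test_null_is_calibrated(self):
        # group and background drawn from the same distribution
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 300
        for _ in range(reps):
            hits_g = rng.binomial(1, 0.3, size=120)
            hits_b = rng.binomial(1, 0.3, size=120)
            table = ContingencyTable(
                int(hits_g.sum()), int(120 - hits_g.sum()),
                int(hits_b.sum()), int(120 - hits_b.sum()),
            )
            if fisher_exact(table).p_two_sided < 0.05:
                rejections += 1
        assert rejections / reps < 0.08

    def test_planted_odds_ratio_recovered(self):
        rng = np.random.default_rng(4)
        base = 0.2
        odds4 = 3.0 * base / (1 - base)
        p4 = odds4 / (1 + odds4)
        ors = []
        for _ in range(50):
            a = int(rng.binomial(500, p4))
            c = int(rng.binomial(500, base))
            r = fisher_exact(ContingencyTable(a, 500 - a, c, 500 - c))
            ors.append(r.odds_ratio)
        assert 2.4 <= float(np.median(ors)) <= 3.75


class TestProfileMatrix:
    def test_uniform_track_fills_cells(self):
        bset = _two_level_set()
        track = SignalTrack([("chr1", 0, 10_000_000, 2.5)])
        pm = profile_matrix(bset, track)
        assert pm.n_columns == 20
        assert np.allclose(pm.matrix[~np.isnan(pm.matrix)], 2.5)
        assert np.allclose(pm.aggregate, 2.5)

    def test_delta_signal_lands_in_central_columns(self):
        bset = _two_level_set()
        b = bset.boundaries[0]
        center = b.position + RES // 2
        track = SignalTrack([("chr1", center - 1, center + 1, 100.0)])
        pm = profile_matrix(bset, track)
        row = pm.matrix[0]
        nz = np.flatnonzero(np.nan_to_num(row))
        assert set(nz) <= {9, 10}
        assert row[nz].sum() > 0

    def test_chromosome_edge_bins_clipped(self):
        spans = [("chr1", 0, 5 * RES)]
        bset = extract_boundaries(make_tads(spans), RES)
        track = SignalTrack([("chr1", 0, 50 * RES, 1.0)])
        pm = profile_matrix(bset, track, chrom_sizes={"chr1": 60 * RES})
        # the boundary at position 0 has flank extending below 0
        row0 = pm.matrix[0]
        assert np.isnan(row0[0])

    def test_flank_not_multiple_of_bin_rejected(self):
        with pytest.raises(ValueError):
            profile_matrix(_two_level_set(), SignalTrack(), bin_width=7000)


class TestGenomeBins:
    SIZES = {"chr1": 100 * RES}

    def test_bin_tiling_count(self):
        bins = classify_genome_bins(
            {"chr1": 100_000}, RES, _empty_set(), SignalTrack(), []
        )
        assert len(bins) == 10

    def test_zero_signal_is_category_zero(self):
        bins = classify_genome_bins(self.SIZES, RES, _empty_set(), SignalTrack(), [])
        assert all(b.dnase_cat == 0 for b in bins)

    def test_positive_bins_split_into_tertiles(self):
        track = SignalTrack(
            [("chr1", i * RES, (i + 1) * RES, float(i + 1)) for i in range(60)]
        )
        bins = classify_genome_bins(self.SIZES, RES, _empty_set(), track, [])
        cats = [b.dnase_cat for b in bins if b.dnase_cat > 0]
        assert len(cats) == 60
        counts = np.bincount(cats)[1:]
        assert counts.max() - counts.min() <= 1
        # ascending signal => first 20 bins are cat 1, last 20 cat 3
        assert bins[0].dnase_cat == 1 and bins[59].dnase_cat == 3

    def test_dsb_peak_spanning_edge_counts_in_both_bins(self):
        dsbs = [GenomicInterval("chr1", 9_000, 11_000)]
        bins = classify_genome_bins(self.SIZES, RES, _empty_set(), SignalTrack(), dsbs)
        assert bins[0].dsb_count == 1 and bins[1].dsb_count == 1
        assert sum(b.dsb_count for b in bins) >= len(dsbs)

    def test_levels_and_genes_assigned(self):
        bset = _two_level_set()
        genes = [GeneRecord("g", "chr1", 105_000, "+", 1000, 9.0)]
        bins = classify_genome_bins(
            {"chr1": 3_000_000}, RES, bset, SignalTrack(), [], genes
        )
        by_bin = {(b.chrom, b.start // RES): b for b in bins}
        assert by_bin[("chr1", 200)].level == 4
        assert by_bin[("chr1", 10)].level == 1
        assert by_bin[("chr1", 11)].level == 0
        assert by_bin[("chr1", 10)].gene_ids == ["g"]

    def test_group_summary_totals_and_active_cut(self):
        bset = _two_level_set()
        genes = [
            GeneRecord("a", "chr1", 105_000, "+", 1000, 9.0),
            GeneRecord("b", "chr1", 115_000, "+", 1000, 4.9),
        ]
        bins = classify_genome_bins(
            {"chr1": 3_000_000}, RES, bset, SignalTrack(), [], genes
        )
        df = bin_group_summary(bins)
        assert df["n_bins"].sum() == len(bins)
        assert df["n_active_genes"].sum() == 1  # FPKM > 5 only


def _empty_set():
    from tadhub.boundary_levels import BoundarySet

    return BoundarySet(resolution=RES, cell_line="x", boundaries=[])


class TestGeneLevels:
    def test_tss_in_boundary_bin(self):
        bset = _two_level_set()
        genes = [GeneRecord("g", "chr1", 2_005_000, "+", 1000, 1.0)]
        assert assign_gene_boundary_levels(genes, bset)["g"] == 4

    def test_promoter_spanning_two_boundaries_takes_max(self):
        spans = [("chr1", 100 * RES, 105 * RES)]  # level-1 at bins 100, 105
        spans += [("chr1", 101 * RES, (101 + k) * RES) for k in (5, 8, 11, 14)]
        bset = extract_boundaries(make_tads(spans), RES)
        # TSS at the very start of bin 101; promoter reaches back into bin 100
        genes = [GeneRecord("g", "chr1", 101 * RES, "+", 1000, 1.0)]
        assert assign_gene_boundary_levels(genes, bset, promoter_pad=1000)["g"] == 4

    def test_far_gene_level_zero(self):
        bset = _two_level_set()
        genes = [GeneRecord("g", "chr1", 9_000_000, "+", 1000, 1.0)]
        assert assign_gene_boundary_levels(genes, bset)["g"] == 0

    def test_flagged_enrichment_detects_planted_bias(self):
        rng = np.random.default_rng(5)
        gene_levels = {}
        flagged = set()
        for i in range(400):
            gid = f"g{i}"
            if i < 100:
                flagged.add(gid)
                gene_levels[gid] = int(rng.random() < 0.6)
            else:
                gene_levels[gid] = int(rng.random() < 0.2)
        r = gene_set_boundary_enrichment(gene_levels, flagged)
        assert r.odds_ratio > 1
        assert r.p_two_sided < 0.01

    def test_flagged_null_not_significant_on_average(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(50):
            gene_levels = {f"g{i}": int(rng.random() < 0.3) for i in range(200)}
            flagged = {f"g{i}" for i in rng.choice(200, size=50, replace=False)}
            pvals.append(gene_set_boundary_enrichment(gene_levels, flagged).p_two_sided)
        assert np.mean([p < 0.05 for p in pvals]) < 0.15

    def test_empty_flagged_rejected(self):
        with pytest.raises(ValueError):
            gene_set_boundary_enrichment({"g": 1}, set())


class TestCompartments:
    def test_all_A_genome(self):
        bset = _two_level_set()
        comps = [GenomicInterval("chr1", 0, 10_000_000, name="A")]
        frac, control = compartment_fraction_by_level(bset, comps)
        assert all(v == 1.0 for v in frac.values())
        assert control == 1.0

    def test_half_and_half_control(self):
        bset = _two_level_set()
        comps = [
            GenomicInterval("chr1", 0, 5_000_000, name="A"),
            GenomicInterval("chr1", 5_000_000, 10_000_000, name="B"),
        ]
        frac, control = compartment_fraction_by_level(bset, comps)
        assert control == 0.5
        assert all(v == 1.0 for v in frac.values())  # all boundaries < 5 Mb

    def test_unlabeled_gap_excluded(self):
        bset = _two_level_set()
        comps = [GenomicInterval("chr1", 0, 1_000_000, name="A")]
        frac, _ = compartment_fraction_by_level(bset, comps)
        # only boundaries below 1 Mb enter the denominator; level 4 at 2 Mb absent
        assert 4 not in frac

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            compartment_fraction_by_level(
                _two_level_set(), [GenomicInterval("chr1", 0, 100, name="C")]
            )
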