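"""Interval logic, enrichment, coverage aggregation, differential binding."""

import numpy as np
import pandas as pd
import pytest

from lofpipe import genomic, simulate


def intervals(rows, chrom="chrS"):
    return pd.DataFrame(
        [{"chrom": chrom, "start": s, "end": e, "name": f"p{i}"}
         for i, (s, e) in enumerate(rows)]
    )


def tss_table(positions, chrom="chrS"):
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(positions))],
        "chrom": chrom, "position": positions, "strand": "+",
    })


class TestRegulatoryClassification:
    def test_peak_near_tss_is_promoter(self):
        out = genomic.classify_regulatory_regions(
            intervals([(5000, 5200)]), tss_table([5500])
        )
        assert out["klass"].iloc[0] == "promoter"
        assert out["distance"].iloc[0] == 300

    def test_distant_peak_is_enhancer(self):
        out = genomic.classify_regulatory_regions(
            intervals([(5000, 5200)]), tss_table([10000])
        )
        assert out["klass"].iloc[0] == "enhancer"

    def test_peak_spanning_tss_distance_zero(self):
        out = genomic.classify_regulatory_regions(
            intervals([(5000, 5200)]), tss_table([5100])
        )
        assert out["klass"].iloc[0] == "promoter"
        assert out["distance"].iloc[0] == 0

    def test_every_peak_labeled_exactly_once(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 100_000, size=50)
        peaks = intervals([(s, s + 200) for s in starts])
        out = genomic.classify_regulatory_regions(
            peaks, tss_table(sorted(rng.integers(0, 100_000, size=20)))
        )
        assert len(out) == 50
        assert set(out["klass"]) <= {"promoter", "enhancer"}


class TestClosestGene:
    def test_peak_inside_gene_body(self):
        genes = pd.DataFrame({"chrom": "chrS", "start": [100], "end": [1000],
                              "gene_id": ["g0"]})
        out = genomic.assign_regions_to_genes(intervals([(200, 300)]), genes)
        assert out["gene_id"].iloc[0] == "g0"
        assert out["distance"].iloc[0] == 0

    def test_equidistant_tie_prefers_leftmost_gene(self):
        out = genomic.assign_regions_to_genes(
            intervals([(2000, 2200)]), tss_table([1000, 3200])
        )
        assert out["gene_id"].iloc[0] == "g0"  # both at distance 1000

    def test_matches_bruteforce_minimizer(self):
        rng = np.random.default_rng(7)
        peaks = intervals(
            [(s, s + int(rng.integers(50, 500)))
             for s in rng.integers(0, 500_000, size=20)]
        )
        positions = rng.integers(0, 500_000, size=10)
        genes = tss_table(positions)
        out = genomic.assign_regions_to_genes(peaks, genes)
        for i, prow in peaks.iterrows():
            dists = genomic.interval_point_distance(
                prow["start"], prow["end"], positions
            )
            candidates = sorted(
                (d, p, f"g{j}") for j, (d, p) in enumerate(zip(dists, positions))
            )
            assert out["gene_id"].iloc[i] == candidates[0][2]
            assert out["distance"].iloc[i] == candidates[0][0]

    def test_peak_on_geneless_chromosome_flagged(self):
        peaks = pd.concat([intervals([(10, 20)]),
                           intervals([(10, 20)], chrom="chrX")],
                          ignore_index=True)
        out = genomic.assign_regions_to_genes(peaks, tss_table([100]))
        assert out["gene_id"].iloc[1] is None
        assert np.isnan(out["distance"].iloc[1])

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            genomic.assign_regions_to_genes(intervals([(0, 10)]),
                                            pd.DataFrame())


class TestBindingEnrichment:
    def test_odds_ratio_arithmetic(self):
        bound = {f"b{i}" for i in range(100)}
        klass = {f"b{i}" for i in range(30)} | {f"c{i}" for i in range(70)}
        background = bound | klass | {f"x{i}" for i in range(830)}
        table, oratio, _ = genomic.binding_enrichment(bound, klass, background)
        assert table.tolist() == [[30, 70], [70, 830]]
        assert oratio == pytest.approx((30 * 830) / (70 * 70))

    def test_independent_sets_give_or_near_one(self):
        rng = np.random.default_rng(1)
        background = {f"g{i}" for i in range(2000)}
        bound = set(rng.choice(sorted(background), 400, replace=False))
        klass = set(rng.choice(sorted(background), 400, replace=False))
        _, oratio, p = genomic.binding_enrichment(bound, klass, background)
        assert 0.6 < oratio < 1.7
        assert p > 0.001

    def test_class_equal_background_rejected(self):
        bg = {"a", "b", "c"}
        with pytest.raises(ValueError):
            genomic.binding_enrichment({"a"}, bg, bg)


class TestFunctionalPartition:
    def make_inputs(self):
        peaks = intervals([(0, 100), (200, 300), (400, 500)])
        assignment = pd.DataFrame({"peak_index": [0, 1, 2],
                                   "gene_id": ["g0", "g1", "g2"],
                                   "distance": [0, 0, 0]})
        de = pd.DataFrame({"gene_id": ["g0", "g1", "g2"],
                           "log2fc": [-2.0, -1.5, 0.5],
                           "basemean": [100.0] * 3,
                           "q": [0.001, 0.2, 0.001]})
        return peaks, assignment, de

    def test_partition_by_significant_downregulation(self):
        peaks, assignment, de = self.make_inputs()
        fn, rest = genomic.functional_binding_partition(peaks, assignment, de)
        assert list(fn["assigned_gene"]) == ["g0"]  # down & significant
        assert len(fn) + len(rest) == 3

    def test_zero_threshold_gives_no_functional_peaks(self):
        peaks, assignment, de = self.make_inputs()
        fn, _ = genomic.functional_binding_partition(peaks, assignment, de,
                                                     q_threshold=0.0)
        assert fn.empty

    def test_recovers_simulated_truth(self):
        art = simulate.gen_regulatory_landscape(
            simulate.LandscapeSimConfig(n_genes=300, genome_length=3_500_000,
                                        n_active_peaks=120, n_tf_peaks=60,
                                        seed=5)
        )
        assignment = genomic.assign_regions_to_genes(art["tf_peaks"], art["tss"])
        fn, rest = genomic.functional_binding_partition(
            art["tf_peaks"], assignment, art["de"]
        )
        expected = art["truth"].bound_gene_ids & art["truth"].down_gene_ids
        assert set(fn["assigned_gene"]) == expected
        assert not set(rest["assigned_gene"]) & expected

    def test_no_de_information_rejected(self):
        peaks, assignment, de = self.make_inputs()
        assignment["gene_id"] = ["zz0", "zz1", "zz2"]
        with pytest.raises(ValueError):
            genomic.functional_binding_partition(peaks, assignment, de)


def step_track(segments, chrom="chrS"):
    return genomic.CoverageTrack.from_bedgraph(pd.DataFrame(
        [{"chrom": chrom, "start": s, "end": e, "value": v}
         for s, e, v in segments]
    ))


def per_base_oracle(segments, a, b):
    """Mean signal over [a, b) by explicit per-base summation."""
    total = 0.0
    for s, e, v in segments:
        for pos in range(max(a, s), min(b, e)):
            total += v
    return total / (b - a)


class TestAggregateSignal:
    def test_constant_track(self):
        track = step_track([(0, 100_000, 2.0)])
        mat, col_means, oob = genomic.aggregate_signal(
            intervals([(40_000, 40_400)]), track, flank=1000, bin_size=10
        )
        assert mat.shape == (1, 200)
        assert np.allclose(mat, 2.0)
        assert not oob.any()

    def test_column_count_arithmetic(self):
        track = step_track([(0, 10, 1.0)])
        mat, _, _ = genomic.aggregate_signal(
            intervals([(50_000, 50_100)]), track, flank=10_000, bin_size=10
        )
        assert mat.shape[1] == 2000

    def test_step_track_matches_per_base_oracle(self):
        segments = [(0, 55, 1.0), (55, 130, 3.5), (200, 260, 0.25)]
        track = step_track(segments)
        regions = intervals([(90, 110)])  # center 100, window [60, 140)
        mat, _, _ = genomic.aggregate_signal(regions, track, flank=40, bin_size=10)
        for j in range(8):
            a, b = 60 + 10 * j, 70 + 10 * j
            assert mat[0, j] == pytest.approx(per_base_oracle(segments, a, b))

    def test_total_signal_conservation(self):
        rng = np.random.default_rng(3)
        edges = np.sort(rng.choice(np.arange(1, 400), 30, replace=False))
        segments = [(int(a), int(b), float(rng.uniform(0, 4)))
                    for a, b in zip(edges[:-1], edges[1:])]
        track = step_track(segments)
        regions = intervals([(150, 250)])  # window [100, 300) covers all edges
        mat, _, _ = genomic.aggregate_signal(regions, track, flank=100, bin_size=10)
        oracle_total = sum(per_base_oracle(segments, 100 + 10 * j, 110 + 10 * j)
                           for j in range(20))
        assert mat[0].sum() == pytest.approx(oracle_total, rel=1e-9)

    def test_out_of_bounds_bins_zero_and_flagged(self):
        track = step_track([(0, 1000, 1.0)])
        mat, _, oob = genomic.aggregate_signal(
            intervals([(0, 20)]), track, flank=100, bin_size=10
        )
        assert oob[0, 0]  # leftmost bin starts below position 0
        assert mat[0, 0] == 0.0

    def test_bad_bin_rejected(self):
        track = step_track([(0, 10, 1.0)])
        with pytest.raises(ValueError):
            genomic.aggregate_signal(intervals([(0, 10)]), track, 100, 0)


class TestFoldChange:
    def test_identical_tracks_give_zero(self):
        t = step_track([(0, 1000, 2.0)])
        fc = genomic.region_signal_fold_change(intervals([(100, 300)]), t, t)
        assert fc["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_global_scaling_removed(self):
        ta = step_track([(0, 1000, 4.0)])
        tb = step_track([(0, 1000, 2.0)])
        fc = genomic.region_signal_fold_change(intervals([(100, 300)]), ta, tb)
        assert fc["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_local_doubling_detected(self):
        base = [(0, 500, 1.0), (500, 600, 1.0), (600, 2000, 1.0)]
        doubled = [(0, 500, 1.0), (500, 600, 2.0), (600, 2000, 1.0)]
        ta, tb = step_track(doubled), step_track(base)
        fc = genomic.region_signal_fold_change(
            intervals([(500, 600), (1000, 1100)]), ta, tb, pseudocount=0.0
        )
        assert fc["log2fc"].iloc[0] > fc["log2fc"].iloc[1]

    def test_zero_total_signal_rejected(self):
        ta = step_track([(0, 10, 0.0)])
        tb = step_track([(0, 10, 1.0)])
        with pytest.raises(ValueError):
            genomic.region_signal_fold_change(intervals([(0, 10)]), ta, tb)


class TestDifferentialBinding:
    def test_identical_counts_nothing_significant(self):
        counts = np.array([[10, 12], [3, 5], [40, 38]])
        res = genomic.differential_binding(counts, counts)
        assert not res["significant"].any()
        assert np.allclose(res["log2fc"], 0.0)

    def test_extreme_region_significant(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 30, size=50)
        a = np.concatenate([[40], base])
        b = np.concatenate([[0], base])
        res = genomic.differential_binding(a[:, None], b[:, None])
        assert res["significant"].iloc[0]
        assert res["q"].iloc[1:].min() > 0.05

    def test_swapping_conditions_negates_log2fc(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 50, size=(30, 2))
        b = rng.integers(0, 50, size=(30, 3))
        r1 = genomic.differential_binding(a, b)
        r2 = genomic.differential_binding(b, a)
        assert np.allclose(r1["log2fc"], -r2["log2fc"])
        assert np.allclose(r1["p"], r2["p"])

    def test_all_zero_region_excluded(self):
        a = np.array([[0], [10]])
        b = np.array([[0], [12]])
        res = genomic.differential_binding(a, b)
        assert not res["tested"].iloc[0]
        assert res["p"].iloc[0] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            genomic.differential_binding(np.array([[-1]]), np.array([[2]]))
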