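"""Interaction calling, empirical background, networks, JI/OCE dynamics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from enhdyn.interactions import (
    BackgroundModel,
    all_node_dynamics,
    bin_pairs,
    build_network,
    call_interactions,
    compare_de_dynamics,
    distal_peak_enrichment,
    dynamic_expression_correlation,
    enrichment_vs_negative,
    fit_background,
    interaction_stats,
    map_bins_to_features,
    nearest_gene_fraction,
    node_dynamics,
)
from enhdyn.regions import GenomicRegion


def pairs_frame(rows):
    return pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])


PROBES = pd.DataFrame({
    "id": ["P1", "N1"],
    "chrom": ["chr1", "chr1"],
    "start": [10_000, 200_000],
    "end": [12_000, 202_000],
    "probe_class": ["promoter", "negative_control"],
})


class TestBinPairs:
    def test_pair_supports_anchor_and_bin(self):
        pairs = pairs_frame([("chr1", 10_500, "chr1", 50_500)])
        sup = bin_pairs(pairs, PROBES)
        row = sup[sup["anchor_id"] == "P1"].iloc[0]
        assert row["bin_start"] == 50_000
        assert row["support"] == 1
        # midpoints: anchor 11000, bin 51000
        assert row["distance"] == 40_000

    def test_seven_identical_pairs_give_support_seven(self):
        pairs = pairs_frame([("chr1", 10_500, "chr1", 50_500)] * 7)
        sup = bin_pairs(pairs, PROBES)
        assert sup.loc[sup["anchor_id"] == "P1", "support"].iloc[0] == 7

    def test_trans_pairs_dropped(self):
        pairs = pairs_frame([("chr1", 10_500, "chr2", 50_500)])
        assert bin_pairs(pairs, PROBES).empty

    def test_distance_cap(self):
        pairs = pairs_frame([("chr1", 10_500, "chr1", 9_000_000)])
        assert bin_pairs(pairs, PROBES, max_distance=2_000_000).empty

    def test_pair_with_both_ends_in_probes_counts_once_per_anchor(self):
        pairs = pairs_frame([("chr1", 10_500, "chr1", 200_500)])
        sup = bin_pairs(pairs, PROBES)
        assert set(sup["anchor_id"]) == {"P1", "N1"}
        assert (sup["support"] == 1).all()

    def test_invalid_bin_size(self):
        with pytest.raises(ValueError):
            bin_pairs(pairs_frame([]), PROBES, bin_size=0)


class TestBackground:
    def test_tail_probability_with_pseudocount(self):
        model = BackgroundModel(
            edges=np.array([2000.0, 2_000_000.0]),
            n_slots=np.array([6]),
            nonzero_values=[np.array([1, 1, 2, 6])],  # plus two zeros
        )
        assert model.tail_p(6, 10_000)[0] == pytest.approx(2 / 7)
        assert model.tail_p(2, 10_000)[0] == pytest.approx((2 + 1) / 7)
        assert model.tail_p(0, 10_000)[0] == pytest.approx(1.0)
        assert model.tail_p(100, 10_000)[0] == pytest.approx(1 / 7)

    def test_all_zero_background(self):
        model = BackgroundModel(edges=np.array([2000.0, 2_000_000.0]),
                                n_slots=np.array([99]),
                                nonzero_values=[np.array([])])
        assert model.tail_p(1, 5000)[0] == pytest.approx(1 / 100)
        assert model.tail_p(0, 5000)[0] == pytest.approx(1.0)

    def test_fit_background_counts_zero_slots(self):
        sup = pd.DataFrame({
            "anchor_id": ["N1"], "chrom": ["chr1"], "bin_start": [150_000],
            "distance": [51_000], "support": [3]})
        neg = PROBES[PROBES["probe_class"] == "negative_control"]
        model = fit_background(sup, neg, {"chr1": 1_000_000},
                               max_distance=100_000, n_distance_bins=3,
                               min_obs=5)
        # slots: all bins within 100 kb of N1's midpoint, zeros included
        assert model.n_slots.sum() > 90
        p = model.tail_p(3, 51_000)[0]
        n = model.n_slots[model.distance_bin(51_000)[0]]
        assert p == pytest.approx(2 / (n + 1))

    def test_no_negative_controls_rejected(self):
        with pytest.raises(ValueError):
            fit_background(pd.DataFrame(), PROBES.iloc[:0], {"chr1": 1000})


def make_support(anchor, bin_start, distance, support):
    return pd.DataFrame({
        "anchor_id": [anchor], "chrom": ["chr1"], "bin_start": [bin_start],
        "distance": [distance], "support": [support]})


class TestCallInteractions:
    BG = {r: BackgroundModel(edges=np.array([2000.0, 2_000_000.0]),
                             n_slots=np.array([9999]),
                             nonzero_values=[np.array([1] * 10)])
          for r in (1, 2)}

    def test_min_support_required_in_both_replicates(self):
        sup = {1: make_support("P1", 50_000, 40_000, 4),
               2: make_support("P1", 50_000, 40_000, 9)}
        calls = call_interactions(sup, self.BG, PROBES, "D1")
        assert not calls["passes"].any() if len(calls) else True

    def test_bonferroni_arithmetic(self):
        sup = {1: make_support("P1", 50_000, 40_000, 6),
               2: make_support("P1", 50_000, 40_000, 6)}
        calls = call_interactions(sup, self.BG, PROBES, "D1")
        (row,) = calls.itertuples()
        assert row.p_r1 == pytest.approx(1 / 10_000)
        # single candidate for this anchor: m = 1
        assert row.p_bonf_r1 == pytest.approx(1 / 10_000)
        assert row.passes

    def test_blacklisted_bins_removed(self):
        sup = {1: make_support("P1", 50_000, 40_000, 6),
               2: make_support("P1", 50_000, 40_000, 6)}
        bl = [GenomicRegion("chr1", 51_000, 51_500, ".", "bl")]
        calls = call_interactions(sup, self.BG, PROBES, "D1", blacklist=bl)
        assert len(calls) == 0

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            call_interactions({1: make_support("P1", 0, 0, 5),
                               2: make_support("P1", 0, 0, 5)},
                              self.BG, PROBES, "D1", alpha=0.0)


class TestEnrichmentVsNegative:
    def test_equal_proportions_fold_one(self):
        fold, p = enrichment_vs_negative(30, 1000, 30, 1000)
        assert fold == pytest.approx(1.0)
        assert p > 0.9

    def test_fold_three_matches_yates_oracle(self):
        fold, p = enrichment_vs_negative(30, 1000, 10, 1000)
        assert fold == pytest.approx(3.0)
        # brute-force Yates-corrected chi-square on the 2x2 table
        a, b, c, d = 30, 970, 10, 990
        n = a + b + c + d
        expected = [[(a + b) * (a + c) / n, (a + b) * (b + d) / n],
                    [(c + d) * (a + c) / n, (c + d) * (b + d) / n]]
        obs = [[a, b], [c, d]]
        chi2 = sum((abs(obs[i][j] - expected[i][j]) - 0.5) ** 2
                   / expected[i][j] for i in range(2) for j in range(2))
        assert p == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_zero_calls_warns_and_returns_nan(self):
        with pytest.warns(UserWarning):
            fold, p = enrichment_vs_negative(0, 100, 0, 100)
        assert np.isnan(fold)

    def test_zero_negative_candidates_rejected(self):
        with pytest.raises(ValueError):
            enrichment_vs_negative(1, 10, 0, 0)


class TestInteractionStats:
    def test_mean_and_long_range_fraction(self):
        calls = pd.DataFrame({"distance": [50_000, 150_000],
                              "passes": [True, True],
                              "anchor_id": ["a", "b"]})
        s = interaction_stats(calls)
        assert s["mean_distance"] == pytest.approx(100_000)
        assert s["frac_gt_100kb"] == pytest.approx(0.5)

    def test_all_short_range(self):
        calls = pd.DataFrame({"distance": [10_000] * 3,
                              "passes": [True] * 3,
                              "anchor_id": list("abc")})
        assert interaction_stats(calls)["frac_gt_100kb"] == 0.0

    def test_empty_calls(self):
        s = interaction_stats(pd.DataFrame(columns=["distance", "passes",
                                                    "anchor_id"]))
        assert s["n"] == 0 and np.isnan(s["mean_distance"])


class TestNearestGeneFraction:
    PROMS = [GenomicRegion("chr1", p, p + 100, "+", f"g{i}")
             for i, p in enumerate((100_000, 300_000, 500_000, 700_000))]

    def call(self, anchor, bin_start):
        return {"anchor_id": anchor, "chrom": "chr1", "bin_start": bin_start,
                "distance": 0, "passes": True}

    def test_manual_tally(self):
        # one call lands nearest its own anchor, three land nearest others
        calls = pd.DataFrame([
            self.call("g0", 110_000),   # nearest gene g0 == anchor: hit
            self.call("g0", 290_000),   # nearest g1: miss
            self.call("g1", 500_000),   # nearest g2: miss
            self.call("g2", 690_000),   # nearest g3: miss
        ])
        assert nearest_gene_fraction(calls, self.PROMS) == pytest.approx(0.25)

    def test_single_promoter_genome(self):
        proms = self.PROMS[:1]
        calls = pd.DataFrame([self.call("g0", 900_000)])
        assert nearest_gene_fraction(calls, proms) == 1.0

    def test_no_promoter_anchored_calls(self):
        calls = pd.DataFrame([self.call("enh7", 110_000)])
        assert np.isnan(nearest_gene_fraction(calls, self.PROMS))


class TestNetworks:
    def calls(self, rows):
        df = pd.DataFrame(rows, columns=["anchor_id", "chrom", "bin_start",
                                         "timepoint", "pass_r1", "pass_r2"])
        df["passes"] = df["pass_r1"] & df["pass_r2"]
        return df

    FEATURES = [GenomicRegion("chr1", 50_000, 50_400, ".", "E1")]

    def test_single_replicate_pass_creates_edge(self):
        calls = map_bins_to_features(
            self.calls([("P1", "chr1", 50_000, "D1", True, False)]),
            self.FEATURES)
        g = build_network(calls, "D1")
        assert g.has_edge("P1", "E1")

    def test_no_calls_empty_network(self):
        calls = map_bins_to_features(self.calls([]), self.FEATURES)
        assert build_network(calls, "D1").number_of_edges() == 0

    def test_duplicate_calls_collapse(self):
        calls = map_bins_to_features(
            self.calls([("P1", "chr1", 50_000, "D1", True, True)] * 3),
            self.FEATURES)
        assert build_network(calls, "D1").number_of_edges() == 1

    def test_unannotated_bin_becomes_synthetic_node(self):
        calls = map_bins_to_features(
            self.calls([("P1", "chr1", 90_000, "D1", True, True)]),
            self.FEATURES)
        g = build_network(calls, "D1")
        assert g.has_edge("P1", "bin:chr1:90000")


class TestNodeDynamics:
    def net(self, edges):
        g = nx.Graph()
        g.add_edges_from(edges)
        return g

    def test_total_loss_gives_ji_zero_oce_one(self):
        a = self.net([("x", "n1")])
        b = nx.Graph()
        ji, oce = node_dynamics(a, b, "x")
        assert ji == 0.0 and oce == 1.0

    def test_identical_neighbor_sets(self):
        a = self.net([("x", "n1"), ("x", "n2")])
        ji, oce = node_dynamics(a, a, "x")
        assert ji == 1.0 and oce == 1.0

    def test_partial_overlap(self):
        a = self.net([("x", "a"), ("x", "b"), ("x", "c")])
        b = self.net([("x", "b"), ("x", "c"), ("x", "d")])
        ji, oce = node_dynamics(a, b, "x")
        assert ji == pytest.approx(0.5)
        assert oce == pytest.approx(2 / 3)

    @settings(max_examples=200, deadline=None)
    @given(st.sets(st.integers(0, 12)), st.sets(st.integers(0, 12)))
    def test_oce_dominates_ji_and_symmetry(self, na, nb):
        a = self.net([("x", f"n{i}") for i in na])
        b = self.net([("x", f"n{i}") for i in nb])
        ji, oce = node_dynamics(a, b, "x")
        ji2, oce2 = node_dynamics(b, a, "x")
        assert (ji, oce) == (ji2, oce2)
        assert 0.0 <= ji <= oce <= 1.0

    def test_all_node_dynamics_covers_union(self):
        a = self.net([("x", "a")])
        b = self.net([("y", "b")])
        dyn = all_node_dynamics(a, b)
        assert set(dyn.index) == {"x", "y", "a", "b"}


class TestCompareDeDynamics:
    def test_extreme_separation_significant(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(100)]
        dyn = pd.DataFrame({
            "ji": 0.0,
            "oce": [0.0] * 50 + [1.0] * 50,
        }, index=nodes)
        de = {n: i < 50 for i, n in enumerate(nodes)}
        stat, p = compare_de_dynamics(dyn, de)
        assert p < 1e-4

    def test_null_gives_large_p_on_average(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(20):
            dyn = pd.DataFrame({"ji": rng.random(60), "oce": rng.random(60)},
                               index=[f"n{i}" for i in range(60)])
            de = {f"n{i}": i % 2 == 0 for i in range(60)}
            ps.append(compare_de_dynamics(dyn, de)[1])
        assert np.mean(ps) > 0.2
        assert min(ps) > 1e-4

    def test_single_node_group_rejected(self):
        dyn = pd.DataFrame({"ji": [0, 1, 1], "oce": [0, 1, 1]},
                           index=["a", "b", "c"])
        with pytest.raises(ValueError):
            compare_de_dynamics(dyn, {"a": True, "b": False, "c": False})


class TestDynamicExpressionCorrelation:
    TPS = ["D1", "D3", "D6"]

    def frame(self, values, ids):
        return pd.DataFrame(values, index=ids, columns=self.TPS)

    def test_identical_profiles_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        prom = self.frame(rng.normal(size=(10, 3)), [f"p{i}" for i in range(10)])
        enh = prom.copy()
        enh.index = [f"e{i}" for i in range(10)]
        pairs = pd.DataFrame({"promoter_id": prom.index,
                              "enhancer_id": enh.index,
                              "timepoint": "D1"})
        mat = dynamic_expression_correlation(pairs, prom, enh)
        assert np.allclose(mat.loc["D1"], 1.0)

    def test_uncoupled_profiles_give_near_zero(self):
        rng = np.random.default_rng(1)
        prom = self.frame(rng.normal(size=(300, 3)),
                          [f"p{i}" for i in range(300)])
        enh = self.frame(rng.normal(size=(300, 3)),
                         [f"e{i}" for i in range(300)])
        pairs = pd.DataFrame({"promoter_id": prom.index,
                              "enhancer_id": enh.index, "timepoint": "D3"})
        mat = dynamic_expression_correlation(pairs, prom, enh)
        assert np.nanmax(np.abs(mat.loc["D3"])) < 0.2

    def test_cells_with_few_pairs_are_nan(self):
        prom = self.frame([[1.0, 2.0, 3.0]], ["p0"])
        enh = self.frame([[1.0, 2.0, 3.0]], ["e0"])
        pairs = pd.DataFrame({"promoter_id": ["p0"], "enhancer_id": ["e0"],
                              "timepoint": ["D1"]})
        mat = dynamic_expression_correlation(pairs, prom, enh)
        assert mat.isna().all().all()

    def test_planted_coupling_yields_diagonal_dominance(self):
        """Contacts active at one timepoint couple expression only there."""
        import warnings

        from enhdyn.expression import count_tags, cpm_normalize
        from enhdyn.io import TIMEPOINTS
        from enhdyn.simulate import (SimulationConfig, gen_ctss,
                                     gen_landscape)

        cfg = SimulationConfig(seed=17, n_promoters=150, n_enhancers=150,
                               frac_enhancers_targeted=1.0,
                               n_planted_interactions=200,
                               expression_coupling_sd=1.0)
        truth = gen_landscape(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tables = gen_ctss(truth, cfg)
        sm_total = [k for k in tables if "total" in k]
        sm_nasc = [k for k in tables if "nascent" in k]
        pc = cpm_normalize(count_tags({s: tables[s] for s in sm_total},
                                      truth.promoter_regions()))
        ec = cpm_normalize(count_tags({s: tables[s] for s in sm_nasc},
                                      truth.enhancer_regions()))

        def tp_mean(log2, sids):
            return pd.DataFrame({
                t: log2[[s for s in sids if s.startswith(t)]].mean(axis=1)
                for t in TIMEPOINTS})

        rows = [(r.other_id, r.anchor_id, r.timepoints)
                for r in truth.planted_interactions.itertuples()
                if "|" not in r.timepoints]
        pairs = pd.DataFrame(rows, columns=["promoter_id", "enhancer_id",
                                            "timepoint"])
        mat = dynamic_expression_correlation(
            pairs, tp_mean(pc.log2_cpm, sm_total),
            tp_mean(ec.log2_cpm, sm_nasc))
        for t in mat.index:
            row = mat.loc[t].dropna()
            if t in row.index and len(row) > 1:
                assert row[t] == row.max()


class TestDistalPeakEnrichment:
    UNIVERSE = [GenomicRegion("chr1", i * 2000, (i + 1) * 2000, ".", f"u{i}")
                for i in range(500)]

    def test_genome_wide_peak_set(self):
        distal = self.UNIVERSE[:100]
        peaks = {"all": [GenomicRegion("chr1", 0, 10_000_000, ".", "peak")]}
        out = distal_peak_enrichment(distal, peaks, self.UNIVERSE)
        assert out.loc["all", "overlap_pct"] == pytest.approx(100.0)
        assert out.loc["all", "fold"] == pytest.approx(1.0)

    def test_disjoint_peak_set(self):
        distal = self.UNIVERSE[:100]
        peaks = {"none": [GenomicRegion("chr2", 0, 1000, ".", "p")]}
        out = distal_peak_enrichment(distal, peaks, self.UNIVERSE)
        assert out.loc["none", "overlap_pct"] == 0.0

    def test_empty_peak_set_gives_nan_row(self):
        out = distal_peak_enrichment(self.UNIVERSE[:10], {"empty": []},
                                     self.UNIVERSE)
        assert out.loc["empty"].isna().all()

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(2)
        # peaks cover 10% of universe bins; distal set drawn with 50% hits
        peak_bins = set(rng.choice(500, size=50, replace=False))
        peaks = {"mark": [self.UNIVERSE[i] for i in sorted(peak_bins)]}
        hit_pool = sorted(peak_bins)
        miss_pool = sorted(set(range(500)) - peak_bins)
        distal_idx = list(rng.choice(hit_pool, 40, replace=False)) + \
            list(rng.choice(miss_pool, 40, replace=False))
        distal = [self.UNIVERSE[i] for i in distal_idx]
        out = distal_peak_enrichment(distal, peaks, self.UNIVERSE)
        assert 4.0 <= out.loc["mark", "fold"] <= 6.0
        assert out.loc["mark", "fisher_p"] < 1e-6
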