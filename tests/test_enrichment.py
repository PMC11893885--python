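"""LD expansion, matched controls, permutation enrichment, characterization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from enhdyn.enrichment import (
    GWASLocus,
    conservation_compare,
    enrichment_test,
    eqtl_enrichment,
    ld_expand,
    match_controls,
    nucleotide_diversity,
    proxy_map,
    region_mean_scores,
    sample_matched_regions,
    snp_covariates,
)
from enhdyn.regions import GenomicRegion


def ld_frame(rows):
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2", "distance"])


class TestLdExpand:
    def test_empty_ld_gives_singleton_loci(self):
        loci = ld_expand(["s1", "s2"], ld_frame([]))
        assert [l.proxies for l in loci] == [frozenset({"s1"}),
                                             frozenset({"s2"})]

    def test_r2_threshold(self):
        ld = ld_frame([("s1", "p1", 0.65, 1000)])
        (locus,) = ld_expand(["s1"], ld, r2_threshold=0.7)
        assert locus.proxies == frozenset({"s1"})
        (locus,) = ld_expand(["s1"], ld, r2_threshold=0.6)
        assert locus.proxies == frozenset({"s1", "p1"})

    def test_window_rule(self):
        ld = ld_frame([("s1", "p1", 0.9, 2_000_000)])
        (locus,) = ld_expand(["s1"], ld, window=1_000_000)
        assert locus.proxies == frozenset({"s1"})

    def test_loci_sharing_proxies_merge(self):
        ld = ld_frame([("s1", "p1", 0.9, 100), ("s2", "p1", 0.9, 100)])
        (locus,) = ld_expand(["s1", "s2"], ld)
        assert locus.index_snps == ("s1", "s2")
        assert locus.proxies == frozenset({"s1", "s2", "p1"})

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            ld_expand(["s1"], ld_frame([]), r2_threshold=1.5)

    def test_locus_invariant(self):
        with pytest.raises(ValueError):
            GWASLocus(("s1",), frozenset({"p1"}))


def variants_frame(n, seed=0, chrom="chr1", span=1_000_000):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(span, size=n, replace=False))
    return pd.DataFrame({
        "id": [f"v{i}" for i in range(n)],
        "chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
        "af": rng.beta(1, 3, size=n),
    })


class TestMatchControls:
    def test_controls_share_covariate_bins(self):
        v = variants_frame(2000)
        cov = snp_covariates(v, ld_frame([]), [])
        controls = match_controls(["v0", "v10"], cov, min_neighbors=50)
        for snp, ids in controls.items():
            assert len(ids) >= 50
            assert snp not in ids
            assert (cov.loc[ids, "maf_bin"] == cov.loc[snp, "maf_bin"]).all()

    def test_maf_distribution_matches(self):
        v = variants_frame(4000, seed=1)
        cov = snp_covariates(v, ld_frame([]), [])
        rng = np.random.default_rng(2)
        index = list(rng.choice(v["id"], size=60, replace=False))
        controls = match_controls(index, cov, min_neighbors=50)
        maf = np.minimum(v.set_index("id")["af"], 1 - v.set_index("id")["af"])
        idx_maf = maf[index].to_numpy()
        ctrl_maf = np.concatenate([maf[ids].to_numpy()
                                   for ids in controls.values()])
        assert stats.ks_2samp(idx_maf, ctrl_maf).pvalue > 0.05

    def test_sparse_bin_widens_with_warning(self):
        v = variants_frame(600)
        cov = snp_covariates(v, ld_frame([]), [])
        with pytest.warns(UserWarning, match="widened|fewer"):
            controls = match_controls(["v0"], cov, min_neighbors=300)
        assert len(controls["v0"]) >= 300

    def test_pool_smaller_than_min_neighbors_rejected(self):
        v = variants_frame(100)
        cov = snp_covariates(v, ld_frame([]), [])
        with pytest.raises(ValueError):
            match_controls(["v0"], cov, min_neighbors=500)


class TestEnrichmentTest:
    def test_whole_genome_regions_give_fold_one_p_one(self):
        v = variants_frame(500)
        cov = snp_covariates(v, ld_frame([]), [])
        index = ["v1", "v5", "v9"]
        controls = match_controls(index, cov, min_neighbors=50)
        loci = ld_expand(index, ld_frame([]))
        genome = [GenomicRegion("chr1", 0, 2_000_000, ".", "all")]
        res = enrichment_test(loci, genome, controls, v, ld_frame([]),
                              n_permutations=100, seed=0)
        assert res.observed == 3
        assert res.expected == pytest.approx(3.0)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test([], [], {}, variants_frame(10), ld_frame([]),
                            n_permutations=0)

    def test_few_permutations_warn(self):
        v = variants_frame(300)
        cov = snp_covariates(v, ld_frame([]), [])
        controls = match_controls(["v0"], cov, min_neighbors=50)
        loci = ld_expand(["v0"], ld_frame([]))
        with pytest.warns(UserWarning, match="permutations"):
            enrichment_test(loci, [], controls, v, ld_frame([]),
                            n_permutations=50, seed=0)

    def test_p_never_zero_or_above_one(self):
        v = variants_frame(500, seed=3)
        cov = snp_covariates(v, ld_frame([]), [])
        index = [f"v{i}" for i in range(0, 50, 5)]
        controls = match_controls(index, cov, min_neighbors=50)
        loci = ld_expand(index, ld_frame([]))
        regions = [GenomicRegion("chr1", 0, 300_000, ".", "r")]
        res = enrichment_test(loci, regions, controls, v, ld_frame([]),
                              n_permutations=200, seed=4)
        assert 0.0 < res.p <= 1.0


class TestSampleMatchedRegions:
    SIZES = {"chr1": 1_000_000, "chr2": 500_000}

    def template(self, lengths):
        return [GenomicRegion("chr1", i * 10_000, i * 10_000 + l, ".", f"t{i}")
                for i, l in enumerate(lengths)]

    def test_length_multiset_preserved(self):
        lengths = [100, 100, 250, 400, 1000]
        out = sample_matched_regions(self.template(lengths), self.SIZES,
                                     seed=0)
        assert sorted(r.length for r in out) == sorted(lengths)

    def test_exclusions_respected(self):
        excl = [GenomicRegion("chr1", 0, 990_000, ".", "tel"),
                GenomicRegion("chr2", 100_000, 500_000, ".", "cen")]
        out = sample_matched_regions(self.template([500] * 30), self.SIZES,
                                     excluded=excl, seed=1)
        for r in out:
            for e in excl:
                assert not r.overlaps(e)

    def test_seed_changes_placement_not_lengths(self):
        t = self.template([200, 300, 400])
        a = sample_matched_regions(t, self.SIZES, seed=1)
        b = sample_matched_regions(t, self.SIZES, seed=2)
        assert sorted(r.length for r in a) == sorted(r.length for r in b)
        assert [(r.chrom, r.start) for r in a] != [(r.chrom, r.start)
                                                   for r in b]
        again = sample_matched_regions(t, self.SIZES, seed=1)
        assert [(r.chrom, r.start) for r in a] == [(r.chrom, r.start)
                                                   for r in again]

    def test_impossible_placement_rejected(self):
        excl = [GenomicRegion("chr1", 0, 1_000_000, ".", "x"),
                GenomicRegion("chr2", 0, 500_000, ".", "y")]
        with pytest.raises(RuntimeError):
            sample_matched_regions(self.template([500]), self.SIZES,
                                   excluded=excl, seed=0, max_retries=50)


class TestConservation:
    def track(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])

    def test_uniform_track_gives_equal_means_and_p_one(self):
        track = self.track([("chr1", 0, 1_000_000, 0.3)])
        a = [GenomicRegion("chr1", 100, 500, ".", "a")]
        b = [GenomicRegion("chr1", 5000, 9000, ".", "b")]
        out = conservation_compare(a, {"rand": b}, track)
        assert out.loc["template", "mean_score"] == pytest.approx(0.3)
        assert out.loc["rand", "mean_score"] == pytest.approx(0.3)
        assert out.loc["rand", "p"] == pytest.approx(1.0)

    def test_base_weighted_mean(self):
        track = self.track([("chr1", 0, 100, 1.0), ("chr1", 100, 200, 0.0)])
        r = [GenomicRegion("chr1", 50, 150, ".", "r")]
        assert region_mean_scores(r, track)["r"] == pytest.approx(0.5)

    def test_single_base_region(self):
        track = self.track([("chr1", 0, 100, 0.7)])
        r = [GenomicRegion("chr1", 42, 43, ".", "r")]
        assert region_mean_scores(r, track)["r"] == pytest.approx(0.7)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            region_mean_scores([], self.track([]))

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        segs, regions_hi, regions_lo = [], [], []
        for i in range(400):
            start = i * 1000
            hi = i % 2 == 0
            segs.append(("chr1", start, start + 1000,
                         np.clip(rng.normal(0.5 if hi else 0.2, 0.05), 0, 1)))
            (regions_hi if hi else regions_lo).append(
                GenomicRegion("chr1", start + 100, start + 900, ".", f"r{i}"))
        out = conservation_compare(regions_hi, {"rand": regions_lo},
                                   self.track(segs))
        assert out.loc["template", "mean_score"] > out.loc["rand", "mean_score"]
        assert out.loc["rand", "p"] < 1e-6


class TestNucleotideDiversity:
    def regions(self):
        return [GenomicRegion("chr1", 0, 100, ".", "a"),
                GenomicRegion("chr1", 200, 300, ".", "b"),
                GenomicRegion("chr1", 400, 500, ".", "empty")]

    def variants(self, afs, positions):
        return pd.DataFrame({
            "id": [f"v{i}" for i in range(len(afs))],
            "chrom": "chr1", "pos": positions, "ref": "A", "alt": "G",
            "af": afs})

    def test_pi_formula_values(self):
        v = self.variants([0.5, 0.0, 0.1], [10, 20, 250])
        out = nucleotide_diversity(self.regions(), v)
        assert out.loc["a", "mean_pi"] == pytest.approx((0.5 + 0.0) / 2)
        assert out.loc["b", "mean_pi"] == pytest.approx(2 * 0.1 * 0.9)
        assert out.loc["b", "n_snps"] == 1

    def test_zero_snp_region_and_log_offset(self):
        v = self.variants([0.5, 0.1], [10, 250])
        out = nucleotide_diversity(self.regions(), v)
        assert out.loc["empty", "mean_pi"] == 0.0
        smallest = 0.18  # the smallest non-zero regional mean
        assert out.loc["empty", "log_mean_pi"] == pytest.approx(
            np.log10(smallest))
        assert out.loc["a", "log_mean_pi"] == pytest.approx(
            np.log10(0.5 + smallest))

    def test_af_out_of_range_rejected(self):
        v = self.variants([1.2], [10])
        with pytest.raises(ValueError):
            nucleotide_diversity(self.regions(), v)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.0, 1.0))
    def test_pi_symmetric_and_bounded(self, af):
        pi = 2 * af * (1 - af)
        pi_flip = 2 * (1 - af) * af
        assert pi == pi_flip
        assert 0.0 <= pi <= 0.5


class TestEqtlEnrichment:
    def test_identical_rates(self):
        region = [f"r{i}" for i in range(100)]
        rand = [f"c{i}" for i in range(100)]
        eqtl = region[:10] + rand[:10]
        fold, p = eqtl_enrichment(region, eqtl, rand)
        assert fold == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_oracle(self):
        region = [f"r{i}" for i in range(1000)]
        rand = [f"c{i}" for i in range(1000)]
        eqtl = region[:40] + rand[:20]
        fold, p = eqtl_enrichment(region, eqtl, rand)
        assert fold == pytest.approx(2.0)
        # brute-force two-sided Fisher: sum of all table probabilities
        # not exceeding the observed one
        M, n, N = 2000, 60, 1000  # pool, eqtls, in-region draws
        probs = {k: stats.hypergeom.pmf(k, M, n, N) for k in range(61)}
        p_obs = probs[40]
        oracle = sum(v for v in probs.values() if v <= p_obs + 1e-12)
        assert p == pytest.approx(oracle, rel=1e-6)

    def test_planted_double_rate_detected(self):
        rng = np.random.default_rng(6)
        region = [f"r{i}" for i in range(5000)]
        rand = [f"c{i}" for i in range(5000)]
        eqtl = [s for s in region if rng.random() < 0.10] + \
            [s for s in rand if rng.random() < 0.05]
        fold, p = eqtl_enrichment(region, eqtl, rand)
        assert 1.6 <= fold <= 2.4
        assert p < 0.01

    def test_empty_random_set_rejected(self):
        with pytest.raises(ValueError):
            eqtl_enrichment(["a"], ["a"], [])
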