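"""Matched-resampling enrichment: matching exactness, estimator behaviour,
and calibration of the set-vs-set comparison."""

import collections

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import esnpnet as en
from esnpnet.enrichment import MatchedSampler, make_focal_keys

from conftest import uniform_gwas


class TestProportionBelow:
    def test_examples(self):
        assert en.proportion_below([0.01, 0.2, 0.04, 0.8]) == 0.5
        assert en.proportion_below([1.0] * 7) == 0.0
        got = en.proportion_below([0.01] * 37 + [0.9] * 64)
        assert round(100 * got, 2) == 36.63  # 37 of 101

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            en.proportion_below([])


def _histogram(keys: pd.DataFrame) -> collections.Counter:
    return collections.Counter(zip(keys["maf_bin"], keys["mode"]))


class TestMatchedDraws:
    def test_draws_reproduce_stratum_histogram(self, ld_panel, ld_panel_keys):
        rng = np.random.default_rng(0)
        focal = list(rng.choice(ld_panel["snps"]["snp_id"], 60, replace=False))
        fk = make_focal_keys(focal, ld_panel_keys)
        sampler = MatchedSampler(fk, ld_panel_keys)
        want = _histogram(fk)
        bins = ld_panel_keys["maf_bin"]
        near = ld_panel_keys["near_gene"]
        for i in range(300):
            ids = sampler.draw_ids(np.random.default_rng(i))
            assert len(ids) == len(set(ids)) == len(fk)
            got = collections.Counter()
            # a drawn SNP satisfies a cis slot only if near a gene; count
            # feasibly: cis slots must be filled by near-gene SNPs
            drawn = ld_panel_keys.loc[ids]
            for b in sorted(set(fk["maf_bin"])):
                n_cis = want.get((b, "cis"), 0)
                n_trans = want.get((b, "trans"), 0)
                sub = drawn[drawn["maf_bin"] == b]
                assert len(sub) == n_cis + n_trans
                assert int(sub["near_gene"].sum()) >= n_cis
                got[b] = len(sub)

    def test_pool_equals_focal_is_trivially_matched(self, ld_panel_keys):
        focal = list(ld_panel_keys.index[:40])
        fk = make_focal_keys(focal, ld_panel_keys)
        sampler = MatchedSampler(fk, ld_panel_keys.loc[focal])
        ids = sampler.draw_ids(np.random.default_rng(1))
        assert _histogram(make_focal_keys(list(ids),
                                          ld_panel_keys)) \
            == _histogram(make_focal_keys(focal, ld_panel_keys))

    def test_ld_multiplicity_uses_single_pool_group(self, ld_panel,
                                                    ld_panel_keys):
        groups = ld_panel_keys.groupby("ld_group")
        gid = next(g for g, grp in groups if len(grp) >= 3)
        focal = list(ld_panel_keys.index[ld_panel_keys["ld_group"] == gid][:3])
        fk = make_focal_keys(focal, ld_panel_keys)
        sampler = MatchedSampler(fk, ld_panel_keys)
        for i in range(50):
            ids = sampler.draw_ids(np.random.default_rng(i))
            drawn_groups = set(ld_panel_keys.loc[ids, "ld_group"])
            assert len(drawn_groups) == 1  # all three from one pool group

    def test_infeasible_stratum_names_the_stratum(self, ld_panel_keys):
        # one focal SNP per LD group so the demand is singleton-stratum
        focal = list(ld_panel_keys.drop_duplicates("ld_group").index[:5])
        fk = make_focal_keys(focal, ld_panel_keys)
        fk.loc[fk.index[0], "maf_bin"] = 5  # pretend a bin the pool lacks
        pool = ld_panel_keys[ld_panel_keys["maf_bin"] != 5]
        assert not (pool["maf_bin"] == 5).any()
        with pytest.raises(ValueError, match="maf_bin 5|maf_bin=5"):
            MatchedSampler(fk, pool)

    def test_draw_matched_set_entry_point(self, ld_panel_keys):
        focal = list(ld_panel_keys.index[10:30])
        fk = make_focal_keys(focal, ld_panel_keys)
        ids = en.draw_matched_set(fk, ld_panel_keys, 0)
        assert len(ids) == len(focal)


class TestEnrichmentTest:
    def test_observed_above_all_null_gives_add_one_p(self, small_study):
        snps = small_study["snps"]
        keys = en.prepare_match_keys(snps, small_study["genes"],
                                     small_study["geno"])
        rng = np.random.default_rng(3)
        focal = list(rng.choice(snps["snp_id"], 25, replace=False))
        gwas = uniform_gwas(snps, rng)
        score = gwas.set_index("snp_id")
        # plant: focal all significant, everything else null
        gwas.loc[gwas["snp_id"].isin(focal), "p"] = 1e-6
        gwas.loc[~gwas["snp_id"].isin(focal), "p"] = \
            0.5 + 0.5 * rng.random((~gwas["snp_id"].isin(focal)).sum())
        res = en.enrichment_test(focal, keys, gwas, n_iter=999, seed=1)
        assert res.observed_prop == 1.0
        assert res.p_empirical == pytest.approx(1 / 1000)
        assert res.fold == pytest.approx(res.observed_prop / res.null_mean)
        assert res.ci95 == pytest.approx(
            (res.null_mean - 1.96 * res.null_sd,
             res.null_mean + 1.96 * res.null_sd))

    def test_null_mean_approaches_alpha(self):
        """Under a uniform GWAS the matched null proportion converges to
        alpha (|mean - 0.05| < 0.005 at 10,000 iterations, focal 500).

        The pool must be large enough that its own realized significant
        fraction sits within the tolerance (20,000 SNPs: sd ~ 0.0015)."""
        cfg = en.SimConfig(seed=41, n_samples=150,
                           block_sizes=tuple([10] * 2000), n_genes=400,
                           n_cis_genes=50)
        geno, snps, genes = en.simulate_genotypes(cfg)
        keys = en.prepare_match_keys(snps, genes, geno)
        rng = np.random.default_rng(2)
        focal = list(rng.choice(snps["snp_id"], 500, replace=False))
        gwas = uniform_gwas(snps, rng)
        res = en.enrichment_test(focal, keys, gwas, n_iter=10_000, seed=4)
        assert abs(res.null_mean - 0.05) < 0.005

    def test_pool_order_invariance_given_seed(self, small_study):
        snps, genes, geno = (small_study["snps"], small_study["genes"],
                             small_study["geno"])
        keys = en.prepare_match_keys(snps, genes, geno)
        rng = np.random.default_rng(5)
        focal = list(rng.choice(snps["snp_id"], 40, replace=False))
        gwas = uniform_gwas(snps, rng)
        res1 = en.enrichment_test(focal, keys, gwas, n_iter=500, seed=9)
        shuffled = keys.sample(frac=1.0, random_state=7)
        res2 = en.enrichment_test(focal, shuffled, gwas, n_iter=500, seed=9)
        assert res1.null_mean == res2.null_mean
        assert res1.p_empirical == res2.p_empirical

    def test_unscored_focal_snps_dropped_and_counted(self, small_study):
        snps = small_study["snps"]
        keys = en.prepare_match_keys(snps, small_study["genes"],
                                     small_study["geno"])
        rng = np.random.default_rng(6)
        focal = list(rng.choice(snps["snp_id"], 30, replace=False))
        gwas = uniform_gwas(snps, rng)
        gwas = gwas[~gwas["snp_id"].isin(focal[:5])]  # unscored focal SNPs
        res = en.enrichment_test(focal, keys, gwas, n_iter=200, seed=2)
        assert res.n_dropped == 5
        assert res.n_snps == 25

    def test_expanded_draws_respect_size_window(self, ld_panel,
                                                ld_panel_keys):
        rng = np.random.default_rng(8)
        snps = ld_panel["snps"]
        focal = list(rng.choice(snps["snp_id"], 40, replace=False))
        nbhd = en.LdNeighborhood(ld_panel["geno"], snps)
        focal_size = len(nbhd.expand(focal))
        fk = make_focal_keys(focal, ld_panel_keys)
        sampler = MatchedSampler(fk, ld_panel_keys)
        gwas = uniform_gwas(snps, rng)
        res = en.enrichment_test(focal, ld_panel_keys, gwas, n_iter=200,
                                 expand=nbhd, seed=3)
        assert res.n_snps == focal_size
        # the accepted draws must fall inside the +/-10% window; replay a
        # few rejection loops directly
        accepted = 0
        draw_rng = np.random.default_rng(10)
        while accepted < 100:
            core = sampler.pool_ids[sampler.draw(draw_rng)]
            size = len(nbhd.expand(core))
            if 0.9 * focal_size <= size <= 1.1 * focal_size:
                accepted += 1


class TestCompareSets:
    def test_degenerate_equal_sets_give_p_one(self, small_study):
        snps = small_study["snps"]
        keys = en.prepare_match_keys(snps, small_study["genes"],
                                     small_study["geno"])
        rng = np.random.default_rng(9)
        background = list(rng.choice(snps["snp_id"], 30, replace=False))
        gwas = uniform_gwas(snps, rng)
        p, res = en.compare_sets(background, background, keys, gwas,
                                 n_iter=200, seed=1)
        assert p == 1.0

    def test_focal_holding_all_signal_gives_minimal_p(self, small_study):
        snps = small_study["snps"]
        keys = en.prepare_match_keys(snps, small_study["genes"],
                                     small_study["geno"])
        rng = np.random.default_rng(10)
        background = list(rng.choice(snps["snp_id"], 120, replace=False))
        focal = background[:30]
        gwas = uniform_gwas(snps, rng)
        gwas["p"] = np.where(gwas["snp_id"].isin(focal), 1e-6,
                             0.5 + 0.5 * rng.random(len(gwas)))
        p, _ = en.compare_sets(focal, background, keys, gwas, n_iter=199,
                               seed=2)
        assert p == pytest.approx(1 / 200)

    def test_non_nested_focal_warns(self, small_study):
        snps = small_study["snps"]
        keys = en.prepare_match_keys(snps, small_study["genes"],
                                     small_study["geno"])
        rng = np.random.default_rng(11)
        ids = list(rng.choice(snps["snp_id"], 40, replace=False))
        gwas = uniform_gwas(snps, rng)
        with pytest.warns(UserWarning, match="not nested"):
            en.compare_sets(ids[:10], ids[5:], keys, gwas, n_iter=100, seed=3)

    def test_null_mid_p_uniform(self, small_study):
        """A matched random subset of the background under a null GWAS:
        the mid-p over replicates is uniform (KS)."""
        snps = small_study["snps"]
        keys = en.prepare_match_keys(snps, small_study["genes"],
                                     small_study["geno"])
        rng = np.random.default_rng(12)
        background = list(rng.choice(snps["snp_id"], 200, replace=False))
        mids = []
        for rep in range(80):
            focal = list(rng.choice(background, 80, replace=False))
            gwas = uniform_gwas(snps, rng)
            _, res = en.compare_sets(focal, background, keys, gwas,
                                     n_iter=300,
                                     seed=int(rng.integers(2 ** 31)))
            mids.append(res.p_mid)
        assert stats.kstest(mids, "uniform").pvalue > 0.01
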