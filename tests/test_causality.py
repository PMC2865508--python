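"""QTL scans, stepwise selection, pleiotropy LRT, causal model selection,
and the three-criteria candidate filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import esnpnet as en
from esnpnet.causality import lod_from_r2
from esnpnet.simulate import CrossData, CrossSpec, SimConfig


def make_cross(seed=0, n=500, chain="causal", b=0.7, markers=11,
               spacing=10.0):
    cfg = SimConfig(seed=seed, cross_spec=CrossSpec(
        n_f2=n, chain=chain, b_lg=b, b_gt=b, n_markers=markers,
        marker_spacing_cm=spacing, n_noise_genes=2))
    return en.simulate_f2_cross(cfg)


class TestQtlScan:
    def test_noise_free_trait_peaks_at_its_marker(self):
        cross = make_cross(seed=1, n=300)
        trait = cross.geno[cross.focal_marker].to_numpy(float) - 1.0
        curve = en.qtl_scan(cross, trait)
        marker, _ = curve.max()
        assert marker == cross.focal_marker
        other_chrom = cross.gmap.loc[cross.gmap["chrom"] == "chr2", "marker"]
        # unlinked chromosome: orders of magnitude below the peak
        assert curve.lod.loc[other_chrom].max() < 0.01 * curve.lod.max()

    def test_lod_matches_r2_identity(self):
        cross = make_cross(seed=2, n=400)
        y = cross.traits["insulin"].to_numpy()
        curve = en.qtl_scan(cross, y)
        m = cross.focal_marker
        g = cross.geno[m].to_numpy(float)
        x = np.column_stack([np.ones(len(y)), g - 1, (g == 1).astype(float)])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r2 = 1 - ((y - x @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert curve.lod.loc[m] == pytest.approx(lod_from_r2(r2, len(y)))

    def test_affine_trait_transform_leaves_curve_unchanged(self):
        cross = make_cross(seed=3, n=300)
        y = cross.traits["insulin"].to_numpy()
        a = en.qtl_scan(cross, y).lod
        b = en.qtl_scan(cross, 3.0 * y - 7.0).lod
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_null_trait_rarely_reaches_lod_4(self):
        hits = 0
        for seed in range(50):
            cross = make_cross(seed=seed, n=500, markers=50, spacing=2.0)
            rng = np.random.default_rng(seed + 1000)
            curve = en.qtl_scan(cross, rng.standard_normal(500))
            hits += curve.lod.max() < 4.0
        assert hits >= 45

    def test_constant_trait_rejected(self):
        cross = make_cross(seed=4, n=100)
        with pytest.raises(ValueError, match="constant"):
            en.qtl_scan(cross, np.ones(100))


class TestForwardStepwise:
    def test_two_planted_qtl_recovered(self):
        hits = 0
        for seed in range(50):
            cross = make_cross(seed=seed, n=500)
            rng = np.random.default_rng(seed + 2000)
            m1 = cross.gmap[cross.gmap["chrom"] == "chr1"]["marker"].iloc[3]
            m2 = cross.gmap[cross.gmap["chrom"] == "chr2"]["marker"].iloc[7]
            y = (0.8 * (cross.geno[m1].to_numpy(float) - 1)
                 + 0.5 * (cross.geno[m2].to_numpy(float) - 1)
                 + rng.standard_normal(500))
            found = en.forward_stepwise_qtl(cross, y, lod_threshold=3.0)
            cm = cross.gmap.set_index("marker")["cM"]
            chrom = cross.gmap.set_index("marker")["chrom"]
            ok = 0
            for planted in (m1, m2):
                ok += any(chrom[h.marker] == chrom[planted]
                          and abs(cm[h.marker] - cm[planted]) <= 10
                          for h in found)
            hits += ok == 2
        assert hits >= 45

    def test_null_trait_selects_nothing(self):
        empties = 0
        for seed in range(20):
            cross = make_cross(seed=seed, n=400)
            rng = np.random.default_rng(seed + 3000)
            found = en.forward_stepwise_qtl(cross, rng.standard_normal(400),
                                            lod_threshold=3.0)
            empties += len(found) == 0
        assert empties >= 19

    def test_max_qtl_respected_and_threshold_monotone(self):
        cross = make_cross(seed=5, n=400)
        y = cross.traits["insulin"].to_numpy()
        assert len(en.forward_stepwise_qtl(cross, y, lod_threshold=0.5,
                                           max_qtl=1)) <= 1
        loose = {h.marker for h in en.forward_stepwise_qtl(
            cross, y, lod_threshold=1.0)}
        tight = {h.marker for h in en.forward_stepwise_qtl(
            cross, y, lod_threshold=3.0)}
        assert tight <= loose


class TestPleiotropy:
    def test_null_p_uniform(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            g = rng.integers(0, 3, 200)
            ps.append(en.pleiotropy_test(g, rng.standard_normal(200),
                                         rng.standard_normal(200))[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shared_marker_effect_detected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed + 500)
            g = rng.integers(0, 3, 500).astype(float)
            t1 = 0.5 * (g - 1) + rng.standard_normal(500)
            t2 = 0.5 * (g - 1) + rng.standard_normal(500)
            hits += en.pleiotropy_test(g, t1, t2)[1] < 0.001
        assert hits >= 47

    def test_trait_correlation_alone_does_not_inflate(self):
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed + 900)
            g = rng.integers(0, 3, 300)
            shared = rng.standard_normal(300)
            t1 = shared + 0.46 * rng.standard_normal(300)
            t2 = shared + 0.46 * rng.standard_normal(300)  # r ~ 0.9
            rejections += en.pleiotropy_test(g, t1, t2)[1] < 0.05
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_rep)
        assert 0.05 - half <= rejections / n_rep <= 0.05 + half

    def test_identical_traits_rejected(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 100)
        t = rng.standard_normal(100)
        with pytest.raises(ValueError, match="identical"):
            en.pleiotropy_test(g, t, t)


class TestCausalModelSelect:
    def test_swap_symmetry(self):
        """Swapping (G, T) must exchange the causal and reactive scores."""
        cross = make_cross(seed=6, n=400)
        L = cross.geno[cross.focal_marker]
        G = cross.expr[cross.focal_gene]
        T = cross.traits["insulin"]
        a = en.causal_model_select(L, G, T)
        b = en.causal_model_select(L, T, G)
        assert a.aic["causal"] == pytest.approx(b.aic["reactive"])
        assert a.aic["reactive"] == pytest.approx(b.aic["causal"])
        assert a.aic["independent"] == pytest.approx(b.aic["independent"])

    def test_winner_attains_minimum_with_margin(self):
        cross = make_cross(seed=7, n=400)
        call = en.causal_model_select(cross.geno[cross.focal_marker],
                                      cross.expr[cross.focal_gene],
                                      cross.traits["insulin"])
        assert call.aic[call.model] == min(call.aic.values())
        assert call.margin >= 0

    def test_degenerate_inputs_rejected(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, 100)
        with pytest.raises(ValueError, match="degenerate"):
            en.causal_model_select(g, np.ones(100), rng.standard_normal(100))


def paper_style_filter_fixture():
    """Synthetic tables mirroring the published filtering cascade: a
    159-gene module, 8 genes with strong cis eQTL inside the linkage
    interval, 5 of them causal, and exactly one with a human cis eSNP
    associated with disease (p = 0.002)."""
    module = [f"mg{i:03d}" for i in range(159)]
    interval = ("chr9", 65_000_000, 95_000_000)
    rows = []
    for i, g in enumerate(module):
        if i < 8:  # inside the interval
            start = 65_000_000 + i * 1_000_000
            rows.append((g, "chr9", start, start + 10_000))
        else:
            rows.append((g, "chr2", 1_000_000 + i * 100_000,
                         1_010_000 + i * 100_000))
    mouse_genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start",
                                              "stop"])
    cis = pd.DataFrame({"gene_id": module[:8], "marker": "mk1",
                        "lod": [5.0] * 8})
    calls = pd.DataFrame({"gene_id": module[:5], "trait": "insulin",
                          "model": "causal", "margin": 4.0})
    orthologs = pd.DataFrame({"mouse_id": module,
                              "human_id": [g.upper() for g in module]})
    human_esnps = pd.DataFrame({
        "snp_id": ["rs1", "rs2", "rs3"],
        "gene_id": ["MG003", "MG004", "MG050"],
        "mode": ["cis", "cis", "cis"],
        "kw_p": [1e-5] * 3, "fdr_pass": True, "tissue": "omental"})
    gwas = pd.DataFrame({"snp_id": ["rs1", "rs2", "rs3"],
                         "chrom": "chr6", "pos": [1, 2, 3],
                         "p": [0.002, 0.40, 0.01]})
    return module, mouse_genes, cis, calls, interval, human_esnps, gwas, \
        orthologs


class TestCandidateFilter:
    def test_paper_style_cascade_yields_single_candidate(self):
        (module, mouse_genes, cis, calls, interval, human_esnps, gwas,
         orthologs) = paper_style_filter_fixture()
        out = en.candidate_filter(module, mouse_genes, cis, calls, interval,
                                  human_esnps, gwas, orthologs)
        # mg003 is causal (first 5), in-interval with cis eQTL (first 8),
        # and its ortholog's cis eSNP associates at 0.002; mg050 fails the
        # interval criterion, mg004's eSNP fails the GWAS threshold
        assert list(out["gene_id"]) == ["mg003"]
        assert out.iloc[0]["p_t2d"] == 0.002

    def test_no_human_association_gives_empty_result(self):
        (module, mouse_genes, cis, calls, interval, human_esnps, gwas,
         orthologs) = paper_style_filter_fixture()
        gwas["p"] = 0.5
        out = en.candidate_filter(module, mouse_genes, cis, calls, interval,
                                  human_esnps, gwas, orthologs)
        assert out.empty

    def test_causal_margin_requirement(self):
        (module, mouse_genes, cis, calls, interval, human_esnps, gwas,
         orthologs) = paper_style_filter_fixture()
        calls["margin"] = 1.0  # below the support threshold
        out = en.candidate_filter(module, mouse_genes, cis, calls, interval,
                                  human_esnps, gwas, orthologs)
        assert out.empty
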