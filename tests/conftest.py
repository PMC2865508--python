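import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import esnpnet as en
from esnpnet.simulate import SimConfig, designate_cis_pairs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_samples=300, block_sizes=tuple([5] * 60),
                     n_genes=150, n_cis_genes=30, cis_effect=1.0)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    geno, snps, genes = en.simulate_genotypes(small_cfg)
    pairs = designate_cis_pairs(snps, genes, small_cfg)
    expr = en.simulate_expression(geno, snps, genes, small_cfg, pairs=pairs)
    gwas = en.simulate_gwas(geno, snps, small_cfg, genes=genes)
    return {"cfg": small_cfg, "geno": geno, "snps": snps, "genes": genes,
            "expr": expr, "gwas": gwas, "pairs": pairs}


@pytest.fixture(scope="session")
def ld_panel():
    """Panel with strong within-block LD so multi-SNP LD groups exist."""
    cfg = SimConfig(seed=7, n_samples=500, block_sizes=tuple([6] * 120),
                    within_block_r=0.93, n_genes=200, n_cis_genes=40)
    geno, snps, genes = en.simulate_genotypes(cfg)
    return {"cfg": cfg, "geno": geno, "snps": snps, "genes": genes}


@pytest.fixture(scope="session")
def ld_panel_keys(ld_panel):
    return en.prepare_match_keys(ld_panel["snps"], ld_panel["genes"],
                                 ld_panel["geno"])


def uniform_gwas(snps: pd.DataFrame, rng) -> pd.DataFrame:
    """Null GWAS table: p-values iid uniform on (0, 1]."""
    return pd.DataFrame({
        "snp_id": snps["snp_id"], "chrom": snps["chrom"], "pos": snps["pos"],
        "p": 1.0 - rng.random(len(snps))})


@pytest.fixture
def make_null_gwas():
    return uniform_gwas
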