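"""Synthetic study generator.

Emulates, at desk scale, the three data worlds the pipeline consumes:

* a genotyped human cohort with LD-block structure, MAF > 5%, and expression
  with planted cis effects plus a module (co-expression factor) architecture;
* case/control GWAS summary statistics from an independent cohort whose
  disease liability is driven by the module factors, so SNPs tagging the
  module-driving loci carry the association signal and everything else is
  null;
* an F2 intercross between two inbred strains with markers on a centimorgan
  map (Haldane recombination), expression, and clinical traits generated
  under a configurable locus -> expression -> trait chain.

LD within a block is induced by a latent Gaussian haplotype copula: each
haplotype's allele indicators share a block-level factor, and the latent
correlation is calibrated by root finding so that the *genotype* (allele
count) correlation has the requested expectation.  All SNPs within a block
share one minor allele frequency; with unequal frequencies a thresholded
Gaussian pair cannot reach high allelic correlation (the phi-coefficient
bound), so block-constant MAF is what makes strong LD attainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from ._rng import substream

__all__ = [
    "ModuleSpec",
    "GwasSpec",
    "CrossSpec",
    "SimConfig",
    "CrossData",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_gwas",
    "simulate_f2_cross",
    "designate_cis_pairs",
    "module_driver_snps",
    "genotype_chisq",
]

# genome layout constants (base pairs)
_SNP_SPACING = 5_000
_BLOCK_GAP = 50_000
_GENE_WIDTH = 10_000


@dataclass(frozen=True)
class ModuleSpec:
    """Co-expression module architecture.

    sizes
        number of genes per module.
    loadings
        per-module factor loading shared by its genes, in [0, 1].
    locus_effect
        effect (correlation scale) of the module-driving SNP on the factor;
        the factor is scaled to unit variance.
    """

    sizes: tuple[int, ...] = (50,)
    loadings: tuple[float, ...] = (0.7,)
    locus_effect: float = 0.7
    var_scale: float = 1.3  # SD multiplier keeping module genes most-variable

    def __post_init__(self):
        if len(self.sizes) != len(self.loadings):
            raise ValueError("module sizes and loadings must have equal length")
        if any(not (0.0 <= l <= 1.0) for l in self.loadings):
            raise ValueError("loadings must lie in [0, 1]")
        if not (0.0 <= self.locus_effect <= 1.0):
            raise ValueError("locus_effect must lie in [0, 1]")


@dataclass(frozen=True)
class GwasSpec:
    """Independent case/control cohort for the disease scan."""

    n_gwas_samples: int = 4000
    liability_effect: float = 0.3
    prevalence: float = 0.2
    test: str = "genotype"  # "genotype" (2x3 chi-square) or "trend" (1 df)

    def __post_init__(self):
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.test not in ("genotype", "trend"):
            raise ValueError("test must be 'genotype' or 'trend'")


@dataclass(frozen=True)
class CrossSpec:
    """F2 intercross layout and the L->G->T chain parameters."""

    n_f2: int = 554
    n_chromosomes: int = 2
    n_markers: int = 21  # per chromosome
    marker_spacing_cm: float = 5.0
    b_lg: float = 0.7
    b_gt: float = 0.7
    noise_sd: float = 1.0
    chain: str = "causal"  # causal | reactive | independent
    n_noise_genes: int = 20

    def __post_init__(self):
        if self.marker_spacing_cm < 0:
            raise ValueError("marker spacing in cM must be non-negative")
        if self.chain not in ("causal", "reactive", "independent"):
            raise ValueError("chain must be causal, reactive or independent")


@dataclass(frozen=True)
class SimConfig:
    """Full study configuration; ``seed`` pins every generator."""

    seed: int = 0
    n_samples: int = 300
    n_chromosomes: int = 2
    block_sizes: tuple[int, ...] = tuple([10] * 200)
    within_block_r: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 500
    cis_effect: float = 1.0
    n_cis_genes: int = 100
    module_spec: ModuleSpec = field(default_factory=ModuleSpec)
    gwas_spec: GwasSpec = field(default_factory=GwasSpec)
    cross_spec: CrossSpec = field(default_factory=CrossSpec)

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        lo, hi = self.maf_range
        if not (0.05 <= lo < hi <= 0.5):
            raise ValueError("maf_range must be an interval within (0.05, 0.5]")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValueError("within_block_r must lie in [0, 1)")
        if any(b <= 0 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if sum(self.module_spec.sizes) + self.n_cis_genes > self.n_genes:
            raise ValueError("module genes plus cis genes exceed n_genes")

    @property
    def n_snps(self) -> int:
        return int(sum(self.block_sizes))


# ---------------------------------------------------------------------------
# latent copula calibration


@lru_cache(maxsize=4096)
def _latent_rho(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation whose thresholded-pair phi equals target_r.

    For two standard normals with correlation rho, each thresholded at the
    MAF quantile q, the allele indicators have correlation
    phi(rho) = (Phi2(q, q; rho) - maf^2) / (maf (1 - maf)),
    which is continuous and increasing with phi(0)=0 and phi(1)=1 (equal
    MAF), so the equation phi(rho) = target has a unique root.
    """
    if target_r <= 0.0:
        return 0.0
    q = stats.norm.ppf(maf)
    denom = maf * (1.0 - maf)

    def gap(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [q, q], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
            allow_singular=True)
        return (p11 - maf * maf) / denom - target_r

    return brentq(gap, 0.0, 1.0 - 1e-9, xtol=1e-8)


def _block_genotypes(rng: np.random.Generator, n: int, m: int,
                     maf: float, target_r: float) -> np.ndarray:
    """n x m genotype block (allele counts 0/1/2) with pairwise correlation
    calibrated to target_r in expectation."""
    rho = _latent_rho(round(float(target_r), 6), round(float(maf), 6))
    q = stats.norm.ppf(maf)
    geno = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        shared = rng.standard_normal(n)[:, None]
        eps = rng.standard_normal((n, m))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
        geno += (z < q).astype(np.int8)
    return geno


# ---------------------------------------------------------------------------
# genotypes, SNP table, gene annotations


def simulate_genotypes(config: SimConfig):
    """Return (genotype DataFrame samples x SNPs, SNP table, gene table).

    SNPs are laid block by block on ``n_chromosomes`` chromosomes; genes tile
    each chromosome so every SNP has annotated genes within cis range.
    """
    rng = substream(config.seed, "genotypes")
    n, blocks = config.n_samples, list(config.block_sizes)
    lo, hi = config.maf_range
    # per-block MAF drawn strictly inside the configured range
    pad = 0.01 * (hi - lo)
    block_maf = rng.uniform(lo + pad, hi - pad, size=len(blocks))

    # assign blocks to chromosomes in contiguous, near-equal runs
    chrom_of_block = np.array_split(np.arange(len(blocks)), config.n_chromosomes)

    geno_cols, snp_rows = [], []
    chrom_extent: dict[str, int] = {}
    snp_counter = 0
    for ci, block_ids in enumerate(chrom_of_block):
        chrom = f"chr{ci + 1}"
        pos = _BLOCK_GAP
        for b in block_ids:
            m = blocks[b]
            geno_cols.append(_block_genotypes(rng, n, m, block_maf[b],
                                              config.within_block_r))
            for _ in range(m):
                snp_counter += 1
                snp_rows.append((f"rs{snp_counter:06d}", chrom, pos,
                                 float(block_maf[b]), int(b)))
                pos += _SNP_SPACING
            pos += _BLOCK_GAP
        chrom_extent[chrom] = pos

    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "maf", "block"])
    samples = [f"s{i + 1:04d}" for i in range(n)]
    geno = pd.DataFrame(np.hstack(geno_cols), index=samples, columns=snps["snp_id"])

    genes = _tile_genes(chrom_extent, config.n_genes)
    return geno, snps, genes


def _tile_genes(chrom_extent: dict[str, int], n_genes: int) -> pd.DataFrame:
    """Spread genes along each chromosome proportionally to its extent."""
    total = sum(chrom_extent.values())
    rows, gid = [], 0
    items = list(chrom_extent.items())
    alloc = [max(1, int(round(n_genes * ext / total))) for _, ext in items]
    # fix rounding drift so the total is exact
    while sum(alloc) > n_genes:
        alloc[int(np.argmax(alloc))] -= 1
    while sum(alloc) < n_genes:
        alloc[int(np.argmin(alloc))] += 1
    for (chrom, ext), k in zip(items, alloc):
        starts = np.linspace(_BLOCK_GAP, max(_BLOCK_GAP + 1, ext - _GENE_WIDTH),
                             k).astype(np.int64)
        for s in starts:
            gid += 1
            rows.append((f"gene{gid:04d}", chrom, int(s), int(s) + _GENE_WIDTH))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "stop"])


# ---------------------------------------------------------------------------
# expression


def module_gene_table(genes: pd.DataFrame, config: SimConfig) -> pd.Series:
    """Module label (1-based) per gene; 0 for genes outside every module.

    Modules occupy consecutive genes from the start of the gene table, which
    keeps module membership deterministic given the configuration.
    """
    labels = pd.Series(0, index=genes["gene_id"], dtype=int)
    offset = 0
    for j, size in enumerate(config.module_spec.sizes, start=1):
        labels.iloc[offset:offset + size] = j
        offset += size
    return labels


def module_driver_snps(snps: pd.DataFrame, genes: pd.DataFrame,
                       config: SimConfig) -> list[str]:
    """One driving SNP per module: the SNP nearest the module's first gene.

    Placing the driver in cis range of a module gene plants an end-to-end
    causal gene: its expression tags a SNP that also raises disease
    liability.
    """
    labels = module_gene_table(genes, config)
    drivers = []
    for j in range(1, len(config.module_spec.sizes) + 1):
        first_gene = genes.loc[genes["gene_id"].isin(labels.index[labels == j])].iloc[0]
        same = snps[snps["chrom"] == first_gene["chrom"]]
        mid = 0.5 * (first_gene["start"] + first_gene["stop"])
        drivers.append(same.iloc[int(np.argmin(np.abs(same["pos"] - mid)))]["snp_id"])
    return drivers


def designate_cis_pairs(snps: pd.DataFrame, genes: pd.DataFrame,
                        config: SimConfig, window: int = 1_000_000) -> pd.DataFrame:
    """Choose the planted (gene, cis SNP) pairs, outside the modules."""
    rng = substream(config.seed, "cis-pairs")
    labels = module_gene_table(genes, config)
    eligible = genes[genes["gene_id"].map(labels).eq(0)]
    chosen = eligible.iloc[rng.choice(len(eligible), size=config.n_cis_genes,
                                      replace=False)]
    rows = []
    for _, g in chosen.sort_values("gene_id").iterrows():
        near = snps[(snps["chrom"] == g["chrom"])
                    & (snps["pos"] >= g["start"] - window)
                    & (snps["pos"] <= g["stop"] + window)]
        if near.empty:
            continue
        rows.append((g["gene_id"], near.iloc[rng.integers(len(near))]["snp_id"]))
    return pd.DataFrame(rows, columns=["gene_id", "snp_id"])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def module_factors(geno: pd.DataFrame, snps: pd.DataFrame, genes: pd.DataFrame,
                   config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance module factors, each partly driven by its driver SNP."""
    drivers = module_driver_snps(snps, genes, config)
    le = config.module_spec.locus_effect
    cols = []
    for d in drivers:
        g = _standardize(geno[d].to_numpy(float))
        cols.append(le * g + np.sqrt(max(0.0, 1.0 - le * le))
                    * rng.standard_normal(len(g)))
    return np.column_stack(cols) if cols else np.empty((len(geno), 0))


def simulate_expression(geno: pd.DataFrame, snps: pd.DataFrame,
                        genes: pd.DataFrame, config: SimConfig,
                        pairs: pd.DataFrame | None = None,
                        window: int = 1_000_000) -> pd.DataFrame:
    """Expression (log-ratio scale): planted cis effects, module factors,
    unit-variance noise.  Designated pairs must satisfy the 1 Mb cis rule."""
    rng = substream(config.seed, "expression")
    if pairs is None:
        pairs = designate_cis_pairs(snps, genes, config, window=window)
    _check_cis(pairs, snps, genes, window)

    n = len(geno)
    expr = rng.standard_normal((n, len(genes)))
    gene_pos = {g: i for i, g in enumerate(genes["gene_id"])}

    # module genes: loading is the gene-factor correlation; the gene is the
    # unit-variance mixture scaled up so module genes rank as most variable
    factors = module_factors(geno, snps, genes, config, rng)
    labels = module_gene_table(genes, config)
    spec = config.module_spec
    for gene_id, lab in labels.items():
        if lab > 0:
            l = spec.loadings[lab - 1]
            j = gene_pos[gene_id]
            expr[:, j] = spec.var_scale * (
                l * factors[:, lab - 1] + np.sqrt(1.0 - l * l) * expr[:, j])

    for _, row in pairs.iterrows():
        expr[:, gene_pos[row["gene_id"]]] += (
            config.cis_effect * geno[row["snp_id"]].to_numpy(float))

    return pd.DataFrame(expr, index=geno.index, columns=genes["gene_id"].to_numpy())


def _check_cis(pairs: pd.DataFrame, snps: pd.DataFrame, genes: pd.DataFrame,
               window: int) -> None:
    s = snps.set_index("snp_id")
    g = genes.set_index("gene_id")
    for _, row in pairs.iterrows():
        snp, gene = s.loc[row["snp_id"]], g.loc[row["gene_id"]]
        ok = (snp["chrom"] == gene["chrom"]
              and gene["start"] - window <= snp["pos"] <= gene["stop"] + window)
        if not ok:
            raise ValueError(
                f"designated pair {row['snp_id']}-{row['gene_id']} violates the "
                f"{window} bp cis rule")


# ---------------------------------------------------------------------------
# GWAS


def genotype_chisq(geno: np.ndarray, case: np.ndarray, test: str = "genotype"):
    """Vectorized per-SNP case/control association p-values.

    geno: n x S allele counts; case: boolean n-vector.
    "genotype": contingency chi-square on the genotype x status table with
    degrees of freedom (classes present - 1); "trend": 1-df Cochran-Armitage
    (n r^2 against chi-square_1).
    """
    case = np.asarray(case, dtype=bool)
    n = len(case)
    if case.sum() == 0 or case.sum() == n:
        raise ValueError("need at least one case and one control")
    if test == "trend":
        g = np.asarray(geno, dtype=float)
        gz = g - g.mean(axis=0)
        cz = case.astype(float) - case.mean()
        denom = np.sqrt((gz ** 2).sum(axis=0) * (cz ** 2).sum())
        with np.errstate(invalid="ignore"):
            r = (gz * cz[:, None]).sum(axis=0) / denom
        stat = n * np.nan_to_num(r) ** 2
        return stats.chi2.sf(stat, df=1)

    counts = np.stack([
        np.stack([((geno == k) & (~case)[:, None]).sum(axis=0),
                  ((geno == k) & case[:, None]).sum(axis=0)], axis=1)
        for k in (0, 1, 2)], axis=1)  # S x 3 x 2
    col = counts.sum(axis=1, keepdims=True)       # status margins
    row = counts.sum(axis=2, keepdims=True)       # genotype margins
    expected = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = cells.sum(axis=(1, 2))
    classes = (row[:, :, 0] > 0).sum(axis=1)
    df = np.maximum(classes - 1, 1)
    p = stats.chi2.sf(stat, df=df)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_gwas(geno_pool: pd.DataFrame, snps: pd.DataFrame, config: SimConfig,
                  genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """GWAS summary table from an independently simulated case/control cohort.

    The cohort re-uses the SNP panel's block structure and MAFs (``geno_pool``
    fixes the panel identity; its samples are not reused).  Liability is a
    weighted sum of the module factors plus standard normal noise; cases are
    the top ``prevalence`` fraction of liability.
    """
    spec = config.gwas_spec
    rng = substream(config.seed, "gwas")
    n = spec.n_gwas_samples

    cols = []
    for b, grp in snps.groupby("block", sort=True):
        cols.append(_block_genotypes(rng, n, len(grp), float(grp["maf"].iloc[0]),
                                     config.within_block_r))
    geno = np.hstack(cols)
    order = np.concatenate([grp.index.to_numpy()
                            for _, grp in snps.groupby("block", sort=True)])
    geno = geno[:, np.argsort(order)]  # back to SNP-table order

    if genes is None:
        genes = _tile_genes({c: int(snps.loc[snps["chrom"] == c, "pos"].max())
                             for c in snps["chrom"].unique()}, config.n_genes)
    drivers = module_driver_snps(snps, genes, config)
    idx = {s: i for i, s in enumerate(snps["snp_id"])}
    le = config.module_spec.locus_effect
    liability = rng.standard_normal(n)
    for d in drivers:
        g = _standardize(geno[:, idx[d]].astype(float))
        factor = le * g + np.sqrt(max(0.0, 1.0 - le * le)) * rng.standard_normal(n)
        liability += spec.liability_effect * factor
    case = liability > np.quantile(liability, 1.0 - spec.prevalence)
    if case.sum() == 0 or (~case).sum() == 0:
        raise ValueError("liability threshold produced an empty case or control arm")

    p = genotype_chisq(geno, case, test=spec.test)
    return pd.DataFrame({"snp_id": snps["snp_id"], "chrom": snps["chrom"],
                         "pos": snps["pos"], "p": p})


# ---------------------------------------------------------------------------
# F2 cross


@dataclass
class CrossData:
    """F2 intercross bundle: genotypes coded 0/1/2 = AA/AB/BB."""

    geno: pd.DataFrame
    gmap: pd.DataFrame          # marker, chrom, cM
    expr: pd.DataFrame
    traits: pd.DataFrame
    focal_marker: str = ""
    focal_gene: str = ""
    chain: str = ""

    GENO_LABELS = ("AA", "AB", "BB")

    @property
    def additive(self) -> pd.DataFrame:
        return self.geno.astype(int) - 1

    @property
    def dominance(self) -> pd.DataFrame:
        return (self.geno == 1).astype(int)


def _haldane(d_cm: float) -> float:
    """Recombination fraction from map distance via Haldane's map function."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def simulate_f2_cross(config: SimConfig) -> CrossData:
    spec = config.cross_spec
    rng = substream(config.seed, "cross")
    n = spec.n_f2

    marker_names, chroms, cms, gametes = [], [], [], []
    for ci in range(spec.n_chromosomes):
        m = spec.n_markers
        cm = np.arange(m) * spec.marker_spacing_cm
        if np.any(np.diff(cm) < 0):
            raise ValueError("marker map must be non-decreasing in cM")
        c = _haldane(spec.marker_spacing_cm)
        chrom_gametes = []
        for _g in range(2):
            alleles = np.empty((n, m), dtype=np.int8)
            alleles[:, 0] = rng.random(n) < 0.5
            for k in range(1, m):
                flip = rng.random(n) < c
                alleles[:, k] = np.where(flip, 1 - alleles[:, k - 1],
                                         alleles[:, k - 1])
            chrom_gametes.append(alleles)
        gametes.append(chrom_gametes[0] + chrom_gametes[1])
        for k in range(m):
            marker_names.append(f"m{ci + 1:02d}_{k + 1:03d}")
            chroms.append(f"chr{ci + 1}")
            cms.append(float(cm[k]))

    geno = np.hstack(gametes)
    samples = [f"f2_{i + 1:04d}" for i in range(n)]
    geno_df = pd.DataFrame(geno, index=samples, columns=marker_names)
    gmap = pd.DataFrame({"marker": marker_names, "chrom": chroms, "cM": cms})

    # causal chain at the middle marker of chromosome 1
    focal_marker = marker_names[spec.n_markers // 2]
    a = geno_df[focal_marker].to_numpy(float) - 1.0
    e1 = spec.noise_sd * rng.standard_normal(n)
    e2 = spec.noise_sd * rng.standard_normal(n)
    if spec.chain == "causal":
        g_vec = spec.b_lg * a + e1
        t_vec = spec.b_gt * g_vec + e2
    elif spec.chain == "reactive":
        t_vec = spec.b_lg * a + e1
        g_vec = spec.b_gt * t_vec + e2
    else:  # independent
        g_vec = spec.b_lg * a + e1
        t_vec = spec.b_gt * a + e2

    focal_gene = "mgene0001"
    expr = rng.standard_normal((n, spec.n_noise_genes + 1))
    expr[:, 0] = g_vec
    expr_df = pd.DataFrame(
        expr, index=samples,
        columns=[focal_gene] + [f"mgene{i + 2:04d}" for i in range(spec.n_noise_genes)])

    # clinical traits: insulin carries the chain signal, glucose mirrors it
    # with flipped sign, islet count is positively correlated
    traits = pd.DataFrame({
        "insulin": t_vec,
        "glucose": -0.6 * t_vec + 0.8 * rng.standard_normal(n),
        "islet_count": 0.5 * t_vec + 0.87 * rng.standard_normal(n),
    }, index=samples)

    return CrossData(geno=geno_df, gmap=gmap, expr=expr_df, traits=traits,
                     focal_marker=focal_marker, focal_gene=focal_gene,
                     chain=spec.chain)
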