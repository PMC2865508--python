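"""eSNP detection: Kruskal-Wallis association per SNP-gene pair, cis/trans
classification by the 1 Mb rule, permutation-based empirical FDR, and
LD-pruned reporting (one top SNP per correlated group per trait).

The scan is rank-based so it is invariant to monotone transforms of
expression and robust to the heavy tails of log-ratio intensity data.  The
matrix engine (`kw_matrix`) computes tie-corrected Kruskal-Wallis H for all
SNP x gene pairs at once from genotype one-hot matrices and per-gene
midranks; `kruskal_wallis` is the scalar entry point used for single pairs
and delegates to scipy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .ld import DEFAULT_R_THRESHOLD

__all__ = ["kruskal_wallis", "classify_cis", "cis_pair_mask", "kw_matrix",
           "map_esnps", "prune_ld_per_gene", "ESNP_COLUMNS"]

ESNP_COLUMNS = ["snp_id", "gene_id", "mode", "kw_p", "fdr_pass", "tissue"]

CIS_WINDOW = 1_000_000


def kruskal_wallis(genotypes, expression) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected midranks) and chi-square p for one pair.

    Missing entries (NaN) are dropped pairwise.  Raises if fewer than two
    genotype groups remain.  A constant expression vector gives (0, 1): the
    ranks carry no information.
    """
    g = np.asarray(genotypes, dtype=float)
    x = np.asarray(expression, dtype=float)
    if g.shape != x.shape:
        raise ValueError("genotype and expression vectors differ in length")
    ok = ~(np.isnan(g) | np.isnan(x))
    g, x = g[ok], x[ok]
    levels = np.unique(g)
    if len(levels) < 2:
        raise ValueError("fewer than two genotype groups: SNP untestable")
    if np.ptp(x) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*[x[g == lv] for lv in levels])
    return float(h), float(p)


def classify_cis(snp, gene, window: int = CIS_WINDOW) -> str:
    """'cis' iff the SNP lies on the gene's chromosome within ``window`` bp of
    the gene body [start, stop]; distance exactly ``window`` counts as cis."""
    if snp["chrom"] != gene["chrom"]:
        return "trans"
    if gene["start"] - window <= snp["pos"] <= gene["stop"] + window:
        return "cis"
    return "trans"


def cis_pair_mask(snps: pd.DataFrame, genes: pd.DataFrame,
                  window: int = CIS_WINDOW) -> np.ndarray:
    """Boolean S x G matrix of cis pairs under the inclusive 1 Mb rule."""
    mask = np.zeros((len(snps), len(genes)), dtype=bool)
    for chrom in snps["chrom"].unique():
        si = np.nonzero((snps["chrom"] == chrom).to_numpy())[0]
        gi = np.nonzero((genes["chrom"] == chrom).to_numpy())[0]
        if not len(si) or not len(gi):
            continue
        pos = snps["pos"].to_numpy()[si][:, None]
        start = genes["start"].to_numpy()[gi][None, :]
        stop = genes["stop"].to_numpy()[gi][None, :]
        mask[np.ix_(si, gi)] = (pos >= start - window) & (pos <= stop + window)
    return mask


def kw_matrix(geno: np.ndarray, expr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tie-corrected Kruskal-Wallis p-values for every SNP x gene pair.

    geno: n x S int codes in {0,1,2}; expr: n x G.  Requires complete
    matrices (the simulator's output); pairs with missing data go through
    the scalar path.  Returns (p: S x G, df: S).
    """
    n, S = geno.shape[0], geno.shape[1]
    ranks = stats.rankdata(expr, axis=0)  # midranks, n x G
    # per-gene tie correction 1 - sum(t^3 - t) / (n^3 - n)
    corr = np.empty(expr.shape[1])
    for j in range(expr.shape[1]):
        _, counts = np.unique(expr[:, j], return_counts=True)
        corr[j] = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)

    onehot = [(geno == k) for k in (0, 1, 2)]  # n x S each
    counts = np.stack([oh.sum(axis=0) for oh in onehot])  # 3 x S
    h = np.zeros((S, expr.shape[1]))
    for oh, nk in zip(onehot, counts):
        sums = oh.T.astype(float) @ ranks  # S x G
        with np.errstate(divide="ignore", invalid="ignore"):
            h += np.where(nk[:, None] > 0, sums ** 2 / nk[:, None], 0.0)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(corr[None, :] > 0, h / corr[None, :], 0.0)
    h = np.clip(h, 0.0, None)

    df = (counts > 0).sum(axis=0) - 1  # S
    p = np.ones((S, expr.shape[1]))
    testable = df >= 1
    p[testable] = stats.chi2.sf(h[testable], df[testable, None])
    p[:, corr <= 0] = 1.0  # constant genes carry no information
    return p, df


def _fdr_threshold(obs: np.ndarray, null: np.ndarray, n_perm: int,
                   target: float) -> float:
    """Largest observed p-value t with plug-in FDR(t) < target, or -inf.

    FDR(t) = (mean permutation count of p <= t) / (observed count of p <= t).
    """
    if obs.size == 0:
        return -np.inf
    o = np.sort(obs)
    ns = np.sort(null)
    null_counts = np.searchsorted(ns, o, side="right") / n_perm
    fdr = null_counts / np.arange(1, len(o) + 1)
    ok = np.nonzero(fdr < target)[0]
    return float(o[ok.max()]) if len(ok) else -np.inf


def prune_ld_per_gene(table: pd.DataFrame, geno: pd.DataFrame,
                      r_threshold: float = DEFAULT_R_THRESHOLD) -> pd.DataFrame:
    """Per gene, collapse SNPs correlated at |r| > threshold (single linkage)
    to the one with the smallest p; ties broken by lexicographic snp_id."""
    kept = []
    for gene_id, grp in table.groupby("gene_id", sort=False):
        snp_ids = sorted(grp["snp_id"])
        if len(snp_ids) == 1:
            kept.append(grp)
            continue
        x = geno[snp_ids].to_numpy(float)
        x = x - x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = np.inf
        x = x / sd
        r = np.abs(x.T @ x) / x.shape[0]
        adj = r > r_threshold
        labels = _components(adj)
        grp = grp.set_index("snp_id").loc[snp_ids].reset_index()
        grp["_g"] = labels
        best = (grp.sort_values(["_g", "kw_p", "snp_id"])
                .groupby("_g", sort=True).head(1).drop(columns="_g"))
        kept.append(best)
    out = pd.concat(kept, ignore_index=True) if kept else table
    return out.sort_values(["gene_id", "snp_id"]).reset_index(drop=True)


def _components(adj: np.ndarray) -> np.ndarray:
    from scipy.sparse.csgraph import connected_components
    _, labels = connected_components(adj, directed=False)
    return labels


def map_esnps(geno: pd.DataFrame, snps: pd.DataFrame, expr: pd.DataFrame,
              genes: pd.DataFrame, *, window: int = CIS_WINDOW,
              fdr_target: float = 0.10, n_perm: int = 10, seed: int = 0,
              include_trans: bool = True, max_trans_pairs: int | None = None,
              r_threshold: float = DEFAULT_R_THRESHOLD,
              tissue: str = "tissue", prune: bool = True) -> pd.DataFrame:
    """Scan all eligible SNP x gene pairs and report FDR-passing eSNPs.

    Cis tests are restricted to the 1 Mb window; trans tests cover every
    remaining pair (optionally capped by ``max_trans_pairs``, subsampled
    deterministically from the seed).  The permutation null shuffles the
    expression sample labels as a whole matrix ``n_perm`` times, preserving
    the gene-gene correlation structure; cis permutations are restricted to
    the same cis windows as the observed tests.  The FDR threshold is chosen
    separately for the cis and trans families (a global plug-in estimator
    within each family), and passing associations are LD-pruned per gene.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if list(geno.index) != list(expr.index):
        raise ValueError("sample identifiers differ between genotypes and expression")

    rng = substream(seed, "eqtl-perm")
    gmat = geno[snps["snp_id"]].to_numpy()
    if np.isnan(gmat.astype(float)).any():
        raise ValueError("map_esnps requires a complete genotype matrix")
    emat = expr[genes["gene_id"]].to_numpy(float)
    n = gmat.shape[0]

    cis = cis_pair_mask(snps, genes, window)
    trans = ~cis
    if not include_trans:
        trans[:] = False
    elif max_trans_pairs is not None and trans.sum() > max_trans_pairs:
        flat = np.nonzero(trans.ravel())[0]
        keep = rng.choice(flat, size=max_trans_pairs, replace=False)
        trans[:] = False
        trans.ravel()[keep] = True

    p_obs, df = kw_matrix(gmat, emat)
    testable = df >= 1
    cis &= testable[:, None]
    trans &= testable[:, None]
    if not cis.any() and not trans.any():
        warnings.warn("no testable SNP-gene pairs", stacklevel=2)
        return pd.DataFrame(columns=ESNP_COLUMNS)

    null_cis, null_trans = [], []
    for _ in range(n_perm):
        perm = rng.permutation(n)
        p_perm, _ = kw_matrix(gmat, emat[perm])
        null_cis.append(p_perm[cis])
        null_trans.append(p_perm[trans])

    rows = []
    for mask, nulls, mode in ((cis, null_cis, "cis"), (trans, null_trans, "trans")):
        obs = p_obs[mask]
        if obs.size == 0:
            continue
        t = _fdr_threshold(obs, np.concatenate(nulls), n_perm, fdr_target)
        si, gi = np.nonzero(mask)
        hit = p_obs[si, gi] <= t
        for a, b in zip(si[hit], gi[hit]):
            rows.append((snps["snp_id"].iloc[a], genes["gene_id"].iloc[b],
                         mode, float(p_obs[a, b]), True, tissue))

    table = pd.DataFrame(rows, columns=ESNP_COLUMNS)
    if table.empty or not prune:
        return table
    return prune_ld_per_gene(table, geno, r_threshold)
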