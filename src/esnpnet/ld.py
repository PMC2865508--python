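"""Linkage-disequilibrium machinery: pairwise genotype correlation, LD
grouping, one-hop set expansion at |r| > 0.89, and MAF binning.

Throughout the package "correlation > 0.89" means the absolute Pearson
correlation of 0/1/2 allele-count codes (not r-squared): composite genotype
correlation needs no phasing and is what a genotype matrix supports
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["LdExpansion", "ld_corr", "ld_groups", "expand_set", "maf_bin",
           "LdNeighborhood", "DEFAULT_R_THRESHOLD", "MAF_BIN_EDGES"]

DEFAULT_R_THRESHOLD = 0.89

# right-closed bin edges over the eligible MAF range (5%, 50%]
MAF_BIN_EDGES = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


def ld_corr(g1, g2) -> float:
    """|Pearson r| between two genotype vectors over shared non-missing samples."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors differ in length")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    if ok.sum() < 3:
        raise ValueError("fewer than 3 overlapping non-missing samples")
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a monomorphic genotype vector")
    return float(abs(np.corrcoef(a, b)[0, 1]))


def _std_matrix(geno: np.ndarray) -> np.ndarray:
    """Column-standardized genotype matrix (missing values mean-imputed).

    With the imputation, X.T @ X / n is the pairwise Pearson correlation up
    to the (small) attenuation missingness introduces; the simulator emits
    complete matrices, where this is exact.
    """
    x = np.asarray(geno, dtype=float)
    mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mean, x) - mean
    sd = x.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic columns correlate with nothing
    return x / sd


def ld_groups(geno: pd.DataFrame, snps: pd.DataFrame,
              r_threshold: float = DEFAULT_R_THRESHOLD,
              window: int | None = 1_000_000) -> pd.Series:
    """Single-linkage LD groups: connected components of the graph joining
    SNPs within ``window`` bp whose |r| exceeds ``r_threshold``.

    Returns a Series mapping snp_id -> integer group id; ids are assigned in
    (chrom, pos, snp_id) order of each group's first member, so the result
    does not depend on the input row order.
    """
    order = snps.sort_values(["chrom", "pos", "snp_id"]).reset_index(drop=True)
    ids = order["snp_id"].to_numpy()
    x = _std_matrix(geno[ids].to_numpy())
    n = x.shape[0]

    rows, cols = [], []
    for chrom, grp in order.groupby("chrom", sort=False):
        gi = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        for a in range(len(gi)):
            if window is None:
                hi = len(gi)
            else:
                hi = int(np.searchsorted(pos, pos[a] + window, side="right"))
            if hi <= a + 1:
                continue
            r = np.abs(x[:, gi[a]] @ x[:, gi[a + 1:hi]]) / n
            hit = np.nonzero(r > r_threshold)[0]
            rows.extend([gi[a]] * len(hit))
            cols.extend(gi[a + 1 + hit])

    m = len(ids)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    _, labels = connected_components(graph, directed=False)
    # relabel components by first occurrence in sorted order
    remap, out = {}, np.empty(m, dtype=int)
    for i, lab in enumerate(labels):
        out[i] = remap.setdefault(lab, len(remap))
    return pd.Series(out, index=ids, name="ld_group")


@dataclass
class LdExpansion:
    """One-hop LD expansion of a core SNP set."""

    core_set: set
    expanded_set: set
    r_threshold: float = DEFAULT_R_THRESHOLD
    anchors: dict = field(default_factory=dict)  # added snp -> (core snp, r)


class LdNeighborhood:
    """Precomputed |r| > threshold partner lists for a genotype panel.

    Expansion during matched resampling calls this thousands of times, so
    partners are computed once (within a positional window per chromosome)
    and looked up afterwards.
    """

    def __init__(self, geno: pd.DataFrame, snps: pd.DataFrame,
                 r_threshold: float = DEFAULT_R_THRESHOLD,
                 window: int | None = 1_000_000):
        self.r_threshold = float(r_threshold)
        order = snps.sort_values(["chrom", "pos", "snp_id"]).reset_index(drop=True)
        ids = order["snp_id"].to_numpy()
        x = _std_matrix(geno[ids].to_numpy())
        n = x.shape[0]
        partners: dict[str, list] = {s: [] for s in ids}
        rvals: dict[tuple, float] = {}
        for chrom, grp in order.groupby("chrom", sort=False):
            gi = grp.index.to_numpy()
            pos = grp["pos"].to_numpy()
            for a in range(len(gi)):
                hi = len(gi) if window is None else int(
                    np.searchsorted(pos, pos[a] + window, side="right"))
                if hi <= a + 1:
                    continue
                r = np.abs(x[:, gi[a]] @ x[:, gi[a + 1:hi]]) / n
                for off in np.nonzero(r > self.r_threshold)[0]:
                    sa, sb = ids[gi[a]], ids[gi[a + 1 + off]]
                    partners[sa].append(sb)
                    partners[sb].append(sa)
                    rvals[(sa, sb)] = rvals[(sb, sa)] = float(r[off])
        self._partners = partners
        self._r = rvals

    def partners(self, snp_id: str) -> list:
        return self._partners.get(snp_id, [])

    def r(self, a: str, b: str) -> float:
        return self._r[(a, b)]

    def expand(self, core) -> set:
        out = set(core)
        for s in core:
            out.update(self._partners.get(s, ()))
        return out


def expand_set(core, geno: pd.DataFrame, snps: pd.DataFrame,
               r_threshold: float = DEFAULT_R_THRESHOLD) -> LdExpansion:
    """Expand ``core`` by every panel SNP with |r| > threshold to a core member.

    One hop only: partners of partners are not chased, mirroring the proxy
    logic of tagging a core SNP on another genotyping panel.
    """
    core = set(core)
    if not core:
        warnings.warn("empty core set: expansion is empty", stacklevel=2)
        return LdExpansion(core_set=set(), expanded_set=set(),
                           r_threshold=r_threshold)
    missing = core - set(snps["snp_id"])
    if missing:
        raise KeyError(f"core SNPs absent from the SNP table: {sorted(missing)[:5]}")

    ids = snps["snp_id"].to_numpy()
    x = _std_matrix(geno[ids].to_numpy())
    n = x.shape[0]
    core_ids = sorted(core)
    core_idx = [int(np.nonzero(ids == c)[0][0]) for c in core_ids]
    r = np.abs(x[:, core_idx].T @ x) / n  # n_core x n_snps

    anchors = {}
    expanded = set(core)
    for j in range(len(ids)):
        if ids[j] in core:
            continue
        hits = np.nonzero(r[:, j] > r_threshold)[0]
        if len(hits):
            best = hits[int(np.argmax(r[hits, j]))]
            expanded.add(ids[j])
            anchors[ids[j]] = (core_ids[best], float(r[best, j]))
    return LdExpansion(core_set=core, expanded_set=expanded,
                       r_threshold=r_threshold, anchors=anchors)


def maf_bin(maf: float) -> int:
    """Bin index 1-5 for MAF in (5,10], (10,20], (20,30], (30,40], (40,50]%."""
    if not (MAF_BIN_EDGES[0] < maf <= MAF_BIN_EDGES[-1]):
        raise ValueError(f"MAF {maf!r} outside the eligible range (0.05, 0.5]")
    return int(np.searchsorted(MAF_BIN_EDGES, maf, side="left"))
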