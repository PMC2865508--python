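"""Weighted co-expression network: variable-gene selection, soft-thresholded
adjacency, topological overlap, module detection by hierarchical clustering,
eigengene summaries, and module-trait correlation.

The adjacency is unsigned, a_ij = |cor(i, j)|^beta (a signed variant is
available); the topological overlap of two genes credits shared neighbours
as well as the direct edge,

    omega_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with connectivity k_i = sum_u a_iu and unit diagonal.  Modules are branches
of the average-linkage dendrogram of 1 - omega under a static height cut;
clusters below the minimum size are left unassigned (label 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["TomMatrix", "ModuleAssignment", "Eigengene",
           "rank_variable_genes", "adjacency", "topological_overlap",
           "coexpression_modules", "module_eigengene", "module_trait_cor",
           "pick_soft_threshold"]


@dataclass
class TomMatrix:
    genes: list
    values: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]


@dataclass
class ModuleAssignment:
    labels: pd.Series             # gene -> module label, 0 = unassigned
    beta: float
    cut_height: float
    min_size: int

    def genes_in(self, module: int) -> list:
        return list(self.labels.index[self.labels == module])


@dataclass
class Eigengene:
    module: int
    scores: pd.Series             # per-sample, unit norm
    var_explained: float


def rank_variable_genes(expr: pd.DataFrame, top_frac: float = 0.25) -> list:
    """Top ``top_frac`` of genes by expression variance (ceiling count).

    Variance of the log-ratio values is the spread measure; ties are broken
    by gene id so the selection is reproducible.
    """
    if not (0.0 < top_frac <= 1.0):
        raise ValueError("top_frac must lie in (0, 1]")
    if expr.shape[1] < 8:
        raise ValueError("need at least 8 genes to rank")
    var = expr.var(axis=0, ddof=1)
    order = sorted(expr.columns, key=lambda g: (-var[g], g))
    k = int(np.ceil(top_frac * expr.shape[1]))
    return order[:k]


def adjacency(expr: pd.DataFrame, beta: float = 6.0,
              signed: bool = False) -> np.ndarray:
    x = expr.to_numpy(float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = expr.columns[np.nonzero(sd == 0)[0][0]]
        raise ValueError(f"constant gene {bad!r}: correlation undefined")
    r = np.corrcoef(x, rowvar=False)
    if signed:
        a = ((1.0 + r) / 2.0) ** beta
    else:
        a = np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def topological_overlap(a: np.ndarray) -> np.ndarray:
    """TOM from an adjacency with zero diagonal; returns unit-diagonal matrix."""
    k = a.sum(axis=0)
    shared = a @ a
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def pick_soft_threshold(expr: pd.DataFrame, betas=range(1, 13),
                        fit_target: float = 0.8, n_bins: int = 10) -> float:
    """Smallest beta whose connectivity distribution fits a power law with
    R^2 >= fit_target (scale-free criterion); falls back to the best fit."""
    best_beta, best_fit = None, -np.inf
    for beta in betas:
        k = adjacency(expr, beta=beta).sum(axis=0)
        k = k[k > 0]
        if len(k) < n_bins:
            continue
        hist, edges = np.histogram(k, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ok = hist > 0
        if ok.sum() < 3:
            continue
        lx, ly = np.log10(centers[ok]), np.log10(hist[ok])
        r2 = stats.pearsonr(lx, ly)[0] ** 2
        if r2 >= fit_target:
            return float(beta)
        if r2 > best_fit:
            best_beta, best_fit = beta, r2
    return float(best_beta if best_beta is not None else 6.0)


def coexpression_modules(expr: pd.DataFrame, beta: float = 6.0,
                         cut_height: float = 0.99, min_size: int = 30,
                         signed: bool = False
                         ) -> tuple[TomMatrix, ModuleAssignment]:
    """Build the weighted network and cut modules from the TOM dendrogram.

    Module labels are 1..M in decreasing module size (ties broken by the
    lexicographically smallest member gene), 0 for unassigned genes, so the
    labelling does not depend on gene input order.
    """
    if expr.shape[1] < 2 * min_size:
        raise ValueError("need at least 2 x min_size genes")
    genes = sorted(expr.columns)
    a = adjacency(expr[genes], beta=beta, signed=signed)
    tom = topological_overlap(a)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    labels = pd.Series(0, index=pd.Index(genes, name="gene_id"), dtype=int)
    clusters = []
    for lab in np.unique(raw):
        members = [g for g, r in zip(genes, raw) if r == lab]
        if len(members) >= min_size:
            clusters.append(members)
    clusters.sort(key=lambda ms: (-len(ms), ms[0]))
    for new_lab, members in enumerate(clusters, start=1):
        labels.loc[members] = new_lab

    return (TomMatrix(genes=genes, values=tom),
            ModuleAssignment(labels=labels, beta=beta, cut_height=cut_height,
                             min_size=min_size))


def module_eigengene(expr: pd.DataFrame, module_genes) -> Eigengene:
    """First principal component of the z-scored module expression.

    Scores have unit norm; var_explained is the leading eigenvalue share.
    Orientation: the eigengene correlates positively with the module's mean
    expression profile, so "module up" means scores up.
    """
    module_genes = list(module_genes)
    if len(module_genes) < 2:
        raise ValueError("module must contain at least 2 genes")
    x = expr[module_genes].to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant gene in module")
    z = (x - x.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, 0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    mean_profile = z.mean(axis=1)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    return Eigengene(module=-1,
                     scores=pd.Series(scores, index=expr.index),
                     var_explained=var_explained)


def module_trait_cor(eigengene: Eigengene, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided t-test p of the eigengene against each trait."""
    common = eigengene.scores.index.intersection(traits.index)
    if len(common) < 10:
        raise ValueError("need at least 10 paired samples")
    e = eigengene.scores.loc[common].to_numpy()
    rows = []
    for trait in traits.columns:
        t = traits.loc[common, trait].to_numpy(float)
        if np.std(t) == 0:
            raise ValueError(f"constant trait {trait!r}")
        r, p = stats.pearsonr(e, t)
        rows.append((trait, float(r), float(p)))
    return pd.DataFrame(rows, columns=["trait", "r", "p"]).set_index("trait")
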