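"""F2-cross genetics: single-marker LOD scans, forward stepwise multi-QTL
selection, a bivariate pleiotropy LRT, likelihood-based causal / reactive /
independent classification of (locus, expression, trait) triples, and the
three-criteria candidate filter combining mouse and human evidence.

Markers are coded additively (a = genotype - 1 over AA/AB/BB) plus a
dominance indicator (d = heterozygote); every fit is ordinary least squares
on those codes, which is exact at the markers (and the simulator places
markers densely enough that interval-mixture refinements add nothing).

The causal inference compares three linear-Gaussian factorizations of the
joint density of locus L, expression G and clinical trait T:

    causal       P(L) P(G|L) P(T|G)     L -> G -> T
    reactive     P(L) P(T|L) P(G|T)     L -> T -> G
    independent  P(L) P(G|L) P(T|L)     L -> G,  L -> T

The winner is the model with the smallest AIC; a configurable AIC margin
over the runner-up decides when a call counts as *supported*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CrossData

__all__ = ["LodCurve", "QtlHit", "CausalCall", "qtl_scan",
           "forward_stepwise_qtl", "pleiotropy_test", "causal_model_select",
           "candidate_filter", "lod_from_r2"]


@dataclass
class LodCurve:
    lod: pd.Series      # marker -> LOD >= 0
    trait: str = ""

    def max(self) -> tuple[str, float]:
        m = self.lod.idxmax()
        return m, float(self.lod.loc[m])


@dataclass
class QtlHit:
    marker: str
    lod: float          # conditional LOD at inclusion


@dataclass
class CausalCall:
    gene_id: str
    trait: str
    locus: str
    aic: dict
    model: str = field(init=False)
    margin: float = field(init=False)

    def __post_init__(self):
        order = sorted(self.aic, key=lambda k: (self.aic[k], k))
        self.model = order[0]
        self.margin = self.aic[order[1]] - self.aic[order[0]]


def _design(cross: CrossData, markers: list[str]) -> np.ndarray:
    cols = [np.ones(len(cross.geno))]
    for m in markers:
        g = cross.geno[m].to_numpy(float)
        cols.append(g - 1.0)
        cols.append((g == 1.0).astype(float))
    return np.column_stack(cols)


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def lod_from_r2(r2: float, n: int) -> float:
    """LOD of a fit with coefficient of determination r2 at sample size n."""
    return float(-(n / 2.0) * np.log10(1.0 - r2))


def qtl_scan(cross: CrossData, trait) -> LodCurve:
    """Additive + dominance regression LOD at every marker."""
    y = _trait_vector(cross, trait)
    ok = ~np.isnan(y)
    if ok.sum() < 30:
        raise ValueError("fewer than 30 informative individuals")
    y = y[ok]
    if np.ptp(y) == 0:
        raise ValueError("constant trait")
    n = len(y)
    rss0 = float(((y - y.mean()) ** 2).sum())
    lods = {}
    for m in cross.geno.columns:
        g = cross.geno[m].to_numpy(float)[ok]
        x = np.column_stack([np.ones(n), g - 1.0, (g == 1.0).astype(float)])
        rss1 = _rss(x, y)
        lods[m] = max(0.0, (n / 2.0) * np.log10(rss0 / rss1)) if rss1 > 0 \
            else float("inf")
    name = trait if isinstance(trait, str) else ""
    return LodCurve(lod=pd.Series(lods), trait=name)


def _trait_vector(cross: CrossData, trait) -> np.ndarray:
    if isinstance(trait, str):
        if trait in cross.traits.columns:
            return cross.traits[trait].to_numpy(float)
        return cross.expr[trait].to_numpy(float)
    return np.asarray(trait, dtype=float)


def forward_stepwise_qtl(cross: CrossData, trait, lod_threshold: float = 3.0,
                         max_qtl: int | None = None) -> list[QtlHit]:
    """Greedy multi-QTL selection: repeatedly add the marker with the best
    conditional LOD given the selected markers while it exceeds the
    threshold."""
    y = _trait_vector(cross, trait)
    ok = ~np.isnan(y)
    y = y[ok]
    n = len(y)
    if np.ptp(y) == 0:
        raise ValueError("constant trait")
    selected: list[QtlHit] = []
    markers = list(cross.geno.columns)
    current_rss = float(((y - y.mean()) ** 2).sum())
    while max_qtl is None or len(selected) < max_qtl:
        chosen = [h.marker for h in selected]
        best = None
        for m in markers:
            if m in chosen:
                continue
            x = _design(cross, chosen + [m])[ok]
            rss = _rss(x, y)
            lod = (n / 2.0) * np.log10(current_rss / rss) if rss > 0 \
                else float("inf")
            if best is None or lod > best[1] or (lod == best[1] and m < best[0]):
                best = (m, lod, rss)
        if best is None or best[1] <= lod_threshold:
            break
        selected.append(QtlHit(marker=best[0], lod=float(best[1])))
        current_rss = best[2]
    return selected


def pleiotropy_test(geno, trait1, trait2) -> tuple[float, float]:
    """Bivariate Gaussian LRT: does the marker affect the trait pair?

    Full model regresses both traits on additive + dominance codes with an
    unconstrained residual covariance; the null drops the marker from both.
    The statistic n log(det S0 / det S1) is referred to chi-square with 4
    degrees of freedom (two codes x two traits).
    """
    g = np.asarray(geno, dtype=float)
    y = np.column_stack([np.asarray(trait1, float), np.asarray(trait2, float)])
    ok = ~(np.isnan(g) | np.isnan(y).any(axis=1))
    g, y = g[ok], y[ok]
    n = len(g)
    if n < 30:
        raise ValueError("fewer than 30 jointly complete individuals")
    if np.allclose(y[:, 0], y[:, 1]):
        raise ValueError("identical traits: residual covariance is singular")
    x1 = np.column_stack([np.ones(n), g - 1.0, (g == 1.0).astype(float)])
    x0 = np.ones((n, 1))

    def resid_cov(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        e = y - x @ beta
        return e.T @ e / n

    s0, s1 = resid_cov(x0), resid_cov(x1)
    d0, d1 = np.linalg.det(s0), np.linalg.det(s1)
    if d1 <= 0:
        raise ValueError("singular residual covariance")
    stat = n * np.log(d0 / d1)
    return float(stat), float(stats.chi2.sf(stat, df=4))


def _gauss_loglik(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Profile log-likelihood and parameter count of y ~ x (OLS, MLE sigma)."""
    n = len(y)
    rss = _rss(x, y)
    if rss <= 0:
        raise ValueError("degenerate residual variance")
    sigma2 = rss / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return ll, x.shape[1] + 1  # coefficients + variance


def causal_model_select(L, G, T, gene_id: str = "", trait: str = "",
                        locus: str = "") -> CausalCall:
    """Pick the best-supported dependency structure for (L, G, T) by AIC.

    The shared P(L) factor cancels between models and is omitted.  Genotype
    enters through additive + dominance codes; G and T enter conditional
    densities linearly.
    """
    g0 = np.asarray(L, dtype=float)
    gv = np.asarray(G, dtype=float)
    tv = np.asarray(T, dtype=float)
    ok = ~(np.isnan(g0) | np.isnan(gv) | np.isnan(tv))
    g0, gv, tv = g0[ok], gv[ok], tv[ok]
    if np.ptp(gv) == 0 or np.ptp(tv) == 0:
        raise ValueError("degenerate variance in G or T")
    n = len(g0)
    xl = np.column_stack([np.ones(n), g0 - 1.0, (g0 == 1.0).astype(float)])

    def on(v):
        return np.column_stack([np.ones(n), v])

    aic = {}
    ll, k = _gauss_loglik(xl, gv)
    ll2, k2 = _gauss_loglik(on(gv), tv)
    aic["causal"] = 2.0 * (k + k2) - 2.0 * (ll + ll2)

    ll, k = _gauss_loglik(xl, tv)
    ll2, k2 = _gauss_loglik(on(tv), gv)
    aic["reactive"] = 2.0 * (k + k2) - 2.0 * (ll + ll2)

    ll, k = _gauss_loglik(xl, gv)
    ll2, k2 = _gauss_loglik(xl, tv)
    aic["independent"] = 2.0 * (k + k2) - 2.0 * (ll + ll2)

    return CausalCall(gene_id=gene_id, trait=trait, locus=locus, aic=aic)


def candidate_filter(module_genes, mouse_genes: pd.DataFrame,
                     mouse_cis_eqtl: pd.DataFrame,
                     causal_calls: pd.DataFrame,
                     interval: tuple[str, int, int],
                     human_esnps: pd.DataFrame, gwas: pd.DataFrame,
                     orthologs: pd.DataFrame, *,
                     p_threshold: float = 0.05, lod_threshold: float = 3.0,
                     causal_margin: float = 2.0) -> pd.DataFrame:
    """Three-criteria susceptibility-gene filter over a module's genes.

    1. the gene body lies inside the linkage interval and has a cis eQTL
       with LOD >= ``lod_threshold`` (``mouse_cis_eqtl``: gene_id, lod);
    2. a causal call (winner 'causal' with AIC margin >= ``causal_margin``)
       for at least one clinical trait (``causal_calls``: gene_id, trait,
       model, margin);
    3. the human ortholog has a cis eSNP whose GWAS p is < ``p_threshold``
       (``human_esnps``: snp_id, gene_id, mode; ``orthologs``: mouse_id,
       human_id).

    Returns one row per passing gene, ordered by ascending best human GWAS
    p, with the supporting evidence attached.  Module genes without an
    ortholog are logged and skipped.
    """
    import logging
    log = logging.getLogger(__name__)

    chrom, lo, hi = interval
    mg = mouse_genes.set_index("gene_id")
    ortho = orthologs.set_index("mouse_id")["human_id"]
    score = gwas.set_index("snp_id")["p"]
    cis_lod = (mouse_cis_eqtl.groupby("gene_id")["lod"].max()
               if len(mouse_cis_eqtl) else pd.Series(dtype=float))
    supported = causal_calls[
        (causal_calls["model"] == "causal")
        & (causal_calls["margin"] >= causal_margin)]
    human_cis = human_esnps[human_esnps["mode"] == "cis"]

    rows, skipped = [], 0
    for gene in module_genes:
        if gene not in ortho.index:
            skipped += 1
            continue
        if gene not in mg.index:
            continue
        ann = mg.loc[gene]
        in_interval = (ann["chrom"] == chrom and ann["start"] >= lo
                       and ann["stop"] <= hi)
        lod = float(cis_lod.get(gene, 0.0))
        if not (in_interval and lod >= lod_threshold):
            continue
        traits = sorted(supported.loc[supported["gene_id"] == gene, "trait"])
        if not traits:
            continue
        human_id = ortho.loc[gene]
        esnps = human_cis[human_cis["gene_id"] == human_id]
        if esnps.empty:
            continue
        ps = score.reindex(esnps["snp_id"]).dropna()
        ps = ps[ps < p_threshold]
        if ps.empty:
            continue
        best_snp = ps.idxmin()
        rows.append((gene, human_id, lod, ";".join(traits), best_snp,
                     float(ps.min())))
    if skipped:
        log.info("skipped %d module genes without an ortholog", skipped)
    out = pd.DataFrame(rows, columns=["gene_id", "human_id", "cis_lod",
                                      "causal_traits", "best_snp", "p_t2d"])
    return out.sort_values(["p_t2d", "gene_id"]).reset_index(drop=True)
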