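"""Gene-set statistics: hypergeometric over-representation with fold
enrichment, two-group t-test expression signatures with q-value FDR, and
sex-adjusted phenotype comparisons with per-sex percent changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = ["GeneSetEnrichment", "hypergeom_enrich", "ttest_signature",
           "qvalue", "phenotype_compare", "PhenotypeComparison",
           "percent_change"]


@dataclass
class GeneSetEnrichment:
    k: int          # overlap
    n: int          # query (e.g. module) size
    K: int          # gene-set size
    N: int          # universe size
    expected: float
    fold: float
    p: float        # upper-tail P(X >= k)


def hypergeom_enrich(k: int, n: int, K: int, N: int) -> GeneSetEnrichment:
    """One-sided over-representation test of a k-gene overlap.

    The upper tail is accumulated in log space (logsumexp over the pmf), so
    p-values far below the double underflow of naive summation, of order
    1e-70 in deeply enriched modules, are still exact.  The expected overlap
    is n K / N and fold = k / expected.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    expected = n * K / N
    fold = k / expected if expected > 0 else float("nan")
    if k == 0:
        p = 1.0
    else:
        xs = np.arange(k, min(n, K) + 1)
        p = float(np.exp(logsumexp(stats.hypergeom.logpmf(xs, N, K, n))))
    return GeneSetEnrichment(k=k, n=n, K=K, N=N, expected=expected,
                             fold=fold, p=min(p, 1.0))


def qvalue(p, lam: float = 0.5) -> tuple[np.ndarray, float]:
    """Storey q-values with the single-lambda pi0 estimator.

    pi0 = #{p > lam} / (m (1 - lam)), capped at 1;
    q_i = min over thresholds t >= p_i of pi0 m t / #{p <= t}.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    pi0 = min(1.0, (p > lam).sum() / (m * (1.0 - lam)))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


def ttest_signature(expr_ko: pd.DataFrame, expr_wt: pd.DataFrame,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Equal-variance two-sample t per gene between knockout and wild type.

    Returns one row per gene: t, p, q, direction ('up'/'down' in the
    knockout), in_signature (p < alpha), degenerate flag for genes with zero
    variance in both groups (p forced to 1).  Attrs carry pi0 and the
    estimated FDR realized at alpha.
    """
    genes = list(expr_ko.columns)
    if list(expr_wt.columns) != genes:
        raise ValueError("knockout and wild-type matrices must share genes")
    if len(expr_ko) < 2 or len(expr_wt) < 2:
        raise ValueError("need at least 2 samples per group")
    a = expr_ko.to_numpy(float)
    b = expr_wt.to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    degenerate = np.isnan(p)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q, pi0 = qvalue(p)
    diff = a.mean(axis=0) - b.mean(axis=0)
    out = pd.DataFrame({
        "gene_id": genes, "t": t, "p": p, "q": q,
        "direction": np.where(diff >= 0, "up", "down"),
        "in_signature": p < alpha, "degenerate": degenerate,
    })
    n_sig = int(out["in_signature"].sum())
    out.attrs["pi0"] = pi0
    out.attrs["fdr_at_alpha"] = (pi0 * len(genes) * alpha / n_sig
                                 if n_sig else float("nan"))
    return out


@dataclass
class PhenotypeComparison:
    trait: str
    per_sex: pd.DataFrame   # rows: sex; columns: mean_wt, sd_wt, mean_ko, sd_ko, pct_change
    p_adjusted: float       # sex-adjusted genotype effect


def phenotype_compare(values, genotype, sex, trait: str = "",
                      ko_label="ko", wt_label="wt") -> PhenotypeComparison:
    """Percent change per sex and a sex-adjusted group-difference test.

    Percent change is 100 (mean_ko - mean_wt) / mean_wt within each sex.
    The adjusted p comes from the t statistic of the genotype coefficient in
    the linear model  trait ~ genotype + sex.
    """
    df = pd.DataFrame({"y": np.asarray(values, float),
                       "geno": list(genotype), "sex": list(sex)}).dropna()
    groups = set(df["geno"])
    if not {ko_label, wt_label} <= groups:
        raise ValueError("both genotype groups must be present")

    rows = []
    for s in sorted(set(df["sex"])):
        sub = df[df["sex"] == s]
        wt = sub.loc[sub["geno"] == wt_label, "y"]
        ko = sub.loc[sub["geno"] == ko_label, "y"]
        if len(wt) == 0 or len(ko) == 0:
            continue  # adjusted test still runs; per-sex change needs both
        rows.append((s, wt.mean(), wt.std(ddof=1), ko.mean(), ko.std(ddof=1),
                     100.0 * (ko.mean() - wt.mean()) / wt.mean()))
    per_sex = pd.DataFrame(rows, columns=["sex", "mean_wt", "sd_wt", "mean_ko",
                                          "sd_ko", "pct_change"]).set_index("sex")

    y = df["y"].to_numpy()
    g = (df["geno"] == ko_label).to_numpy(float)
    sexes = sorted(set(df["sex"]))
    x = np.column_stack([np.ones(len(df)), g]
                        + [(df["sex"] == s).to_numpy(float) for s in sexes[1:]])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = len(y) - x.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(x.T @ x)
    tstat = beta[1] / np.sqrt(cov[1, 1])
    p = 2.0 * stats.t.sf(abs(tstat), dof)
    return PhenotypeComparison(trait=trait, per_sex=per_sex, p_adjusted=float(p))


def percent_change(mean_ko: float, mean_wt: float) -> float:
    """100 (ko - wt) / wt; the sign convention used in phenotype tables."""
    return 100.0 * (mean_ko - mean_wt) / mean_wt
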