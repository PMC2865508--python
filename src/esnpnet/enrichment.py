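"""Matched-resampling SNP-set enrichment against GWAS summary statistics.

The question: is a focal SNP set (e.g. eSNPs) enriched for small disease
association p-values relative to random SNP sets drawn from a pool and
matched on the features that drive association probability by themselves -
MAF bin (five bins over (5%, 50%]), location relative to protein-coding
genes (cis-like SNPs are matched to near-gene pool SNPs), LD multiplicity
(k co-grouped focal SNPs are replaced by k SNPs from a single pool LD
group), and, in expanded mode, the total LD-expanded set size within a
+/-10% window.  The observed proportion of SNPs below the GWAS threshold is
compared to the null distribution of that proportion over the matched
draws.

Randomness order contract: each draw consumes the generator in a fixed,
documented order - multi-SNP LD groups first (in ascending focal group id),
then singleton strata in ascending (maf_bin, mode) order - and pool arrays
are sorted by snp_id, so results are invariant to input row order given the
seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import as_rng
from .ld import LdNeighborhood, maf_bin

__all__ = [
    "EnrichmentResult",
    "proportion_below",
    "prepare_match_keys",
    "make_focal_keys",
    "MatchedSampler",
    "draw_matched_set",
    "enrichment_test",
    "compare_sets",
]

log = logging.getLogger(__name__)


def proportion_below(p_values, alpha: float = 0.05) -> float:
    """Fraction of p-values strictly below ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return float((p < alpha).mean())


@dataclass
class EnrichmentResult:
    """Summary of one matched-resampling enrichment test."""

    n_snps: int
    alpha: float
    observed_prop: float
    null_mean: float
    null_sd: float
    ci95: tuple[float, float]
    z: float
    p_empirical: float     # add-one estimator, ties count as exceeding
    p_plain: float         # plain proportion, strict exceedance
    p_mid: float           # mid-p (ties count half); uniform under the null
    p_approx: float        # upper-tail normal at z; nan when sd == 0
    fold: float
    n_iter: int
    n_dropped: int = 0     # focal SNPs without a GWAS score

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci95"] = list(self.ci95)
        return d


# ---------------------------------------------------------------------------
# match keys


def prepare_match_keys(snps: pd.DataFrame, genes: pd.DataFrame | None = None,
                       geno: pd.DataFrame | None = None, *,
                       window: int = 1_000_000,
                       r_threshold: float = 0.89,
                       ld_window: int | None = 1_000_000) -> pd.DataFrame:
    """Per-SNP matching features: maf_bin, near_gene, ld_group.

    ``near_gene`` is whether the SNP lies within ``window`` bp of any
    annotated gene (all True when no gene table is supplied); ``ld_group``
    comes from single-linkage grouping at |r| > r_threshold (singletons when
    no genotype panel is supplied).
    """
    bins = np.array([maf_bin(m) for m in snps["maf"]])
    if genes is not None:
        from .eqtl import cis_pair_mask
        near = cis_pair_mask(snps, genes, window).any(axis=1)
    else:
        near = np.ones(len(snps), dtype=bool)
    if geno is not None:
        from .ld import ld_groups
        grp = ld_groups(geno, snps, r_threshold=r_threshold, window=ld_window)
        groups = grp.loc[snps["snp_id"]].to_numpy()
    else:
        groups = np.arange(len(snps))
    return pd.DataFrame({"maf_bin": bins, "near_gene": near, "ld_group": groups},
                        index=pd.Index(snps["snp_id"], name="snp_id"))


def make_focal_keys(focal, pool_keys: pd.DataFrame,
                    modes: pd.Series | None = None) -> pd.DataFrame:
    """Focal-set match keys drawn from the pool's feature table.

    ``modes`` maps snp_id -> 'cis'/'trans' (e.g. from an eSNP table; a SNP
    that is cis for any gene counts as cis).  Without it, location relative
    to genes decides the mode.
    """
    ids = list(dict.fromkeys(focal))  # preserve order, drop duplicates
    missing = [s for s in ids if s not in pool_keys.index]
    if missing:
        raise KeyError(f"focal SNPs absent from the pool: {missing[:5]}")
    sub = pool_keys.loc[ids]
    if modes is not None:
        mode = pd.Series(modes).reindex(ids)
        mode = mode.fillna(pd.Series(
            np.where(sub["near_gene"], "cis", "trans"), index=sub.index))
    else:
        mode = pd.Series(np.where(sub["near_gene"], "cis", "trans"),
                         index=sub.index)
    return pd.DataFrame({"maf_bin": sub["maf_bin"], "mode": mode,
                         "ld_group": sub["ld_group"]}, index=sub.index)


# ---------------------------------------------------------------------------
# matched sampler


class MatchedSampler:
    """Draws SNP sets from a pool matched to a focal set's key histogram.

    The focal set is decomposed into LD groups; groups of size k >= 2 are
    matched group-wise (k SNPs from one pool LD group able to reproduce the
    group's per-stratum composition), singletons are matched stratum-wise.
    Cis strata draw from near-gene pool SNPs; trans strata draw from the
    whole bin.  All sampling within one draw is without replacement.
    """

    def __init__(self, focal_keys: pd.DataFrame, pool_keys: pd.DataFrame):
        pool = pool_keys.sort_index()
        self.pool_ids = pool.index.to_numpy()
        self._bin = pool["maf_bin"].to_numpy()
        self._near = pool["near_gene"].to_numpy(bool)
        self._group = pool["ld_group"].to_numpy()

        # stratum -> sorted array of pool positions
        self._stratum: dict[tuple[int, str], np.ndarray] = {}
        for b in np.unique(self._bin):
            in_bin = self._bin == b
            self._stratum[(int(b), "cis")] = np.nonzero(in_bin & self._near)[0]
            self._stratum[(int(b), "trans")] = np.nonzero(in_bin)[0]

        # focal decomposition
        fk = focal_keys
        counts = fk.groupby("ld_group").size()
        multi_ids = counts.index[counts >= 2]
        self.single_need: dict[tuple[int, str], int] = {}
        singles = fk[~fk["ld_group"].isin(multi_ids)]
        for (b, m), grp in singles.groupby(["maf_bin", "mode"]):
            self.single_need[(int(b), str(m))] = len(grp)

        # pool LD groups with >= 2 members, keyed by group id
        g_order = np.argsort(self._group, kind="stable")
        self._pool_groups: dict[int, np.ndarray] = {}
        for gid, members in _split_by(self._group[g_order], g_order):
            if len(members) >= 2:
                self._pool_groups[int(gid)] = members

        self.multis: list[dict] = []
        for gid in sorted(multi_ids):
            grp = fk[fk["ld_group"] == gid]
            hist = {(int(b), str(m)): len(g)
                    for (b, m), g in grp.groupby(["maf_bin", "mode"])}
            cands = [pg for pg, members in sorted(self._pool_groups.items())
                     if self._group_can_supply(members, hist)]
            if not cands:
                raise ValueError(
                    f"no pool LD group can match a focal group of size "
                    f"{len(grp)} with composition {hist}")
            self.multis.append({"hist": hist, "candidates": cands,
                                "size": len(grp)})

        # stratum feasibility: totals including multi demand
        total_need: dict[tuple[int, str], int] = dict(self.single_need)
        for m in self.multis:
            for k, v in m["hist"].items():
                total_need[k] = total_need.get(k, 0) + v
        for key, need in total_need.items():
            have = len(self._stratum.get(key, ()))
            if have < need:
                raise ValueError(
                    f"infeasible stratum (maf_bin={key[0]}, mode={key[1]}): "
                    f"need {need}, pool has {have}")
        # cis and trans needs in one bin compete for the same SNPs
        for b in {k[0] for k in total_need}:
            joint = total_need.get((b, "cis"), 0) + total_need.get((b, "trans"), 0)
            have = len(self._stratum.get((b, "trans"), ()))
            if joint > have:
                raise ValueError(
                    f"infeasible maf_bin {b}: need {joint} SNPs in total, "
                    f"pool bin has {have}")

        self.n_focal = len(fk)

    def _group_can_supply(self, members: np.ndarray, hist: dict) -> bool:
        total_by_bin: dict[int, int] = {}
        for (b, mode), k in hist.items():
            total_by_bin[b] = total_by_bin.get(b, 0) + k
            if mode == "cis":
                if (self._near[members] & (self._bin[members] == b)).sum() < k:
                    return False
        for b, k in total_by_bin.items():
            if (self._bin[members] == b).sum() < k:
                return False
        return True

    # -- single draw ------------------------------------------------------

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One matched draw; returns pool positions (use .pool_ids to map)."""
        chosen: list[np.ndarray] = []
        used_groups: set[int] = set()

        for m in self.multis:
            cands = [c for c in m["candidates"] if c not in used_groups]
            if not cands:
                raise ValueError("matched draw infeasible: candidate pool LD "
                                 "groups exhausted within one draw")
            pg = cands[int(rng.integers(len(cands)))]
            used_groups.add(pg)
            members = self._pool_groups[pg]
            picked = _pick_from_group(members, m["hist"], self._bin, self._near,
                                      rng)
            chosen.append(picked)

        used = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
        for key in sorted(self.single_need):
            need = self.single_need[key]
            cand = self._stratum[key]
            if len(used):
                cand = cand[~np.isin(cand, used, assume_unique=False)]
            if len(cand) < need:
                raise ValueError(f"matched draw infeasible in stratum {key}")
            pick = rng.choice(cand, size=need, replace=False)
            chosen.append(pick)
            used = np.concatenate([used, pick])
        return used

    def draw_ids(self, rng: np.random.Generator) -> np.ndarray:
        return self.pool_ids[self.draw(rng)]

    # -- vectorized null (no multi groups, no expansion) ------------------

    @property
    def vectorizable(self) -> bool:
        return not self.multis

    def null_counts(self, rng: np.random.Generator, n_iter: int,
                    sig: np.ndarray, chunk: int = 2000) -> np.ndarray:
        """Counts of significant SNPs per draw, vectorized across draws.

        Valid only when every focal LD group is a singleton.  Per MAF bin,
        cis picks come from the near-gene SNPs and trans picks from the
        remaining bin members, each round using fresh uniform keys so every
        subset is equally likely, and the cis picks masked out of the trans
        round to keep the draw without replacement.
        """
        if not self.vectorizable:
            raise RuntimeError("vectorized path requires singleton focal groups")
        needs: dict[int, list[int]] = {}
        for (b, mode), k in self.single_need.items():
            entry = needs.setdefault(int(b), [0, 0])
            entry[0 if mode == "cis" else 1] += k
        out = np.zeros(n_iter, dtype=np.int64)
        for start in range(0, n_iter, chunk):
            rows = min(chunk, n_iter - start)
            total = np.zeros(rows, dtype=np.int64)
            for b, (c, t) in sorted(needs.items()):
                a_idx = self._stratum[(b, "cis")]
                all_idx = self._stratum[(b, "trans")]
                sig_a = sig[a_idx]
                sig_all = sig[all_idx]
                cis_cols = None
                if c > 0:
                    if c >= len(a_idx):
                        cis_cols = np.broadcast_to(np.arange(len(a_idx)),
                                                   (rows, len(a_idx)))
                    else:
                        keys = rng.random((rows, len(a_idx)))
                        cis_cols = np.argpartition(keys, c - 1, axis=1)[:, :c]
                    total += sig_a[cis_cols].sum(axis=1)
                if t > 0:
                    keys = rng.random((rows, len(all_idx)))
                    if cis_cols is not None:
                        # positions of near-gene SNPs inside the full bin array
                        a_pos = np.searchsorted(all_idx, a_idx)
                        np.put_along_axis(keys, a_pos[np.ascontiguousarray(cis_cols)],
                                          np.inf, axis=1)
                    tc = np.argpartition(keys, t - 1, axis=1)[:, :t]
                    total += sig_all[tc].sum(axis=1)
            out[start:start + rows] = total
        return out


def _split_by(sorted_keys: np.ndarray, values: np.ndarray):
    """Yield (key, values-with-that-key) over a key-sorted pairing."""
    if len(sorted_keys) == 0:
        return
    edges = np.nonzero(np.diff(sorted_keys))[0] + 1
    starts = np.concatenate([[0], edges])
    stops = np.concatenate([edges, [len(sorted_keys)]])
    for a, b in zip(starts, stops):
        yield sorted_keys[a], np.sort(values[a:b])


def _pick_from_group(members: np.ndarray, hist: dict, bins: np.ndarray,
                     near: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Pick SNPs from one pool LD group matching a stratum histogram.

    Cis strata are filled first from near-gene members (the scarcer
    resource), then trans strata from whatever remains in the bin.
    """
    picked: list[int] = []
    taken = np.zeros(len(members), dtype=bool)
    for (b, mode) in sorted(hist, key=lambda k: (k[0], k[1] != "cis")):
        k = hist[(b, mode)]
        ok = (bins[members] == b) & ~taken
        if mode == "cis":
            ok &= near[members]
        idx = np.nonzero(ok)[0]
        if len(idx) < k:
            raise ValueError("pool LD group cannot supply the focal composition")
        sel = rng.choice(idx, size=k, replace=False)
        taken[sel] = True
        picked.extend(members[sel])
    return np.array(picked, dtype=int)


def draw_matched_set(focal_keys: pd.DataFrame, pool_keys: pd.DataFrame,
                     rng) -> np.ndarray:
    """One matched draw; returns an array of pool snp_ids."""
    return MatchedSampler(focal_keys, pool_keys).draw_ids(as_rng(rng))


# ---------------------------------------------------------------------------
# enrichment tests


def _score_map(gwas: pd.DataFrame) -> pd.Series:
    s = gwas.set_index("snp_id")["p"]
    if s.index.has_duplicates:
        raise ValueError("duplicate snp_id in the GWAS table")
    return s


def _summarize(observed: float, null: np.ndarray, n_snps: int, alpha: float,
               n_iter: int, n_dropped: int) -> EnrichmentResult:
    mean = float(null.mean())
    sd = float(null.std())
    exceed_eq = int((null >= observed).sum())
    exceed = int((null > observed).sum())
    if sd > 0:
        z = (observed - mean) / sd
        p_approx = float(stats.norm.sf(z))
    else:
        z, p_approx = float("nan"), float("nan")
        log.warning("degenerate null (sd = 0): normal approximation undefined")
    return EnrichmentResult(
        n_snps=n_snps, alpha=alpha, observed_prop=observed, null_mean=mean,
        null_sd=sd, ci95=(mean - 1.96 * sd, mean + 1.96 * sd), z=float(z),
        p_empirical=(1 + exceed_eq) / (n_iter + 1),
        p_plain=exceed / n_iter,
        p_mid=(exceed + 0.5 * (1 + exceed_eq - exceed)) / (n_iter + 1),
        p_approx=p_approx,
        fold=observed / mean if mean > 0 else float("inf"),
        n_iter=n_iter, n_dropped=n_dropped)


def enrichment_test(focal, pool_keys: pd.DataFrame, gwas: pd.DataFrame, *,
                    modes: pd.Series | None = None,
                    n_iter: int = 100_000, alpha: float = 0.05,
                    expand: LdNeighborhood | None = None,
                    size_tol: float = 0.10, max_attempts: int = 1000,
                    seed=None) -> EnrichmentResult:
    """Matched-resampling enrichment of a focal SNP set for small GWAS p.

    With ``expand`` (a precomputed LD neighborhood), the statistic is
    computed on the one-hop LD expansion of each set, and null draws are
    rejection-sampled until their expanded size lies within ``size_tol`` of
    the expanded focal size - without this, random sets with richer LD
    structure would be favoured even under the null.

    p_empirical uses the add-one permutation estimator counting ties as
    exceeding; p_plain is the plain strict-exceedance proportion; p_approx
    is the upper normal tail at z, reported for resolution beyond 1/n_iter.
    """
    rng = as_rng(seed)
    score = _score_map(gwas)
    focal_keys = focal if isinstance(focal, pd.DataFrame) else \
        make_focal_keys(focal, pool_keys, modes=modes)

    scored = focal_keys.index.isin(score.index)
    n_dropped = int((~scored).sum())
    if n_dropped:
        log.info("dropping %d focal SNPs without a GWAS score", n_dropped)
        focal_keys = focal_keys[scored]
    if focal_keys.empty:
        raise ValueError("no focal SNPs with GWAS scores")
    pool_keys = pool_keys[pool_keys.index.isin(score.index)]

    sampler = MatchedSampler(focal_keys, pool_keys)
    sig = (score.reindex(sampler.pool_ids).to_numpy() < alpha)

    if expand is not None:
        focal_exp = expand.expand(focal_keys.index)
        focal_size = len(focal_exp)
        exp_scored = [s for s in focal_exp if s in score.index]
        observed = proportion_below(score.loc[exp_scored].to_numpy(), alpha)
        n_snps = focal_size
        null = np.empty(n_iter)
        lo = (1.0 - size_tol) * focal_size
        hi = (1.0 + size_tol) * focal_size
        id_sig = dict(zip(sampler.pool_ids, sig))
        for i in range(n_iter):
            for attempt in range(max_attempts):
                core = sampler.pool_ids[sampler.draw(rng)]
                ex = expand.expand(core)
                if lo <= len(ex) <= hi:
                    break
            else:
                raise RuntimeError(
                    f"expanded-draw rejection cap hit ({max_attempts} attempts; "
                    f"target size window [{lo:.0f}, {hi:.0f}])")
            vals = [id_sig[s] for s in ex if s in id_sig]
            null[i] = np.mean(vals)
    else:
        observed = proportion_below(score.loc[focal_keys.index].to_numpy(), alpha)
        n_snps = len(focal_keys)
        if sampler.vectorizable:
            counts = sampler.null_counts(rng, n_iter, sig)
            null = counts / sampler.n_focal
        else:
            null = np.empty(n_iter)
            for i in range(n_iter):
                null[i] = sig[sampler.draw(rng)].mean()

    return _summarize(observed, null, n_snps, alpha, n_iter, n_dropped)


def compare_sets(focal, background, pool_keys: pd.DataFrame,
                 gwas: pd.DataFrame, *, modes: pd.Series | None = None,
                 n_iter: int = 100_000, alpha: float = 0.05,
                 expand: LdNeighborhood | None = None,
                 size_tol: float = 0.10, seed=None
                 ) -> tuple[float, EnrichmentResult]:
    """Is the focal set more enriched than matched same-size subsets of a
    background set?  One-sided p for "focal more enriched" (nested design:
    the null resamples the background at the focal composition)."""
    focal_ids = list(focal if not isinstance(focal, pd.DataFrame)
                     else focal.index)
    background = list(background)
    if not set(focal_ids) <= set(background):
        warnings.warn("focal set is not nested in the background set",
                      stacklevel=2)
    # non-nested focal SNPs are kept scoreable by pooling them with the
    # background; under the intended nested design this is a no-op
    bg_keys = pool_keys.loc[pool_keys.index.isin(set(background)
                                                 | set(focal_ids))]
    res = enrichment_test(focal, bg_keys, gwas, modes=modes, n_iter=n_iter,
                          alpha=alpha, expand=expand, size_tol=size_tol,
                          seed=seed)
    return res.p_empirical, res
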