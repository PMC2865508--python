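"""Stage-oriented pipeline over the synthetic (or any loaded) study.

Stage order: simulate -> esnp -> expand -> enrich -> network -> causal ->
candidates -> genesets.  Each stage writes its outputs to the results
directory and is skipped on re-run when they already exist, so a failed run
resumes from its last completed stage.  A provenance JSON records the seed
and parameters; identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from ._rng import substream
from .causality import candidate_filter, causal_model_select, qtl_scan
from .enrichment import compare_sets, enrichment_test, prepare_match_keys
from .eqtl import map_esnps
from .ld import LdNeighborhood, expand_set
from .network import coexpression_modules, module_eigengene, module_trait_cor
from .simulate import (CrossData, SimConfig, module_driver_snps,
                       module_gene_table, simulate_expression,
                       simulate_f2_cross, simulate_genotypes, simulate_gwas)

log = logging.getLogger(__name__)

# map-distance to physical-distance convention for the synthetic mouse genome
CM_TO_BP = 2_000_000


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain (YAML-friendly) mapping."""
    from .simulate import CrossSpec, GwasSpec, ModuleSpec

    d = dict(d or {})
    sub = {}
    if "module_spec" in d:
        m = dict(d.pop("module_spec"))
        for k in ("sizes", "loadings"):
            if k in m:
                m[k] = tuple(m[k])
        sub["module_spec"] = ModuleSpec(**m)
    if "gwas_spec" in d:
        sub["gwas_spec"] = GwasSpec(**d.pop("gwas_spec"))
    if "cross_spec" in d:
        sub["cross_spec"] = CrossSpec(**d.pop("cross_spec"))
    if "block_sizes" in d:
        d["block_sizes"] = tuple(d["block_sizes"])
    return SimConfig(**d, **sub)


def simulate_study(config: SimConfig) -> dict:
    """All synthetic pieces of one study under one seed."""
    geno, snps, genes = simulate_genotypes(config)
    expr = simulate_expression(geno, snps, genes, config)
    gwas = simulate_gwas(geno, snps, config, genes=genes)
    cross = simulate_f2_cross(config)
    return {"geno": geno, "snps": snps, "genes": genes, "expr": expr,
            "gwas": gwas, "cross": cross}


# ---------------------------------------------------------------------------
# mouse-side evidence for the candidate filter


def mouse_reference(cross: CrossData, interval_halfwidth_cm: float = 15.0):
    """Synthetic mouse gene annotations and the linkage interval.

    The focal gene sits at its driving marker's position (cM mapped to bp);
    the remaining cross genes are spread over the other chromosome, outside
    the interval.  The interval spans the focal marker +/- the half-width.
    """
    gmap = cross.gmap.set_index("marker")
    focal = gmap.loc[cross.focal_marker]
    focal_bp = int(focal["cM"] * CM_TO_BP) + 1
    rows = [(cross.focal_gene, focal["chrom"], focal_bp, focal_bp + 10_000)]
    others = [g for g in cross.expr.columns if g != cross.focal_gene]
    other_chrom = [c for c in gmap["chrom"].unique() if c != focal["chrom"]]
    spread_chrom = other_chrom[0] if other_chrom else focal["chrom"]
    for i, g in enumerate(others):
        start = 1 + i * 2_000_000
        rows.append((g, spread_chrom, start, start + 10_000))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "stop"])
    interval = (str(focal["chrom"]),
                max(0, focal_bp - int(interval_halfwidth_cm * CM_TO_BP)),
                focal_bp + int(interval_halfwidth_cm * CM_TO_BP))
    return genes, interval


def mouse_evidence(cross: CrossData, mouse_genes: pd.DataFrame,
                   trait: str = "insulin", lod_threshold: float = 3.0,
                   cis_window_bp: int = 10_000_000):
    """Scan every cross expression trait; return (cis eQTL table, causal calls).

    A gene's cis LOD is its best LOD among markers within ``cis_window_bp``
    of the gene body (marker cM mapped to bp); the causal call is made at
    that marker against the clinical trait.
    """
    gmap = cross.gmap.copy()
    gmap["bp"] = (gmap["cM"] * CM_TO_BP).astype(int) + 1
    ann = mouse_genes.set_index("gene_id")
    cis_rows, call_rows = [], []
    for gene in cross.expr.columns:
        curve = qtl_scan(cross, gene)
        a = ann.loc[gene]
        local = gmap[(gmap["chrom"] == a["chrom"])
                     & (gmap["bp"] >= a["start"] - cis_window_bp)
                     & (gmap["bp"] <= a["stop"] + cis_window_bp)]
        if local.empty:
            continue
        sub = curve.lod.loc[local["marker"]]
        best_marker = sub.idxmax()
        best_lod = float(sub.loc[best_marker])
        cis_rows.append((gene, best_marker, best_lod))
        if best_lod >= lod_threshold:
            call = causal_model_select(cross.geno[best_marker],
                                       cross.expr[gene], cross.traits[trait],
                                       gene_id=gene, trait=trait,
                                       locus=best_marker)
            call_rows.append((gene, trait, best_marker, call.model,
                              call.margin))
    cis = pd.DataFrame(cis_rows, columns=["gene_id", "marker", "lod"])
    calls = pd.DataFrame(call_rows, columns=["gene_id", "trait", "locus",
                                             "model", "margin"])
    return cis, calls


def ortholog_map(cross: CrossData, human_genes: pd.DataFrame,
                 config: SimConfig) -> pd.DataFrame:
    """Synthetic mouse-to-human ortholog table.

    The planted mouse gene maps to the first human module gene (whose cis
    region holds the module-driving SNP); the remaining cross genes map to
    non-module human genes in order.
    """
    labels = module_gene_table(human_genes, config)
    module_first = labels.index[labels > 0][0]
    non_module = [g for g in human_genes["gene_id"] if labels[g] == 0]
    rows = [(cross.focal_gene, module_first)]
    others = [g for g in cross.expr.columns if g != cross.focal_gene]
    for m, h in zip(others, non_module):
        rows.append((m, h))
    return pd.DataFrame(rows, columns=["mouse_id", "human_id"])


def end_to_end_candidates(config: SimConfig, *, n_perm: int = 5,
                          lod_threshold: float = 3.0,
                          p_threshold: float = 0.05,
                          causal_margin: float = 2.0):
    """Full mouse+human candidate-gene run on one synthetic study.

    Returns (candidate table, planted mouse gene id).  The planted gene
    passes when its cis locus is linked, its causal call wins, its human
    ortholog's cis eSNP is found, and that eSNP associates with disease.
    """
    study = simulate_study(config)
    cross = study["cross"]
    mouse_genes, interval = mouse_reference(cross)
    cis, calls = mouse_evidence(cross, mouse_genes,
                                lod_threshold=lod_threshold)
    esnps = map_esnps(study["geno"], study["snps"], study["expr"],
                      study["genes"], include_trans=False, n_perm=n_perm,
                      seed=config.seed)
    orthologs = ortholog_map(cross, study["genes"], config)
    module_mouse_genes = list(cross.expr.columns)
    cands = candidate_filter(module_mouse_genes, mouse_genes, cis, calls,
                             interval, esnps, study["gwas"], orthologs,
                             p_threshold=p_threshold,
                             lod_threshold=lod_threshold,
                             causal_margin=causal_margin)
    return cands, cross.focal_gene


# ---------------------------------------------------------------------------
# staged runner


def run_pipeline(config, outdir, *, force: bool = False) -> Path:
    """Run every stage on the configured synthetic study; resume from disk.

    ``config``: YAML path or mapping with keys ``seed``, ``sim`` (SimConfig
    overrides) and optional per-stage parameter blocks (esnp, enrich,
    network).  Returns the results directory.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    seed = int(config.get("seed", 0))
    sim_over = dict(config.get("sim", {}))
    sim_over.setdefault("seed", seed)
    sim = config_from_dict(sim_over)
    esnp_par = dict(config.get("esnp", {}))
    enrich_par = dict(config.get("enrich", {}))
    net_par = dict(config.get("network", {}))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def done(*names):
        return all((outdir / n).exists() for n in names) and not force

    # stage: simulate
    if done("genotypes.tsv", "snps.tsv", "genes.tsv", "expression.tsv",
            "gwas.tsv", "cross"):
        log.info("stage simulate: cached, skipping")
        study = {
            "geno": io.read_genotypes(outdir / "genotypes.tsv"),
            "snps": io.read_snp_table(outdir / "snps.tsv"),
            "genes": io.read_gene_table(outdir / "genes.tsv"),
            "expr": io.read_expression(outdir / "expression.tsv"),
            "gwas": io.read_gwas(outdir / "gwas.tsv"),
            "cross": io.read_cross(outdir / "cross"),
        }
        cross0 = simulate_f2_cross(sim)  # focal metadata is not serialized
        study["cross"].focal_marker = cross0.focal_marker
        study["cross"].focal_gene = cross0.focal_gene
    else:
        study = simulate_study(sim)
        io.write_study(outdir, geno=study["geno"], snps=study["snps"],
                       genes=study["genes"], expr=study["expr"],
                       gwas=study["gwas"], cross=study["cross"])
        log.info("stage simulate: wrote study (%d SNPs, %d genes, %d samples)",
                 len(study["snps"]), len(study["genes"]), len(study["geno"]))

    # stage: esnp
    if done("esnps.tsv"):
        log.info("stage esnp: cached, skipping")
        esnps = io.read_esnps(outdir / "esnps.tsv")
    else:
        esnps = map_esnps(study["geno"], study["snps"], study["expr"],
                          study["genes"], seed=seed,
                          **{k: v for k, v in esnp_par.items()})
        io.write_esnps(esnps, outdir / "esnps.tsv")
        log.info("stage esnp: %d associations after FDR and LD pruning",
                 len(esnps))

    # stage: expand
    if done("expanded_esnps.tsv"):
        log.info("stage expand: cached, skipping")
        expanded = set(pd.read_csv(outdir / "expanded_esnps.tsv",
                                   sep="\t")["snp_id"])
    else:
        core = sorted(set(esnps["snp_id"]))
        exp = expand_set(core, study["geno"], study["snps"]) if core else None
        expanded = exp.expanded_set if exp else set()
        pd.DataFrame({"snp_id": sorted(expanded)}).to_csv(
            outdir / "expanded_esnps.tsv", sep="\t", index=False)
        log.info("stage expand: %d -> %d SNPs", len(core), len(expanded))

    # stage: enrich
    if done("enrichment.json"):
        log.info("stage enrich: cached, skipping")
    else:
        keys = prepare_match_keys(study["snps"], study["genes"], study["geno"])
        modes = esnps.sort_values("kw_p").drop_duplicates("snp_id") \
                     .set_index("snp_id")["mode"]
        focal = sorted(set(esnps["snp_id"]))
        summary = {}
        if focal:
            res = enrichment_test(
                focal, keys, study["gwas"], modes=modes,
                n_iter=int(enrich_par.get("n_iter", 1000)),
                alpha=float(enrich_par.get("alpha", 0.05)),
                seed=substream(seed, "enrich"))
            summary["all_esnps"] = res.to_dict()
            labels = module_gene_table(study["genes"], sim)
            module_genes = set(labels.index[labels > 0])
            mod_focal = sorted(set(
                esnps.loc[esnps["gene_id"].isin(module_genes), "snp_id"]))
            if mod_focal and len(mod_focal) < len(focal):
                p, res2 = compare_sets(
                    mod_focal, focal, keys, study["gwas"], modes=modes,
                    n_iter=int(enrich_par.get("n_iter", 1000)),
                    seed=substream(seed, "enrich-compare"))
                summary["module_vs_all"] = res2.to_dict()
        with open(outdir / "enrichment.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        log.info("stage enrich: wrote enrichment.json")

    # stage: network
    if done("modules.tsv", "eigengenes.tsv"):
        log.info("stage network: cached, skipping")
        modules = pd.read_csv(outdir / "modules.tsv", sep="\t")
    else:
        from .network import rank_variable_genes
        selected = rank_variable_genes(
            study["expr"], top_frac=float(net_par.get("top_frac", 0.25)))
        min_size = min(int(net_par.get("min_size", 30)), len(selected) // 2)
        tom, assign = coexpression_modules(
            study["expr"][selected], beta=float(net_par.get("beta", 6)),
            cut_height=float(net_par.get("cut_height", 0.99)),
            min_size=min_size)
        modules = assign.labels.rename("module").reset_index()
        modules.to_csv(outdir / "modules.tsv", sep="\t", index=False)
        eig_rows = {}
        for m in sorted(set(assign.labels) - {0}):
            eig = module_eigengene(study["expr"], assign.genes_in(m))
            eig_rows[f"module_{m}"] = eig.scores
        pd.DataFrame(eig_rows).to_csv(outdir / "eigengenes.tsv", sep="\t")
        log.info("stage network: %d modules",
                 len(set(assign.labels) - {0}))

    # stage: causal (+ candidates)
    if done("causal_calls.tsv", "candidates.tsv"):
        log.info("stage causal/candidates: cached, skipping")
    else:
        cross = study["cross"]
        mouse_genes, interval = mouse_reference(cross)
        cis, calls = mouse_evidence(cross, mouse_genes)
        calls.to_csv(outdir / "causal_calls.tsv", sep="\t", index=False)
        orthologs = ortholog_map(cross, study["genes"], sim)
        cands = candidate_filter(list(cross.expr.columns), mouse_genes, cis,
                                 calls, interval, esnps, study["gwas"],
                                 orthologs)
        cands.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        log.info("stage causal/candidates: %d causal calls, %d candidates",
                 len(calls), len(cands))

    # stage: genesets (module overlap with causal-supported genes)
    if done("geneset_enrichment.json"):
        log.info("stage genesets: cached, skipping")
    else:
        from .genesets import hypergeom_enrich
        labels = module_gene_table(study["genes"], sim)
        module_genes = set(labels.index[labels > 0])
        esnp_genes = set(esnps["gene_id"])
        universe = set(study["genes"]["gene_id"])
        overlap = len(module_genes & esnp_genes)
        res = hypergeom_enrich(overlap, len(module_genes), len(esnp_genes),
                               len(universe))
        with open(outdir / "geneset_enrichment.json", "w") as fh:
            json.dump(asdict(res), fh, indent=2)
        log.info("stage genesets: module/eSNP-gene overlap fold %.2f", res.fold)

    with open(outdir / "provenance.json", "w") as fh:
        json.dump({"seed": seed, "sim": _jsonable(asdict(sim)),
                   "esnp": esnp_par, "enrich": enrich_par,
                   "network": net_par}, fh, indent=2)
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
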