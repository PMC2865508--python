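"""Readers and writers for every table the pipeline touches.

Tab-separated text with a header row is the canonical interchange format;
missing values are written as "NA".  Coordinates are 1-based and inclusive
throughout, including the BED-like gene table.  VCF support is limited to
genotype (GT) extraction via pysam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

NA = "NA"


# -- genotypes ---------------------------------------------------------------

def write_genotypes(geno: pd.DataFrame, path) -> None:
    out = geno.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=NA)


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA],
                     keep_default_na=False)
    arr = df.to_numpy()
    bad = ~(pd.isna(arr) | np.isin(arr, [0, 1, 2]))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype code {arr[i, j]!r} at sample {df.index[i]!r}, "
            f"SNP {df.columns[j]!r} in {path}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate SNP ids in {path}")
    return df


def write_vcf(geno: pd.DataFrame, snps: pd.DataFrame, path) -> None:
    """Minimal VCF (GT field only, unphased, REF=A ALT=B placeholders)."""
    samples = list(geno.index)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for _, row in snps.iterrows():
            col = geno[row["snp_id"]]
            gts = "\t".join("./." if pd.isna(v) else gt_strings[int(v)]
                            for v in col)
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                     f"A\tB\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract (genotype matrix, SNP table without MAF) from a VCF via pysam."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        cols, meta = {}, []
        for rec in vf:
            counts = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    counts.append(np.nan)
                else:
                    counts.append(float(sum(gt)))
            if rec.id in cols:
                raise ValueError(f"duplicate SNP id {rec.id!r} in {path}")
            cols[rec.id] = counts
            meta.append((rec.id, rec.chrom, rec.pos))
    geno = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    snps = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos"])
    return geno, snps


# -- flat tables -------------------------------------------------------------

def _read_table(path, required: list[str], name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed {name} table {path}: {err}") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table {path} lacks columns {missing}")
    return df


def write_snp_table(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_snp_table(path) -> pd.DataFrame:
    df = _read_table(path, ["snp_id", "chrom", "pos", "maf"], "SNP")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id {dup!r} in {path}")
    return df


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_gene_table(path) -> pd.DataFrame:
    df = _read_table(path, ["gene_id", "chrom", "start", "stop"], "gene")
    if (df["start"] > df["stop"]).any():
        raise ValueError(f"gene with start > stop in {path}")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    out = expr.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=NA)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA],
                       keep_default_na=False)


def write_gwas(gwas: pd.DataFrame, path) -> None:
    gwas.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_gwas(path) -> pd.DataFrame:
    df = _read_table(path, ["snp_id", "chrom", "pos", "p"], "GWAS")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError(f"GWAS p-values outside (0, 1] in {path}")
    return df


def write_esnps(esnps: pd.DataFrame, path) -> None:
    esnps.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_esnps(path) -> pd.DataFrame:
    return _read_table(path, ["snp_id", "gene_id", "mode", "kw_p", "fdr_pass",
                              "tissue"], "eSNP")


def read_orthologs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None if _headerless(path) else 0,
                     na_values=[NA], keep_default_na=False)
    df.columns = ["mouse_id", "human_id"] + list(df.columns[2:])
    return df[["mouse_id", "human_id"]]


def _headerless(path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return "mouse_id" not in first


def write_orthologs(orthologs: pd.DataFrame, path) -> None:
    orthologs.to_csv(path, sep="\t", index=False, na_rep=NA)


# -- gene sets (GMT) ---------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# -- F2 cross bundle ---------------------------------------------------------

def write_cross(cross, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes(cross.geno, outdir / "cross_genotypes.tsv")
    cross.gmap.to_csv(outdir / "cross_map.tsv", sep="\t", index=False)
    write_expression(cross.expr, outdir / "cross_expression.tsv")
    write_expression(cross.traits, outdir / "cross_traits.tsv")


def read_cross(indir):
    from .simulate import CrossData

    indir = Path(indir)
    return CrossData(
        geno=read_genotypes(indir / "cross_genotypes.tsv"),
        gmap=pd.read_csv(indir / "cross_map.tsv", sep="\t"),
        expr=read_expression(indir / "cross_expression.tsv"),
        traits=read_expression(indir / "cross_traits.tsv"))


# -- study bundle ------------------------------------------------------------

@dataclass
class StudyBundle:
    """Validated handles for one study's inputs."""

    geno: pd.DataFrame | None = None
    snps: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    expr: pd.DataFrame | None = None
    gwas: pd.DataFrame | None = None
    gene_sets: dict | None = None
    orthologs: pd.DataFrame | None = None
    cross: object | None = None
    provenance: dict = field(default_factory=dict)
    mismatches: dict = field(default_factory=dict)


_LOADERS = {
    "genotypes": read_genotypes,
    "snps": read_snp_table,
    "genes": read_gene_table,
    "expression": read_expression,
    "gwas": read_gwas,
    "gene_sets": read_gmt,
    "orthologs": read_orthologs,
    "cross": read_cross,
}

_FIELD = {"genotypes": "geno", "snps": "snps", "genes": "genes",
          "expression": "expr", "gwas": "gwas", "gene_sets": "gene_sets",
          "orthologs": "orthologs", "cross": "cross"}


def load_study(config, strict: bool = False) -> StudyBundle:
    """Load and cross-validate the inputs named in a YAML config.

    The config maps input names (genotypes, snps, genes, expression, gwas,
    gene_sets, orthologs, cross) to paths, relative to the config file.
    Identifier mismatches between tables are counted and logged; strict
    mode aborts on any mismatch.
    """
    if isinstance(config, (str, Path)):
        base = Path(config).parent
        with open(config) as fh:
            config = yaml.safe_load(fh)
    else:
        base = Path(".")
    inputs = config.get("inputs", config)

    bundle = StudyBundle(provenance={"config": {k: str(v)
                                                for k, v in inputs.items()}})
    for key, path in inputs.items():
        if key not in _LOADERS:
            continue
        setattr(bundle, _FIELD[key], _LOADERS[key](base / path))

    mism = {}
    if bundle.geno is not None and bundle.expr is not None:
        mism["samples_geno_not_expr"] = len(
            set(bundle.geno.index) - set(bundle.expr.index))
    if bundle.geno is not None and bundle.snps is not None:
        mism["snps_table_not_geno"] = len(
            set(bundle.snps["snp_id"]) - set(bundle.geno.columns))
    if bundle.gwas is not None and bundle.snps is not None:
        mism["snps_table_not_gwas"] = len(
            set(bundle.snps["snp_id"]) - set(bundle.gwas["snp_id"]))
    bundle.mismatches = mism
    for name, count in mism.items():
        if count:
            log.warning("identifier mismatch %s: %d", name, count)
    if strict and any(mism.values()):
        raise ValueError(f"identifier mismatches in strict mode: {mism}")
    return bundle


def write_study(outdir, geno=None, snps=None, genes=None, expr=None,
                gwas=None, cross=None, vcf: bool = False) -> None:
    """Write a simulator output directory in the canonical layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if geno is not None:
        write_genotypes(geno, outdir / "genotypes.tsv")
        if vcf and snps is not None:
            write_vcf(geno, snps, outdir / "genotypes.vcf")
    if snps is not None:
        write_snp_table(snps, outdir / "snps.tsv")
    if genes is not None:
        write_gene_table(genes, outdir / "genes.tsv")
    if expr is not None:
        write_expression(expr, outdir / "expression.tsv")
    if gwas is not None:
        write_gwas(gwas, outdir / "gwas.tsv")
    if cross is not None:
        write_cross(cross, outdir / "cross")
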