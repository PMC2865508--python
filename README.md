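# esnpnet

Expression-associated SNPs (eSNPs) — SNPs that associate with the
transcript abundance of some gene — are a functionally anchored subset of
all genotyped variants. `esnpnet` implements a filtering cascade that asks
whether an eSNP set from metabolic tissues is enriched for association with
a disease (type 2 diabetes is the motivating case) in GWAS summary
statistics, and then sharpens the set through a co-expression network and
its causally supported subnetwork, ending in a three-criteria
candidate-gene filter that combines mouse-cross and human evidence.

The package is aimed at statistical geneticists who want the full pipeline
— eQTL mapping, matched-resampling SNP-set enrichment, weighted network
modules, causal model selection on an F2 cross — as tested, reusable
library code with a CLI, plus a synthetic-data generator that emulates the
study designs so every stage runs at desk scale without access to the
original cohorts.

## The core statistic

For a focal SNP set *S* scored against GWAS p-values, the observed
statistic is the proportion of SNPs with p < 0.05. Its null distribution
comes from (by default) 100,000 random SNP sets drawn from a genotyped pool
and **matched** to *S* on:

* MAF bin — five bins over (5%, 10%], (10%, 20%], …, (40%, 50%];
* location — SNPs tested in cis are matched to pool SNPs within 1 Mb of a
  gene;
* LD multiplicity — k focal SNPs sharing one LD group (single-linkage
  components at |r| > 0.89) are replaced by k SNPs from a single pool LD
  group;
* in expanded mode (the focal set augmented with every panel SNP at
  |r| > 0.89 with a member), the expanded null set's size must land within
  ±10% of the expanded focal size.

The test reports the observed proportion, the null mean ± SD with a 95% CI,
Z = (obs − mean)/SD, the fold obs/mean, an add-one empirical p, and a
normal-tail approximation for resolution beyond 1/n_iter.

Downstream, co-expression modules are cut from the topological overlap
matrix of a soft-thresholded network (a_ij = |cor|^β), each summarized by
its eigengene (first principal component); causal / reactive / independent
models for (locus L, expression G, trait T) are discriminated by AIC over
the linear-Gaussian factorizations P(G|L)P(T|G), P(T|L)P(G|T), and
P(G|L)P(T|L); and gene-set overlaps use the one-sided hypergeometric test
with fold = observed / expected overlap.

## Worked example

```sh
esnpnet --verbose run --seed 5 --out results/
```

runs every stage on the default synthetic study (2,000 SNPs, 500 genes,
300 samples, plus an independent 4,000-sample GWAS cohort and a 554-animal
F2 cross) and logs

```
stage simulate: wrote study (2000 SNPs, 500 genes, 300 samples)
stage esnp: 1504 associations after FDR and LD pruning
stage expand: 744 -> 744 SNPs
stage enrich: wrote enrichment.json
stage network: 1 modules
stage causal/candidates: 1 causal calls, 1 candidates
```

`results/enrichment.json` then tells the pipeline's central story in two
rows. The full eSNP set is barely enriched — observed 4.6% of SNPs below
the GWAS 0.05 threshold against a matched-null 4.3% (fold 1.06,
p = 0.36) — because most eSNPs tag genes unrelated to disease. Restricting
to eSNPs of the co-expression module's genes and comparing against
equal-composition draws from all eSNPs gives observed 47.6% vs null 6.6%:
a 7.2-fold enrichment at the empirical-p floor of 1,000 iterations
(p = 0.001, Z ≈ 8.0). That is the planted behaviour — the generator routes
disease liability through the module's driving loci — and it is the same
filtering logic that motivates the method on real cohorts. Library use
mirrors the CLI: see `esnpnet.enrichment_test`,
`esnpnet.coexpression_modules`, `esnpnet.causal_model_select`,
`esnpnet.candidate_filter`.

In Python, the same statistics that the enrichment summary tables of a
published analysis print can be recomputed from their counts:

```python
>>> import esnpnet as en
>>> r = en.hypergeom_enrich(k=57, n=159, K=432, N=35_345)
>>> round(r.fold, 1), float(f"{r.p:.3g}")
(29.3, 5.26e-68)
```

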