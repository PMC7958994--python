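# methqtl

Methylation-adjusted cis-eQTL mapping: collapse CpG methylation around each
SNP into a single distance-weighted covariate, map expression quantitative
trait loci with and without that covariate, classify how significance
changes, call eGenes, and test whether the resulting eQTL groups are
enriched for GWAS trait categories.

## Who this is for

Groups with matched genotype, DNA methylation (array beta values) and
RNA-seq data from the same samples — e.g. a primary hepatocyte cohort —
who want to ask whether local DNA methylation modulates the association
between a SNP and a nearby gene's expression. The package also ships a
synthetic-data generator that plants known causal architectures
(direct, methylation-confounded, methylation-suppressed), so the whole
pipeline is testable without any cohort data.

## The model

For SNP *s*, every CpG within a ±2.5 kb window gets an initial weight that
decays linearly with its distance *d* (bp):

```
w = 1 − d / 2500
```

With a single contributing CpG the SNP-level methylation value is simply
`M = w · m` (the raw weight multiplies the beta value `m`). With `N ≥ 2`
CpGs, weights are normalized, `w_f,i = w_i / Σ_k w_k`, and

```
M = Σ_i  w_f,i · m_i        (per sample; a convex combination)
```

`M` then enters an ordinary least-squares eQTL regression as a
locus-specific covariate. For each cis pair (SNP within 1 Mb of the gene's
TSS):

```
PC-adjusted:     y = β₀ + β_g·g + γ·C + ε
meth-adjusted:   y = β₀ + β_g·g + β_M·M + γ·C + ε
```

where `y` is inverse-normal-transformed expression, `g` the alt-allele
dosage, and `C` global covariates (sex, platform, genotype PCs, PEER
factors). Inference is on `β_g`, with Benjamini–Hochberg FDR across all
pairs in a run. Pairs are then classified as methylation-only, shared, or
PC-only significant; PC-significant pairs whose nominal p-value grows
(shrinks) under adjustment form the "decreased" ("increased") significance
groups, and each group's SNPs are tested for GWAS trait-category
enrichment with Fisher's exact test against all tested SNPs, after
expanding the GWAS catalog with LD proxies at r² > 0.8.

## Worked example

```python
from methqtl.synthetic_data import SimulationConfig, simulate_bundle
from methqtl.eqtl_model import map_eqtls, call_egenes
from methqtl.comparison_enrichment import classify_pairs

bundle, truth, cov_table = simulate_bundle(SimulationConfig(seed=1))
print(f"covered {cov_table.summary.n_covered}/40 SNPs, "
      f"mean {cov_table.summary.mean_cpgs:.2f} CpGs/SNP")
pc = map_eqtls(bundle, cov_table, model="pc")
meth = map_eqtls(bundle, cov_table, model="meth")
comp, counts = classify_pairs(pc, meth, alpha=0.05)
print(f"pc-significant {counts['pc_only'] + counts['shared']}, "
      f"meth-significant {counts['meth_only'] + counts['shared']}, "
      f"shared {counts['shared']}")
print(f"eGenes (meth model): {len(call_egenes(meth))}")
```

prints

```
covered 39/40 SNPs, mean 2.82 CpGs/SNP
pc-significant 11, meth-significant 3, shared 3
eGenes (meth model): 3
```

The default configuration emulates a 53-sample design: 40 SNPs (MAF ≥
0.05), one target gene each, ~3 CpGs per SNP window, and a planted mix of
null / direct / confounded / suppressed architectures. At this small
sample size the methylation-adjusted model finds fewer significant pairs
than the PC model — confounded pairs lose significance once methylation is
adjusted for, which is exactly the behavior the comparison stage
quantifies. The same pipeline is available from the shell:

```
methqtl --seed 1 pipeline --out run/
```

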