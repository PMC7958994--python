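# Methods

## Methylation collapse

Each SNP's methylation covariate summarizes the CpGs within ±2,500 bp
(`window_bp`, the distance at which the linear weight `w = 1 − d/2500`
reaches zero). The window is interpreted as ±2,500 bp around the SNP
rather than a 2,500 bp total span: the weight formula is defined for
distances up to 2,500 bp, which a 2.5 kb total span could never produce.

Two deliberate asymmetries of the weighting scheme are preserved exactly:

* **Single CpG.** `M = (1 − d/2500)·m` — the raw weight multiplies the
  beta value and is *not* renormalized, so a lone CpG far from the SNP
  contributes a small covariate value. This differs in kind from the
  `N ≥ 2` case, where weights are normalized to sum to one and `M` is a
  convex combination of betas. A dedicated test asserts the two code
  paths disagree for `d > 0`; the `renormalize_single` flag (default off)
  offers the self-consistent alternative.
* **Window-edge CpGs.** CpGs at exactly `d = 2500` are inside the window
  but carry weight zero. A SNP whose CpGs *all* sit at the edge has no
  usable covariate (the weight normalizer would be zero) and is treated
  as uncovered. The same rule applies to a single CpG at the edge, whose
  covariate would be identically zero.

Pairwise Pearson correlations between the CpG betas at each multi-CpG SNP
are computed and reported in the collapse summary, but are not used
downstream.

Beta values are used on their natural [0, 1] proportion scale (no
logit/M-value transform), matching how methylation proportions enter the
covariate definition.

## eQTL regression

For every cis pair the genotype effect is estimated by OLS with the
global covariates, plus the collapsed methylation covariate under the
adjusted model. Implementation notes:

* cis window: TSS ± 1 Mb by default (boundary inclusive); gene-body ±
  1 Mb is available via `anchor="body"` since "1 Mb around the gene" is
  ambiguous.
* p-values are two-sided from the t distribution with
  `df = n_used − rank(design)`; a p-value that underflows double
  precision is floored at the smallest positive double and flagged
  `p_underflow`.
* Missing genotypes drop the affected samples for that pair only;
  `n_used` is reported per test. Rank-deficient designs (monomorphic
  dosage in the used samples, `M` collinear with `g`) are skipped with a
  reason code rather than raising.
* SNPs without a usable methylation covariate are fit without the `M`
  term under the adjusted model (`uncovered="baseline"`), keeping the
  pair universe identical between models so the comparison stage sees a
  complete join; `uncovered="skip"` excludes them instead.
* BH-FDR is computed per model run over all pairs actually tested in
  that run; no hierarchical (eGene-level) correction is applied. eGenes
  are genes with ≥ 1 pair at FDR < 0.05; ties for the best SNP break by
  smaller nominal p, then lexicographic rsid.

## Expression preparation

TPM is computed as count/length rates normalized to one million per
sample; gene length is the union of exonic bases when a GTF is supplied,
else the annotated span (BED) or a user table. The low-expression rule
removes a gene when TPM < 0.1 in ≥ 20% of samples or counts ≤ 6 in ≥ 20%
of samples ("at least 20%" implemented as ≥, both fractions exposed as
flags; per-gene reason codes record which rule fired). Surviving genes
are inverse-normal transformed per gene with average ranks and the
(r − ½)/n offset (Blom's (r − ⅜)/(n + ¼) available); downstream tests are
therefore rank-based, which is why no TMM-style between-sample
normalization is in the core path (a simple CPM option exists).

## Comparison and enrichment

Pair classification joins the two runs on (SNP, gene): methylation-only
(`fdr_meth < α ≤ fdr_pc`), shared, PC-only, not significant. Direction of
change uses nominal p-values, not FDR, because step-up flattening creates
wide FDR ties. The three analysis groups are: group 1 = methylation-only;
groups 2/3 = PC-significant pairs whose nominal p decreased/increased
under adjustment. Groups 2/3 are defined over *all* PC-significant pairs
by default; the variant restricted to shared-significant pairs is also
computed (columns `group2_shared`/`group3_shared`) since either reading
is defensible.

Enrichment contrasts each group's deduplicated SNPs against all SNPs
tested in the run (not the genome — the group arises from that tested
universe). GWAS annotations transfer to LD proxies at r² strictly > 0.8;
a proxy tagging several index variants carries the union of their
categories. Per category, a 2×2 Fisher's exact test (two-sided) is
BH-corrected across the categories tested in the call; odds ratios use a
Haldane 0.5 correction when the table has an empty cell. A seeded
label-permutation test is available as a sensitivity alternative. Both
overlap conventions (distinct SNPs, distinct associations) are reported.
Trait-to-category bucketing is user-supplied; a default 17-category
mapping ships with the package.

## Synthetic data

The generator emulates the targeted study design: 53 samples by default,
independent biallelic SNPs with MAF uniform on [0.05, 0.5] and dosages
drawn Binomial(2, MAF); Poisson(3) CpGs per SNP window (truncated at 95),
positions uniform in the window; betas are inverse-logit of a per-CpG
baseline (uniform on [−1.5, 1.5]) plus an optional meQTL shift per alt
allele plus Gaussian noise, guaranteeing values strictly inside (0, 1)
without clipping. Global covariates mirror the adjustment set: sex and
platform binaries, two genotype-PC stand-ins, ten PEER stand-ins.

One target gene is planted per SNP (TSS 50 kb downstream, within the cis
window; at the default 200 kb SNP spacing neighboring SNPs also fall in
cis, exercising the pair enumeration). Four architectures:

* `null` — covariates and noise only;
* `direct` — `β_g·g` added;
* `confounded` — `β_g·g + β_m·M` with a real meQTL, so the marginal
  genotype effect exceeds the conditional one and significance drops
  after adjustment;
* `suppressed` — as confounded but with `β_m` set against `β_g` so the
  marginal effect is masked and emerges only after adjustment. Exact
  masking depends on the realized methylation–genotype slope
  `λ = cov(M, g)/var(g)`, so the generator calibrates `β_m = −β_g/λ`
  per gene (magnitude capped at 50 to avoid blow-up when λ ≈ 0). This is
  the generator's formalization of a suppressor variable.

`M` here is the *collapsed* covariate of the SNP, so planted mediation
acts through exactly the quantity the pipeline adjusts for. Scenario
genes that require methylation are guaranteed at least one CpG.

`scenario_fixture_config` provides the canonical large-effect fixture
used by the scenario tests: n = 200, one planted gene plus two null
genes, MAF on [0.2, 0.5], meQTL effect 1.0 with CpG noise 0.6. Those
values put the methylation–genotype correlation near 0.7–0.8 — strong
enough for genuine confounding/suppression, while leaving the adjusted
model enough independent genotype variation to detect the conditional
effect; a much stronger meQTL makes `M` and `g` nearly collinear and no
finite sample could separate them.

Counts for file-based fixtures are `round(2^(b + y))` with a per-gene
baseline `b ~ U(4, 10)` — monotone in the latent expression per gene, so
the rank-based normalization recovers the planted ordering.

What the generator does **not** emulate: LD between SNPs (SNPs are
independent; LD exists only in the explicit proxy table), count
overdispersion structure, cell-type heterogeneity, batch-correlated
methylation, or realistic CpG spatial correlation. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to those real-data features.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small designs — 40 SNP–gene
loci at n = 53 for the descriptive pipeline, 2,000 single-pair null
fixtures for calibration, 500 replicates at n = 200 for effect recovery,
100 replicates per mediation scenario — sizes at which every statistical
check is well-powered while the whole suite stays fast. Other
conventions: coordinates are 1-based inclusive internally (BED converted
on read); dosage prefers the DS field over GT; multi-allelic records and
indels are rejected; an optional exact Hardy–Weinberg filter is off by
default (inputs are assumed post-QC); result tables are written with 12
significant digits so round-trips are lossless at printed precision.

## Known limitations

* The regression is mass-univariate OLS; no kinship/relatedness random
  effect, no interaction (g × M) term, and no trans analysis.
* FDR is pair-level per run; eGene calling inherits it without a
  hierarchical correction, so eGene counts are liberal relative to
  permutation-based schemes.
* The enrichment background is the tested-SNP universe; with few tested
  SNPs the Fisher tables are sparse and the permutation option is the
  safer choice.
* Methylation enters as a single collapsed value per SNP; CpGs are not
  modelled individually, and the distance weighting assumes influence
  decays linearly and identically for all loci.
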