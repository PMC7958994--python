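"""Synthetic genotype/methylation/expression bundles with planted truth.

The generator emulates the study design the pipeline targets: ~53 hepatocyte
samples with matched SNP dosages (MAF >= 0.05), CpG beta values clustered
within +/-2.5 kb of SNPs (about 3 CpGs per covered SNP, truncated at 95),
and gene expression driven by one of four planted architectures per gene:

    null        y = C*gamma + eps
    direct      y = beta_g*G + C*gamma + eps
    confounded  y = beta_g*G + beta_m*M + C*gamma + eps, with a real meQTL,
                so adjusting for M attenuates the marginal G association
    suppressed  as confounded but with beta_m chosen against beta_g so the
                marginal G effect is masked and only emerges after adjustment

M is the distance-weighted collapsed methylation covariate of the SNP, so
the planted mediation acts through exactly the quantity the pipeline
adjusts for. For the suppressed architecture, masking the marginal effect
requires beta_m to offset beta_g through the realized methylation-genotype
slope lambda = cov(M, G)/var(G); the generator calibrates
beta_m = -beta_g/lambda per gene (magnitude capped at 50).

Global covariates mirror the study's adjustment set: two binaries (sex,
platform), two genotype-PC stand-ins and ten PEER-factor stand-ins, all
with modest planted effects on expression.

Everything is a pure function of the seed; fixtures written to disk are
byte-identical across runs with the same configuration.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .expression_prep import ExpressionMatrix, inverse_normal_transform
from .io_formats import (CovariateMatrix, DEFAULT_TRAIT_CATEGORIES, GeneModel,
                         GenotypeMatrix, HarmonizedBundle, MethylationTable,
                         write_gene_bed)
from .methylation_collapse import CovariateTable, build_covariate_table

SCENARIOS = ("null", "direct", "confounded", "suppressed")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror the emulated study design."""

    n_samples: int = 53
    n_snps: int = 40
    maf_range: tuple[float, float] = (0.05, 0.5)
    chrom: str = "1"
    first_pos: int = 1_000_000
    snp_spacing_bp: int = 200_000
    window_bp: int = 2500
    cpg_rate: float = 3.0          # expected CpGs per SNP window
    max_cpgs: int = 95
    meqtl_effect: float = 2.0      # logit-beta shift per alt allele
    cpg_noise_sd: float = 0.3
    cpg_baseline_range: tuple[float, float] = (-1.5, 1.5)
    scenarios: tuple[str, ...] | None = None  # per gene; None = cycle
    beta_g: float = 1.0            # genotype -> expression, SD units/allele
    beta_m: float = 1.5            # methylation -> expression
    noise_sd: float = 1.0
    covariate_effect_sd: float = 0.3
    tss_offset_bp: int = 50_000
    gene_length_bp: int = 20_000
    n_categories: int = 17
    gwas_frac: float = 0.4         # fraction of SNPs with a GWAS assignment
    ld_proxy_frac: float = 0.5     # fraction of assignments routed via LD
    enriched_category: str | None = None
    enrichment_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 3:
            raise ValueError("n_samples must be at least 3")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.cpg_rate < 0:
            raise ValueError("cpg_rate must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.scenarios is not None:
            bad = set(self.scenarios) - set(SCENARIOS)
            if bad:
                raise ValueError(f"unknown scenario(s): {sorted(bad)}")

    def resolved_scenarios(self) -> tuple[str, ...]:
        if self.scenarios is not None:
            if len(self.scenarios) != self.n_snps:
                raise ValueError("scenarios must list one entry per SNP")
            return tuple(self.scenarios)
        cycle = ("direct", "confounded", "suppressed", "null")
        return tuple(cycle[i % 4] for i in range(self.n_snps))


def scenario_fixture_config(scenario: str, seed: int,
                            n_samples: int = 200) -> SimulationConfig:
    """Canonical large-effect fixture for one mediation scenario.

    One planted gene (plus two null genes) at a well-powered sample size.
    The meQTL effect (1.0 on the logit scale) and CpG noise (0.6) are set
    so the collapsed covariate correlates with genotype at roughly 0.7-0.8:
    strong enough for real confounding/suppression, while leaving the
    methylation-adjusted model enough independent genotype variation to
    detect the planted conditional effect. MAF is kept away from the lower
    bound so the genotype variance does not collapse.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    return SimulationConfig(
        n_samples=n_samples, n_snps=3,
        scenarios=(scenario, "null", "null"),
        snp_spacing_bp=3_000_000,  # one cis pair per gene
        maf_range=(0.2, 0.5), meqtl_effect=1.0, cpg_noise_sd=0.6,
        beta_g=1.0, beta_m=1.5, noise_sd=1.0, seed=seed)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def sample_ids(config: SimulationConfig) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(config.n_samples)]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Independent biallelic SNPs; dosage ~ Binomial(2, maf) per sample."""
    rng = _rng(config, 1)
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    dosage = rng.binomial(2, mafs[:, None],
                          size=(config.n_snps, config.n_samples)).astype(float)
    snps = pd.DataFrame({
        "rsid": [f"rs{100000 + i}" for i in range(config.n_snps)],
        "chrom": config.chrom,
        "pos": config.first_pos
        + np.arange(config.n_snps) * config.snp_spacing_bp,
        "ref": "A",
        "alt": "G",
    })
    gm = GenotypeMatrix(snps, sample_ids(config), dosage)
    gm.validate()
    return gm


def simulate_cpgs(genotypes: GenotypeMatrix,
                  config: SimulationConfig) -> MethylationTable:
    """CpGs per SNP window ~ Poisson(cpg_rate) truncated at ``max_cpgs``.

    Betas are inverse-logit of a per-CpG baseline plus (for SNPs whose
    scenario plants a meQTL) ``meqtl_effect`` per alt allele, plus noise —
    guaranteed inside (0, 1) with no clipping. Scenario genes that require
    methylation are guaranteed at least one CpG.
    """
    rng = _rng(config, 2)
    scenarios = config.resolved_scenarios()
    n = genotypes.n_samples
    ids, chroms, positions, betas = [], [], [], []
    for i in range(genotypes.n_snps):
        snp = genotypes.snps.iloc[i]
        k = min(int(rng.poisson(config.cpg_rate)), config.max_cpgs)
        needs_meth = scenarios[i] in ("confounded", "suppressed")
        if needs_meth and k == 0:
            k = 1
        if k == 0:
            continue
        offsets = rng.choice(2 * config.window_bp + 1, size=k, replace=False)
        pos = snp["pos"] - config.window_bp + np.sort(offsets)
        b0 = rng.uniform(*config.cpg_baseline_range, size=k)
        effect = config.meqtl_effect if needs_meth else 0.0
        logit = (b0[:, None] + effect * genotypes.dosage[i][None, :]
                 + rng.normal(0.0, config.cpg_noise_sd, size=(k, n)))
        for j in range(k):
            ids.append(f"cg{i:04d}_{j:02d}")
            chroms.append(snp["chrom"])
            positions.append(int(pos[j]))
        betas.append(expit(logit))
    if not ids:
        empty = pd.DataFrame(columns=["cpg_id", "chrom", "pos"])
        return MethylationTable(empty, list(genotypes.samples),
                                np.empty((0, n)))
    cpgs = pd.DataFrame({"cpg_id": ids, "chrom": chroms, "pos": positions})
    mt = MethylationTable(cpgs, list(genotypes.samples), np.vstack(betas))
    mt.validate()
    return mt.sort()


def simulate_covariates(config: SimulationConfig) -> CovariateMatrix:
    """Sex + platform binaries, 2 genotype-PC and 10 PEER stand-ins."""
    rng = _rng(config, 3)
    n = config.n_samples
    cols, names = [], []
    for name in ("sex", "platform"):
        v = rng.integers(0, 2, size=n).astype(float)
        if v.var() == 0:  # re-balance degenerate tiny-n draws
            v[rng.integers(0, n)] = 1.0 - v[0]
        cols.append(v)
        names.append(name)
    for name in ("pc1", "pc2", *[f"peer{i + 1}" for i in range(10)]):
        cols.append(rng.normal(size=n))
        names.append(name)
    cm = CovariateMatrix(sample_ids(config), names, np.column_stack(cols))
    cm.validate()
    return cm


def _planted_genes(genotypes: GenotypeMatrix,
                   config: SimulationConfig) -> list[GeneModel]:
    genes = []
    for i in range(genotypes.n_snps):
        snp = genotypes.snps.iloc[i]
        tss = int(snp["pos"]) + config.tss_offset_bp
        genes.append(GeneModel(gene_id=f"gene{i:04d}", chrom=str(snp["chrom"]),
                               start=tss, end=tss + config.gene_length_bp,
                               strand="+"))
    return genes


def simulate_expression(genotypes: GenotypeMatrix,
                        covariate_table: CovariateTable,
                        covariates: CovariateMatrix,
                        config: SimulationConfig,
                        ) -> tuple[ExpressionMatrix, list[GeneModel],
                                   pd.DataFrame]:
    """Continuous expression (one target gene per SNP) plus planted truth.

    Returns the expression matrix at stage 'filtered' (ready for the
    inverse normal transform), the gene models, and a truth table with
    every planted coefficient.
    """
    rng = _rng(config, 4)
    scenarios = config.resolved_scenarios()
    n = config.n_samples
    C = covariates.values
    genes = _planted_genes(genotypes, config)
    values = np.empty((genotypes.n_snps, n))
    truth_rows = []
    for i in range(genotypes.n_snps):
        snp = genotypes.snps.iloc[i]
        scen = scenarios[i]
        g = genotypes.dosage[i]
        gamma = rng.normal(0.0, config.covariate_effect_sd,
                           size=C.shape[1])
        eps = rng.normal(0.0, config.noise_sd, size=n)
        y = C @ gamma + eps
        beta_g_used, beta_m_used, meqtl_used, n_cpgs = 0.0, 0.0, 0.0, 0
        cov = covariate_table.covariates.get(snp["rsid"])
        if scen in ("confounded", "suppressed"):
            if cov is None:
                raise ValueError(
                    f"scenario {scen!r} for {snp['rsid']} requires at least "
                    "one usable CpG in its window")
            M = cov.M
            n_cpgs = cov.n_cpgs
            meqtl_used = config.meqtl_effect
            beta_g_used = config.beta_g
            if scen == "suppressed":
                var_g = g.var()
                lam = (np.cov(M, g)[0, 1] / var_g) if var_g > 0 else 0.0
                if abs(lam) < 1e-8:
                    beta_m_used = -np.sign(config.beta_g) * 50.0
                else:
                    beta_m_used = float(np.clip(-config.beta_g / lam,
                                                -50.0, 50.0))
            else:
                beta_m_used = config.beta_m
            y = y + beta_g_used * g + beta_m_used * M
        elif scen == "direct":
            beta_g_used = config.beta_g
            y = y + beta_g_used * g
            if cov is not None:
                n_cpgs = cov.n_cpgs
        else:  # null
            if cov is not None:
                n_cpgs = cov.n_cpgs
        values[i] = y
        truth_rows.append([genes[i].gene_id, snp["rsid"], scen, beta_g_used,
                           beta_m_used, meqtl_used, n_cpgs])
    expr = ExpressionMatrix([g.gene_id for g in genes], sample_ids(config),
                            values, "filtered")
    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "snp", "scenario", "beta_g", "beta_m", "meqtl_effect",
        "n_cpgs"])
    return expr, genes, truth


def expression_to_counts(expr: ExpressionMatrix,
                         config: SimulationConfig) -> ExpressionMatrix:
    """Map continuous expression to integer counts, monotone per gene.

    Counts are round(2^(b_g + y)) with a per-gene baseline b_g ~ U(4, 10),
    so ranks (hence the inverse normal transform) are preserved up to
    rounding and depth normalization.
    """
    rng = _rng(config, 6)
    base = rng.uniform(4.0, 10.0, size=expr.n_genes)
    counts = np.rint(2.0 ** (base[:, None] + expr.values))
    return ExpressionMatrix(list(expr.gene_ids), list(expr.samples),
                            counts, "counts")


def simulate_gwas_resources(genotypes: GenotypeMatrix, truth: pd.DataFrame,
                            config: SimulationConfig,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GWAS catalog associations and LD pairs over the simulated SNPs.

    A fraction of SNPs receives a trait assignment; ``ld_proxy_frac`` of
    assignments are routed through an external index variant linked to the
    SNP by an LD pair with r2 ~ U(0.5, 1), so only r2 > 0.8 proxies carry
    the annotation over. Planted enrichment over-assigns
    ``enriched_category`` to SNPs with a non-null planted effect.
    """
    rng = _rng(config, 5)
    categories = list(DEFAULT_TRAIT_CATEGORIES[:config.n_categories])
    is_eqtl = dict(zip(truth["snp"], truth["scenario"] != "null"))
    gwas_rows, ld_rows = [], []
    k = 0
    for i in range(genotypes.n_snps):
        rsid = genotypes.snps["rsid"].iloc[i]
        p_assign = config.gwas_frac
        forced_cat = None
        if (config.enriched_category is not None and is_eqtl.get(rsid, False)
                and config.enrichment_factor > 1.0):
            p_assign = min(1.0, config.gwas_frac * config.enrichment_factor)
            forced_cat = config.enriched_category
        if rng.uniform() >= p_assign:
            continue
        cat = forced_cat if forced_cat is not None else \
            categories[rng.integers(0, len(categories))]
        pvalue = 10.0 ** rng.uniform(-30.0, -8.0)
        if rng.uniform() < config.ld_proxy_frac:
            index_rsid = f"rsG{900000 + k}"
            k += 1
            r2 = rng.uniform(0.5, 1.0)
            ld_rows.append([index_rsid, rsid, float(r2)])
            gwas_rows.append([index_rsid, cat, cat, pvalue])
        else:
            gwas_rows.append([rsid, cat, cat, pvalue])
    gwas = pd.DataFrame(gwas_rows,
                        columns=["rsid", "trait", "category", "pvalue"])
    ld = pd.DataFrame(ld_rows, columns=["rsid_a", "rsid_b", "r2"])
    return gwas, ld


def simulate_bundle(config: SimulationConfig, int_transform: bool = True,
                    ) -> tuple[HarmonizedBundle, pd.DataFrame, CovariateTable]:
    """Full in-memory bundle: genotypes, methylation, expression, covariates,
    genes, plus the planted truth table and the collapsed covariate table."""
    genotypes = simulate_genotypes(config)
    methylation = simulate_cpgs(genotypes, config)
    covariates = simulate_covariates(config)
    cov_table = build_covariate_table(genotypes, methylation, config.window_bp)
    expr, genes, truth = simulate_expression(genotypes, cov_table,
                                             covariates, config)
    if int_transform:
        expr = inverse_normal_transform(expr)
    bundle = HarmonizedBundle(genotype=genotypes, methylation=methylation,
                              expression=expr, covariates=covariates,
                              genes=genes)
    return bundle, truth, cov_table


def _write_vcf(genotypes: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(genotypes.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i in range(genotypes.n_snps):
            snp = genotypes.snps.iloc[i]
            calls = [gt_map.get(int(d), "./.") if np.isfinite(d) else "./."
                     for d in genotypes.dosage[i]]
            fh.write(f"{snp['chrom']}\t{snp['pos']}\t{snp['rsid']}\t"
                     f"{snp['ref']}\t{snp['alt']}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def make_fixture(config: SimulationConfig, outdir: str | Path) -> list[Path]:
    """Write the complete fixture to disk; byte-identical under one seed.

    Files: genotypes.vcf, methylation.tsv, counts.tsv, covariates.tsv,
    genes.bed, gwas_catalog.tsv, ld_pairs.tsv, truth.tsv. The catalog's
    trait column carries the category label itself, so no separate
    trait-category mapping is needed for fixtures.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotypes = simulate_genotypes(config)
    methylation = simulate_cpgs(genotypes, config)
    covariates = simulate_covariates(config)
    cov_table = build_covariate_table(genotypes, methylation, config.window_bp)
    expr, genes, truth = simulate_expression(genotypes, cov_table,
                                             covariates, config)
    counts = expression_to_counts(expr, config)
    gwas, ld = simulate_gwas_resources(genotypes, truth, config)

    paths = []

    def _tsv(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        paths.append(p)

    vcf_path = outdir / "genotypes.vcf"
    _write_vcf(genotypes, vcf_path)
    paths.append(vcf_path)

    meth_df = pd.DataFrame(methylation.beta, columns=methylation.samples)
    meth_df = pd.concat([methylation.cpgs.reset_index(drop=True), meth_df],
                        axis=1)
    _tsv(meth_df, "methylation.tsv")

    counts_df = counts.to_frame()
    counts_df.iloc[:, 1:] = counts_df.iloc[:, 1:].astype(int)
    _tsv(counts_df, "counts.tsv")

    cov_df = pd.DataFrame(covariates.values, columns=covariates.names)
    cov_df.insert(0, "sample_id", covariates.samples)
    _tsv(cov_df, "covariates.tsv")

    bed_path = outdir / "genes.bed"
    write_gene_bed(genes, bed_path)
    paths.append(bed_path)

    catalog = pd.DataFrame({"SNPS": gwas["rsid"],
                            "DISEASE/TRAIT": gwas["trait"],
                            "P-VALUE": gwas["pvalue"]})
    _tsv(catalog, "gwas_catalog.tsv")
    _tsv(ld, "ld_pairs.tsv")
    _tsv(truth, "truth.tsv")
    return paths


def config_from_dict(d: dict) -> SimulationConfig:
    known = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
    d = dict(d)
    for key in ("maf_range", "cpg_baseline_range", "scenarios"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
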