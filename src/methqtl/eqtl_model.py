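"""Cis-eQTL mapping with an optional per-SNP methylation covariate.

Every SNP within 1 Mb of a gene's TSS (or gene body, by config) is tested
against that gene with ordinary least squares:

    pc model:    y ~ 1 + g + C
    meth model:  y ~ 1 + g + M + C

where g is the alt-allele dosage, C the global covariates (sex, platform,
batch, genotype PCs, PEER factors) and M the SNP's collapsed methylation
covariate. Inference is on the genotype coefficient only, with two-sided
p-values from the t distribution at n - rank(design) degrees of freedom,
and Benjamini-Hochberg FDR across all pairs tested in a run.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel, GenotypeMatrix, HarmonizedBundle
from .methylation_collapse import CovariateTable

CIS_BP_DEFAULT = 1_000_000

RESULT_COLUMNS = ["snp", "gene", "model", "beta", "se", "tstat", "pvalue",
                  "fdr", "n_cpgs", "n_used", "reason"]

#: smallest positive double; p-values that underflow are floored here and
#: flagged with reason "p_underflow"
P_FLOOR = float(np.nextafter(0.0, 1.0))


def enumerate_cis_pairs(genotypes: GenotypeMatrix, genes: list[GeneModel],
                        cis_bp: int = CIS_BP_DEFAULT, anchor: str = "tss",
                        ) -> list[tuple[str, str]]:
    """All (rsid, gene_id) pairs with the SNP inside the gene's cis window.

    ``anchor='tss'`` takes TSS +/- cis_bp (boundary inclusive);
    ``anchor='body'`` takes [start - cis_bp, end + cis_bp].
    """
    if cis_bp <= 0:
        raise ValueError("cis_bp must be positive")
    if anchor not in ("tss", "body"):
        raise ValueError(f"unknown cis anchor {anchor!r}")
    snps = genotypes.snps
    pairs: list[tuple[str, str]] = []
    for gene in genes:
        if anchor == "tss":
            lo, hi = gene.tss - cis_bp, gene.tss + cis_bp
        else:
            lo, hi = gene.start - cis_bp, gene.end + cis_bp
        on = snps[(snps["chrom"] == gene.chrom)
                  & (snps["pos"] >= lo) & (snps["pos"] <= hi)]
        pairs.extend((rsid, gene.gene_id) for rsid in on["rsid"])
    return pairs


def fit_pair(y: np.ndarray, g: np.ndarray, M: np.ndarray | None,
             C: np.ndarray | None, model: str = "pc") -> dict:
    """OLS fit of one SNP-gene pair; inference on the genotype coefficient.

    Samples with a missing value in y, g or M are dropped for this pair
    only. Rank-deficient designs (monomorphic genotype in the used samples,
    M collinear with g, ...) are reported with a reason code instead of
    estimates.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    use_m = model == "meth" and M is not None
    cols = [np.ones_like(y), g]
    mask = np.isfinite(y) & np.isfinite(g)
    if use_m:
        M = np.asarray(M, dtype=float)
        mask &= np.isfinite(M)
        cols.append(M)
    if C is not None and C.size:
        cols.extend(np.asarray(C, dtype=float).T)
    X = np.column_stack(cols)[mask]
    yy = y[mask]
    n, p = X.shape
    out = {"beta": np.nan, "se": np.nan, "tstat": np.nan, "pvalue": np.nan,
           "n_used": int(n), "reason": ""}
    if n <= p:
        out["reason"] = "insufficient_samples"
        return out
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        out["reason"] = "rank_deficient"
        return out
    beta, _, _, _ = np.linalg.lstsq(X, yy, rcond=None)
    resid = yy - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(max(sigma2, 0.0) * xtx_inv[1, 1]))
    b = float(beta[1])
    if se == 0.0:
        t = np.inf if b > 0 else (-np.inf if b < 0 else 0.0)
    else:
        t = b / se
    pval = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    if pval <= 0.0:
        pval = P_FLOOR
        out["reason"] = "p_underflow"
    out.update(beta=b, se=se, tstat=float(t), pvalue=pval)
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (with monotonicity)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def map_eqtls(bundle: HarmonizedBundle,
              covariate_table: CovariateTable | None = None,
              model: str = "pc", cis_bp: int = CIS_BP_DEFAULT,
              anchor: str = "tss", uncovered: str = "baseline",
              ) -> pd.DataFrame:
    """Fit every cis pair under one model and attach BH-FDR.

    Under ``model='meth'``, SNPs without a usable collapsed covariate are
    either fit without the M term (``uncovered='baseline'``, default, which
    keeps the pair universe identical between models) or skipped
    (``uncovered='skip'``). FDR is computed across the pairs actually
    tested in this run.
    """
    if model not in ("pc", "meth"):
        raise ValueError(f"unknown model {model!r}")
    if uncovered not in ("baseline", "skip"):
        raise ValueError(f"unknown uncovered policy {uncovered!r}")
    expr = bundle.expression
    if getattr(expr, "stage", None) != "int_normalized":
        raise ValueError("expression must be inverse-normal transformed "
                         f"(stage 'int_normalized', got {expr.stage!r})")
    pairs = enumerate_cis_pairs(bundle.genotype, bundle.genes, cis_bp, anchor)
    if not pairs:
        raise ValueError("no cis SNP-gene pairs to test")
    gene_idx = {g: i for i, g in enumerate(expr.gene_ids)}
    snp_idx = {r: i for i, r in enumerate(bundle.genotype.snps["rsid"])}
    C = bundle.covariates.values
    rows = []
    for rsid, gene_id in pairs:
        if gene_id not in gene_idx:
            continue  # gene removed by expression filtering
        y = expr.values[gene_idx[gene_id]]
        g = bundle.genotype.dosage[snp_idx[rsid]]
        M, n_cpgs = None, 0
        if model == "meth" and covariate_table is not None:
            cov = covariate_table.covariates.get(rsid)
            if cov is not None:
                M, n_cpgs = cov.M, cov.n_cpgs
            elif uncovered == "skip":
                rows.append([rsid, gene_id, model, np.nan, np.nan, np.nan,
                             np.nan, np.nan, 0, 0, "no_usable_cpg"])
                continue
        fit = fit_pair(y, g, M, C, model)
        rows.append([rsid, gene_id, model, fit["beta"], fit["se"],
                     fit["tstat"], fit["pvalue"], np.nan, n_cpgs,
                     fit["n_used"], fit["reason"]])
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    tested = results["pvalue"].notna()
    if tested.any():
        results.loc[tested, "fdr"] = bh_fdr(results.loc[tested, "pvalue"])
    results = results.sort_values(["gene", "snp"], kind="mergesort")
    return results.reset_index(drop=True)


def call_egenes(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Genes with at least one pair at FDR < alpha, with their best SNP.

    Ties at identical (fdr, pvalue) break to the lexicographically smaller
    rsid.
    """
    if results.empty:
        raise ValueError("empty result table")
    tested = results[results["pvalue"].notna()].copy()
    calls = []
    for gene_id, sub in tested.groupby("gene", sort=True):
        best = sub.sort_values(["fdr", "pvalue", "snp"],
                               kind="mergesort").iloc[0]
        if best["fdr"] < alpha:
            calls.append([gene_id, best["snp"], float(best["fdr"]),
                          best["model"]])
    return pd.DataFrame(calls, columns=["gene_id", "best_snp", "best_fdr",
                                        "model"])
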