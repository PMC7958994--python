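"""Collapse CpG methylation around each SNP into one distance-weighted covariate.

For each SNP, CpGs within ``window_bp`` (default 2500 bp either side) get an
initial weight that decays linearly with distance d:

    w = 1 - d / window

With a single contributing CpG the covariate is M = w * m — the raw weight
multiplies the beta value and is deliberately NOT renormalized, so a lone
distant CpG contributes little. With two or more CpGs the weights are
normalized to sum to one and M is the convex combination

    w_f,i = w_i / sum_k w_k ,   M = sum_i w_f,i * m_i

per sample. The asymmetry between the two cases is part of the method; the
``renormalize_single`` flag offers the self-consistent alternative (a single
CpG then gets weight 1 regardless of distance).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MethylationTable

WINDOW_BP_DEFAULT = 2500


@dataclass
class CollapseWeights:
    """Distances and weights for the CpGs contributing to one SNP."""

    snp_rsid: str
    cpg_ids: list[str]
    d: np.ndarray          # base-pair distances, d <= window
    w_initial: np.ndarray  # 1 - d/window
    w_final: np.ndarray    # normalized if N >= 2, else w_initial

    @property
    def n(self) -> int:
        return len(self.cpg_ids)


@dataclass
class SnpMethylationCovariate:
    """Per-SNP collapsed methylation value M across samples."""

    snp_rsid: str
    M: np.ndarray
    n_cpgs: int
    weights: CollapseWeights


@dataclass
class CollapseSummary:
    n_snps_total: int
    n_covered: int
    mean_cpgs: float
    min_cpgs: int
    max_cpgs: int
    uncovered_rsids: list[str]
    #: mean pairwise Pearson correlation of CpG betas, per multi-CpG SNP
    #: (descriptive only; not used downstream)
    pairwise_beta_corr: dict[str, float] = field(default_factory=dict)


@dataclass
class CovariateTable:
    covariates: dict[str, SnpMethylationCovariate]
    summary: CollapseSummary

    def get_M(self, rsid: str) -> np.ndarray | None:
        cov = self.covariates.get(rsid)
        return None if cov is None else cov.M


def find_window_cpgs(snp_chrom: str, snp_pos: int,
                     methylation: MethylationTable,
                     window_bp: int = WINDOW_BP_DEFAULT,
                     ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """CpGs on the SNP's chromosome with |pos - snp_pos| <= window_bp.

    Returns (cpg_ids, distances, row_indices) ordered by distance then
    position. CpGs at exactly the window edge are included (weight 0).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    cpgs = methylation.cpgs
    on_chrom = cpgs.index[cpgs["chrom"] == snp_chrom]
    if len(on_chrom) == 0:
        return [], np.empty(0, dtype=int), np.empty(0, dtype=int)
    pos = cpgs.loc[on_chrom, "pos"].to_numpy()
    lo = np.searchsorted(pos, snp_pos - window_bp, side="left")
    hi = np.searchsorted(pos, snp_pos + window_bp, side="right")
    idx = np.asarray(on_chrom)[lo:hi]
    d = np.abs(cpgs.loc[idx, "pos"].to_numpy() - snp_pos)
    order = np.lexsort((cpgs.loc[idx, "pos"].to_numpy(), d))
    idx, d = idx[order], d[order]
    ids = [str(c) for c in cpgs.loc[idx, "cpg_id"]]
    return ids, d.astype(int), idx


def compute_weights(distances: np.ndarray, window_bp: int = WINDOW_BP_DEFAULT,
                    renormalize_single: bool = False,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Initial and final weights for a set of CpG distances.

    Returns (w_initial, w_final). With N >= 2 CpGs whose initial weights
    all vanish (every CpG exactly at the window edge), or a single CpG
    with zero weight, there is no usable covariate and a ValueError is
    raised; callers treat the SNP as uncovered.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        return np.empty(0), np.empty(0)
    if (d < 0).any() or (d > window_bp).any():
        raise ValueError("distance outside [0, window_bp]")
    w_initial = 1.0 - d / window_bp
    total = w_initial.sum()
    if total <= 0:
        raise ValueError("all CpG weights are zero (window-edge CpGs only)")
    if d.size == 1:
        w_final = np.array([1.0]) if renormalize_single else w_initial.copy()
    else:
        w_final = w_initial / total
    return w_initial, w_final


def collapse_snp_methylation(rsid: str, cpg_ids: list[str],
                             distances: np.ndarray, betas: np.ndarray,
                             window_bp: int = WINDOW_BP_DEFAULT,
                             renormalize_single: bool = False,
                             ) -> SnpMethylationCovariate:
    """Collapse aligned CpG beta rows into the per-SNP covariate M."""
    if len(cpg_ids) != betas.shape[0] or len(cpg_ids) != len(distances):
        raise ValueError(f"cpg ids, distances and beta rows mismatched for {rsid}")
    w_initial, w_final = compute_weights(distances, window_bp,
                                         renormalize_single)
    M = w_final @ betas
    weights = CollapseWeights(rsid, list(cpg_ids),
                              np.asarray(distances, dtype=int),
                              w_initial, w_final)
    return SnpMethylationCovariate(rsid, M, len(cpg_ids), weights)


def build_covariate_table(genotypes: GenotypeMatrix,
                          methylation: MethylationTable,
                          window_bp: int = WINDOW_BP_DEFAULT,
                          renormalize_single: bool = False) -> CovariateTable:
    """Collapse methylation for every SNP with at least one usable CpG.

    SNPs whose CpGs carry zero total weight (edge-only) or with no CpG in
    the window are listed as uncovered. The summary reports coverage, the
    CpG-count distribution, and per-SNP mean pairwise CpG beta correlation
    (descriptive).
    """
    covariates: dict[str, SnpMethylationCovariate] = {}
    uncovered: list[str] = []
    corr: dict[str, float] = {}
    for i in range(genotypes.n_snps):
        snp = genotypes.snps.iloc[i]
        ids, d, rows = find_window_cpgs(snp["chrom"], int(snp["pos"]),
                                        methylation, window_bp)
        if not ids:
            uncovered.append(snp["rsid"])
            continue
        betas = methylation.beta[rows]
        try:
            cov = collapse_snp_methylation(snp["rsid"], ids, d, betas,
                                           window_bp, renormalize_single)
        except ValueError:
            uncovered.append(snp["rsid"])
            continue
        covariates[snp["rsid"]] = cov
        if len(ids) >= 2:
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(betas)
            iu = np.triu_indices(len(ids), k=1)
            vals = c[iu]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                corr[snp["rsid"]] = float(vals.mean())
    counts = [c.n_cpgs for c in covariates.values()]
    summary = CollapseSummary(
        n_snps_total=genotypes.n_snps,
        n_covered=len(covariates),
        mean_cpgs=float(np.mean(counts)) if counts else 0.0,
        min_cpgs=int(min(counts)) if counts else 0,
        max_cpgs=int(max(counts)) if counts else 0,
        uncovered_rsids=uncovered,
        pairwise_beta_corr=corr,
    )
    return CovariateTable(covariates, summary)


def covariate_frame(table: CovariateTable, samples: list[str]) -> pd.DataFrame:
    """Wide table of collapsed covariates: rsid, n_cpgs, one M column per sample."""
    rows = []
    for rsid, cov in table.covariates.items():
        rows.append([rsid, cov.n_cpgs, *cov.M])
    return pd.DataFrame(rows, columns=["rsid", "n_cpgs", *samples])


def weights_frame(table: CovariateTable) -> pd.DataFrame:
    """Long table of per-CpG weights: rsid, cpg_id, distance, w_initial, w_final."""
    rows = []
    for rsid, cov in table.covariates.items():
        w = cov.weights
        for j in range(w.n):
            rows.append([rsid, w.cpg_ids[j], int(w.d[j]),
                         float(w.w_initial[j]), float(w.w_final[j])])
    return pd.DataFrame(rows, columns=["rsid", "cpg_id", "distance",
                                       "w_initial", "w_final"])
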