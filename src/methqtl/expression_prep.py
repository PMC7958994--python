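"""Expression normalization: counts -> TPM -> filtering -> inverse normal.

The analysis-ready values are per-gene rank-based normal quantiles, so the
eQTL regressions downstream are robust to the raw count scale; only a simple
library-size (CPM) scaling is offered ahead of filtering.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

STAGES = ("counts", "tpm", "filtered", "int_normalized")


@dataclass
class ExpressionMatrix:
    gene_ids: list[str]
    samples: list[str]
    values: np.ndarray  # n_genes x n_samples
    stage: str = "counts"

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError("expression shape mismatch")
        if self.stage == "counts" and (self.values < 0).any():
            raise ValueError("counts must be non-negative")

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids),
                                self.values[:, idx], self.stage)

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        ids = [g for g, k in zip(self.gene_ids, keep) if k]
        return ExpressionMatrix(ids, list(self.samples), self.values[keep],
                                self.stage)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.samples)
        df.insert(0, "gene_id", self.gene_ids)
        return df


def read_expression_table(path, stage: str = "counts") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError("expression table must start with a gene_id column")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in expression table")
    em = ExpressionMatrix([str(g) for g in df["gene_id"]],
                          [str(c) for c in df.columns[1:]],
                          df.iloc[:, 1:].to_numpy(dtype=float), stage)
    em.validate()
    return em


def library_normalize(counts: ExpressionMatrix, method: str = "none",
                      ) -> ExpressionMatrix:
    """Optional library-size scaling before filtering: 'none' or 'cpm'."""
    if method == "none":
        return counts
    if method != "cpm":
        raise ValueError(f"unknown libnorm method {method!r}")
    depth = counts.values.sum(axis=0)
    if (depth == 0).any():
        bad = [s for s, d in zip(counts.samples, depth) if d == 0]
        raise ValueError(f"zero library size for sample(s): {bad}")
    return ExpressionMatrix(list(counts.gene_ids), list(counts.samples),
                            counts.values / depth * 1e6, counts.stage)


def compute_tpm(counts: ExpressionMatrix,
                gene_lengths: dict[str, float]) -> ExpressionMatrix:
    """Transcripts per million: counts scaled by gene length, then by depth.

    Each sample column of the result sums to 1e6.
    """
    missing = [g for g in counts.gene_ids if g not in gene_lengths]
    if missing:
        raise ValueError(f"no gene length for: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    lengths = np.array([gene_lengths[g] for g in counts.gene_ids], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.values / lengths[:, None]
    depth = rate.sum(axis=0)
    if (depth <= 0).any():
        bad = [s for s, d in zip(counts.samples, depth) if d <= 0]
        raise ValueError(f"TPM undefined for all-zero sample(s): {bad}")
    return ExpressionMatrix(list(counts.gene_ids), list(counts.samples),
                            rate / depth * 1e6, "tpm")


def filter_genes(counts: ExpressionMatrix, tpm: ExpressionMatrix,
                 tpm_min: float = 0.1, count_min: float = 6,
                 frac: float = 0.2) -> tuple[np.ndarray, list[str]]:
    """Low-expression removal mask.

    A gene is REMOVED when TPM < ``tpm_min`` in at least ``frac`` of samples,
    or counts <= ``count_min`` in at least ``frac`` of samples ("at least"
    implemented as >=). Returns (keep mask, per-gene reason codes; empty
    string = kept).
    """
    if counts.values.shape != tpm.values.shape:
        raise ValueError("counts and tpm matrices must share shape")
    n = len(counts.samples)
    frac_low_tpm = (tpm.values < tpm_min).sum(axis=1) / n
    frac_low_count = (counts.values <= count_min).sum(axis=1) / n
    low_tpm = frac_low_tpm >= frac
    low_count = frac_low_count >= frac
    reasons = []
    for lt, lc in zip(low_tpm, low_count):
        tags = [t for t, f in (("low_tpm", lt), ("low_count", lc)) if f]
        reasons.append(";".join(tags))
    keep = ~(low_tpm | low_count)
    return keep, reasons


def inverse_normal_transform(matrix: ExpressionMatrix,
                             offset: str = "half") -> ExpressionMatrix:
    """Per-gene rank-to-normal-quantile transform.

    Ranks use the average-tie convention. ``offset='half'`` maps rank r to
    the standard normal quantile of (r - 0.5)/n; ``offset='blom'`` uses
    (r - 3/8)/(n + 1/4). Constant gene rows are rank-degenerate and raise.
    """
    values = matrix.values
    n = values.shape[1]
    out = np.empty_like(values, dtype=float)
    for i, row in enumerate(values):
        if np.ptp(row) == 0:
            raise ValueError(
                f"constant expression row for gene {matrix.gene_ids[i]}")
        r = rankdata(row, method="average")
        if offset == "half":
            q = (r - 0.5) / n
        elif offset == "blom":
            q = (r - 3.0 / 8.0) / (n + 0.25)
        else:
            raise ValueError(f"unknown offset {offset!r}")
        out[i] = ndtri(q)
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.samples),
                            out, "int_normalized")


def prepare_expression(counts: ExpressionMatrix,
                       gene_lengths: dict[str, float],
                       tpm_min: float = 0.1, count_min: float = 6,
                       frac: float = 0.2, libnorm: str = "none",
                       offset: str = "half",
                       ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Counts to analysis-ready expression in one call.

    Returns the inverse-normal matrix over surviving genes plus a per-gene
    filter report (gene_id, kept, reason).
    """
    normed = library_normalize(counts, libnorm)
    tpm = compute_tpm(normed, gene_lengths)
    keep, reasons = filter_genes(counts, tpm, tpm_min, count_min, frac)
    report = pd.DataFrame({"gene_id": counts.gene_ids, "kept": keep,
                           "reason": reasons})
    filtered = ExpressionMatrix(
        [g for g, k in zip(counts.gene_ids, keep) if k],
        list(counts.samples), counts.values[keep], "filtered")
    if filtered.n_genes == 0:
        raise ValueError("no genes survive expression filtering")
    return inverse_normal_transform(filtered, offset), report
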