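"""Compare PC- vs methylation-adjusted eQTL runs and test GWAS enrichment.

Pairs are classified by which model calls them significant (BH-FDR < alpha)
and by the direction of the nominal p-value change. Three analysis groups
follow:

    group 1: significant only with methylation adjustment,
    group 2: PC-significant and more significant after adjustment,
    group 3: PC-significant and less significant after adjustment.

Each group's SNPs are overlapped with GWAS catalog variants (expanded with
LD proxies at r2 > 0.8) and tested per trait category with Fisher's exact
test against the background of all SNPs tested in the run, BH-corrected
across categories.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl_model import bh_fdr

GROUP_LABELS = ("meth_only", "shared", "pc_only", "not_significant")


def classify_pairs(pc_results: pd.DataFrame, meth_results: pd.DataFrame,
                   alpha: float = 0.05, allow_partial: bool = False,
                   ) -> tuple[pd.DataFrame, dict]:
    """Join the two model runs pair-by-pair and assign comparison groups.

    Both tables must cover the same (snp, gene) universe unless
    ``allow_partial`` is set, in which case one-sided pairs are dropped
    with a flag count. Pairs untested in either run (reason codes) are
    labelled 'not_tested' and excluded from the four-way partition.
    """
    pc = pc_results.rename(columns={"beta": "beta_pc", "pvalue": "p_pc",
                                    "fdr": "fdr_pc"})
    me = meth_results.rename(columns={"beta": "beta_meth", "pvalue": "p_meth",
                                      "fdr": "fdr_meth"})
    merged = pc[["snp", "gene", "beta_pc", "p_pc", "fdr_pc"]].merge(
        me[["snp", "gene", "beta_meth", "p_meth", "fdr_meth", "n_cpgs"]],
        on=["snp", "gene"], how="outer", indicator=True)
    one_sided = merged["_merge"] != "both"
    if one_sided.any() and not allow_partial:
        bad = merged.loc[one_sided, ["snp", "gene"]].iloc[0]
        raise ValueError(
            f"pair ({bad['snp']}, {bad['gene']}) present in only one "
            "result table; pass allow_partial=True to drop such pairs")
    merged = merged[~one_sided].drop(columns="_merge").reset_index(drop=True)

    tested = merged["p_pc"].notna() & merged["p_meth"].notna()
    sig_pc = tested & (merged["fdr_pc"] < alpha)
    sig_me = tested & (merged["fdr_meth"] < alpha)
    group = np.where(~tested, "not_tested",
             np.where(sig_me & ~sig_pc, "meth_only",
              np.where(sig_me & sig_pc, "shared",
               np.where(sig_pc, "pc_only", "not_significant"))))
    direction = np.where(~tested, "",
                 np.where(merged["p_meth"] < merged["p_pc"], "increased",
                  np.where(merged["p_meth"] > merged["p_pc"], "decreased",
                           "unchanged")))
    merged["group"] = group
    merged["direction"] = direction
    # paper-style analysis groups over all pc-significant pairs
    merged["group1"] = group == "meth_only"
    merged["group2"] = sig_pc & (merged["p_meth"] < merged["p_pc"])
    merged["group3"] = sig_pc & (merged["p_meth"] > merged["p_pc"])
    # alternative reading: groups 2/3 restricted to shared-significant pairs
    merged["group2_shared"] = merged["group2"] & sig_me
    merged["group3_shared"] = merged["group3"] & sig_me

    counts = {lab: int((group == lab).sum()) for lab in GROUP_LABELS}
    counts["not_tested"] = int((~tested).sum())
    counts["n_pairs"] = int(len(merged))
    for g in ("group1", "group2", "group3", "group2_shared", "group3_shared"):
        counts[g] = int(merged[g].sum())
    return merged, counts


def effect_size_correlation(comparisons: pd.DataFrame,
                            subset: str | np.ndarray | None = None,
                            ) -> tuple[float, float, int]:
    """Spearman correlation of genotype effect sizes between the two models.

    ``subset`` may be a group label ('meth_only', 'shared', 'group1', ...)
    or a boolean mask; None uses every tested pair.
    """
    df = comparisons[comparisons["p_pc"].notna() & comparisons["p_meth"].notna()]
    if isinstance(subset, str):
        if subset in GROUP_LABELS:
            df = df[df["group"] == subset]
        elif subset in ("group1", "group2", "group3",
                        "group2_shared", "group3_shared"):
            df = df[df[subset]]
        else:
            raise ValueError(f"unknown subset {subset!r}")
    elif subset is not None:
        df = df[np.asarray(subset)]
    n = len(df)
    if n < 3:
        raise ValueError(f"need at least 3 pairs for a correlation, got {n}")
    rho, p = stats.spearmanr(df["beta_pc"], df["beta_meth"])
    return float(rho), float(p), n


def expand_ld(gwas: pd.DataFrame, ld: pd.DataFrame,
              r2_threshold: float = 0.8) -> dict[str, set[tuple[str, str]]]:
    """Map each rsid reachable from the GWAS catalog to its associations.

    Every catalog rsid maps to its own (rsid, category) associations; LD
    proxies at r2 strictly above the threshold inherit the associations of
    every index variant they tag (deduplicated as a set).
    """
    assoc: dict[str, set[tuple[str, str]]] = {}
    by_rsid: dict[str, set[tuple[str, str]]] = {}
    for row in gwas.itertuples(index=False):
        by_rsid.setdefault(row.rsid, set()).add((row.rsid, row.category))
    for rsid, pairs in by_rsid.items():
        assoc.setdefault(rsid, set()).update(pairs)
    if len(ld):
        keep = ld[ld["r2"] > r2_threshold]
        for row in keep.itertuples(index=False):
            for index_rsid, proxy in ((row.rsid_a, row.rsid_b),
                                      (row.rsid_b, row.rsid_a)):
                if index_rsid in by_rsid:
                    assoc.setdefault(proxy, set()).update(by_rsid[index_rsid])
    return assoc


def overlap_eqtls_gwas(group_snps, gwas_map: dict[str, set[tuple[str, str]]],
                       ) -> pd.DataFrame:
    """Overlap a deduplicated SNP set with the LD-expanded GWAS map.

    Returns one row per overlapping SNP with its category set and the
    number of distinct originating associations.
    """
    rows = []
    for rsid in sorted(set(group_snps)):
        if rsid in gwas_map:
            pairs = gwas_map[rsid]
            cats = sorted({c for _, c in pairs})
            rows.append([rsid, ";".join(cats), len(pairs)])
    return pd.DataFrame(rows, columns=["rsid", "categories", "n_associations"])


def overlap_counts(group_snps, gwas_map) -> dict[str, int]:
    """Both readings of 'overlap': distinct SNPs and distinct associations."""
    ov = overlap_eqtls_gwas(group_snps, gwas_map)
    assoc = set()
    for rsid in ov["rsid"]:
        assoc.update(gwas_map[rsid])
    return {"n_overlap_snps": int(len(ov)),
            "n_overlap_associations": int(len(assoc))}


def _category_hits(snps: set[str], gwas_map, category: str) -> int:
    return sum(1 for s in snps
               if s in gwas_map and any(c == category for _, c in gwas_map[s]))


def enrichment_test(group_snps, background_snps, gwas_map,
                    categories=None, method: str = "fisher",
                    n_permutations: int = 10_000,
                    seed: int | None = 0) -> pd.DataFrame:
    """Per-category enrichment of a SNP group against a background.

    The 2x2 table contrasts group vs background-only SNPs by overlap with
    the category's (LD-expanded) GWAS variants; two-sided Fisher's exact
    p-values, odds ratios with a Haldane 0.5 correction when a margin is
    zero, BH-FDR across the categories tested in this call, and the
    in-group overlap proportion for plotting. ``method='permutation'``
    replaces the Fisher p-value with a seeded label-permutation p-value.
    """
    group = set(group_snps)
    background = set(background_snps)
    if not group <= background:
        raise ValueError("group SNPs must be a subset of the background")
    rest = background - group
    if categories is None:
        categories = sorted({c for pairs in gwas_map.values()
                             for _, c in pairs})
    rows = []
    rng = np.random.default_rng(seed)
    bg_list = sorted(background)
    for cat in categories:
        a = _category_hits(group, gwas_map, cat)
        b = _category_hits(rest, gwas_map, cat)
        table = np.array([[a, len(group) - a], [b, len(rest) - b]])
        if len(group) == 0:
            rows.append([cat, a, len(group), b, len(rest),
                         np.nan, np.nan, np.nan, "empty_group"])
            continue
        if len(rest) == 0:  # group == background: no contrast to test
            rows.append([cat, a, len(group), b, len(rest),
                         1.0, 1.0, np.nan, "no_background_contrast"])
            continue
        if method == "fisher":
            _, p = stats.fisher_exact(table, alternative="two-sided")
        elif method == "permutation":
            hit = np.array([1 if _category_hits({s}, gwas_map, cat) else 0
                            for s in bg_list])
            obs = a
            k = len(group)
            perm = np.array([hit[rng.permutation(len(bg_list))[:k]].sum()
                             for _ in range(n_permutations)])
            mu = hit.sum() * k / len(bg_list)
            p = (1 + np.sum(np.abs(perm - mu) >= abs(obs - mu))) / (
                n_permutations + 1)
        else:
            raise ValueError(f"unknown enrichment method {method!r}")
        t = table.astype(float)
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any() or \
                (t == 0).any():
            t = t + 0.5  # Haldane correction for empty cells/margins
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        rows.append([cat, a, len(group), b, len(rest), float(odds),
                     float(p), np.nan, ""])
    out = pd.DataFrame(rows, columns=[
        "category", "n_overlap_in_group", "n_group",
        "n_overlap_background", "n_background_only", "odds_ratio",
        "pvalue", "fdr", "flag"])
    tested = out["pvalue"].notna()
    if tested.any():
        out.loc[tested, "fdr"] = bh_fdr(out.loc[tested, "pvalue"])
    out["proportion"] = np.where(out["n_group"] > 0,
                                 out["n_overlap_in_group"] / out["n_group"],
                                 np.nan)
    return out
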