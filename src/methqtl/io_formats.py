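"""Readers, writers and sample harmonization for the eQTL pipeline.

All genomic coordinates are 1-based inclusive internally (VCF/GTF
convention); BED inputs are converted on read. Genotypes are stored as
alt-allele dosages in [0, 2] with NaN marking missing calls, methylation
as beta values in [0, 1].
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ontology-style trait categories used to bucket GWAS catalog traits.
DEFAULT_TRAIT_CATEGORIES: tuple[str, ...] = (
    "lipid or lipoprotein measurement",
    "immune system disorder",
    "liver enzyme measurement",
    "digestive system disorder",
    "cardiovascular disease",
    "cancer",
    "metabolic disorder",
    "neurological disorder",
    "psychiatric disorder",
    "body measurement",
    "hematological measurement",
    "inflammatory measurement",
    "kidney disease",
    "respiratory disease",
    "drug response",
    "bone measurement",
    "other measurement",
)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """SNP-by-sample alt-allele dosage matrix.

    ``snps`` is a DataFrame with columns rsid, chrom, pos, ref, alt; rows
    align with the rows of ``dosage``. Missing genotypes are NaN and the
    affected samples are dropped per-SNP at model-fit time.
    """

    snps: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        if self.dosage.shape != (len(self.snps), len(self.samples)):
            raise ValueError("dosage shape does not match snps x samples")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("SNP positions must be strictly positive")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosage values must lie in [0, 2]")
        if self.snps["rsid"].duplicated().any():
            dup = self.snps.loc[self.snps["rsid"].duplicated(), "rsid"].iloc[0]
            raise ValueError(f"duplicate rsid: {dup}")

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(self.snps.reset_index(drop=True),
                              list(sample_ids), self.dosage[:, idx])


@dataclass
class MethylationTable:
    """CpG-by-sample beta-value matrix, sorted by (chrom, pos)."""

    cpgs: pd.DataFrame  # columns: cpg_id, chrom, pos
    samples: list[str]
    beta: np.ndarray

    @property
    def n_cpgs(self) -> int:
        return len(self.cpgs)

    def validate(self) -> None:
        if self.beta.shape != (len(self.cpgs), len(self.samples)):
            raise ValueError("beta shape does not match cpgs x samples")
        if self.cpgs["cpg_id"].duplicated().any():
            dup = self.cpgs.loc[self.cpgs["cpg_id"].duplicated(), "cpg_id"].iloc[0]
            raise ValueError(f"duplicate cpg_id: {dup}")
        bad = (self.beta < -1e-9) | (self.beta > 1 + 1e-9)
        if bad.any():
            i = int(np.argwhere(bad)[0, 0])
            raise ValueError(
                f"beta value out of [0, 1] for CpG {self.cpgs['cpg_id'].iloc[i]}")

    def sort(self) -> "MethylationTable":
        order = self.cpgs.sort_values(["chrom", "pos"], kind="mergesort").index
        return MethylationTable(
            self.cpgs.loc[order].reset_index(drop=True),
            list(self.samples),
            self.beta[np.asarray(order)],
        )

    def subset_samples(self, sample_ids: list[str]) -> "MethylationTable":
        idx = [self.samples.index(s) for s in sample_ids]
        return MethylationTable(self.cpgs.reset_index(drop=True),
                                list(sample_ids), self.beta[:, idx])


@dataclass(frozen=True)
class GeneModel:
    """One gene: 1-based inclusive span plus strand-resolved TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r} "
                             f"for {self.gene_id}")
        if self.start > self.end:
            raise ValueError(f"start > end for gene {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class CovariateMatrix:
    """Global (sample-level) covariates: sex, platform, batch, PCs, PEER."""

    samples: list[str]
    names: list[str]
    values: np.ndarray  # n_samples x n_covariates

    @property
    def n_covariates(self) -> int:
        return len(self.names)

    def validate(self) -> None:
        if self.values.shape != (len(self.samples), len(self.names)):
            raise ValueError("covariate shape mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("covariate names must be unique")
        if len(self.samples) > 1:
            var = self.values.var(axis=0)
            if (var == 0).any():
                bad = [n for n, v in zip(self.names, var) if v == 0]
                raise ValueError(f"zero-variance covariate column(s): {bad}")

    def subset_samples(self, sample_ids: list[str]) -> "CovariateMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return CovariateMatrix(list(sample_ids), list(self.names),
                               self.values[idx])


@dataclass
class HarmonizedBundle:
    """All data types restricted to one shared, identically ordered sample set."""

    genotype: GenotypeMatrix
    methylation: MethylationTable
    expression: "object"  # ExpressionMatrix; kept loose to avoid cycle
    covariates: CovariateMatrix
    genes: list[GeneModel] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return self.genotype.samples


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _is_biallelic_snv(ref: str, alts: list[str]) -> bool:
    return (len(alts) == 1 and alts[0] is not None
            and len(ref) == 1 and len(alts[0]) == 1
            and ref in "ACGT" and alts[0] in "ACGT")


def hwe_exact_test(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Mid-less exact test: sums the probabilities of all heterozygote counts,
    conditional on the allele counts, no more probable than the observed one.
    """
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    # probability over het counts with the parity of n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.zeros(len(hets))
    from scipy.special import gammaln
    for i, h in enumerate(hets):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logp[i] = (gammaln(n + 1) - gammaln(h + 1) - gammaln(rare_hom + 1)
                   - gammaln(common_hom + 1) + h * np.log(2)
                   + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1)
                   - gammaln(2 * n + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_het]
    if obs.size == 0:
        return 1.0
    return float(min(1.0, p[p <= obs[0] * (1 + 1e-12)].sum()))


def read_genotypes(path: str | Path, maf_min: float = 0.05,
                   hwe_p_min: float | None = None) -> GenotypeMatrix:
    """Load biallelic SNVs from a VCF as dosages, dropping low-MAF sites.

    Dosage comes from the DS FORMAT field when present, otherwise from
    counting alt alleles in GT; missing GT becomes NaN. Multi-allelic
    records and indels are rejected. MAF is computed from the mean dosage
    over non-missing samples; sites with MAF < ``maf_min`` are dropped.
    ``hwe_p_min`` optionally applies an exact Hardy-Weinberg filter to
    hard-called genotypes (default off: inputs are assumed post-QC).
    """
    from cyvcf2 import VCF

    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, dosages = [], []
    for k, rec in enumerate(vcf):
        if rec.POS <= 0:
            raise ValueError(f"non-positive POS at record {k + 1} of {path}")
        if not _is_biallelic_snv(rec.REF, rec.ALT):
            continue
        try:
            ds = rec.format("DS")
        except KeyError:  # DS not declared in the header
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
            dose = np.where((dose < -0.5) | (dose > 2.5), np.nan, dose)
            dose = np.clip(dose, 0.0, 2.0)
        else:
            dose = np.empty(len(samples))
            for i, gt in enumerate(rec.genotypes):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    dose[i] = np.nan
                else:
                    dose[i] = float(sum(1 for a in alleles if a == 1))
        ok = np.isfinite(dose)
        if not ok.any():
            continue
        p_alt = dose[ok].mean() / 2.0
        maf = min(p_alt, 1.0 - p_alt)
        if maf < maf_min:
            continue
        if hwe_p_min is not None:
            hard = np.rint(dose[ok]).astype(int)
            p_hwe = hwe_exact_test(int((hard == 1).sum()),
                                   int((hard == 0).sum()),
                                   int((hard == 2).sum()))
            if p_hwe < hwe_p_min:
                continue
        rsid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        rows.append((rsid, str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0]))
        dosages.append(dose)
    if not rows:
        raise ValueError(f"no SNPs survive filtering in {path}")
    snps = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "ref", "alt"])
    dosage = np.vstack(dosages)
    order = snps.sort_values(["chrom", "pos"], kind="mergesort").index
    gm = GenotypeMatrix(snps.loc[order].reset_index(drop=True), samples,
                        dosage[np.asarray(order)])
    gm.validate()
    return gm


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def read_methylation_table(path: str | Path) -> MethylationTable:
    """Read a TSV with columns cpg_id, chrom, pos and one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["cpg_id", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"methylation table missing column(s): {missing}")
    samples = [c for c in df.columns if c not in required]
    if not samples:
        raise ValueError("methylation table has no sample columns")
    beta = df[samples].to_numpy(dtype=float)
    mt = MethylationTable(df[required].copy(), samples, beta)
    mt.validate()
    return mt.sort()


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene records from a GTF or a 6-column BED.

    GTF coordinates are used as-is (1-based inclusive); BED start is
    converted from 0-based half-open. TSS is the start on + strand and
    the end on - strand.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3") or \
            "".join(path.suffixes[-2:]).lower() in (".gtf.gz",):
        return _read_genes_gtf(path)
    return _read_genes_bed(path)


def _read_genes_gtf(path: Path) -> list[GeneModel]:
    import pyranges as pr

    gr = pr.read_gtf(str(path)).df
    genes = gr[gr["Feature"] == "gene"]
    if "gene_id" not in genes.columns or genes["gene_id"].isna().any():
        raise ValueError(f"GTF gene record without gene_id in {path}")
    out = []
    for _, row in genes.iterrows():
        out.append(GeneModel(
            gene_id=str(row["gene_id"]),
            chrom=str(row["Chromosome"]),
            start=int(row["Start"]) + 1,  # pyranges stores 0-based starts
            end=int(row["End"]),
            strand=str(row["Strand"]),
        ))
    return out


def _read_genes_bed(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str})
    if df["name"].isna().any():
        raise ValueError(f"BED gene record without a name field in {path}")
    return [GeneModel(gene_id=str(r["name"]), chrom=str(r["chrom"]),
                      start=int(r["start"]) + 1, end=int(r["end"]),
                      strand=str(r["strand"]))
            for _, r in df.iterrows()]


def write_gene_bed(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_exonic_gene_lengths(path: str | Path) -> dict[str, int]:
    """Collapsed-model gene lengths: union of exon bases per gene from a GTF."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    exons = df[df["Feature"] == "exon"]
    lengths: dict[str, int] = {}
    for gene_id, sub in exons.groupby("gene_id"):
        ivs = sorted(zip(sub["Start"], sub["End"]))
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        lengths[str(gene_id)] = int(total)
    return lengths


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def read_covariates(path: str | Path) -> CovariateMatrix:
    """Read a sample-by-covariate TSV; categorical columns are expanded to
    k-1 indicator columns, zero-variance columns dropped with a warning."""
    df = pd.read_csv(path, sep="\t")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df.loc[df[id_col].duplicated(), id_col].iloc[0]
        raise ValueError(f"duplicate sample id: {dup}")
    samples = [str(s) for s in df[id_col]]
    cols, names = [], []
    for col in df.columns[1:]:
        series = df[col]
        if pd.api.types.is_numeric_dtype(series):
            if series.isna().any():
                raise ValueError(f"missing value in numeric covariate {col!r}")
            values = series.to_numpy(dtype=float)[:, None]
            labels = [col]
        else:
            dummies = pd.get_dummies(series, prefix=col, drop_first=True)
            values = dummies.to_numpy(dtype=float)
            labels = list(dummies.columns)
        for j, lab in enumerate(labels):
            v = values[:, j]
            if len(v) > 1 and v.var() == 0:
                logger.warning("dropping zero-variance covariate %r", lab)
                continue
            cols.append(v)
            names.append(str(lab))
    values = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    cm = CovariateMatrix(samples, names, values)
    cm.validate()
    return cm


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def align_samples(genotype: GenotypeMatrix,
                  methylation: MethylationTable,
                  expression,
                  covariates: CovariateMatrix,
                  genes: list[GeneModel] | None = None) -> HarmonizedBundle:
    """Restrict every table to the shared samples, identically ordered.

    Order follows the genotype matrix. The intersection must leave enough
    samples to identify the full regression (intercept + genotype +
    methylation term + global covariates).
    """
    tables = {
        "genotype": list(genotype.samples),
        "methylation": list(methylation.samples),
        "expression": list(expression.samples),
        "covariates": list(covariates.samples),
    }
    shared = [s for s in tables["genotype"]
              if all(s in ids for ids in tables.values())]
    for name, ids in tables.items():
        dropped = sorted(set(ids) - set(shared))
        if dropped:
            logger.info("align_samples: dropped %d sample(s) from %s: %s",
                        len(dropped), name, ",".join(dropped))
    min_n = 3 + covariates.n_covariates + 2
    if len(shared) < min_n:
        raise ValueError(
            f"sample intersection has {len(shared)} samples; at least "
            f"{min_n} required for an identifiable model")
    return HarmonizedBundle(
        genotype=genotype.subset_samples(shared),
        methylation=methylation.subset_samples(shared),
        expression=expression.subset_samples(shared),
        covariates=covariates.subset_samples(shared),
        genes=list(genes) if genes else [],
    )


# ---------------------------------------------------------------------------
# GWAS catalog and LD resources
# ---------------------------------------------------------------------------

def default_category_map() -> dict[str, str]:
    """Trait-to-category mapping shipped with the package."""
    with resources.files("methqtl.data").joinpath("trait_categories.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["trait"], df["category"]))


def read_gwas_resources(catalog_path: str | Path,
                        ld_path: str | Path | None,
                        p_threshold: float = 5e-8,
                        r2_threshold: float = 0.8,
                        category_map: dict[str, str] | str | Path | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load genome-wide-significant GWAS associations and an LD pair table.

    The catalog must carry ``SNPS``, ``P-VALUE`` and ``DISEASE/TRAIT``
    columns (NHGRI-EBI dialect). Traits are bucketed into ontology
    categories through ``category_map`` (dict, or TSV path with columns
    trait/category); with no map the trait string is used as the category
    verbatim. Traits missing from a supplied map are kept with category
    "uncategorized" and a warning. Associations with p >= ``p_threshold``
    and LD pairs with r2 <= ``r2_threshold`` are discarded.
    """
    cat = pd.read_csv(catalog_path, sep="\t")
    colmap = {}
    for want in ("SNPS", "P-VALUE", "DISEASE/TRAIT"):
        found = [c for c in cat.columns if c.upper() == want]
        if not found:
            raise ValueError(f"GWAS catalog missing column {want!r}")
        colmap[want] = found[0]
    gwas = pd.DataFrame({
        "rsid": cat[colmap["SNPS"]].astype(str),
        "trait": cat[colmap["DISEASE/TRAIT"]].astype(str),
        "pvalue": pd.to_numeric(cat[colmap["P-VALUE"]], errors="coerce"),
    })
    gwas = gwas[gwas["pvalue"] < p_threshold].reset_index(drop=True)

    if isinstance(category_map, (str, Path)):
        cm = pd.read_csv(category_map, sep="\t")
        category_map = dict(zip(cm["trait"], cm["category"]))
    if category_map is None:
        gwas["category"] = gwas["trait"]
    else:
        cats = gwas["trait"].map(category_map)
        n_miss = int(cats.isna().sum())
        if n_miss:
            logger.warning("%d GWAS trait(s) without a category; kept as "
                           "'uncategorized'", n_miss)
        gwas["category"] = cats.fillna("uncategorized")

    if ld_path is None:
        ld = pd.DataFrame(columns=["rsid_a", "rsid_b", "r2"])
    else:
        ld = pd.read_csv(ld_path, sep="\t")
        for c in ("rsid_a", "rsid_b", "r2"):
            if c not in ld.columns:
                raise ValueError(f"LD table missing column {c!r}")
        if ((ld["r2"] < 0) | (ld["r2"] > 1)).any():
            raise ValueError("LD r2 values must lie in [0, 1]")
        ld = ld[ld["r2"] > r2_threshold].reset_index(drop=True)
    return gwas, ld


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table with enough digits to round-trip exactly."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
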