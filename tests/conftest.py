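import numpy as np
import pandas as pd
import pytest

from methqtl.io_formats import (CovariateMatrix, GenotypeMatrix,
                                MethylationTable)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    "##contig=<ID=2>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
)


def write_vcf(path, records, samples=("S1", "S2", "S3"), fmt="GT"):
    """records: list of (chrom, pos, rsid, ref, alt, [calls...])."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, rsid, ref, alt, calls in records:
            fh.write(f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\t"
                     f"{fmt}\t" + "\t".join(calls) + "\n")
    return path


def make_genotypes(dosage, positions=None, chrom="1", samples=None):
    dosage = np.asarray(dosage, dtype=float)
    n_snps, n_samples = dosage.shape
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n_snps)]
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_samples)]
    snps = pd.DataFrame({
        "rsid": [f"rs{i + 1}" for i in range(n_snps)],
        "chrom": chrom, "pos": positions, "ref": "A", "alt": "G"})
    return GenotypeMatrix(snps, list(samples), dosage)


def make_methylation(positions, beta, chrom="1", samples=None):
    beta = np.asarray(beta, dtype=float)
    if samples is None:
        samples = [f"S{i + 1}" for i in range(beta.shape[1])]
    cpgs = pd.DataFrame({
        "cpg_id": [f"cg{i + 1}" for i in range(len(positions))],
        "chrom": chrom, "pos": positions})
    return MethylationTable(cpgs, list(samples), beta).sort()


def make_covariates(values, samples=None, names=None):
    values = np.asarray(values, dtype=float)
    if samples is None:
        samples = [f"S{i + 1}" for i in range(values.shape[0])]
    if names is None:
        names = [f"c{i + 1}" for i in range(values.shape[1])]
    return CovariateMatrix(list(samples), list(names), values)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition bundle (53 samples) shared across tests."""
    from methqtl.synthetic_data import SimulationConfig, simulate_bundle
    return simulate_bundle(SimulationConfig(seed=11))
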