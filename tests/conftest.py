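import numpy as np
import pandas as pd
import pytest

from gccscan.io_gwas import PhenoTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_pheno_frame(n_mz=0, n_dz=0, n_singletons=0, seed=0) -> pd.DataFrame:
    """Small phenotype table with valid twin structure."""
    r = np.random.default_rng(seed)
    rows = []
    fam = 0
    for zyg, count, size in (("MZ", n_mz, 2), ("DZ", n_dz, 2), ("singleton", n_singletons, 1)):
        for _ in range(count):
            age = float(r.uniform(40, 80))
            for k in range(size):
                rows.append(
                    {
                        "sample_id": f"f{fam}_{k}",
                        "phenotype": float(r.standard_normal()),
                        "age": age,
                        "sex": "male" if r.integers(2) else "female",
                        "family_id": f"f{fam}",
                        "zygosity": zyg,
                    }
                )
            fam += 1
    return pd.DataFrame(rows)


@pytest.fixture
def pheno_small() -> PhenoTable:
    return PhenoTable(make_pheno_frame(n_mz=2, n_dz=3, n_singletons=2, seed=1))


VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, records, samples=("s1", "s2", "s3")):
    """records: list of (chrom, pos, vid, ref, alt, info_str, fmt, calls)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(samples="\t".join(samples)))
        for chrom, pos, vid, ref, alt, info, fmt, calls in records:
            fh.write(
                "\t".join([chrom, str(pos), vid, ref, alt, ".", "PASS", info, fmt] + list(calls))
                + "\n"
            )
    return path
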