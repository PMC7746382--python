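"""Genotype, phenotype, and result I/O plus post-imputation variant filters.

Dosages are expected alternate-allele counts in [0, 2] (VCF ``DS`` convention);
coordinates are 1-based inclusive throughout. Variant filtering implements the
standard post-imputation thresholds: minor allele frequency at least 5% and an
imputation INFO score above 0.6 (hard-typed variants with no INFO value pass
the INFO filter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError, ParseError, SchemaError

__all__ = [
    "SnpMeta",
    "DosageMatrix",
    "PhenoTable",
    "AssocResult",
    "read_dosage_vcf",
    "read_dosage_matrix",
    "filter_variants",
    "read_pheno",
    "write_assoc",
    "read_assoc",
]

VALID_SEX = {"male", "female"}
VALID_ZYGOSITY = {"MZ", "DZ", "singleton"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpMeta:
    """Per-SNP metadata. ``maf`` is the minor allele frequency in [0, 0.5];
    ``info`` is the imputation quality metric in [0, 1], or None for
    hard-typed variants."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float
    info: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise IntegrityError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise IntegrityError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")
        if self.info is not None and not (0.0 <= self.info <= 1.0 + 1e-12):
            raise IntegrityError(f"{self.snp_id}: info {self.info} outside [0, 1]")


def _maf_from_dosages(col: np.ndarray) -> float:
    """MAF = min(freq, 1 - freq) with freq = mean(dosage)/2 over non-missing."""
    m = np.nanmean(col) / 2.0 if np.any(np.isfinite(col)) else 0.0
    return float(min(m, 1.0 - m))


@dataclass
class DosageMatrix:
    """samples x snps dosage matrix; missing entries are NaN."""

    samples: list[str]
    snps: list[SnpMeta]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.snps)):
            raise IntegrityError(
                f"dosage matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate snp_id in DosageMatrix")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2.0 + 1e-9):
            raise IntegrityError("dosage values must lie in [0, 2] or be missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snp_ids().index(snp_id)
        return self.values[:, j]

    def subset_snps(self, keep: Sequence[int]) -> "DosageMatrix":
        keep = list(keep)
        return DosageMatrix(
            samples=list(self.samples),
            snps=[self.snps[j] for j in keep],
            values=self.values[:, keep].copy(),
        )

    def subset_samples(self, keep: Sequence[int]) -> "DosageMatrix":
        keep = list(keep)
        return DosageMatrix(
            samples=[self.samples[i] for i in keep],
            snps=list(self.snps),
            values=self.values[keep, :].copy(),
        )


PHENO_COLUMNS = ["sample_id", "phenotype", "age", "sex", "family_id", "zygosity"]


@dataclass
class PhenoTable:
    """Per-sample phenotype and covariates with twin family structure.

    Required columns: sample_id, phenotype, age, sex (male/female),
    family_id, zygosity (MZ/DZ/singleton). Families group at most two
    samples and zygosity is constant within a family.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"phenotype table missing columns: {missing}")
        df = self.data.reset_index(drop=True).copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["family_id"] = df["family_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise IntegrityError(f"duplicate sample_id: {dup!r}")
        bad_sex = set(df["sex"].dropna().unique()) - VALID_SEX
        if bad_sex:
            raise IntegrityError(f"invalid sex values: {sorted(bad_sex)}")
        bad_zyg = set(df["zygosity"].dropna().unique()) - VALID_ZYGOSITY
        if bad_zyg:
            raise IntegrityError(f"invalid zygosity values: {sorted(bad_zyg)}")
        grouped = df.groupby("family_id", sort=False)
        sizes = grouped.size()
        if (sizes > 2).any():
            fam = sizes[sizes > 2].index[0]
            raise IntegrityError(f"family {fam!r} has {sizes[fam]} members (max 2)")
        nzyg = grouped["zygosity"].nunique()
        if (nzyg > 1).any():
            fam = nzyg[nzyg > 1].index[0]
            raise IntegrityError(f"family {fam!r} has inconsistent zygosity")
        self.data = df

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def phenotype(self) -> np.ndarray:
        return self.data["phenotype"].to_numpy(dtype=float)

    @property
    def family_ids(self) -> np.ndarray:
        return self.data["family_id"].to_numpy()

    @property
    def zygosity(self) -> np.ndarray:
        return self.data["zygosity"].to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "PhenoTable":
        idx = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return PhenoTable(idx[PHENO_COLUMNS + [c for c in idx.columns if c not in PHENO_COLUMNS]])


@dataclass
class AssocResult:
    """One SNP under one model. beta/se are present only for the directional
    linear models; the GCC association strength A has no direction."""

    snp_id: str
    model: str
    statistic: float
    pvalue: float
    n_used: int
    beta: Optional[float] = None
    se: Optional[float] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise IntegrityError(
                f"{self.snp_id}/{self.model}: pvalue {self.pvalue} outside (0, 1]"
            )
        if self.model == "gcc" and (self.beta is not None or self.se is not None):
            raise IntegrityError("GCC results carry no beta/se (A has no direction)")
        if self.model in ("kinship", "lme") and (self.beta is None or self.se is None):
            raise IntegrityError(f"{self.model} results require beta and se")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_dosage_vcf(
    path: str,
    dosage_field: str = "DS",
    fallback_to_genotype: bool = False,
) -> DosageMatrix:
    """Read per-sample dosages from a VCF.

    Dosages come from the named FORMAT field (``DS`` by default). When the
    field is absent and ``fallback_to_genotype`` is set, hard genotype calls
    are converted to allele counts. Missing entries become NaN. The per-SNP
    INFO score is taken from the ``INFO`` key of the INFO column when present.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise ParseError(f"cannot open VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    metas: list[SnpMeta] = []
    columns: list[np.ndarray] = []
    for i, var in enumerate(vcf):
        try:
            dos = _variant_dosages(var, dosage_field, fallback_to_genotype, len(samples))
        except SchemaError:
            raise
        except Exception as exc:
            raise ParseError(f"malformed VCF record at variant #{i + 1} "
                             f"({var.CHROM}:{var.POS}): {exc}") from exc
        info_val = var.INFO.get("INFO")
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        metas.append(
            SnpMeta(
                snp_id=snp_id,
                chrom=str(var.CHROM),
                pos=int(var.POS),
                ref_allele=var.REF,
                alt_allele=var.ALT[0] if var.ALT else ".",
                maf=_maf_from_dosages(dos),
                info=float(info_val) if info_val is not None else None,
            )
        )
        columns.append(dos)

    values = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return DosageMatrix(samples=samples, snps=metas, values=values)


def _variant_dosages(var, dosage_field: str, fallback: bool, n_samples: int) -> np.ndarray:
    fmt = None
    try:
        fmt = var.format(dosage_field)
    except KeyError:
        fmt = None
    if fmt is not None:
        dos = np.asarray(fmt, dtype=float).reshape(n_samples, -1)[:, 0]
        dos = dos.copy()
        dos[~np.isfinite(dos)] = np.nan
        dos[dos < -1] = np.nan  # htslib missing-value sentinel
        return dos
    if not fallback:
        raise SchemaError(
            f"FORMAT field {dosage_field!r} absent at {var.CHROM}:{var.POS} "
            "and genotype fallback disabled"
        )
    # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
    gt = np.asarray(var.gt_types)
    dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
    return dos.astype(float)


def read_dosage_matrix(path: str, sep: str = "\t") -> DosageMatrix:
    """Read a delimited dosage table: header of SNP ids, first column sample
    id, numeric body. MAF is computed from column means (mean dosage / 2)."""
    try:
        df = pd.read_csv(path, sep=sep, dtype={0: str})
    except Exception as exc:
        raise ParseError(f"cannot read dosage matrix {path!r}: {exc}") from exc
    if df.shape[1] < 2:
        raise SchemaError("dosage matrix needs a sample-id column plus >=1 SNP column")
    sample_col = df.columns[0]
    samples = df[sample_col].astype(str).tolist()
    body = df.drop(columns=[sample_col])
    values = np.empty((len(samples), body.shape[1]))
    for j, col in enumerate(body.columns):
        numeric = pd.to_numeric(body[col], errors="coerce")
        bad = numeric.isna() & body[col].notna() & (body[col].astype(str).str.strip() != "")
        bad &= ~body[col].astype(str).str.strip().isin([".", "NA", "nan"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric dosage at row {row + 2}, column {col!r}: "
                f"{body[col].iloc[row]!r}"
            )
        values[:, j] = numeric.to_numpy(dtype=float)
    metas = [
        SnpMeta(
            snp_id=str(col), chrom="0", pos=j + 1, ref_allele="N", alt_allele="N",
            maf=_maf_from_dosages(values[:, j]),
        )
        for j, col in enumerate(body.columns)
    ]
    return DosageMatrix(samples=samples, snps=metas, values=values)


def filter_variants(
    dm: DosageMatrix, maf_min: float = 0.05, info_min: float = 0.6
) -> DosageMatrix:
    """Keep SNPs with maf >= maf_min and INFO > info_min (missing INFO passes).

    Idempotent; preserves SNP order.
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= info_min <= 1.0):
        raise ConfigError(
            f"thresholds must lie in [0, 1]: maf_min={maf_min}, info_min={info_min}"
        )
    keep = [
        j
        for j, s in enumerate(dm.snps)
        if s.maf >= maf_min and (s.info is None or s.info > info_min)
    ]
    return dm.subset_snps(keep)


def read_pheno(path: str, sep: str = "\t") -> PhenoTable:
    """Read a delimited phenotype/covariate table with the required columns."""
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise ParseError(f"cannot read phenotype table {path!r}: {exc}") from exc
    return PhenoTable(df)


ASSOC_COLUMNS = ["snp_id", "chrom", "pos", "model", "statistic", "beta", "se", "pvalue", "n_used"]


def write_assoc(results: Sequence[AssocResult], path: str) -> None:
    """Write association results as a tab-delimited table (fixed column order,
    12 significant digits, NA for absent beta/se)."""

    def fmt(v) -> str:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "NA"
        if isinstance(v, float):
            return f"{v:.12g}"
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(ASSOC_COLUMNS) + "\n")
        for r in results:
            row = [r.snp_id, r.chrom if r.chrom is not None else "NA",
                   r.pos if r.pos is not None else "NA", r.model,
                   fmt(r.statistic), fmt(r.beta), fmt(r.se), fmt(r.pvalue), r.n_used]
            fh.write("\t".join(str(fmt(v)) if isinstance(v, float) else str(v) for v in row) + "\n")


def read_assoc(path: str) -> list[AssocResult]:
    """Read back an association table written by :func:`write_assoc`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"association table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            AssocResult(
                snp_id=str(row["snp_id"]),
                model=str(row["model"]),
                statistic=float(row["statistic"]),
                pvalue=float(row["pvalue"]),
                n_used=int(row["n_used"]),
                beta=None if pd.isna(row["beta"]) else float(row["beta"]),
                se=None if pd.isna(row["se"]) else float(row["se"]),
                chrom=None if pd.isna(row["chrom"]) else str(row["chrom"]),
                pos=None if pd.isna(row["pos"]) else int(row["pos"]),
            )
        )
    return out
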