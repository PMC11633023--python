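"""Case-control genotype data: container, GAMETES-style I/O, and QC filters.

A dataset is a samples-by-SNPs matrix of genotype codes (0 = homozygous
major allele, 1 = heterozygous, 2 = homozygous minor allele) together with
a binary phenotype vector (0 = control, 1 = case).  Missing genotypes are
held as the in-memory sentinel ``MISSING`` (-1) and written to disk as the
token ``NA``; they are only permitted before quality control.

All user-facing SNP indices in this package are 1-based, matching the
search space [1, n] used by the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import DataError, EmptyAfterQCError

MISSING = -1
MISSING_TOKEN = "NA"

_SEPARATORS = {"gametes_tsv": "\t", "csv": ","}
_VALID_GENOTYPE_TOKENS = {"0", "1", "2", MISSING_TOKEN}


@dataclass
class GenotypeDataset:
    """Genotype matrix plus binary phenotype for m samples and n SNPs."""

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise DataError("genotype matrix must be two-dimensional")
        m, n = self.genotypes.shape
        if m < 1:
            raise DataError("dataset needs at least one sample")
        if n < 2:
            raise DataError("dataset needs at least two SNPs")
        if self.phenotype.shape != (m,):
            raise DataError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{m} samples"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"invalid genotype code {self.genotypes[i, j]} at sample "
                f"{i + 1}, SNP {j + 1} (expected 0/1/2 or missing)"
            )
        if not np.isin(self.phenotype, (0, 1)).all():
            i = int(np.flatnonzero(~np.isin(self.phenotype, (0, 1)))[0])
            raise DataError(
                f"invalid phenotype {self.phenotype[i]} at sample {i + 1} "
                "(expected 0 = control, 1 = case)"
            )
        if self.snp_ids is None:
            self.snp_ids = [f"SNP{j + 1}" for j in range(n)]
        else:
            self.snp_ids = [str(s) for s in self.snp_ids]
            if len(self.snp_ids) != n:
                raise DataError(
                    f"{len(self.snp_ids)} SNP ids for {n} genotype columns"
                )

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.genotypes == MISSING).any())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
            and self.snp_ids == other.snp_ids
        )


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control cut-offs, defaulting to common GWAS practice.

    Samples with a genotype missing rate >= ``sample_missing_max`` are
    dropped; SNPs are dropped when their missing rate >= ``snp_missing_max``,
    their Hardy-Weinberg equilibrium p-value in controls is below
    ``hwe_p_min``, or their minor allele frequency is below ``maf_min``.
    """

    sample_missing_max: float = 0.02
    snp_missing_max: float = 0.05
    hwe_p_min: float = 1e-4
    maf_min: float = 0.1

    def __post_init__(self) -> None:
        for name in ("sample_missing_max", "snp_missing_max", "hwe_p_min",
                     "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class QCRemoval:
    """One removed sample or SNP, with the reason it failed."""

    kind: str          # "sample" or "snp"
    label: str
    reason: str
    value: float


def read_dataset(path: str | Path, dialect: str = "gametes_tsv") -> GenotypeDataset:
    """Read a GAMETES-style table: SNP columns then a final class column."""
    sep = _separator(dialect)
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed table in {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise DataError(
            f"{path}: need at least two SNP columns plus a class column"
        )
    raw = df.to_numpy(dtype=object)
    empty = pd.isna(raw) | (raw == "")
    if empty.any():
        i, j = np.argwhere(empty)[0]
        raise DataError(
            f"{path}: short row {i + 1} (missing field in column "
            f"{df.columns[j]!r})"
        )
    geno_tokens = raw[:, :-1]
    bad = ~np.isin(geno_tokens.astype(str), list(_VALID_GENOTYPE_TOKENS))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"{path}: invalid genotype {geno_tokens[i, j]!r} at row {i + 1}, "
            f"column {df.columns[j]!r} (expected 0/1/2 or {MISSING_TOKEN})"
        )
    class_tokens = raw[:, -1].astype(str)
    if not np.isin(class_tokens, ("0", "1")).all():
        i = int(np.flatnonzero(~np.isin(class_tokens, ("0", "1")))[0])
        raise DataError(
            f"{path}: non-binary class {class_tokens[i]!r} at row {i + 1}"
        )
    genotypes = np.where(
        geno_tokens.astype(str) == MISSING_TOKEN, MISSING, geno_tokens
    ).astype(np.int64)
    phenotype = class_tokens.astype(np.int64)
    return GenotypeDataset(genotypes, phenotype, list(df.columns[:-1]))


def write_dataset(
    ds: GenotypeDataset, path: str | Path, dialect: str = "gametes_tsv"
) -> Path:
    """Write ``ds`` as a header + one-row-per-sample delimited text file."""
    sep = _separator(dialect)
    path = Path(path)
    tokens = ds.genotypes.astype(object)
    tokens[ds.genotypes == MISSING] = MISSING_TOKEN
    df = pd.DataFrame(tokens, columns=ds.snp_ids)
    df["Class"] = ds.phenotype
    df.to_csv(path, sep=sep, index=False)
    return path


def _separator(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown dialect {dialect!r}; choose from {sorted(_SEPARATORS)}"
        ) from None


def hwe_test(genotype_counts: Sequence[int]) -> tuple[float, float]:
    """Chi-square (1 df) goodness-of-fit test for Hardy-Weinberg equilibrium.

    ``genotype_counts`` is the (hom-major, het, hom-minor) count triple.
    Monomorphic SNPs (estimated allele frequency 0 or 1) return p = 1 by
    convention.
    """
    n0, n1, n2 = (int(c) for c in genotype_counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    total = n0 + n1 + n2
    if total == 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n2 + n1) / (2 * total)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = total * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    observed = np.array([n0, n1, n2], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


def minor_allele_frequency(column: np.ndarray) -> float:
    """MAF of one genotype column (missing entries must be removed first)."""
    column = np.asarray(column)
    if column.size == 0:
        return 0.0
    p = float((2 * (column == 2).sum() + (column == 1).sum()) / (2 * column.size))
    return min(p, 1.0 - p)


def _major_genotype(column: np.ndarray) -> int:
    """Homozygote of the more frequent allele (0, or 2 if coding is flipped)."""
    observed = column[column != MISSING]
    if observed.size == 0:
        return 0
    p = (2 * (observed == 2).sum() + (observed == 1).sum()) / (2 * observed.size)
    return 2 if p > 0.5 else 0


def qc_filter(
    ds: GenotypeDataset, thr: QCThresholds | None = None
) -> tuple[GenotypeDataset, list[QCRemoval]]:
    """Apply sample-then-SNP quality control and impute residual missingness.

    Samples are removed first (missing rate >= ``sample_missing_max``).
    SNP-level statistics are then computed on the surviving samples with
    missing genotypes counted as the major-allele homozygote -- i.e. on the
    column exactly as it will look after imputation -- so the filter is
    idempotent and every retained SNP verifiably satisfies the thresholds.
    HWE is tested in controls only.  Remaining missing genotypes are imputed
    to the per-SNP major-allele genotype.
    """
    thr = thr or QCThresholds()
    report: list[QCRemoval] = []

    miss_rate = (ds.genotypes == MISSING).mean(axis=1)
    keep_samples = miss_rate < thr.sample_missing_max
    for i in np.flatnonzero(~keep_samples):
        report.append(QCRemoval(
            "sample", f"sample{i + 1}",
            f"missing rate >= {thr.sample_missing_max}", float(miss_rate[i]),
        ))
    if not keep_samples.any():
        raise EmptyAfterQCError("all samples removed by QC")

    gt = ds.genotypes[keep_samples]
    phen = ds.phenotype[keep_samples]
    controls = phen == 0

    keep_snps = np.ones(ds.n_snps, dtype=bool)
    imputed = gt.copy()
    for j in range(ds.n_snps):
        col = gt[:, j]
        snp_miss = float((col == MISSING).mean())
        if snp_miss >= thr.snp_missing_max:
            keep_snps[j] = False
            report.append(QCRemoval(
                "snp", ds.snp_ids[j],
                f"missing rate >= {thr.snp_missing_max}", snp_miss))
            continue
        filled = np.where(col == MISSING, _major_genotype(col), col)
        imputed[:, j] = filled
        ctrl = filled[controls]
        if ctrl.size:
            counts = ((ctrl == 0).sum(), (ctrl == 1).sum(), (ctrl == 2).sum())
            _, p_hwe = hwe_test(counts)
            if p_hwe < thr.hwe_p_min:
                keep_snps[j] = False
                report.append(QCRemoval(
                    "snp", ds.snp_ids[j],
                    f"HWE p in controls < {thr.hwe_p_min}", p_hwe))
                continue
        maf = minor_allele_frequency(filled)
        if maf < thr.maf_min:
            keep_snps[j] = False
            report.append(QCRemoval(
                "snp", ds.snp_ids[j], f"MAF < {thr.maf_min}", maf))

    if keep_snps.sum() < 2:
        raise EmptyAfterQCError(
            f"only {int(keep_snps.sum())} SNP(s) remain after QC"
        )
    filtered = GenotypeDataset(
        imputed[:, keep_snps],
        phen,
        [s for s, k in zip(ds.snp_ids, keep_snps) if k],
    )
    return filtered, report
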