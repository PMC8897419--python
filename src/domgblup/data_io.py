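"""Genotype and phenotype I/O, filtering and fixed-effect correction.

Genotypes are held as integer allele-dosage codes: 0, 1, 2 count copies of
the second (A2) allele; ``MISSING`` (-1) marks an unobserved genotype.
Phenotypes are corrected for categorical fixed effects by ordinary least
squares before any genetic analysis; downstream modules only ever see the
corrected values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfoundingError,
    DataError,
    DimensionError,
    EmptyDataError,
    FormatError,
)

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype code.
MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """n individuals x m loci of biallelic genotype codes.

    ``codes[i, j]`` counts copies of the A2 allele of locus ``j`` carried by
    individual ``i`` (0/1/2), or :data:`MISSING`.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    codes: np.ndarray
    allele_labels: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, m = self.codes.shape
        if len(self.individual_ids) != n or len(self.locus_ids) != m:
            raise DimensionError("id lists do not match code matrix shape")
        if n < 2:
            raise DataError(f"need at least 2 individuals, got {n}")
        if m < 1:
            raise EmptyDataError("no loci")
        if len(set(self.individual_ids)) != n:
            raise DataError("duplicate individual identifiers")
        if len(set(self.locus_ids)) != m:
            raise DataError("duplicate locus identifiers")
        bad = set(np.unique(self.codes)) - _VALID_CODES
        if bad:
            raise DataError(f"invalid genotype codes: {sorted(bad)}")
        if self.allele_labels is not None and len(self.allele_labels) != m:
            raise DimensionError("allele_labels length does not match locus count")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {ind: i for i, ind in enumerate(self.individual_ids)}
        try:
            rows = [index[i] for i in ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise DataError(f"unknown individual id {exc.args[0]!r}") from exc
        return GenotypeMatrix(
            list(ids), list(self.locus_ids), self.codes[rows], self.allele_labels
        )


@dataclass
class PhenotypeTable:
    """Raw trait values plus categorical covariates, keyed by individual id."""

    individual_ids: list[str]
    trait_values: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.trait_values = np.asarray(self.trait_values, dtype=float)
        n = len(self.individual_ids)
        if self.trait_values.shape != (n,):
            raise DimensionError("trait_values length does not match individual_ids")
        if len(set(self.individual_ids)) != n:
            raise DataError("duplicate individual identifiers in phenotypes")
        if np.all(np.isnan(self.trait_values)):
            raise DataError("no non-missing trait values")
        if len(self.covariates) not in (0, n):
            raise DimensionError("covariate table length does not match individuals")
        observed = ~np.isnan(self.trait_values)
        for col in self.covariates.columns:
            vals = self.covariates[col].to_numpy()[observed]
            if any(pd.isna(v) or str(v) == "" for v in vals):
                raise DataError(f"missing covariate {col!r} for a phenotyped individual")


@dataclass
class CorrectedPhenotypes:
    """Trait values with fixed effects removed (grand mean retained)."""

    individual_ids: list[str]
    values: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.individual_ids),):
            raise DimensionError("values length does not match individual_ids")

    def subset(self, ids: Sequence[str]) -> "CorrectedPhenotypes":
        index = {ind: i for i, ind in enumerate(self.individual_ids)}
        rows = [index[i] for i in ids]
        return CorrectedPhenotypes(list(ids), self.values[rows], self.trait_name)


@dataclass
class AlleleFrequencies:
    """Per-locus frequency of the allele whose homozygote is coded 2."""

    locus_ids: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.locus_ids),):
            raise DimensionError("p length does not match locus_ids")
        ok = np.isnan(self.p) | ((self.p >= 0.0) & (self.p <= 1.0))
        if not np.all(ok):
            raise DataError("allele frequencies outside [0, 1]")

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p


# ---------------------------------------------------------------------------
# genotype reading / writing
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read biallelic SNP genotypes as 0/1/2 codes of the A2 allele.

    Parameters
    ----------
    path:
        Input file.
    format:
        One of ``vcf``, ``plink_raw`` (PLINK ``--recode A`` text output) or
        ``tsv`` (internal dialect: header of locus ids, one row per
        individual, entries 0/1/2/NA).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_raw":
        return _read_plink_raw(path)
    if format == "tsv":
        return _read_tsv(path)
    raise FormatError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise FormatError("cyvcf2 is required for VCF input") from exc
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    locus_ids: list[str] = []
    labels: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            col[i] = MISSING if (a < 0 or b < 0) else a + b
        columns.append(col)
        locus_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        labels.append((var.REF, var.ALT[0]))
    if skipped:
        logger.info("skipped %d non-biallelic/non-SNP sites in %s", skipped, path)
    if not columns:
        raise EmptyDataError(f"no usable biallelic SNP sites in {path}")
    return GenotypeMatrix(samples, locus_ids, np.column_stack(columns), labels)


def _read_plink_raw(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:
        raise FormatError(f"cannot parse PLINK .raw file {path}: {exc}") from exc
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if "IID" not in df.columns:
        raise FormatError(f"{path} lacks an IID column (is it PLINK --recode A output?)")
    snp_cols = [c for c in df.columns if c not in meta]
    if not snp_cols:
        raise EmptyDataError(f"no SNP columns in {path}")
    codes = df[snp_cols].to_numpy(dtype=float)
    out = np.full(codes.shape, MISSING, dtype=np.int8)
    ok = ~np.isnan(codes)
    vals = codes[ok]
    if not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
        raise FormatError(f"non-0/1/2 dosage values in {path}")
    out[ok] = vals.astype(np.int8)
    # strip the trailing _<allele> PLINK appends to SNP names
    locus_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    if len(set(locus_ids)) != len(locus_ids):
        locus_ids = snp_cols
    return GenotypeMatrix(df["IID"].astype(str).tolist(), locus_ids, out)


def _read_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse genotype TSV {path}: {exc}") from exc
    if df.shape[1] < 1:
        raise EmptyDataError(f"no locus columns in {path}")
    raw = df.to_numpy()
    out = np.full(raw.shape, MISSING, dtype=np.int8)
    for val, code in (("0", 0), ("1", 1), ("2", 2)):
        out[raw == val] = code
    known = np.isin(raw, ("0", "1", "2", "NA", "nan")) | pd.isna(raw)
    if not known.all():
        bad = raw[~known][0]
        raise FormatError(f"unrecognised genotype entry {bad!r} in {path}")
    return GenotypeMatrix(
        df.index.astype(str).tolist(), [str(c) for c in df.columns], out
    )


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the internal TSV dialect (round-trips exactly)."""
    strings = g.codes.astype(object)
    df = pd.DataFrame(strings, index=g.individual_ids, columns=g.locus_ids)
    df = df.replace(MISSING, "NA")
    df.index.name = "id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# frequencies / filtering / imputation
# ---------------------------------------------------------------------------


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    """p_i = mean non-missing code at locus i divided by 2; NaN if all missing."""
    codes = g.codes.astype(float)
    codes[g.codes == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(codes, axis=0) / 2.0
    n_undefined = int(np.isnan(p).sum())
    if n_undefined:
        logger.warning("%d loci have no non-missing genotypes (p undefined)", n_undefined)
    return AlleleFrequencies(list(g.locus_ids), p)


def filter_maf(
    g: GenotypeMatrix, threshold: float, freqs: AlleleFrequencies | None = None
) -> tuple[GenotypeMatrix, int]:
    """Drop loci with minor allele frequency strictly below ``threshold``.

    The boundary is inclusive: a locus with MAF exactly equal to the
    threshold is retained.  Returns the filtered matrix and the number of
    loci removed.
    """
    if not 0.0 <= threshold <= 0.5:
        raise DataError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    if freqs is None:
        freqs = allele_frequencies(g)
    maf = np.minimum(freqs.p, 1.0 - freqs.p)
    keep = maf >= threshold  # NaN compares False: all-missing loci are dropped too
    n_removed = int((~keep).sum())
    if not keep.any():
        raise EmptyDataError("MAF filter removed every locus")
    if n_removed:
        logger.info("MAF filter removed %d of %d loci", n_removed, g.m)
    out = GenotypeMatrix(
        list(g.individual_ids),
        [lid for lid, k in zip(g.locus_ids, keep) if k],
        g.codes[:, keep],
        [al for al, k in zip(g.allele_labels, keep) if k] if g.allele_labels else None,
    )
    return out, n_removed


def impute_missing(g: GenotypeMatrix, freqs: AlleleFrequencies) -> np.ndarray:
    """Replace missing codes with the locus mean code 2*p_i (float output)."""
    if list(freqs.locus_ids) != list(g.locus_ids):
        raise DimensionError("allele frequencies are not aligned with genotype loci")
    out = g.codes.astype(float)
    miss = g.codes == MISSING
    if miss.any():
        fill = np.broadcast_to(2.0 * freqs.p, out.shape)
        out[miss] = fill[miss]
    return out


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(
    path: str | Path,
    trait: str,
    id_column: str = "id",
    covariates: Iterable[str] = (),
) -> PhenotypeTable:
    """Read a CSV/TSV phenotype table (delimiter sniffed from the extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise FormatError(f"cannot parse phenotype table {path}: {exc}") from exc
    for col in [id_column, trait, *covariates]:
        if col not in df.columns:
            raise DataError(f"phenotype table {path} lacks column {col!r}")
    cov = df[list(covariates)].astype(str) if covariates else pd.DataFrame()
    return PhenotypeTable(
        df[id_column].astype(str).tolist(),
        pd.to_numeric(df[trait], errors="coerce").to_numpy(),
        cov.reset_index(drop=True),
        trait_name=trait,
    )


def design_matrix(
    covariates: pd.DataFrame, covariate_names: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded dummies, lexicographically first level as
    reference for each factor."""
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names: list[str] = ["intercept"]
    for name in covariate_names:
        if name not in covariates.columns:
            raise DataError(f"unknown covariate {name!r}")
        levels = sorted(map(str, pd.unique(covariates[name].astype(str))))
        for level in levels[1:]:
            cols.append((covariates[name].astype(str) == level).to_numpy(float))
            names.append(f"{name}[{level}]")
    return np.column_stack(cols), names


def correct_fixed_effects(
    ph: PhenotypeTable, covariate_names: Sequence[str] = ()
) -> CorrectedPhenotypes:
    """OLS-remove categorical fixed effects; keep the grand mean.

    Returns ``y - X @ beta_hat + mean(y)`` over the phenotyped (non-missing
    trait) records only.  Raises :class:`ConfoundingError` when the dummy
    design is rank deficient after dropping one reference level per factor.
    """
    observed = ~np.isnan(ph.trait_values)
    ids = [i for i, ok in zip(ph.individual_ids, observed) if ok]
    y = ph.trait_values[observed]
    if not covariate_names:
        return CorrectedPhenotypes(ids, y.copy(), ph.trait_name)
    cov = ph.covariates.loc[observed].reset_index(drop=True)
    X, names = design_matrix(cov, covariate_names)
    # QR-based alias detection: near-zero diagonal of R flags dependent columns
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    aliased = [names[j] for j in range(X.shape[1]) if diag[j] <= tol]
    if aliased:
        raise ConfoundingError(aliased)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    corrected = y - X @ beta + y.mean()
    return CorrectedPhenotypes(ids, corrected, ph.trait_name)


def write_phenotypes_csv(ph: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame({"id": ph.individual_ids, ph.trait_name: ph.trait_values})
    for col in ph.covariates.columns:
        df[col] = ph.covariates[col].to_numpy()
    df.to_csv(path, index=False)


def align_genotyped_phenotyped(
    g: GenotypeMatrix, y: CorrectedPhenotypes
) -> CorrectedPhenotypes:
    """Drop phenotyped individuals without genotypes (with a warning)."""
    genotyped = set(g.individual_ids)
    keep = [i for i in y.individual_ids if i in genotyped]
    dropped = len(y.individual_ids) - len(keep)
    if dropped:
        logger.warning("dropping %d phenotyped individuals without genotypes", dropped)
    if not keep:
        raise EmptyDataError("no individual is both genotyped and phenotyped")
    return y.subset(keep)
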