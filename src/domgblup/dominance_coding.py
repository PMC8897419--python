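"""Locus-specific dominance degrees and the weighted genotype coding.

For each locus the degree of dominance is estimated from the mean corrected
phenotypes of the three genotype classes:

    x_min = min(mean_00, mean_11)
    x_max = max(mean_00, mean_11)
    raw_d = 2 * (mean_het - x_min) / (x_max - x_min)

The heterozygote is then re-coded with the clipped weight C_d (default
bounds [0, 2]: from no dominance up to complete dominance; wider bounds
admit overdominance).  When the homozygote means are reversed
(mean_00 > mean_11) the homozygote codes 0 and 2 are swapped so that code 2
always tags the favourable homozygote in the estimation data.

Loci where the degree cannot be estimated (a genotype class below
``min_class_count``, or homozygote means equal to within tolerance) fall
back to the plain additive code C_d = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import MISSING, CorrectedPhenotypes, GenotypeMatrix
from .errors import DataError, DimensionError

#: relative spread below which homozygote means are considered tied
DEGENERATE_SPREAD_REL = 1e-12


@dataclass
class GenotypeClassMeans:
    """Per-locus mean corrected phenotype and count of each genotype class.

    ``means``/``counts`` are (m, 3) arrays for codes 0, 1, 2; a class with
    count 0 has mean NaN.  ``n_subset`` records how many individuals the
    means were computed over.
    """

    locus_ids: list[str]
    means: np.ndarray
    counts: np.ndarray
    n_subset: int

    def __post_init__(self) -> None:
        m = len(self.locus_ids)
        self.means = np.asarray(self.means, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.means.shape != (m, 3) or self.counts.shape != (m, 3):
            raise DimensionError("means/counts must be (m, 3)")
        if (self.counts < 0).any():
            raise DataError("negative class count")


@dataclass
class DominanceCoding:
    """Per-locus dominance weight and homozygote orientation.

    ``raw_d`` is NaN for fallback loci.  Invariants: ``lower <= c_d <= upper``;
    ``fallback`` implies ``c_d == 1`` and ``flip == False``.
    """

    locus_ids: list[str]
    raw_d: np.ndarray
    c_d: np.ndarray
    flip: np.ndarray
    fallback: np.ndarray
    bounds: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        m = len(self.locus_ids)
        self.raw_d = np.asarray(self.raw_d, dtype=float)
        self.c_d = np.asarray(self.c_d, dtype=float)
        self.flip = np.asarray(self.flip, dtype=bool)
        self.fallback = np.asarray(self.fallback, dtype=bool)
        for arr in (self.raw_d, self.c_d, self.flip, self.fallback):
            if arr.shape != (m,):
                raise DimensionError("coding arrays must have one entry per locus")
        lo, hi = self.bounds
        if ((self.c_d < lo - 1e-12) | (self.c_d > hi + 1e-12)).any():
            raise DataError("C_d outside clipping bounds")
        if (self.c_d[self.fallback] != 1.0).any() or self.flip[self.fallback].any():
            raise DataError("fallback loci must have C_d == 1 and flip == False")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "raw_d": self.raw_d,
                "c_d": self.c_d,
                "flip": self.flip,
                "fallback": self.fallback,
            }
        )

    def to_tsv(self, path: str | Path, class_counts: np.ndarray | None = None) -> None:
        df = self.to_frame()
        if class_counts is not None:
            df["count_00"] = class_counts[:, 0]
            df["count_01"] = class_counts[:, 1]
            df["count_11"] = class_counts[:, 2]
        df.to_csv(path, sep="\t", index=False)


def genotype_class_means(
    g: GenotypeMatrix,
    y: CorrectedPhenotypes,
    subset: set[str] | list[str] | None = None,
) -> GenotypeClassMeans:
    """Mean corrected phenotype per genotype class, over ``subset`` only.

    ``subset`` defaults to all individuals that are both genotyped and
    phenotyped; it must contain at least two such individuals.  Missing
    genotypes never contribute (only observed 0/1/2 codes are classed).
    """
    pheno_index = {ind: i for i, ind in enumerate(y.individual_ids)}
    if subset is None:
        subset = set(y.individual_ids)
    else:
        subset = set(subset)
    rows, yvals = [], []
    for i, ind in enumerate(g.individual_ids):
        if ind in subset and ind in pheno_index:
            rows.append(i)
            yvals.append(y.values[pheno_index[ind]])
    if len(rows) < 2:
        raise DataError("need >= 2 genotyped+phenotyped individuals in subset")
    codes = g.codes[rows]
    yv = np.asarray(yvals, dtype=float)
    means = np.full((g.m, 3), np.nan)
    counts = np.zeros((g.m, 3), dtype=int)
    for c in (0, 1, 2):
        mask = codes == c
        counts[:, c] = mask.sum(axis=0)
        sums = yv @ mask
        with np.errstate(invalid="ignore"):
            means[:, c] = np.where(counts[:, c] > 0, sums / counts[:, c], np.nan)
    return GenotypeClassMeans(list(g.locus_ids), means, counts, len(rows))


def estimate_dominance(
    class_means: GenotypeClassMeans,
    min_class_count: int | float = 3,
    bounds: tuple[float, float] = (0.0, 2.0),
) -> DominanceCoding:
    """Per-locus degree of dominance with clipping, flips, and fallbacks."""
    lo, hi = bounds
    if not lo <= 1.0 <= hi:
        raise DataError("bounds must bracket 1 so the additive fallback is legal")
    means, counts = class_means.means, class_means.counts
    m = means.shape[0]

    mean00, mean01, mean11 = means[:, 0], means[:, 1], means[:, 2]
    x_min = np.fmin(mean00, mean11)
    x_max = np.fmax(mean00, mean11)
    spread = x_max - x_min
    defined = np.isfinite(mean00) & np.isfinite(mean01) & np.isfinite(mean11)
    scale = np.nanstd(means[defined]) if defined.any() else 1.0
    if not np.isfinite(scale) or scale == 0.0:
        scale = 1.0
    fallback = (
        (counts < min_class_count).any(axis=1)
        | ~defined
        | (spread < DEGENERATE_SPREAD_REL * scale)
    )

    raw_d = np.full(m, np.nan)
    ok = ~fallback
    raw_d[ok] = 2.0 * (mean01[ok] - x_min[ok]) / spread[ok]
    c_d = np.ones(m)
    c_d[ok] = np.clip(raw_d[ok], lo, hi)
    flip = np.zeros(m, dtype=bool)
    flip[ok] = mean00[ok] > mean11[ok]
    return DominanceCoding(list(class_means.locus_ids), raw_d, c_d, flip, fallback, bounds)


def apply_coding(g: GenotypeMatrix, coding: DominanceCoding) -> np.ndarray:
    """Re-code genotypes as 0 / C_d / 2 (flipped loci swap 0 and 2).

    Missing entries are filled with the column mean of the coded column,
    consistent with mean imputation of the raw codes.
    """
    if list(coding.locus_ids) != list(g.locus_ids):
        raise DimensionError("dominance coding is not aligned with genotype loci")
    out = g.codes.astype(float)
    miss = g.codes == MISSING
    out[miss] = np.nan
    out[:, coding.flip] = 2.0 - out[:, coding.flip]
    het = g.codes == 1
    out[het] = np.broadcast_to(coding.c_d, out.shape)[het]
    if miss.any():
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(out, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, coding.c_d)
        out[miss] = np.broadcast_to(col_mean, out.shape)[miss]
    return out
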