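"""Genomic relationship matrices: additive G, dominance D, and the combined
additive-dominance matrix built from the weighted genotype coding.

All three share the construction `scaled cross-product of a column-coded
marker matrix`:

* additive G: codes 0/1/2 centred by 2 p_i, scaled by sum 2 p_i (1 - p_i);
* dominance D: heterozygosity codes (-2 p_i^2, 2 p_i q_i, -2 q_i^2) scaled
  by sum (2 p_i q_i)^2, with p_i the frequency of the allele coded 2;
* combined G_ad: weighted codes 0 / C_d / 2 (post flip), centred by 2 p_i of
  the allele coded 2 *after* flipping, with the additive scaling constant.

Centring uses the frequency of the coded-2 allele.  The source text
nominally centres by the frequency of allele 1 while coding A2A2 as 2;
taken literally that destroys the zero-mean property centring exists for,
so the literal variant is only available via ``centering="literal_a1"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, LinAlgError

from .data_io import AlleleFrequencies, GenotypeMatrix, impute_missing
from .errors import ConditioningError, DataError, DimensionError

KINDS = ("G_additive", "D_dominance", "G_ad_combined")


@dataclass
class RelationshipMatrix:
    """Symmetric n x n genomic relationship matrix."""

    kind: str
    values: np.ndarray
    individual_ids: list[str]
    denominator: float
    ridge_added: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.kind not in KINDS:
            raise DataError(f"unknown relationship kind {self.kind!r}")
        if self.values.shape != (n, n):
            raise DimensionError("matrix shape does not match individual count")
        if not np.isfinite(self.values).all():
            raise DataError("non-finite relationship entries")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise DataError("relationship matrix is not symmetric")
        if not self.denominator > 0:
            raise DataError("non-positive scaling denominator")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def indices_of(self, ids) -> np.ndarray:
        index = {ind: i for i, ind in enumerate(self.individual_ids)}
        try:
            return np.array([index[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise DataError(f"individual {exc.args[0]!r} absent from matrix") from exc

    def to_text(self, path: str | Path) -> None:
        """ids header then the lower triangle, row per individual."""
        with open(path, "w") as fh:
            fh.write("# kind=%s denominator=%.17g ridge=%.17g\n"
                     % (self.kind, self.denominator, self.ridge_added))
            fh.write("\t".join(self.individual_ids) + "\n")
            for i in range(self.n):
                fh.write("\t".join("%.17g" % v for v in self.values[i, : i + 1]) + "\n")


def _cross_product(coded: np.ndarray, denominator: float, kind: str,
                   ids: list[str], meta: dict) -> RelationshipMatrix:
    if denominator <= 0:
        raise DataError(f"zero scaling denominator for {kind} (all loci monomorphic?)")
    values = coded @ coded.T / denominator
    values = (values + values.T) / 2.0  # kill asymmetric rounding
    return RelationshipMatrix(kind, values, ids, denominator, meta=meta)


def build_combined_Gad(
    coded: np.ndarray,
    freqs: AlleleFrequencies,
    individual_ids: list[str],
    flip: np.ndarray | None = None,
    centering: str = "coded2",
) -> RelationshipMatrix:
    """Combined additive-dominance matrix from a 0 / C_d / 2 coded matrix.

    ``coded`` must already be post-flip and post-weighting (the output of
    :func:`domgblup.dominance_coding.apply_coding`).  ``flip`` marks loci
    whose homozygote codes were swapped, so that centring can use the
    frequency of the allele coded 2 after flipping.
    """
    coded = np.asarray(coded, dtype=float)
    n, m = coded.shape
    if len(individual_ids) != n:
        raise DimensionError("individual_ids length does not match coded rows")
    if freqs.p.shape != (m,):
        raise DimensionError("allele frequencies not aligned with coded columns")
    p = freqs.p
    if flip is None:
        flip = np.zeros(m, dtype=bool)
    if centering == "coded2":
        p_centre = np.where(flip, 1.0 - p, p)
    elif centering == "literal_a1":
        p_centre = np.where(flip, p, 1.0 - p)
    else:
        raise DataError(f"unknown centering mode {centering!r}")
    denominator = float(np.sum(2.0 * p * (1.0 - p)))
    M = coded - 2.0 * p_centre
    return _cross_product(
        M, denominator, "G_ad_combined", list(individual_ids),
        {"centering": centering, "n_flipped": int(flip.sum())},
    )


def build_additive_G(
    g: GenotypeMatrix, freqs: AlleleFrequencies, centering: str = "coded2"
) -> RelationshipMatrix:
    """VanRaden-style additive matrix from 0/1/2 codes (mean-imputed)."""
    coded = impute_missing(g, freqs)
    out = build_combined_Gad(coded, freqs, list(g.individual_ids), centering=centering)
    return RelationshipMatrix(
        "G_additive", out.values, out.individual_ids, out.denominator, meta=out.meta
    )


def build_dominance_D(g: GenotypeMatrix, freqs: AlleleFrequencies) -> RelationshipMatrix:
    """Dominance matrix from heterozygosity codes, scaled by sum (2pq)^2."""
    if list(freqs.locus_ids) != list(g.locus_ids):
        raise DimensionError("allele frequencies are not aligned with genotype loci")
    p, q = freqs.p, 1.0 - freqs.p
    denominator = float(np.sum((2.0 * p * q) ** 2))
    coef = np.stack([-2.0 * p**2, 2.0 * p * q, -2.0 * q**2])  # codes 0,1,2
    H = np.empty(g.codes.shape, dtype=float)
    for c in (0, 1, 2):
        mask = g.codes == c
        H[mask] = np.broadcast_to(coef[c], H.shape)[mask]
    miss = g.codes == -1
    if miss.any():
        with np.errstate(invalid="ignore"):
            H[miss] = np.nan
            col_mean = np.nanmean(H, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        H[miss] = np.broadcast_to(col_mean, H.shape)[miss]
    return _cross_product(H, denominator, "D_dominance", list(g.individual_ids), {})


def ensure_invertible(
    R: RelationshipMatrix, ridge_start: float = 1e-8, ridge_max: float = 1e-2
) -> RelationshipMatrix:
    """Smallest diagonal ridge from {0, r0, 10 r0, ...} making Cholesky succeed."""
    ridge = 0.0
    while True:
        try:
            cho_factor(R.values + ridge * np.eye(R.n), lower=True)
            break
        except LinAlgError:
            ridge = ridge_start if ridge == 0.0 else ridge * 10.0
            if ridge > ridge_max:
                raise ConditioningError(
                    f"{R.kind} not factorisable even with ridge {ridge:.0e}; "
                    "data likely degenerate"
                )
    if ridge == 0.0:
        return R
    return RelationshipMatrix(
        R.kind,
        R.values + ridge * np.eye(R.n),
        list(R.individual_ids),
        R.denominator,
        ridge_added=R.ridge_added + ridge,
        meta=dict(R.meta),
    )
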