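"""Synthetic genotypes and traits with controllable per-locus dominance.

Genotypes are drawn under Hardy-Weinberg proportions at independent loci
(an optional first-order latent correlation between adjacent loci is
available for robustness experiments).  Each QTL j contributes
``a_j * v`` where ``v`` is 0, ``delta_j`` or 2 for the three genotype
classes — the same 0 / delta / 2 value scale the weighted coding estimates
— so a simulated ``delta_j`` is directly comparable to an estimated
heterozygote weight.  Residual variance is solved analytically from the
realised genetic variance to hit a target broad-sense heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_io import GenotypeMatrix, PhenotypeTable
from .errors import DataError

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_dataset",
    "scenario_presets",
]


@dataclass(frozen=True)
class SimulationScenario:
    n_individuals: int = 500
    n_loci: int = 1000
    n_qtl: int = 50
    maf_range: tuple[float, float] = (0.01, 0.5)
    qtl_effect_sd: float = 1.0
    #: ((degree, fraction), ...) — exact counts: floor for all but the last
    dominance_mix: tuple[tuple[float, float], ...] = ((1.0, 1.0),)
    target_h2_broad: float = 0.5
    fixed_effects: Mapping[str, Mapping[str, float]] | None = None
    ld_rho: float = 0.0
    hidden_qtl: bool = False
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_h2_broad < 1.0:
            raise DataError("target_h2_broad must be in (0, 1)")
        if self.n_qtl > self.n_loci:
            raise DataError("n_qtl cannot exceed n_loci")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise DataError("maf_range must lie within (0, 0.5]")
        if abs(sum(f for _, f in self.dominance_mix) - 1.0) > 1e-9:
            raise DataError("dominance_mix fractions must sum to 1")
        if not 0.0 <= self.ld_rho < 1.0:
            raise DataError("ld_rho must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise DataError("missing_rate must be in [0, 1)")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: pd.DataFrame  # locus_id, a, delta
    genetic_values: np.ndarray
    var_genetic: float
    var_residual: float
    scenario: SimulationScenario = field(repr=False, default=None)

    @property
    def realized_h2(self) -> float:
        vp = float(np.var(self.phenotypes.trait_values, ddof=1))
        return self.var_genetic / vp if vp > 0 else np.nan


def _haplotypes(rng: np.random.Generator, n: int, p: np.ndarray, rho: float) -> np.ndarray:
    """One allele (0/1) per individual x locus; AR(1) latent-normal LD."""
    m = len(p)
    if rho == 0.0:
        return (rng.random((n, m)) < p).astype(np.int8)
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    innov = rng.standard_normal((n, m - 1)) * np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    return (z < norm.ppf(p)).astype(np.int8)


def simulate_genotypes(
    scenario: SimulationScenario, rng: np.random.Generator
) -> tuple[GenotypeMatrix, np.ndarray]:
    """HWE genotypes; returns the matrix and the true allele frequencies."""
    n, m = scenario.n_individuals, scenario.n_loci
    p = rng.uniform(*scenario.maf_range, size=m)
    codes = _haplotypes(rng, n, p, scenario.ld_rho) + _haplotypes(
        rng, n, p, scenario.ld_rho
    )
    codes = codes.astype(np.int8)
    if scenario.missing_rate > 0:
        mask = rng.random(codes.shape) < scenario.missing_rate
        codes[mask] = -1
    ids = [f"ind{i:05d}" for i in range(n)]
    loci = [f"snp{j:05d}" for j in range(m)]
    return GenotypeMatrix(ids, loci, codes), p


def _dominance_degrees(scenario: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    """Exact per-degree counts: floor(fraction * n_qtl) for all but the last
    mixture entry, remainder to the last; positions shuffled."""
    nq = scenario.n_qtl
    deltas = np.empty(nq)
    used = 0
    mix = scenario.dominance_mix
    for i, (deg, frac) in enumerate(mix):
        count = nq - used if i == len(mix) - 1 else int(np.floor(frac * nq))
        deltas[used : used + count] = deg
        used += count
    rng.shuffle(deltas)
    return deltas


def simulate_trait(
    g: GenotypeMatrix, scenario: SimulationScenario, rng: np.random.Generator
) -> SimulatedDataset:
    """Attach a trait with per-QTL additive effects and dominance degrees."""
    n, m = g.n, g.m
    qtl = np.sort(rng.choice(m, size=scenario.n_qtl, replace=False))
    a = rng.normal(0.0, scenario.qtl_effect_sd, size=scenario.n_qtl)
    deltas = _dominance_degrees(scenario, rng)

    codes = g.codes[:, qtl].astype(float)
    codes[g.codes[:, qtl] == -1] = np.nan
    values = np.where(codes == 1, deltas, codes)
    values = np.nan_to_num(values, nan=0.0)  # missing QTL genotypes contribute 0
    gvals = values @ a

    var_g = float(np.var(gvals, ddof=1))
    if var_g <= 0:
        raise DataError("degenerate scenario: zero realised genetic variance")
    h2 = scenario.target_h2_broad
    var_e = var_g * (1.0 - h2) / h2
    y = gvals + rng.normal(0.0, np.sqrt(var_e), size=n)

    cov = pd.DataFrame(index=range(n))
    if scenario.fixed_effects:
        for factor, level_effects in scenario.fixed_effects.items():
            levels = sorted(level_effects)
            assigned = rng.choice(levels, size=n)
            cov[factor] = assigned
            y = y + np.array([level_effects[l] for l in assigned])

    truth = pd.DataFrame(
        {"locus_id": [g.locus_ids[j] for j in qtl], "a": a, "delta": deltas}
    )
    geno_out = g
    if scenario.hidden_qtl:
        keep = np.setdiff1d(np.arange(m), qtl)
        geno_out = GenotypeMatrix(
            list(g.individual_ids),
            [g.locus_ids[j] for j in keep],
            g.codes[:, keep],
            [g.allele_labels[j] for j in keep] if g.allele_labels else None,
        )
    phen = PhenotypeTable(list(g.individual_ids), y, cov, trait_name="trait")
    return SimulatedDataset(geno_out, phen, truth, gvals, var_g, var_e, scenario)


def simulate_dataset(scenario: SimulationScenario, seed: int) -> SimulatedDataset:
    """Genotypes + trait from a single seed (deterministic)."""
    rng = np.random.default_rng(seed)
    g, _ = simulate_genotypes(scenario, rng)
    return simulate_trait(g, scenario, rng)


def scenario_presets() -> dict[str, SimulationScenario]:
    """Named regimes spanning purely additive to dominance-rich traits."""
    return {
        "additive": SimulationScenario(
            n_individuals=1000, n_loci=2000, n_qtl=50,
            dominance_mix=((1.0, 1.0),), target_h2_broad=0.5,
        ),
        "mixed_dominance": SimulationScenario(
            n_individuals=1000, n_loci=2000, n_qtl=20,
            maf_range=(0.2, 0.5),
            dominance_mix=((2.0, 0.5), (0.0, 0.5)), target_h2_broad=0.3,
        ),
        "low_h2_dominant": SimulationScenario(
            n_individuals=1000, n_loci=2000, n_qtl=10,
            maf_range=(0.3, 0.5),
            dominance_mix=((2.0, 1.0),), target_h2_broad=0.15,
        ),
        "null": SimulationScenario(
            n_individuals=1000, n_loci=2000, n_qtl=50,
            dominance_mix=((1.0, 1.0),), target_h2_broad=0.01,
        ),
    }


def preset(name: str, **overrides) -> SimulationScenario:
    presets = scenario_presets()
    if name not in presets:
        raise DataError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return replace(presets[name], **overrides) if overrides else presets[name]
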