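"""k-fold cross-validation of the three model shapes and model comparison.

The weighted-heterozygote model re-estimates its per-locus dominance
weights, and rebuilds its combined relationship matrix, inside every
training fold — validation phenotypes never touch any training-stage
quantity.  The additive and two-component models reuse dataset-level
matrices (genotypes are never masked, only phenotypes).

Predictive ability is the Pearson correlation between predicted total
genetic values and held-out corrected phenotypes, per fold by default.
Model differences are tested by paired bootstrap over validation
individuals with Bonferroni adjustment, and summarised as compact letter
groups (models sharing a letter do not differ at the adjusted level).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    AlleleFrequencies,
    CorrectedPhenotypes,
    GenotypeMatrix,
    allele_frequencies,
)
from .dominance_coding import apply_coding, estimate_dominance, genotype_class_means
from .errors import DataError, DimensionError, NumericalError
from .relationship_matrices import (
    build_additive_G,
    build_combined_Gad,
    build_dominance_D,
)
from .reml_blup import ModelSpec, gblup_predict, reml_fit

logger = logging.getLogger(__name__)

MODELS = ("CADM", "AM", "ADM")


@dataclass
class CVConfig:
    """Knobs for cross-validation runs."""

    min_class_count: int | float = 3
    cd_bounds: tuple[float, float] = (0.0, 2.0)
    train_only_frequencies: bool = False
    centering: str = "coded2"
    reml_max_iter: int = 200
    reml_tol: float = 1e-8
    em_warmup: int = 3
    # the direct V^-1 route avoids inverting near-singular relationship
    # matrices inside every fold; it matches the MME route to solver precision
    predict_method: str = "direct"
    pooling: str = "fold"  # or "replicate"
    n_boot: int = 10_000
    alpha: float = 0.01
    bootstrap_seed: int = 0


@dataclass
class FoldPlan:
    replicate: int
    seed: int
    folds: list[list[str]]

    def __post_init__(self) -> None:
        all_ids = list(itertools.chain.from_iterable(self.folds))
        if len(all_ids) != len(set(all_ids)):
            raise DataError("folds are not disjoint")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise DataError("fold sizes differ by more than 1")


@dataclass
class FoldRecord:
    model: str
    replicate: int
    fold: int
    r: float
    b: float
    val_ids: list[str]
    pred: np.ndarray
    y_val: np.ndarray
    converged: bool = True
    excluded: bool = False


@dataclass
class ComparisonResult:
    pvalues: dict[tuple[str, str], float]
    pvalues_adjusted: dict[tuple[str, str], float]
    letters: dict[str, str]
    alpha: float
    n_boot: int


@dataclass
class CVResult:
    records: list[FoldRecord]
    models: list[str]
    k: int
    replicates: int
    seed: int
    n_excluded_folds: int = 0
    comparison: ComparisonResult | None = None
    config: CVConfig = field(default_factory=CVConfig)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": rec.model,
                    "replicate": rec.replicate,
                    "fold": rec.fold,
                    "r": rec.r,
                    "b": rec.b,
                    "converged": rec.converged,
                    "excluded": rec.excluded,
                }
                for rec in self.records
            ]
        )

    def fold_values(self, model: str, what: str = "r") -> np.ndarray:
        vals = [
            getattr(rec, what)
            for rec in self.records
            if rec.model == model and not rec.excluded
        ]
        return np.asarray(vals, dtype=float)

    def aggregate(self) -> pd.DataFrame:
        rows = []
        for model in self.models:
            recs = [
                rec for rec in self.records if rec.model == model and not rec.excluded
            ]
            b = np.array([rec.b for rec in recs])
            if self.config.pooling == "replicate":
                reps = sorted({rec.replicate for rec in recs})
                r = np.array(
                    [np.mean([x.r for x in recs if x.replicate == rep]) for rep in reps]
                )
            else:
                r = np.array([rec.r for rec in recs])
            se = r.std(ddof=1) / math.sqrt(len(r)) if len(r) > 1 else np.nan
            rows.append(
                {
                    "model": model,
                    "mean_r": r.mean(),
                    "se_r": se,
                    "mean_bias": b.mean(),
                    "n_folds": len(r),
                    "letter": self.comparison.letters.get(model, "")
                    if self.comparison
                    else "",
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


def make_folds(ids, k: int, replicate_seeds) -> list[FoldPlan]:
    """Per replicate, a uniformly random partition into k near-equal folds."""
    ids = list(ids)
    if k < 2:
        raise DataError("k must be >= 2")
    if k > len(ids):
        raise DataError(f"k={k} exceeds number of individuals ({len(ids)})")
    plans = []
    for rep, seed in enumerate(replicate_seeds):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(ids))
        base, extra = divmod(len(ids), k)
        folds, start = [], 0
        for f in range(k):
            size = base + (1 if f < extra else 0)
            folds.append([ids[i] for i in perm[start : start + size]])
            start += size
        plans.append(FoldPlan(rep, int(seed), folds))
    return plans


# ---------------------------------------------------------------------------
# per-fold metrics
# ---------------------------------------------------------------------------


def predictive_ability(pred: np.ndarray, y_val: np.ndarray) -> float:
    """Pearson correlation between predictions and held-out phenotypes."""
    pred = np.asarray(pred, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if len(pred) < 3:
        raise DataError("need >= 3 validation individuals")
    if np.std(pred) == 0:
        raise NumericalError("constant predictions: correlation undefined")
    return float(np.corrcoef(pred, y_val)[0, 1])


def prediction_bias(pred: np.ndarray, y_val: np.ndarray) -> float:
    """OLS slope of phenotype on prediction; 1 = dispersion-unbiased."""
    pred = np.asarray(pred, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    vx = np.var(pred)
    if vx == 0:
        raise NumericalError("zero-variance predictions: slope undefined")
    return float(np.cov(pred, y_val, ddof=0)[0, 1] / vx)


# ---------------------------------------------------------------------------
# the cross-validation loop
# ---------------------------------------------------------------------------


def run_cv(
    g: GenotypeMatrix,
    y: CorrectedPhenotypes,
    models=("CADM", "AM", "ADM"),
    k: int = 5,
    replicates: int = 10,
    seed: int = 0,
    config: CVConfig | None = None,
    compare: bool = True,
) -> CVResult:
    """Run the full CV protocol on identical fold plans for every model."""
    config = config or CVConfig()
    models = [m.upper() for m in models]
    unknown = set(models) - set(MODELS)
    if unknown:
        raise DataError(f"unknown models: {sorted(unknown)}")
    if not models:
        raise DataError("no models requested")

    genotyped = set(g.individual_ids)
    common = [i for i in y.individual_ids if i in genotyped]
    if len(common) < k:
        raise DataError("fewer genotyped+phenotyped individuals than folds")
    y = y.subset(common)

    freqs_all = allele_frequencies(g)
    G = D = None
    if "AM" in models or "ADM" in models:
        G = build_additive_G(g, freqs_all, centering=config.centering)
    if "ADM" in models:
        D = build_dominance_D(g, freqs_all)

    replicate_seeds = np.random.SeedSequence(seed).generate_state(replicates)
    plans = make_folds(common, k, replicate_seeds)

    records: list[FoldRecord] = []
    n_excluded = 0
    for plan in plans:
        for fold_idx, val_ids in enumerate(plan.folds):
            val_set = set(val_ids)
            train_ids = [i for i in common if i not in val_set]
            y_train = y.subset(train_ids)
            y_val = y.subset(val_ids)
            fold_records: list[FoldRecord] = []
            any_failed = False
            for model in models:
                spec = _model_spec(
                    model, g, freqs_all, G, D, y, train_ids, config
                )
                est = reml_fit(
                    y_train,
                    spec,
                    max_iter=config.reml_max_iter,
                    tol=config.reml_tol,
                    em_warmup=config.em_warmup,
                )
                rec = FoldRecord(
                    model, plan.replicate, fold_idx, np.nan, np.nan,
                    list(val_ids), np.empty(0), y_val.values, est.converged,
                )
                if est.converged:
                    try:
                        preds = gblup_predict(
                            y_train, spec, est, method=config.predict_method
                        )
                        pv = preds.subset_total(val_ids)
                        rec.pred = pv
                        rec.r = predictive_ability(pv, y_val.values)
                        rec.b = prediction_bias(pv, y_val.values)
                    except NumericalError as exc:
                        logger.warning(
                            "fold %d/%d %s failed: %s",
                            plan.replicate, fold_idx, model, exc,
                        )
                        rec.converged = False
                fold_records.append(rec)
                any_failed = any_failed or not rec.converged
            if any_failed:
                # listwise exclusion keeps the comparison fair
                n_excluded += 1
                for rec in fold_records:
                    rec.excluded = True
            records.extend(fold_records)

    result = CVResult(
        records, models, k, replicates, seed,
        n_excluded_folds=n_excluded, config=config,
    )
    if compare and len(models) >= 2:
        result.comparison = bootstrap_compare(
            result, n_boot=config.n_boot, alpha=config.alpha,
            seed=config.bootstrap_seed,
        )
    return result


def _model_spec(model, g, freqs_all, G, D, y, train_ids, config) -> ModelSpec:
    if model == "AM":
        return ModelSpec("AM", [G])
    if model == "ADM":
        return ModelSpec("ADM", [G, D], ["additive", "dominance"])
    # CADM: training-only class means -> weights -> per-fold matrix
    if config.train_only_frequencies:
        freqs = allele_frequencies(g.subset_individuals(train_ids))
        freqs = AlleleFrequencies(list(g.locus_ids), freqs.p)
    else:
        freqs = freqs_all
    class_means = genotype_class_means(g, y, subset=set(train_ids))
    coding = estimate_dominance(
        class_means, min_class_count=config.min_class_count, bounds=config.cd_bounds
    )
    coded = apply_coding(g, coding)
    Gad = build_combined_Gad(
        coded, freqs, list(g.individual_ids), flip=coding.flip,
        centering=config.centering,
    )
    return ModelSpec("CADM", [Gad])


# ---------------------------------------------------------------------------
# bootstrap comparison
# ---------------------------------------------------------------------------


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _pooled_by_replicate(result: CVResult, model: str):
    """Per replicate: (pred, y) pooled over that replicate's folds."""
    out = {}
    for rec in result.records:
        if rec.model != model or rec.excluded:
            continue
        out.setdefault(rec.replicate, ([], []))
        out[rec.replicate][0].append(rec.pred)
        out[rec.replicate][1].append(rec.y_val)
    return {
        rep: (np.concatenate(p), np.concatenate(yv)) for rep, (p, yv) in out.items()
    }


def bootstrap_compare(
    result: CVResult,
    n_boot: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
    chunk: int = 500,
) -> ComparisonResult:
    """Paired bootstrap of correlation differences, Bonferroni-adjusted.

    For each model pair, validation individuals are resampled with
    replacement (the same resample for both models), the correlation
    difference is computed per replicate from the replicate-pooled
    predictions and averaged across replicates; the two-sided p-value is
    ``2 * min(P(diff <= 0), P(diff >= 0))`` with the +1 finite-sample
    correction.
    """
    if len(result.models) < 2:
        raise DataError("need at least two models to compare")
    if n_boot < 100:
        logger.warning("n_boot=%d is very small; p-values will be coarse", n_boot)
    pooled = {m: _pooled_by_replicate(result, m) for m in result.models}
    reps = sorted(set.intersection(*(set(p) for p in pooled.values())))
    if not reps:
        raise DataError("no completed replicates to compare")
    for m in result.models:
        for rep in reps:
            if len(pooled[m][rep][1]) != len(pooled[result.models[0]][rep][1]):
                raise DataError("mismatched fold plans across models")

    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(result.models, 2))
    pvalues: dict[tuple[str, str], float] = {}
    for m1, m2 in pairs:
        diffs = np.zeros(n_boot)
        for rep in reps:
            p1, y1 = pooled[m1][rep]
            p2, _ = pooled[m2][rep]
            n = len(y1)
            for start in range(0, n_boot, chunk):
                stop = min(start + chunk, n_boot)
                idx = rng.integers(0, n, size=(stop - start, n))
                c1 = _rowwise_corr(p1[idx], y1[idx])
                c2 = _rowwise_corr(p2[idx], y1[idx])
                diffs[start:stop] += np.nan_to_num(c1 - c2)
        diffs /= len(reps)
        le = int(np.sum(diffs <= 0)) + 1
        ge = int(np.sum(diffs >= 0)) + 1
        pvalues[(m1, m2)] = min(1.0, 2.0 * min(le, ge) / (n_boot + 1))

    adj = {pair: min(1.0, p * len(pairs)) for pair, p in pvalues.items()}
    letters = _letter_groups(result, adj, alpha)
    return ComparisonResult(pvalues, adj, letters, alpha, n_boot)


def _letter_groups(result: CVResult, adj_p, alpha: float) -> dict[str, str]:
    """Compact letter display from the non-significance graph."""
    models = sorted(result.models, key=lambda m: -result.fold_values(m, "r").mean())
    differ = {
        frozenset(pair) for pair, p in adj_p.items() if p < alpha
    }
    # maximal cliques of mutually non-different models, greedy over ranking
    groups: list[list[str]] = []
    for m in models:
        placed = False
        for grp in groups:
            if all(frozenset((m, other)) not in differ for other in grp):
                grp.append(m)
                placed = True
        if not placed:
            groups.append([m])
    # drop groups fully contained in another
    groups = [
        g for i, g in enumerate(groups)
        if not any(set(g) < set(h) for j, h in enumerate(groups) if i != j)
    ]
    letters = {m: "" for m in models}
    for letter, grp in zip("ABCDEFGHIJKLMNOPQRSTUVWXYZ", groups):
        for m in grp:
            letters[m] += letter
    return letters
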