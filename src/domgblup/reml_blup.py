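"""Restricted maximum likelihood (average-information algorithm) and GBLUP.

The mixed model is ``y = 1*mu + sum_k Z u_k + e`` with ``u_k ~ N(0, R_k
sigma_k^2)`` for each genomic relationship matrix ``R_k`` and ``e ~ N(0, I
sigma_e^2)``.  One genetic component is used for the additive-only and the
combined additive-dominance models, two (additive + dominance) for the
two-component model.

``reml_fit`` maximises the restricted log-likelihood

    l = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ]        (constants omitted)

with a few EM warm-up steps followed by average-information updates,
step-halving whenever a step would decrease the log-likelihood, and
pinning of components that hit the lower bound (1e-8 of the phenotypic
variance).  Predictions solve Henderson's mixed-model equations; an
algebraically equivalent direct ``V^-1`` route is kept as an oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .data_io import CorrectedPhenotypes
from .errors import DataError, DimensionError, NumericalError
from .relationship_matrices import RelationshipMatrix, ensure_invertible

#: lower bound on a variance component, as a fraction of phenotypic variance
LOWER_BOUND_FRACTION = 1e-8

#: average-information matrix condition number above which the likelihood is
#: reported as flat (components not separately identifiable)
FLAT_AI_CONDITION = 1e8


@dataclass
class ModelSpec:
    """A model shape: ordered genetic relationship matrices + intercept."""

    name: str
    genetic_matrices: list[RelationshipMatrix]
    component_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids0 = None
        for R in self.genetic_matrices:
            if ids0 is None:
                ids0 = list(R.individual_ids)
            elif list(R.individual_ids) != ids0:
                raise DimensionError("genetic matrices must share individual ordering")
        if not self.component_names:
            self.component_names = [R.kind for R in self.genetic_matrices]

    @property
    def individual_ids(self) -> list[str]:
        if not self.genetic_matrices:
            return []
        return list(self.genetic_matrices[0].individual_ids)

    @property
    def n_components(self) -> int:
        return len(self.genetic_matrices)


@dataclass
class VarianceEstimates:
    """REML variance components (genetic components first, residual last)."""

    components: np.ndarray
    component_names: list[str]
    proportions: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    pinned: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    ai_condition: float = np.nan

    @property
    def residual(self) -> float:
        return float(self.components[-1])

    @property
    def phenotypic_variance(self) -> float:
        return float(self.components.sum())

    @property
    def flat_likelihood(self) -> bool:
        """True when components are not separately identifiable."""
        return bool(np.isfinite(self.ai_condition) and self.ai_condition > FLAT_AI_CONDITION)

    def report(self) -> dict:
        return {
            "components": {n: float(v) for n, v in zip(self.component_names, self.components)},
            "proportions": {n: float(v) for n, v in zip(self.component_names, self.proportions)},
            "loglik": float(self.loglik),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
            "pinned": {n: bool(v) for n, v in zip(self.component_names, self.pinned)},
            "flat_likelihood": self.flat_likelihood,
            "ai_condition": None if not np.isfinite(self.ai_condition) else float(self.ai_condition),
            "loglik_trace": [float(v) for v in self.loglik_trace],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.report(), indent=2))


@dataclass
class GeneticValuePredictions:
    """Predicted genetic effects for every individual in the matrices."""

    individual_ids: list[str]
    component_effects: np.ndarray  # (n, K)
    component_names: list[str]

    @property
    def total(self) -> np.ndarray:
        return self.component_effects.sum(axis=1)

    def subset_total(self, ids) -> np.ndarray:
        index = {ind: i for i, ind in enumerate(self.individual_ids)}
        try:
            rows = [index[i] for i in ids]
        except KeyError as exc:
            raise DataError(f"individual {exc.args[0]!r} absent from predictions") from exc
        return self.total[rows]


# ---------------------------------------------------------------------------
# likelihood workspaces
# ---------------------------------------------------------------------------


class _GeneralWorkspace:
    """Explicit-V quantities for any number of components."""

    def __init__(self, y: np.ndarray, R_tt: list[np.ndarray]):
        self.y = y
        self.n = len(y)
        self.X = np.ones((self.n, 1))
        self.R = list(R_tt) + [np.eye(self.n)]

    def _decompose(self, theta: np.ndarray):
        V = sum(t * R for t, R in zip(theta, self.R))
        c, low = linalg.cho_factor(V, lower=True)
        logdetV = 2.0 * np.log(np.diag(c)).sum()
        Vinv = linalg.cho_solve((c, low), np.eye(self.n))
        VinvX = Vinv @ self.X
        xtvx = (self.X.T @ VinvX).item()
        P = Vinv - VinvX @ VinvX.T / xtvx
        Py = P @ self.y
        ll = -0.5 * (logdetV + np.log(xtvx) + float(self.y @ Py))
        return ll, P, Py

    def loglik(self, theta: np.ndarray) -> float:
        try:
            return self._decompose(theta)[0]
        except linalg.LinAlgError as exc:
            raise NumericalError(f"V not positive definite: {exc}") from exc

    def quantities(self, theta: np.ndarray):
        ll, P, Py = self._decompose(theta)
        K = len(self.R)
        RPy = [R @ Py for R in self.R]
        score = np.empty(K)
        for k in range(K):
            score[k] = -0.5 * (np.sum(P * self.R[k]) - float(Py @ RPy[k]))
        PRPy = [P @ v for v in RPy]
        AI = np.empty((K, K))
        for k in range(K):
            for l in range(k, K):
                AI[k, l] = AI[l, k] = 0.5 * float(PRPy[k] @ RPy[l])
        return ll, score, AI


class _EigenWorkspace:
    """O(n) per-evaluation quantities for a single genetic matrix.

    V = s_g G + s_e I diagonalises in the eigenbasis of G, so every REML
    quantity reduces to sums over eigenvalues.
    """

    def __init__(self, y: np.ndarray, G_tt: np.ndarray):
        self.n = len(y)
        lam, U = linalg.eigh(G_tt)
        self.lam = lam
        self.yt = U.T @ y
        self.xt = U.T @ np.ones(self.n)

    def _core(self, theta: np.ndarray):
        d = theta[0] * self.lam + theta[1]
        if np.any(d <= 0):
            raise NumericalError("V not positive definite")
        xtvx = float(np.sum(self.xt**2 / d))
        beta = float(np.sum(self.xt * self.yt / d)) / xtvx
        py = (self.yt - self.xt * beta) / d
        ypy = float(np.sum(self.yt * py))
        ll = -0.5 * (np.log(d).sum() + np.log(xtvx) + ypy)
        return d, xtvx, py, ll

    def loglik(self, theta: np.ndarray) -> float:
        return self._core(theta)[3]

    def _apply_P(self, d, xtvx, v):
        w = v / d
        return w - (self.xt / d) * (float(np.sum(self.xt * w)) / xtvx)

    def quantities(self, theta: np.ndarray):
        d, xtvx, py, ll = self._core(theta)
        # tr(P R) = tr(V^-1 R) - x'V^-1 R V^-1 x / x'V^-1 x, R in {G, I}
        trPG = float(np.sum(self.lam / d) - np.sum(self.xt**2 * self.lam / d**2) / xtvx)
        trPI = float(np.sum(1.0 / d) - np.sum(self.xt**2 / d**2) / xtvx)
        Gpy = self.lam * py
        score = np.array(
            [
                -0.5 * (trPG - float(np.sum(py * Gpy))),
                -0.5 * (trPI - float(np.sum(py * py))),
            ]
        )
        PGpy = self._apply_P(d, xtvx, Gpy)
        PIpy = self._apply_P(d, xtvx, py)
        AI = 0.5 * np.array(
            [
                [float(Gpy @ PGpy), float(Gpy @ PIpy)],
                [float(Gpy @ PIpy), float(py @ PIpy)],
            ]
        )
        return ll, score, AI


def _training_view(y: CorrectedPhenotypes, spec: ModelSpec):
    yvals = np.asarray(y.values, dtype=float)
    if np.isnan(yvals).any():
        raise DataError("corrected phenotypes contain missing values")
    if spec.genetic_matrices:
        t = spec.genetic_matrices[0].indices_of(y.individual_ids)
        R_tt = [R.values[np.ix_(t, t)] for R in spec.genetic_matrices]
    else:
        R_tt = []
    return yvals, R_tt


def _make_workspace(yvals: np.ndarray, R_tt: list[np.ndarray]):
    if len(R_tt) == 1:
        return _EigenWorkspace(yvals, R_tt[0])
    return _GeneralWorkspace(yvals, R_tt)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def reml_loglik(
    y: CorrectedPhenotypes, spec: ModelSpec, components: np.ndarray
) -> float:
    """Restricted log-likelihood (constants omitted, consistent across calls).

    ``components`` holds one variance per genetic matrix followed by the
    residual variance.
    """
    components = np.asarray(components, dtype=float)
    if components.shape != (spec.n_components + 1,):
        raise DimensionError("expected one variance per genetic matrix plus residual")
    if (components < 0).any():
        raise DataError("negative variance component")
    yvals, R_tt = _training_view(y, spec)
    if not R_tt:
        n = len(yvals)
        s2 = components[0]
        rss = float(np.sum((yvals - yvals.mean()) ** 2))
        return -0.5 * ((n - 1) * np.log(s2) + np.log(n / s2) + np.log(s2) + rss / s2)
    return _make_workspace(yvals, R_tt).loglik(components)


def reml_fit(
    y: CorrectedPhenotypes,
    spec: ModelSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
    em_warmup: int = 3,
    start: np.ndarray | None = None,
) -> VarianceEstimates:
    """AI-REML with EM warm-up, step-halving and bound pinning."""
    yvals, R_tt = _training_view(y, spec)
    n = len(yvals)
    if n < 3:
        raise DataError("need at least 3 phenotyped individuals")
    vp = float(np.var(yvals, ddof=1))
    if vp <= 0:
        raise DataError("phenotypes have zero variance")
    names = list(spec.component_names) + ["residual"]

    if not R_tt:
        # residual-only model: exact closed form sigma^2 = RSS / (n - 1)
        s2 = float(np.sum((yvals - yvals.mean()) ** 2) / (n - 1))
        comp = np.array([s2])
        ll = reml_loglik(y, spec, comp)
        return VarianceEstimates(
            comp, names, comp / comp.sum(), ll, 0, True,
            np.zeros(1, dtype=bool), [ll], ai_condition=np.nan,
        )

    K = len(R_tt)
    lb = LOWER_BOUND_FRACTION * vp
    if start is not None:
        theta = np.asarray(start, dtype=float).copy()
        if theta.shape != (K + 1,):
            raise DimensionError("start must have one entry per component + residual")
    else:
        theta = np.array([0.5 * vp / K] * K + [0.5 * vp])
    theta = np.maximum(theta, lb)

    ws = _make_workspace(yvals, R_tt)
    ll = ws.loglik(theta)
    trace = [ll]
    pinned = np.zeros(K + 1, dtype=bool)
    converged = False
    ai_cond = np.nan
    it = 0
    for it in range(1, max_iter + 1):
        ll, score, AI = ws.quantities(theta)
        with np.errstate(all="ignore"):
            ai_cond = float(np.linalg.cond(AI))
        # release pinned components whose gradient points back inside
        pinned &= ~(score > 0)
        free = ~pinned

        delta = np.zeros(K + 1)
        use_em = it <= em_warmup
        if not use_em:
            A = AI[np.ix_(free, free)]
            try:
                step = linalg.solve(A, score[free], assume_a="sym")
                if not np.all(np.isfinite(step)):
                    raise linalg.LinAlgError("non-finite AI step")
                delta[free] = step
            except (linalg.LinAlgError, ValueError):
                use_em = True
        if use_em:
            delta[free] = 2.0 * theta[free] ** 2 * score[free] / n

        # step-halving: never accept a decrease in the log-likelihood
        new_ll = ll
        cand = theta
        frac = 1.0
        for _ in range(60):
            trial = np.maximum(theta + frac * delta, lb)
            trial[pinned] = lb
            try:
                trial_ll = ws.loglik(trial)
            except NumericalError:
                trial_ll = -np.inf
            if trial_ll >= ll - 1e-12:
                cand, new_ll = trial, trial_ll
                break
            frac *= 0.5

        pinned |= (cand <= lb * (1 + 1e-12)) & (score < 0)
        cand = np.maximum(cand, lb)
        cand[pinned] = lb

        rel_change = np.max(np.abs(cand - theta) / np.maximum(theta, lb))
        dll = new_ll - ll
        theta = cand
        trace.append(new_ll)
        if rel_change < tol or abs(dll) < 1e-9:
            converged = True
            break

    # pinned components are reported at the (tiny) bound, not exactly zero,
    # so downstream variance ratios stay defined; proportions print as 0.000
    theta_out = theta.copy()
    total = theta_out.sum()
    return VarianceEstimates(
        theta_out, names, theta_out / total, trace[-1], it, converged,
        pinned, trace, ai_condition=ai_cond,
    )


def gblup_predict(
    y_train: CorrectedPhenotypes,
    spec: ModelSpec,
    estimates: VarianceEstimates,
    predict_ids=None,
    method: str = "mme",
) -> GeneticValuePredictions:
    """BLUP of genetic effects for every individual in the matrices.

    ``method="mme"`` solves Henderson's mixed-model equations (requires
    invertible relationship matrices; a small ridge is added if needed);
    ``method="direct"`` uses the equivalent
    ``u_k = sigma_k^2 R_k[:, t] V_t^-1 (y - X beta)`` formula and never
    inverts the relationship matrices.
    """
    if not spec.genetic_matrices:
        raise DataError("model has no genetic component to predict")
    ids_all = spec.individual_ids
    n_all = len(ids_all)
    t = spec.genetic_matrices[0].indices_of(y_train.individual_ids)
    yt = np.asarray(y_train.values, dtype=float)
    comps = np.asarray(estimates.components, dtype=float)
    sig_e = comps[-1]
    if sig_e <= 0:
        raise NumericalError("non-positive residual variance")
    K = spec.n_components
    pinned = np.asarray(estimates.pinned, dtype=bool)
    active = [k for k in range(K) if not pinned[k]]

    effects = np.zeros((n_all, K))
    if active:
        if method == "mme":
            effects = _predict_mme(spec, comps, active, t, yt, effects)
        elif method == "direct":
            effects = _predict_direct(spec, comps, active, t, yt, effects)
        else:
            raise DataError(f"unknown prediction method {method!r}")

    preds = GeneticValuePredictions(ids_all, effects, list(spec.component_names))
    if predict_ids is not None:
        preds.subset_total(predict_ids)  # validates membership
    return preds


def _predict_mme(spec, comps, active, t, yt, effects):
    n_all = len(spec.individual_ids)
    nt = len(t)
    sig_e = comps[-1]
    A = len(active)
    size = 1 + A * n_all
    C = np.zeros((size, size))
    rhs = np.zeros(size)
    ztz = np.zeros(n_all)
    np.add.at(ztz, t, 1.0)
    zty = np.zeros(n_all)
    np.add.at(zty, t, yt)
    xtz = ztz  # intercept column of ones
    C[0, 0] = nt
    rhs[0] = yt.sum()
    for a, k in enumerate(active):
        r0 = 1 + a * n_all
        C[0, r0 : r0 + n_all] = xtz
        C[r0 : r0 + n_all, 0] = xtz
        rhs[r0 : r0 + n_all] = zty
        Rk = ensure_invertible(spec.genetic_matrices[k])
        cf = linalg.cho_factor(Rk.values, lower=True)
        Rinv = linalg.cho_solve(cf, np.eye(n_all))
        block = np.diag(ztz) + (sig_e / comps[k]) * Rinv
        C[r0 : r0 + n_all, r0 : r0 + n_all] = block
        for b, _ in enumerate(active):
            if b == a:
                continue
            c0 = 1 + b * n_all
            C[r0 : r0 + n_all, c0 : c0 + n_all] = np.diag(ztz)
    try:
        sol = linalg.solve(C, rhs, assume_a="sym")
    except linalg.LinAlgError as exc:
        raise NumericalError(f"singular mixed-model equations: {exc}") from exc
    for a, k in enumerate(active):
        effects[:, k] = sol[1 + a * n_all : 1 + (a + 1) * n_all]
    return effects


def _predict_direct(spec, comps, active, t, yt, effects):
    nt = len(t)
    sig_e = comps[-1]
    Vt = sig_e * np.eye(nt)
    for k in active:
        Vt += comps[k] * spec.genetic_matrices[k].values[np.ix_(t, t)]
    cf = linalg.cho_factor(Vt, lower=True)
    ones = np.ones(nt)
    Vinv_y = linalg.cho_solve(cf, yt)
    Vinv_1 = linalg.cho_solve(cf, ones)
    beta = float(ones @ Vinv_y) / float(ones @ Vinv_1)
    w = linalg.cho_solve(cf, yt - beta)
    for k in active:
        effects[:, k] = comps[k] * (spec.genetic_matrices[k].values[:, t] @ w)
    return effects
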