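"""Mixed-model variance component estimation.

The observed phenotypic variance of a trait is partitioned as

    sigma2_p = sigma2_1 + ... + sigma2_n + sigma2_e

where each component k corresponds to a Gaussian random effect with
covariance ``sigma2_k * Sigma_k`` (``Sigma_k`` a subject-by-subject
relatedness or data-derived covariance matrix) and ``sigma2_e`` is the
residual.  Components are estimated by restricted maximum likelihood
(REML; plain ML available for model comparison with differing fixed
effects) using average-information (AI) updates with
expectation-maximization-style fixed-point fallback steps whenever an AI
step leaves the feasible region.

For a model with a single relatedness component the problem is rotated
into the eigenbasis of the component matrix, making every iteration O(n);
the dense path handles arbitrarily many components.  Both paths maximize
the same (restricted) likelihood and use the same update rules.

Estimated variances are reported both in trait units and as proportions
``lambda_k = sigma2_k / sigma2_p``; the proportion attached to the
additive component is the narrow-sense heritability h2.

Nested models are compared with likelihood ratio tests; because a tested
variance component sits on the boundary of the parameter space under the
null, the default null distribution is the 1/2:1/2 mixture of a point
mass at zero and chi-square(1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import RelatednessMatrix

logger = logging.getLogger(__name__)


class NonIdentifiableError(ValueError):
    """A component matrix is numerically proportional to the identity."""


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trajectory: list[dict] | None = None):
        super().__init__(message)
        self.trajectory = trajectory or []


@dataclass
class FitControl:
    tol: float = 1e-8           # relative log-likelihood change
    grad_tol: float = 1e-6      # score norm at the solution
    max_iter: int = 200
    start: np.ndarray | None = None  # full theta (components + residual)


@dataclass
class VarCompModel:
    """One trait, its fixed effects, and an ordered list of random components."""

    trait: str
    components: list[tuple[str, RelatednessMatrix]]
    covariate_terms: tuple[str, ...] = ()
    conditioning_dosages: pd.DataFrame | None = None  # subjects x variants


@dataclass
class VarCompFit:
    component_names: list[str]
    sigma2: np.ndarray          # per component, trait-variance units
    sigma2_e: float
    loglik: float
    method: str                 # "REML" | "ML"
    n: int
    n_fixed: int
    fixed_signature: tuple[str, ...]
    converged: bool
    n_iter: int
    gradient_norm: float
    boundary: list[str] = field(default_factory=list)
    se: np.ndarray | None = None      # per component + residual (last)
    trait: str | None = None

    @property
    def sigma2_p(self) -> float:
        return float(self.sigma2.sum() + self.sigma2_e)

    @property
    def lambdas(self) -> dict[str, float]:
        tot = self.sigma2_p
        out = {nm: float(s2) / tot for nm, s2 in
               zip(self.component_names, self.sigma2)}
        out["residual"] = self.sigma2_e / tot
        return out

    def to_frame(self) -> pd.DataFrame:
        lam = self.lambdas
        rows = []
        se = self.se if self.se is not None else [np.nan] * (len(self.sigma2) + 1)
        for k, nm in enumerate(self.component_names):
            rows.append({"trait": self.trait, "component": nm,
                         "sigma2": self.sigma2[k], "lambda": lam[nm],
                         "se": se[k], "loglik": self.loglik,
                         "converged": self.converged,
                         "boundary": nm in self.boundary})
        rows.append({"trait": self.trait, "component": "residual",
                     "sigma2": self.sigma2_e, "lambda": lam["residual"],
                     "se": se[-1], "loglik": self.loglik,
                     "converged": self.converged, "boundary": False})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Likelihood kernels
# ---------------------------------------------------------------------------

class _DenseKernel:
    """REML/ML derivatives with explicit n x n matrices."""

    def __init__(self, y: np.ndarray, X: np.ndarray, K: list[np.ndarray],
                 method: str):
        self.y, self.X, self.K = y, X, K
        self.n, self.p = X.shape
        self.method = method

    def stats(self, theta: np.ndarray):
        n, p = self.n, self.p
        V = theta[-1] * np.eye(n)
        for t, Kj in zip(theta[:-1], self.K):
            V += t * Kj
        L = np.linalg.cholesky(V)
        Vinv = np.linalg.inv(V)
        logdetV = 2.0 * float(np.log(np.diag(L)).sum())
        VinvX = Vinv @ self.X
        XtVinvX = self.X.T @ VinvX
        C = np.linalg.inv(XtVinvX)
        P = Vinv - VinvX @ C @ VinvX.T
        Py = P @ self.y
        yPy = float(self.y @ Py)
        Q = P if self.method == "REML" else Vinv
        mats = self.K + [None]  # None = identity (residual)
        ncomp = len(mats)
        trQK = np.empty(ncomp)
        yPKPy = np.empty(ncomp)
        KPy = np.empty((n, ncomp))
        for j, Kj in enumerate(mats):
            if Kj is None:
                trQK[j] = float(np.trace(Q))
                KPy[:, j] = Py
            else:
                trQK[j] = float(np.sum(Q * Kj))
                KPy[:, j] = Kj @ Py
            yPKPy[j] = float(Py @ KPy[:, j])
        PKPy = P @ KPy
        AI = 0.5 * (KPy.T @ PKPy)
        score = 0.5 * (yPKPy - trQK)
        if self.method == "REML":
            sgn, logdetC = np.linalg.slogdet(XtVinvX)
            ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetC + yPy)
        else:
            ll = -0.5 * (n * np.log(2 * np.pi) + logdetV + yPy)
        return ll, score, AI, yPKPy, trQK


class _DiagKernel:
    """Single-component fast path in the eigenbasis of the component matrix.

    After rotating by the eigenvectors of K, ``V = diag(t1 * w + te)`` and
    all REML quantities are O(n p^2) per evaluation.  Produces the same
    statistics as the dense kernel.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, w: np.ndarray,
                 U: np.ndarray, method: str):
        self.y = U.T @ y
        self.X = U.T @ X
        self.w = w
        self.n, self.p = X.shape
        self.method = method

    def stats(self, theta: np.ndarray):
        n, p = self.n, self.p
        t1, te = theta[0], theta[1]
        v = t1 * self.w + te
        vinv = 1.0 / v
        logdetV = float(np.log(v).sum())
        Xv = self.X * vinv[:, None]
        XtVinvX = self.X.T @ Xv
        C = np.linalg.inv(XtVinvX)

        def P_dot(a: np.ndarray) -> np.ndarray:
            va = vinv * a
            return va - Xv @ (C @ (self.X.T @ va))

        Py = P_dot(self.y)
        yPy = float(self.y @ Py)
        mats_w = [self.w, np.ones(n)]
        if self.method == "REML":
            # tr(P D) = sum(d/v) - tr(C X'Vinv D Vinv X)
            B = Xv.T  # p x n, rows X_a / v
            trQK = np.array([
                float((d * vinv).sum())
                - float(np.einsum("ab,an,bn,n->", C, B, B, d * 1.0))
                for d in mats_w
            ])
        else:
            trQK = np.array([float((d * vinv).sum()) for d in mats_w])
        KPy = np.column_stack([d * Py for d in mats_w])
        yPKPy = np.array([float(Py @ KPy[:, j]) for j in range(2)])
        PKPy = np.column_stack([P_dot(KPy[:, j]) for j in range(2)])
        AI = 0.5 * (KPy.T @ PKPy)
        score = 0.5 * (yPKPy - trQK)
        if self.method == "REML":
            sgn, logdetC = np.linalg.slogdet(XtVinvX)
            ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetC + yPy)
        else:
            ll = -0.5 * (n * np.log(2 * np.pi) + logdetV + yPy)
        return ll, score, AI, yPKPy, trQK


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

def _check_identifiable(names: Sequence[str], K: Sequence[np.ndarray]) -> None:
    for nm, Kj in zip(names, K):
        diag_mean = float(np.trace(Kj)) / Kj.shape[0]
        if diag_mean <= 0:
            continue
        if np.linalg.norm(Kj - diag_mean * np.eye(Kj.shape[0])) \
                <= 1e-8 * np.linalg.norm(Kj):
            raise NonIdentifiableError(
                f"component {nm!r} is numerically proportional to the "
                "identity and cannot be separated from the residual"
            )


def _maximize(kernel, theta0: np.ndarray, free: np.ndarray,
              control: FitControl):
    """Run AI updates with EM-style fixed-point fallback on the free
    components; returns (theta, loglik, n_iter, grad_norm, trajectory).

    A returned gradient norm of +inf signals the caller that one or more
    components were driven to the small positive floor with a negative
    score: the constrained maximum has them on the boundary, so they
    should be pinned at zero and the rest refit.
    """
    theta = theta0.copy()
    scale = max(theta0.sum(), 1e-12)
    floor = 1e-8 * scale
    ll, score, AI, yPKPy, trQK = kernel.stats(theta)
    traj = [{"iter": 0, "loglik": ll, "theta": theta.copy()}]
    it = 0

    def projected_norm(th, sc):
        g = sc.copy()
        clamped = free & (th <= 1.01 * floor) & (g < 0)
        g[clamped] = 0.0
        return float(np.linalg.norm(g[np.flatnonzero(free)]))

    for it in range(1, control.max_iter + 1):
        f = np.flatnonzero(free)
        if f.size == 0:
            break
        # EM-style fixed point: theta * yPKPy / tr(QK); positive by
        # construction and ascends toward the stationary point.
        em = theta.copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(trQK > 0, yPKPy / trQK, 1.0)
        em[f] = np.maximum(theta[f] * ratio[f], floor)

        step = np.zeros_like(theta)
        try:
            step[f] = np.linalg.solve(AI[np.ix_(f, f)], score[f])
            ai_ok = bool(np.all(np.isfinite(step[f])))
        except np.linalg.LinAlgError:
            ai_ok = False
        proposal = None
        if ai_ok and np.all(theta[f] + step[f] >= floor):
            proposal = theta.copy()
            proposal[f] += step[f]
        elif ai_ok:
            # the AI step wants one or more components negative: the
            # candidate optimum has them on the boundary — fix them at
            # the floor and fully re-maximize the remaining components
            clamped = free & (theta + step < floor)
            sub_free = free & ~clamped
            sub_theta = theta.copy()
            sub_theta[clamped] = floor
            try:
                sub_theta, sub_ll, _, _, sub_traj = _maximize(
                    kernel, sub_theta, sub_free, control)
                if sub_ll > ll - 1e-10:
                    proposal = sub_theta
            except ConvergenceError:
                proposal = None
        if proposal is None:
            proposal = em
        new_ll, new_score, new_AI, new_yPKPy, new_trQK = kernel.stats(proposal)
        if new_ll < ll - 1e-10 and not np.array_equal(proposal, em):
            em_stats = kernel.stats(em)
            if em_stats[0] > new_ll:
                proposal = em
                new_ll, new_score, new_AI, new_yPKPy, new_trQK = em_stats
        # step-halve toward the current point if the likelihood drops
        halvings = 0
        while new_ll < ll - 1e-10 and halvings < 20:
            proposal[f] = np.maximum(0.5 * (proposal[f] + theta[f]), floor)
            new_ll, new_score, new_AI, new_yPKPy, new_trQK = \
                kernel.stats(proposal)
            halvings += 1
        rel_change = abs(new_ll - ll) / (abs(ll) + 1.0)
        theta, ll, score, AI, yPKPy, trQK = \
            proposal, new_ll, new_score, new_AI, new_yPKPy, new_trQK
        traj.append({"iter": it, "loglik": ll, "theta": theta.copy()})
        grad_norm = projected_norm(theta, score)
        if rel_change < control.tol and grad_norm < control.grad_tol:
            at_floor = free & (theta <= 1.01 * floor) & (score < 0)
            at_floor[-1] = False  # residual never pinned
            if at_floor.any():
                return theta, ll, it, float("inf"), traj
            return theta, ll, it, grad_norm, traj
    grad_norm = projected_norm(theta, score) if free.any() else 0.0
    at_floor = free & (theta <= 1.01 * floor) & (score < 0)
    at_floor[-1] = False
    if at_floor.any():
        return theta, ll, it, float("inf"), traj
    if grad_norm < max(control.grad_tol, 1e-4):
        # likelihood surface is flat to numerical precision
        return theta, ll, it, grad_norm, traj
    raise ConvergenceError(
        f"REML did not converge in {control.max_iter} iterations "
        f"(gradient norm {grad_norm:.2e})", traj)


def fit_reml(y: np.ndarray, X: np.ndarray | None,
             components: Sequence[tuple[str, RelatednessMatrix | np.ndarray]],
             *, method: str = "REML", control: FitControl | None = None,
             fixed_signature: tuple[str, ...] = ("intercept",),
             trait: str | None = None) -> VarCompFit:
    """Fit variance components for one trait vector.

    ``X`` is the fixed-effect design (an intercept column is used when
    None).  ``components`` pairs names with relatedness structures; the
    residual identity component is implicit.  Components whose estimates
    are driven to zero are pinned there, flagged ``boundary`` and the
    remaining components refit, so the result is the constrained maximum
    over the nonnegative orthant.
    """
    if control is None:
        control = FitControl()
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = [nm for nm, _ in components]
    K: list[np.ndarray] = []
    eig = None
    for _, mat in components:
        if isinstance(mat, RelatednessMatrix):
            K.append(mat.values)
            if len(components) == 1:
                eig = mat.eigen()
        else:
            K.append(np.asarray(mat, dtype=float))
    ncomp = len(K)
    if n < X.shape[1] + ncomp + 1:
        raise ValueError(
            f"n={n} too small for {X.shape[1]} fixed effects and "
            f"{ncomp} variance components"
        )
    _check_identifiable(names, K)

    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("trait has zero variance")

    if ncomp == 0:
        return _residual_only_fit(y, X, method, fixed_signature, trait)

    if ncomp == 1:
        if eig is None:
            w, U = np.linalg.eigh(K[0])
        else:
            w, U = eig
        kernel = _DiagKernel(y, X, w, U, method)
    else:
        kernel = _DenseKernel(y, X, K, method)

    theta = (control.start.copy() if control.start is not None
             else np.full(ncomp + 1, vary / (ncomp + 1)))
    free = np.ones(ncomp + 1, dtype=bool)
    boundary: list[str] = []
    for _round in range(ncomp + 1):
        theta, ll, n_iter, grad_norm, traj = _maximize(kernel, theta, free,
                                                       control)
        if np.isfinite(grad_norm):
            break
        # pin the collapsed component(s) at zero and refit the rest
        floor = 1e-8 * max(theta.sum(), 1e-12)
        _, score, *_ = kernel.stats(theta)
        pin = free & (theta <= 100 * floor) & (score < 0)
        pin[-1] = False  # the residual stays free
        if not pin.any():
            grad_norm = float(np.linalg.norm(score[np.flatnonzero(free)]))
            break
        for j in np.flatnonzero(pin):
            theta[j] = 0.0
            free[j] = False
            boundary.append(names[j])
    else:  # pragma: no cover - all components pinned
        _, score, *_ = kernel.stats(theta)
        ll = kernel.stats(theta)[0]
        grad_norm = float(np.linalg.norm(score[free]))

    # standard errors from the inverse AI matrix over free parameters
    se = np.full(ncomp + 1, np.nan)
    try:
        _, _, AI, _, _ = kernel.stats(np.maximum(theta, 1e-12 * vary))
        f = np.flatnonzero(free)
        cov = np.linalg.inv(AI[np.ix_(f, f)])
        se[f] = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        pass

    return VarCompFit(
        component_names=names,
        sigma2=np.maximum(theta[:-1], 0.0),
        sigma2_e=float(theta[-1]),
        loglik=float(ll),
        method=method,
        n=n,
        n_fixed=X.shape[1],
        fixed_signature=fixed_signature,
        converged=True,
        n_iter=n_iter,
        gradient_norm=grad_norm,
        boundary=boundary,
        se=se,
        trait=trait,
    )


def _residual_only_fit(y, X, method, fixed_signature, trait) -> VarCompFit:
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    rss = float(r @ r)
    if method == "REML":
        s2 = rss / (n - p)
        sgn, logdetXtX = np.linalg.slogdet(X.T @ X / s2)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + n * np.log(s2)
                     + logdetXtX + rss / s2)
    else:
        s2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + rss / s2)
    return VarCompFit(
        component_names=[], sigma2=np.zeros(0), sigma2_e=s2, loglik=float(ll),
        method=method, n=n, n_fixed=p, fixed_signature=fixed_signature,
        converged=True, n_iter=0, gradient_norm=0.0, trait=trait,
        se=np.array([np.sqrt(2 * s2**2 / max(n - p, 1))]),
    )


def fit_variance_components(model: VarCompModel, data, *,
                            method: str = "REML",
                            control: FitControl | None = None) -> VarCompFit:
    """Fit ``model`` for one prepared trait in a :class:`TraitMatrix`.

    Uses the prepared (residualized + inverse-normalized) trait values
    when available, raw values otherwise.  Subjects with a missing trait
    value are dropped and all component matrices subset accordingly.
    Conditioning genotype dosages, if present, enter as fixed effects
    alongside the intercept.
    """
    if data.prepared is not None and model.trait in data.prepared.columns:
        y_all = data.prepared[model.trait]
    else:
        y_all = data.values[model.trait]
    y_all = y_all.dropna()
    subjects = [str(i) for i in y_all.index]

    X_cols = [np.ones(len(subjects))]
    signature = ["intercept"]
    if model.covariate_terms:
        from .phenotypes import _design_matrix
        D = _design_matrix(data.covariates.loc[y_all.index],
                           model.covariate_terms)
        for c in D.columns:
            X_cols.append(D[c].to_numpy(dtype=float))
            signature.append(str(c))
    if model.conditioning_dosages is not None:
        cond = model.conditioning_dosages.loc[y_all.index]
        for c in cond.columns:
            col = cond[c].to_numpy(dtype=float)
            col = np.where(np.isnan(col), np.nanmean(col), col)
            X_cols.append(col)
            signature.append(f"snp:{c}")
    X = np.column_stack(X_cols)

    comps = [(nm, mat.subset(subjects)) for nm, mat in model.components]
    return fit_reml(y_all.to_numpy(dtype=float), X, comps, method=method,
                    control=control, fixed_signature=tuple(signature),
                    trait=model.trait)


# ---------------------------------------------------------------------------
# Model comparison and summaries
# ---------------------------------------------------------------------------

def lrt_compare(fit_null: VarCompFit, fit_alt: VarCompFit,
                null_dist: str = "chisq_mixture") -> tuple[float, float]:
    """Likelihood ratio test of nested variance-component models.

    Returns ``(statistic, p)``.  Under the default ``chisq_mixture`` null
    (tested variance on the boundary) the p-value is half the
    chi-square(1) tail; ``chisq`` uses the plain chi-square(1).
    """
    if fit_null.method != fit_alt.method:
        raise ValueError("LRT requires fits with the same likelihood "
                         f"({fit_null.method} vs {fit_alt.method})")
    if fit_null.method == "REML" and \
            fit_null.fixed_signature != fit_alt.fixed_signature:
        raise ValueError("REML log-likelihoods are not comparable across "
                         "different fixed effects; use ML")
    if not set(fit_null.component_names) <= set(fit_alt.component_names):
        raise ValueError("models are not nested")
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if stat < 0:
        if stat < -1e-6:
            logger.warning("negative LRT statistic %.3g clamped to 0", stat)
        stat = 0.0
    if null_dist == "chisq_mixture":
        p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    elif null_dist == "chisq":
        p = float(stats.chi2.sf(stat, df=1))
    else:
        raise ValueError(f"unknown null distribution {null_dist!r}")
    return stat, p


def variance_proportions(fit: VarCompFit) -> dict[str, float]:
    """Proportions of phenotypic variance, plus ``h2`` when an additive
    component (named 'additive' or 'kinship') is present."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    if fit.sigma2_p <= 0:
        raise ValueError("all variance estimates are zero")
    lam = fit.lambdas
    for key in ("additive", "kinship"):
        if key in lam:
            lam["h2"] = lam[key]
            break
    else:
        if not fit.component_names:
            lam["h2"] = 0.0
    return lam


@dataclass
class SelectionStep:
    candidate: str
    p_value: float
    statistic: float
    accepted: bool
    skipped: dict[str, str] = field(default_factory=dict)


@dataclass
class SelectionResult:
    selected: list[str]
    final_fit: VarCompFit
    steps: list[SelectionStep]

    def audit(self) -> list[dict]:
        return [
            {"step": k + 1, "candidate": s.candidate, "p": s.p_value,
             "statistic": s.statistic, "accepted": s.accepted,
             "skipped": s.skipped}
            for k, s in enumerate(self.steps)
        ]


def sequential_component_selection(
        base: VarCompModel,
        candidates: Sequence[tuple[str, RelatednessMatrix]],
        data, alpha: float = 0.05, *, method: str = "REML",
        null_dist: str = "chisq_mixture",
        control: FitControl | None = None) -> SelectionResult:
    """Greedy forward selection of variance components by LRT.

    At each step every remaining candidate is added to the current model,
    the candidate with the smallest LRT p-value is selected if
    ``p < alpha``, and the procedure repeats until no candidate reaches
    the threshold.  Ties break by candidate list order; failed fits are
    skipped with the reason recorded.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    current = VarCompModel(base.trait, list(base.components),
                           base.covariate_terms, base.conditioning_dosages)
    current_fit = fit_variance_components(current, data, method=method,
                                          control=control)
    remaining = list(candidates)
    selected: list[str] = []
    steps: list[SelectionStep] = []
    while remaining:
        best: tuple[float, float, int, VarCompFit] | None = None
        skipped: dict[str, str] = {}
        for idx, (nm, mat) in enumerate(remaining):
            trial = VarCompModel(base.trait, current.components + [(nm, mat)],
                                 base.covariate_terms,
                                 base.conditioning_dosages)
            try:
                fit = fit_variance_components(trial, data, method=method,
                                              control=control)
                stat, p = lrt_compare(current_fit, fit, null_dist)
            except (NonIdentifiableError, ConvergenceError, ValueError) as exc:
                skipped[nm] = str(exc)
                continue
            if best is None or p < best[0]:
                best = (p, stat, idx, fit)
        if best is None:
            steps.append(SelectionStep("<none>", np.nan, np.nan, False,
                                       skipped))
            break
        p, stat, idx, fit = best
        nm, mat = remaining[idx]
        accepted = p < alpha
        steps.append(SelectionStep(nm, p, stat, accepted, skipped))
        if not accepted:
            break
        selected.append(nm)
        current = VarCompModel(base.trait, current.components + [(nm, mat)],
                               base.covariate_terms,
                               base.conditioning_dosages)
        current_fit = fit
        remaining.pop(idx)
    return SelectionResult(selected, current_fit, steps)
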