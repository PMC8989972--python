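"""Bivariate mixed-model genetic and environmental correlation.

For a pair of prepared traits the stacked model is

    [y1, y2] ~ N(mu, G (x) A + E (x) I)

with ``A`` the additive relationship matrix (2 x kinship), ``G`` the 2x2
genetic covariance ``[[sg1, sg12], [sg12, sg2]]`` and ``E`` the residual
covariance.  The cross covariances ``sg12`` and ``se12`` are
unconstrained (no Cholesky reparameterization), so the implied genetic
correlation ``rho_g = sg12 / sqrt(sg1 * sg2)`` can fall outside [-1, 1].
Out-of-range estimates — common when one or both traits have low
heritability — are flagged and reported as missing in matrix outputs
rather than clipped, mirroring how such estimates are treated in
practice.

Maximum likelihood is used (not REML); after rotating both traits into
the eigenbasis of ``A`` the covariance matrix is block diagonal in 2x2
blocks, so each likelihood evaluation is O(n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .pedigree import RelatednessMatrix


@dataclass
class BivariateFit:
    trait1: str
    trait2: str
    h2_1: float
    h2_2: float
    sigma_g12: float
    rho_g: float
    sigma_e12: float
    rho_e: float
    loglik: float
    n: int
    converged: bool
    masked: bool
    mask_reason: str = ""

    @property
    def rho_g_reported(self) -> float:
        """rho_g for matrix outputs: NaN when masked."""
        return np.nan if self.masked else self.rho_g


def _additive_values(kinship: RelatednessMatrix) -> np.ndarray:
    if kinship.kind == "kinship":
        return 2.0 * kinship.values
    return kinship.values


def _neg_loglik(theta: np.ndarray, w: np.ndarray, y1: np.ndarray,
                y2: np.ndarray) -> float:
    """-2 log L up to constants for rotated traits with block covariance.

    theta = (sg1, sg2, sg12, se1, se2, se12); per rotated coordinate i the
    2x2 covariance is [[sg1 w + se1, sg12 w + se12], [., sg2 w + se2]].
    """
    sg1, sg2, sg12, se1, se2, se12 = theta
    a = sg1 * w + se1
    d = sg2 * w + se2
    b = sg12 * w + se12
    det = a * d - b * b
    floor = 1e-12 * max(1.0, float(np.max(a) * np.max(d)))
    if np.any(det <= floor) or np.any(a <= 0) or np.any(d <= 0):
        # smooth, finite penalty keeps finite-difference gradients usable
        violation = float(np.sum(np.maximum(floor - det, 0))
                          + np.sum(np.maximum(-a, 0))
                          + np.sum(np.maximum(-d, 0)))
        return 1e10 * (1.0 + violation)
    quad = (d * y1 * y1 - 2 * b * y1 * y2 + a * y2 * y2) / det
    return float(np.sum(np.log(det) + quad))


def fit_bivariate(trait1: str, trait2: str, kinship: RelatednessMatrix,
                  data, *, max_restarts: int = 3,
                  min_h2_for_rho: float = 1e-3) -> BivariateFit:
    """ML bivariate fit of two prepared traits sharing a kinship structure.

    Both traits are restricted to their common observed subjects (>= 30
    required), de-meaned, and fitted in the eigenbasis of ``A = 2 phi``.
    ``rho_g`` is left unconstrained; ``|rho_g| > 1`` sets the mask flag,
    as does a numerically zero heritability for either trait.
    """
    y1_all = data.prepared_trait(trait1).dropna()
    y2_all = data.prepared_trait(trait2).dropna()
    common = y1_all.index.intersection(y2_all.index)
    if len(common) < 30:
        raise ValueError(
            f"only {len(common)} shared subjects for {trait1!r}/{trait2!r}; "
            "need >= 30"
        )
    subjects = [str(i) for i in common]
    A = RelatednessMatrix(subjects,
                          _additive_values(kinship.subset(subjects)),
                          "additive")
    w, U = A.eigen()
    y1 = U.T @ (y1_all.loc[common].to_numpy(dtype=float)
                - y1_all.loc[common].mean())
    y2 = U.T @ (y2_all.loc[common].to_numpy(dtype=float)
                - y2_all.loc[common].mean())
    n = len(common)

    v1 = float(np.var(y1))
    v2 = float(np.var(y2))
    c12 = float(np.mean(y1 * y2))
    eps = 1e-8
    bounds = [(eps, None), (eps, None), (None, None),
              (eps, None), (eps, None), (None, None)]

    best = None
    starts = [
        np.array([v1 / 2, v2 / 2, c12 / 2, v1 / 2, v2 / 2, c12 / 2]),
        np.array([v1 * 0.8, v2 * 0.8, c12 * 0.8, v1 * 0.2, v2 * 0.2,
                  c12 * 0.2]),
        np.array([v1 * 0.2, v2 * 0.2, 0.0, v1 * 0.8, v2 * 0.8, c12 * 0.8]),
    ]
    for x0 in starts[:max_restarts]:
        x0 = x0.copy()
        x0[[0, 1, 3, 4]] = np.maximum(x0[[0, 1, 3, 4]], 10 * eps)
        res = optimize.minimize(_neg_loglik, x0, args=(w, y1, y2),
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 1000, "ftol": 1e-14,
                                         "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"bivariate fit failed for {trait1!r}/{trait2!r}")
    # derivative-free polish: the profile near the optimum is flat enough
    # that L-BFGS with numerical gradients can stop early; alternate
    # restarted Nelder-Mead until the objective stops improving
    for _ in range(3):
        polish = optimize.minimize(
            _neg_loglik, best.x, args=(w, y1, y2), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-11, "fatol": 1e-13})
        if polish.fun < best.fun - 1e-10:
            best = polish
        else:
            if polish.fun < best.fun:
                best = polish
            break

    sg1, sg2, sg12, se1, se2, se12 = best.x
    h2_1 = sg1 / (sg1 + se1)
    h2_2 = sg2 / (sg2 + se2)
    rho_e = se12 / np.sqrt(se1 * se2)

    masked = False
    reason = ""
    if min(h2_1, h2_2) < min_h2_for_rho:
        rho_g = np.nan
        masked = True
        reason = "zero heritability"
    else:
        rho_g = sg12 / np.sqrt(sg1 * sg2)
        if abs(rho_g) > 1:
            masked = True
            reason = "out of range"
    if not masked and abs(rho_e) > 1:
        masked = True
        reason = "residual correlation out of range"

    return BivariateFit(
        trait1=trait1, trait2=trait2, h2_1=float(h2_1), h2_2=float(h2_2),
        sigma_g12=float(sg12), rho_g=float(rho_g), sigma_e12=float(se12),
        rho_e=float(rho_e), loglik=-0.5 * float(best.fun)
        - n * np.log(2 * np.pi), n=n, converged=bool(best.success),
        masked=masked, mask_reason=reason,
    )


def correlation_matrices(data, pairs: Sequence[tuple[str, str]],
                         kinship: RelatednessMatrix
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Genetic and phenotypic correlation matrices for the given pairs.

    Returns ``(rho_g matrix, Pearson matrix, long table)``.  Genetic
    entries come from :func:`fit_bivariate` with out-of-range masking
    (NaN); phenotypic entries are pairwise-complete Pearson correlations.
    Pairs with fewer than 3 complete observations are missing with the
    reason recorded in the long table.
    """
    traits = sorted({t for pair in pairs for t in pair})
    rho_g = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    pearson = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    rows = []
    for t1, t2 in pairs:
        x = data.prepared_trait(t1)
        y = data.prepared_trait(t2)
        complete = x.notna() & y.notna()
        row: dict = {"trait1": t1, "trait2": t2}
        if complete.sum() < 3:
            rho_g.loc[t1, t2] = rho_g.loc[t2, t1] = np.nan
            pearson.loc[t1, t2] = pearson.loc[t2, t1] = np.nan
            row.update(rho_g=np.nan, rho_e=np.nan, rho_p=np.nan,
                       h2_1=np.nan, h2_2=np.nan, masked=True,
                       reason="fewer than 3 complete observations")
            rows.append(row)
            continue
        r_p = float(np.corrcoef(x[complete], y[complete])[0, 1])
        pearson.loc[t1, t2] = pearson.loc[t2, t1] = r_p
        fit = fit_bivariate(t1, t2, kinship, data)
        rho_g.loc[t1, t2] = rho_g.loc[t2, t1] = fit.rho_g_reported
        row.update(rho_g=fit.rho_g, rho_e=fit.rho_e, rho_p=r_p,
                   h2_1=fit.h2_1, h2_2=fit.h2_2, masked=fit.masked,
                   reason=fit.mask_reason)
        rows.append(row)
    return rho_g, pearson, pd.DataFrame(rows)
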