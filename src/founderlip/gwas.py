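"""Pedigree-aware association scans and multiple-testing machinery.

The single-variant scan is two-stage, as in EMMAX/GRAMMAR-style LMM GWAS:

1. fit the null model ``trait ~ covariates (+ conditioning genotypes)``
   with the additive relatedness component by REML, fixing the estimated
   covariance structure ``V``;
2. for each variant, estimate the allele-dosage effect by generalized
   least squares under that structure and test it with a Wald t statistic
   against the residual degrees of freedom.  The residual scale is
   re-estimated per variant, so with an identity-proportional structure
   the scan reduces exactly to per-variant ordinary least squares.

Effects are reported in SD units of the prepared trait.  The module also
implements sequential conditional analysis (counting independent signals
within a locus by repeatedly conditioning on the current top variant),
the PC-based multiple-testing threshold (base genome-wide level divided
by the number of principal components needed to explain a target
fraction of trait variance), the plain Bonferroni threshold used for
replication look-ups, and the analytic power of a replication test with
an optional winner's-curse halving of the discovery effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .pedigree import RelatednessMatrix
from .varcomp import (FitControl, NonIdentifiableError, VarCompModel,
                      fit_variance_components)


@dataclass
class AssocRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str
    trait: str
    effect_allele: str
    eaf: float
    beta: float
    se: float
    t: float
    p: float
    n: int
    conditioning: tuple[str, ...] = ()
    skipped: str = ""


@dataclass
class ThresholdResult:
    n_traits: int
    pc_count: int
    variance_fraction: float
    base_level: float
    significance_threshold: float
    suggestive_threshold: float


def records_to_frame(records: Sequence[AssocRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"chrom": r.chrom, "pos": r.pos, "rsid": r.rsid, "ref": r.ref,
         "alt": r.alt, "eaf": r.eaf, "beta": r.beta, "se": r.se, "t": r.t,
         "p": r.p, "n": r.n, "trait": r.trait,
         "conditioning_set": ",".join(r.conditioning), "skipped": r.skipped}
        for r in records
    ])


def association_scan(trait: str, g: GenotypeMatrix,
                     kinship: RelatednessMatrix, data, *,
                     covariate_terms: Sequence[str] = (),
                     conditioning: Sequence[str] = (),
                     control: FitControl | None = None
                     ) -> list[AssocRecord]:
    """Two-stage LMM association scan of one prepared trait.

    ``conditioning`` names variants (rsIDs) in ``g`` whose dosages enter
    the null model as fixed effects; monomorphic variants and variants
    collinear with the covariates/conditioning set are skipped with the
    reason recorded on the returned record.
    """
    y_all = data.prepared_trait(trait).dropna()
    subjects = [str(i) for i in y_all.index]
    g_sub = g.subset_subjects(subjects)
    n = len(subjects)

    cond_idx = [g.variant_index(c) for c in conditioning]
    cond_df = None
    if cond_idx:
        cond = g_sub.dosages[:, cond_idx]
        cond = np.where(np.isnan(cond), np.nanmean(cond, axis=0), cond)
        cond_df = pd.DataFrame(cond, index=y_all.index,
                               columns=[g.variants[k].rsid for k in cond_idx])

    A_vals = (2.0 * kinship.values if kinship.kind == "kinship"
              else kinship.values)
    A = RelatednessMatrix(kinship.ids, A_vals, "additive").subset(subjects)
    null = VarCompModel(trait, [("additive", A)],
                        tuple(covariate_terms), cond_df)
    try:
        fit = fit_variance_components(null, data, method="REML",
                                      control=control)
        w, U = A.eigen()
        v = fit.sigma2[0] * w + fit.sigma2_e
    except NonIdentifiableError:
        # relatedness structure proportional to identity: unrelated
        # subjects, plain weighted (= ordinary) least squares
        null = VarCompModel(trait, [], tuple(covariate_terms), cond_df)
        fit = fit_variance_components(null, data, method="REML",
                                      control=control)
        U = np.eye(n)
        v = np.full(n, fit.sigma2_e)
    sqw = 1.0 / np.sqrt(v)

    X_cols = [np.ones(n)]
    if covariate_terms:
        from .phenotypes import _design_matrix
        D = _design_matrix(data.covariates.loc[y_all.index],
                           list(covariate_terms))
        X_cols += [D[c].to_numpy(dtype=float) for c in D.columns]
    if cond_df is not None:
        X_cols += [cond_df[c].to_numpy(dtype=float) for c in cond_df.columns]
    X = np.column_stack(X_cols)

    yt = (U.T @ y_all.to_numpy(dtype=float)) * sqw
    Xt = (U.T @ X) * sqw[:, None]
    Q, _ = np.linalg.qr(Xt)
    y_res = yt - Q @ (Q.T @ yt)
    p_fixed = X.shape[1]
    df = n - p_fixed - 1

    conditioning_tuple = tuple(conditioning)
    records: list[AssocRecord] = []
    Gt = (U.T @ np.nan_to_num(
        g_sub.dosages - np.nanmean(g_sub.dosages, axis=0), nan=0.0)) \
        * sqw[:, None]
    # the per-variant column keeps its original (unrotated) mean via the
    # intercept; centering before rotation only changes the intercept
    freqs = g_sub.alt_frequencies()
    for k, var in enumerate(g_sub.variants):
        base = {"chrom": var.chrom, "pos": var.pos, "ref": var.ref,
                "alt": var.alt, "rsid": var.rsid, "trait": trait,
                "effect_allele": var.alt, "eaf": float(freqs[k]), "n": n,
                "conditioning": conditioning_tuple}
        if not (0 < freqs[k] < 1):
            records.append(AssocRecord(**base, beta=np.nan, se=np.nan,
                                       t=np.nan, p=np.nan,
                                       skipped="monomorphic"))
            continue
        x = Gt[:, k]
        x_res = x - Q @ (Q.T @ x)
        xx = float(x_res @ x_res)
        if xx <= 1e-10 * float(x @ x) or xx == 0.0:
            records.append(AssocRecord(**base, beta=np.nan, se=np.nan,
                                       t=np.nan, p=np.nan,
                                       skipped="collinear"))
            continue
        beta = float(x_res @ y_res) / xx
        resid = y_res - beta * x_res
        s2 = float(resid @ resid) / df
        se = np.sqrt(s2 / xx)
        tstat = beta / se
        p = 2.0 * float(stats.t.sf(abs(tstat), df))
        p = max(p, np.nextafter(0, 1))
        records.append(AssocRecord(**base, beta=beta, se=se, t=tstat, p=p))
    return records


# ---------------------------------------------------------------------------
# Conditional analysis
# ---------------------------------------------------------------------------

def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chr:start-end`` (half-open) into 1-based inclusive bounds."""
    chrom, span = region.split(":")
    start, end = span.split("-")
    return chrom, int(start) + 1, int(end)


@dataclass
class ConditionalResult:
    signals: list[str]                  # ordered independent index variants
    rounds: list[pd.DataFrame] = field(default_factory=list)


def conditional_scan(trait: str, g: GenotypeMatrix,
                     kinship: RelatednessMatrix, data, *,
                     region: str | tuple[str, int, int] | None = None,
                     covariate_terms: Sequence[str] = (),
                     alpha: float = 5e-8,
                     conditioning: Sequence[str] = (),
                     max_signals: int = 20) -> ConditionalResult:
    """Sequential conditional analysis of a locus.

    Repeatedly scans the region, adds the top variant to the conditioning
    set while its p-value is below ``alpha``, and returns the ordered
    conditioning set as the independent signals.
    """
    if region is not None:
        if isinstance(region, str):
            chrom, start, end = parse_region(region)
        else:
            chrom, start, end = region
        idx = [k for k, v in enumerate(g.variants)
               if v.chrom == chrom and start <= v.pos <= end]
        g = g.subset_variants(idx)
    cond = list(conditioning)
    result = ConditionalResult(signals=[])
    for _ in range(max_signals):
        records = association_scan(trait, g, kinship, data,
                                   covariate_terms=covariate_terms,
                                   conditioning=cond)
        frame = records_to_frame(records)
        result.rounds.append(frame)
        valid = frame[frame["skipped"] == ""]
        if valid.empty or valid["p"].min() >= alpha:
            break
        top = valid.loc[valid["p"].idxmin(), "rsid"]
        result.signals.append(top)
        cond.append(top)
    return result


# ---------------------------------------------------------------------------
# Multiple-testing thresholds
# ---------------------------------------------------------------------------

def multiple_testing_threshold(data, *, variance_fraction: float = 0.95,
                               base_level: float = 5e-8) -> ThresholdResult:
    """PC-based multiple-testing correction.

    Eigen-decomposes the complete-case correlation matrix of the prepared
    traits, finds the smallest number of principal components whose
    cumulative eigenvalue fraction reaches ``variance_fraction``, and
    divides ``base_level`` by that count.
    """
    if data.prepared is None:
        raise ValueError("traits must be prepared first")
    complete = data.prepared.dropna(axis=0)
    n_traits = data.prepared.shape[1]
    if n_traits < 2:
        raise ValueError("need at least 2 traits")
    if complete.shape[0] < n_traits:
        raise ValueError(
            f"only {complete.shape[0]} complete-case subjects for "
            f"{n_traits} traits; the correlation matrix would be singular — "
            "subset the traits first"
        )
    corr = np.corrcoef(complete.to_numpy(dtype=float), rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    cum = np.cumsum(eig) / eig.sum()
    k = int(np.searchsorted(cum, variance_fraction) + 1)
    return threshold_from_pc_count(n_traits, k,
                                   variance_fraction=variance_fraction,
                                   base_level=base_level)


def threshold_from_pc_count(n_traits: int, pc_count: int, *,
                            variance_fraction: float = 0.95,
                            base_level: float = 5e-8) -> ThresholdResult:
    """Adjusted threshold arithmetic given an already-known PC count."""
    if not 1 <= pc_count <= n_traits:
        raise ValueError("PC count must be in [1, number of traits]")
    return ThresholdResult(
        n_traits=n_traits, pc_count=pc_count,
        variance_fraction=variance_fraction, base_level=base_level,
        significance_threshold=base_level / pc_count,
        suggestive_threshold=base_level,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Plain Bonferroni threshold ``alpha / n_tests`` for replication
    look-ups of a fixed variant list."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def classify_significance(p: np.ndarray | float,
                          thresholds: ThresholdResult) -> np.ndarray:
    """Partition p-values into 'significant' / 'suggestive' / 'ns' bands."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    out = np.where(p < thresholds.significance_threshold, "significant",
                   np.where(p < thresholds.suggestive_threshold,
                            "suggestive", "ns"))
    return out


# ---------------------------------------------------------------------------
# Replication-exclusion power
# ---------------------------------------------------------------------------

def replication_exclusion_power(beta: float, maf: float, n: int,
                                alpha: float,
                                winners_curse_factor: float = 1.0) -> float:
    """Analytic power of a two-sided replication test.

    For a standardized additive effect ``beta`` (SD units per effect
    allele) at minor allele frequency ``maf`` in a replication sample of
    size ``n``, the Wald noncentrality is
    ``beta * factor * sqrt(2 maf (1 - maf) n)`` and power is the mass of
    the shifted normal beyond the two-sided critical values.  A factor of
    0.5 halves the discovery effect to adjust for winner's curse.  High
    power with a null replication result supports excluding the variant
    as causal.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if winners_curse_factor <= 0:
        raise ValueError("winner's-curse factor must be positive")
    ncp = beta * winners_curse_factor * np.sqrt(2 * maf * (1 - maf) * n)
    z = stats.norm.isf(alpha / 2)
    return float(stats.norm.sf(z - ncp) + stats.norm.cdf(-z - ncp))


def genomic_control_lambda(p: np.ndarray) -> float:
    """Genomic-control inflation factor: median chi-square over its null
    median."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / stats.chi2.ppf(0.5, df=1))
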