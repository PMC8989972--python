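"""Trait container and phenotype preparation.

Lipidomic traits are prepared in two steps before any genetic analysis:

1. residualize on covariates (age, age squared, sex, and technical batch
   factors) by ordinary least squares;
2. rank-based inverse normal transformation (INT) of the residuals with
   the Blom offset, ``z_i = Phi^{-1}((r_i - 3/8) / (n + 1/4))``.

Traditional lipids go through the same two steps minus the technical
factors.  Prepared traits are on a unit-SD normal scale, which is also the
scale on which association effect sizes are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

LIPID_CLASSES = (
    "ACT", "CE", "Cer", "DAG", "FA", "GlcCer", "LPC", "LPE",
    "PC", "PE", "PI", "SM", "TAG", "ST", "TRAD",
)


class DegenerateTraitError(ValueError):
    """Trait has (numerically) zero residual variance after adjustment."""


@dataclass
class TraitMatrix:
    """Subjects x traits with covariates and class annotations.

    ``values`` holds raw trait values (NaN = missing), ``covariates`` the
    adjustment variables (numeric or categorical), ``classes`` maps trait
    name -> lipid class, and ``prepared`` caches residualized +
    inverse-normalized values.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    classes: dict[str, str] = field(default_factory=dict)
    batch_covariates: tuple[str, ...] = ()
    prepared: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.covariates.index):
            raise ValueError("trait and covariate tables must share subjects")
        unknown = set(self.classes.values()) - set(LIPID_CLASSES)
        if unknown:
            raise ValueError(f"unknown lipid classes: {sorted(unknown)}")

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def traits_in_class(self, cls: str) -> list[str]:
        return [t for t in self.traits if self.classes.get(t) == cls]

    def prepared_trait(self, trait: str) -> pd.Series:
        if self.prepared is None or trait not in self.prepared:
            raise KeyError(
                f"trait {trait!r} has not been prepared; call prepare_traits"
            )
        return self.prepared[trait]


def _design_matrix(cov: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Expand covariate terms into a numeric design (no intercept column).

    ``"age^2"`` squares a numeric column; categorical/object columns are
    expanded to indicator columns dropping a reference level.
    """
    parts: list[pd.DataFrame] = []
    for term in terms:
        if term.endswith("^2"):
            base = term[:-2]
            col = pd.to_numeric(cov[base], errors="raise")
            parts.append((col**2).to_frame(term))
        else:
            col = cov[term]
            if col.dtype.kind in "ifu":
                parts.append(pd.to_numeric(col).to_frame(term))
            else:
                dummies = pd.get_dummies(col.astype("category"),
                                         prefix=term, drop_first=True)
                parts.append(dummies.astype(float))
    if not parts:
        return pd.DataFrame(index=cov.index)
    return pd.concat(parts, axis=1)


def residualize_covariates(t: TraitMatrix, trait: str,
                           covariate_terms: Sequence[str]) -> pd.Series:
    """OLS residuals of one trait on the given covariate terms.

    Subjects with a missing trait value are dropped (the returned series
    only covers analyzed subjects).  Aliased (exactly collinear) design
    columns raise with the offending terms named.
    """
    y = pd.to_numeric(t.values[trait], errors="raise")
    keep = y.notna()
    y = y[keep]
    if len(y) == 0:
        raise DegenerateTraitError(f"trait {trait!r} has no observed values")
    X = _design_matrix(t.covariates.loc[keep.index[keep]], covariate_terms)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing covariate values in: {bad}")
    Xm = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # identify collinear columns by rank-revealing QR on the scaled design
        _, R, piv = _qr_pivot(Xm)
        dropped = [(["intercept"] + list(X.columns))[k]
                   for k in piv[rank:]]
        raise ValueError(f"rank-deficient covariate design; collinear terms: "
                         f"{dropped}")
    beta, *_ = np.linalg.lstsq(Xm, y.to_numpy(dtype=float), rcond=None)
    resid = y.to_numpy(dtype=float) - Xm @ beta
    if resid.std() <= 1e-12 * max(1.0, float(np.abs(y).max())):
        raise DegenerateTraitError(
            f"trait {trait!r} has zero residual variance after adjustment"
        )
    return pd.Series(resid, index=y.index, name=trait)


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def inverse_normal_transform(x: pd.Series | np.ndarray, *,
                             offset: float = 3.0 / 8.0) -> pd.Series:
    """Rank-based inverse normal transform with a configurable offset.

    ``z_i = Phi^{-1}((r_i - c) / (n + 1 - 2c))`` with average ranks for
    ties (so equal inputs map to equal outputs) and missing values
    propagated.  The default ``c = 3/8`` is the Blom convention, for which
    the denominator is ``n + 1/4``.
    """
    s = pd.Series(x)
    obs = s.dropna()
    n = len(obs)
    if n < 3:
        raise ValueError(f"need >=3 non-missing values, got {n}")
    if obs.nunique() == 1:
        raise ValueError("all values identical; transform undefined")
    ranks = stats.rankdata(obs.to_numpy(), method="average")
    z = stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))
    out = pd.Series(np.nan, index=s.index, name=s.name, dtype=float)
    out.loc[obs.index] = z
    return out


def prepare_traits(t: TraitMatrix, *,
                   covariate_terms: Sequence[str] | None = None,
                   int_offset: float = 3.0 / 8.0) -> TraitMatrix:
    """Residualize and inverse-normalize every trait; fills ``t.prepared``.

    Lipid species are adjusted for all covariate terms; traits in the TRAD
    class skip the technical batch factors.  Default terms: age, age^2,
    sex, plus ``t.batch_covariates``.
    """
    if covariate_terms is None:
        base = [c for c in ("age", "sex") if c in t.covariates.columns]
        if "age" in base:
            base.insert(1, "age^2")
        covariate_terms = base + list(t.batch_covariates)
    prepared = {}
    for trait in t.traits:
        terms = list(covariate_terms)
        if t.classes.get(trait) == "TRAD":
            terms = [c for c in terms if c not in t.batch_covariates]
        resid = residualize_covariates(t, trait, terms)
        prepared[trait] = inverse_normal_transform(resid, offset=int_offset)
    t.prepared = pd.DataFrame(prepared).reindex(t.values.index)
    return t


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trait_table(phenotype_tsv: str | Path, sidecar_yaml: str | Path
                     ) -> TraitMatrix:
    """Load a phenotype/covariate TSV plus a YAML sidecar.

    The sidecar maps trait names to lipid classes under ``classes:`` and
    names covariate roles under ``covariates:`` (keys ``age``, ``sex``,
    ``batch`` — the latter a list of column names).
    """
    df = pd.read_csv(phenotype_tsv, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    with open(sidecar_yaml) as fh:
        meta = yaml.safe_load(fh)
    classes: dict[str, str] = dict(meta.get("classes", {}))
    cov_spec = meta.get("covariates", {})
    cov_cols = [c for c in (cov_spec.get("age"), cov_spec.get("sex")) if c]
    batch = tuple(cov_spec.get("batch", []))
    cov_cols += list(batch)
    trait_cols = [c for c in df.columns if c not in cov_cols]
    covariates = df[cov_cols].copy()
    if cov_spec.get("sex") in covariates:
        covariates[cov_spec["sex"]] = covariates[cov_spec["sex"]].astype(str)
    values = df[trait_cols].apply(pd.to_numeric, errors="coerce")
    rename = {}
    if cov_spec.get("age") and cov_spec["age"] != "age":
        rename[cov_spec["age"]] = "age"
    if cov_spec.get("sex") and cov_spec["sex"] != "sex":
        rename[cov_spec["sex"]] = "sex"
    covariates = covariates.rename(columns=rename)
    return TraitMatrix(values, covariates, classes, batch)


def write_trait_table(t: TraitMatrix, phenotype_tsv: str | Path,
                      sidecar_yaml: str | Path) -> None:
    df = pd.concat([t.values, t.covariates], axis=1)
    df.to_csv(phenotype_tsv, sep="\t", index_label="id")
    meta = {
        "classes": dict(t.classes),
        "covariates": {
            "age": "age" if "age" in t.covariates else None,
            "sex": "sex" if "sex" in t.covariates else None,
            "batch": list(t.batch_covariates),
        },
    }
    with open(sidecar_yaml, "w") as fh:
        yaml.safe_dump(meta, fh)
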