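"""Pedigree parsing and expected relatedness matrices.

A pedigree here is the usual directed acyclic parent-offspring structure:
every individual is either a founder (both parents unknown) or has exactly
two parents present in the pedigree.  From it we compute the two expected
covariance structures used as random-effect covariance matrices in the
mixed models:

* the kinship matrix ``phi`` — ``phi[i, j]`` is the probability that an
  allele drawn at random from *i* and one drawn at random from *j* are
  identical by descent (IBD).  The additive relationship matrix is
  ``A = 2 * phi``.
* the dominance (fraternity) matrix — ``d[i, j]`` is the probability that
  *i* and *j* share their whole genotype IBD, the covariance structure of
  dominance deviations.

Kinship uses the standard tabular recursion in topological order; the
dominance coefficient uses the product-of-parental-kinships formula, which
is exact for non-inbred pairs (see :func:`dominance_matrix` for how
inbreeding is handled).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_PARENT_TOKENS = ("0", "", "NA", ".")

SEX_CODES = {
    "1": "male",
    "2": "female",
    "m": "male",
    "f": "female",
    "male": "male",
    "female": "female",
    "0": "unknown",
    "na": "unknown",
    ".": "unknown",
    "unknown": "unknown",
    "-9": "unknown",
}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, single parent...)."""


@dataclass(frozen=True)
class PedigreeRecord:
    iid: str
    father: str | None
    mother: str | None
    sex: str = "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """Validated pedigree with a cached topological order.

    Invariants enforced at construction: unique ids, both-or-neither
    parents, parents present as records, acyclicity (a topological order
    with parents before offspring exists).
    """

    records: list[PedigreeRecord]
    _index: dict[str, int] = field(init=False, repr=False)
    _topo: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [r.iid for r in self.records]
        seen: set[str] = set()
        for iid in ids:
            if iid in seen:
                raise PedigreeError(f"duplicate individual id {iid!r}")
            seen.add(iid)
        self._index = {iid: k for k, iid in enumerate(ids)}
        for r in self.records:
            if (r.father is None) != (r.mother is None):
                raise PedigreeError(
                    f"individual {r.iid!r} has exactly one known parent; "
                    "both or neither must be given"
                )
            for p in (r.father, r.mother):
                if p is not None and p not in self._index:
                    raise PedigreeError(
                        f"parent {p!r} of {r.iid!r} is not in the pedigree"
                    )
        self._topo = self._topological_order()
        self._check_sexes()

    def _topological_order(self) -> list[str]:
        # Kahn's algorithm over parent->child edges; leftover nodes form a cycle.
        children: dict[str, list[str]] = {r.iid: [] for r in self.records}
        indeg = {r.iid: 0 for r in self.records}
        for r in self.records:
            for p in (r.father, r.mother):
                if p is not None:
                    children[p].append(r.iid)
                    indeg[r.iid] += 1
        queue = [iid for iid, d in indeg.items() if d == 0]
        order: list[str] = []
        while queue:
            iid = queue.pop()
            order.append(iid)
            for c in children[iid]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(self.records):
            cyclic = sorted(iid for iid, d in indeg.items() if d > 0)
            raise PedigreeError(
                "pedigree contains a cycle (self-ancestry) involving: "
                + ", ".join(cyclic)
            )
        return order

    def _check_sexes(self) -> None:
        for r in self.records:
            if r.father is not None:
                f = self.records[self._index[r.father]]
                if f.sex == "female":
                    raise PedigreeError(
                        f"father {r.father!r} of {r.iid!r} is recorded as female"
                    )
            if r.mother is not None:
                m = self.records[self._index[r.mother]]
                if m.sex == "male":
                    raise PedigreeError(
                        f"mother {r.mother!r} of {r.iid!r} is recorded as male"
                    )

    # -- convenience accessors -------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [r.iid for r in self.records]

    @property
    def founders(self) -> list[str]:
        return [r.iid for r in self.records if r.is_founder]

    @property
    def topological_order(self) -> list[str]:
        return list(self._topo)

    def record(self, iid: str) -> PedigreeRecord:
        try:
            return self.records[self._index[iid]]
        except KeyError:
            raise PedigreeError(f"unknown individual id {iid!r}") from None

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, iid: object) -> bool:
        return iid in self._index


@dataclass
class RelatednessMatrix:
    """Symmetric subject-by-subject covariance structure.

    ``kind`` is one of ``kinship``, ``additive``, ``dominance``, ``grm``,
    ``class_covariance``.  Values are dimensionless covariance coefficients
    in the order of ``ids``.
    """

    ids: list[str]
    values: np.ndarray
    kind: str
    _eigen: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("relatedness matrix is not symmetric")

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (eigenvalues, eigenvectors)."""
        if self._eigen is None:
            w, U = np.linalg.eigh(self.values)
            self._eigen = (w, U)
        return self._eigen

    def subset(self, ids: Sequence[str]) -> "RelatednessMatrix":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        try:
            idx = np.array([pos[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"subject {exc.args[0]!r} not in matrix") from None
        return RelatednessMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str) -> "RelatednessMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(dtype=float), kind)


def _clean_token(tok: object) -> str:
    return str(tok).strip()


def parse_pedigree(
    path: str | Path,
    *,
    missing_tokens: Iterable[str] = MISSING_PARENT_TOKENS,
    family_column: bool | None = None,
) -> Pedigree:
    """Read a PED-style pedigree file into a validated :class:`Pedigree`.

    Expected columns: ``id father mother sex`` (tab- or whitespace-
    separated; a leading family column is tolerated and ignored).  Missing
    parents are encoded by any of ``missing_tokens``.  Parents referenced
    but absent as rows are auto-added as founders with a warning.

    ``family_column=None`` auto-detects: files with five or more columns
    are assumed to carry a leading family column.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     comment="#")
    if df.shape[1] < 4:
        raise PedigreeError(
            f"pedigree file needs >=4 columns (id father mother sex); "
            f"got {df.shape[1]}"
        )
    if family_column is None:
        family_column = df.shape[1] >= 5
    offset = 1 if family_column else 0
    if df.shape[1] < 4 + offset:
        raise PedigreeError("too few columns after the family column")

    missing = {t.lower() for t in missing_tokens} | {"nan"}

    def parent(tok: object) -> str | None:
        s = _clean_token(tok)
        return None if s.lower() in missing else s

    rows: list[tuple[str, str | None, str | None, str]] = []
    for _, row in df.iterrows():
        iid = _clean_token(row.iloc[offset])
        fa = parent(row.iloc[offset + 1])
        mo = parent(row.iloc[offset + 2])
        sex = SEX_CODES.get(_clean_token(row.iloc[offset + 3]).lower(), "unknown")
        rows.append((iid, fa, mo, sex))

    present = {iid for iid, *_ in rows}
    implied: dict[str, str] = {}  # id -> sex implied by parental role
    for _, fa, mo, _ in rows:
        if fa is not None and fa not in present:
            implied[fa] = "male"
        if mo is not None and mo not in present:
            implied[mo] = "female"
    if implied:
        logger.warning(
            "%d parent(s) referenced but absent as rows; added as founders: %s",
            len(implied), ", ".join(sorted(implied)),
        )
    records = [PedigreeRecord(iid, None, None, sex) for iid, sex in implied.items()]
    records += [PedigreeRecord(*r) for r in rows]
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write ``id father mother sex`` TSV with '0' for missing parents."""
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for r in ped.records:
            fh.write(
                f"{r.iid}\t{r.father or '0'}\t{r.mother or '0'}\t{sex_out[r.sex]}\n"
            )


def _kinship_full(ped: Pedigree) -> tuple[np.ndarray, dict[str, int]]:
    """Tabular kinship over the whole pedigree in topological order."""
    order = ped.topological_order
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    K = np.zeros((n, n))
    for iid in order:
        i = pos[iid]
        rec = ped.record(iid)
        if rec.is_founder:
            K[i, i] = 0.5
            # off-diagonals with earlier individuals stay 0 unless the
            # earlier individual descends from this founder — impossible in
            # topological order, so nothing to do.
        else:
            f, m = pos[rec.father], pos[rec.mother]
            K[i, :i] = 0.5 * (K[f, :i] + K[m, :i])
            K[:i, i] = K[i, :i]
            K[i, i] = 0.5 * (1.0 + K[f, m])
    return K, pos


def kinship_matrix(ped: Pedigree, subjects: Sequence[str] | None = None
                   ) -> RelatednessMatrix:
    """Expected kinship coefficients ``phi`` for the requested subjects.

    Founders have ``phi(i, i) = 1/2`` and are unrelated to each other;
    non-founders follow the recursion ``phi(i, i) = (1 + phi(f, m)) / 2``
    and ``phi(i, j) = (phi(f, j) + phi(m, j)) / 2``.
    """
    if subjects is None:
        subjects = ped.ids
    K, pos = _kinship_full(ped)
    try:
        idx = np.array([pos[s] for s in subjects], dtype=int)
    except KeyError as exc:
        raise PedigreeError(f"subject {exc.args[0]!r} not in pedigree") from None
    return RelatednessMatrix(list(subjects), K[np.ix_(idx, idx)], "kinship")


def additive_matrix(ped: Pedigree, subjects: Sequence[str] | None = None
                    ) -> RelatednessMatrix:
    """Additive (numerator) relationship matrix ``A = 2 * phi``."""
    k = kinship_matrix(ped, subjects)
    return RelatednessMatrix(k.ids, 2.0 * k.values, "additive")


def dominance_matrix(ped: Pedigree, subjects: Sequence[str] | None = None
                     ) -> RelatednessMatrix:
    """Fraternity (dominance) coefficients for the requested subjects.

    For distinct non-founders *i*, *j* with parents (f_i, m_i), (f_j, m_j):

        d(i, j) = phi(f_i, f_j) * phi(m_i, m_j) + phi(f_i, m_j) * phi(m_i, f_j)

    with ``d(i, i) = 1`` and ``d = 0`` when either member of a distinct
    pair is a founder.  The product formula is exact for non-inbred pairs;
    it is applied to all pairs, and a warning lists inbred individuals when
    any are present (their pairwise entries are approximate).
    """
    if subjects is None:
        subjects = ped.ids
    K, pos = _kinship_full(ped)
    for s in subjects:
        if s not in pos:
            raise PedigreeError(f"subject {s!r} not in pedigree")
    n = len(subjects)

    # parent index arrays; -1 marks founders
    fa = np.full(n, -1, dtype=int)
    mo = np.full(n, -1, dtype=int)
    for k_, s in enumerate(subjects):
        rec = ped.record(s)
        if not rec.is_founder:
            fa[k_] = pos[rec.father]
            mo[k_] = pos[rec.mother]

    D = np.zeros((n, n))
    nonf = np.flatnonzero(fa >= 0)
    if nonf.size:
        f, m = fa[nonf], mo[nonf]
        D[np.ix_(nonf, nonf)] = (K[np.ix_(f, f)] * K[np.ix_(m, m)]
                                 + K[np.ix_(f, m)] * K[np.ix_(m, f)])
    np.fill_diagonal(D, 1.0)

    self_k = np.array([K[pos[s], pos[s]] for s in subjects])
    inbred = [s for s, phi in zip(subjects, self_k) if phi > 0.5 + 1e-12]
    if inbred:
        warnings.warn(
            "dominance coefficients use the non-inbred product formula; "
            f"{len(inbred)} inbred individual(s) present: "
            + ", ".join(inbred[:10]) + ("..." if len(inbred) > 10 else ""),
            stacklevel=2,
        )
    return RelatednessMatrix(list(subjects), D, "dominance")
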