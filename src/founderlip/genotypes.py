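"""Genotype QC and data-derived covariance matrices.

Holds the genotype container, the per-variant QC filter (call rate, minor
allele frequency, Hardy-Weinberg), the SNP genetic-relationship matrix
(GRM, GCTA convention: per-variant standardized dosages averaged over
variants) and the subject-by-subject covariance matrix built from a block
of phenotypes (used to model the contribution of a lipidome class to a
trait's variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import RelatednessMatrix


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    rsid: str = "."

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix (alt-allele count in [0, 2]).

    ``dosages[i, k]`` is the dosage of subject ``ids[i]`` at
    ``variants[k]``; missing values are NaN.
    """

    ids: list[str]
    variants: list[Variant]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} subjects x {len(self.variants)} variants"
            )
        ok = np.isnan(self.dosages) | (
            (self.dosages >= -1e-9) & (self.dosages <= 2 + 1e-9)
        )
        if not ok.all():
            raise ValueError("dosages must be in [0, 2] or missing")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant records (chrom, pos, ref, alt)")

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def variant_index(self, rsid_or_key: str | tuple) -> int:
        for k, v in enumerate(self.variants):
            if v.rsid == rsid_or_key or v.key == rsid_or_key:
                return k
        raise KeyError(f"variant {rsid_or_key!r} not found")

    def subset_variants(self, which: Sequence[int] | Sequence[str]
                        ) -> "GenotypeMatrix":
        if len(which) and isinstance(which[0], str):
            idx = [self.variant_index(w) for w in which]
        else:
            idx = list(which)  # type: ignore[arg-type]
        return GenotypeMatrix(
            self.ids, [self.variants[k] for k in idx], self.dosages[:, idx]
        )

    def subset_subjects(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return GenotypeMatrix(list(ids), self.variants, self.dosages[idx, :])

    def alt_frequencies(self) -> np.ndarray:
        """Sample alt-allele frequency per variant, ignoring missing."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QcThresholds:
    max_missing: float = 0.02
    min_maf: float = 0.01
    min_hwe_p: float = 1e-10


@dataclass
class QcReport:
    table: pd.DataFrame  # rsid, chrom, pos, call_rate, maf, hwe_p, pass, reasons

    @property
    def n_pass(self) -> int:
        return int(self.table["pass"].sum())

    @property
    def n_fail(self) -> int:
        return int((~self.table["pass"]).sum())


def hwe_chisq_p(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """1-df chi-square Hardy-Weinberg test on genotype counts."""
    n = n_ref_hom + n_het + n_alt_hom
    if n == 0:
        return np.nan
    p = (2 * n_alt_hom + n_het) / (2 * n)
    exp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    obs = np.array([n_ref_hom, n_het, n_alt_hom], dtype=float)
    if p in (0.0, 1.0):
        return 1.0  # monomorphic: trivially consistent with HWE
    chisq = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chisq, df=1))


def variant_qc(g: GenotypeMatrix, thresholds: QcThresholds | None = None
               ) -> tuple[GenotypeMatrix, QcReport]:
    """Filter variants on call rate, minor allele frequency and HWE.

    HWE is tested only for hard-call variants (all non-missing dosages in
    {0, 1, 2}); dosage variants get ``hwe_p = NaN`` and are not filtered
    on HWE.  MAF is folded (always <= 0.5).
    """
    if thresholds is None:
        thresholds = QcThresholds()
    if len(g.variants) == 0:
        raise ValueError("empty genotype matrix")

    n_subj = len(g.ids)
    rows = []
    keep: list[int] = []
    for k, v in enumerate(g.variants):
        d = g.dosages[:, k]
        obs = d[~np.isnan(d)]
        call_rate = len(obs) / n_subj
        af = obs.mean() / 2.0 if len(obs) else np.nan
        maf = min(af, 1 - af) if np.isfinite(af) else np.nan
        hard = len(obs) > 0 and np.all(np.isin(obs, (0.0, 1.0, 2.0)))
        if hard:
            hwe_p = hwe_chisq_p(int((obs == 0).sum()), int((obs == 1).sum()),
                                int((obs == 2).sum()))
        else:
            hwe_p = np.nan
        reasons = []
        if 1 - call_rate > thresholds.max_missing:
            reasons.append("missingness")
        if not np.isfinite(maf) or maf < thresholds.min_maf:
            reasons.append("MAF")
        if np.isfinite(hwe_p) and hwe_p < thresholds.min_hwe_p:
            reasons.append("HWE")
        ok = not reasons
        if ok:
            keep.append(k)
        rows.append({
            "rsid": v.rsid, "chrom": v.chrom, "pos": v.pos,
            "call_rate": call_rate, "maf": maf, "hwe_p": hwe_p,
            "pass": ok, "reasons": ",".join(reasons),
        })
    report = QcReport(pd.DataFrame(rows))
    if not keep:
        warnings.warn("all variants removed by QC", stacklevel=2)
    filtered = g.subset_variants(keep)
    return filtered, report


# ---------------------------------------------------------------------------
# Relationship matrices from data
# ---------------------------------------------------------------------------

def snp_grm(g: GenotypeMatrix, variant_subset: Sequence[str] | None = None
            ) -> RelatednessMatrix:
    """GCTA-style SNP genetic relationship matrix.

    Each dosage column is standardized as ``w = (g - 2p) / sqrt(2p(1-p))``
    with ``p`` the sample alt-allele frequency; ``G = W W' / m``.  Missing
    dosages are mean-imputed (to ``2p``) before standardization, i.e. they
    contribute zero.
    """
    sub = g if variant_subset is None else g.subset_variants(list(variant_subset))
    if len(sub.variants) == 0:
        raise ValueError("empty variant subset for GRM")
    p = sub.alt_frequencies()
    mono = np.flatnonzero((p <= 0) | (p >= 1) | ~np.isfinite(p))
    if mono.size:
        names = ", ".join(sub.variants[k].rsid for k in mono[:10])
        raise ValueError(f"monomorphic variant(s) in GRM subset: {names}")
    W = sub.dosages - 2 * p
    W[np.isnan(W)] = 0.0  # mean imputation
    W /= np.sqrt(2 * p * (1 - p))
    G = W @ W.T / len(sub.variants)
    return RelatednessMatrix(sub.ids, G, "grm")


def class_covariance(values: pd.DataFrame) -> RelatednessMatrix:
    """Subject-by-subject covariance matrix from a block of traits.

    ``values`` is subjects x traits (index = subject ids).  Columns are
    standardized to mean 0, variance 1 (denominator ``n``), and
    ``S = X X' / m`` with ``m`` the number of traits, so ``trace(S) = n``
    and fitted variance components sit on a heritability-like scale.
    """
    if values.shape[1] == 0:
        raise ValueError("empty trait subset for class covariance")
    X = values.to_numpy(dtype=float)
    if np.isnan(X).any():
        # subject-mean completion keeps S PSD and is adequate for the low
        # missingness this structure is used with
        col_means = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(col_means, idx[1])
    sd = X.std(axis=0)
    const = np.flatnonzero(sd <= 0)
    if const.size:
        names = ", ".join(values.columns[k] for k in const[:10])
        raise ValueError(f"constant trait(s) in class covariance: {names}")
    X = (X - X.mean(axis=0)) / sd
    S = X @ X.T / X.shape[1]
    return RelatednessMatrix([str(i) for i in values.index], S, "class_covariance")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, *, prefer_dosage: bool = False) -> GenotypeMatrix:
    """Read genotypes from a VCF using the GT (hard calls) or DS field.

    Multi-allelic records must be split upstream; they are rejected with a
    clear error.  Positions are 1-based as in the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    variants: list[Variant] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                "split multi-allelics upstream"
            )
        dosage = None
        if prefer_dosage:
            try:
                ds = rec.format("DS")
            except KeyError:
                ds = None
            if ds is not None:
                dosage = np.asarray(ds, dtype=float).reshape(-1)
        if dosage is None:
            gts = rec.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
            dosage = np.choose(gts, [0.0, 1.0, np.nan, 2.0])
        variants.append(Variant(str(rec.CHROM), int(rec.POS), rec.REF,
                                rec.ALT[0], rec.ID or "."))
        cols.append(dosage)
    vcf.close()
    if not cols:
        raise ValueError(f"no variants in {path}")
    return GenotypeMatrix(ids, variants, np.column_stack(cols))


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call genotypes as an uncompressed VCFv4.2 text file.

    Non-integer dosages are rounded to the nearest hard call; missing
    dosages become ``./.``.
    """
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    order = np.lexsort(
        ([v.pos for v in g.variants], [v.chrom for v in g.variants])
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chrom for v in g.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.ids) + "\n")
        for k in order:
            v = g.variants[k]
            d = g.dosages[:, k]
            calls = [
                "./." if np.isnan(x) else gt_codes[int(round(x))] for x in d
            ]
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


def read_variant_list(path: str | Path) -> pd.DataFrame:
    """Known-variant list TSV with header (rsID, chrom, pos, ref, alt[, trait])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"rsID", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant list missing columns: {sorted(missing)}")
    return df
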