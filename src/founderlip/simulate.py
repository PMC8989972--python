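"""Synthetic founder-population data.

Generates the three inputs every other module consumes, with known truth:

* a multi-generation pedigree descended from a closed founder set
  (random or cousin-biased mating, the latter producing inbreeding);
* gene-dropped genotypes — founder alleles drawn at specified
  frequencies (or seeded as exact copy counts, so a rare founder variant
  can drift to high frequency) and transmitted by fair meioses, with
  optional LD blocks in which variants co-segregate on founder
  haplotypes;
* lipidome-like traits built generatively from the same covariance
  structures the estimation models assume: each trait is a sum of
  component draws (additive, dominance, class factors), each scaled to
  an exact target fraction of the phenotypic variance, plus fixed
  variant effects in SD units, plus covariate contamination (age, sex,
  batch) with known coefficients so phenotype preparation can be tested.

Randomness comes from counter-based (Philox) streams keyed by
``(seed, operation, item)``, so adding variants never perturbs trait
draws and the same seed reproduces byte-identical outputs.

The module also provides a gene-drop Monte-Carlo estimator of IBD
allele- and genotype-sharing, used as an independent oracle for the
recursive kinship and dominance coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, Variant
from .pedigree import Pedigree, PedigreeRecord, RelatednessMatrix, \
    dominance_matrix, kinship_matrix

# operation indices for child RNG streams
_STREAM_PEDIGREE = 0
_STREAM_GENOTYPES = 1
_STREAM_TRAITS = 2
_STREAM_COVARIATES = 3
_STREAM_IBD = 4


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed=[seed, *key]))


@dataclass
class VariantSpec:
    """Independent biallelic variants at a founder frequency."""
    freq: float
    count: int = 1
    chrom: str = "1"


@dataclass
class EnrichedVariantSpec:
    """Variant seeded as an exact allele-copy count in the founders.

    Emulates a rare allele carried into a founder population by a handful
    of founders; across gene-drop replicates its final-generation
    frequency drifts, sometimes far above the founder frequency.
    """
    founder_copies: int
    beta: float = 0.0  # SD units per allele, applied by simulate_lipidome
    chrom: str = "2"


@dataclass
class LDBlockSpec:
    """A causal variant plus proxies co-segregating on founder haplotypes.

    Proxy alleles copy the causal allele on each founder haplotype with
    probability ``r`` (else an independent draw at the causal frequency),
    and the whole block is transmitted without recombination, so final
    dosage correlations are high for ``r`` near 1.
    """
    n_proxies: int
    r: float = 0.95
    causal_copies: int | None = None
    causal_freq: float | None = None
    chrom: str = "3"
    start: int = 1_000_000


@dataclass
class TraitSpec:
    name: str
    lipid_class: str = "PC"
    additive: float = 0.0
    dominance: float = 0.0
    class_fractions: dict[str, float] = field(default_factory=dict)
    variant_betas: dict[str, float] = field(default_factory=dict)

    @property
    def residual(self) -> float:
        used = self.additive + self.dominance + sum(
            self.class_fractions.values())
        if used > 1 + 1e-9:
            raise ValueError(
                f"variance fractions for {self.name!r} sum to {used} > 1")
        return max(1.0 - used, 0.0)


@dataclass
class SimConfig:
    seed: int = 0
    n_founders: int = 150
    generations: int = 6
    mean_sibship: float = 2.5
    mating: str = "random"          # "random" | "cousin"
    cousin_bias: float = 8.0        # kinship weight exponent for "cousin"
    variants: list[VariantSpec] = field(default_factory=list)
    enriched: list[EnrichedVariantSpec] = field(default_factory=list)
    ld_blocks: list[LDBlockSpec] = field(default_factory=list)
    traits: list[TraitSpec] = field(default_factory=list)
    class_correlation: float = 0.4  # within-class latent-factor correlation
    raw_scale: bool = False         # exponentiate observed trait values
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.3, "batch": 0.2})


def generation_of(iid: str) -> int:
    """Generation index encoded in simulated ids ('G3_I12' -> 3)."""
    return int(iid.split("_")[0][1:])


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Non-overlapping-generation pedigree from a closed founder set.

    Couples form within a generation (random, or biased toward related
    mates under the "cousin" rule, which produces inbreeding); offspring
    counts are Poisson around ``mean_sibship``.  Ids encode the
    generation: ``G{g}_I{k}``.
    """
    if cfg.n_founders < 2:
        raise ValueError("need at least 2 founders")
    if cfg.generations < 1:
        raise ValueError("need at least 1 generation")
    rng = _rng(cfg.seed, _STREAM_PEDIGREE)
    records: list[PedigreeRecord] = []
    current: list[PedigreeRecord] = []
    for k in range(cfg.n_founders):
        sex = "male" if k % 2 == 0 else "female"
        rec = PedigreeRecord(f"G0_I{k}", None, None, sex)
        records.append(rec)
        current.append(rec)

    for gen in range(1, cfg.generations):
        males = [r for r in current if r.sex == "male"]
        females = [r for r in current if r.sex == "female"]
        if not males or not females:
            raise ValueError(
                f"generation {gen - 1} has no eligible mates "
                f"({len(males)} males, {len(females)} females)"
            )
        rng.shuffle(males)
        if cfg.mating == "cousin":
            ped_so_far = Pedigree(list(records))
            ids = [r.iid for r in males] + [r.iid for r in females]
            phi = kinship_matrix(ped_so_far, ids).values
            nm = len(males)
            couples = []
            available = list(range(len(females)))
            for mi, male in enumerate(males):
                if not available:
                    break
                kv = np.array([phi[mi, nm + fj] for fj in available])
                wgt = np.exp(cfg.cousin_bias * kv / max(kv.max(), 1e-9)) \
                    if kv.max() > 0 else np.ones(len(available))
                pick = rng.choice(len(available), p=wgt / wgt.sum())
                couples.append((male, females[available[pick]]))
                available.pop(pick)
        else:
            rng.shuffle(females)
            couples = list(zip(males, females))

        nxt: list[PedigreeRecord] = []
        k = 0
        for father, mother in couples:
            for _ in range(rng.poisson(cfg.mean_sibship)):
                sex = "male" if rng.random() < 0.5 else "female"
                rec = PedigreeRecord(f"G{gen}_I{k}", father.iid, mother.iid,
                                     sex)
                nxt.append(rec)
                records.append(rec)
                k += 1
        if not nxt:
            raise ValueError(f"generation {gen} is empty; increase "
                             "mean_sibship or founder count")
        current = nxt
    return Pedigree(records)


def mean_mate_kinship(ped: Pedigree) -> float:
    """Mean kinship between the parents of each non-founder (couples
    counted once)."""
    couples = {(r.father, r.mother) for r in ped.records
               if not r.is_founder}
    if not couples:
        return 0.0
    ids = sorted({i for c in couples for i in c})
    phi = kinship_matrix(ped, ids)
    pos = {iid: k for k, iid in enumerate(ids)}
    return float(np.mean([phi.values[pos[f], pos[m]] for f, m in couples]))


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def _founder_haplotypes(cfg: SimConfig, n_founders: int
                        ) -> tuple[list[Variant], np.ndarray, np.ndarray]:
    """Founder haplotype alleles for all configured variants.

    Returns (variants, haps[founder, 2, m], block_id[m]); block_id is -1
    for independently segregating variants.
    """
    variants: list[Variant] = []
    cols: list[np.ndarray] = []
    blocks: list[int] = []
    pos = {}
    vidx = 0

    def next_pos(chrom: str, step: int = 10_000) -> int:
        pos[chrom] = pos.get(chrom, 0) + step
        return pos[chrom]

    for spec in cfg.variants:
        for _ in range(spec.count):
            rng = _rng(cfg.seed, _STREAM_GENOTYPES, vidx)
            cols.append(rng.random((n_founders, 2)) < spec.freq)
            variants.append(Variant(spec.chrom, next_pos(spec.chrom),
                                    "A", "G", f"var{vidx}"))
            blocks.append(-1)
            vidx += 1
    for e_i, spec in enumerate(cfg.enriched):
        if spec.founder_copies > 2 * n_founders:
            raise ValueError(
                f"enriched variant asks for {spec.founder_copies} copies "
                f"but only {2 * n_founders} founder alleles exist")
        rng = _rng(cfg.seed, _STREAM_GENOTYPES, vidx)
        hap = np.zeros((n_founders, 2), dtype=bool)
        flat = rng.choice(2 * n_founders, size=spec.founder_copies,
                          replace=False)
        hap.reshape(-1)[flat] = True
        cols.append(hap)
        variants.append(Variant(spec.chrom, next_pos(spec.chrom),
                                "C", "T", f"enr{e_i}"))
        blocks.append(-1)
        vidx += 1
    for b_i, spec in enumerate(cfg.ld_blocks):
        rng = _rng(cfg.seed, _STREAM_GENOTYPES, 10_000 + b_i)
        if spec.causal_copies is not None:
            causal = np.zeros(2 * n_founders, dtype=bool)
            flat = rng.choice(2 * n_founders, size=spec.causal_copies,
                              replace=False)
            causal[flat] = True
        elif spec.causal_freq is not None:
            causal = rng.random(2 * n_founders) < spec.causal_freq
        else:
            raise ValueError("LD block needs causal_copies or causal_freq")
        freq = causal.mean() if causal.any() else 0.05
        cols.append(causal.reshape(n_founders, 2))
        variants.append(Variant(spec.chrom, spec.start, "C", "T",
                                f"blk{b_i}_causal"))
        blocks.append(b_i)
        for j in range(spec.n_proxies):
            copy = rng.random(2 * n_founders) < spec.r
            indep = rng.random(2 * n_founders) < freq
            proxy = np.where(copy, causal, indep)
            cols.append(proxy.reshape(n_founders, 2))
            variants.append(Variant(spec.chrom, spec.start + 1000 * (j + 1),
                                    "A", "G", f"blk{b_i}_prox{j}"))
            blocks.append(b_i)
    if not variants:
        raise ValueError("no variants configured")
    haps = np.stack(cols, axis=-1)  # founders x 2 x m
    return variants, haps, np.asarray(blocks)


def gene_drop_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Drop founder alleles down the pedigree with fair meioses.

    Variants segregate independently except within LD blocks, which share
    one meiosis per transmission (no recombination inside a block).
    """
    founders = ped.founders
    variants, fhaps, block_id = _founder_haplotypes(cfg, len(founders))
    m = len(variants)
    order = ped.topological_order
    pos = {iid: k for k, iid in enumerate(order)}
    haps = np.zeros((len(order), 2, m), dtype=bool)
    f_index = {iid: k for k, iid in enumerate(founders)}

    # per-block meiosis sharing: variants in a block use one chooser
    uniq_blocks = [b for b in sorted(set(block_id)) if b >= 0]
    block_members = {b: np.flatnonzero(block_id == b) for b in uniq_blocks}
    indep = np.flatnonzero(block_id == -1)

    rng = _rng(cfg.seed, _STREAM_GENOTYPES, 999_999)
    for iid in order:
        i = pos[iid]
        rec = ped.record(iid)
        if rec.is_founder:
            haps[i] = fhaps[f_index[iid]]
            continue
        for h, parent in enumerate((rec.father, rec.mother)):
            p = pos[parent]
            choose = np.empty(m, dtype=np.int64)
            choose[indep] = rng.integers(0, 2, size=indep.size)
            for b in uniq_blocks:
                choose[block_members[b]] = rng.integers(0, 2)
            haps[i, h] = np.take_along_axis(
                haps[p], choose[None, :], axis=0)[0]
    dosages = haps.sum(axis=1).astype(float)
    return GenotypeMatrix(order, variants, dosages)


# ---------------------------------------------------------------------------
# Monte-Carlo IBD oracle
# ---------------------------------------------------------------------------

def gene_drop_ibd(ped: Pedigree, pairs: Sequence[tuple[str, str]],
                  n_reps: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo IBD sharing from gene-dropping a single labeled locus.

    Every founder carries two unique allele labels; after each drop the
    kinship estimate for a pair is the probability that a random allele
    from each is the same label, and the genotype-sharing estimate is the
    probability that the two unordered label pairs coincide.  Returns a
    table with columns phi_hat, phi_se, d_hat, d_se.
    """
    order = ped.topological_order
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    rng = _rng(seed, _STREAM_IBD)
    # labels: founder f carries 2f, 2f+1; replicate axis is vectorized
    haps = np.zeros((n, 2, n_reps), dtype=np.int32)
    label = 0
    for iid in order:
        i = pos[iid]
        rec = ped.record(iid)
        if rec.is_founder:
            haps[i, 0] = 2 * label
            haps[i, 1] = 2 * label + 1
            label += 1
            continue
        for h, parent in enumerate((rec.father, rec.mother)):
            p = pos[parent]
            choose = rng.integers(0, 2, size=n_reps)
            haps[i, h] = np.take_along_axis(haps[p], choose[None, :],
                                            axis=0)[0]
    rows = []
    for a, b in pairs:
        ia, ib = pos[a], pos[b]
        share = np.zeros(n_reps)
        for x in range(2):
            for y in range(2):
                share += haps[ia, x] == haps[ib, y]
        phi = share / 4.0
        same = ((haps[ia, 0] == haps[ib, 0]) & (haps[ia, 1] == haps[ib, 1])) \
            | ((haps[ia, 0] == haps[ib, 1]) & (haps[ia, 1] == haps[ib, 0]))
        rows.append({
            "id1": a, "id2": b,
            "phi_hat": float(phi.mean()),
            "phi_se": float(phi.std(ddof=1) / np.sqrt(n_reps)),
            "d_hat": float(same.mean()),
            "d_se": float(same.std(ddof=1) / np.sqrt(n_reps)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def scaled_component(L: np.ndarray, fraction: float,
                     rng: np.random.Generator,
                     shared: np.ndarray | None = None,
                     share_weight: float = 0.0) -> np.ndarray:
    """Draw ``L z`` and rescale to an exact sample-variance fraction.

    ``shared`` mixes in a pre-drawn latent vector (already in trait
    space) with weight ``sqrt(share_weight)`` to induce block correlation
    between traits drawing from the same latent.
    """
    n = L.shape[0]
    z = L @ rng.standard_normal(n)
    if shared is not None and share_weight > 0:
        z = np.sqrt(share_weight) * shared + np.sqrt(1 - share_weight) * z
    sd = z.std()
    if sd <= 0 or fraction <= 0:
        return np.zeros(n)
    return z * (np.sqrt(fraction) / sd)


def _chol_psd(values: np.ndarray) -> np.ndarray:
    jitter = 1e-8 * max(float(np.trace(values)) / values.shape[0], 1.0)
    return np.linalg.cholesky(values + jitter * np.eye(values.shape[0]))


def simulate_lipidome(ped: Pedigree, g: GenotypeMatrix | None,
                      cfg: SimConfig,
                      subjects: Sequence[str] | None = None
                      ):
    """Generate traits with specified variance fractions; returns
    ``(TraitMatrix, truth)``.

    Each trait is a sum of component draws, each rescaled to its exact
    target fraction of phenotypic variance: additive (Cholesky factor of
    ``A = 2 phi``), dominance, per-class structures (from already
    simulated species in that class), plus variant fixed effects in SD
    units and covariate contamination with the coefficients recorded in
    ``truth``.  Within-class correlation is induced by a shared latent
    factor at ``cfg.class_correlation``.
    """
    from .genotypes import class_covariance
    from .phenotypes import TraitMatrix

    if subjects is None:
        subjects = ped.ids
    subjects = list(subjects)
    n = len(subjects)
    if not cfg.traits:
        raise ValueError("no traits configured")

    rng_cov = _rng(cfg.seed, _STREAM_COVARIATES)
    age = rng_cov.uniform(20, 80, size=n)
    sex = np.array([ped.record(s).sex for s in subjects])
    sex = np.where(sex == "unknown",
                   np.where(rng_cov.random(n) < 0.5, "male", "female"), sex)
    batch = rng_cov.integers(0, 4, size=n)

    need_A = any(t.additive > 0 for t in cfg.traits)
    need_D = any(t.dominance > 0 for t in cfg.traits)
    L_A = _chol_psd(2.0 * kinship_matrix(ped, subjects).values) if need_A \
        else None
    L_D = _chol_psd(dominance_matrix(ped, subjects).values) if need_D \
        else None

    dosage = {}
    if g is not None:
        g_sub = g.subset_subjects(subjects)
        dosage = {v.rsid: g_sub.dosages[:, k]
                  for k, v in enumerate(g_sub.variants)}

    # shared latents per class for block correlation, drawn in the
    # additive and iid spaces
    classes = sorted({t.lipid_class for t in cfg.traits})
    shared_a = {}
    shared_e = {}
    for ci, c in enumerate(classes):
        r = _rng(cfg.seed, _STREAM_TRAITS, 50_000 + ci)
        shared_a[c] = (L_A @ r.standard_normal(n)) if L_A is not None \
            else r.standard_normal(n)
        shared_e[c] = r.standard_normal(n)

    values: dict[str, np.ndarray] = {}
    genetic_values: dict[str, np.ndarray] = {}
    truth: dict = {"traits": {}, "covariate_effects": dict(
        cfg.covariate_effects)}
    rho = cfg.class_correlation

    # species (no class_fractions) first, then composite traits that
    # reference class structures built from the species
    ordered = sorted(cfg.traits, key=lambda t: bool(t.class_fractions))
    for ti, spec in enumerate(ordered):
        rng = _rng(cfg.seed, _STREAM_TRAITS, ti)
        y = np.zeros(n)
        g_part = np.zeros(n)
        if spec.additive > 0:
            comp = scaled_component(L_A, spec.additive, rng,
                                    shared_a[spec.lipid_class], rho)
            y += comp
            g_part += comp
        if spec.dominance > 0:
            comp = scaled_component(L_D, spec.dominance, rng)
            y += comp
            g_part += comp
        for cls, frac in spec.class_fractions.items():
            members = [t.name for t in cfg.traits
                       if t.lipid_class == cls and t.name in values]
            if not members:
                raise ValueError(
                    f"trait {spec.name!r} requests class {cls!r} but no "
                    "species of that class were simulated first")
            block = pd.DataFrame({m: values[m] for m in members},
                                 index=subjects)
            S = class_covariance(block)
            y += scaled_component(_chol_psd(S.values), frac, rng)
        if spec.residual > 0:
            y += scaled_component(np.eye(n), spec.residual, rng,
                                  shared_e[spec.lipid_class], rho)
        for rsid, beta in spec.variant_betas.items():
            if rsid not in dosage:
                raise ValueError(f"variant {rsid!r} not in genotypes")
            y = y + beta * dosage[rsid]
        values[spec.name] = y
        genetic_values[spec.name] = g_part
        truth["traits"][spec.name] = {
            "class": spec.lipid_class, "additive": spec.additive,
            "dominance": spec.dominance,
            "class_fractions": dict(spec.class_fractions),
            "residual": spec.residual,
            "variant_betas": dict(spec.variant_betas),
        }

    ce = cfg.covariate_effects
    contamination = (ce.get("age", 0.0) * (age - age.mean())
                     + ce.get("sex", 0.0) * (sex == "female")
                     + ce.get("batch", 0.0) * (batch - batch.mean()))
    observed = {}
    for name, y in values.items():
        obs = y + contamination
        observed[name] = np.exp(obs) if cfg.raw_scale else obs

    tm = TraitMatrix(
        values=pd.DataFrame(observed, index=pd.Index(subjects, name="id")),
        covariates=pd.DataFrame(
            {"age": age, "sex": sex, "batch": batch.astype(str)},
            index=pd.Index(subjects, name="id")),
        classes={t.name: t.lipid_class for t in cfg.traits},
        batch_covariates=("batch",),
    )
    truth["latent"] = pd.DataFrame(values, index=tm.values.index)
    truth["genetic"] = pd.DataFrame(genetic_values, index=tm.values.index)
    return tm, truth
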