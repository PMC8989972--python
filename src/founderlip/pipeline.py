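"""End-to-end study pipeline.

Runs the full analysis flow from one YAML config: simulate (or load)
inputs -> phenotype preparation -> relatedness matrices -> heritability
with and without adjustment for enriched large-effect variants -> class
variance decomposition -> correlations -> GWAS -> conditional analysis
-> multiple-testing thresholds.  Each stage writes its outputs, a log
entry and a checksum into the run manifest; re-running with an unchanged
config and inputs skips completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bivariate, genotypes, gwas, pedigree, phenotypes, simulate, \
    varcomp

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prepare", "relatedness", "h2", "decompose", "corr",
          "gwas", "conditional", "thresholds")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    # inputs (ignored when simulate is enabled)
    pedigree_path: str | None = None
    vcf_path: str | None = None
    phenotype_path: str | None = None
    phenotype_sidecar: str | None = None
    adjustment_variants: list[str] = field(default_factory=list)
    # stage toggles
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # thresholds (defaults follow standard founder-population practice)
    qc_max_missing: float = 0.02
    qc_min_hwe_p: float = 1e-10
    qc_min_maf: float = 0.01
    alpha: float = 0.05
    variance_fraction: float = 0.95
    base_gwas_level: float = 5e-8
    nominal_adjustment_p: float = 1e-3
    h2_screen_p: float = 0.01
    # synthetic-data block (used when "simulate" is in stages)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.__dict__, sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _default_sim_config(cfg: RunConfig) -> simulate.SimConfig:
    sim = dict(cfg.sim)
    traits = [simulate.TraitSpec(**t) for t in sim.pop("traits", [])]
    if not traits:
        traits = ([simulate.TraitSpec(f"SM_{k}", "SM", additive=0.5)
                   for k in range(4)]
                  + [simulate.TraitSpec(f"TAG_{k}", "TAG", additive=0.3)
                     for k in range(4)])
    variants = [simulate.VariantSpec(**v) for v in sim.pop("variants", [])] \
        or [simulate.VariantSpec(freq=0.3, count=50)]
    enriched = [simulate.EnrichedVariantSpec(**e)
                for e in sim.pop("enriched", [])]
    blocks = [simulate.LDBlockSpec(**b) for b in sim.pop("ld_blocks", [])]
    return simulate.SimConfig(seed=cfg.seed, traits=traits, variants=variants,
                              enriched=enriched, ld_blocks=blocks, **sim)


@dataclass
class _RunState:
    ped: pedigree.Pedigree | None = None
    gmat: genotypes.GenotypeMatrix | None = None
    traits: phenotypes.TraitMatrix | None = None
    kinship: pedigree.RelatednessMatrix | None = None
    dominance: pedigree.RelatednessMatrix | None = None
    h2_table: pd.DataFrame | None = None
    top_hits: pd.DataFrame | None = None


def run_pipeline(cfg: RunConfig, *, resume: bool = False) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    The manifest maps each stage to its status, output files and
    checksums.  With ``resume=True`` a stage whose outputs already exist
    under the same config digest is skipped (outputs are still loaded for
    downstream stages).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    digest = cfg.digest()
    previous = {}
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_digest") == digest:
            previous = old.get("stages", {})

    manifest: dict = {"config_digest": digest, "stages": {}}
    state = _RunState()

    def record(stage: str, outputs: list[Path], status: str = "ok") -> None:
        manifest["stages"][stage] = {
            "status": status,
            "outputs": [str(p) for p in outputs],
            "checksums": {p.name: _checksum(p) for p in outputs
                          if p.exists()},
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)

    def completed(stage: str) -> bool:
        prev = previous.get(stage)
        if not prev or prev.get("status") != "ok":
            return False
        return all(Path(p).exists() for p in prev["outputs"])

    stage = "<init>"
    try:
        for stage in STAGES:
            if stage not in cfg.stages:
                continue
            skip = completed(stage)
            _run_stage(stage, cfg, state, outdir, skip=skip)
            if skip:
                manifest["stages"][stage] = dict(previous[stage],
                                                 status="skipped(resume)")
                with open(manifest_path, "w") as fh:
                    json.dump(manifest, fh, indent=2)
            else:
                record(stage, _stage_outputs(stage, outdir))
    except Exception as exc:
        failed = stage  # noqa: F821 - bound by the loop
        manifest["stages"][failed] = {"status": f"failed: {exc}"}
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    return manifest


def _stage_outputs(stage: str, outdir: Path) -> list[Path]:
    patterns = {
        "simulate": ["pedigree.ped", "genotypes.vcf", "phenotypes.tsv",
                     "phenotypes.yaml", "truth.yaml"],
        "prepare": ["prepared.tsv"],
        "relatedness": ["kinship.tsv", "dominance.tsv"],
        "h2": ["heritability.tsv"],
        "decompose": ["decomposition.json"],
        "corr": ["correlations.tsv"],
        "gwas": ["gwas.tsv"],
        "conditional": ["conditional.json"],
        "thresholds": ["thresholds.json"],
    }
    return [outdir / name for name in patterns[stage]]


def _run_stage(stage: str, cfg: RunConfig, state: _RunState, outdir: Path,
               *, skip: bool) -> None:
    logger.info("stage %s%s", stage, " (resume: skipped)" if skip else "")
    loaders = {
        "simulate": _stage_simulate, "prepare": _stage_prepare,
        "relatedness": _stage_relatedness, "h2": _stage_h2,
        "decompose": _stage_decompose, "corr": _stage_corr,
        "gwas": _stage_gwas, "conditional": _stage_conditional,
        "thresholds": _stage_thresholds,
    }
    loaders[stage](cfg, state, outdir, skip)


def _load_inputs(cfg: RunConfig, state: _RunState, outdir: Path) -> None:
    if state.ped is None:
        path = cfg.pedigree_path or outdir / "pedigree.ped"
        state.ped = pedigree.parse_pedigree(path)
    if state.gmat is None:
        path = cfg.vcf_path or outdir / "genotypes.vcf"
        if Path(path).exists():
            state.gmat = genotypes.read_vcf(path)
    if state.traits is None:
        ppath = cfg.phenotype_path or outdir / "phenotypes.tsv"
        spath = cfg.phenotype_sidecar or outdir / "phenotypes.yaml"
        state.traits = phenotypes.read_trait_table(ppath, spath)


def _stage_simulate(cfg, state, outdir, skip) -> None:
    sim_cfg = _default_sim_config(cfg)
    ped = simulate.simulate_pedigree(sim_cfg)
    gmat = simulate.gene_drop_genotypes(ped, sim_cfg) \
        if (sim_cfg.variants or sim_cfg.enriched or sim_cfg.ld_blocks) \
        else None
    last_gen = max(simulate.generation_of(i) for i in ped.ids)
    subjects = [i for i in ped.ids
                if simulate.generation_of(i) >= last_gen - 1]
    traits, truth = simulate.simulate_lipidome(ped, gmat, sim_cfg, subjects)
    if not skip:
        pedigree.write_pedigree(ped, outdir / "pedigree.ped")
        if gmat is not None:
            genotypes.write_vcf(gmat, outdir / "genotypes.vcf")
        phenotypes.write_trait_table(traits, outdir / "phenotypes.tsv",
                                     outdir / "phenotypes.yaml")
        with open(outdir / "truth.yaml", "w") as fh:
            yaml.safe_dump(truth["traits"], fh)
    state.ped, state.traits = ped, traits
    if gmat is not None:
        state.gmat = gmat.subset_subjects(subjects)


def _stage_prepare(cfg, state, outdir, skip) -> None:
    _load_inputs(cfg, state, outdir)
    phenotypes.prepare_traits(state.traits)
    if not skip:
        state.traits.prepared.to_csv(outdir / "prepared.tsv", sep="\t",
                                     index_label="id")


def _stage_relatedness(cfg, state, outdir, skip) -> None:
    _load_inputs(cfg, state, outdir)
    subjects = state.traits.ids
    state.kinship = pedigree.kinship_matrix(state.ped, subjects)
    state.dominance = pedigree.dominance_matrix(state.ped, subjects)
    if not skip:
        state.kinship.write_tsv(outdir / "kinship.tsv")
        state.dominance.write_tsv(outdir / "dominance.tsv")


def _require(state: _RunState, cfg, outdir, *attrs) -> None:
    if state.traits is None or state.traits.prepared is None:
        _load_inputs(cfg, state, outdir)
        phenotypes.prepare_traits(state.traits)
    if "kinship" in attrs and state.kinship is None:
        subjects = state.traits.ids
        state.kinship = pedigree.kinship_matrix(state.ped, subjects)
        state.dominance = pedigree.dominance_matrix(state.ped, subjects)


def _adjustment_dosages(cfg, state) -> pd.DataFrame | None:
    if not cfg.adjustment_variants or state.gmat is None:
        return None
    found = [v for v in cfg.adjustment_variants
             if v in set(state.gmat.rsids)]
    if not found:
        return None
    sub = state.gmat.subset_variants(found)
    return pd.DataFrame(sub.dosages, index=state.traits.values.index,
                        columns=found)


def _stage_h2(cfg, state, outdir, skip) -> None:
    _require(state, cfg, outdir, "kinship")
    A = pedigree.RelatednessMatrix(state.kinship.ids,
                                   2 * state.kinship.values, "additive")
    adj = _adjustment_dosages(cfg, state)
    rows = []
    for trait in state.traits.traits:
        base = varcomp.VarCompModel(trait, [("additive", A)])
        fit = varcomp.fit_variance_components(base, state.traits)
        null = varcomp.fit_variance_components(
            varcomp.VarCompModel(trait, []), state.traits)
        _, p = varcomp.lrt_compare(null, fit)
        row = {"trait": trait, "h2": fit.lambdas["additive"], "h2_p": p}
        # adjusted model for traits nominally associated with any
        # adjustment variant
        if adj is not None:
            use = _nominal_adjustment_columns(trait, adj, state, cfg)
            if use:
                m_adj = varcomp.VarCompModel(trait, [("additive", A)],
                                             conditioning_dosages=adj[use])
                fit_adj = varcomp.fit_variance_components(m_adj, state.traits)
                row["h2_adjusted"] = fit_adj.lambdas["additive"]
                row["adjusted_for"] = ",".join(use)
            else:
                row["h2_adjusted"] = row["h2"]
                row["adjusted_for"] = ""
        rows.append(row)
    state.h2_table = pd.DataFrame(rows)
    if not skip:
        state.h2_table.to_csv(outdir / "heritability.tsv", sep="\t",
                              index=False)


def _nominal_adjustment_columns(trait, adj, state, cfg) -> list[str]:
    """Adjust a trait only when it is nominally associated with an
    enriched variant (single-variant LMM p below the nominal level)."""
    use = []
    for col in adj.columns:
        recs = gwas.association_scan(
            trait, state.gmat.subset_variants([col]), state.kinship,
            state.traits)
        if recs and np.isfinite(recs[0].p) \
                and recs[0].p < cfg.nominal_adjustment_p:
            use.append(col)
    return use


def _stage_decompose(cfg, state, outdir, skip) -> None:
    _require(state, cfg, outdir, "kinship")
    traits = state.traits
    A = pedigree.RelatednessMatrix(state.kinship.ids,
                                   2 * state.kinship.values, "additive")
    target_traits = traits.traits_in_class("TRAD") or traits.traits[:1]
    # candidate components: one covariance matrix per lipid class
    candidates = []
    for cls in sorted({c for c in traits.classes.values() if c != "TRAD"}):
        members = traits.traits_in_class(cls)
        if len(members) >= 2:
            block = traits.values[members].loc[traits.values.index]
            candidates.append((cls, genotypes.class_covariance(block)))
    results = {}
    for trait in target_traits:
        base = varcomp.VarCompModel(trait, [("additive", A)])
        sel = varcomp.sequential_component_selection(
            base, candidates, traits, alpha=cfg.alpha)
        results[trait] = {
            "selected": sel.selected,
            "lambdas": sel.final_fit.lambdas,
            "steps": sel.audit(),
        }
    if not skip:
        with open(outdir / "decomposition.json", "w") as fh:
            json.dump(results, fh, indent=2, default=float)


def _stage_corr(cfg, state, outdir, skip) -> None:
    _require(state, cfg, outdir, "kinship")
    traits = state.traits.traits
    pairs = [(traits[i], traits[j]) for i in range(len(traits))
             for j in range(i + 1, len(traits))]
    _, _, long = bivariate.correlation_matrices(state.traits, pairs,
                                                state.kinship)
    if not skip:
        long.to_csv(outdir / "correlations.tsv", sep="\t", index=False)


def _stage_gwas(cfg, state, outdir, skip) -> None:
    _require(state, cfg, outdir, "kinship")
    if state.gmat is None:
        raise ValueError("GWAS stage requires genotypes")
    filtered, _ = genotypes.variant_qc(
        state.gmat, genotypes.QcThresholds(cfg.qc_max_missing,
                                           cfg.qc_min_maf, cfg.qc_min_hwe_p))
    frames = []
    for trait in state.traits.traits:
        recs = gwas.association_scan(trait, filtered, state.kinship,
                                     state.traits)
        frames.append(gwas.records_to_frame(recs))
    table = pd.concat(frames, ignore_index=True)
    state.top_hits = table[table["skipped"] == ""]
    if not skip:
        table.to_csv(outdir / "gwas.tsv", sep="\t", index=False)


def _stage_conditional(cfg, state, outdir, skip) -> None:
    _require(state, cfg, outdir, "kinship")
    if state.top_hits is None or state.top_hits.empty:
        results = {}
    else:
        hits = state.top_hits[state.top_hits["p"] < cfg.base_gwas_level]
        results = {}
        for trait in hits["trait"].unique():
            sub = hits[hits["trait"] == trait]
            top = sub.loc[sub["p"].idxmin()]
            window = (str(top["chrom"]), int(top["pos"]) - 1_000_000,
                      int(top["pos"]) + 1_000_000)
            res = gwas.conditional_scan(
                trait, state.gmat, state.kinship, state.traits,
                region=window, alpha=cfg.base_gwas_level)
            results[trait] = res.signals
    if not skip:
        with open(outdir / "conditional.json", "w") as fh:
            json.dump(results, fh, indent=2)


def _stage_thresholds(cfg, state, outdir, skip) -> None:
    _require(state, cfg, outdir)
    try:
        th = gwas.multiple_testing_threshold(
            state.traits, variance_fraction=cfg.variance_fraction,
            base_level=cfg.base_gwas_level)
        payload = {
            "n_traits": th.n_traits, "pc_count": th.pc_count,
            "significance_threshold": th.significance_threshold,
            "suggestive_threshold": th.suggestive_threshold,
        }
    except ValueError as exc:
        payload = {"error": str(exc)}
    if not skip:
        with open(outdir / "thresholds.json", "w") as fh:
            json.dump(payload, fh, indent=2)
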