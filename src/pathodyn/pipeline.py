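"""End-to-end orchestration: synth -> fit -> pattern -> associates ->
enrichment -> drugs, from a single YAML config with one global seed.

Each stage reads the previous stage's TSV/GMT outputs from the run
directory and writes its own, so any stage can be re-run or resumed in
isolation; a JSON manifest records the config hash, per-stage seeds and
output paths.  Stage seeds are derived from the global seed by fixed
offsets so a single integer reproduces the whole run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .drug_matching import rank_drug_candidates
from .enrichment import celltype_enrichment, cluster_terms_kappa, ora_hypergeometric
from .fitting import ModelConfig, fit_subject
from .group_stats import FACTORS, factor_contributions, group_spatial_pattern
from .hemodynamics import HemoParams
from .neurodynamics import ThetaTriplet, WCParams
from .synthetic_data import (GroundTruth, generate_celltype_specificity,
                             generate_cohort, generate_connectome,
                             generate_drug_signature_library,
                             generate_expression_matrix,
                             generate_observed_falff, generate_term_sets)
from .transcriptomics import select_associates

__all__ = ["PipelineConfig", "RunManifest", "load_config", "run_pipeline"]

logger = logging.getLogger("pathodyn")

STAGES = ("synth", "fit", "pattern", "associates", "enrichment", "drugs")
# fixed per-stage seed offsets from the global seed
_SEED_OFFSETS = {s: 1000 + 17 * i for i, s in enumerate(STAGES)}


@dataclass
class SynthConfig:
    n_regions: int = 16
    density: float = 0.3
    n_cu: int = 6
    n_ad: int = 6
    theta_scale: float = 0.8
    noise_sd: float = 0.01
    n_genes: int = 500
    n_planted: int = 30
    planted_rho: float = 0.9
    n_celltypes: int = 8
    boost: float = 5.0
    n_terms: int = 30
    term_size: int = 40
    n_drugs: int = 40
    n_planted_up: int = 3
    n_planted_down: int = 3
    strength: float = 0.9
    target_factor: str = "interaction"


@dataclass
class FitConfig:
    budget: int = 300
    bound: float = 2.0   # symmetric box half-width per theta weight


@dataclass
class AssociatesConfig:
    n_boot: int = 2000
    level: float = 0.99


@dataclass
class EnrichmentConfig:
    n_boot: int = 2000
    kappa_threshold: float = 0.3
    alpha: float = 0.05


@dataclass
class DrugsConfig:
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    model: ModelConfig = field(default_factory=lambda: ModelConfig().small_test_profile())
    fit: FitConfig = field(default_factory=FitConfig)
    associates: AssociatesConfig = field(default_factory=AssociatesConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    drugs: DrugsConfig = field(default_factory=DrugsConfig)


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    outputs: dict[str, list[str]]
    package_version: str
    timestamps: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


_SECTION_TYPES = {
    "synth": SynthConfig,
    "fit": FitConfig,
    "associates": AssociatesConfig,
    "enrichment": EnrichmentConfig,
    "drugs": DrugsConfig,
}
_MODEL_SECTIONS = ("dynamics", "hemodynamics", "falff")


def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    cfg = PipelineConfig()
    allowed_top = {"seed", *_SECTION_TYPES, *_MODEL_SECTIONS}
    unknown = set(raw) - allowed_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            block = raw[section] or {}
            valid = set(cls.__dataclass_fields__)
            bad = set(block) - valid
            if bad:
                raise ValueError(f"unknown keys in '{section}': {sorted(bad)}")
            setattr(cfg, section, replace(getattr(cfg, section), **block))
    model = cfg.model
    if "dynamics" in raw:
        block = dict(raw["dynamics"] or {})
        sim_keys = {"dt", "duration", "burn_in", "tr", "sim_seed",
                    "input_amplitude", "input_components"}
        wc_updates = {k: v for k, v in block.items()
                      if k in WCParams.__dataclass_fields__}
        sim_updates = {k: v for k, v in block.items() if k in sim_keys}
        bad = set(block) - set(wc_updates) - sim_keys
        if bad:
            raise ValueError(f"unknown keys in 'dynamics': {sorted(bad)}")
        model = replace(model, wc=replace(model.wc, **wc_updates), **sim_updates)
    if "hemodynamics" in raw:
        block = dict(raw["hemodynamics"] or {})
        bad = set(block) - set(HemoParams.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown keys in 'hemodynamics': {sorted(bad)}")
        model = replace(model, hemo=replace(model.hemo, **block))
    if "falff" in raw:
        block = dict(raw["falff"] or {})
        if set(block) - {"mode"}:
            raise ValueError("unknown keys in 'falff'")
        if "mode" in block:
            model = replace(model, falff_mode=block["mode"])
    cfg.model = model
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_synth(cfg: PipelineConfig, outdir: Path, seed: int) -> list[Path]:
    s = cfg.synth
    conn = generate_connectome(s.n_regions, s.density, seed=seed)
    cohort, truth = generate_cohort(conn, n_cu=s.n_cu, n_ad=s.n_ad,
                                    theta_scale=s.theta_scale, seed=seed + 1)
    cohort = generate_observed_falff(cohort, conn, cfg.model,
                                     noise_sd=s.noise_sd, seed=seed + 2)

    # ground-truth alteration pattern (from the true thetas) used as the
    # spatial target for the planted expression subset
    from .fitting import subject_profile
    contrib = {f: [] for f in FACTORS}
    groups = []
    for rec in cohort:
        c, _ = factor_contributions(ThetaTriplet(*rec.true_thetas),
                                    subject_profile(rec), cfg.model.wc.theta0)
        for f in FACTORS:
            contrib[f].append(c[f])
        groups.append(rec.group)
    target = group_spatial_pattern(np.array(contrib[s.target_factor]),
                                   np.array(groups), s.target_factor).z

    X, gene_ids, planted = generate_expression_matrix(
        s.n_genes, s.n_regions, target, s.n_planted, s.planted_rho,
        seed=seed + 3)
    truth.planted_genes = planted

    spec, spec_genes, celltypes = generate_celltype_specificity(
        s.n_genes, s.n_celltypes, planted, celltype_id(0), boost=s.boost,
        seed=seed + 4)
    truth.planted_celltypes = [celltype_id(0)]

    terms = generate_term_sets(gene_ids, planted, n_terms=s.n_terms,
                               term_size=s.term_size, seed=seed + 5)

    up = [f"D{d:03d}" for d in range(s.n_planted_up)]
    down = [f"D{d:03d}" for d in range(s.n_planted_up,
                                       s.n_planted_up + s.n_planted_down)]
    library = generate_drug_signature_library(
        gene_ids, s.n_drugs, up, down, planted, strength=s.strength,
        seed=seed + 6)
    truth.planted_drugs = {**{d: "up" for d in up}, **{d: "down" for d in down}}

    io.write_connectome(conn, outdir / "connectome.tsv")
    io.write_cohort(cohort, conn.labels, outdir / "cohort.tsv")
    io.write_matrix_tsv(X, gene_ids, conn.labels, outdir / "expression.tsv",
                        index_label="gene")
    io.write_matrix_tsv(spec, spec_genes, celltypes, outdir / "specificity.tsv",
                        index_label="gene")
    io.write_gmt(terms, outdir / "ontology.gmt")
    io.write_drug_signatures(library, outdir / "drug_signatures.tsv")
    truth.to_json(outdir / "truth.json")
    return [outdir / n for n in ("connectome.tsv", "cohort.tsv",
                                 "expression.tsv", "specificity.tsv",
                                 "ontology.gmt", "drug_signatures.tsv",
                                 "truth.json")]


def celltype_id(i: int) -> str:
    return f"CT{i:02d}"


def _stage_fit(cfg: PipelineConfig, outdir: Path, seed: int) -> list[Path]:
    conn = io.read_connectome(outdir / "connectome.tsv")
    cohort, _ = io.read_cohort(outdir / "cohort.tsv")
    b = cfg.fit.bound
    rows = []
    for i, rec in enumerate(cohort):
        t0 = time.time()
        est = fit_subject(rec, conn, cfg.model, bounds=((-b, b),) * 3,
                          budget=cfg.fit.budget, seed=seed + i)
        logger.info("fit %s: objective %.4f (%d evals, %.1f s)",
                    rec.subject_id, est.objective_value, est.n_evaluations,
                    time.time() - t0)
        rows.append((rec.subject_id, rec.group, est.thetas.theta_abeta,
                     est.thetas.theta_tau, est.thetas.theta_interaction,
                     est.objective_value, est.n_evaluations, est.seed))
    pd.DataFrame(rows, columns=["subject", "group", "theta_abeta", "theta_tau",
                                "theta_interaction", "objective", "n_eval",
                                "seed"]).to_csv(outdir / "thetas.tsv",
                                                sep="\t", index=False)
    return [outdir / "thetas.tsv"]


def _stage_pattern(cfg: PipelineConfig, outdir: Path, seed: int) -> list[Path]:
    from .fitting import subject_profile
    conn = io.read_connectome(outdir / "connectome.tsv")
    cohort, labels = io.read_cohort(outdir / "cohort.tsv")
    thetas = pd.read_csv(outdir / "thetas.tsv", sep="\t").set_index("subject")
    contrib = {f: [] for f in FACTORS}
    groups = []
    for rec in cohort:
        row = thetas.loc[rec.subject_id]
        triplet = ThetaTriplet(row["theta_abeta"], row["theta_tau"],
                               row["theta_interaction"])
        c, _ = factor_contributions(triplet, subject_profile(rec),
                                    cfg.model.wc.theta0)
        for f in FACTORS:
            contrib[f].append(c[f])
        groups.append(rec.group)
    out = {}
    for f in FACTORS:
        pat = group_spatial_pattern(np.array(contrib[f]), np.array(groups), f)
        out[f"z_{f}"] = pat.z
        out[f"p_{f}"] = pat.p
    pd.DataFrame(out, index=pd.Index(labels, name="region")).to_csv(
        outdir / "patterns.tsv", sep="\t")
    return [outdir / "patterns.tsv"]


def _stage_associates(cfg: PipelineConfig, outdir: Path, seed: int) -> list[Path]:
    patterns = pd.read_csv(outdir / "patterns.tsv", sep="\t", index_col=0)
    expr = io.read_matrix_tsv(outdir / "expression.tsv")
    paths = []
    gmt: dict[str, list[str]] = {}
    for i, f in enumerate(FACTORS):
        assoc = select_associates(patterns[f"z_{f}"].to_numpy(float),
                                  expr.to_numpy(float), list(expr.index),
                                  n_boot=cfg.associates.n_boot,
                                  level=cfg.associates.level, seed=seed + i)
        df = pd.DataFrame([asdict(a) for a in assoc])
        path = outdir / f"associates_{f}.tsv"
        df.to_csv(path, sep="\t", index=False)
        gmt[f"{f}_associates"] = [a.gene for a in assoc if a.selected]
        paths.append(path)
    io.write_gmt(gmt, outdir / "associates.gmt")
    paths.append(outdir / "associates.gmt")
    return paths


def _stage_enrichment(cfg: PipelineConfig, outdir: Path, seed: int) -> list[Path]:
    expr = io.read_matrix_tsv(outdir / "expression.tsv")
    background = set(expr.index)
    terms = io.read_gmt(outdir / "ontology.gmt")
    assoc_sets = io.read_gmt(outdir / "associates.gmt")
    spec = io.read_matrix_tsv(outdir / "specificity.tsv")
    ora_rows, ct_rows = [], []
    for fname, genes in assoc_sets.items():
        query = set(genes) & background
        if not query:
            logger.warning("empty associate set %s; skipping enrichment", fname)
            continue
        enriched = ora_hypergeometric(query, terms, background)
        significant = [t for t in enriched if t.q < cfg.enrichment.alpha]
        if significant:
            cluster_terms_kappa(significant, query,
                                threshold=cfg.enrichment.kappa_threshold)
        for t in enriched:
            ora_rows.append((fname, t.term, t.overlap, t.term_size,
                             t.query_size, t.background_size, t.p, t.q,
                             t.cluster, t.is_representative))
        for r in celltype_enrichment(query, spec, n_boot=cfg.enrichment.n_boot,
                                     seed=seed):
            ct_rows.append((fname, r.celltype, r.observed, r.boot_mean,
                            r.boot_sd, r.delta, r.p, r.q))
    pd.DataFrame(ora_rows, columns=["query", "term", "k", "K", "n", "N", "p",
                                    "q", "cluster", "representative"]
                 ).to_csv(outdir / "ora.tsv", sep="\t", index=False)
    pd.DataFrame(ct_rows, columns=["query", "celltype", "observed",
                                   "boot_mean", "boot_sd", "delta", "p", "q"]
                 ).to_csv(outdir / "celltypes.tsv", sep="\t", index=False)
    return [outdir / "ora.tsv", outdir / "celltypes.tsv"]


def _stage_drugs(cfg: PipelineConfig, outdir: Path, seed: int) -> list[Path]:
    library = io.read_drug_signatures(outdir / "drug_signatures.tsv")
    assoc_sets = io.read_gmt(outdir / "associates.gmt")
    rows = []
    for fname, genes in assoc_sets.items():
        if not genes:
            continue
        for s in rank_drug_candidates(set(genes), library,
                                      alpha=cfg.drugs.alpha):
            rows.append((fname, s.drug, s.u, s.z, s.p, s.q, s.direction))
    pd.DataFrame(rows, columns=["query", "drug", "U", "z", "p", "q",
                                "direction"]).to_csv(outdir / "drugs.tsv",
                                                     sep="\t", index=False)
    return [outdir / "drugs.tsv"]


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "fit": _stage_fit,
    "pattern": _stage_pattern,
    "associates": _stage_associates,
    "enrichment": _stage_enrichment,
    "drugs": _stage_drugs,
}

_STAGE_OUTPUTS = {
    "synth": ["connectome.tsv", "cohort.tsv", "expression.tsv",
              "specificity.tsv", "ontology.gmt", "drug_signatures.tsv",
              "truth.json"],
    "fit": ["thetas.tsv"],
    "pattern": ["patterns.tsv"],
    "associates": [f"associates_{f}.tsv" for f in FACTORS] + ["associates.gmt"],
    "enrichment": ["ora.tsv", "celltypes.tsv"],
    "drugs": ["drugs.tsv"],
}


def run_pipeline(config: PipelineConfig | str | Path, outdir,
                 stages: tuple[str, ...] = STAGES,
                 resume: bool = False) -> RunManifest:
    """Execute the requested stages in dependency order.

    With ``resume``, a stage whose outputs all exist is skipped.  Returns
    the run manifest (also written to ``outdir/manifest.json``).
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {s: config.seed + _SEED_OFFSETS[s] for s in STAGES}
    manifest = RunManifest(config_hash=_config_hash(config), seeds=seeds,
                           outputs={}, package_version=_version())
    for stage in stages:
        expected = [outdir / n for n in _STAGE_OUTPUTS[stage]]
        if resume and all(p.exists() for p in expected):
            logger.info("stage %s: outputs exist, skipping (resume)", stage)
            manifest.outputs[stage] = [str(p) for p in expected]
            continue
        t0 = time.time()
        produced = _STAGE_FUNCS[stage](config, outdir, seeds[stage])
        logger.info("stage %s finished in %.1f s", stage, time.time() - t0)
        manifest.outputs[stage] = [str(p) for p in produced]
        manifest.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")
    for stage, paths in manifest.outputs.items():
        for p in paths:
            if not Path(p).exists():
                raise RuntimeError(f"stage {stage} output missing: {p}")
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("pathodyn")
    except PackageNotFoundError:
        return "unknown"
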