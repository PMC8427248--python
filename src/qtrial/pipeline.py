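"""End-to-end pipeline: ingest or simulate, then ANOVA, genetic parameters,
mean separation and the multivariate suite, written as a reproducible
report bundle.

Outputs (all CSV unless noted) in the configured directory:

* ``anova_fvalues.csv``      per-trait F and p for genotype, environment, G x E
* ``anova_<layout>.csv``     full sources-of-variation tables, long form
* ``means.csv``              genotype means, SDs and LSD letters per trait,
                             with grand-mean / LSD / CV footer rows
* ``genetics.csv``           variance components, h2, GCV/PCV, GA/GAM
* ``correlation_r.csv`` / ``correlation_p.csv``
* ``pca_loadings.csv``       loadings plus eigenvalue / variability /
                             cumulative footer rows
* ``pca_scores.csv``         genotype scores
* ``clusters.csv`` / ``dendrogram.nwk``
* ``manifest.json``          seed, config hash, library versions

The bundle is byte-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import combined_anova, mean_separation, rcbd_anova
from .genetics import DEFAULT_SELECTION_INTENSITY, genetic_summary
from .multivariate import correlation_matrix, hierarchical_cluster, important_traits, pca
from .synthetic import MultiTraitSpec, TrialDesign, VarianceSpec, simulate_multitrait
from .trial_core import TrialTable, TrialDataError, genotype_mean_table

log = logging.getLogger("qtrial")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """All pipeline tunables; defaults follow common variety-trial practice
    (alpha = 0.05, selection intensity 2.06 at 5 %, |loading| > 0.3,
    k = 3 clusters, combined-analysis effective replication)."""

    input: str | None = None            # trial CSV; mutually exclusive with simulate
    simulate: dict | None = None        # {design: {g,e,r}, traits: {name: {mu,var_g,...}}, correlation: [[...]]}
    out: str = "qtrial_out"
    seed: int = 0
    alpha: float = 0.05
    selection_intensity: float = DEFAULT_SELECTION_INTENSITY
    r_policy: str = "combined"
    genotype_denominator: str = "pooled"
    sd_basis: str = "plots"
    loading_threshold: float = 0.3
    k_clusters: int = 3
    standardize_cluster: bool = True
    traits: list[str] | None = None     # restrict analysis to these traits

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _spec_from_config(sim: dict, seed: int) -> tuple[TrialDesign, MultiTraitSpec]:
    d = sim.get("design", {})
    design = TrialDesign(g=int(d.get("g", 17)), e=int(d.get("e", 3)),
                         r=int(d.get("r", 3)), seed=seed)
    traits = sim.get("traits")
    if traits:
        specs = {name: VarianceSpec(**kw) for name, kw in traits.items()}
        corr = sim.get("correlation")
        corr = np.asarray(corr, dtype=float) if corr is not None else None
        spec = MultiTraitSpec(specs=specs, genetic_correlation=corr)
    else:
        from .synthetic import cowpea_like_spec

        spec = cowpea_like_spec()
    return design, spec


def load_or_simulate(cfg: PipelineConfig) -> TrialTable:
    if cfg.input and cfg.simulate:
        raise ValueError("config must give either 'input' or 'simulate', not both")
    if cfg.input:
        table = TrialTable.from_csv(cfg.input)
    elif cfg.simulate is not None:
        design, spec = _spec_from_config(cfg.simulate, cfg.seed)
        table = simulate_multitrait(design, spec)
    else:
        raise ValueError("config must give an 'input' path or a 'simulate' block")
    if cfg.traits:
        missing = [t for t in cfg.traits if t not in table.traits]
        if missing:
            raise TrialDataError(f"configured trait column(s) not in data: {missing}")
        table = TrialTable(table.data[table.data["trait"].isin(cfg.traits)])
    return table


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format=_FLOAT_FMT, **kw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    t0 = time.perf_counter()
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    table = load_or_simulate(cfg)
    g, e, r = table.design_counts
    log.info("trial loaded: g=%d e=%d r=%d traits=%d", g, e, r, len(table.traits))
    outputs: list[str] = []

    def record(name: str) -> Path:
        outputs.append(name)
        return out / name

    # -- ANOVA ---------------------------------------------------------------
    stage = time.perf_counter()
    long_rows, fvals = [], []
    for trait in table.traits:
        if e >= 2:
            aov = combined_anova(table, trait, genotype_denominator=cfg.genotype_denominator)
        else:
            aov = rcbd_anova(table, trait, table.environments[0])
        tab = aov.table.reset_index(names="source")
        tab.insert(0, "trait", trait)
        long_rows.append(tab)
        row = {"trait": trait,
               "F_G": aov.table.loc["genotype", "F"],
               "p_G": aov.table.loc["genotype", "p"]}
        if e >= 2:
            row.update(
                F_E=aov.table.loc["environment", "F"],
                p_E=aov.table.loc["environment", "p"],
                F_GxE=aov.table.loc["genotype x environment", "F"],
                p_GxE=aov.table.loc["genotype x environment", "p"],
            )
        fvals.append(row)
    layout = "combined" if e >= 2 else "single"
    _write(pd.concat(long_rows, ignore_index=True), record(f"anova_{layout}.csv"), index=False)
    _write(pd.DataFrame(fvals), record("anova_fvalues.csv"), index=False)
    log.info("anova stage done in %.2fs", time.perf_counter() - stage)

    # -- means with LSD separation -------------------------------------------
    stage = time.perf_counter()
    mtab = genotype_mean_table(table, sd_basis=cfg.sd_basis)
    blocks = {}
    footer = {}
    for trait in table.traits:
        sep = mean_separation(
            table, trait, alpha=cfg.alpha, sd_basis=cfg.sd_basis,
            genotype_denominator=cfg.genotype_denominator,
        )
        blocks[(trait, "mean")] = sep.means
        blocks[(trait, "sd")] = sep.sds
        blocks[(trait, "letters")] = pd.Series(sep.letters)
        footer[trait] = {"grand_mean": sep.grand_mean,
                         f"LSD({cfg.alpha:g})": sep.lsd, "CV%": sep.cv}
    means_df = pd.DataFrame(blocks)
    foot = pd.DataFrame(footer)
    foot.columns = pd.MultiIndex.from_product([foot.columns, ["mean"]])
    _write(pd.concat([means_df, foot]), record("means.csv"))
    log.info("means stage done in %.2fs", time.perf_counter() - stage)

    # -- genetic parameters ----------------------------------------------------
    stage = time.perf_counter()
    summary = genetic_summary(
        table, i=cfg.selection_intensity, r_policy=cfg.r_policy,
        genotype_denominator=cfg.genotype_denominator, annotate=True,
    )
    _write(summary, record("genetics.csv"), index_label="trait")
    log.info("genetics stage done in %.2fs", time.perf_counter() - stage)

    # -- multivariate ----------------------------------------------------------
    stage = time.perf_counter()
    if len(table.traits) >= 2 and g >= 3:
        corr = correlation_matrix(mtab)
        _write(corr.r, record("correlation_r.csv"), index_label="trait")
        _write(corr.p, record("correlation_p.csv"), index_label="trait")

        pc = pca(mtab)
        load = pc.loadings.copy()
        load.loc["Eigenvalue"] = pc.eigenvalues
        load.loc["Variability (%)"] = pc.variability_pct
        load.loc["Cumulative (%)"] = pc.cumulative_pct
        _write(load, record("pca_loadings.csv"), index_label="trait")
        _write(pc.scores, record("pca_scores.csv"), index_label="genotype")
        flags = important_traits(pc, threshold=cfg.loading_threshold)
        _write(flags, record("pca_important.csv"), index_label="trait")

        clus = hierarchical_cluster(mtab, k=min(cfg.k_clusters, g),
                                    standardize=cfg.standardize_cluster)
        _write(clus.assignments.to_frame(), record("clusters.csv"), index_label="genotype")
        nwk = record("dendrogram.nwk")
        nwk.write_text(clus.to_newick() + "\n")
    log.info("multivariate stage done in %.2fs", time.perf_counter() - stage)

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "qtrial_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "design": {"g": g, "e": e, "r": r},
        "traits": list(table.traits),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return manifest
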