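"""End-to-end orchestration: simulate-or-load, preprocess, estimate the
GGM, extract the focal neighborhood, compare strata, fit covariate models.

Every run is driven by a :class:`PipelineConfig` (YAML-loadable), uses a
single integer seed for all randomness, and writes plain-text artifacts plus
a JSON manifest.  With deterministic imputation, two runs with the same
config produce byte-identical outputs, so the manifest carries no wall-clock
fields.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as unio
from . import __version__
from .containers import AbundanceMatrix, CovariateTable
from .effects import effects_table, family_threshold, fit_effects, flag_significance
from .network import build_graph, edge_table, k_neighborhood, write_graphml
from .pcor import bh_fdr, partial_correlation_matrix
from .preprocess import drop_duplicates, filter_missingness, impute, log_transform, runday_normalize
from .strata import compare_all_pairs, stratified_pcor
from .synthetic import CovariateSpec, SyntheticCohort, edge_recovery_metrics, generate_cohort, generate_truth

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def _default_effects() -> dict:
    # planted covariate effects on the natural-log scale; the medication
    # effect on the xanthine analogue and the sex effect on the urate
    # analogue mirror the magnitudes the covariate models should detect
    return {
        (0, "sex"): -0.206,
        (0, "age"): 0.004,
        (1, "medication"): -0.896,
        (1, "sex"): 0.059,
        (2, "snp1"): 0.20,
    }


@dataclass
class SimulationParams:
    """Cohort-scale defaults: 1,764 samples, 40 metabolites plus one
    duplicate analyte at Pearson r = 0.60 to its source, sparse planted
    partial correlations of magnitude 0.2-0.4 (expected edge count ~58),
    20 measurement days, 10 % missing cells."""

    n: int = 1764
    p: int = 40
    edge_density: float = 0.075
    pcor_low: float = 0.2
    pcor_high: float = 0.4
    n_rundays: int = 20
    runday_effect_sd: float = 0.1
    missing_rate: float = 0.10
    duplicate_source: int = 1
    duplicate_r: float = 0.60
    missing_mechanism: str = "mcar"
    covariate_effects: dict = field(default_factory=_default_effects)

    def metabolite_ids(self) -> list[str]:
        ids = [f"met{j:03d}" for j in range(self.p)]
        ids[0] = "urate"
        ids[1] = "xanthine"
        return ids


@dataclass
class PipelineConfig:
    outdir: str | Path = "uratenet_run"
    seed: int = 0
    # exactly one of (input paths, simulation) must be set
    input_abundance: str | None = None
    input_covariates: str | None = None
    simulation: SimulationParams | None = None

    focal_metabolite: str = "urate"
    neighborhood_k: int = 3
    fdr_q: float = 0.05
    fdr_method: str = "bh"
    duplicate_ids: list[str] = field(default_factory=list)
    stratum_column: str = "sex"
    alpha: float = 0.05
    metabolite_missing_threshold: float = 0.20
    sample_missing_threshold: float = 0.10
    impute_iterations: int = 10
    impute_deterministic: bool = False
    adjust_df: bool = True
    condition_on_snps: bool = True

    def __post_init__(self) -> None:
        has_paths = self.input_abundance is not None or self.input_covariates is not None
        if has_paths and self.simulation is not None:
            raise ConfigError("give either input paths or simulation "
                              "parameters, not both")
        if not has_paths and self.simulation is None:
            raise ConfigError("one of input paths or simulation parameters "
                              "is required")
        if has_paths and (self.input_abundance is None or self.input_covariates is None):
            raise ConfigError("both input_abundance and input_covariates "
                              "paths are required")
        for name in ("fdr_q", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must be in (0,1), got {v}")
        if self.neighborhood_k < 0:
            raise ConfigError(f"neighborhood_k must be >= 0, got {self.neighborhood_k}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            effects = sim.pop("covariate_effects", None)
            sim = SimulationParams(**sim)
            if effects is not None:
                sim.covariate_effects = {
                    (int(k.split(",")[0]), k.split(",")[1]): float(v)
                    for k, v in effects.items()}
        return cls(simulation=sim, **raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)
    fdr_cutoff: float | None = None
    n_edges: int = 0
    neighborhood_nodes: int = 0
    neighborhood_edges: int = 0
    recovery: dict | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True,
                          default=str) + "\n"


def simulate_cohort(params: SimulationParams, seed: int) -> SyntheticCohort:
    """Generate the configured synthetic cohort (truth seed and cohort seed
    are both derived from the single pipeline seed)."""
    truth = generate_truth(params.p, params.edge_density,
                           (params.pcor_low, params.pcor_high), seed=seed,
                           covariate_effects=params.covariate_effects,
                           duplicate_spec=(params.duplicate_source,
                                           params.duplicate_r))
    return generate_cohort(truth, params.n, CovariateSpec(),
                           n_rundays=params.n_rundays,
                           runday_effect_sd=params.runday_effect_sd,
                           missing_rate=params.missing_rate,
                           seed=seed + 1,
                           missing_mechanism=params.missing_mechanism,
                           metabolite_ids=params.metabolite_ids())


def preprocess_chain(raw: AbundanceMatrix, config: PipelineConfig,
                     duplicate_ids: list[str]):
    """normalize -> filter -> log -> impute -> drop duplicates."""
    norm = runday_normalize(raw)
    filtered, report = filter_missingness(norm,
                                          config.metabolite_missing_threshold,
                                          config.sample_missing_threshold)
    logged = log_transform(filtered)
    imputed = impute(logged, n_iterations=config.impute_iterations,
                     seed=config.seed + 2,
                     deterministic=config.impute_deterministic)
    present = [d for d in duplicate_ids if d in imputed.metabolite_ids]
    deduped = drop_duplicates(imputed, present)
    return deduped, report


def run_pipeline(config: PipelineConfig) -> RunManifest:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_dict(config), version=__version__)

    # --- obtain cohort -------------------------------------------------
    cohort = None
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation, config.seed)
        raw, covariates = cohort.abundance, cohort.covariates
        duplicate_ids = list(config.duplicate_ids)
        if cohort.duplicate_id and cohort.duplicate_id not in duplicate_ids:
            duplicate_ids.append(cohort.duplicate_id)
        unio.write_abundance_tsv(raw, outdir / "abundance_raw.tsv")
        unio.write_covariates_tsv(covariates, outdir / "covariates.tsv")
        unio.write_truth_json(cohort.truth, outdir / "truth.json")
    else:
        raw = unio.read_abundance_tsv(config.input_abundance)
        covariates = unio.read_covariates_tsv(config.input_covariates)
        duplicate_ids = list(config.duplicate_ids)
    manifest.stages["raw"] = {"n": raw.n_samples, "p": raw.n_metabolites}

    # --- preprocessing -------------------------------------------------
    data, report = preprocess_chain(raw, config, duplicate_ids)
    covariates = covariates.aligned_to(data.sample_ids)
    (outdir / "filter_report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True) + "\n")
    unio.write_abundance_tsv(data, outdir / "abundance_processed.tsv")
    manifest.stages["processed"] = {"n": data.n_samples, "p": data.n_metabolites}

    # --- pooled GGM ----------------------------------------------------
    cond = covariates.conditioning_frame(include=("age", "sex"),
                                         include_snps=config.condition_on_snps)
    pcor = partial_correlation_matrix(data, cond, adjust_df=config.adjust_df)
    decision = bh_fdr(pcor, q=config.fdr_q, method=config.fdr_method)
    unio.write_pcor_result(pcor, decision, outdir)
    manifest.fdr_cutoff = decision.data_driven_cutoff

    graph = build_graph(pcor, decision)
    manifest.n_edges = graph.number_of_edges()
    write_graphml(graph, outdir / "network.graphml")
    edge_table(graph, pcor).to_csv(outdir / "network_edges.tsv", sep="\t",
                                   index=False)

    # --- focal neighborhood -------------------------------------------
    hood = k_neighborhood(graph, config.focal_metabolite, config.neighborhood_k)
    manifest.neighborhood_nodes = hood.number_of_nodes()
    manifest.neighborhood_edges = hood.number_of_edges()
    write_graphml(hood, outdir / "neighborhood.graphml")
    edge_table(hood, pcor).to_csv(outdir / "neighborhood_edges.tsv", sep="\t",
                                  index=False)
    logger.info("network: %d edges; %d-neighborhood of %s: %d nodes, %d edges",
                manifest.n_edges, config.neighborhood_k,
                config.focal_metabolite, manifest.neighborhood_nodes,
                manifest.neighborhood_edges)

    # --- sex-stratified comparison ------------------------------------
    strata = stratified_pcor(data, covariates, config.stratum_column,
                             adjust_df=config.adjust_df)
    hood_edges = [tuple(sorted(e)) for e in hood.edges]
    rename = ({f"r_0": "r_male", f"r_1": "r_female"}
              if config.stratum_column == "sex" else {})
    if hood_edges:
        net_cmp = compare_all_pairs(strata, family="network_edges",
                                    alpha=config.alpha,
                                    network_edges=hood_edges,
                                    adjust_df=config.adjust_df)
        net_cmp.rename(columns=rename).to_csv(
            outdir / "sex_differences_network.tsv", sep="\t", index=False)
        manifest.stages["sex_differences_network"] = {
            "m": net_cmp.attrs["m"], "threshold": net_cmp.attrs["threshold"],
            "n_significant": int(net_cmp["significant"].sum())}
    glob_cmp = compare_all_pairs(strata, family="all_pairs",
                                 alpha=config.alpha,
                                 adjust_df=config.adjust_df)
    glob_cmp.rename(columns=rename).to_csv(
        outdir / "sex_differences_global.tsv", sep="\t", index=False)
    manifest.stages["sex_differences_global"] = {
        "m": glob_cmp.attrs["m"], "threshold": glob_cmp.attrs["threshold"],
        "n_significant": int(glob_cmp["significant"].sum())}

    # --- covariate effect models on network metabolites ----------------
    net_metabolites = sorted(hood.nodes)
    thr = family_threshold(len(net_metabolites), 2, config.alpha)
    est = flag_significance(fit_effects(data, covariates, net_metabolites),
                            thr)
    eff = effects_table(est)
    eff.to_csv(outdir / "effects.tsv", sep="\t")
    manifest.stages["effects"] = {
        "n_metabolites": len(net_metabolites), "threshold": thr,
        "n_significant": int(sum(e.significant for e in est))}

    # --- recovery scoring (simulated runs only) -------------------------
    if cohort is not None:
        index_of = {mid: cohort.metabolite_index[mid]
                    for mid in data.metabolite_ids}
        rec = edge_recovery_metrics(graph, cohort.truth, index_of)
        manifest.recovery = {"tpr": rec.tpr, "fdp": rec.fdp,
                             "n_planted": rec.n_planted,
                             "n_recovered": rec.n_recovered}
        (outdir / "recovery.json").write_text(
            json.dumps(manifest.recovery, indent=1, sort_keys=True) + "\n")

    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["outdir"] = str(d["outdir"])
    sim = d.get("simulation")
    if sim is not None:
        sim["covariate_effects"] = {f"{j},{c}": v for (j, c), v in
                                    sim["covariate_effects"].items()}
    return d
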