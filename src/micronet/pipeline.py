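"""End-to-end orchestration: ingest or simulate counts, filter, correlate,
select the RMT threshold, build the network, detect modules, classify node
roles, associate modules with the trait, and write every artifact.

All configuration lives in a :class:`PipelineConfig` (YAML-loadable); every
stochastic stage derives its stream from the single ``seed`` so a config
reproduces its artifact directory byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import preprocess, rmt, network, topology, traits as traits_mod
from .synthetic import SyntheticParams, generate_community

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for malformed or inconsistent pipeline configuration."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults follow the emulated study
    (50% prevalence cutoff, role cutoffs Zi 2.5 / Pi 0.62)."""

    otu_table: str | None = None       # path; None -> simulate
    otu_dialect: str = "tsv"
    trait_table: str | None = None
    synthetic: dict = field(default_factory=dict)
    prevalence: float = 0.5
    pseudocount: float = 1e-6
    log_transform: bool = True
    s_min: float = 0.30
    s_max: float = 0.99
    s_step: float = 0.01
    rmt_alpha: float = 0.05
    min_nodes: int = 30
    z_cut: float = 2.5
    p_cut: float = 0.62
    n_perm: int = 999
    seed: int = 0
    out_dir: str = "micronet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("otu_table", "trait_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        if not 0 <= self.prevalence <= 1:
            raise ConfigError("prevalence must be in [0, 1]")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s ...", name)
                return fn(*args, **kwargs)
            except (ConfigError, StageError):
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the artifact directory.

    Artifacts (all deterministic given the seed): filtered OTU table,
    similarity matrix CSV, RMT scan CSV, GraphML + edge list, node-role
    CSV, module-trait CSV, Mantel report, and a JSON run manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table, trait_tab = _load_inputs(config)
    logger.info("input: %d OTUs x %d samples", table.n_otus, table.n_samples)

    filtered = _stage("prevalence_filter")(preprocess.prevalence_filter)(
        table, config.prevalence)
    mio.write_otu_table(filtered, out / "filtered_otu_table.tsv")
    logger.info("prevalence filter kept %d / %d OTUs", filtered.n_otus, table.n_otus)

    abund = _stage("relative_abundance")(preprocess.relative_abundance)(filtered)
    corr_input = _stage("log_transform")(preprocess.log_transform)(
        abund, config.pseudocount) if config.log_transform else abund

    # drop zero-variance profiles before correlating
    sd = corr_input.values.std(axis=1)
    keep = np.flatnonzero(sd > 0)
    corr_input = preprocess.AbundanceMatrix(
        [corr_input.otu_ids[i] for i in keep], list(corr_input.sample_ids),
        corr_input.values[keep], log_transformed=corr_input.log_transformed)

    sim = _stage("pearson_similarity")(rmt.pearson_similarity)(corr_input)
    pd.DataFrame(sim.signed, index=sim.otu_ids, columns=sim.otu_ids).to_csv(
        out / "similarity_matrix.csv")

    scan = _stage("rmt_threshold_scan")(rmt.rmt_threshold_scan)(
        sim, s_min=config.s_min, s_max=config.s_max, step=config.s_step,
        alpha=config.rmt_alpha, min_nodes=config.min_nodes)
    scan.scan.to_csv(out / "rmt_scan.csv", index=False)
    logger.info("RMT threshold s* = %.2f", scan.threshold)

    net = _stage("build_network")(network.build_network)(sim, scan.threshold)
    part = _stage("fast_greedy_modules")(network.fast_greedy_modules)(net)
    logger.info("network: %d nodes, %d edges, %d modules, Q = %.3f",
                net.number_of_nodes(), net.number_of_edges(), part.n_modules, part.q)

    phylum_of = {oid: mio.parse_lineage(lin).phylum
                 for oid, lin in zip(filtered.otu_ids, filtered.lineages)}
    topo = _stage("node_topology")(topology.node_topology)(
        net, part, z_cut=config.z_cut, p_cut=config.p_cut, phylum_of=phylum_of)
    topo.to_csv(out / "node_roles.csv", index=False)

    mio.write_network_graphml(net, topo, part.labels, out / "network.graphml")
    mio.write_edge_list(net, out / "edges.tsv")

    summary = network.network_summary(net, part)

    if trait_tab is not None:
        trait = trait_tab.aligned_to(abund.sample_ids)
        full_abund = abund  # module-trait analysis on relative abundance
        results = _stage("module_trait_correlation")(
            traits_mod.module_trait_correlation)(full_abund, part, trait)
        pd.DataFrame([{"module": r.module, "size": r.size, "r": r.r, "p": r.p,
                       "variance_explained": r.variance_explained}
                      for r in results]).to_csv(out / "module_trait.csv", index=False)
        mantel = _stage("mantel_test")(traits_mod.connectivity_trait_mantel)(
            net, full_abund, trait, n_perm=config.n_perm, seed=config.seed)
        pd.DataFrame([{"mantel_r": mantel.r, "p": mantel.p,
                       "n_perm": mantel.n_perm}]).to_csv(
            out / "mantel.csv", index=False)

    # out_dir is a location, not an analysis parameter: keep it out of the
    # recorded config so identical analyses hash identically
    recorded = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    manifest = {
        "config": recorded,
        "config_hash": hashlib.sha256(
            json.dumps(recorded, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "threshold": scan.threshold,
        "network_summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _load_inputs(config: PipelineConfig):
    if config.otu_table is not None:
        table = mio.read_otu_table(config.otu_table, dialect=config.otu_dialect)
        trait_tab = (mio.read_trait_table(config.trait_table)
                     if config.trait_table else None)
        return table, trait_tab
    params = SyntheticParams(**{**config.synthetic, "seed": config.seed})
    table, trait_tab, _ = generate_community(params)
    return table, trait_tab
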