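"""Pipeline orchestration: run the full workflow from one configuration.

Stages run in dependency order — simulate → microbiome → da → cytometry →
integrate → validate — with every output file checksummed into a run
manifest so identical configuration + seed reproduces identical bytes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from codami import __version__, coda, da, integrate, io, microbiome, netval
from codami import cytometry as cyto
from codami import simulate as sim

log = logging.getLogger("codami")

STAGES = ("simulate", "microbiome", "da", "cytometry", "integrate", "validate")


@dataclass
class PipelineConfig:
    """All knobs of a full run; round-trips losslessly through YAML."""

    seed: int = 0
    out_dir: str = "codami_run"
    stages: tuple[str, ...] = STAGES
    log_level: str = "INFO"
    # microbiome stage
    retain_prevalence: float = 0.10
    retain_abundance: float = 1e-4
    glom_rank: str = "genus"
    beta_metric: str = "aitchison"
    n_perm: int = 999
    permanova_gate: float = 0.01
    # consensus DA
    alpha_q: float = 0.01
    effect_min: float = 1.0
    # cytometry
    gate_alpha: float = 0.05
    tissue_fdr: float = 0.05
    # integration
    rho_cutoff: float = 0.45
    r_min: float = 0.6
    edge_fdr: float = 0.01
    fdr_perm: int = 100
    n_boot: int = 100
    # validation
    er_replicates: int = 1000
    k_max: int = 8
    min_bycluster_cor: float = 0.85

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def with_stages(self, stages) -> "PipelineConfig":
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        return replace(self, stages=tuple(s for s in STAGES if s in stages))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class MissingUpstreamError(RuntimeError):
    pass


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise MissingUpstreamError(
            f"stage {needed_by!r} needs {path.name} from stage {stage!r}; "
            f"run it first or enable it in the config")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = io.ensure_dir(config.out_dir)
    outputs: dict[str, list[str]] = {}

    def emit(stage: str, name: str):
        outputs.setdefault(stage, []).append(name)
        return out / name

    if "simulate" in config.stages:
        log.info("simulate: coupled microbiome + cytometry datasets")
        micro, gating, truth = sim.simulate_coupled(sim.demo_config(config.seed))
        io.write_count_table(micro, emit("simulate", "counts.tsv"),
                             emit("simulate", "sample_metadata.tsv"))
        io.write_gating_csv(gating, emit("simulate", "gating.csv"))
        io.write_tree_spec(gating.tree, emit("simulate", "gating_tree.yaml"))
        truth.factors.to_csv(emit("simulate", "latent_factors.tsv"), sep="\t")

    micro = gating = None

    def load_micro():
        nonlocal micro
        if micro is None:
            micro = io.read_count_table(
                _require(out / "counts.tsv", "simulate", "microbiome"),
                _require(out / "sample_metadata.tsv", "simulate", "microbiome"))
        return micro

    def load_gating():
        nonlocal gating
        if gating is None:
            gating = io.read_gating_csv(
                _require(out / "gating.csv", "simulate", "cytometry"),
                _require(out / "sample_metadata.tsv", "simulate", "cytometry"))
        return gating

    if "microbiome" in config.stages:
        log.info("microbiome: retain-resolve, diversity, ordination, PERMANOVA")
        table = load_micro()
        rr = microbiome.retain_resolve(table, config.retain_prevalence,
                                       config.retain_abundance, config.glom_rank)
        io.write_count_table(rr.table, emit("microbiome", "retained_counts.tsv"),
                             out / "sample_metadata.tsv")
        io.write_json(asdict(rr.audit), emit("microbiome", "retain_resolve_audit.json"))
        alpha = pd.DataFrame({m: microbiome.alpha_diversity(table, m)
                              for m in ("shannon", "inv_simpson", "richness")})
        alpha.to_csv(emit("microbiome", "alpha_diversity.tsv"), sep="\t",
                     index_label="sample")
        trends = pd.concat({m: microbiome.test_alpha_trend(alpha[m], table.metadata)
                            for m in alpha.columns}, names=["metric", "term"])
        trends.to_csv(emit("microbiome", "alpha_trends.tsv"), sep="\t")
        dist = microbiome.beta_distance(table, config.beta_metric)
        io.write_distance_matrix(dist, emit("microbiome", "beta_distance.tsv"))
        coords, eig = microbiome.pcoa(dist, k=3)
        coords.to_csv(emit("microbiome", "pcoa_coordinates.tsv"), sep="\t",
                      index_label="sample")
        res = microbiome.permanova(dist, table.metadata["timepoint"],
                                   n_perm=config.n_perm, seed=config.seed,
                                   pairwise_gate=config.permanova_gate)
        payload = {"pseudo_F": res.pseudo_F, "R2": res.R2, "p": res.p,
                   "n_perm": res.n_perm}
        if res.pairwise is not None:
            payload["pairwise"] = res.pairwise.to_dict("records")
        io.write_json(payload, emit("microbiome", "permanova.json"))

    if "da" in config.stages:
        log.info("da: consensus differential abundance (thresholds q<%g, |L2FC|>%g)",
                 config.alpha_q, config.effect_min)
        retained = io.read_count_table(
            _require(out / "retained_counts.tsv", "microbiome", "da"),
            _require(out / "sample_metadata.tsv", "simulate", "da"))
        resA = da.fit_model_A(retained)
        resB = da.fit_model_B(retained)
        for res, name in ((resA, "da_model_A.tsv"), (resB, "da_model_B.tsv")):
            tidy = pd.concat({"effect": res.effects, "p": res.p_pairwise,
                              "q": res.q_pairwise}, axis=1)
            tidy["p_global"] = res.p_global
            tidy["q_global"] = res.q_global
            tidy.to_csv(emit("da", name), sep="\t", index_label="taxon")
        cset = da.consensus(resA, resB, config.alpha_q, config.effect_min)
        cset.frame().to_csv(emit("da", "consensus_taxa.tsv"), sep="\t", index=False)

    if "cytometry" in config.stages:
        log.info("cytometry: nested global LRT and follow-up contrasts "
                 "(gate alpha=%g, within-tissue FDR<%g)",
                 config.gate_alpha, config.tissue_fdr)
        gds = load_gating()
        res = cyto.nested_global_test(gds, seed=config.seed)
        io.write_json({"lambda_overall": res.lambda_overall, "df": res.df,
                       "p": res.p, "partitions": res.partition_log},
                      emit("cytometry", "global_test.json"))
        res.subtree_stats.to_csv(emit("cytometry", "subtree_stats.tsv"),
                                 sep="\t", index=False)
        follow = cyto.followup_contrasts(gds, fdr=config.tissue_fdr,
                                         gate_alpha=config.gate_alpha,
                                         seed=config.seed)
        follow.to_csv(emit("cytometry", "followup_contrasts.tsv"), sep="\t",
                      index=False)

    if "integrate" in config.stages:
        log.info("integrate: Mantel, proportionality (rho>%g) and Spearman "
                 "(|r|>%g, FDR<%g) networks", config.rho_cutoff, config.r_min,
                 config.edge_fdr)
        gds = load_gating()
        consensus_path = out / "consensus_taxa.tsv"
        retained = io.read_count_table(
            _require(out / "retained_counts.tsv", "microbiome", "integrate"),
            out / "sample_metadata.tsv")
        keep = [t for t in retained.taxa if t != microbiome.OTHER_ID]
        if consensus_path.exists():
            chosen = pd.read_csv(consensus_path, sep="\t")
            if len(chosen):
                keep = sorted(set(chosen["taxon"]))
        rel = retained.subset_samples(gds.samples).relative_abundance()
        clr_micro = coda.clr(coda.replace_zeros(rel))[keep]
        clr_immune = coda.uss_transform(gds, standardize=False)
        uss = coda.uss_transform(gds)
        d_micro = microbiome.beta_distance(retained.subset_samples(uss.index),
                                           "aitchison")
        from skbio import DistanceMatrix
        from scipy.spatial.distance import pdist, squareform
        d_immune = DistanceMatrix(squareform(pdist(uss.to_numpy())),
                                  ids=list(uss.index))
        mres = integrate.mantel(d_micro, d_immune, n_perm=config.n_perm,
                                strata=gds.metadata["sex"], seed=config.seed)
        io.write_json({"r": mres.r, "p": mres.p, "n_perm": mres.n_perm,
                       "stratified": mres.stratified},
                      emit("integrate", "mantel.json"))
        curve = integrate.update_cutoffs(
            pd.concat([clr_micro, clr_immune], axis=1),
            n_perm=config.fdr_perm, seed=config.seed)
        curve.table.to_csv(emit("integrate", "rho_fdr_curve.tsv"), sep="\t",
                           index=False)
        redges = integrate.rho_edges(clr_micro, clr_immune, config.rho_cutoff)
        redges.to_csv(emit("integrate", "rho_edges.tsv"), sep="\t", index=False)
        io.write_network(integrate.build_network(redges),
                         emit("integrate", "rho_network.graphml"))
        sedges = integrate.spearman_clr_network(
            clr_micro, clr_immune, r_min=config.r_min, fdr_max=config.edge_fdr,
            n_boot=config.n_boot, seed=config.seed)
        sedges.to_csv(emit("integrate", "spearman_edges.tsv"), sep="\t",
                      index=False)
        io.write_network(integrate.build_network(sedges),
                         emit("integrate", "spearman_network.graphml"))

    if "validate" in config.stages:
        log.info("validate: topology vs %d Erdos-Renyi replicates",
                 config.er_replicates)
        results = {}
        for name in ("rho", "spearman"):
            path = _require(out / f"{name}_network.graphml", "integrate",
                            "validate")
            G = io.read_network(path)
            summary = netval.topology_summary(G, seed=config.seed)
            results[name] = {"topology": summary.as_dict()}
            if G.number_of_edges() > 0:
                comp = netval.null_compare(G, B=config.er_replicates,
                                           seed=config.seed)
                comp.table.to_csv(emit("validate", f"{name}_null_compare.tsv"),
                                  sep="\t", index_label="metric")
                results[name]["null_B"] = comp.B
        io.write_json(results, emit("validate", "topology_summary.json"))
        # by-cluster model selection on the rho association matrix
        redges_path = out / "rho_edges.tsv"
        if redges_path.exists():
            table = load_micro()
            gds = load_gating()
            retained = io.read_count_table(out / "retained_counts.tsv",
                                           out / "sample_metadata.tsv")
            keep = [t for t in retained.taxa if t != microbiome.OTHER_ID]
            rel = retained.subset_samples(gds.samples).relative_abundance()
            clr_micro = coda.clr(coda.replace_zeros(rel))[keep]
            rho = integrate.proportionality_rho(clr_micro)
            res = netval.ward_cluster_select(rho.to_numpy(),
                                             config.min_bycluster_cor,
                                             k_max=min(config.k_max, len(keep)))
            pd.DataFrame({"feature": keep, "cluster": res.labels}).to_csv(
                emit("validate", "taxon_clusters.tsv"), sep="\t", index=False)

    manifest = {
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": list(config.stages),
        "outputs": {
            stage: {name: _sha256(out / name) for name in names}
            for stage, names in outputs.items()
        },
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
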