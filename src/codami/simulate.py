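"""Synthetic co-developing microbiome + cytometry data with known ground truth.

The generator emulates the design of a postnatal mouse time course: four
ordered timepoints (P7, P14, P24, 8W at 7/14/24/56 days), two sexes, six
replicates per sex per timepoint. Microbial counts follow successional
waves — an early-dominant family declining as a second family peaks at the
middle timepoint and a third plateaus post-weaning — with lower sequencing
depth and higher inter-sample dispersion at the first timepoint. Cytometry
data are drawn over a depth-4 gating tree (pan-marker → T/B → CD4/CD8
quadrant → functional quadrant) with planted age trends on the
multinomial-logit scale. Coupled mode injects shared latent Gaussian
factors into a taxon's log-abundance and a gated population's logit
fraction before sampling, giving the integration stage a recoverable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from codami.datasets import GatingDataset, GatingTree, TaxaCountTable


class ConfigurationError(ValueError):
    """An invalid or internally inconsistent simulation configuration."""


@dataclass(frozen=True)
class Wave:
    """Gaussian bump in log-abundance over age for one taxon family."""

    family: str
    peak_age: float  # days
    amplitude: float  # peak boost in natural-log abundance units
    width: float  # Gaussian sd in days


@dataclass(frozen=True)
class Coupling:
    """Shared latent factor loading between a taxon and a gated population.

    Either side may be None (a one-sided loading, used to plant taxon-only
    modules). Couplings sharing a ``factor`` name share one latent Gaussian
    per sample. The taxon side receives the signed loading and the cell
    side its magnitude, so negative loadings plant anti-coupled
    (negatively associated) pairs.
    """

    taxon: str | None
    node: str | None
    loading: float
    factor: str | None = None


@dataclass(frozen=True)
class StepEffect:
    """Planted step change in one taxon's log abundance from an onset age.

    ``baseline_log`` optionally pins the taxon's baseline log abundance
    (instead of the random community draw) so the planted signal sits at a
    chosen abundance tier; differentially abundant taxa recovered from real
    developmental data are typically well-established community members.
    """

    taxon: str
    onset_age: float  # days; applies to samples at or after this age
    log2_effect: float
    baseline_log: float | None = None


@dataclass(frozen=True)
class GatingNodeSpec:
    """One internal gating node: children, baseline composition, age effects.

    ``effects`` maps child name -> per-timepoint offsets (logit scale, one
    per timepoint in order). ``precision`` is the Dirichlet precision of the
    child block.
    """

    children: tuple[str, ...]
    baseline: tuple[float, ...]
    effects: dict[str, tuple[float, ...]] = field(default_factory=dict)
    precision: float = 50.0


def default_taxonomy(n_background: int = 20) -> pd.Series:
    """Taxon id -> 7-rank lineage for the default community.

    28 taxa carry the successional-wave families; ``n_background`` further
    taxa (default 20, giving 48 total) sit in two flat commensal families.
    """
    half = n_background // 2
    groups = [
        ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae",
         ["Lactobacillus", "Ligilactobacillus", "Limosilactobacillus"], 6),
        ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae",
         ["Bacteroides"], 6),
        ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Muribaculaceae",
         ["Muribaculum", "Duncaniella"], 6),
        ("Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae",
         ["Enterococcus"], 4),
        ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae",
         ["Streptococcus"], 4),
        ("Pseudomonadota", "Gammaproteobacteria", "Enterobacterales",
         "Morganellaceae", ["Proteus"], 2),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae",
         ["Blautia", "Roseburia"], n_background - half),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Ruminococcaceae",
         ["Faecalibacterium"], half),
    ]
    lineages = {}
    for phylum, klass, order, family, genera, n in groups:
        for i in range(n):
            genus = genera[i % len(genera)]
            tid = f"{genus}_sp{i + 1}"
            lineages[tid] = ";".join(
                ["Bacteria", phylum, klass, order, family, genus, tid])
    return pd.Series(lineages, name="lineage")


def default_waves() -> list[Wave]:
    return [
        Wave("Lactobacillaceae", peak_age=7.0, amplitude=3.0, width=8.0),
        Wave("Streptococcaceae", peak_age=7.0, amplitude=2.0, width=8.0),
        Wave("Bacteroidaceae", peak_age=14.0, amplitude=3.0, width=7.0),
        Wave("Muribaculaceae", peak_age=56.0, amplitude=3.0, width=28.0),
    ]


def default_tree_spec() -> dict[str, GatingNodeSpec]:
    """Depth-4 gating tree: CD45 → T/B → CD4/CD8 quadrant → functional quadrant."""
    return {
        "CD45": GatingNodeSpec(
            children=("CD3+CD19-", "CD3-CD19+"),
            baseline=(0.35, 0.65),
            effects={"CD3+CD19-": (0.0, 0.3, 1.4, 1.8)},
            precision=40.0,
        ),
        "CD45/CD3+CD19-": GatingNodeSpec(
            children=("CD4+CD8-", "CD8+CD4-", "CD4+CD8+", "CD4-CD8-"),
            baseline=(0.35, 0.15, 0.05, 0.45),
            effects={"CD8+CD4-": (0.0, 0.2, 1.2, 1.6),
                     "CD4+CD8+": (0.0, 0.1, 0.5, 0.7)},
            precision=60.0,
        ),
        "CD45/CD3+CD19-/CD4+CD8-": GatingNodeSpec(
            children=("FoxP3+RORgT-", "FoxP3-RORgT+", "FoxP3+RORgT+",
                      "FoxP3-RORgT-"),
            baseline=(0.10, 0.04, 0.01, 0.85),
            effects={"FoxP3-RORgT+": (0.0, 0.2, 1.5, 1.2),
                     "FoxP3+RORgT+": (0.0, 0.0, 1.0, 1.0)},
            precision=70.0,
        ),
    }


def null_tree_spec() -> dict[str, GatingNodeSpec]:
    """The default gating tree with every per-timepoint effect zeroed."""
    return {node: GatingNodeSpec(spec.children, spec.baseline, {}, spec.precision)
            for node, spec in default_tree_spec().items()}


def linear_trend_tree_spec(node: str = "CD45", child: str = "CD3+CD19-",
                           total_effect: float = 1.0) -> dict[str, GatingNodeSpec]:
    """Null tree with one branch carrying a linear-in-age logit trend
    reaching ``total_effect`` logit units at the last timepoint."""
    spec = null_tree_spec()
    ages = np.array([7.0, 14.0, 24.0, 56.0])
    ramp = total_effect * (ages - ages[0]) / (ages[-1] - ages[0])
    target = spec[node]
    spec[node] = GatingNodeSpec(target.children, target.baseline,
                                {child: tuple(ramp)}, target.precision)
    return spec


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment."""

    timepoints: tuple[tuple[str, float], ...] = (
        ("P7", 7.0), ("P14", 14.0), ("P24", 24.0), ("8W", 56.0))
    n_per_group: int = 6
    sexes: tuple[str, ...] = ("F", "M")
    seed: int = 0
    depth_per_timepoint: dict[str, float] = field(
        default_factory=lambda: {"P7": 20000.0, "P14": 50000.0,
                                 "P24": 50000.0, "8W": 50000.0})
    dispersion_per_timepoint: dict[str, float] = field(
        default_factory=lambda: {"P7": 30.0, "P14": 150.0,
                                 "P24": 150.0, "8W": 150.0})
    taxonomy: pd.Series = field(default_factory=default_taxonomy)
    baseline_log_sd: float = 1.0
    wave_spec: tuple[Wave, ...] = field(
        default_factory=lambda: tuple(default_waves()))
    tree_spec: dict[str, GatingNodeSpec] = field(
        default_factory=default_tree_spec)
    tissue: str = "IEL"
    coupling_spec: tuple[Coupling, ...] = ()
    da_spec: tuple[StepEffect, ...] = ()
    baseline_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        ages = [a for _, a in self.timepoints]
        if sorted(ages) != ages or len(set(ages)) != len(ages):
            raise ConfigurationError("timepoints must be strictly increasing in age")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be at least 2")
        labels = {t for t, _ in self.timepoints}
        for d in (self.depth_per_timepoint, self.dispersion_per_timepoint):
            if not labels <= set(d):
                raise ConfigurationError(f"missing per-timepoint values for {labels - set(d)}")
        families = set(self._family_of().values)
        for w in self.wave_spec:
            if w.family not in families:
                raise ConfigurationError(f"wave references unknown family {w.family!r}")
        tree = self.gating_tree()  # validates rooted-tree structure
        n_t = len(self.timepoints)
        for node, spec in self.tree_spec.items():
            if len(spec.children) != len(spec.baseline):
                raise ConfigurationError(f"node {node!r}: children/baseline length mismatch")
            if abs(sum(spec.baseline) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"node {node!r}: sibling baselines sum to {sum(spec.baseline):g} != 1")
            for child, eff in spec.effects.items():
                if child not in spec.children:
                    raise ConfigurationError(f"node {node!r}: effect on unknown child {child!r}")
                if len(eff) != n_t:
                    raise ConfigurationError(
                        f"node {node!r}/{child!r}: need {n_t} per-timepoint effects")
        taxa = set(self.taxonomy.index)
        nodes = set(tree.nodes)
        for c in self.coupling_spec:
            if c.taxon is not None and c.taxon not in taxa:
                raise ConfigurationError(f"coupling references unknown taxon {c.taxon!r}")
            if c.node is not None and c.node not in nodes:
                raise ConfigurationError(f"coupling references unknown node {c.node!r}")
            if c.taxon is None and c.node is None:
                raise ConfigurationError("coupling must name a taxon or a node")
        for s in self.da_spec:
            if s.taxon not in taxa:
                raise ConfigurationError(f"step effect on unknown taxon {s.taxon!r}")
        for t in self.baseline_overrides:
            if t not in taxa:
                raise ConfigurationError(f"baseline override on unknown taxon {t!r}")

    # -- helpers ------------------------------------------------------------
    def _family_of(self) -> pd.Series:
        return self.taxonomy.str.split(";").str[4]

    def gating_tree(self) -> GatingTree:
        roots = [n for n in self.tree_spec if "/" not in n]
        if len(roots) != 1:
            raise ConfigurationError(f"tree_spec must have exactly one root, got {roots}")
        children = {node: [f"{node}/{c}" for c in spec.children]
                    for node, spec in self.tree_spec.items()}
        return GatingTree(root=roots[0], children=children)

    def sample_frame(self) -> pd.DataFrame:
        """Deterministic sample metadata: one row per timepoint × sex × replicate."""
        rows = []
        for tp, age in self.timepoints:
            for sex in self.sexes:
                for i in range(1, self.n_per_group + 1):
                    rows.append((f"{tp}_{sex}{i}", tp, age, sex))
        meta = pd.DataFrame(rows, columns=["sample", "timepoint", "age", "sex"])
        meta = meta.set_index("sample")
        order = [t for t, _ in self.timepoints]
        meta["timepoint"] = pd.Categorical(meta["timepoint"], categories=order,
                                           ordered=True)
        meta["tissue"] = self.tissue
        return meta

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _latent_factors(config: SimulationConfig, rng, samples: pd.Index):
    """Per-sample latent Gaussians and the log/logit shifts they induce."""
    factors: dict[str, np.ndarray] = {}
    taxon_shift = pd.DataFrame(0.0, index=samples, columns=config.taxonomy.index)
    node_shift: dict[str, pd.Series] = {}
    for i, c in enumerate(config.coupling_spec):
        name = c.factor if c.factor is not None else f"_pair{i}"
        if name not in factors:
            factors[name] = rng.standard_normal(len(samples))
        z = factors[name]
        if c.taxon is not None:
            taxon_shift[c.taxon] += c.loading * z
        if c.node is not None:
            node_shift.setdefault(c.node, pd.Series(0.0, index=samples))
            node_shift[c.node] += abs(c.loading) * pd.Series(z, index=samples)
    return factors, taxon_shift, node_shift


def _microbiome_from(config: SimulationConfig, rng,
                     taxon_shift: pd.DataFrame | None) -> TaxaCountTable:
    meta = config.sample_frame()
    taxa = config.taxonomy.index
    family = config._family_of()
    baseline = rng.normal(0.0, config.baseline_log_sd, size=len(taxa))
    for t, b in config.baseline_overrides.items():
        baseline[taxa.get_loc(t)] = b
    for s in config.da_spec:
        if s.baseline_log is not None:
            baseline[taxa.get_loc(s.taxon)] = s.baseline_log
    counts = np.zeros((len(taxa), len(meta)), dtype=np.int64)
    for j, (sample, row) in enumerate(meta.iterrows()):
        age = row["age"]
        log_mu = baseline.copy()
        for w in config.wave_spec:
            bump = w.amplitude * np.exp(-0.5 * ((age - w.peak_age) / w.width) ** 2)
            log_mu += np.where(family.values == w.family, bump, 0.0)
        for s in config.da_spec:
            if age >= s.onset_age:
                log_mu[taxa.get_loc(s.taxon)] += s.log2_effect * np.log(2.0)
        if taxon_shift is not None:
            log_mu += taxon_shift.loc[sample].to_numpy()
        p = np.exp(log_mu - log_mu.max())
        p /= p.sum()
        conc = config.dispersion_per_timepoint[str(row["timepoint"])]
        q = rng.dirichlet(p * conc)
        depth = rng.poisson(config.depth_per_timepoint[str(row["timepoint"])])
        counts[:, j] = rng.multinomial(depth, q)
    table = pd.DataFrame(counts, index=taxa, columns=meta.index)
    return TaxaCountTable(table, config.taxonomy, meta)


def _gating_from(config: SimulationConfig, rng,
                 node_shift: dict[str, pd.Series] | None) -> GatingDataset:
    meta = config.sample_frame()
    tree = config.gating_tree()
    tp_index = {t: i for i, (t, _) in enumerate(config.timepoints)}
    props = pd.DataFrame(np.nan, index=meta.index, columns=tree.nodes)
    props[tree.root] = 1.0
    node_shift = node_shift or {}
    for node, spec in config.tree_spec.items():
        child_ids = [f"{node}/{c}" for c in spec.children]
        eta0 = np.log(np.asarray(spec.baseline, dtype=float))
        block = np.empty((len(meta), len(child_ids)))
        for j, (sample, row) in enumerate(meta.iterrows()):
            t = tp_index[str(row["timepoint"])]
            eta = eta0.copy()
            for k, (child, cid) in enumerate(zip(spec.children, child_ids)):
                eta[k] += spec.effects.get(child, (0.0,) * len(tp_index))[t]
                if cid in node_shift:
                    eta[k] += node_shift[cid].loc[sample]
            mu = np.exp(eta - eta.max())
            mu /= mu.sum()
            block[j] = rng.dirichlet(mu * spec.precision)
        props[child_ids] = block
    return GatingDataset(tree, props, meta)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Exchangeable-null configuration for type-I calibration.

    Calibration of a test's size requires groups that are exchangeable
    under the null, so wave amplitudes are zeroed AND depth/dispersion are
    equalized across timepoints: with unequal Dirichlet precision the
    expected transformed abundances E[log q_i] = psi(c p_i) - psi(c) differ
    between groups even at zero amplitude, which is a true difference, not
    a type-I error setting.
    """
    base = SimulationConfig(seed=seed)
    labels = {t for t, _ in base.timepoints}
    defaults = dict(
        seed=seed,
        wave_spec=tuple(Wave(w.family, w.peak_age, 0.0, w.width)
                        for w in base.wave_spec),
        depth_per_timepoint={t: 50000.0 for t in labels},
        dispersion_per_timepoint={t: 150.0 for t in labels},
        tree_spec=null_tree_spec(),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def spike_in_config(seed: int = 0, taxon: str = "Blautia_sp1",
                    onset_age: float = 24.0, log2_effect: float = 2.0,
                    baseline_log: float = 1.5, n_taxa: int = 100,
                    **overrides) -> SimulationConfig:
    """Spike-in power configuration: one planted step on a null background.

    The planted taxon sits at the established-community-member tier
    (baseline log abundance 1.5, a few percent mean share); recovery of
    fold changes on much rarer taxa is limited by Dirichlet sampling noise
    rather than by the models.
    """
    taxonomy = default_taxonomy(n_background=n_taxa - 28)
    return null_config(
        seed=seed,
        taxonomy=taxonomy,
        da_spec=(StepEffect(taxon, onset_age, log2_effect, baseline_log),),
        **overrides,
    )


# Planted couplings target populous gates (several % of parent or more):
# a latent factor on a 4-5% population is mostly swallowed by the gate's own
# Dirichlet sampling noise, which no association measure can undo.
RECOVERY_PAIRS: tuple[tuple[str, str], ...] = (
    ("Bacteroides_sp2", "CD45/CD3+CD19-/CD8+CD4-"),
    ("Lactobacillus_sp1", "CD45/CD3+CD19-/CD4+CD8-/FoxP3+RORgT-"),
    ("Muribaculum_sp1", "CD45/CD3+CD19-/CD4-CD8-"),
    ("Streptococcus_sp1", "CD45/CD3+CD19-"),
    ("Enterococcus_sp1", "CD45/CD3+CD19-/CD4+CD8-"),
)


def coupled_config(seed: int = 0, loading: float = 1.5,
                   pairs=RECOVERY_PAIRS, **overrides) -> SimulationConfig:
    """Coupled-recovery configuration: planted microbe–immune pairs on an
    exchangeable-null background, coupled taxa pinned at the
    established-member tier (baseline log abundance 1.5)."""
    return null_config(
        seed=seed,
        coupling_spec=tuple(Coupling(t, n, loading) for t, n in pairs),
        baseline_overrides={t: 1.5 for t, _ in pairs},
        **overrides,
    )


MODULE_TAXA: dict[str, tuple[str, ...]] = {
    "modA": ("Bacteroides_sp1", "Bacteroides_sp2", "Bacteroides_sp4",
             "Muribaculum_sp1", "Duncaniella_sp2"),
    "modB": ("Lactobacillus_sp1", "Ligilactobacillus_sp2", "Streptococcus_sp1",
             "Streptococcus_sp2", "Enterococcus_sp1"),
}


def demo_config(seed: int = 0, loading: float = 1.5) -> SimulationConfig:
    """Full study conditions plus planted association structure.

    Successional waves and gating-tree age trends are active; two disjoint
    five-taxon modules share within-module latent factors, and five
    microbe–immune pairs carry cross-dataset couplings — the modular
    topology (dense bacterial clusters bridged by immune cells) that the
    network stages are meant to expose.
    """
    couplings = [Coupling(t, None, loading, mod)
                 for mod, taxa in MODULE_TAXA.items() for t in taxa]
    couplings += [Coupling(t, n, loading) for t, n in RECOVERY_PAIRS]
    pinned = {t: 1.5 for taxa in MODULE_TAXA.values() for t in taxa}
    pinned.update({t: 1.5 for t, _ in RECOVERY_PAIRS})
    return SimulationConfig(seed=seed, coupling_spec=tuple(couplings),
                            baseline_overrides=pinned)


def simulate_microbiome(config: SimulationConfig) -> TaxaCountTable:
    """Dirichlet-multinomial counts whose expected log-abundances follow the
    configured successional waves."""
    rng = np.random.default_rng(config.seed)
    return _microbiome_from(config, rng, None)


def simulate_cytometry(config: SimulationConfig) -> GatingDataset:
    """Gating proportions drawn per internal node from a Dirichlet whose mean
    follows the node's per-timepoint logit effects."""
    rng = np.random.default_rng(config.seed)
    return _gating_from(config, rng, None)


@dataclass
class CoupledTruth:
    """Ground truth of a coupled simulation: latent factors and memberships."""

    factors: pd.DataFrame  # sample × factor latent values
    couplings: tuple[Coupling, ...]

    def module_of(self) -> dict[str, str]:
        """Feature id -> latent-factor (module) name."""
        out = {}
        for i, c in enumerate(self.couplings):
            name = c.factor if c.factor is not None else f"_pair{i}"
            for fid in (c.taxon, c.node):
                if fid is not None:
                    out[fid] = name
        return out


def simulate_coupled(
    config: SimulationConfig,
) -> tuple[TaxaCountTable, GatingDataset, CoupledTruth]:
    """Microbiome + cytometry datasets sharing planted latent factors."""
    if not config.coupling_spec:
        raise ConfigurationError("coupled mode needs a non-empty coupling_spec")
    rng = np.random.default_rng(config.seed)
    meta = config.sample_frame()
    factors, taxon_shift, node_shift = _latent_factors(config, rng, meta.index)
    micro = _microbiome_from(config, rng, taxon_shift)
    gating = _gating_from(config, rng, node_shift)
    truth = CoupledTruth(pd.DataFrame(factors, index=meta.index),
                         config.coupling_spec)
    return micro, gating, truth
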