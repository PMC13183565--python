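"""Microbiome-side analysis: retain–resolve denoising, alpha diversity with
trend tests, beta-diversity ordination, and PERMANOVA with pairwise follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity.alpha import chao1
from skbio.stats.ordination import pcoa as _skbio_pcoa

from codami import coda
from codami.datasets import RANKS, TaxaCountTable
from codami.stats import bh_adjust

OTHER_ID = "other"


@dataclass
class RetainResolveAudit:
    initial: int
    retained_round1: int
    glommed_candidates: int
    retained_round2: int
    other_merged: int


@dataclass
class RetainResolveResult:
    table: TaxaCountTable
    audit: RetainResolveAudit
    assignment: pd.Series  # input taxon -> output row id


def _passes(counts: pd.DataFrame, prevalence_min: float,
            abundance_min: float) -> pd.Series:
    """Prevalence AND mean-relative-abundance filter per row."""
    totals = counts.sum(axis=0)
    rel = counts.div(totals, axis=1)
    prevalence = (counts > 0).mean(axis=1)
    return (prevalence >= prevalence_min) & (rel.mean(axis=1) >= abundance_min)


def retain_resolve(
    table: TaxaCountTable,
    prevalence_min: float = 0.10,
    abundance_min: float = 1e-4,
    glom_rank: str = "genus",
) -> RetainResolveResult:
    """Two-round taxon denoising.

    Round 1 retains taxa meeting prevalence and mean-relative-abundance
    criteria at native resolution. The remainder are agglomerated (counts
    summed) to ``glom_rank``; glommed groups passing the same criteria are
    retained, and everything else is merged into a single ``other`` row.
    Per-sample totals are conserved exactly.
    """
    if not 0 <= prevalence_min < 1 or not 0 <= abundance_min < 1:
        raise ValueError("thresholds must lie in [0, 1)")
    if glom_rank not in RANKS:
        raise ValueError(f"unknown rank {glom_rank!r}; expected one of {RANKS}")
    if table.counts.empty:
        raise ValueError("empty count table")
    counts = table.counts
    # the per-sample relative abundances are computed once, on the full table
    round1 = _passes(counts, prevalence_min, abundance_min)
    retained1 = counts.index[round1]
    remainder = counts.index[~round1]

    lineage_frame = table.lineage_frame()
    rank_depth = lineage_frame.shape[1]
    rank_pos = RANKS.index(glom_rank)
    if rank_pos >= rank_depth:
        raise ValueError(f"rank {glom_rank!r} deeper than provided lineages")

    glom_key = table.lineage.loc[remainder].str.split(";").str[: rank_pos + 1].str.join(";")
    glommed = counts.loc[remainder].groupby(glom_key).sum()
    totals = counts.sum(axis=0)
    rel_glommed = glommed.div(totals, axis=1)
    prevalence = (glommed > 0).mean(axis=1)
    round2 = (prevalence >= prevalence_min) & (rel_glommed.mean(axis=1) >= abundance_min)
    retained2_keys = glommed.index[round2]
    other_keys = glommed.index[~round2]

    pad = rank_depth - rank_pos - 1

    def glom_id(key: str) -> str:
        return f"{glom_rank}:{key.split(';')[-1]}"

    rows, lineages = [], {}
    out = counts.loc[retained1].copy()
    for tid in retained1:
        lineages[tid] = table.lineage.loc[tid]
    for key in retained2_keys:
        gid = glom_id(key)
        rows.append(pd.Series(glommed.loc[key], name=gid))
        lineages[gid] = ";".join([key] + ["NA"] * pad) if pad else key
    other_counts = glommed.loc[other_keys].sum(axis=0)
    rows.append(pd.Series(other_counts, name=OTHER_ID))
    lineages[OTHER_ID] = ";".join([OTHER_ID] + ["NA"] * (rank_depth - 1))
    out = pd.concat([out, pd.DataFrame(rows)]) if rows else out
    out = out.astype(np.int64)

    assignment = pd.Series(index=counts.index, dtype=object)
    assignment.loc[retained1] = retained1
    for key in retained2_keys:
        members = glom_key.index[glom_key == key]
        assignment.loc[members] = glom_id(key)
    assignment.loc[assignment.isna()] = OTHER_ID

    audit = RetainResolveAudit(
        initial=len(counts),
        retained_round1=len(retained1),
        glommed_candidates=len(glommed),
        retained_round2=len(retained2_keys),
        other_merged=len(other_keys),
    )
    result = TaxaCountTable(out, pd.Series(lineages), table.metadata)
    return RetainResolveResult(result, audit, assignment)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

ALPHA_METRICS = ("shannon", "inv_simpson", "richness", "chao1")


def alpha_diversity(table: TaxaCountTable, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity.

    shannon = -sum p ln p; inv_simpson = 1 / sum p^2; richness = number of
    observed taxa. ``chao1`` is a simple nonparametric richness estimate
    standing in for model-based estimators.
    """
    if metric not in ALPHA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {ALPHA_METRICS}")
    counts = table.counts
    if metric == "richness":
        return (counts > 0).sum(axis=0).rename("richness").astype(float)
    if metric == "chao1":
        return pd.Series(
            {s: float(chao1(counts[s].to_numpy())) for s in counts.columns},
            name="chao1",
        )
    rel = table.relative_abundance()  # samples × taxa
    p = rel.to_numpy()
    if metric == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        return pd.Series(-terms.sum(axis=1), index=rel.index, name="shannon")
    return pd.Series(1.0 / (p**2).sum(axis=1), index=rel.index, name="inv_simpson")


def test_alpha_trend(values: pd.Series, metadata: pd.DataFrame) -> pd.DataFrame:
    """OLS of a diversity metric on timepoint + sex with per-term F-tests."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = metadata.loc[values.index, ["timepoint", "sex"]].copy()
    for col in ("timepoint", "sex"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    df["y"] = values.to_numpy(dtype=float)
    if np.ptp(df["y"].to_numpy()) == 0:
        return pd.DataFrame({"F": [0.0, 0.0], "p": [1.0, 1.0]},
                            index=["timepoint", "sex"])
    fit = smf.ols("y ~ C(timepoint) + C(sex)", data=df).fit()
    rank = np.linalg.matrix_rank(fit.model.exog)
    if rank < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design: timepoint and sex are aliased")
    table = sm.stats.anova_lm(fit, typ=2)
    table = table.rename(index={"C(timepoint)": "timepoint", "C(sex)": "sex"})
    return table[["F", "PR(>F)"]].rename(columns={"PR(>F)": "p"}).dropna()


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

BETA_METRICS = ("jaccard", "bray_curtis", "aitchison")


def beta_distance(table: TaxaCountTable, metric: str = "aitchison",
                  delta: float | None = None) -> DistanceMatrix:
    """Sample × sample distances on relative abundances.

    Jaccard works on presence/absence, Bray–Curtis on relative abundances,
    and Aitchison on CLR-transformed data after multiplicative zero
    replacement (applied internally).
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {BETA_METRICS}")
    rel = table.relative_abundance()
    if metric == "jaccard":
        condensed = pdist(rel.to_numpy() > 0, metric="jaccard")
    elif metric == "bray_curtis":
        condensed = pdist(rel.to_numpy(), metric="braycurtis")
    else:
        unzeroed = coda.replace_zeros(rel, delta)
        condensed = pdist(coda.clr(unzeroed).to_numpy(), metric="euclidean")
    return DistanceMatrix(squareform(condensed), ids=list(rel.index))


def pcoa(dist: DistanceMatrix, k: int = 2) -> tuple[pd.DataFrame, pd.Series]:
    """Principal coordinate analysis.

    Returns the first k coordinate axes (scaled by sqrt eigenvalue; axes
    with negative eigenvalues are dropped) and the full eigenvalue spectrum,
    negative values included.
    """
    n = len(dist.ids)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(dist, method="eigh", number_of_dimensions=0)
    eigvals = pd.Series(res.eigvals.to_numpy(), name="eigenvalue").reset_index(drop=True)
    positive = int((eigvals > 0).sum())
    take = min(k, positive)
    coords = res.samples.iloc[:, :take]
    coords.index = list(dist.ids)
    coords.columns = [f"PC{i + 1}" for i in range(take)]
    return coords, eigvals


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    pairwise: pd.DataFrame | None  # groupA, groupB, pseudo_F, p, q


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """(pseudo-F, R2) from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(
    dist: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    pairwise_gate: float = 0.01,
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson partitioning) with permutation p-value.

    Pairwise group comparisons run only when the omnibus p falls below
    ``pairwise_gate`` and are BH-adjusted.
    """
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse",
                      stacklevel=2)
    groups = pd.Series(groups).loc[list(dist.ids)].astype(str)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"every group needs >=2 samples; got {sizes.to_dict()}")
    codes = pd.Categorical(groups, categories=levels).codes.astype(np.int64)
    d2 = np.asarray(dist.data) ** 2
    rng = np.random.default_rng(seed)
    f_obs, r2 = _permanova_stats(d2, codes, len(levels))
    exceed = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_stats(d2, rng.permutation(codes), len(levels))
        exceed += f_perm >= f_obs
    p = (1 + exceed) / (n_perm + 1)

    pairwise = None
    if p < pairwise_gate and len(levels) > 2:
        rows = []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                pair = groups.index[np.isin(codes, [i, j])]
                sub = dist.filter(list(pair))
                res = permanova(sub, groups.loc[pair], n_perm=n_perm,
                                seed=seed + 1, pairwise_gate=np.inf)
                rows.append((levels[i], levels[j], res.pseudo_F, res.p))
        pairwise = pd.DataFrame(rows, columns=["groupA", "groupB", "pseudo_F", "p"])
        pairwise["q"] = bh_adjust(pairwise["p"].to_numpy())
    return PermanovaResult(f_obs, r2, p, n_perm, pairwise)
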