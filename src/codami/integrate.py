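"""Cross-dataset integration: Mantel tests, proportionality (ρ) and
Spearman-CLR association measures, permutation-based FDR cutoff selection,
and association-network assembly.

The microbiome and cytometry tables are CLR-transformed separately (each
respecting its own compositional geometry) and column-concatenated;
associations are then computed uniformly across all within- and
cross-dataset feature pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform

from codami.stats import bh_adjust


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    stratified: bool


def _offdiag(D: np.ndarray) -> np.ndarray:
    return squareform(np.asarray(D, dtype=float), checks=False)


def mantel(D1, D2, n_perm: int = 999, strata: pd.Series | None = None,
           seed: int = 0) -> MantelResult:
    """Mantel test: Pearson correlation of two distance matrices.

    The permutation null relabels the samples of the second matrix (rows
    and columns jointly); with ``strata`` given, labels are only permuted
    within strata (the within-block permutation form of a covariate-
    stratified — "partial" — Mantel test). One-sided (greater) p-value.
    """
    ids = None
    for D in (D1, D2):
        these = list(getattr(D, "ids", range(np.asarray(getattr(D, "data", D)).shape[0])))
        if ids is not None and these != ids:
            raise ValueError("distance matrices cover different samples")
        ids = these
    A = np.asarray(getattr(D1, "data", D1), dtype=float)
    B = np.asarray(getattr(D2, "data", D2), dtype=float)
    n = A.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    a = _offdiag(A)
    r_obs = float(np.corrcoef(a, _offdiag(B))[0, 1])
    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = pd.Series(strata).iloc[: n] if len(strata) != n else pd.Series(strata)
        strata = strata.to_numpy()
        groups = [np.flatnonzero(strata == g) for g in pd.unique(strata)]
    exceed = 0
    for _ in range(n_perm):
        perm = np.arange(n)
        if strata is None:
            perm = rng.permutation(n)
        else:
            for idx in groups:
                perm[idx] = idx[rng.permutation(len(idx))]
        r_perm = np.corrcoef(a, _offdiag(B[np.ix_(perm, perm)]))[0, 1]
        exceed += r_perm >= r_obs
    p = (1 + exceed) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, strata is not None)


def proportionality_rho(clr_data: pd.DataFrame) -> pd.DataFrame:
    """Proportionality ρ(i, j) = 1 - var(clr_i - clr_j)/(var_i + var_j).

    Algebraically 2·cov(i,j)/(var_i + var_j): 1 for perfectly proportional
    parts, symmetric, bounded in [-1, 1]. Zero-variance features yield NaN
    for their pairs.
    """
    X = clr_data.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    cov = np.cov(X, rowvar=False)
    var = np.diag(cov).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = var[:, None] + var[None, :]
        rho = 2.0 * cov / denom
        rho[denom == 0] = np.nan
    zero_var = var == 0
    rho[zero_var, :] = np.nan
    rho[:, zero_var] = np.nan
    np.fill_diagonal(rho, np.where(zero_var, np.nan, 1.0))
    return pd.DataFrame(rho, index=clr_data.columns, columns=clr_data.columns)


@dataclass
class FdrCurve:
    """Estimated FDR over a grid of association cutoffs."""

    table: pd.DataFrame  # columns: cutoff, observed, permuted_mean, fdr, flagged
    n_perm: int

    def cutoff_for(self, fdr_max: float) -> float | None:
        """Smallest cutoff on the grid achieving FDR below ``fdr_max``."""
        ok = self.table[self.table["fdr"] < fdr_max]
        return float(ok["cutoff"].iloc[0]) if len(ok) else None


def update_cutoffs(clr_data: pd.DataFrame, cutoffs=None, n_perm: int = 100,
                   seed: int = 0, method: str = "rho") -> FdrCurve:
    """Permutation FDR estimate for an association-strength cutoff grid.

    Each permutation shuffles every feature column independently across
    samples — preserving marginals while breaking all cross-feature
    association — and recomputes the association matrix. FDR(c) is the mean
    permuted count of associations above c divided by the observed count
    (positive ρ for ``method='rho'``, |r| for ``method='spearman'``),
    clipped to [0, 1]. A zero observed count is flagged and reported as 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.05, 1.0, 0.05), 3)
    cutoffs = np.asarray(cutoffs, dtype=float)

    def assoc_counts(df: pd.DataFrame) -> np.ndarray:
        if method == "rho":
            vals = _offdiag(proportionality_rho(df).to_numpy())
        elif method == "spearman":
            vals = np.abs(_offdiag(stats.spearmanr(df.to_numpy()).statistic))
        else:
            raise ValueError(f"unknown method {method!r}")
        vals = vals[~np.isnan(vals)]
        return (vals[:, None] > cutoffs[None, :]).sum(axis=0)

    observed = assoc_counts(clr_data)
    rng = np.random.default_rng(seed)
    X = clr_data.to_numpy(dtype=float)
    permuted = np.zeros((n_perm, len(cutoffs)))
    for b in range(n_perm):
        Xp = np.column_stack([X[rng.permutation(X.shape[0]), j]
                              for j in range(X.shape[1])])
        permuted[b] = assoc_counts(pd.DataFrame(Xp, columns=clr_data.columns))
    mean_perm = permuted.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(observed > 0, mean_perm / np.maximum(observed, 1), 0.0)
    table = pd.DataFrame({
        "cutoff": cutoffs,
        "observed": observed,
        "permuted_mean": mean_perm,
        "fdr": np.clip(fdr, 0.0, 1.0),
        "flagged": observed == 0,
    })
    return FdrCurve(table, n_perm)


def spearman_clr_network(
    clr_micro: pd.DataFrame,
    clr_immune: pd.DataFrame,
    r_min: float = 0.6,
    fdr_max: float = 0.01,
    n_boot: int = 500,
    seed: int = 0,
    influence_screen: bool = True,
) -> pd.DataFrame:
    """Signed Spearman edges over the concatenated CLR datasets.

    All within- and cross-dataset pairs are tested (t approximation), BH is
    applied across every pair, and edges require |r| > ``r_min`` and
    q < ``fdr_max``. Each surviving edge carries a bootstrap support
    fraction (|r| > r_min over sample resamples) and, when
    ``influence_screen`` is on, must keep |r| above threshold under every
    leave-one-out sample deletion (an automated guard against single-point
    artifacts).
    """
    if not clr_micro.index.equals(clr_immune.index):
        raise ValueError("datasets must share samples in the same order")
    data = pd.concat([clr_micro, clr_immune], axis=1)
    n, m = data.shape
    for col in data.columns:
        vals = data[col]
        if vals.duplicated().mean() > 0.5:
            warnings.warn(f"feature {col!r} has ties in >50% of values",
                          stacklevel=2)
    rmat = stats.spearmanr(data.to_numpy()).statistic
    if m == 2:  # scipy returns a scalar for two columns
        rmat = np.array([[1.0, float(rmat)], [float(rmat), 1.0]])
    iu, ju = np.triu_indices(m, k=1)
    r = rmat[iu, ju]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    q = bh_adjust(p)
    keep = (np.abs(r) > r_min) & (q < fdr_max)
    micro_set = set(clr_micro.columns)
    cols = list(data.columns)
    rows = []
    kept_pairs = [(int(i), int(j), float(rv), float(qv))
                  for i, j, rv, qv in zip(iu[keep], ju[keep], r[keep], q[keep])]
    if kept_pairs:
        rng = np.random.default_rng(seed)
        X = data.to_numpy()
        boot_hits = np.zeros(len(kept_pairs))
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Xb = X[idx]
            for e, (i, j, _rv, _qv) in enumerate(kept_pairs):
                rb = stats.spearmanr(Xb[:, i], Xb[:, j]).statistic
                boot_hits[e] += abs(rb) > r_min
        for e, (i, j, rv, qv) in enumerate(kept_pairs):
            if influence_screen:
                loo_ok = True
                for drop in range(n):
                    mask = np.arange(n) != drop
                    r_loo = stats.spearmanr(X[mask, i], X[mask, j]).statistic
                    if abs(r_loo) <= r_min:
                        loo_ok = False
                        break
                if not loo_ok:
                    continue
            rows.append({
                "source": cols[i], "target": cols[j], "weight": rv,
                "sign": int(np.sign(rv)), "q": qv, "method": "spearman",
                "source_type": "taxon" if cols[i] in micro_set else "immune_cell",
                "target_type": "taxon" if cols[j] in micro_set else "immune_cell",
                "bootstrap_support": boot_hits[e] / n_boot,
            })
    return pd.DataFrame(rows, columns=["source", "target", "weight", "sign",
                                       "q", "method", "source_type",
                                       "target_type", "bootstrap_support"])


def rho_edges(clr_micro: pd.DataFrame, clr_immune: pd.DataFrame,
              rho_min: float = 0.45) -> pd.DataFrame:
    """Proportionality edges: pairs with ρ above ``rho_min``.

    Only positive ρ is thresholded (reciprocal/negative proportionality is
    not robust to the choice of reference); pair the cutoff with
    :func:`update_cutoffs` to know the FDR it buys.
    """
    if not clr_micro.index.equals(clr_immune.index):
        raise ValueError("datasets must share samples in the same order")
    data = pd.concat([clr_micro, clr_immune], axis=1)
    rho = proportionality_rho(data)
    micro_set = set(clr_micro.columns)
    cols = list(data.columns)
    iu, ju = np.triu_indices(len(cols), k=1)
    vals = rho.to_numpy()[iu, ju]
    keep = ~np.isnan(vals) & (vals > rho_min)
    rows = [{
        "source": cols[i], "target": cols[j], "weight": float(v),
        "sign": 1, "method": "rho",
        "source_type": "taxon" if cols[i] in micro_set else "immune_cell",
        "target_type": "taxon" if cols[j] in micro_set else "immune_cell",
    } for i, j, v in zip(iu[keep], ju[keep], vals[keep])]
    return pd.DataFrame(rows, columns=["source", "target", "weight", "sign",
                                       "method", "source_type", "target_type"])


def build_network(edges: pd.DataFrame, nodes: pd.DataFrame | None = None) -> nx.Graph:
    """Assemble a simple undirected typed association network.

    ``nodes`` (optional) declares the admissible features with columns
    ``type`` (taxon / immune_cell) and optionally ``tissue``; edges
    referencing undeclared features raise, duplicate edges with conflicting
    weights raise.
    """
    G = nx.Graph()
    if nodes is not None:
        for fid, row in nodes.iterrows():
            G.add_node(fid, **row.dropna().to_dict())
    known = set(G.nodes) if nodes is not None else None
    for _, e in edges.iterrows():
        u, v = e["source"], e["target"]
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        if known is not None and (u not in known or v not in known):
            missing = u if u not in known else v
            raise ValueError(f"edge references undeclared feature {missing!r}")
        if G.has_edge(u, v):
            if abs(G[u][v]["weight"] - e["weight"]) > 1e-12:
                raise ValueError(f"duplicate edge {u!r}-{v!r} with conflicting weights")
            continue
        attrs = {k: e[k] for k in ("weight", "sign", "method") if k in e}
        G.add_edge(u, v, **attrs)
        if known is None:
            G.nodes[u].setdefault("type", e.get("source_type"))
            G.nodes[v].setdefault("type", e.get("target_type"))
    return G
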