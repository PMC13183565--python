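"""Network topology metrics and Erdős–Rényi null-model validation.

An observed association network is compared with an ensemble of uniform
G(n, m) random graphs matched on node and edge count. Per-metric Z-tests
flag topology (clustering, path length, modularity, betweenness) that a
density-matched random graph would not produce.

Conventions (chosen to make the metric set internally consistent):

* average path length (APL) is the mean BFS shortest-path length over
  *connected* ordered pairs;
* betweenness is unnormalized, per node, with each unordered pair counted
  once, so on a connected graph the exact identity
  ``mean betweenness = (n - 1) (APL - 1) / 2`` holds;
* the average clustering coefficient (ACC) averages local coefficients over
  all nodes, with degree < 2 nodes contributing 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import squareform

NULL_METRICS = ["acc", "apl", "diameter", "mean_betweenness", "modularity"]


def er_random_graph(n: int, m: int, rng) -> nx.Graph:
    """Uniform draw from G(n, m): m distinct edges among all n(n-1)/2 pairs."""
    n_pairs = n * (n - 1) // 2
    if not 0 <= m <= n_pairs:
        raise ValueError(f"m={m} outside [0, {n_pairs}] for n={n}")
    rng = np.random.default_rng(rng)
    chosen = rng.choice(n_pairs, size=m, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(zip(iu[chosen].tolist(), ju[chosen].tolist()))
    return G


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    average_degree: float
    acc: float
    apl: float
    diameter: float
    modularity: float
    mean_betweenness: float
    component_count: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _path_stats(G: nx.Graph) -> tuple[float, float, int]:
    """(APL over connected ordered pairs, diameter of largest component,
    component count) via sparse BFS."""
    n = G.number_of_nodes()
    if n == 0 or G.number_of_edges() == 0:
        return float("nan"), float("nan"), n
    adj = nx.to_scipy_sparse_array(G, weight=None, format="csr")
    n_comp, labels = connected_components(adj, directed=False)
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    apl = float(dist[finite].mean()) if finite.any() else float("nan")
    sizes = np.bincount(labels)
    big = np.flatnonzero(labels == sizes.argmax())
    sub = dist[np.ix_(big, big)]
    diameter = float(sub[np.isfinite(sub)].max()) if len(big) > 1 else 0.0
    return apl, diameter, int(n_comp)


def topology_summary(G: nx.Graph, seed: int = 0) -> TopologySummary:
    """All topology metrics of a simple undirected graph.

    Modularity comes from a Louvain partition at resolution 1 with a fixed
    seed; it is therefore algorithm-dependent, unlike the other metrics.
    """
    n = G.number_of_nodes()
    m = G.number_of_edges()
    if n == 0:
        return TopologySummary(0, 0, 0.0, 0.0, 0.0, float("nan"), float("nan"),
                               float("nan"), 0.0, 0)
    density = 2 * m / (n * (n - 1)) if n > 1 else 0.0
    avg_degree = 2 * m / n
    acc = float(np.mean(list(nx.clustering(G).values())))
    apl, diameter, n_comp = _path_stats(G)
    if m > 0:
        btw = float(np.mean(list(
            nx.betweenness_centrality(G, normalized=False).values())))
        parts = nx.community.louvain_communities(G, seed=seed)
        modularity = float(nx.community.modularity(G, parts))
    else:
        btw = 0.0
        modularity = float("nan")
    return TopologySummary(n, m, density, avg_degree, acc, apl, diameter,
                           modularity, btw, n_comp)


def er_null_ensemble(
    n: int,
    m: int,
    B: int = 1000,
    seed: int = 0,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Metric table (one row per replicate) over B uniform G(n, m) draws."""
    metrics = metrics or NULL_METRICS
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(B):
        G = er_random_graph(n, m, rng)
        if "modularity" in metrics:
            summ = topology_summary(G, seed=b)
            rows.append({k: getattr(summ, k) for k in metrics})
        else:
            row = {}
            if "acc" in metrics:
                row["acc"] = float(np.mean(list(nx.clustering(G).values())))
            if {"apl", "diameter"} & set(metrics):
                apl, diameter, _ = _path_stats(G)
                row.update({k: v for k, v in
                            [("apl", apl), ("diameter", diameter)] if k in metrics})
            if "mean_betweenness" in metrics:
                row["mean_betweenness"] = float(np.mean(list(
                    nx.betweenness_centrality(G, normalized=False).values())))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class NullComparison:
    """Observed metrics vs an Erdős–Rényi G(n, m) null ensemble."""

    table: pd.DataFrame  # index: metric; columns: observed, null_mean, null_sd, z, p
    B: int
    seed: int


def null_compare(G: nx.Graph, B: int = 1000, seed: int = 0) -> NullComparison:
    """Z-test each topology metric of ``G`` against matched G(n, m) draws."""
    if B < 100:
        raise ValueError("B must be at least 100")
    obs = topology_summary(G, seed=seed)
    ens = er_null_ensemble(G.number_of_nodes(), G.number_of_edges(), B, seed)
    rows = {}
    for metric in NULL_METRICS:
        null_mean = float(ens[metric].mean())
        null_sd = float(ens[metric].std(ddof=1))
        observed = getattr(obs, metric)
        if null_sd > 0 and np.isfinite(observed):
            z = (observed - null_mean) / null_sd
            p = 2 * stats.norm.sf(abs(z))
        else:
            z, p = float("nan"), float("nan")
        rows[metric] = dict(observed=observed, null_mean=null_mean,
                            null_sd=null_sd, z=z, p=p)
    return NullComparison(pd.DataFrame(rows).T, B=B, seed=seed)


def cor_to_dist(r, squared: bool = False):
    """Correlation to dissimilarity: sqrt(2(1 - r)) (or 2(1 - r) if squared).

    The square-root form is the cor2dist convention and is Euclidean for a
    proper correlation matrix.
    """
    r = np.asarray(r, dtype=float)
    if (np.abs(r) > 1 + 1e-12).any():
        raise ValueError("correlations must lie in [-1, 1]")
    d = 2.0 * (1.0 - np.clip(r, -1.0, 1.0))
    out = d if squared else np.sqrt(d)
    return float(out) if out.ndim == 0 else out


def by_cluster_matrix(assoc: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Replace each entry by the mean association of its cluster-pair block.

    Within-cluster blocks average off-diagonal entries only; the diagonal is
    left at its observed values (it is excluded from all comparisons).
    """
    assoc = np.asarray(assoc, dtype=float)
    out = assoc.copy()
    ids = np.unique(labels)
    for a in ids:
        ia = np.flatnonzero(labels == a)
        for b in ids:
            ib = np.flatnonzero(labels == b)
            block = assoc[np.ix_(ia, ib)]
            if a == b:
                if len(ia) > 1:
                    mask = ~np.eye(len(ia), dtype=bool)
                    out[np.ix_(ia, ia)] = block[mask].mean()
                    out[ia, ia] = assoc[ia, ia]
            else:
                out[np.ix_(ia, ib)] = block.mean()
    return out


@dataclass
class WardClusterResult:
    linkage: np.ndarray
    k: int
    labels: np.ndarray
    cor_by_k: pd.Series
    criterion_met: bool


def ward_cluster_select(
    assoc,
    min_bycluster_cor: float = 0.85,
    k_max: int | None = None,
    squared: bool = False,
) -> WardClusterResult:
    """Ward clustering of an association matrix with by-cluster model selection.

    Associations are converted to dissimilarities via :func:`cor_to_dist`,
    clustered with Ward linkage, and for each k the by-cluster (block-mean)
    matrix is correlated with the observed matrix over off-diagonal entries;
    the smallest k reaching ``min_bycluster_cor`` is chosen. If no k
    qualifies, k_max is returned with ``criterion_met=False``.
    """
    if isinstance(assoc, pd.DataFrame):
        assoc = assoc.to_numpy(dtype=float)
    assoc = np.asarray(assoc, dtype=float)
    if assoc.ndim != 2 or assoc.shape[0] != assoc.shape[1]:
        raise ValueError("association matrix must be square")
    if not np.allclose(assoc, assoc.T, atol=1e-10):
        raise ValueError("association matrix must be symmetric")
    n = assoc.shape[0]
    k_max = k_max or n
    dist = cor_to_dist(assoc, squared=squared)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="ward")
    iu = np.triu_indices(n, k=1)
    observed = assoc[iu]
    cors = {}
    chosen = None
    labels_for = {}
    for k in range(1, k_max + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        labels_for[k] = labels
        model = by_cluster_matrix(assoc, labels)[iu]
        if np.allclose(model, observed):
            cor = 1.0
        elif np.std(model) == 0 or np.std(observed) == 0:
            cor = 0.0
        else:
            cor = float(np.corrcoef(model, observed)[0, 1])
        cors[k] = cor
        if chosen is None and cor >= min_bycluster_cor:
            chosen = k
            break
    met = chosen is not None
    k = chosen if met else k_max
    return WardClusterResult(Z, k, labels_for[k], pd.Series(cors), met)
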