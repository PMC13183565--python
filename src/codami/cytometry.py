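"""Compositional analysis of hierarchical flow-cytometry gating data.

Each internal node of the gating tree defines a small composition (the
fraction-of-parent of its children). Two-component nodes are modeled with
beta regression; larger nodes with Dirichlet regression in the alternative
parameterization — component means through a multinomial-logit link (first
component as reference) and a scalar precision φ through a log link, so
concentrations are α_c = μ_c φ. Sub-trees on different branches are
conditionally independent, so per-node likelihood-ratio statistics for a
common-mean null add up to one global statistic Λ_overall with summed
degrees of freedom. Nodes whose components are positively correlated
(violating the Dirichlet's negative-dependence structure) are first split
into sub-blocks and tested as a deeper tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, psi

from codami.datasets import GatingDataset
from codami.stats import bh_adjust, polynomial_contrasts

_EPS = 1e-12


def shrink_unit(Y: np.ndarray) -> np.ndarray:
    """Pull compositions off the simplex boundary: (y(n-1) + 1/k) / n.

    The standard beta-regression adjustment, extended to k components so
    row sums are preserved exactly (k=2 reduces to (y(n-1)+0.5)/n).
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    k = Y.shape[1] if Y.ndim == 2 else 2
    return (Y * (n - 1) + 1.0 / k) / n


def dirichlet_loglik(Y, mu, phi) -> float:
    """Dirichlet log-likelihood in mean/precision form (α = μφ).

    ``Y`` and ``mu`` are sample × k on the open simplex; ``phi`` is scalar
    or per-sample. For k=2 this is exactly the beta density in its
    mean/precision parameterization.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (Y.shape[0],))
    if ((Y <= 0) | (Y >= 1)).any():
        raise ValueError("boundary proportions: shrink away from 0/1 first")
    if (phi <= 0).any():
        raise ValueError("precision must be positive")
    alpha = mu * phi[:, None]
    per_sample = (gammaln(phi) - gammaln(alpha).sum(axis=1)
                  + ((alpha - 1.0) * np.log(Y)).sum(axis=1))
    return float(per_sample.sum())


@dataclass
class DirichletFit:
    """ML fit of a Dirichlet (or beta, k=2) regression."""

    beta: np.ndarray  # (k-1) × p mean coefficients, component 1 reference
    gamma: np.ndarray  # precision coefficients (log link)
    loglik: float
    converged: bool
    vcov: np.ndarray | None  # over the packed parameter vector
    k: int
    n_params: int

    def mu(self, X: np.ndarray) -> np.ndarray:
        eta = np.zeros((X.shape[0], self.k))
        eta[:, 1:] = X @ self.beta.T
        e = np.exp(eta - eta.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def phi(self, Z: np.ndarray) -> np.ndarray:
        return np.exp(Z @ self.gamma)


def _pack(beta: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    return np.concatenate([beta.ravel(), gamma.ravel()])


def _neg_loglik_grad(theta, Y, X, Z, k):
    n, p = X.shape
    pz = Z.shape[1]
    beta = theta[: (k - 1) * p].reshape(k - 1, p)
    gamma = theta[(k - 1) * p:]
    eta = np.zeros((n, k))
    eta[:, 1:] = X @ beta.T
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    mu = e / e.sum(axis=1, keepdims=True)
    phi = np.exp(Z @ gamma)
    alpha = mu * phi[:, None]
    logY = np.log(Y)
    ll = (gammaln(phi) - gammaln(alpha).sum(axis=1)
          + ((alpha - 1.0) * logY).sum(axis=1)).sum()
    # gradient
    g = logY - psi(alpha)  # n × k
    weighted = (mu * g).sum(axis=1, keepdims=True)
    d_eta = phi[:, None] * mu * (g - weighted)  # n × k
    g_beta = d_eta[:, 1:].T @ X  # (k-1) × p
    d_zeta = phi * (psi(phi) + (mu * (logY - psi(alpha))).sum(axis=1))
    g_gamma = Z.T @ d_zeta
    return -ll, -_pack(g_beta, g_gamma)


def _start_values(Y, X, Z, k, rng=None):
    n, p = X.shape
    logratio = np.log(Y[:, 1:]) - np.log(Y[:, [0]])
    beta, *_ = np.linalg.lstsq(X, logratio, rcond=None)
    beta = beta.T  # (k-1) × p
    gamma = np.zeros(Z.shape[1])
    gamma[0] = np.log(10.0)
    if rng is not None:
        beta = beta + rng.normal(0, 0.3, beta.shape)
        gamma = gamma + rng.normal(0, 0.5, gamma.shape)
    return beta, gamma


def _hessian_fd(theta, args, step=1e-5):
    """Central finite differences of the analytic gradient."""
    m = theta.size
    H = np.empty((m, m))
    for j in range(m):
        tp = theta.copy(); tp[j] += step
        tm = theta.copy(); tm[j] -= step
        _, gp = _neg_loglik_grad(tp, *args)
        _, gm = _neg_loglik_grad(tm, *args)
        H[:, j] = (gp - gm) / (2 * step)
    return (H + H.T) / 2


def fit_dirichlet_regression(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None = None,
    n_restarts: int = 5,
    tol: float = 1e-8,
    seed: int = 0,
    want_vcov: bool = True,
) -> DirichletFit:
    """Maximum likelihood Dirichlet regression (alternative parameterization).

    Quasi-Newton (L-BFGS-B) with analytic gradients; random restarts if the
    first solve does not converge. ``Z`` is the precision design (default
    intercept only). Rows of ``Y`` must be interior; use :func:`shrink_unit`.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = Y.shape
    if k < 2:
        raise ValueError("need at least 2 components")
    if ((Y <= 0) | (Y >= 1)).any():
        raise ValueError("boundary proportions: shrink away from 0/1 first")
    Z = np.ones((n, 1)) if Z is None else np.asarray(Z, dtype=float)
    args = (Y, X, Z, k)
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(1 + n_restarts):
        beta0, gamma0 = _start_values(Y, X, Z, k, rng if attempt else None)
        res = optimize.minimize(
            _neg_loglik_grad, _pack(beta0, gamma0), args=args, jac=True,
            method="L-BFGS-B", options={"maxiter": 500, "ftol": tol, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            best = res if res.fun <= best.fun else best
            break
    theta = best.x
    p = X.shape[1]
    beta = theta[: (k - 1) * p].reshape(k - 1, p)
    gamma = theta[(k - 1) * p:]
    vcov = None
    if want_vcov:
        try:
            vcov = np.linalg.inv(_hessian_fd(theta, args))
        except np.linalg.LinAlgError:
            vcov = None
    return DirichletFit(beta=beta, gamma=gamma, loglik=-best.fun,
                        converged=bool(best.success), vcov=vcov, k=k,
                        n_params=theta.size)


def fit_beta_regression(y: np.ndarray, X: np.ndarray,
                        Z: np.ndarray | None = None, **kwargs) -> DirichletFit:
    """Beta regression (logit mean, log precision) as the k=2 Dirichlet case.

    ``y`` holds the modeled component's fractions; zeros/ones must be
    pre-shrunk with :func:`shrink_unit`. The returned ``beta`` row is the
    logit-mean coefficient vector of the modeled component.
    """
    y = np.asarray(y, dtype=float).ravel()
    Y = np.column_stack([1.0 - y, y])  # component 2 = modeled fraction
    return fit_dirichlet_regression(Y, X, Z=Z, **kwargs)


# ---------------------------------------------------------------------------
# tree partitioning
# ---------------------------------------------------------------------------

@dataclass
class PartitionDecision:
    split: bool
    groups: list[list[int]]  # column indices; [all] when not split
    p_values: np.ndarray | None = None


def check_subtree_partition(Y: np.ndarray, alpha: float = 0.05) -> PartitionDecision:
    """Split a node's components when some are significantly positively
    correlated (violating Dirichlet negative dependence).

    One-sided Pearson tests on each pair, Bonferroni-adjusted across the
    C(k,2) pairs so the familywise spurious-split rate stays at ``alpha``;
    the union of components in significant positive pairs forms one
    sub-block, the remainder the other.
    """
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    if k < 3:
        return PartitionDecision(False, [list(range(k))])
    r = np.corrcoef(Y.T)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, _EPS, None))
    pvals = stats.t.sf(t, n - 2)  # one-sided: positive correlation
    threshold = alpha / (k * (k - 1) / 2)
    positive = set()
    for i in range(k):
        for j in range(i + 1, k):
            if pvals[i, j] < threshold:
                positive |= {i, j}
    if not positive or len(positive) == k:
        return PartitionDecision(False, [list(range(k))], pvals)
    group1 = sorted(positive)
    group2 = [c for c in range(k) if c not in positive]
    return PartitionDecision(True, [group1, group2], pvals)


# ---------------------------------------------------------------------------
# nested global test
# ---------------------------------------------------------------------------

@dataclass
class NestedTestResult:
    lambda_overall: float
    df: int
    p: float
    subtree_stats: pd.DataFrame  # node, k, LRT, df, p
    partition_log: list[str] = field(default_factory=list)


def _timepoint_design(metadata: pd.DataFrame):
    levels = metadata[["timepoint", "age"]].drop_duplicates().sort_values("age")
    ages = levels["age"].to_numpy(dtype=float)
    labels = levels["timepoint"].astype(str).tolist()
    P = polynomial_contrasts(ages, degree=len(ages) - 1)
    idx = metadata["timepoint"].astype(str).map(
        {t: i for i, t in enumerate(labels)}).to_numpy()
    X_full = np.column_stack([np.ones(len(metadata))] + [P[j, idx] for j in
                                                         range(P.shape[0])])
    X_null = X_full[:, :1]
    return X_null, X_full, P, labels


def _block_lrt(Yb: np.ndarray, X_null, X_full, seed: int):
    """(LRT, df, fitted null) for a timepoint effect on one component block."""
    k = Yb.shape[1]
    q = X_full.shape[1] - X_null.shape[1]
    if k == 2:
        f0 = fit_beta_regression(Yb[:, 1], X_null, seed=seed, want_vcov=False)
        f1 = fit_beta_regression(Yb[:, 1], X_full, seed=seed, want_vcov=False)
    else:
        f0 = fit_dirichlet_regression(Yb, X_null, seed=seed, want_vcov=False)
        f1 = fit_dirichlet_regression(Yb, X_full, seed=seed, want_vcov=False)
    lrt = max(0.0, 2.0 * (f1.loglik - f0.loglik))
    return lrt, (k - 1) * q, f0


def _collect_blocks(data: GatingDataset, partition_alpha: float):
    """Shrunk, renormalized component blocks per sub-tree after partitioning."""
    pieces: list[tuple[str, np.ndarray]] = []
    partition_log: list[str] = []
    for node in data.tree.internal_nodes:
        block = data.child_block(node).to_numpy()
        Yb = shrink_unit(block)
        Yb = Yb / Yb.sum(axis=1, keepdims=True)
        decision = check_subtree_partition(Yb, alpha=partition_alpha)
        if decision.split:
            partition_log.append(
                f"{node}: split into {decision.groups} (positive correlation)")
            sums = np.column_stack([Yb[:, g].sum(axis=1) for g in decision.groups])
            pieces.append((f"{node}[blocks]", sums / sums.sum(axis=1, keepdims=True)))
            for gi, g in enumerate(decision.groups):
                if len(g) >= 2:
                    sub = Yb[:, g]
                    pieces.append((f"{node}[group{gi}]",
                                   sub / sub.sum(axis=1, keepdims=True)))
        else:
            pieces.append((node, Yb))
    return pieces, partition_log


def nested_global_test(data: GatingDataset, partition_alpha: float = 0.05,
                       seed: int = 0, n_bartlett: int = 40) -> NestedTestResult:
    """Global LRT for a timepoint effect summed over gating sub-trees.

    Under the null every sub-tree has a common mean vector across groups;
    Λ_overall sums the per-sub-tree LRTs and is referred to a χ² with the
    summed degrees of freedom (sub-trees are conditionally independent).

    With a dozen parameters per quadrant node and a few dozen samples the
    raw χ² reference is anticonservative, so a bootstrap small-sample
    correction is applied by default: ``n_bartlett`` datasets are drawn
    from the fitted null of each block, Λ is recomputed on each, and the
    p-value is read from a scaled χ² (Satterthwaite: scale and df matched
    to the bootstrap null mean and variance of Λ). The reported Λ and df
    are the raw summed statistics. Set ``n_bartlett=0`` for the plain
    χ²(df) reference.
    """
    X_null, X_full, _, _ = _timepoint_design(data.metadata)
    pieces, partition_log = _collect_blocks(data, partition_alpha)
    rows = []
    null_fits = []
    for name, Yp in pieces:
        try:
            lrt, df, f0 = _block_lrt(Yp, X_null, X_full, seed)
        except (ValueError, np.linalg.LinAlgError) as err:  # pragma: no cover
            warnings.warn(f"sub-tree {name!r} unfittable ({err}); excluded",
                          stacklevel=2)
            continue
        rows.append({"node": name, "k": Yp.shape[1], "LRT": lrt, "df": df,
                     "p": stats.chi2.sf(lrt, df)})
        null_fits.append((Yp.shape, f0))
    table = pd.DataFrame(rows)
    lam = float(table["LRT"].sum())
    df = int(table["df"].sum())

    p_value = float(stats.chi2.sf(lam, df))
    if n_bartlett and lam > 0:
        rng = np.random.default_rng(seed + 987654)
        n = len(data.samples)
        totals = np.zeros(n_bartlett)
        for (_shape, f0) in null_fits:
            mu0 = f0.mu(X_null[:1])[0]  # constant under the null
            phi0 = float(f0.phi(np.ones((1, 1)))[0])
            alpha0 = mu0 * phi0
            for b in range(n_bartlett):
                Yb = rng.dirichlet(alpha0, size=n)
                Yb = shrink_unit(Yb)
                Yb = Yb / Yb.sum(axis=1, keepdims=True)
                try:
                    lrt_b, _, _ = _block_lrt(Yb, X_null, X_full, seed)
                except (ValueError, np.linalg.LinAlgError):  # pragma: no cover
                    continue
                totals[b] += lrt_b
        m, v = totals.mean(), totals.var(ddof=1)
        if m > 0 and v > 0:
            scale = v / (2 * m)
            nu = 2 * m**2 / v
            p_value = float(stats.chi2.sf(lam / scale, nu))
    return NestedTestResult(lam, df, p_value, table, partition_log)


# ---------------------------------------------------------------------------
# follow-up contrasts
# ---------------------------------------------------------------------------

def followup_contrasts(data: GatingDataset, fdr: float = 0.05,
                       gate_alpha: float | None = 0.05,
                       seed: int = 0) -> pd.DataFrame:
    """Sequential-interval Wald tests per component, BH within tissue.

    Each component's fraction-of-parent is modeled with beta regression on
    timepoint; reverse-difference contrasts estimate each adjacent-interval
    change on the logit scale. Runs only when the global test clears
    ``gate_alpha`` (set None to always run).
    """
    if gate_alpha is not None:
        overall = nested_global_test(data, seed=seed)
        if overall.p >= gate_alpha:
            return pd.DataFrame(columns=["tissue", "node", "component",
                                         "interval", "estimate", "se", "p",
                                         "q", "direction"])
    X_null, X_full, P, labels = _timepoint_design(data.metadata)
    k_t = len(labels)
    rows = []
    for node in data.tree.internal_nodes:
        block = data.child_block(node)
        children = list(block.columns)
        Yb = shrink_unit(block.to_numpy())
        for ci, child in enumerate(children):
            y = Yb[:, ci]
            fit = fit_beta_regression(y, X_full, seed=seed)
            if fit.vcov is None:
                continue
            b = fit.beta[0]
            V = fit.vcov[: len(b), : len(b)]
            for i in range(k_t - 1):
                d = np.zeros(len(b))
                d[1:] = P[:, i + 1] - P[:, i]
                est = float(d @ b)
                se = float(np.sqrt(d @ V @ d))
                z = est / se if se > 0 else np.nan
                rows.append({
                    "tissue": data.metadata["tissue"].iloc[0],
                    "node": node, "component": child,
                    "interval": f"{labels[i]}->{labels[i + 1]}",
                    "estimate": est, "se": se,
                    "p": 2 * stats.norm.sf(abs(z)),
                    "direction": "up" if est > 0 else "down",
                })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = np.nan
        for tissue, idx in out.groupby("tissue").groups.items():
            out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out


def fitted_curve_table(data: GatingDataset, node: str, n_grid: int = 50,
                       seed: int = 0) -> pd.DataFrame:
    """Smooth fitted mean/precision curves over age for plotting.

    Refits the node block with age (weeks, continuous) as the regressor —
    a visualization aid, not the inferential model.
    """
    block = data.child_block(node)
    Yb = shrink_unit(block.to_numpy())
    Yb = Yb / Yb.sum(axis=1, keepdims=True)
    weeks = data.metadata["age"].to_numpy(dtype=float) / 7.0
    X = np.column_stack([np.ones(len(weeks)), weeks])
    fit = (fit_beta_regression(Yb[:, 1], X, seed=seed) if Yb.shape[1] == 2
           else fit_dirichlet_regression(Yb, X, seed=seed))
    grid = np.linspace(weeks.min(), weeks.max(), n_grid)
    Xg = np.column_stack([np.ones(n_grid), grid])
    mu = fit.mu(Xg)
    out = pd.DataFrame(mu, columns=list(block.columns))
    out.insert(0, "weeks", grid)
    out["phi"] = fit.phi(np.ones((n_grid, 1)))
    return out
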