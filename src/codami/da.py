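"""Consensus differential abundance from two bias-corrected log-linear models.

Model A regresses CLR-transformed abundances on the design and removes the
compositional bias shared by all taxa by subtracting the mode of each
coefficient across taxa (the coefficient-mode idea). Model B regresses
log counts with a per-sample offset standing in for the unknown sampling
fraction, estimated by iterating between taxon-wise fits and median
residuals per sample. Both models test a global age trend via weighted
(orthonormal) polynomial contrasts on the actual ages, plus sequential
adjacent-timepoint contrasts, BH-corrected within each contrast family.
The consensus set is the intersection of both models' significant taxa at
shared q-value and effect-size thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from codami import coda
from codami.datasets import TaxaCountTable
from codami.stats import (  # noqa: F401  (re-exported module surface)
    bh_adjust,
    half_sample_mode,
    polynomial_contrasts,
    reverse_difference_contrasts,
)

LOG2 = np.log(2.0)


@dataclass
class DAResult:
    """Per-taxon effects and tests from one differential-abundance model.

    Effects are adjacent-interval changes in log2 units; q-values are BH
    within (model, interval) families and q_global within the model.
    """

    model_id: str
    effects: pd.DataFrame  # taxa × intervals, log2 scale
    se: pd.DataFrame
    p_pairwise: pd.DataFrame
    q_pairwise: pd.DataFrame
    p_global: pd.Series
    q_global: pd.Series
    converged: bool = True
    n_iter: int = 0

    @property
    def intervals(self) -> list[str]:
        return list(self.effects.columns)

    def significant(self, alpha_q: float = 0.01, effect_min: float = 1.0) -> pd.DataFrame:
        """Boolean taxa × interval mask of q < alpha_q and |effect| > effect_min."""
        return (self.q_pairwise < alpha_q) & (self.effects.abs() > effect_min)


def _design(metadata: pd.DataFrame, include_sex: bool = True):
    """Design matrix: intercept + orthonormal age-polynomial contrasts
    (saturated in timepoint) + centered sex; plus the pieces needed to map
    coefficients back onto timepoint-level means."""
    levels = metadata[["timepoint", "age"]].drop_duplicates().sort_values("age")
    labels = levels["timepoint"].astype(str).tolist()
    ages = levels["age"].to_numpy(dtype=float)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 timepoints")
    P = polynomial_contrasts(ages, degree=k - 1)  # (k-1) × k
    level_idx = metadata["timepoint"].astype(str).map({t: i for i, t in enumerate(labels)})
    cols = [np.ones(len(metadata))]
    names = ["intercept"]
    for j in range(k - 1):
        cols.append(P[j, level_idx.to_numpy()])
        names.append(f"poly{j + 1}")
    if include_sex and metadata["sex"].nunique() > 1:
        sexes = sorted(metadata["sex"].unique())
        cols.append(np.where(metadata["sex"] == sexes[-1], 0.5, -0.5))
        names.append("sex")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    counts = metadata.groupby("timepoint", observed=True).size()
    if (counts < 2).any():
        raise ValueError("need at least 2 samples per timepoint")
    return X, names, P, labels


def _wald_tables(Y: np.ndarray, X: np.ndarray, names: list[str],
                 P: np.ndarray, labels: list[str], taxa, model_id: str,
                 bias_correct: str | None, converged: bool = True,
                 n_iter: int = 0) -> DAResult:
    """Shared OLS + contrast machinery for both DA models.

    ``Y`` is samples × taxa on a natural-log-like scale. ``bias_correct``
    subtracts a robust across-taxa location (``"mode"`` for model A,
    ``"median"`` for model B) from every non-intercept coefficient before
    testing: a shared shift of all taxa — compositional closure in model A,
    the design-aligned part of the sampling fractions in model B — is not a
    differential signal. Wald tests use HC3 (leverage-adjusted)
    heteroscedasticity-robust covariances, since dispersion genuinely
    differs between developmental timepoints.
    """
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # p × T
    resid = Y - X @ B
    dof = n - p
    leverage = np.einsum("np,pq,nq->n", X, XtX_inv, X)
    W = (resid / (1.0 - leverage)[:, None]) ** 2  # n × T, HC3 weights
    Mh = X @ XtX_inv  # n × p

    if bias_correct == "mode":
        for j in range(1, p):
            B[j] = B[j] - half_sample_mode(B[j])
    elif bias_correct == "median":
        for j in range(1, p):
            B[j] = B[j] - np.median(B[j])
    elif bias_correct is not None:
        raise ValueError(f"unknown bias correction {bias_correct!r}")

    poly_rows = [i for i, nm in enumerate(names) if nm.startswith("poly")]
    q_terms = len(poly_rows)
    A = Mh[:, poly_rows]  # n × q
    Bp = B[poly_rows]  # q × T
    cov = np.einsum("nq,nt,nr->tqr", A, W, A)  # T × q × q robust cov
    wald = np.einsum("qt,tqr,rt->t", Bp, np.linalg.inv(cov), Bp)
    p_global = pd.Series(sps.f.sf(wald / q_terms, q_terms, dof), index=taxa,
                         name="p_global")

    k = len(labels)
    intervals = [f"{labels[i]}->{labels[i + 1]}" for i in range(k - 1)]
    eff = np.empty((len(taxa), k - 1))
    se = np.empty_like(eff)
    pvals = np.empty_like(eff)
    for i in range(k - 1):
        d = P[:, i + 1] - P[:, i]  # weights on poly coefficients
        diff = d @ Bp
        a = A @ d
        var = (a[:, None] ** 2 * W).sum(axis=0)
        eff[:, i] = diff / LOG2
        se[:, i] = np.sqrt(var) / LOG2
        t = diff / np.sqrt(var)
        pvals[:, i] = 2 * sps.t.sf(np.abs(t), dof)
    qvals = np.column_stack([bh_adjust(pvals[:, i]) for i in range(k - 1)])

    return DAResult(
        model_id=model_id,
        effects=pd.DataFrame(eff, index=taxa, columns=intervals),
        se=pd.DataFrame(se, index=taxa, columns=intervals),
        p_pairwise=pd.DataFrame(pvals, index=taxa, columns=intervals),
        q_pairwise=pd.DataFrame(qvals, index=taxa, columns=intervals),
        p_global=p_global,
        q_global=pd.Series(bh_adjust(p_global.to_numpy()), index=taxa,
                           name="q_global"),
        converged=converged,
        n_iter=n_iter,
    )


def fit_model_A(table: TaxaCountTable, zero_factor: float = 0.5,
                include_sex: bool = True) -> DAResult:
    """CLR-OLS with coefficient-mode compositional bias correction.

    Counts are closed to proportions first and zeros multiplicatively
    replaced with ``zero_factor`` times the smallest observed non-zero
    proportion; working on the proportion scale makes the model exactly
    invariant to per-sample count scaling (the compositional property the
    model exists for).
    """
    X, names, P, labels = _design(table.metadata, include_sex)
    rel = coda.closure(table.counts.T.to_numpy(dtype=float))  # samples × taxa
    positive = rel[rel > 0]
    Y = coda.clr(coda.replace_zeros(rel, zero_factor * positive.min()))
    return _wald_tables(Y, X, names, P, labels, table.taxa, "A_clr_bias",
                        bias_correct="mode")


def fit_model_B(table: TaxaCountTable, pseudocount: float = 1.0,
                include_sex: bool = True, max_iter: int = 50,
                tol: float = 1e-6) -> DAResult:
    """Log-count OLS with iteratively estimated per-sample offsets.

    The offset plays the role of an unknown per-sample sampling fraction:
    alternately fit taxon models given the offsets and update each sample's
    offset by its median residual across taxa, until stable.
    """
    X, names, P, labels = _design(table.metadata, include_sex)
    Y = np.log(table.counts.T.to_numpy(dtype=float) + pseudocount)
    n = Y.shape[0]
    H = np.linalg.inv(X.T @ X) @ X.T
    offsets = np.zeros(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        B = H @ (Y - offsets[:, None])
        resid = Y - offsets[:, None] - X @ B
        delta = np.median(resid, axis=1)
        previous = offsets
        offsets = offsets + delta
        # the design-spanned part of the offsets is not identifiable (it is
        # absorbed by the coefficients); keep only the residualized part
        offsets = offsets - X @ (H @ offsets)
        if np.max(np.abs(offsets - previous)) < tol:
            converged = True
            break
    return _wald_tables(Y - offsets[:, None], X, names, P, labels, table.taxa,
                        "B_offset_bias", bias_correct="median",
                        converged=converged, n_iter=it)


@dataclass
class ConsensusSet:
    """Taxa significant in both models per adjacent interval."""

    per_interval: dict[str, frozenset[str]]
    alpha_q: float
    effect_min: float

    @property
    def all_taxa(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.per_interval.values():
            out |= s
        return out

    def frame(self) -> pd.DataFrame:
        rows = [(iv, t) for iv, s in self.per_interval.items() for t in sorted(s)]
        return pd.DataFrame(rows, columns=["interval", "taxon"])


def consensus(resA: DAResult, resB: DAResult, alpha_q: float = 0.01,
              effect_min: float = 1.0) -> ConsensusSet:
    """Intersect the two models' significant sets per interval."""
    if not resA.effects.index.equals(resB.effects.index):
        raise ValueError("models were fit on different taxon sets")
    if resA.intervals != resB.intervals:
        raise ValueError("models cover different intervals")
    sigA = resA.significant(alpha_q, effect_min)
    sigB = resB.significant(alpha_q, effect_min)
    both = sigA & sigB
    per_interval = {
        iv: frozenset(both.index[both[iv]]) for iv in resA.intervals
    }
    return ConsensusSet(per_interval, alpha_q, effect_min)
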