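"""Small shared statistical helpers: contrast builders, BH adjustment, and a
robust mode estimator."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def polynomial_contrasts(ages, degree: int) -> np.ndarray:
    """Orthonormal polynomial contrasts on (possibly unequally spaced) ages.

    Built by Gram–Schmidt (QR) on powers of the centered ages; row j of the
    returned (degree × k) matrix is the degree-(j+1) contrast, each row
    summing to 0 with unit norm.
    """
    ages = np.asarray(ages, dtype=float)
    if len(np.unique(ages)) != len(ages):
        raise ValueError("ages must be distinct")
    if np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing")
    k = len(ages)
    if not 1 <= degree < k:
        raise ValueError(f"degree must be in [1, {k - 1}]")
    centered = ages - ages.mean()
    V = np.vander(centered, N=degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    # fix sign so the leading (highest-power) coefficient is positive
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    return Q[:, 1:].T


def reverse_difference_contrasts(k: int) -> np.ndarray:
    """(k-1) × k contrasts, row i estimating level_{i+1} - level_i."""
    if k < 2:
        raise ValueError("need at least 2 levels")
    C = np.zeros((k - 1, k))
    for i in range(k - 1):
        C[i, i] = -1.0
        C[i, i + 1] = 1.0
    return C


def half_sample_mode(x) -> float:
    """Midpoint of the densest half-width window of the data.

    A robust, deterministic mode estimate: the shortest window covering half
    the sorted values, reported by its midpoint.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty input")
    if n <= 2:
        return float(x.mean())
    h = (n + 1) // 2
    widths = x[h - 1:] - x[: n - h + 1]
    i = int(np.argmin(widths))
    return float((x[i] + x[i + h - 1]) / 2.0)
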