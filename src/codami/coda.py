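"""Compositional primitives: closure, zero replacement, CLR, Aitchison
distance, and the three-step USS transform for gated cytometry data.

All operations act on sample × feature tables (DataFrame or ndarray, samples
as rows). A composition is a row of non-negative parts carrying only
relative information; closure rescales it to the unit simplex, the centered
log-ratio (CLR) maps it to a zero-sum real vector, and Aitchison distance is
the Euclidean distance between CLR vectors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from codami.datasets import DegenerateSampleError, GatingDataset


class MustUnzeroError(ValueError):
    """Zeros reached a log-ratio step; run zero replacement first."""


def _as_array(x):
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), x
    return np.asarray(x, dtype=float), None


def _like(values: np.ndarray, template):
    if template is not None:
        return pd.DataFrame(values, index=template.index, columns=template.columns)
    return values


def closure(counts):
    """Rescale each row to sum to 1.

    Raises :class:`DegenerateSampleError` naming the first all-zero sample.
    """
    vals, template = _as_array(counts)
    vals = np.atleast_2d(vals)
    if (vals < 0).any():
        raise ValueError("negative entries are not a composition")
    totals = vals.sum(axis=1)
    if (totals == 0).any():
        i = int(np.argmax(totals == 0))
        name = template.index[i] if template is not None else i
        raise DegenerateSampleError(f"sample {name!r} has zero total")
    out = vals / totals[:, None]
    return _like(out, template)


def replace_zeros(comp, delta: float | None = None):
    """Multiplicative zero replacement on a closed composition.

    Zeros become ``delta``; the non-zero parts of a row with ``z`` zeros are
    shrunk by ``(1 - z * delta)`` so the row stays closed exactly. Default
    ``delta`` is half the smallest non-zero proportion in the table.
    """
    vals, template = _as_array(comp)
    vals = np.atleast_2d(vals)
    positive = vals[vals > 0]
    if positive.size == 0:
        raise ValueError("composition has no positive entries")
    if delta is None:
        delta = 0.5 * positive.min()
    if delta <= 0:
        raise ValueError("delta must be positive")
    zeros = vals == 0
    n_zero = zeros.sum(axis=1)
    # delta must stay below every row's smallest positive part, else the
    # replacement would reorder parts or drive the rescale factor negative
    row_min_pos = np.where(vals > 0, vals, np.inf).min(axis=1)
    too_big = (n_zero > 0) & (delta >= row_min_pos)
    if too_big.any():
        i = int(np.argmax(too_big))
        raise ValueError(
            f"delta={delta:g} is not below the smallest positive entry "
            f"({row_min_pos[i]:g}) of row {i}"
        )
    out = vals * (1.0 - n_zero * delta)[:, None]
    out[zeros] = delta
    return _like(out, template)


def clr(comp):
    """Centered log-ratio: ln(x_i / geometric mean of the row).

    Rows of the output sum to zero. Input must be strictly positive.
    """
    vals, template = _as_array(comp)
    vals = np.atleast_2d(vals)
    if (vals <= 0).any():
        raise MustUnzeroError("CLR requires strictly positive parts; replace zeros first")
    logged = np.log(vals)
    out = logged - logged.mean(axis=1, keepdims=True)
    return _like(out, template)


def aitchison_distance(x, y) -> float:
    """Euclidean distance between the CLR images of two compositions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    cx = clr(closure(x))
    cy = clr(closure(y))
    return float(np.linalg.norm(cx - cy))


def standardize_columns(df: pd.DataFrame, warn: bool = True):
    """Z-score each column; constant columns are dropped with a warning."""
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant) and warn:
        warnings.warn(
            f"dropping {len(constant)} constant feature(s): {list(constant)[:5]}",
            stacklevel=2,
        )
    keep = df.columns.difference(constant, sort=False)
    return (df[keep] - mean[keep]) / sd[keep]


def uss_transform(
    gating: GatingDataset,
    delta: float | None = None,
    drop_complements: bool = True,
    standardize: bool = True,
) -> pd.DataFrame:
    """Unzero–stabilize–standardize transform of a gating dataset.

    Step 1 (unzero): multiplicative zero replacement within each sibling
    block of the gating tree. Step 2 (stabilize): CLR within each sibling
    block, so features live on an unconstrained log-ratio scale. Step 3
    (standardize): z-score each feature column across samples. For
    two-child blocks the second CLR column is the exact negative of the
    first; when ``drop_complements`` is set the redundant complement column
    is dropped. ``standardize=False`` stops after step 2 (the blockwise-CLR
    scale wanted by variance-sensitive association measures such as
    proportionality).
    """
    pieces = []
    for node in gating.tree.internal_nodes:
        block = gating.child_block(node)
        positive = block.to_numpy()[block.to_numpy() > 0]
        block_delta = delta if delta is not None else 0.5 * positive.min()
        stabilized = clr(replace_zeros(closure(block), block_delta))
        if drop_complements and stabilized.shape[1] == 2:
            stabilized = stabilized.iloc[:, [0]]
        pieces.append(stabilized)
    combined = pd.concat(pieces, axis=1)
    return standardize_columns(combined) if standardize else combined
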