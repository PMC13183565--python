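"""Core data containers shared by every pipeline stage.

Two root objects: :class:`TaxaCountTable` for the microbiome side (taxon ×
sample integer counts with ranked lineages and sample metadata) and
:class:`GatingDataset` for the cytometry side (a rooted gating tree plus
per-sample fraction-of-parent proportions at every node).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]

CLOSURE_TOL = 1e-9


class DegenerateSampleError(ValueError):
    """A sample with zero total mass where a composition is required."""


@dataclass
class TaxaCountTable:
    """Taxon × sample count table with lineages and sample metadata.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, taxa as rows, samples as columns.
    lineage : Series
        Taxon id -> semicolon-joined ranked lineage, kingdom first.
    metadata : DataFrame
        Sample id -> at least ``timepoint`` (ordered label), ``age``
        (numeric, days) and ``sex``.
    """

    counts: pd.DataFrame
    lineage: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        missing = self.counts.columns.difference(self.metadata.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if not self.counts.index.equals(self.lineage.index):
            self.lineage = self.lineage.reindex(self.counts.index)
            if self.lineage.isna().any():
                raise ValueError("taxa without lineage entries")
        depths = self.lineage.str.count(";").unique()
        if len(depths) > 1:
            raise ValueError("lineages have inconsistent rank depth")

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def lineage_frame(self) -> pd.DataFrame:
        """Lineage split into one column per rank (as deep as provided)."""
        parts = self.lineage.str.split(";", expand=True)
        parts.columns = RANKS[: parts.shape[1]]
        return parts

    def relative_abundance(self) -> pd.DataFrame:
        """Sample × taxon relative abundances (rows sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise DegenerateSampleError(f"sample {bad!r} has zero total count")
        return (self.counts / totals).T

    def subset_samples(self, samples) -> "TaxaCountTable":
        samples = pd.Index(samples)
        return TaxaCountTable(
            self.counts[samples], self.lineage, self.metadata.loc[samples]
        )


@dataclass
class GatingTree:
    """Rooted tree of gated populations, node ids are '/'-joined paths."""

    root: str
    children: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise ValueError(f"node {node!r} reachable twice; not a tree")
            seen.add(node)
            stack.extend(self.children.get(node, []))
        declared = {self.root} | {c for cs in self.children.values() for c in cs}
        if declared - seen:
            raise ValueError(f"unreachable nodes: {sorted(declared - seen)}")
        self._nodes = sorted(seen)

    @property
    def nodes(self) -> list[str]:
        return list(self._nodes)

    @property
    def internal_nodes(self) -> list[str]:
        return [n for n in self._nodes if self.children.get(n)]

    @property
    def leaves(self) -> list[str]:
        return [n for n in self._nodes if not self.children.get(n)]

    def parent_of(self) -> dict[str, str]:
        return {c: p for p, cs in self.children.items() for c in cs}

    def path_to_root(self, node: str) -> list[str]:
        parent = self.parent_of()
        path = [node]
        while path[-1] != self.root:
            path.append(parent[path[-1]])
        return path


@dataclass
class GatingDataset:
    """Gating tree + per-sample fraction-of-parent at every node.

    ``proportions`` is sample × node; the root column is identically 1 and
    the children of every internal node sum to 1 for every sample.
    """

    tree: GatingTree
    proportions: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.tree.nodes) - set(self.proportions.columns)
        if missing:
            raise ValueError(f"nodes without proportions: {sorted(missing)}")
        missing_meta = self.proportions.index.difference(self.metadata.index)
        if len(missing_meta):
            raise ValueError(f"samples without metadata: {list(missing_meta)[:5]}")
        self.validate()

    def validate(self, tol: float = CLOSURE_TOL) -> None:
        """Enforce closure at every internal node, naming offenders."""
        root_col = self.proportions[self.tree.root]
        if not np.allclose(root_col, 1.0, atol=tol):
            raise ValueError("root fraction must be identically 1")
        vals = self.proportions
        if ((vals < -tol) | (vals > 1 + tol)).any().any():
            raise ValueError("proportions outside [0, 1]")
        for node in self.tree.internal_nodes:
            sums = vals[self.tree.children[node]].sum(axis=1)
            bad = sums.index[np.abs(sums - 1.0) > tol]
            if len(bad):
                raise ValueError(
                    f"children of {node!r} sum to {sums[bad[0]]:.6g} != 1 "
                    f"for sample {bad[0]!r}"
                )

    @property
    def samples(self) -> pd.Index:
        return self.proportions.index

    def child_block(self, node: str) -> pd.DataFrame:
        """Sample × child fraction-of-parent block for one internal node."""
        return self.proportions[self.tree.children[node]]

    def absolute_fractions(self) -> pd.DataFrame:
        """Fraction of the root population, multiplying down the tree."""
        out = {}
        for node in self.tree.nodes:
            path = self.tree.path_to_root(node)
            out[node] = self.proportions[path].prod(axis=1)
        return pd.DataFrame(out, index=self.proportions.index)

    def subset_samples(self, samples) -> "GatingDataset":
        samples = pd.Index(samples)
        return GatingDataset(
            self.tree, self.proportions.loc[samples], self.metadata.loc[samples]
        )
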