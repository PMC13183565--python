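"""Readers and writers for the pipeline's on-disk formats.

Count tables and metadata travel as TSV (taxa rows with a ``lineage``
column; samples as columns), gating data as long-format CSV
(sample_id, node_path, proportion_of_parent) from which the tree topology
is reconstructed, and networks as GraphML or GML via networkx.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from codami.datasets import GatingDataset, GatingTree, TaxaCountTable


class ParseError(ValueError):
    """Malformed input file; the message carries file and line context."""


def write_count_table(table: TaxaCountTable, counts_path, metadata_path) -> None:
    out = table.counts.copy()
    out.insert(0, "lineage", table.lineage)
    out.to_csv(counts_path, sep="\t", index_label="taxon")
    meta = table.metadata.copy()
    meta.to_csv(metadata_path, sep="\t", index_label="sample")


def read_count_table(counts_path, metadata_path) -> TaxaCountTable:
    df = pd.read_csv(counts_path, sep="\t", index_col="taxon")
    if "lineage" not in df.columns:
        raise ParseError(f"{counts_path}: missing 'lineage' column")
    lineage = df.pop("lineage")
    for i, (taxon, row) in enumerate(df.iterrows(), start=2):
        bad = row[pd.to_numeric(row, errors="coerce").isna()]
        if len(bad):
            raise ParseError(
                f"{counts_path}:{i}: non-numeric count {bad.iloc[0]!r} "
                f"for taxon {taxon!r}, sample {bad.index[0]!r}")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    if "timepoint" in meta.columns and "age" in meta.columns:
        order = (meta[["timepoint", "age"]].drop_duplicates()
                 .sort_values("age")["timepoint"].tolist())
        meta["timepoint"] = pd.Categorical(meta["timepoint"], categories=order,
                                           ordered=True)
    df.index.name = None
    lineage.index.name = None
    return TaxaCountTable(df.astype(np.int64), lineage, meta)


def write_gating_csv(gating: GatingDataset, path, metadata_path=None) -> None:
    long = gating.proportions.stack().rename("proportion_of_parent")
    long.index.names = ["sample_id", "node_path"]
    long.reset_index().to_csv(path, index=False)
    if metadata_path is not None:
        gating.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def _tree_from_paths(paths) -> GatingTree:
    children: dict[str, list[str]] = {}
    roots = set()
    for p in sorted(set(paths)):
        if "/" in p:
            parent = p.rsplit("/", 1)[0]
            children.setdefault(parent, []).append(p)
        else:
            roots.add(p)
    if len(roots) != 1:
        raise ParseError(f"expected exactly one root node, found {sorted(roots)}")
    return GatingTree(root=roots.pop(), children=children)


def read_gating_csv(path, metadata_path) -> GatingDataset:
    df = pd.read_csv(path)
    required = {"sample_id", "node_path", "proportion_of_parent"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    numeric = pd.to_numeric(df["proportion_of_parent"], errors="coerce")
    if numeric.isna().any():
        i = int(numeric.index[numeric.isna()][0])
        raise ParseError(
            f"{path}:{i + 2}: non-numeric proportion "
            f"{df['proportion_of_parent'].iloc[i]!r}")
    df["proportion_of_parent"] = numeric
    props = df.pivot(index="sample_id", columns="node_path",
                     values="proportion_of_parent")
    if props.isna().any().any():
        sample = props.index[props.isna().any(axis=1)][0]
        raise ParseError(f"{path}: sample {sample!r} is missing some nodes")
    tree = _tree_from_paths(props.columns)
    props.index.name = None
    props.columns.name = None
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    if "timepoint" in meta.columns and "age" in meta.columns:
        order = (meta[["timepoint", "age"]].drop_duplicates()
                 .sort_values("age")["timepoint"].tolist())
        meta["timepoint"] = pd.Categorical(meta["timepoint"], categories=order,
                                           ordered=True)
    return GatingDataset(tree, props, meta.loc[props.index])


def write_tree_spec(tree: GatingTree, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"root": tree.root, "children": tree.children}, fh)


def read_tree_spec(path) -> GatingTree:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return GatingTree(root=spec["root"], children=spec.get("children", {}))


def write_network(G: nx.Graph, path, fmt: str = "graphml") -> None:
    G = nx.Graph(G)
    for _, data in G.nodes(data=True):
        for k, v in list(data.items()):
            if v is None:
                data[k] = ""
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "gml":
        nx.write_gml(G, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "graphml") -> nx.Graph:
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "gml":
        return nx.read_gml(path)
    raise ValueError(f"unknown network format {fmt!r}")


def write_distance_matrix(dm, path) -> None:
    pd.DataFrame(np.asarray(dm.data), index=list(dm.ids),
                 columns=list(dm.ids)).to_csv(path, sep="\t", index_label="sample")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
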