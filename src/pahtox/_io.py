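"""Tabular / tree / graph serialization helpers.

All tables are tab-delimited with a header line; matrices carry a row-id
first column; floats use 10 significant digits so re-runs diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy.cluster.hierarchy import to_tree

FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index=True, index_label=index_label, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _quote(label: str) -> str:
    # newick-reserved characters -> quoted label
    if any(ch in label for ch in "(),:;[] '\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def linkage_to_newick(Z, labels) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = FLOAT_FMT % (parent_height - node.dist)
        if node.is_leaf():
            return f"{_quote(str(labels[node.id]))}:{length}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"


def write_graphml(edges: pd.DataFrame, path, nodes=None) -> None:
    from .network import to_graph

    import networkx as nx

    nx.write_graphml(to_graph(edges, nodes=nodes), path)
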