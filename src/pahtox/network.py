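"""Condition-similarity network inference over treatments.

Each condition (treatment or vehicle control) is summarized by its mean
expression profile over the top coefficient-of-variation genes.  Pairwise
similarity is the plug-in mutual information of the joint histogram after
equal-frequency discretization of each profile.  The MI matrix is then
background-corrected into Z-scores either

* mode ``"clr"`` — the Context Likelihood of Relatedness transform: each
  node's off-diagonal MI row provides a background (mu_i, sigma_i);
  z_i = max(0, (MI_ij - mu_i)/sigma_i) and Z_ij = sqrt(z_i^2 + z_j^2); or
* mode ``"global"`` — a single standardization of all off-diagonal MI
  values to mean 0, sd 1.

Connectors (edges) are pairs with Z strictly above a threshold (default 1),
and the two broad transcriptomic clusters are obtained by average-linkage
clustering of the condition profiles under correlation distance, with the
cluster containing the vehicle controls labeled "A".
"""

from __future__ import annotations

import math
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

__all__ = [
    "ControlSplitError",
    "ZMatrix",
    "discretize_equal_frequency",
    "empirical_mi",
    "mi_matrix",
    "clr_z",
    "network_edges",
    "condition_clusters",
]


class ControlSplitError(RuntimeError):
    """Raised when the vehicle controls do not fall in a single cluster."""


class ZMatrix(NamedTuple):
    values: pd.DataFrame
    mode: str


def discretize_equal_frequency(x, bins: int) -> np.ndarray:
    """Equal-frequency bin labels in {0..bins-1}.

    Deterministic: stable rank with ties split by original index, so each
    bin receives floor/ceil(n/bins) observations regardless of ties.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if bins < 1:
        raise ValueError(f"bins must be >= 1, got {bins}")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * bins) // n


def empirical_mi(x, y, bins: int) -> float:
    """Plug-in mutual information (nats) of two profiles after
    per-vector equal-frequency discretization into ``bins`` levels.

    A constant vector occupies a single level and contributes zero
    information, so MI is 0 whenever either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2 * bins:
        raise ValueError(f"need length >= 2*bins = {2 * bins}, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    lx = discretize_equal_frequency(x, bins)
    ly = discretize_equal_frequency(y, bins)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (lx, ly), 1.0)
    joint /= len(x)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))
    return max(0.0, mi)


def mi_matrix(cm: pd.DataFrame, bins: int | None = None) -> pd.DataFrame:
    """Symmetric condition x condition MI matrix over condition rows.

    ``bins`` defaults to floor(sqrt(n_genes)) (22 for the standard 500-gene
    profile).  The diagonal is set to 0 and ignored downstream.
    """
    if cm.shape[0] < 2:
        raise ValueError("need at least 2 conditions")
    n_genes = cm.shape[1]
    if bins is None:
        bins = int(math.floor(math.sqrt(n_genes)))
    vals = cm.to_numpy(dtype=float)
    n = cm.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = empirical_mi(vals[i], vals[j], bins)
    return pd.DataFrame(out, index=cm.index, columns=cm.index)


def clr_z(mim: pd.DataFrame, mode: str = "clr", ddof: int = 1) -> ZMatrix:
    """Background-correct an MI matrix into Z-scores.

    mode "clr": per-node backgrounds, z_i = max(0, (MI_ij - mu_i)/sigma_i),
    Z_ij = sqrt(z_i^2 + z_j^2); entries are >= 0.
    mode "global": Z_ij = (MI_ij - mean)/sd over all off-diagonal entries,
    giving off-diagonal mean 0 and sd 1 exactly.
    All MI values equal yields an all-zero matrix with a warning.
    """
    if mode not in ("clr", "global"):
        raise ValueError(f"mode must be 'clr' or 'global', got {mode!r}")
    n = mim.shape[0]
    if n < 3:
        raise ValueError("need at least 3 conditions for a Z background")
    m = mim.to_numpy(dtype=float)
    if not np.allclose(m, m.T):
        raise ValueError("MI matrix must be symmetric")
    off = ~np.eye(n, dtype=bool)
    if np.ptp(m[off]) == 0:
        warnings.warn("all off-diagonal MI values equal; Z matrix is all zero")
        z = np.zeros((n, n))
    elif mode == "global":
        mu = m[off].mean()
        sd = m[off].std(ddof=ddof)
        z = (m - mu) / sd
        np.fill_diagonal(z, 0.0)
    else:
        rows = np.where(off, m, np.nan)
        mu = np.nanmean(rows, axis=1)
        sd = np.nanstd(rows, axis=1, ddof=ddof)
        sd = np.where(sd == 0, np.inf, sd)  # flat row -> zero contribution
        zi = np.clip((m - mu[:, None]) / sd[:, None], 0.0, None)
        z = np.sqrt(zi**2 + zi.T**2)
        np.fill_diagonal(z, 0.0)
    return ZMatrix(pd.DataFrame(z, index=mim.index, columns=mim.columns), mode)


def network_edges(z: ZMatrix | pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Undirected edge list of condition pairs with Z strictly above threshold."""
    zdf = z.values if isinstance(z, ZMatrix) else z
    names = list(zdf.index)
    m = zdf.to_numpy(dtype=float)
    records = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if m[i, j] > threshold:
                records.append((names[i], names[j], float(m[i, j])))
    return pd.DataFrame(records, columns=["node_a", "node_b", "z"])


def to_graph(edges: pd.DataFrame, nodes=None):
    """networkx Graph from an edge list (keeps isolated nodes when given)."""
    import networkx as nx

    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for row in edges.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, weight=float(row.z))
    return g


def condition_clusters(
    cm: pd.DataFrame,
    controls,
    k: int = 2,
    method: str = "average",
):
    """Two broad transcriptomic clusters of conditions.

    Average-linkage agglomerative clustering under correlation distance
    (1 - Pearson r) of condition profiles, cut at ``k``.  The cluster
    containing the vehicle controls is labeled "A", the other "B" (further
    clusters, if k > 2, get "C", ...).  Controls split across clusters
    raise :class:`ControlSplitError`.

    Returns (condition -> label Series, scipy linkage matrix).
    """
    controls = list(controls)
    missing = [c for c in controls if c not in cm.index]
    if missing:
        raise ValueError(f"controls absent from condition matrix: {missing}")
    dist = pdist(cm.to_numpy(dtype=float), metric="correlation")
    Z = scipy_linkage(dist, method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    raw = pd.Series(raw, index=cm.index)
    ctrl_clusters = set(raw.loc[controls])
    if len(ctrl_clusters) != 1:
        raise ControlSplitError(
            "control-split: vehicle controls fall in more than one cluster"
        )
    ctrl_lab = ctrl_clusters.pop()
    others = sorted(set(raw.unique()) - {ctrl_lab})
    relabel = {ctrl_lab: "A"}
    for i, lab in enumerate(others):
        relabel[lab] = chr(ord("B") + i)
    labels = raw.map(relabel).rename("cluster")
    return labels, Z
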