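"""Integration and segregation metrics for weighted functional networks.

Five scalar network metrics are reported: network density, mean nodal
degree, mean nodal strength, mean clustering coefficient, and global
efficiency. Degree and strength are normalized by the node count N;
clustering is the Onnela geometric-mean-of-triangles form on weights
rescaled by the network maximum; efficiency uses edge length = 1/weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import WeightedGraph, network_density


@dataclass
class NodeMetrics:
    """Per-node metric vectors for one network (all length N)."""

    node_ids: list[str]
    degree_norm: np.ndarray
    strength_norm: np.ndarray
    clustering: np.ndarray
    efficiency: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "degree_norm": self.degree_norm,
            "strength_norm": self.strength_norm,
            "clustering": self.clustering,
            "efficiency": self.efficiency,
        }


def nodal_degree_strength(g: WeightedGraph) -> tuple[np.ndarray, np.ndarray]:
    """Per-node nonzero-edge count and incident-weight sum, each / N.

    The mean over nodes of the first vector is the "mean nodal degree",
    of the second the "mean nodal strength". Dividing by N makes
    mean degree equal density * (N-1)/N exactly.
    """
    w = g.weights
    n = w.shape[0]
    degree = np.count_nonzero(w, axis=1) / n
    strength = w.sum(axis=1) / n
    return degree, strength


def weighted_clustering(g: WeightedGraph) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    Weights are first rescaled by the network maximum; the coefficient is
    the sum over ordered neighbor pairs of the geometric mean of the
    three triangle weights, divided by k_i (k_i - 1). Nodes of degree
    below 2 get 0.
    """
    w = g.weights
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    what = (w / wmax) ** (1.0 / 3.0)
    triangles = np.diag(what @ what @ what)  # sum of (w_ij w_ih w_jh)^(1/3)
    k = np.count_nonzero(w, axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def _distance_matrix(g: WeightedGraph) -> np.ndarray:
    w = g.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


def nodal_efficiency(g: WeightedGraph) -> np.ndarray:
    """Per-node mean inverse shortest-path length to all other nodes.

    Path length is the sum of inverse edge weights along the path;
    disconnected pairs contribute 0 (1/inf).
    """
    n = g.n_nodes
    if n < 2:
        return np.zeros(n)
    d = _distance_matrix(g)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(g: WeightedGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    return float(nodal_efficiency(g).mean())


def node_metrics(g: WeightedGraph) -> NodeMetrics:
    """All per-node metric vectors for one network."""
    degree, strength = nodal_degree_strength(g)
    return NodeMetrics(
        node_ids=list(g.node_ids),
        degree_norm=degree,
        strength_norm=strength,
        clustering=weighted_clustering(g),
        efficiency=nodal_efficiency(g),
    )


def network_summary(g: WeightedGraph) -> dict[str, float]:
    """The five scalar network metrics, with node SDs where applicable.

    SDs are sample standard deviations over nodes (denominator N - 1),
    matching the "mean +/- SD" reporting convention.
    """
    nm = node_metrics(g)
    return {
        "density": network_density(g),
        "mean_nodal_degree": float(nm.degree_norm.mean()),
        "sd_nodal_degree": float(nm.degree_norm.std(ddof=1)),
        "mean_nodal_strength": float(nm.strength_norm.mean()),
        "sd_nodal_strength": float(nm.strength_norm.std(ddof=1)),
        "mean_clustering": float(nm.clustering.mean()),
        "sd_clustering": float(nm.clustering.std(ddof=1)),
        "global_efficiency": float(nm.efficiency.mean()),
    }
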