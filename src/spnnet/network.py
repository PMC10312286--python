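"""Group-network construction: averaging, percolation thresholding, density.

Percolation thresholding removes the weakest edges up to the largest
threshold that still preserves the giant connected component of the
input graph, avoiding the random-graph characteristics of very dense
functional networks while never fragmenting them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)


@dataclass
class WeightedGraph:
    """Undirected weighted graph over atlas nodes.

    ``weights`` is a symmetric N x N matrix with zero diagonal and
    nonnegative entries; ``provenance`` records the group/condition and
    the percolation threshold that produced the graph.
    """

    node_ids: list[str]
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if len(self.node_ids) != w.shape[0]:
            raise ValueError("node_ids length must equal matrix size")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.min() < 0:
            raise ValueError("weights must be nonnegative")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def density(self) -> float:
        return network_density(self)


def group_average(
    matrices: list[ConnectivityMatrix],
    excluded: set[str] | None = None,
    label: str = "group",
    condition: str = "",
) -> ConnectivityMatrix:
    """Element-wise mean connectivity over the non-excluded subjects."""
    excluded = excluded or set()
    kept = [m for m in matrices if m.label not in excluded]
    if not kept:
        raise ValueError("no matrices left after exclusion")
    ref_ids = kept[0].node_ids
    for m in kept[1:]:
        if m.node_ids != ref_ids:
            raise ValueError(f"node-order mismatch for subject {m.label!r}")
    mean = np.mean([m.weights for m in kept], axis=0)
    mean = (mean + mean.T) / 2.0  # enforce exact symmetry after summation
    np.fill_diagonal(mean, 0.0)
    return ConnectivityMatrix(
        weights=mean,
        label=label,
        condition=condition or kept[0].condition,
        n_timepoints=kept[0].n_timepoints,
        node_ids=list(ref_ids),
    )


def _giant_component(weights: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest connected component of the nonzero graph."""
    n_comp, labels = connected_components(
        csr_matrix(weights), directed=False
    )
    sizes = np.bincount(labels, minlength=n_comp)
    return labels == np.argmax(sizes)


def percolation_threshold(cm: ConnectivityMatrix | WeightedGraph) -> WeightedGraph:
    """Threshold a connectivity matrix at the percolation point.

    Finds tau*, the largest edge weight such that deleting every edge
    with weight strictly below tau* leaves the giant connected component
    with the same node set as in the unthresholded graph, and returns the
    graph with exactly those edges (weights preserved, ties at tau* kept).

    The search inserts edges in descending weight order into a union-find
    structure; tau* is the weight of the edge that first joins all giant-
    component nodes. If the input is already disconnected, the giant
    component is its largest component and the smaller components are
    retained unthresholded, with a warning.
    """
    w = np.asarray(cm.weights, dtype=float)
    n = w.shape[0]
    if n < 2 or not np.any(w > 0):
        raise ValueError("graph has no edges; nothing to threshold")
    giant = _giant_component(w)
    if giant.sum() < n:
        logger.warning(
            "input graph is disconnected: giant component has %d of %d nodes; "
            "smaller components retained unthresholded", int(giant.sum()), n,
        )
    ii, jj = np.triu_indices(n, k=1)
    in_giant_edge = giant[ii] & giant[jj] & (w[ii, jj] > 0)
    ei, ej, ew = ii[in_giant_edge], jj[in_giant_edge], w[ii, jj][in_giant_edge]
    order = np.argsort(-ew, kind="stable")

    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    remaining = int(giant.sum()) - 1  # merges needed to connect the giant set
    tau = ew[order[0]] if len(order) else 0.0
    for k in order:
        ra, rb = find(int(ei[k])), find(int(ej[k]))
        if ra != rb:
            parent[ra] = rb
            remaining -= 1
            tau = float(ew[k])
            if remaining == 0:
                break

    out = w.copy()
    giant_pair = np.outer(giant, giant)
    out[giant_pair & (w < tau)] = 0.0
    prov = dict(getattr(cm, "provenance", {}) or {})
    prov.update(
        {
            "threshold": tau,
            "giant_component_size": int(giant.sum()),
            "label": getattr(cm, "label", prov.get("label", "")),
            "condition": getattr(cm, "condition", prov.get("condition", "")),
        }
    )
    g = WeightedGraph(node_ids=list(cm.node_ids), weights=out, provenance=prov)
    g.provenance["density"] = g.density
    return g


def network_density(g: WeightedGraph | ConnectivityMatrix) -> float:
    """Nonzero unordered edge count divided by N(N-1)/2 possible pairs."""
    w = np.asarray(g.weights)
    n = w.shape[0]
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    return float(np.count_nonzero(w[iu]) / len(iu[0]))
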