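"""Hub taxonomy: connector/provincial hubs, high-influence nodes, pillars.

A node is a hub when its nodal degree or strength lies more than
``hub_sd`` standard deviations above the network mean. Hubs split into
connector hubs (participation coefficient at or above a fraction of the
network maximum, facilitating intermodular communication) and provincial
hubs (below it, intramodular). Non-hub nodes ranking in the top
``top_pct`` percent of both degree and strength are high-influence
nodes; everything else is normal. Hubs whose degree or strength reaches
``pillar_sd`` SDs above the mean are additionally flagged as network
pillars — the key carriers of communicative load.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .community import Partition
from .metrics import nodal_degree_strength
from .network import WeightedGraph

logger = logging.getLogger(__name__)

CATEGORIES = ("connector_hub", "provincial_hub", "high_influence", "normal")


@dataclass
class NodeProfile:
    """Classification record for one node of one network."""

    node_id: str
    degree_norm: float
    strength_norm: float
    participation: float
    category: str
    pillar: bool

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.pillar and self.category not in ("connector_hub", "provincial_hub"):
            raise ValueError("only hubs can be pillars")


@dataclass
class HubCensus:
    """Category counts for one network."""

    counts: dict[str, int]
    provenance: dict | None = None

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.counts)
        if missing:
            raise ValueError(f"census missing categories {sorted(missing)}")

    @property
    def n_nodes(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[c] for c in CATEGORIES], dtype=float)


def participation_coefficient(
    g: WeightedGraph, partition: Partition, weighted: bool = True
) -> np.ndarray:
    """P_i = 1 - sum_m (s_im / s_i)^2 over the partition's modules.

    ``s_im`` is node i's summed edge weight into module m (edge counts
    instead when ``weighted=False``). Isolated nodes get P = 0. Values
    lie in [0, 1 - 1/M] for an M-module partition.
    """
    if partition.node_ids != list(g.node_ids):
        raise ValueError("partition and graph are over different node sets")
    w = g.weights if weighted else (g.weights > 0).astype(float)
    labels = np.asarray(partition.labels)
    n = w.shape[0]
    m = labels.max() + 1
    alloc = np.zeros((n, m))
    for mod in range(m):
        alloc[:, mod] = w[:, labels == mod].sum(axis=1)
    s = alloc.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac2 = np.where(s[:, None] > 0, (alloc / s[:, None]) ** 2, 0.0)
    p = np.where(s > 0, 1.0 - frac2.sum(axis=1), 0.0)
    return p


def _top_mask(values: np.ndarray, top_pct: float) -> np.ndarray:
    """Nearest-rank top-percent mask on a descending sort; ties admitted."""
    n = len(values)
    k = max(1, math.ceil(top_pct / 100.0 * n))
    cutoff = np.sort(values)[::-1][k - 1]
    return values >= cutoff


def classify_nodes(
    g: WeightedGraph,
    partition: Partition,
    hub_sd: float = 1.0,
    top_pct: float = 30.0,
    connector_frac: float = 0.10,
    pillar_sd: float = 1.5,
    top_rule: str = "intersection",
    participation_weighted: bool = True,
) -> list[NodeProfile]:
    """Assign every node a category and a pillar flag.

    Means and SDs of degree and strength are taken over all N nodes of
    this network (sample SD, denominator N-1). Hubs use a strict ">"
    cutoff ("more than" ``hub_sd`` SD above the mean), pillars an
    inclusive ">=" one ("at least" ``pillar_sd`` SD). The high-influence
    band takes, by default, the intersection of the top-``top_pct``
    degree and strength sets (``top_rule="union"`` for the alternative
    reading).
    """
    degree, strength = nodal_degree_strength(g)
    part = participation_coefficient(g, partition, weighted=participation_weighted)
    n = len(degree)
    mu_d, mu_s = degree.mean(), strength.mean()
    sd_d = degree.std(ddof=1) if n > 1 else 0.0
    sd_s = strength.std(ddof=1) if n > 1 else 0.0
    if sd_d == 0 and sd_s == 0:
        logger.warning("degenerate network: zero SD in both degree and strength; "
                       "all nodes classified normal")
        hubs = np.zeros(n, dtype=bool)
        pillars = np.zeros(n, dtype=bool)
        high = np.zeros(n, dtype=bool)
    else:
        hubs = (degree > mu_d + hub_sd * sd_d) | (strength > mu_s + hub_sd * sd_s)
        pillars = hubs & (
            (degree >= mu_d + pillar_sd * sd_d) | (strength >= mu_s + pillar_sd * sd_s)
        )
        top_d = _top_mask(degree, top_pct)
        top_s = _top_mask(strength, top_pct)
        band = (top_d & top_s) if top_rule == "intersection" else (top_d | top_s)
        high = band & ~hubs
    p_max = part.max()
    # a network with no intermodular weight at all has no connectors
    connector = hubs & (part >= connector_frac * p_max) & (part > 0)
    profiles = []
    for i, node in enumerate(g.node_ids):
        if hubs[i]:
            cat = "connector_hub" if connector[i] else "provincial_hub"
        elif high[i]:
            cat = "high_influence"
        else:
            cat = "normal"
        profiles.append(
            NodeProfile(
                node_id=node,
                degree_norm=float(degree[i]),
                strength_norm=float(strength[i]),
                participation=float(part[i]),
                category=cat,
                pillar=bool(pillars[i]),
            )
        )
    return profiles


def hub_census(profiles: list[NodeProfile], provenance: dict | None = None) -> HubCensus:
    """Count nodes per category."""
    counts = {c: 0 for c in CATEGORIES}
    for p in profiles:
        counts[p.category] += 1
    return HubCensus(counts=counts, provenance=provenance)


def hub_homogeneity_test(
    census_a: HubCensus, census_b: HubCensus
) -> tuple[float, int, float]:
    """Pearson chi-squared test of homogeneity on category frequencies.

    The category x network contingency table is built from the two
    censuses; categories empty in both networks are dropped first (they
    carry no information and would break the expected counts), giving
    df = (remaining categories - 1). No continuity correction.
    """
    if census_a.n_nodes != census_b.n_nodes:
        raise ValueError("censuses cover different node counts")
    va, vb = census_a.as_vector(), census_b.as_vector()
    keep = (va + vb) > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-empty categories; test degenerate")
    table = np.vstack([va[keep], vb[keep]])
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
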