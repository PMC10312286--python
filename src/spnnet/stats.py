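"""Permutation-based group comparison of network metrics.

Network metrics rarely have known sampling distributions, so group and
condition contrasts use permutation t tests: the pooled values are
randomly re-split at the original group sizes (or exhaustively
enumerated when feasible) and the two-sample t statistic of each split
forms the null distribution.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .metrics import global_efficiency, node_metrics
from .network import network_density, group_average, percolation_threshold

logger = logging.getLogger(__name__)

NODE_METRICS = ("degree_norm", "strength_norm", "clustering", "efficiency")
SUBJECT_METRICS = ("density", "global_efficiency")


@dataclass
class MetricComparison:
    """Result of one permutation comparison."""

    metric: str
    mean_a: float
    mean_b: float
    observed_diff: float
    p: float
    n_permutations: int
    unit: str
    seed: int | None = None
    exact: bool = False

    def __post_init__(self) -> None:
        if not self.exact and self.p < 1.0 / (self.n_permutations + 1) - 1e-15:
            raise ValueError("p below the add-one floor 1/(n_perm + 1)")


def _t_statistic(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = math.sqrt(sp2 * (1 / na + 1 / nb))
    diff = a.mean() - b.mean()
    if denom == 0:
        return 0.0 if diff == 0 else math.inf
    return float(diff / denom)


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 20000,
    seed: int | None = None,
    metric: str = "",
    unit: str = "node",
) -> MetricComparison:
    """Two-sided permutation t test on two samples.

    Monte-Carlo null: p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm).
    When the number of distinct splits C(n_a + n_b, n_a) is at most
    ``n_perm`` the null is enumerated exactly instead and p is the exact
    tail fraction over all splits.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size
    if pooled.var() == 0:
        warnings.warn("zero pooled variance; permutation test is uninformative")
        return MetricComparison(metric, float(a.mean()), float(b.mean()), 0.0,
                                1.0, n_perm, unit, seed, exact=True)
    t_obs = _t_statistic(a, b)
    thresh = abs(t_obs) * (1 - 1e-12)
    n_splits = math.comb(n, na)
    if n_splits <= n_perm:
        count = 0
        idx_all = set(range(n))
        for comb_a in combinations(range(n), na):
            pa = pooled[list(comb_a)]
            pb = pooled[sorted(idx_all - set(comb_a))]
            if abs(_t_statistic(pa, pb)) >= thresh:
                count += 1
        p = count / n_splits
        return MetricComparison(metric, float(a.mean()), float(b.mean()),
                                float(a.mean() - b.mean()), float(p),
                                n_splits, unit, seed, exact=True)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    pa, pb = perms[:, :na], perms[:, na:]
    va = pa.var(axis=1, ddof=1) if na > 1 else np.zeros(n_perm)
    vb = pb.var(axis=1, ddof=1) if n - na > 1 else np.zeros(n_perm)
    sp2 = ((na - 1) * va + (n - na - 1) * vb) / (n - 2)
    denom = np.sqrt(sp2 * (1 / na + 1 / (n - na)))
    diff = pa.mean(axis=1) - pb.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(denom > 0, diff / denom,
                          np.where(diff == 0, 0.0, np.inf))
    count = int(np.sum(np.abs(t_perm) >= thresh))
    p = (1 + count) / (1 + n_perm)
    return MetricComparison(metric, float(a.mean()), float(b.mean()),
                            float(a.mean() - b.mean()), float(p),
                            n_perm, unit, seed, exact=False)


def _scalar_metric(matrices, metric: str) -> float:
    graph = percolation_threshold(group_average(list(matrices)))
    if metric == "density":
        return network_density(graph)
    if metric == "global_efficiency":
        return global_efficiency(graph)
    raise ValueError(f"unsupported subject-level metric {metric!r}")


def _subjectwise_comparison(
    matrices_a, matrices_b, metric: str, n_perm: int, seed: int | None
) -> MetricComparison:
    """Permute subject group labels and recompute the scalar through the
    full averaging + thresholding pipeline."""
    obs_a = _scalar_metric(matrices_a, metric)
    obs_b = _scalar_metric(matrices_b, metric)
    observed = obs_a - obs_b
    pool = list(matrices_a) + list(matrices_b)
    n_a = len(matrices_a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(pool))
        da = _scalar_metric([pool[i] for i in idx[:n_a]], metric)
        db = _scalar_metric([pool[i] for i in idx[n_a:]], metric)
        if abs(da - db) >= abs(observed) - 1e-15:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MetricComparison(metric, obs_a, obs_b, observed, float(p),
                            n_perm, "subject", seed, exact=False)


def compare_networks(
    graph_a,
    graph_b,
    metrics: tuple[str, ...] = NODE_METRICS,
    unit: str = "node",
    n_perm: int = 20000,
    seed: int | None = None,
    matrices_a=None,
    matrices_b=None,
    bonferroni_m: int | None = None,
) -> list[MetricComparison]:
    """Compare network metrics between two networks or two groups.

    ``unit="node"`` compares the per-node metric vectors of the two
    graphs (degree, strength, clustering, nodal efficiency).
    ``unit="subject"`` permutes subject group labels and recomputes
    scalar metrics (density, global efficiency) through the full
    pipeline; it requires the per-subject connectivity matrices.

    A Bonferroni-adjusted alpha (0.05 / m) is attached to each result's
    comparison count when ``bonferroni_m`` is given.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(len(metrics))]
    results = []
    if unit == "node":
        nm_a, nm_b = node_metrics(graph_a).as_dict(), node_metrics(graph_b).as_dict()
        for met, s in zip(metrics, child_seeds):
            if met not in NODE_METRICS:
                raise ValueError(f"metric {met!r} is not node-level; "
                                 f"use unit='subject' for {SUBJECT_METRICS}")
            results.append(
                permutation_test(nm_a[met], nm_b[met], n_perm=n_perm, seed=s,
                                 metric=met, unit="node")
            )
    elif unit == "subject":
        if matrices_a is None or matrices_b is None:
            raise ValueError("subject-level comparison needs per-subject matrices")
        for met, s in zip(metrics, child_seeds):
            if met not in SUBJECT_METRICS:
                raise ValueError(f"metric {met!r} is not subject-level scalar")
            results.append(
                _subjectwise_comparison(matrices_a, matrices_b, met, n_perm, s)
            )
    else:
        raise ValueError("unit must be 'node' or 'subject'")
    if bonferroni_m:
        alpha = 0.05 / bonferroni_m
        for r in results:
            logger.info("%s: p=%.4g (Bonferroni alpha=%.4g)", r.metric, r.p, alpha)
    return results
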