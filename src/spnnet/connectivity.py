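"""Normalized-mutual-information connectivity estimation.

Edge weights are NMI coefficients: the classical mutual information of an
ROI pair divided by the geometric mean of the two marginal Shannon
entropies, giving a statistical-dependence measure on a scale from 0
(independence) to 1 (mutual dependence). MI and the entropies are
estimated on a joint equal-width histogram with ``n_bins`` bins per axis
(Rice rule by default, see :func:`default_n_bins`); logs are natural
(the base cancels in the ratio) and 0*log(0) terms contribute zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


class DegenerateSeriesError(ValueError):
    """A constant series has zero entropy; NMI is undefined for it."""


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N NMI edge-weight matrix for one subject or group.

    Invariants: off-diagonal weights in [0, 1], zero diagonal, exact
    symmetry (each unordered pair is computed once).
    """

    weights: np.ndarray
    label: str = ""
    condition: str = ""
    n_timepoints: int = 0
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be exactly symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        off = w[~np.eye(w.shape[0], dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("off-diagonal weights must lie in [0, 1]")
        self.weights = w
        if self.node_ids is None:
            self.node_ids = [f"roi{j}" for j in range(w.shape[0])]
        elif len(self.node_ids) != w.shape[0]:
            raise ValueError("node_ids length must equal matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def default_n_bins(n_timepoints: int) -> int:
    """Histogram bin count per axis: the Rice rule ``ceil(2 * T**(1/3))``.

    The plug-in MI estimator is positively biased by roughly
    ``(n_bins - 1)^2 / 2T`` nats; the Rice rule keeps that bias small
    (mean NMI < 0.1 between independent series at the epoch counts this
    pipeline produces) while retaining enough resolution to detect
    dependence.
    """
    return int(math.ceil(2.0 * n_timepoints ** (1.0 / 3.0)))


def _digitize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin codes in [0, n_bins); the maximum falls in the last bin."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSeriesError("constant series has zero entropy")
    codes = np.floor((x - lo) * (n_bins / (hi - lo))).astype(np.intp)
    return np.minimum(codes, n_bins - 1)


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def estimate_nmi(x: np.ndarray, y: np.ndarray, n_bins: int | None = None) -> float:
    """NMI(X;Y) = MI(X;Y) / sqrt(H(X) * H(Y)) on a joint equal-width histogram.

    Accumulation is symmetric in the two arguments, so
    ``estimate_nmi(x, y) == estimate_nmi(y, x)`` exactly. The result is
    clipped to [0, 1] (the histogram plug-in estimator can stray outside
    by floating-point dust only).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if n_bins is None:
        n_bins = default_n_bins(x.size)
    cx = _digitize(x, n_bins)
    cy = _digitize(y, n_bins)
    joint = np.bincount(cx * n_bins + cy, minlength=n_bins * n_bins).astype(float)
    joint = joint.reshape(n_bins, n_bins)
    hx = _entropy_from_counts(joint.sum(axis=1))
    hy = _entropy_from_counts(joint.sum(axis=0))
    p = joint / x.size
    nz = p > 0
    # summing in sorted order makes the accumulation invariant to the
    # argument order (a swap just transposes the joint histogram)
    plogp = float(np.sort(p[nz] * np.log(p[nz])).sum())
    # MI = sum p log p  -  sum p log px  -  sum p log py  =  plogp + H(X) + H(Y)
    mi = plogp + hx + hy
    return float(np.clip(mi / math.sqrt(hx * hy), 0.0, 1.0))


def build_connectivity_matrix(
    epochs: np.ndarray,
    n_bins: int | None = None,
    label: str = "",
    condition: str = "",
    node_ids: list[str] | None = None,
) -> ConnectivityMatrix:
    """Pairwise NMI over the columns of a ``(T, N)`` epoch matrix.

    All joint histograms are accumulated in one blocked matrix product
    over per-column one-hot bin indicators, which is algebraically the
    pairwise computation of :func:`estimate_nmi` done for every pair at
    once.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 2:
        raise ValueError("epochs must be a (T, N) matrix")
    t, n = epochs.shape
    if t < 2 or n < 2:
        raise ValueError("need at least 2 timepoints and 2 ROIs")
    if n_bins is None:
        n_bins = default_n_bins(t)
    ids = node_ids or [f"roi{j}" for j in range(n)]
    codes = np.empty((t, n), dtype=np.intp)
    for j in range(n):
        try:
            codes[:, j] = _digitize(epochs[:, j], n_bins)
        except DegenerateSeriesError:
            raise DegenerateSeriesError(
                f"ROI {ids[j]!r} has a constant epoch series"
            ) from None
    onehot = np.zeros((t, n * n_bins))
    onehot[np.arange(t)[:, None], np.arange(n) * n_bins + codes] = 1.0
    joint = onehot.T @ onehot  # (n*b, n*b) block (i,j) = joint histogram of pair
    p = joint / t
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    pair_plogp = plogp.reshape(n, n_bins, n, n_bins).sum(axis=(1, 3))
    h = np.array(
        [_entropy_from_counts(np.bincount(codes[:, j], minlength=n_bins)) for j in range(n)]
    )
    mi = pair_plogp + h[:, None] + h[None, :]
    nmi = mi / np.sqrt(np.outer(h, h))
    out_of_range = int(np.sum((nmi < 0) | (nmi > 1)) - n)  # diagonal overshoots 1
    if out_of_range > 0:
        logger.debug("clipped %d NMI values to [0, 1]", out_of_range)
    nmi = np.clip(nmi, 0.0, 1.0)
    np.fill_diagonal(nmi, 0.0)
    nmi = np.triu(nmi, 1)
    nmi = nmi + nmi.T  # exact symmetry: each pair stored once, mirrored
    return ConnectivityMatrix(
        weights=nmi, label=label, condition=condition, n_timepoints=t, node_ids=ids
    )


def mean_connectivity_strength(cm: ConnectivityMatrix) -> float:
    """Mean of the N(N-1)/2 upper-triangular off-diagonal weights."""
    w = cm.weights
    if w.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    iu = np.triu_indices(w.shape[0], k=1)
    return float(w[iu].mean())


def tukey_fence_outliers(
    values: np.ndarray, k: float = 1.5
) -> set[int]:
    """Indices falling outside Tukey's fences ``[Q1 - k*IQR, Q3 + k*IQR]``.

    Quartiles use the linear-interpolation method. Used to exclude
    subjects with abnormal mean connectivity strength before group
    averaging.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("Tukey's fences need at least 4 values")
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return set(np.flatnonzero((values < lo) | (values > hi)).tolist())
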