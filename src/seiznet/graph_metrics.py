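"""Weighted graph statistics of functional-connectivity matrices.

All functions operate on a symmetric, non-negative adjacency matrix with a
zero diagonal (edge weights are rectified correlations in [0, 1]):

* ``density`` — total edge weight over the N(N-1)/2 possible edges.
* ``clustering_coefficient`` — mean Onnela (cube-root) weighted clustering.
* ``characteristic_path_length`` — mean shortest-path distance with edge
  length 1/w; disconnected pairs are excluded and counted.
* ``assortativity`` — Pearson correlation of endpoint strengths over edges
  (both orientations), the weighted assortativity coefficient.
* ``modularity`` — Newman's spectral community detection (leading
  eigenvector, recursive bisection, Kernighan-Lin-style fine-tuning) with
  resolution gamma, returning Q of the detected partition.
* ``spectral_radius`` — largest eigenvalue of A.
* ``synchronizability`` — lambda_2 / lambda_max of the Laplacian L = D - A.

Undefined results (disconnected path length, degenerate assortativity) are
returned as NaN and logged, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivitySeries

logger = logging.getLogger(__name__)

__all__ = [
    "METRICS",
    "MetricSeries",
    "density",
    "clustering_coefficient",
    "characteristic_path_length",
    "assortativity",
    "modularity",
    "modularity_value",
    "spectral_radius",
    "synchronizability",
    "metric_timeseries",
    "metrics_frame",
]

METRICS = (
    "density",
    "clustering",
    "path_length",
    "assortativity",
    "modularity",
    "spectral_radius",
    "synchronizability",
)

_EIG_ZERO_TOL = 1e-12


def _check_adjacency(A: np.ndarray, min_nodes: int = 2) -> np.ndarray:
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if A.shape[0] < min_nodes:
        raise ValueError(f"need at least {min_nodes} nodes")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("edge weights must be non-negative")
    if np.any(np.diag(A) != 0):
        A = A.copy()
        np.fill_diagonal(A, 0.0)
    return A


def density(A: np.ndarray) -> float:
    """Total edge weight divided by the number of possible edges."""
    A = _check_adjacency(A)
    n = A.shape[0]
    return float(np.triu(A, 1).sum() / (n * (n - 1) / 2))


def clustering_coefficient(A: np.ndarray) -> float:
    """Mean weighted clustering coefficient (Onnela cube-root formula).

    Per node, the geometric-mean weight of closed triangles over the
    ``k (k - 1)`` pairs its binary degree allows; nodes with degree < 2
    contribute 0.
    """
    A = _check_adjacency(A, min_nodes=3)
    k = (A > 0).sum(axis=1)
    w3 = np.cbrt(A)
    tri = np.diag(w3 @ w3 @ w3)  # 2x the triangle weight around each node
    denom = k * (k - 1)
    c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return float(c.mean())


def characteristic_path_length(
    A: np.ndarray, return_disconnected: bool = False
) -> float | tuple[float, int]:
    """Mean shortest-path distance over connected node pairs.

    Edge length is the inverse weight (strong coupling = short distance);
    pairs without a connecting path are excluded from the mean and their
    count reported.  NaN if no pair is connected.
    """
    A = _check_adjacency(A)
    n = A.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(A > 0, 1.0 / np.where(A > 0, A, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    d = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_disc = int((off & ~finite).sum() // 2)
    if not finite.any():
        logger.warning("path length undefined: graph has no connected pair")
        value = float("nan")
    else:
        value = float(d[finite].mean())
    if n_disc:
        logger.info("%d disconnected node pair(s) excluded from path length", n_disc)
    return (value, n_disc) if return_disconnected else value


def assortativity(A: np.ndarray) -> float:
    """Weighted assortativity: endpoint-strength correlation over edges.

    Each undirected edge contributes both orientations, making the
    coefficient the symmetric Pearson correlation of node strengths at
    edge endpoints.  NaN when endpoint strengths have no variance.
    """
    A = _check_adjacency(A)
    s = A.sum(axis=1)
    i, j = np.nonzero(np.triu(A, 1))
    if len(i) < 2:
        logger.warning("assortativity undefined: fewer than 2 edges")
        return float("nan")
    x = np.concatenate([s[i], s[j]])
    y = np.concatenate([s[j], s[i]])
    sx = x.std()
    if sx <= 0:
        logger.warning("assortativity undefined: zero endpoint-strength variance")
        return float("nan")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / sx**2)


def modularity_value(A: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Q of a given partition, with weighted degrees and 2m = total weight.

    ``Q = (1/2m) * sum_ij (A_ij - gamma * k_i k_j / 2m) * [c_i == c_j]``.
    """
    A = _check_adjacency(A)
    labels = np.asarray(labels)
    two_m = A.sum()
    if two_m <= 0:
        raise ValueError("modularity undefined for a zero-weight graph")
    k = A.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    B = A - gamma * np.outer(k, k) / two_m
    return float(B[same].sum() / two_m)


def _leading_eigvec(B: np.ndarray) -> np.ndarray:
    """Leading eigenvector of a symmetric matrix, deterministically oriented."""
    vals, vecs = np.linalg.eigh(B)
    v = vecs[:, -1]
    # orient so the largest-magnitude entry is positive (sign of eigh is arbitrary)
    pivot = int(np.argmax(np.abs(v)))
    if v[pivot] < 0:
        v = -v
    return v


def _kl_refine(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin-style node-moving refinement of a bisection.

    Repeated full passes: every node is flipped once per pass in order of
    best gain (ties broken by lowest node index); the best configuration
    seen during the pass is kept if it improves s^T Bg s.
    """
    n = len(s)
    score = float(s @ Bg @ s)
    improved = True
    while improved:
        improved = False
        s_pass = s.copy()
        moved = np.zeros(n, dtype=bool)
        best_score, best_s = score, s.copy()
        cur = score
        for _ in range(n):
            # gain of flipping node i: delta = -4 s_i (Bg s)_i + 4 Bg_ii
            bs = Bg @ s_pass
            gains = -4.0 * s_pass * bs + 4.0 * np.diag(Bg)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            cur += gains[i]
            s_pass[i] = -s_pass[i]
            moved[i] = True
            if cur > best_score + 1e-13:
                best_score, best_s = cur, s_pass.copy()
        if best_score > score + 1e-13:
            score, s = best_score, best_s
            improved = True
    return s


def modularity(
    A: np.ndarray, gamma: float = 1.0
) -> tuple[float, np.ndarray]:
    """Community detection by Newman's spectral method; returns (Q, labels).

    Recursive bisection on the leading eigenvector of the (generalized)
    modularity matrix with Kernighan-Lin fine-tuning, stopping when no
    split increases Q.  Deterministic: eigenvector entries within 1e-12 of
    zero join the positive group and ties break by node index.
    """
    A = _check_adjacency(A)
    two_m = A.sum()
    if two_m <= 0:
        raise ValueError("modularity undefined for a zero-weight graph")
    n = A.shape[0]
    k = A.sum(axis=1)
    B = A - gamma * np.outer(k, k) / two_m

    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack = [np.arange(n)]
    while stack:
        idx = stack.pop()
        if len(idx) < 2:
            continue
        Bsub = B[np.ix_(idx, idx)]
        Bg = Bsub - np.diag(Bsub.sum(axis=1))  # generalized modularity matrix
        v = _leading_eigvec(Bg)
        s = np.where(v >= -_EIG_ZERO_TOL, 1.0, -1.0)
        s = _kl_refine(Bg, s)
        dq = float(s @ Bg @ s) / (2.0 * two_m)
        if dq <= 1e-12 or np.all(s > 0) or np.all(s < 0):
            continue  # indivisible
        pos, neg = idx[s > 0], idx[s < 0]
        labels[neg] = next_label
        next_label += 1
        stack.append(pos)
        stack.append(neg)

    # compact labels deterministically by first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return modularity_value(A, labels, gamma), labels


def spectral_radius(A: np.ndarray) -> float:
    """Largest eigenvalue of the adjacency matrix."""
    A = _check_adjacency(A, min_nodes=1)
    return float(np.linalg.eigvalsh(A)[-1])


def synchronizability(A: np.ndarray) -> float:
    """lambda_2 / lambda_max of the Laplacian L = D - A; in [0, 1].

    Near 0 for disconnected graphs (lambda_2 = 0); 1 for the complete
    graph, whose nonzero Laplacian eigenvalues coincide.
    """
    A = _check_adjacency(A)
    if A.sum() <= 0:
        raise ValueError("synchronizability undefined for a zero-weight graph")
    L = np.diag(A.sum(axis=1)) - A
    eig = np.linalg.eigvalsh(L)
    lam2 = max(eig[1], 0.0)  # clip numerical negatives
    return float(lam2 / eig[-1])


@dataclass
class MetricSeries:
    """One metric evaluated on every smoothed window of one segment."""

    segment_id: str
    condition: str
    metric: str
    values: np.ndarray
    times_min: np.ndarray  # window starts, minutes relative to onset


def metric_timeseries(
    series: ConnectivitySeries, gamma: float = 1.0
) -> list[MetricSeries]:
    """Evaluate all seven metrics on every matrix of a rectified series."""
    if series.stage != "rectified":
        raise ValueError(
            f"metrics expect a rectified series, got stage={series.stage!r}"
        )
    times = series.onset_relative_minutes
    values = {m: np.empty(len(series)) for m in METRICS}
    for w, A in enumerate(series.matrices):
        total = A.sum()
        values["density"][w] = density(A)
        values["clustering"][w] = clustering_coefficient(A)
        values["path_length"][w] = characteristic_path_length(A)
        values["assortativity"][w] = assortativity(A)
        if total > 0:
            values["modularity"][w] = modularity(A, gamma)[0]
            values["synchronizability"][w] = synchronizability(A)
        else:
            values["modularity"][w] = np.nan
            values["synchronizability"][w] = np.nan
        values["spectral_radius"][w] = spectral_radius(A)
    return [
        MetricSeries(series.segment_id, series.condition, m, values[m], times)
        for m in METRICS
    ]


def metrics_frame(all_series: list[MetricSeries]) -> pd.DataFrame:
    """Long-format table: segment_id, condition, metric, window_start_min, value."""
    rows = []
    for ms in all_series:
        for t, v in zip(ms.times_min, ms.values):
            rows.append((ms.segment_id, ms.condition, ms.metric, t, v))
    return pd.DataFrame(
        rows, columns=["segment_id", "condition", "metric", "window_start_min", "value"]
    )
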