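"""Independent brute-force graph-metric implementations used as oracles.

Deliberately naive: explicit loops, Floyd-Warshall, direct formula
evaluation, and the non-symmetric eigenvalue routine — sharing no code
path with seiznet.graph_metrics.
"""

from __future__ import annotations

import math

import numpy as np


def density_bf(A: np.ndarray) -> float:
    n = len(A)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += A[i, j]
    return total / (n * (n - 1) / 2)


def clustering_bf(A: np.ndarray) -> float:
    n = len(A)
    cs = []
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and A[i, j] > 0)
        if k < 2:
            cs.append(0.0)
            continue
        tri = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    tri += (A[i, j] * A[i, h] * A[j, h]) ** (1.0 / 3.0)
        cs.append(tri / (k * (k - 1)))
    return float(np.mean(cs))


def path_length_bf(A: np.ndarray) -> float:
    """Floyd-Warshall over 1/w edge lengths; mean over finite pairs."""
    n = len(A)
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and A[i, j] > 0:
                d[i, j] = 1.0 / A[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and math.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def assortativity_bf(A: np.ndarray) -> float:
    """Pearson correlation of endpoint strengths over oriented edges."""
    n = len(A)
    s = A.sum(axis=1)
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if i != j and A[i, j] > 0:
                xs.append(s[i])
                ys.append(s[j])
    if len(xs) < 4 or np.std(xs) == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def spectral_radius_bf(A: np.ndarray) -> float:
    return float(np.max(np.real(np.linalg.eigvals(A))))


def synchronizability_bf(A: np.ndarray) -> float:
    L = np.diag(A.sum(axis=1)) - A
    eig = np.sort(np.real(np.linalg.eigvals(L)))
    return float(max(eig[1], 0.0) / eig[-1])


def modularity_value_bf(A: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Q by direct double-sum evaluation with weighted degrees."""
    n = len(A)
    two_m = A.sum()
    k = A.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m
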