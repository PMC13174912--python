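"""Independent reference implementations used only by the tests.

These deliberately share no code with the package: single-linkage merge
heights via a plain union-find sweep, and kernel-ridge prediction via an
explicit dense matrix inversion.
"""

from __future__ import annotations

import numpy as np


def single_linkage_heights(dist: np.ndarray) -> list[float]:
    """Merge heights of single-linkage clustering by naive union-find."""
    n = len(dist)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            a = parent[a]
        return a

    edges = sorted(
        (dist[i, j], i, j) for i in range(n) for j in range(i + 1, n)
    )
    heights: list[float] = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            heights.append(float(w))
    return sorted(heights)


def krr_predict_dense(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_query: np.ndarray,
    alpha: float,
    gamma: float,
) -> np.ndarray:
    """Laplacian-KRR prediction via explicit (K + aI)^-1, element-wise kernel."""
    n = len(X_train)
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = np.exp(-gamma * np.sum(np.abs(X_train[i] - X_train[j])))
    coef = np.linalg.inv(K + alpha * np.eye(n)) @ y_train
    m = len(X_query)
    k = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            k[i, j] = np.exp(-gamma * np.sum(np.abs(X_query[i] - X_train[j])))
    return k @ coef


def regression_stats(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(R2, RMSE, MAE) from first principles."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    err = y_true - y_pred
    rmse = float(np.sqrt(sum(e * e for e in err) / len(err)))
    mae = float(sum(abs(e) for e in err) / len(err))
    ss_res = float(sum(e * e for e in err))
    ss_tot = float(sum((v - np.mean(y_true)) ** 2 for v in y_true))
    return 1.0 - ss_res / ss_tot, rmse, mae
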