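"""Independent brute-force oracles used by the tests.

Everything here is written as plain double loops or direct dense-matrix
formulas, deliberately avoiding the package's own vectorized paths.
"""

import math

import numpy as np


def vanraden_double_loop(dosage: np.ndarray) -> np.ndarray:
    n, m = dosage.shape
    p = np.array([(dosage[:, j] + 1.0).sum() / (2.0 * n) for j in range(m)])
    H = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            H[i, j] = dosage[i, j] - 2.0 * (p[j] - 0.5)
    denom = sum(2.0 * p[j] * (1.0 - p[j]) for j in range(m))
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            G[i, k] = sum(H[i, j] * H[k, j] for j in range(m)) / denom
    return G


def su_double_loop(dosage: np.ndarray) -> np.ndarray:
    n, m = dosage.shape
    p = np.array([(dosage[:, j] + 1.0).sum() / (2.0 * n) for j in range(m)])
    Z = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            w = 2.0 * p[j] * (1.0 - p[j])
            Z[i, j] = 1.0 - w if dosage[i, j] == 0 else -w
    denom = sum(
        2.0 * p[j] * (1.0 - p[j]) * (1.0 - 2.0 * p[j] * (1.0 - p[j])) for j in range(m)
    )
    D = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            D[i, k] = sum(Z[i, j] * Z[k, j] for j in range(m)) / denom
    return D


def dense_reml_loglik(V: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Textbook restricted log-likelihood from explicit dense matrices:
    -1/2 [log|V| + log|X'V^-1 X| + y'Py + (N - f) log 2 pi]."""
    N, f = X.shape
    Vinv = np.linalg.inv(V)
    XtViX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtViX) @ X.T @ Vinv
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + float(y @ P @ y)
        + (N - f) * math.log(2.0 * math.pi)
    )


def grid_search_single_kernel(K, X, y, grid_a, grid_e):
    """Argmax of the dense REML formula over a (s2_a, s2_e) grid."""
    best = (-np.inf, None, None)
    I = np.eye(len(y))
    for sa in grid_a:
        for se in grid_e:
            logl = dense_reml_loglik(sa * K + se * I, X, y)
            if logl > best[0]:
                best = (logl, sa, se)
    return best
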