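"""Independent reference implementations used only by the tests.

These deliberately avoid the package's algorithms: Wright's relationship
coefficients by memoized coancestry recursion (vs the tabular method),
BLUP by dense generalized least squares on the marginal covariance (vs the
mixed model equations), and single-trait REML by eigen-rotated profile
likelihood (vs EM/AI iteration on the MME).
"""

from __future__ import annotations

import sys

import numpy as np
from scipy.optimize import minimize_scalar


def kinship_oracle(sire, dam) -> np.ndarray:
    """Numerator relationships from Wright's coancestry recursion.

    f(i,i) = (1 + f(s_i, d_i)) / 2 and, for the later-born j,
    f(i,j) = (f(i, s_j) + f(i, d_j)) / 2; unknown parents contribute 0.
    Returns A with a_ij = 2 f(i,j).
    """
    sys.setrecursionlimit(100000)
    memo: dict = {}

    def f(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            val = 0.5 * (1.0 + f(sire[i], dam[i]))
        else:
            val = 0.5 * (f(i, sire[j]) + f(i, dam[j]))
        memo[key] = val
        return val

    n = len(sire)
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = 2.0 * f(i, j)
    return A


def gls_blup_oracle(y, X, K, sigma_a2, sigma_e2):
    """Single-trait BLUP via the marginal model, dense.

    V = K sigma_a2 + I sigma_e2 over the phenotyped animals; returns
    (b, a) with a for every animal in K given records on the first
    len(y) == K rows subset ``obs`` (pass K restricted appropriately).
    """
    y = np.asarray(y, dtype=float)
    K = np.asarray(K, dtype=float)
    n = y.size
    V = K[:n, :n] * sigma_a2 + np.eye(n) * sigma_e2
    Vinv = np.linalg.inv(V)
    if X.shape[1]:
        b = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        resid = y - X @ b
    else:
        b = np.zeros(0)
        resid = y
    a = sigma_a2 * K[:, :n] @ Vinv @ resid
    return b, a


def eigen_reml_oracle(y, X, K):
    """Single-trait REML by profile likelihood after eigen-rotation.

    Projects onto the orthogonal complement of X, rotates by the
    eigenvectors of the projected relationship matrix, and maximizes the
    restricted likelihood over the variance ratio by 1-D optimization.
    Returns (sigma_a2, sigma_e2).
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Q, _ = np.linalg.qr(X, mode="complete")
    Qc = Q[:, p:]
    w, V = np.linalg.eigh(Qc.T @ K @ Qc)
    z = V.T @ (Qc.T @ y)

    def negll(log_lam):
        lam = np.exp(log_lam)
        d = lam * w + 1.0
        s2 = np.mean(z**2 / d)
        return 0.5 * (np.sum(np.log(d)) + (n - p) * np.log(s2))

    res = minimize_scalar(negll, bounds=(-12, 12), method="bounded",
                          options={"xatol": 1e-12})
    lam = np.exp(res.x)
    d = lam * w + 1.0
    se2 = np.mean(z**2 / d)
    return lam * se2, se2
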