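"""Constrained quadratic-programming kernels for the factorization steps.

Two small QP families recur throughout the alternating factorization:

* simplex-constrained least squares, min ||t - M p||^2 over p >= 0,
  sum(p) = 1, solved by projected gradient with step 1/L (L the largest
  eigenvalue of M'M) and Euclidean projection onto the simplex;
* box-constrained least squares, min ||t - m'P||^2 over 0 <= m <= 1,
  solved by cyclic coordinate descent on the shared Gram matrix.

Both are monotone-descent methods, so warm-starting from the previous
iterate guarantees the alternating algorithm's residual sum of squares
never increases.  Problems are batched: all samples (or all genes)
share one Gram matrix, and iterations are vectorized across the batch.
Near-singular Gram matrices get a tiny ridge (1e-10) and a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

RIDGE = 1e-10
COND_LIMIT = 1e12


def project_simplex(Y: np.ndarray) -> np.ndarray:
    """Euclidean projection of each column of Y onto the probability simplex."""
    k, n = Y.shape
    U = np.sort(Y, axis=0)[::-1, :]
    css = np.cumsum(U, axis=0) - 1.0
    idx = np.arange(1, k + 1)[:, None]
    cond = U - css / idx > 0
    rho = k - np.argmax(cond[::-1, :], axis=0) - 1  # last True per column
    theta = css[rho, np.arange(n)] / (rho + 1.0)
    return np.maximum(Y - theta[None, :], 0.0)


def _prep_gram(G: np.ndarray, what: str) -> np.ndarray:
    diag = np.diag(G)
    scale = diag.max() if diag.size else 1.0
    if scale <= 0 or np.linalg.cond(G) > COND_LIMIT:
        warnings.warn(
            f"rank-deficient system in {what}; adding ridge {RIDGE:g}", RuntimeWarning
        )
        G = G + RIDGE * np.eye(G.shape[0])
    return G


def solve_simplex_batch(
    M: np.ndarray,
    T: np.ndarray,
    P0: np.ndarray | None = None,
    max_iter: int = 20000,
    tol: float = 1e-12,
) -> np.ndarray:
    """Minimize ||T - M P||_F^2 columnwise subject to simplex columns of P.

    Projected gradient with fixed step 1/L; monotone in the objective,
    converging linearly when M has full column rank.
    """
    k = M.shape[1]
    G = _prep_gram(M.T @ M, "proportion estimation")
    C = M.T @ T  # k x n
    n = T.shape[1]
    if P0 is None:
        P = np.full((k, n), 1.0 / k)
    else:
        P = project_simplex(np.asarray(P0, dtype=float).copy())
    L = float(np.linalg.eigvalsh(G)[-1])
    if L <= 0:
        return P
    step = 1.0 / L
    for _ in range(max_iter):
        grad = G @ P - C
        P_new = project_simplex(P - step * grad)
        delta = np.abs(P_new - P).max()
        P = P_new
        if delta < tol:
            break
    return P


def solve_box_batch(
    P: np.ndarray,
    T: np.ndarray,
    M0: np.ndarray | None = None,
    lower: float = 0.0,
    upper: float = 1.0,
    max_iter: int = 20000,
    tol: float = 1e-12,
) -> np.ndarray:
    """Minimize ||T - M P||_F^2 rowwise subject to lower <= M <= upper.

    Cyclic coordinate descent over the k components, vectorized across
    all gene rows of T; each coordinate update is an exact 1D minimum,
    so the objective is monotone non-increasing from any start.
    ``upper=None`` drops the upper bound (nonnegative least squares).
    """
    k = P.shape[0]
    G = _prep_gram(P @ P.T, "profile estimation")
    B = T @ P.T  # genes x k
    g = T.shape[0]
    if M0 is None:
        M = np.full((g, k), 0.5 * (lower + (upper if upper is not None else lower + 1.0)))
    else:
        M = np.asarray(M0, dtype=float).copy()
        np.clip(M, lower, upper, out=M)
    diag = np.maximum(np.diag(G).copy(), 1e-300)
    for _ in range(max_iter):
        delta = 0.0
        for j in range(k):
            # exact minimizer of the quadratic in M[:, j], others fixed
            num = B[:, j] - M @ G[:, j] + M[:, j] * G[j, j]
            new = num / diag[j]
            np.clip(new, lower, upper, out=new)
            delta = max(delta, float(np.abs(new - M[:, j]).max(initial=0.0)))
            M[:, j] = new
        if delta < tol:
            break
    return M
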