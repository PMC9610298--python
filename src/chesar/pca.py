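"""Covariance-matrix principal component analysis via NIPALS.

NIPALS (nonlinear iterative partial least squares) extracts principal
components one at a time.  For a mean-centered matrix X it alternates

    p = X' t / (t' t),   p <- p / ||p||,   t = X p

until the score vector stabilises, then deflates X <- X - t p' and repeats.
The extracted (t_i, p_i) pairs satisfy X = sum_i t_i p_i', the loadings are
the covariance-matrix eigenvectors and var(t_i) are its eigenvalues.

Deterministic conventions used here: iteration starts from the residual
column with the largest variance, and each loading is signed so that its
largest-magnitude element is positive (PCA signs are otherwise arbitrary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAResult", "mean_center", "nipals_pca", "project"]

#: Relative change of the score vector below which a component has converged.
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000


@dataclass(frozen=True)
class PCAResult:
    """Scores, loadings and variance bookkeeping for k extracted components.

    ``explained_fraction[i]`` is var(t_i) divided by the total variance of
    the centered input; over all ``rank`` components the fractions sum to 1.
    ``converged[i]`` is False for any component that hit ``max_iter`` (the
    component is still returned).
    """

    scores: np.ndarray          # (n, k)
    loadings: np.ndarray        # (p, k), unit-norm orthogonal columns
    eigenvalues: np.ndarray     # (k,) variances of the score vectors
    explained_fraction: np.ndarray
    column_means: np.ndarray    # (p,)
    n_iterations: np.ndarray    # (k,)
    converged: np.ndarray       # (k,) bool

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def mean_center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-center X; returns (centered matrix, column means)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError(f"need a 2-D matrix with >= 2 rows, got shape {X.shape}")
    means = X.mean(axis=0)
    return X - means, means


def nipals_pca(
    X: np.ndarray,
    k: int | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PCAResult:
    """Extract ``k`` principal components of X by NIPALS with deflation.

    X is centered internally (the stored column means allow projection of
    new rows later).  ``k`` defaults to min(n_rows - 1, n_cols) and may not
    exceed it.  Columns with zero variance simply contribute zero loading.
    """
    Xc, means = mean_center(X)
    n, p = Xc.shape
    k_max = min(n - 1, p)
    if k is None:
        k = k_max
    if not 1 <= k <= k_max:
        raise ValueError(f"k must be in [1, {k_max}], got {k}")

    total_var = float(np.sum(Xc**2)) / (n - 1)
    scores = np.zeros((n, k))
    loadings = np.zeros((p, k))
    eigenvalues = np.zeros(k)
    n_iter = np.zeros(k, dtype=int)
    converged = np.ones(k, dtype=bool)

    R = Xc.copy()
    for j in range(k):
        col_var = R.var(axis=0)
        t = R[:, int(np.argmax(col_var))].copy()
        t_norm = np.linalg.norm(t)
        if t_norm == 0.0:  # residual exhausted: remaining components are zero
            break
        for it in range(1, max_iter + 1):
            pvec = R.T @ t / (t @ t)
            pvec /= np.linalg.norm(pvec)
            t_new = R @ pvec
            new_norm = np.linalg.norm(t_new)
            # full score-vector change: norm-only convergence stalls early
            # because the eigenvalue converges quadratically in the angle
            done = np.linalg.norm(t_new - t) <= tol * max(new_norm, 1e-300)
            t, t_norm = t_new, new_norm
            if done:
                break
        else:
            converged[j] = False
        n_iter[j] = it
        # deterministic sign: largest-|.| loading element made positive
        flip = np.argmax(np.abs(pvec))
        if pvec[flip] < 0:
            pvec, t = -pvec, -t
        scores[:, j] = t
        loadings[:, j] = pvec
        eigenvalues[j] = t @ t / (n - 1)
        R -= np.outer(t, pvec)

    explained = eigenvalues / total_var if total_var > 0 else np.zeros(k)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        eigenvalues=eigenvalues,
        explained_fraction=explained,
        column_means=means,
        n_iterations=n_iter,
        converged=converged,
    )


def project(result: PCAResult, new_rows: np.ndarray) -> np.ndarray:
    """Scores of new observations: (new_rows - column_means) @ loadings."""
    new_rows = np.atleast_2d(np.asarray(new_rows, dtype=float))
    if new_rows.shape[1] != result.column_means.size:
        raise ValueError(
            f"expected {result.column_means.size} columns, got {new_rows.shape[1]}"
        )
    return (new_rows - result.column_means) @ result.loadings
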