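"""Pairwise distances, centering schemes, and neighborhood rank matrices.

All multiscale statistics in this package operate on an ``n x n`` matrix of
pairwise dissimilarities, transformed by one of several centering schemes:

``double``
    The classical distance-correlation (Dcorr) centering: subtract row means,
    column means, add back the grand mean, and zero the diagonal.
``unbiased``
    U-centering, yielding the unbiased distance-correlation (Mcorr) estimator.
    Row/column sums are divided by ``n - 2`` and the total by
    ``(n - 1)(n - 2)``; the diagonal is exactly zero.
``mantel``
    Subtract the grand mean of the off-diagonal entries; zero diagonal.
``single_column`` / ``single_row``
    Subtract column means / row means; zero diagonal.

Rank matrices encode, for every observation, the nearest-neighbor ordering of
all other observations; the self-distance always receives rank 1 so that a
neighborhood of size ``k = n`` contains every pair.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "pairwise_distances",
    "center_distance_matrix",
    "rank_matrix",
    "CENTERING_SCHEMES",
    "SUPPORTED_METRICS",
]

SUPPORTED_METRICS = ("euclidean", "sqeuclidean", "cityblock")
CENTERING_SCHEMES = ("double", "unbiased", "mantel", "single_column", "single_row")


def _as_sample_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"sample matrix must be 2-D (rows = observations), got ndim={X.ndim}")
    if not np.all(np.isfinite(X)):
        raise ValueError("sample matrix contains non-finite entries")
    return X


def pairwise_distances(X, metric: str = "euclidean") -> np.ndarray:
    """Compute the ``n x n`` matrix of pairwise distances between rows of ``X``.

    Parameters
    ----------
    X : array-like, shape (n, d) or (n,)
        Observations in rows; a 1-D array is treated as ``n`` scalar samples.
    metric : str
        One of ``euclidean`` (default), ``sqeuclidean``, ``cityblock``.

    Returns
    -------
    ndarray, shape (n, n)
        Symmetric, zero-diagonal, nonnegative distance matrix.
    """
    X = _as_sample_matrix(X)
    if metric not in SUPPORTED_METRICS:
        raise ValueError(f"unsupported metric {metric!r}; choose from {SUPPORTED_METRICS}")
    D = cdist(X, X, metric=metric)
    # enforce exact symmetry / zero diagonal against floating-point asymmetry
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def check_distance_matrix(D) -> np.ndarray:
    """Validate a user-supplied square distance matrix."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {D.shape}")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(D < 0):
        raise ValueError("distance matrix has negative entries")
    return D


def center_distance_matrix(D, scheme: str = "unbiased") -> np.ndarray:
    """Apply a centering scheme to a distance matrix.

    See the module docstring for the scheme definitions. All schemes return a
    matrix with a zero diagonal.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if scheme not in CENTERING_SCHEMES:
        raise ValueError(f"unknown centering scheme {scheme!r}; choose from {CENTERING_SCHEMES}")
    if scheme == "unbiased" and n < 3:
        raise ValueError("unbiased (U-)centering requires n >= 3")

    if scheme == "double":
        row = D.mean(axis=1, keepdims=True)
        col = D.mean(axis=0, keepdims=True)
        A = D - row - col + D.mean()
    elif scheme == "unbiased":
        row = D.sum(axis=1, keepdims=True) / (n - 2)
        col = D.sum(axis=0, keepdims=True) / (n - 2)
        A = D - row - col + D.sum() / ((n - 1) * (n - 2))
    elif scheme == "mantel":
        if n > 1:
            off_mean = (D.sum() - np.trace(D)) / (n * (n - 1))
        else:
            off_mean = 0.0
        A = D - off_mean
    elif scheme == "single_column":
        A = D - D.mean(axis=0, keepdims=True)
    else:  # single_row
        A = D - D.mean(axis=1, keepdims=True)
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    return A


def rank_matrix(D, axis: str = "column") -> np.ndarray:
    """Within-column (or within-row) nearest-neighbor ranks of a distance matrix.

    For ``axis="column"``, entry ``(i, j)`` is the rank of observation ``i``
    among the neighbors of ``j``: rank 1 is the self-distance, rank 2 the
    nearest distinct neighbor, and so on. Ties are broken by the smaller
    observation index (stable), and the self-distance always ranks first.
    """
    D = np.asarray(D, dtype=float)
    if axis == "row":
        return rank_matrix(D.T, axis="column").T
    if axis != "column":
        raise ValueError("axis must be 'column' or 'row'")
    n = D.shape[0]
    key = D.copy()
    np.fill_diagonal(key, -np.inf)  # self sorts strictly first
    order = np.argsort(key, axis=0, kind="stable")
    ranks = np.empty((n, n), dtype=np.intp)
    ranks[order, np.arange(n)[None, :]] = np.arange(1, n + 1)[:, None]
    return ranks
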