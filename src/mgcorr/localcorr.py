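"""Local (scale-restricted) generalized correlations and the MGC-Map.

A *scale* is a pair ``(k, l)`` of neighborhood sizes. The local correlation
``c_kl`` is a Pearson-style correlation between the two centered distance
matrices, restricted to entries whose X-distance lies within the ``k``
nearest neighbors (by column rank) and whose Y-distance lies within the
``l`` nearest neighbors (by row rank); entries outside the neighborhood are
treated as zero and all first and second moments are taken over the full
``n^2`` positions. This makes every ``c_kl`` a bona-fide correlation in
``[-1, 1]``, and ``c_nn`` recovers the global generalized correlation
(Dcorr, Mcorr or Mantel, depending on the centering scheme).

The full ``n x n`` grid of local correlations is the MGC-Map. It is computed
in ``O(n^2)`` after ranking by scattering each product ``a_ij * b_ij`` onto
its rank pair and accumulating with 2-D prefix sums, rather than evaluating
each scale independently (which would cost ``O(n^4)``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "global_correlation",
    "local_correlation_at_scale",
    "all_local_correlations",
]

# A scale's variance factor below this fraction of the total sum of squares is
# treated as zero (catastrophic-cancellation guard); the correlation is then 0.
_VAR_RTOL = 1e-13


def _check_pair(A, B):
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"centered matrices must be square with equal shape, got {A.shape} vs {B.shape}")
    return A, B


def global_correlation(A, B) -> float:
    """Global generalized correlation between two centered matrices.

    Pearson correlation of the ``n^2`` entries of ``A`` against those of
    ``B``. With double centering this is Dcorr, with U-centering Mcorr, with
    Mantel centering the Mantel coefficient. Returns 0 when either matrix has
    zero entry-variance.
    """
    A, B = _check_pair(A, B)
    n = A.shape[0]
    a = A.ravel()
    b = B.ravel()
    n2 = n * n
    cov = a @ b - a.sum() * b.sum() / n2
    va = a @ a - a.sum() ** 2 / n2
    vb = b @ b - b.sum() ** 2 / n2
    if va <= 0 or vb <= 0:
        return 0.0
    return float(cov / np.sqrt(va * vb))


def local_correlation_at_scale(A, B, ranks_a, ranks_b, k: int, l: int) -> float:
    """Local correlation at a single scale ``(k, l)``, by direct masking.

    ``ranks_a`` are within-column ranks of the X distance matrix, ``ranks_b``
    within-row ranks of the Y distance matrix (rank 1 = self). Entries of
    ``A`` with column rank > ``k`` and entries of ``B`` with row rank > ``l``
    are zeroed, then the plain Pearson correlation of the two flattened
    vectors is returned. Quadratic per scale; the reference against which the
    fast map is checked.
    """
    A, B = _check_pair(A, B)
    n = A.shape[0]
    if not (1 <= k <= n) or not (1 <= l <= n):
        raise ValueError(f"scale ({k}, {l}) out of range [1, {n}]")
    ma = np.where(np.asarray(ranks_a) <= k, A, 0.0).ravel()
    mb = np.where(np.asarray(ranks_b) <= l, B, 0.0).ravel()
    if np.ptp(ma) == 0 or np.ptp(mb) == 0:
        return 0.0
    r = np.corrcoef(ma, mb)[0, 1]
    if not np.isfinite(r):
        return 0.0
    return float(r)


def all_local_correlations(A, B, ranks_a, ranks_b) -> np.ndarray:
    """The MGC-Map: local correlations at every scale ``(k, l)``.

    Returns an ``n x n`` array ``C`` with ``C[k-1, l-1] = c_kl`` (1-based
    scales). Each product ``a_ij b_ij`` belongs to every scale at least as
    large as its rank pair, so scattering products at their rank pair and
    taking cumulative sums along both axes yields all restricted sums at once.
    """
    A, B = _check_pair(A, B)
    n = A.shape[0]
    ra = np.asarray(ranks_a).ravel() - 1  # 0-based rank bins
    rb = np.asarray(ranks_b).ravel() - 1
    a = A.ravel()
    b = B.ravel()
    n2 = n * n

    cum_ab = np.bincount(ra * n + rb, weights=a * b, minlength=n2).reshape(n, n)
    np.cumsum(cum_ab, axis=0, out=cum_ab)
    np.cumsum(cum_ab, axis=1, out=cum_ab)

    ea = np.cumsum(np.bincount(ra, weights=a, minlength=n))
    eb = np.cumsum(np.bincount(rb, weights=b, minlength=n))
    va = np.cumsum(np.bincount(ra, weights=a * a, minlength=n))
    vb = np.cumsum(np.bincount(rb, weights=b * b, minlength=n))

    cov = cum_ab - np.outer(ea, eb) / n2
    da = va - ea * ea / n2
    db = vb - eb * eb / n2
    da[da <= _VAR_RTOL * max(va[-1], 0.0)] = 0.0
    db[db <= _VAR_RTOL * max(vb[-1], 0.0)] = 0.0
    denom = np.sqrt(np.outer(da, db))
    C = np.divide(cov, denom, out=np.zeros_like(cov), where=denom > 0)
    return C
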