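"""Feature-space affinities for stochastic neighbor embeddings.

Each sample :math:`x_i` is given a Gaussian neighborhood whose bandwidth
:math:`\\sigma_i` is calibrated by bisection so that the perplexity
:math:`2^{H_i}` of the conditional distribution

.. math::

    p_{j|i} = \\frac{\\exp(-\\lVert x_i - x_j\\rVert^2 / 2\\sigma_i^2)}
                    {\\sum_{k \\neq i} \\exp(-\\lVert x_i - x_k\\rVert^2 / 2\\sigma_i^2)}

equals a user-specified target (the effective number of neighbors).  The
conditional distributions are then symmetrized into the joint matrix
``p_ij = (p_{i|j} + p_{j|i}) / (2n)``, which sums to one over all ordered
pairs and is the reference distribution matched by the embedding.

Entropy is taken in base 2 throughout so that perplexity is exactly
``2**H``.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "squared_pairwise_distances",
    "conditional_affinities",
    "row_perplexity",
    "calibrate_bandwidths",
    "symmetrize",
    "joint_affinities",
]

# floor applied to probabilities before taking logarithms
_PROB_FLOOR = 1e-12


def _as_float_matrix(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {X.shape}")
    return X


def squared_pairwise_distances(X) -> np.ndarray:
    """Squared Euclidean distance matrix of the rows of ``X``.

    Parameters
    ----------
    X : array-like of shape (n_samples, n_features)
        Feature matrix; every entry must be finite.

    Returns
    -------
    ndarray of shape (n_samples, n_samples)
        Symmetric, zero-diagonal matrix of ``||x_i - x_j||^2``.
    """
    X = _as_float_matrix(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    finite_rows = np.isfinite(X).all(axis=1)
    if not finite_rows.all():
        bad = int(np.flatnonzero(~finite_rows)[0])
        raise ValueError(f"non-finite feature values in sample row {bad}")
    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    # exact symmetry despite floating-point cancellation
    return 0.5 * (d2 + d2.T)


def conditional_affinities(d2, sigma) -> np.ndarray:
    """Row-normalized Gaussian conditional probabilities ``p_{j|i}``.

    Exponents are shifted by the row maximum before exponentiation.  A row
    whose off-diagonal exponentials all underflow falls back to a uniform
    distribution over its n-1 neighbors with a warning, so one degenerate
    sample cannot poison a whole batch.
    """
    d2 = _as_float_matrix(d2, "d2")
    n = d2.shape[0]
    sigma = np.asarray(sigma, dtype=float).reshape(-1)
    if sigma.shape[0] != n:
        raise ValueError(f"sigma has length {sigma.shape[0]}, expected {n}")
    if not (np.isfinite(sigma).all() and (sigma > 0).all()):
        raise ValueError("all bandwidths must be positive and finite")

    with np.errstate(over="ignore"):
        beta = 1.0 / (2.0 * sigma**2)  # per-row precision
    logits = -d2 * beta[:, None]
    np.fill_diagonal(logits, -np.inf)
    rowmax = np.max(logits, axis=1, keepdims=True)
    # a fully degenerate row (all exponents -inf) must not turn into NaN
    logits = logits - np.where(np.isfinite(rowmax), rowmax, 0.0)
    p = np.exp(logits)
    np.fill_diagonal(p, 0.0)
    rowsum = p.sum(axis=1)
    dead = rowsum <= 0.0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} row(s) with fully underflowed affinities; "
            "falling back to uniform neighbor weights",
            RuntimeWarning,
            stacklevel=2,
        )
        p[dead] = 1.0
        p[dead, np.flatnonzero(dead)] = 0.0
        rowsum = p.sum(axis=1)
    return p / rowsum[:, None]


def row_perplexity(p_cond, i: int | None = None):
    """Perplexity ``2**H`` of conditional affinity rows (base-2 entropy).

    Zero-probability entries contribute nothing to the entropy.  With
    ``i=None`` the perplexity of every row is returned as a vector.
    """
    p = np.asarray(p_cond, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
        rows = p
    elif i is not None:
        rows = p[[i]]
    else:
        rows = p
    q = np.clip(rows, _PROB_FLOOR, None)
    h = -np.where(rows > 0, rows * np.log2(q), 0.0).sum(axis=1)
    perp = 2.0**h
    return float(perp[0]) if (i is not None or perp.shape[0] == 1) else perp


def _perplexities_at_log_sigma(d2: np.ndarray, log_sigma: np.ndarray) -> np.ndarray:
    """Perplexity of every row of ``d2`` at per-row bandwidths ``exp(log_sigma)``."""
    beta = 0.5 * np.exp(-2.0 * log_sigma)  # 1 / (2 sigma^2)
    logits = -d2 * beta[:, None]
    np.fill_diagonal(logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    np.fill_diagonal(p, 0.0)
    rowsum = p.sum(axis=1)
    rowsum[rowsum <= 0.0] = 1.0  # fully-underflowed row: entropy 0 below
    p /= rowsum[:, None]
    q = np.clip(p, _PROB_FLOOR, None)
    h = -np.where(p > 0, p * np.log2(q), 0.0).sum(axis=1)
    return 2.0**h


def calibrate_bandwidths(
    d2,
    perplexity: float,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> np.ndarray:
    """Per-sample Gaussian bandwidths matching a target perplexity.

    For every row a bisection on ``log sigma`` finds ``sigma_i`` such that
    the conditional distribution's perplexity equals ``perplexity`` within
    ``tol``.  Row entropy is non-decreasing in sigma, which makes the target
    monotone-bracketable; the initial bracket ``[1e-20, 1e20]`` is widened
    if needed.  All rows are bisected in lockstep (vectorized), which keeps
    per-batch recalibration during training cheap.

    Parameters
    ----------
    d2 : ndarray (n, n)
        Squared pairwise distances.
    perplexity : float
        Target effective neighbor count; must satisfy ``1 < P <= n - 1``.
    tol : float
        Tolerance on the achieved perplexity.
    max_iter : int
        Bisection iteration cap; on hitting it the midpoint of the closest
        bracket is returned with a warning.

    Returns
    -------
    ndarray of shape (n,)
        Calibrated ``sigma_i``.
    """
    d2 = _as_float_matrix(d2, "d2")
    n = d2.shape[0]
    if not 1.0 < perplexity <= n - 1:
        raise ValueError(
            f"perplexity must lie in (1, n-1] = (1, {n - 1}], got {perplexity}"
        )
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be > 0 and max_iter >= 1")

    off = d2 + np.where(np.eye(n, dtype=bool), np.nan, 0.0)
    degenerate = np.nanmax(off, axis=1) == np.nanmin(off, axis=1)
    if degenerate.any() and abs((n - 1) - perplexity) > tol:
        warnings.warn(
            f"{int(degenerate.sum())} row(s) have all-equal distances; their "
            f"perplexity is pinned at {n - 1}, target {perplexity} unattainable",
            RuntimeWarning,
            stacklevel=2,
        )

    lo = np.full(n, np.log(1e-20))
    hi = np.full(n, np.log(1e20))
    # entropy increases with sigma: widen until every row brackets the target
    for _ in range(100):
        p_lo = _perplexities_at_log_sigma(d2, lo)
        p_hi = _perplexities_at_log_sigma(d2, hi)
        too_high = (p_lo > perplexity) & ~degenerate
        too_low = (p_hi < perplexity + tol) & ~degenerate
        if not (too_high.any() or too_low.any()):
            break
        lo[too_high] -= 10.0
        hi[too_low] += 10.0

    converged = degenerate.copy()
    mid = np.zeros(n)
    for _ in range(max_iter):
        mid = np.where(converged, mid, 0.5 * (lo + hi))
        p_mid = _perplexities_at_log_sigma(d2, mid)
        newly = np.abs(p_mid - perplexity) <= tol
        converged |= newly
        if converged.all():
            break
        go_up = ~converged & (p_mid < perplexity)
        go_dn = ~converged & ~(p_mid < perplexity)
        lo[go_up] = mid[go_up]
        hi[go_dn] = mid[go_dn]
    else:
        mid = np.where(converged, mid, 0.5 * (lo + hi))
    if not converged.all():
        warnings.warn(
            f"bisection hit max_iter={max_iter} on "
            f"{int((~converged).sum())} row(s); returning bracket midpoint",
            RuntimeWarning,
            stacklevel=2,
        )
    sigma = np.exp(mid)
    sigma[degenerate] = 1.0
    return sigma


def symmetrize(p_cond) -> np.ndarray:
    """Joint affinities ``p_ij = (p_{i|j} + p_{j|i}) / (2n)``.

    The result is symmetric with zero diagonal and unit total mass.
    """
    p = _as_float_matrix(p_cond, "p_cond")
    n = p.shape[0]
    return (p + p.T) / (2.0 * n)


def joint_affinities(
    X,
    perplexity: float = 30.0,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> np.ndarray:
    """Full pipeline: features -> calibrated joint probability matrix P."""
    d2 = squared_pairwise_distances(X)
    sigma = calibrate_bandwidths(d2, perplexity, tol=tol, max_iter=max_iter)
    return symmetrize(conditional_affinities(d2, sigma))
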