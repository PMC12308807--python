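"""Embedding-space affinities and the Kullback–Leibler embedding loss.

Low-dimensional similarities use a Student-t kernel with ``alpha`` degrees
of freedom,

.. math::

    q_{ij} = \\frac{(1 + \\lVert z_i - z_j\\rVert^2/\\alpha)^{-(\\alpha+1)/2}}
                  {\\sum_{k \\neq l} (1 + \\lVert z_k - z_l\\rVert^2/\\alpha)^{-(\\alpha+1)/2}},

whose heavy tails let moderately distant points in feature space be placed
far apart in the embedding (the crowding-problem fix).  ``alpha`` is
conventionally set equal to the embedding dimensionality.  The training
objective is the Kullback–Leibler divergence

.. math::

    D_{KL}(P\\,\\Vert\\,Q) = \\sum_{i \\neq j} p_{ij} \\log\\frac{p_{ij}}{q_{ij}}

in nats.  Its gradient with respect to the embedded coordinates has the
closed form

.. math::

    \\frac{\\partial D_{KL}}{\\partial z_i}
      = \\frac{2(\\alpha+1)}{\\alpha} \\sum_j (p_{ij} - q_{ij})
        \\left(1 + \\lVert z_i - z_j\\rVert^2/\\alpha\\right)^{-1} (z_i - z_j),

which reduces to the familiar ``4 * sum (p-q)(1+d^2)^{-1} dz`` at alpha=1.
"""

from __future__ import annotations

import warnings

import numpy as np

from .affinity import squared_pairwise_distances

__all__ = [
    "student_q_matrix",
    "kl_divergence",
    "kl_gradient",
    "kl_gradient_check",
]

_Q_FLOOR = 1e-12


def _student_numerators(Z: np.ndarray, alpha: float) -> np.ndarray:
    d2 = squared_pairwise_distances(Z)
    num = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    np.fill_diagonal(num, 0.0)
    return num


def student_q_matrix(Z, alpha: float | None = None) -> np.ndarray:
    """Joint Student-t probabilities ``q_ij`` of an embedded batch.

    Parameters
    ----------
    Z : array-like of shape (n_samples, n_components)
        Embedded coordinates.
    alpha : float, optional
        Degrees of freedom of the kernel; defaults to the embedding
        dimensionality.

    Returns
    -------
    ndarray (n, n)
        Symmetric, zero-diagonal, sums to 1 over all ordered pairs.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError(f"Z must be 2-D, got shape {Z.shape}")
    if alpha is None:
        alpha = float(Z.shape[1])
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    num = _student_numerators(Z, alpha)
    return num / num.sum()


def kl_divergence(P, Q) -> float:
    """Kullback–Leibler divergence ``sum_{i!=j} p log(p/q)`` in nats.

    Terms with ``p_ij = 0`` contribute zero.  A ``q_ij = 0`` under positive
    ``p_ij`` is floored at 1e-12 with a warning (cannot occur for a
    Student-t kernel on finite coordinates).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs Q {Q.shape}")
    mask = P > 0
    if (Q[mask] <= 0).any():
        warnings.warn(
            "q_ij = 0 where p_ij > 0; flooring q at 1e-12",
            RuntimeWarning,
            stacklevel=2,
        )
    q = np.clip(Q, _Q_FLOOR, None)
    return float(np.where(mask, P * np.log(np.where(mask, P, 1.0) / q), 0.0).sum())


def kl_gradient(P, Z, alpha: float | None = None) -> np.ndarray:
    """Analytic gradient of the KL loss with respect to the embedding ``Z``."""
    P = np.asarray(P, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if alpha is None:
        alpha = float(Z.shape[1])
    num = _student_numerators(Z, alpha)
    Q = num / num.sum()
    d2 = squared_pairwise_distances(Z)
    w = (P - Q) / (1.0 + d2 / alpha)
    np.fill_diagonal(w, 0.0)
    # sum_j w_ij (z_i - z_j), vectorized
    g = w.sum(axis=1)[:, None] * Z - w @ Z
    return (2.0 * (alpha + 1.0) / alpha) * g


def kl_gradient_check(P, Z, alpha: float | None = None, step: float = 1e-5) -> float:
    """Max abs deviation between analytic and central finite-difference gradients.

    Intended for small batches (n <= 10); validates the backpropagation
    entry point of training.
    """
    P = np.asarray(P, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if alpha is None:
        alpha = float(Z.shape[1])
    analytic = kl_gradient(P, Z, alpha)
    numeric = np.empty_like(Z)
    for i in range(Z.shape[0]):
        for k in range(Z.shape[1]):
            zp = Z.copy()
            zp[i, k] += step
            zm = Z.copy()
            zm[i, k] -= step
            fp = kl_divergence(P, student_q_matrix(zp, alpha))
            fm = kl_divergence(P, student_q_matrix(zm, alpha))
            numeric[i, k] = (fp - fm) / (2.0 * step)
    return float(np.abs(analytic - numeric).max())
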