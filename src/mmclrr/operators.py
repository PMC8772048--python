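"""Proximal and closed-form operators used by the LADMAP solver.

Each function is the exact minimizer of a small convex (or orthogonally
constrained) subproblem:

* :func:`soft_threshold` — prox of ``eps * ||.||_1``.
* :func:`svt`            — prox of ``eps * ||.||_*`` (singular value thresholding).
* :func:`l21_column_shrink` — prox of ``tau * ||.||_{2,1}`` (column-wise shrinkage).
* :func:`orthogonal_factor` — argmax of ``tr(W^T B)`` over orthogonal ``W``
  (the orthogonal Procrustes solution).
"""

from __future__ import annotations

import numpy as np

__all__ = ["soft_threshold", "svt", "l21_column_shrink", "orthogonal_factor"]


def soft_threshold(a: np.ndarray, eps: float) -> np.ndarray:
    """Elementwise soft thresholding ``sgn(a) * max(|a| - eps, 0)``.

    This is the proximal operator of ``eps * ||.||_1``: the unique minimizer of
    ``eps * ||Z||_1 + 0.5 * ||Z - a||_F^2``.

    Parameters
    ----------
    a : ndarray
        Input array (any shape).
    eps : float
        Nonnegative threshold.
    """
    if eps < 0:
        raise ValueError(f"soft_threshold requires eps >= 0, got {eps}")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - eps, 0.0)


def svt(a: np.ndarray, eps: float) -> np.ndarray:
    """Singular value thresholding: shrink the spectrum of ``a`` by ``eps``.

    Computes ``U S_eps(Sigma) V^T`` where ``a = U Sigma V^T`` is the thin SVD
    and ``S_eps`` is :func:`soft_threshold` on the singular values.  This is
    the proximal operator of ``eps * ||.||_*`` (nuclear norm).
    """
    if eps < 0:
        raise ValueError(f"svt requires eps >= 0, got {eps}")
    a = np.asarray(a, dtype=float)
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    s = np.maximum(s - eps, 0.0)
    keep = s > 0
    if not np.any(keep):
        return np.zeros_like(a)
    return (u[:, keep] * s[keep]) @ vt[keep]


def l21_column_shrink(g: np.ndarray, tau: float) -> np.ndarray:
    """Column-wise shrinkage, the proximal operator of ``tau * ||.||_{2,1}``.

    Column ``i`` of the result is ``(||g_i|| - tau)/||g_i|| * g_i`` when
    ``||g_i|| > tau`` and zero otherwise.  Zero columns stay zero.
    """
    if tau < 0:
        raise ValueError(f"l21_column_shrink requires tau >= 0, got {tau}")
    g = np.asarray(g, dtype=float)
    norms = np.linalg.norm(g, axis=0)
    scale = np.zeros_like(norms)
    pos = norms > tau
    scale[pos] = (norms[pos] - tau) / norms[pos]
    return g * scale


def orthogonal_factor(b: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes solution ``W = U V^T`` for ``b = U Sigma V^T``.

    Among all orthogonal matrices, ``W`` maximizes ``tr(W^T b)``.  Full
    (not thin) singular vector matrices are used so that the result is
    exactly orthogonal even when ``b`` is rank deficient; ``b = 0`` yields
    the identity.
    """
    b = np.asarray(b, dtype=float)
    if b.shape[0] != b.shape[1]:
        raise ValueError("orthogonal_factor expects a square matrix")
    u, _, vt = np.linalg.svd(b, full_matrices=True)
    return u @ vt
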