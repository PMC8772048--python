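"""k-nearest-neighbour heat-kernel graphs and their Laplacians.

The manifold regularizer of the solver penalizes ``tr(Z L Z^T)`` where
``L = D - H`` is the combinatorial Laplacian of a symmetric kNN graph with
Gaussian (heat kernel) edge weights

    H_ij = exp(-||x_i - x_j||^2 / (2 t^2))   if j in kNN(i) or i in kNN(j),
           0                                 otherwise,

built on the sample columns of one data view.  A small penalty keeps the
low-dimensional representations of nearby samples close, preserving the
local geometry of the data manifold.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances

__all__ = [
    "NeighborWeights",
    "GraphLaplacian",
    "pairwise_sq_distances",
    "heat_kernel_weights",
    "build_laplacian",
    "view_laplacian",
]


@dataclasses.dataclass(frozen=True)
class NeighborWeights:
    """Symmetric nonnegative heat-kernel weight matrix on a kNN graph."""

    weights: np.ndarray  # (N, N), symmetric, zero diagonal, entries in [0, 1]
    k: int
    t: float


@dataclasses.dataclass(frozen=True)
class GraphLaplacian:
    """Combinatorial graph Laplacian ``L = D - H`` with its degree matrix."""

    laplacian: np.ndarray  # (N, N), symmetric PSD, zero row sums
    degree: np.ndarray  # (N, N) diagonal


def pairwise_sq_distances(x: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between the sample columns of ``x``.

    Parameters
    ----------
    x : ndarray of shape (n_features, n_samples)

    Returns
    -------
    ndarray of shape (n_samples, n_samples)
        Symmetric, nonnegative, zero diagonal.
    """
    x = np.asarray(x, dtype=float)
    d2 = euclidean_distances(x.T, squared=True)
    np.fill_diagonal(d2, 0.0)
    # exact symmetry regardless of floating point evaluation order
    return np.clip((d2 + d2.T) / 2.0, 0.0, None)


def _knn_mask(d2: np.ndarray, k: int) -> np.ndarray:
    """Boolean OR-neighbourhood mask: (i, j) True iff j in kNN(i) or i in kNN(j).

    Ties in distance are broken deterministically in favour of the lower
    sample index (stable argsort).  A point is never its own neighbour.
    """
    n = d2.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k_neighbors must satisfy 1 <= k < n_samples; got k={k}, n={n}")
    d = d2.copy()
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), k)
    mask = np.zeros((n, n), dtype=bool)
    mask[rows, order[:, :k].ravel()] = True
    return mask | mask.T


def heat_kernel_weights(x: np.ndarray, k: int = 5, t: float | str = "auto") -> NeighborWeights:
    """Gaussian edge weights on the symmetric kNN graph of the sample columns.

    ``t="auto"`` sets the kernel width to the mean Euclidean distance over
    the retained kNN edges (zero-distance duplicate pairs contribute zero to
    the mean).  If every retained edge has zero length, ``t`` falls back to 1,
    which makes all retained weights 1.
    """
    d2 = pairwise_sq_distances(x)
    mask = _knn_mask(d2, k)
    if t == "auto":
        edge_d = np.sqrt(d2[mask])
        t_val = float(edge_d.mean()) if edge_d.size and edge_d.mean() > 0 else 1.0
    else:
        t_val = float(t)
        if t_val <= 0:
            raise ValueError(f"kernel width t must be positive, got {t}")
    w = np.where(mask, np.exp(-d2 / (2.0 * t_val**2)), 0.0)
    np.fill_diagonal(w, 0.0)
    return NeighborWeights(weights=w, k=k, t=t_val)


def build_laplacian(w: NeighborWeights | np.ndarray) -> GraphLaplacian:
    """Combinatorial Laplacian ``L = D - H`` with ``D_ii = sum_j H_ji``."""
    h = w.weights if isinstance(w, NeighborWeights) else np.asarray(w, dtype=float)
    deg = np.diag(h.sum(axis=0))
    return GraphLaplacian(laplacian=deg - h, degree=deg)


def view_laplacian(x: np.ndarray, k: int = 5, t: float | str = "auto") -> GraphLaplacian:
    """Convenience: heat-kernel kNN graph Laplacian of one view in one call."""
    return build_laplacian(heat_kernel_weights(x, k=k, t=t))
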