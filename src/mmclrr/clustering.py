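"""Normalized-cuts spectral clustering of the fused representation.

The fused matrix ``Z*`` is turned into a symmetric nonnegative affinity
``A = (|Z*| + |Z*^T|) / 2`` (diagonal zeroed, the standard low-rank
representation convention) and partitioned with the normalized-cuts
relaxation: the bottom eigenvectors of the symmetric-normalized Laplacian
``I - D^{-1/2} A D^{-1/2}``, row-normalized, discretized by k-means.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

__all__ = ["ClusterAssignment", "symmetrize_affinity", "ncuts", "NCutsClustering"]

_DEGREE_FLOOR = 1e-12


@dataclasses.dataclass
class ClusterAssignment:
    """Cluster labels (1..c) for the N samples, with provenance."""

    labels: np.ndarray  # (N,), values in 1..n_clusters
    n_clusters: int
    seed: int
    warning: str | None = None


def symmetrize_affinity(z_star: np.ndarray) -> np.ndarray:
    """``A = (|Z*| + |Z*^T|)/2`` with zeroed diagonal."""
    z = np.asarray(z_star, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("Z* must be a square matrix")
    a = (np.abs(z) + np.abs(z.T)) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def ncuts(affinity: np.ndarray, n_clusters: int, seed: int = 0) -> ClusterAssignment:
    """Normalized cuts on a symmetric nonnegative affinity matrix.

    Bottom ``n_clusters`` eigenvectors of ``I - D^{-1/2} A D^{-1/2}``, rows
    scaled to unit length, then k-means with 50 restarts at the given seed.
    Zero-degree (isolated) samples have their degree floored at 1e-12 with a
    warning.  Labels are reported in 1..c.
    """
    a = np.asarray(affinity, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("affinity must be square")
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    n = a.shape[0]
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds n_samples={n}")
    if np.any(a < -1e-12) or np.linalg.norm(a - a.T) > 1e-8 * max(1.0, np.linalg.norm(a)):
        raise ValueError("affinity must be symmetric and nonnegative")

    warning = None
    deg = a.sum(axis=1)
    if np.any(deg <= _DEGREE_FLOOR):
        warning = f"{int(np.sum(deg <= _DEGREE_FLOOR))} isolated sample(s); degree floored"
        warnings.warn(warning, RuntimeWarning, stacklevel=2)
        deg = np.maximum(deg, _DEGREE_FLOOR)

    d_inv_sqrt = 1.0 / np.sqrt(deg)
    l_sym = np.eye(n) - d_inv_sqrt[:, None] * a * d_inv_sqrt[None, :]
    l_sym = (l_sym + l_sym.T) / 2.0
    _, vecs = scipy.linalg.eigh(l_sym, subset_by_index=[0, n_clusters - 1])
    row_norms = np.linalg.norm(vecs, axis=1)
    vecs = vecs / np.maximum(row_norms, _DEGREE_FLOOR)[:, None]

    km = KMeans(n_clusters=n_clusters, n_init=50, random_state=seed)
    labels = km.fit_predict(vecs) + 1

    if len(np.unique(labels)) < n_clusters:
        warning = (warning + "; " if warning else "") + (
            f"only {len(np.unique(labels))} of {n_clusters} requested clusters populated"
        )
        warnings.warn(warning, RuntimeWarning, stacklevel=2)
    return ClusterAssignment(
        labels=labels, n_clusters=n_clusters, seed=seed, warning=warning
    )


class NCutsClustering(ClusterMixin, BaseEstimator):
    """scikit-learn wrapper around :func:`ncuts`.

    ``fit(A)`` expects a square matrix: either an already symmetric
    nonnegative affinity or a raw fused representation, which is passed
    through :func:`symmetrize_affinity` first when ``symmetrize=True``.
    """

    def __init__(self, n_clusters: int = 2, random_state: int = 0, symmetrize: bool = True):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.symmetrize = symmetrize

    def fit(self, X: np.ndarray, y: None = None) -> "NCutsClustering":
        a = symmetrize_affinity(X) if self.symmetrize else np.asarray(X, dtype=float)
        assignment = ncuts(a, self.n_clusters, seed=self.random_state)
        self.affinity_ = a
        self.assignment_ = assignment
        self.labels_ = assignment.labels
        return self

    def fit_predict(self, X: np.ndarray, y: None = None) -> np.ndarray:
        return self.fit(X).labels_
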