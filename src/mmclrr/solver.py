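"""LADMAP solver for multi-view manifold-regularized compact low-rank
representation.

The model learns, for each view ``X^(v)`` (features x samples), a
representation ``Z^(v)`` through a concept-factorization dictionary
``X^(v) W^(v)`` (``W`` orthogonal), minimizing

    sum_v [ ||Z^(v)||_*  +  gamma1 ||Z^(v)||_1  +  gamma2 ||E^(v)||_{2,1}
            + gamma3 tr(Z^(v) L^(v) Z^(v)^T) ]
    + sum_{v != w} gamma_view ||Z^(v) - Z^(w)||_F^2

    s.t.  X^(v) = X^(v) W^(v) Z^(v) + E^(v),   W^(v)^T W^(v) = I.

The augmented-Lagrangian splitting introduces three copies of ``Z``
(``Z_A`` carries the nuclear + manifold terms, ``Z_B`` the l1 term, ``Z_C``
the cross-view consistency term) plus the dictionary code
``Hcode = W Z``, five Lagrange multipliers ``Y1..Y5``, and one shared
adaptive penalty ``mu`` grown geometrically each iteration.

Each ``update_*`` function below is the exact (or linearized-proximal)
minimizer of its subproblem; :class:`MmCLRR` wires them into the full
alternating loop.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .datasets import MultiViewDataset, as_view_matrices
from .graph import GraphLaplacian, view_laplacian
from .operators import l21_column_shrink, orthogonal_factor, soft_threshold, svt

__all__ = [
    "ViewState",
    "SolverDiagnostics",
    "SolverResult",
    "DivergenceError",
    "MmCLRR",
    "update_Z",
    "update_ZA",
    "update_ZB",
    "update_ZC",
    "update_E",
    "update_H",
    "update_W",
    "update_multipliers",
    "fuse_affinity",
]


class DivergenceError(RuntimeError):
    """Raised when a state matrix turns non-finite during iteration."""


@dataclasses.dataclass
class ViewState:
    """All per-view variables of the augmented Lagrangian.

    ``X`` is (M_v, N); ``Z``, ``Z_A``, ``Z_B``, ``Z_C``, ``Hcode``, ``W`` and
    ``Y2..Y5`` are (N, N); ``E`` and ``Y1`` are (M_v, N).  ``lap_norm2`` and
    ``x_norm2_sq`` cache the spectral norm of the Laplacian and the squared
    spectral norm of ``X`` for the linearized ``Z_A`` step.
    """

    X: np.ndarray
    laplacian: np.ndarray
    Z: np.ndarray
    Z_A: np.ndarray
    Z_B: np.ndarray
    Z_C: np.ndarray
    Hcode: np.ndarray
    W: np.ndarray
    E: np.ndarray
    Y1: np.ndarray
    Y2: np.ndarray
    Y3: np.ndarray
    Y4: np.ndarray
    Y5: np.ndarray
    lap_norm2: float = 0.0
    x_norm2_sq: float = 0.0

    @classmethod
    def initial(cls, x: np.ndarray, laplacian: np.ndarray) -> "ViewState":
        """Zero-initialized state (W = I), fully deterministic."""
        x = np.asarray(x, dtype=float)
        m, n = x.shape
        lap = np.asarray(laplacian, dtype=float)
        if lap.shape != (n, n):
            raise ValueError(f"laplacian shape {lap.shape} does not match n_samples={n}")
        zeros_n = lambda: np.zeros((n, n))  # noqa: E731
        return cls(
            X=x,
            laplacian=lap,
            Z=zeros_n(),
            Z_A=zeros_n(),
            Z_B=zeros_n(),
            Z_C=zeros_n(),
            Hcode=zeros_n(),
            W=np.eye(n),
            E=np.zeros((m, n)),
            Y1=np.zeros((m, n)),
            Y2=zeros_n(),
            Y3=zeros_n(),
            Y4=zeros_n(),
            Y5=zeros_n(),
            lap_norm2=float(np.linalg.norm(lap, 2)),
            x_norm2_sq=float(np.linalg.norm(x, 2) ** 2),
        )


@dataclasses.dataclass
class SolverDiagnostics:
    """Per-iteration convergence bookkeeping.

    ``residuals`` has one row per iteration with the maximum-over-views
    relative violation of the five constraints, in the order
    (X=XH+E, H=WZ, Z=Z_A, Z=Z_B, Z=Z_C).
    """

    n_iter: int
    residuals: np.ndarray  # (n_iter, 5)
    mu_trajectory: np.ndarray  # (n_iter,)
    converged: bool
    w_ortho_error: np.ndarray  # (n_iter,) max over views of ||W^T W - I||_F

    def to_dict(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "converged": self.converged,
            "residuals": self.residuals.tolist(),
            "mu_trajectory": self.mu_trajectory.tolist(),
            "w_ortho_error": self.w_ortho_error.tolist(),
        }


@dataclasses.dataclass
class SolverResult:
    """Final per-view factors, the fused representation and diagnostics."""

    Z: list[np.ndarray]
    E: list[np.ndarray]
    W: list[np.ndarray]
    Z_star: np.ndarray
    diagnostics: SolverDiagnostics


# ---------------------------------------------------------------------------
# Per-variable updates.  Each takes the current state and the shared penalty
# mu (all five penalties are kept equal) and returns the new value.
# ---------------------------------------------------------------------------


def update_Z(state: ViewState, mu: float) -> np.ndarray:
    """Exact minimizer of the ``Z`` subproblem.

    Solves ``[mu W^T W + 3 mu I] Z = mu W^T Hcode + mu (Z_A + Z_B + Z_C)
    + W^T Y2 - Y3 - Y4 - Y5``; with ``W`` orthogonal the system matrix is
    ``4 mu I`` and the solve is exact.
    """
    w = state.W
    lhs = mu * (w.T @ w) + 3.0 * mu * np.eye(w.shape[0])
    rhs = (
        mu * (w.T @ state.Hcode)
        + mu * (state.Z_A + state.Z_B + state.Z_C)
        + w.T @ state.Y2
        - state.Y3
        - state.Y4
        - state.Y5
    )
    return np.linalg.solve(lhs, rhs)


def update_ZA(
    state: ViewState,
    mu: float,
    gamma3: float,
    eta_includes_data_norm: bool = True,
) -> np.ndarray:
    """Linearized proximal step for the nuclear-norm + manifold subproblem.

    One gradient step on the smooth part followed by singular value
    thresholding at ``1/eta`` with step size
    ``eta = 2 gamma3 ||L||_2 + mu (1 + ||X||_2^2)``.  The ``||X||_2^2`` term
    is not required by the Lipschitz constant of this subproblem (it only
    enlarges ``eta``, slowing but never breaking the step) and can be
    dropped via ``eta_includes_data_norm=False``.
    """
    lap = state.laplacian
    grad = gamma3 * (state.Z_A @ lap.T + state.Z_A @ lap) + mu * (
        state.Z_A - state.Z - state.Y3 / mu
    )
    eta = 2.0 * gamma3 * state.lap_norm2 + mu * (
        1.0 + (state.x_norm2_sq if eta_includes_data_norm else 0.0)
    )
    return svt(state.Z_A - grad / eta, 1.0 / eta)


def update_ZB(state: ViewState, mu: float, gamma1: float) -> np.ndarray:
    """Exact l1 prox: ``Z_B = S_{gamma1/mu}(Z + Y4/mu)``."""
    return soft_threshold(state.Z + state.Y4 / mu, gamma1 / mu)


def update_ZC(
    states: Sequence[ViewState], v: int, mu: float, gamma_view: float
) -> np.ndarray:
    """Exact minimizer of the cross-view consistency subproblem for view v.

    ``Z_C = [2 gamma (m_v - 1) + mu]^-1 (2 gamma sum_{w != v} Z^(w)
    + mu Z^(v) + Y5)``; with a single view the sum is empty and this
    reduces to ``Z + Y5/mu``.
    """
    m_v = len(states)
    state = states[v]
    other_sum = sum(
        (states[w].Z for w in range(m_v) if w != v),
        start=np.zeros_like(state.Z),
    )
    denom = 2.0 * gamma_view * (m_v - 1) + mu
    return (2.0 * gamma_view * other_sum + mu * state.Z + state.Y5) / denom


def update_E(state: ViewState, mu: float, gamma2: float) -> np.ndarray:
    """Exact l2,1 prox on ``G = X - X Hcode + Y1/mu`` at level ``gamma2/mu``."""
    g = state.X - state.X @ state.Hcode + state.Y1 / mu
    return l21_column_shrink(g, gamma2 / mu)


def update_H(state: ViewState, mu: float) -> np.ndarray:
    """Exact minimizer of the dictionary-code subproblem.

    ``Hcode = (mu X^T X + mu I)^-1 (mu X^T X - mu X^T E + X^T Y1
    + mu W Z - Y2)``.  The system is positive definite for any mu > 0.
    """
    x = state.X
    xtx = x.T @ x
    lhs = mu * xtx + mu * np.eye(xtx.shape[0])
    rhs = (
        mu * xtx
        - mu * (x.T @ state.E)
        + x.T @ state.Y1
        + mu * (state.W @ state.Z)
        - state.Y2
    )
    return np.linalg.solve(lhs, rhs)


def update_W(state: ViewState, mu: float, damping: float = 0.0) -> np.ndarray:
    """Orthogonal Procrustes update ``W = U V^T`` of ``B = (Hcode + Y2/mu) Z^T``.

    With ``damping = 0`` this is the exact subproblem solution.  With
    ``damping = alpha > 0`` the update is the inertial variant
    ``W = W_prev @ polar(W_prev^T B + alpha ||B||_2 I)``: because ``Z`` is
    driven toward low rank, ``B`` always has near-zero singular values,
    where the exact polar factor is discontinuous — rounding-level input
    differences then steer the whole trajectory to different stationary
    points.  The spectral shift bounds the conditioning of the step while
    leaving the fixed points unchanged (at a fixed point ``W_prev^T B`` is
    symmetric positive semidefinite, so the shifted polar factor is the
    identity).

    When ``B`` is numerically zero (e.g. ``Z = 0`` at start) the subproblem
    is constant over the orthogonal group; the previous W is kept so the
    step is deterministic and feasible.
    """
    b = (state.Hcode + state.Y2 / mu) @ state.Z.T
    if np.linalg.norm(b) < 1e-12:
        return state.W
    if damping == 0.0:
        return orthogonal_factor(b)
    n = b.shape[0]
    target = state.W.T @ b + damping * np.linalg.norm(b, 2) * np.eye(n)
    return state.W @ orthogonal_factor(target)


def update_multipliers(state: ViewState, mu: float) -> None:
    """Dual ascent on all five constraints (in place), at step mu each."""
    state.Y1 = state.Y1 + mu * (state.X - state.X @ state.Hcode - state.E)
    state.Y2 = state.Y2 + mu * (state.Hcode - state.W @ state.Z)
    state.Y3 = state.Y3 + mu * (state.Z - state.Z_A)
    state.Y4 = state.Y4 + mu * (state.Z - state.Z_B)
    state.Y5 = state.Y5 + mu * (state.Z - state.Z_C)


def fuse_affinity(z_list: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise mean of the per-view representations (the fused ``Z*``)."""
    if len(z_list) == 0:
        raise ValueError("fuse_affinity needs at least one representation")
    shapes = {z.shape for z in z_list}
    if len(shapes) != 1:
        raise ValueError(f"representations differ in shape: {shapes}")
    return np.mean(np.stack([np.asarray(z, dtype=float) for z in z_list]), axis=0)


# ---------------------------------------------------------------------------
# Residuals and the full fit loop
# ---------------------------------------------------------------------------


def constraint_residuals(state: ViewState) -> np.ndarray:
    """Relative Frobenius violations of the five constraints of one view."""
    x_scale = max(np.linalg.norm(state.X), np.finfo(float).tiny)
    z_scale = max(1.0, np.linalg.norm(state.Z))
    return np.array(
        [
            np.linalg.norm(state.X - state.X @ state.Hcode - state.E) / x_scale,
            np.linalg.norm(state.Hcode - state.W @ state.Z) / z_scale,
            np.linalg.norm(state.Z - state.Z_A) / z_scale,
            np.linalg.norm(state.Z - state.Z_B) / z_scale,
            np.linalg.norm(state.Z - state.Z_C) / z_scale,
        ]
    )


_STATE_FIELDS = ("Z", "Z_A", "Z_B", "Z_C", "Hcode", "W", "E", "Y1", "Y2", "Y3", "Y4", "Y5")


def _check_finite(states: Sequence[ViewState], iteration: int) -> None:
    for v, st in enumerate(states):
        for name in _STATE_FIELDS:
            if not np.all(np.isfinite(getattr(st, name))):
                raise DivergenceError(
                    f"non-finite values in {name} of view {v} at iteration {iteration}"
                )


class MmCLRR(BaseEstimator):
    """Multi-view manifold-regularized compact low-rank representation.

    A scikit-learn style estimator: ``fit`` takes a list of per-view
    features x samples matrices (or a :class:`~mmclrr.datasets.MultiViewDataset`)
    sharing one sample axis, runs the LADMAP loop and exposes the learned
    factors as fitted attributes.

    Parameters
    ----------
    gamma1, gamma2, gamma3, gamma_view : float
        Weights of the l1, l2,1, manifold and cross-view consistency terms.
    k_neighbors : int
        Neighbour count for the per-view graphs built when none are passed
        to ``fit``.
    kernel_t : float or "auto"
        Heat-kernel width for those graphs.
    mu0, mu_max, rho : float
        Initial value, cap and per-iteration growth factor of the shared
        adaptive penalty.
    tol : float
        Convergence threshold on the maximum relative constraint residual
        over all views.
    max_iter : int
        Iteration cap; hitting it leaves ``converged_`` False (no exception).
    w_damping : float
        Spectral shift of the inertial dictionary (W) update; see
        :func:`update_W`.  Zero recovers the exact Procrustes step, whose
        ill-conditioning at the low-rank solutions this model seeks makes
        runs irreproducible across linear-algebra backends.
    eta_includes_data_norm : bool
        Include the ``||X||_2^2`` term in the linearized ``Z_A`` step size.

    Attributes
    ----------
    Z_, E_, W_ : lists of ndarray
        Per-view representation, column-sparse error and dictionary factors.
    Z_star_ : ndarray of shape (n_samples, n_samples)
        Fused representation, the elementwise mean of ``Z_``.
    diagnostics_ : SolverDiagnostics
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        gamma1: float = 0.1,
        gamma2: float = 10.0,
        gamma3: float = 0.1,
        gamma_view: float = 1.0,
        k_neighbors: int = 5,
        kernel_t: float | str = "auto",
        mu0: float = 1e-2,
        mu_max: float = 1e6,
        rho: float = 1.1,
        tol: float = 1e-6,
        max_iter: int = 500,
        w_damping: float = 0.0,
        eta_includes_data_norm: bool = True,
    ):
        self.gamma1 = gamma1
        self.gamma2 = gamma2
        self.gamma3 = gamma3
        self.gamma_view = gamma_view
        self.k_neighbors = k_neighbors
        self.kernel_t = kernel_t
        self.mu0 = mu0
        self.mu_max = mu_max
        self.rho = rho
        self.tol = tol
        self.max_iter = max_iter
        self.w_damping = w_damping
        self.eta_includes_data_norm = eta_includes_data_norm

    def fit(
        self,
        X: "MultiViewDataset | Sequence[np.ndarray]",
        y: None = None,
        laplacians: "Sequence[GraphLaplacian | np.ndarray] | None" = None,
    ) -> "MmCLRR":
        """Run the alternating LADMAP loop to convergence or ``max_iter``."""
        mats = as_view_matrices(X)
        for g in (self.gamma1, self.gamma2, self.gamma3, self.gamma_view):
            if g < 0:
                raise ValueError("regularization weights must be nonnegative")
        if self.rho < 1 or not 0 < self.mu0 <= self.mu_max:
            raise ValueError("need rho >= 1 and 0 < mu0 <= mu_max")

        if laplacians is None:
            laplacians = [
                view_laplacian(m, k=self.k_neighbors, t=self.kernel_t) for m in mats
            ]
        if len(laplacians) != len(mats):
            raise ValueError("need exactly one laplacian per view")
        laps = [
            lp.laplacian if isinstance(lp, GraphLaplacian) else np.asarray(lp, float)
            for lp in laplacians
        ]

        states = [ViewState.initial(m, lp) for m, lp in zip(mats, laps)]
        mu = float(self.mu0)
        n = states[0].Z.shape[0]
        eye = np.eye(n)
        res_hist: list[np.ndarray] = []
        mu_hist: list[float] = []
        ortho_hist: list[float] = []
        converged = False

        for it in range(1, self.max_iter + 1):
            for v, st in enumerate(states):
                st.Z = update_Z(st, mu)
                st.Z_A = update_ZA(
                    st, mu, self.gamma3, self.eta_includes_data_norm
                )
                st.Z_B = update_ZB(st, mu, self.gamma1)
                st.Z_C = update_ZC(states, v, mu, self.gamma_view)
                st.E = update_E(st, mu, self.gamma2)
                st.Hcode = update_H(st, mu)
                st.W = update_W(st, mu, self.w_damping)
                update_multipliers(st, mu)
            _check_finite(states, it)
            res = np.max([constraint_residuals(st) for st in states], axis=0)
            res_hist.append(res)
            mu_hist.append(mu)
            ortho_hist.append(
                max(np.linalg.norm(st.W.T @ st.W - eye) for st in states)
            )
            if res.max() < self.tol:
                converged = True
                break
            mu = min(self.rho * mu, self.mu_max)

        self.Z_ = [st.Z for st in states]
        self.E_ = [st.E for st in states]
        self.W_ = [st.W for st in states]
        self.Z_star_ = fuse_affinity(self.Z_)
        self.diagnostics_ = SolverDiagnostics(
            n_iter=len(res_hist),
            residuals=np.asarray(res_hist),
            mu_trajectory=np.asarray(mu_hist),
            converged=converged,
            w_ortho_error=np.asarray(ortho_hist),
        )
        self.n_iter_ = len(res_hist)
        self.converged_ = converged
        return self

    def result_(self) -> SolverResult:
        """Bundle the fitted factors as a :class:`SolverResult`."""
        return SolverResult(
            Z=self.Z_,
            E=self.E_,
            W=self.W_,
            Z_star=self.Z_star_,
            diagnostics=self.diagnostics_,
        )
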