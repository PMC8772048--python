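"""Independent reference implementations used only by the tests.

Everything here is written flat against numpy/scipy, without importing
mmclrr's solver or operator modules, so agreement between the package and
these routines is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from scipy.optimize import minimize, minimize_scalar


# ---------------------------------------------------------------------------
# numeric prox minimizers
# ---------------------------------------------------------------------------


def prox_l1_objective(z, a, eps):
    return eps * np.abs(z).sum() + 0.5 * ((z - a) ** 2).sum()


def prox_l1_numeric(a: np.ndarray, eps: float) -> np.ndarray:
    """Entrywise scalar minimization of eps*|z| + 0.5*(z - a)^2."""
    out = np.empty_like(a, dtype=float)
    flat_a = a.ravel()
    flat_o = out.ravel()
    for i, ai in enumerate(flat_a):
        res = minimize_scalar(
            lambda z: eps * abs(z) + 0.5 * (z - ai) ** 2,
            bounds=(-abs(ai) - 1.0, abs(ai) + 1.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        flat_o[i] = res.x
    return out


def prox_nuclear_objective(z: np.ndarray, a: np.ndarray, eps: float) -> float:
    return eps * scipy.linalg.svdvals(z).sum() + 0.5 * np.sum((z - a) ** 2)


def prox_nuclear_numeric(a: np.ndarray, eps: float) -> np.ndarray:
    """Derivative-free minimization of eps*||Z||_* + 0.5*||Z - A||_F^2.

    Nelder-Mead on the flattened matrix; the objective is convex, so the
    simplex converges to the global minimizer for the small matrices used
    in the tests.
    """
    shape = a.shape

    def obj(flat):
        return prox_nuclear_objective(flat.reshape(shape), a, eps)

    res = minimize(
        obj,
        a.ravel(),
        method="Nelder-Mead",
        options={"maxiter": 60000, "xatol": 1e-10, "fatol": 1e-12, "adaptive": True},
    )
    return res.x.reshape(shape)


def prox_l21_numeric(g: np.ndarray, tau: float) -> np.ndarray:
    """Columnwise 1-D minimization over the scale factor alpha >= 0.

    By rotational symmetry the minimizer of tau*||e|| + 0.5*||e - g_i||^2
    is collinear with g_i, so each column reduces to a scalar problem in
    the scale alpha of e = alpha * g_i.
    """
    out = np.zeros_like(g, dtype=float)
    for i in range(g.shape[1]):
        gi = g[:, i]
        nrm = np.linalg.norm(gi)
        if nrm == 0:
            continue
        res = minimize_scalar(
            lambda al: tau * al * nrm + 0.5 * (al - 1.0) ** 2 * nrm**2,
            bounds=(0.0, 2.0),
            method="bounded",
            options={"xatol": 1e-13},
        )
        out[:, i] = res.x * gi
    return out


def random_orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


# ---------------------------------------------------------------------------
# brute-force metric oracles
# ---------------------------------------------------------------------------


def accuracy_by_permutation(truth: np.ndarray, pred: np.ndarray) -> float:
    """Max agreement over all permutations of predicted labels (percent)."""
    from itertools import permutations

    t_vals = np.unique(truth)
    p_vals = np.unique(pred)
    best = 0
    # pad the smaller label set so every permutation is a full matching
    k = max(len(t_vals), len(p_vals))
    t_pad = list(t_vals) + [None] * (k - len(t_vals))
    for perm in permutations(t_pad, len(p_vals)):
        mapping = dict(zip(p_vals, perm))
        mapped = np.array([mapping[p] for p in pred], dtype=object)
        best = max(best, int(np.sum(mapped == truth.astype(object))))
    return 100.0 * best / truth.size


def pair_counts_loop(truth: np.ndarray, pred: np.ndarray) -> dict:
    """O(N^2) enumeration of all sample pairs."""
    n = truth.size
    a = b = fp = fn = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_t = truth[i] == truth[j]
            same_p = pred[i] == pred[j]
            if same_t and same_p:
                a += 1
            elif not same_t and not same_p:
                b += 1
            elif same_p:
                fp += 1
            else:
                fn += 1
    return {"a": a, "b": b, "TP": a, "FP": fp, "FN": fn, "total": n * (n - 1) // 2}


# ---------------------------------------------------------------------------
# independent single-view solver
# ---------------------------------------------------------------------------


def single_view_lrr(
    x: np.ndarray,
    lap: np.ndarray,
    gamma1: float,
    gamma2: float,
    gamma3: float,
    mu0: float = 1e-2,
    mu_max: float = 1e6,
    rho: float = 1.1,
    tol: float = 1e-6,
    max_iter: int = 500,
    w_damping: float = 1.0,
) -> np.ndarray:
    """Flat LADMAP for the one-view model
    min ||Z||_* + g1 ||Z||_1 + g2 ||E||_{2,1} + g3 tr(Z L Z^T)
    s.t. X = X W Z + E, W^T W = I, written directly from the update
    equations with scipy SVDs (no mmclrr imports).  The dictionary step
    uses the same spectrally shifted inertial Procrustes rule as the
    package (the exact polar factor is discontinuous at the low-rank
    solutions this model produces, so undamped trajectories are not
    reproducible across backends).
    """
    m, n = x.shape
    z = za = zb = zc = h = np.zeros((n, n))
    w = np.eye(n)
    e = np.zeros((m, n))
    y1 = np.zeros((m, n))
    y2 = y3 = y4 = y5 = np.zeros((n, n))
    mu = mu0
    lap_2 = np.linalg.norm(lap, 2)
    x_2sq = np.linalg.norm(x, 2) ** 2
    xtx = x.T @ x
    x_nrm = np.linalg.norm(x)

    for _ in range(max_iter):
        # Z
        z = np.linalg.solve(
            mu * w.T @ w + 3 * mu * np.eye(n),
            mu * w.T @ h + mu * (za + zb + zc) + w.T @ y2 - y3 - y4 - y5,
        )
        # Z_A: linearized step + SVT
        grad = gamma3 * (za @ lap.T + za @ lap) + mu * (za - z - y3 / mu)
        eta = 2 * gamma3 * lap_2 + mu * (1 + x_2sq)
        tgt = za - grad / eta
        u, s, vt = scipy.linalg.svd(tgt, full_matrices=False)
        s = np.maximum(s - 1.0 / eta, 0.0)
        za = (u * s) @ vt
        # Z_B: soft threshold
        tgt = z + y4 / mu
        zb = np.sign(tgt) * np.maximum(np.abs(tgt) - gamma1 / mu, 0.0)
        # Z_C: single view -> consistency term vanishes
        zc = z + y5 / mu
        # E: column shrinkage
        g = x - x @ h + y1 / mu
        nrm = np.linalg.norm(g, axis=0)
        scale = np.where(nrm > gamma2 / mu, (nrm - gamma2 / mu) / np.maximum(nrm, 1e-300), 0.0)
        e = g * scale
        # H
        h = np.linalg.solve(
            mu * xtx + mu * np.eye(n),
            mu * xtx - mu * x.T @ e + x.T @ y1 + mu * w @ z - y2,
        )
        # W: inertial Procrustes with spectral shift
        bmat = (h + y2 / mu) @ z.T
        if np.linalg.norm(bmat) >= 1e-12:
            shifted = w.T @ bmat + w_damping * np.linalg.norm(bmat, 2) * np.eye(n)
            u, _, vt = scipy.linalg.svd(shifted)
            w = w @ (u @ vt)
        # multipliers
        y1 = y1 + mu * (x - x @ h - e)
        y2 = y2 + mu * (h - w @ z)
        y3 = y3 + mu * (z - za)
        y4 = y4 + mu * (z - zb)
        y5 = y5 + mu * (z - zc)

        zs = max(1.0, np.linalg.norm(z))
        res = max(
            np.linalg.norm(x - x @ h - e) / x_nrm,
            np.linalg.norm(h - w @ z) / zs,
            np.linalg.norm(z - za) / zs,
            np.linalg.norm(z - zb) / zs,
            np.linalg.norm(z - zc) / zs,
        )
        if res < tol:
            break
        mu = min(rho * mu, mu_max)
    return z
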