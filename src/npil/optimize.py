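"""Non-negative L1-penalized least squares by a log-barrier interior-point method.

Solves  min ||A x - b||^2 + k . x   subject to  x >= 0
(for x >= 0 the L1 penalty k * ||x||_1 is the linear term k . x, so the
problem is a convex QP over the non-negative orthant).

The implementation follows the classical barrier scheme: minimize
``t * f(x) - sum(log x)`` by damped Newton steps, multiply ``t`` by a fixed
factor per stage, and stop once the duality-gap bound ``m / t`` (m = number
of constraints) falls below tolerance.  The quadratic part enters only
through callbacks, so structured problems (e.g. the banded calcium Hessian)
can supply O(T) Newton solves while small dense problems use a Cholesky
factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class BarrierInfo:
    converged: bool
    stages: int
    newton_steps: int
    gap_bound: float
    objective: float
    objective_history: list = field(default_factory=list)


def _barrier_nnls(
    Qmul,
    q: np.ndarray,
    k: np.ndarray,
    x0: np.ndarray,
    hess_solve,
    *,
    gap_tol: float = 1e-8,
    barrier_mult: float = 10.0,
    max_stages: int = 60,
    max_newton: int = 50,
) -> tuple[np.ndarray, BarrierInfo]:
    """Minimize ``x.Q x - 2 q.x + k.x`` over x > 0 by the barrier method.

    Parameters
    ----------
    Qmul : callable(x) -> Q @ x
    hess_solve : callable(x, t, rhs) -> solution of (2 t Q + diag(1/x^2)) d = rhs
    """
    m = q.size
    x = np.asarray(x0, dtype=float).copy()
    if np.any(x <= 0):
        raise ValueError("interior-point start must be strictly positive")

    def f(x):
        return float(x @ Qmul(x) - 2.0 * q @ x + k @ x)

    f0 = f(x)
    # start t so the initial gap bound is commensurate with the objective scale
    t = m / max(abs(f0), 1.0)
    total_newton = 0
    stages = 0
    tol_scale = max(abs(f0), 1.0)
    while stages < max_stages:
        stages += 1
        # Newton centering at this t
        for _ in range(max_newton):
            g = t * (2.0 * Qmul(x) - 2.0 * q + k) - 1.0 / x
            dx = hess_solve(x, t, -g)
            decrement = float(-g @ dx)
            if decrement <= 0:  # numerical loss of descent direction
                break
            total_newton += 1
            # keep strictly feasible
            neg = dx < 0
            step = 1.0
            if np.any(neg):
                step = min(1.0, 0.99 * np.min(-x[neg] / dx[neg]))
            phi0 = t * f(x) - np.sum(np.log(x))
            gdx = float(g @ dx)
            for _ in range(60):
                xn = x + step * dx
                if np.all(xn > 0):
                    phin = t * f(xn) - np.sum(np.log(xn))
                    if phin <= phi0 + 0.25 * step * gdx:
                        break
                step *= 0.5
            else:
                xn = x
            x = xn
            if decrement / 2.0 < 1e-10 * t * tol_scale + 1e-14:
                break
        gap = m / t
        if gap <= gap_tol * tol_scale:
            info = BarrierInfo(True, stages, total_newton, gap, f(x))
            return x, info
        t *= barrier_mult
    warnings.warn(
        "barrier method hit the stage limit before reaching the gap tolerance",
        ConvergenceWarning,
    )
    return x, BarrierInfo(False, stages, total_newton, m / t, f(x))


def nonneg_l1_least_squares(
    A: np.ndarray,
    b: np.ndarray,
    k: float | np.ndarray = 0.0,
    *,
    x0: np.ndarray | None = None,
    gap_tol: float = 1e-8,
    barrier_mult: float = 10.0,
    max_stages: int = 60,
    return_info: bool = False,
):
    """argmin ||A x - b||^2 + k ||x||_1  s.t.  x >= 0 (dense path).

    Deterministic for fixed inputs.  ``k`` may be a scalar or per-coefficient
    vector of penalty weights.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite entries in A or b")
    n = A.shape[1]
    kvec = np.broadcast_to(np.asarray(k, dtype=float), (n,)).copy()
    if np.any(kvec < 0):
        raise ValueError("penalty weights must be non-negative")
    Q = A.T @ A
    q = A.T @ b

    def Qmul(x):
        return Q @ x

    def hess_solve(x, t, rhs):
        H = 2.0 * t * Q + np.diag(1.0 / x**2)
        c, low = cho_factor(H, check_finite=False)
        return cho_solve((c, low), rhs, check_finite=False)

    if x0 is None:
        xls, *_ = np.linalg.lstsq(A, b, rcond=None)
        scale = max(float(np.max(np.abs(xls))), float(np.mean(np.abs(b))), 1e-6)
        x0 = np.clip(xls, 1e-3 * scale, None)
    x, info = _barrier_nnls(
        Qmul, q, kvec, x0, hess_solve,
        gap_tol=gap_tol, barrier_mult=barrier_mult, max_stages=max_stages,
    )
    info.objective += float(b @ b)
    if return_info:
        return x, info
    return x


def nnls_l1_objective(A: np.ndarray, b: np.ndarray, x: np.ndarray, k) -> float:
    r = A @ x - b
    kvec = np.broadcast_to(np.asarray(k, dtype=float), x.shape)
    return float(r @ r + kvec @ np.abs(x))
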