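"""Step II: joint intensity and smooth-background estimation.

Given the fine-grid support ``Omega`` from Step I, the temporal mean
frame ``ybar`` is explained as ``A x + b`` with the intensity ``x``
living on ``Omega`` and a smooth background ``b`` on the camera grid:

    min_{x, b}  1/2 ||ybar - A x - b||^2
                + mu ||grad_Omega x||^2 + beta ||grad b||^2
                + iota ( sum_i phi(x_i) + ||x_{off Omega}||^2 + sum_j phi(b_j) )

where ``phi`` is a one-sided quadratic penalizing negative entries and
``iota`` is chosen large so the soft penalties act as the constraints
``x >= 0``, ``x = 0`` off the support, ``b >= 0``.  The problem is
solved by alternate proximal-gradient minimization: the smooth parts
are handled by gradient steps (their Lipschitz constants do not involve
``iota``) and the ``iota``-weighted separable penalties by closed-form
proximal maps, so the large penalty weight does not slow convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .operators import ForwardOperator

__all__ = [
    "SupportGradient",
    "IntensitySolution",
    "build_support_gradient",
    "phi_penalty",
    "phi_gradient",
    "prox_intensity",
    "prox_background",
    "solve_intensity",
]


@dataclass
class SupportGradient:
    """Difference operator over 8-neighbor pairs restricted to a support."""

    support: np.ndarray = field(repr=False)
    pairs: np.ndarray = field(repr=False)  # (n_pairs, 2) flat indices, i < j
    matrix: sp.csr_matrix = field(repr=False)
    grid_size: int = 0

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


@dataclass
class IntensitySolution:
    """Result of Step II."""

    intensity: np.ndarray = field(repr=False)  # fine grid, flat
    background: np.ndarray = field(repr=False)  # coarse grid, flat
    mu: float = 0.0
    beta: float = 0.0
    iota: float = 0.0
    objective_trace: list = field(default_factory=list, repr=False)
    converged: bool = True


_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def build_support_gradient(support: np.ndarray, L: int) -> SupportGradient:
    """Isotropic difference operator over the 8-neighborhood within ``Omega``.

    Each unordered neighbor pair with both endpoints in the support
    contributes one difference, scaled by the inverse pixel distance
    (``1`` for axial, ``1/sqrt(2)`` for diagonal neighbors), so on the
    full grid the axial terms reproduce the standard forward-difference
    gradient energy and the diagonal terms complete the isotropic
    stencil.
    """
    support = np.asarray(support, dtype=int).ravel()
    if support.size == 0:
        raise ValueError("support is empty")
    mask = np.zeros(L * L, dtype=bool)
    mask[support] = True
    rr, cc = np.divmod(support, L)
    pairs = []
    weights = []
    for dr, dc in _NEIGHBORS8:
        if (dr, dc) < (0, 0) or (dr == 0 and dc < 0):
            continue  # each unordered pair once: keep (0,1),(1,-1),(1,0),(1,1)
        r2, c2 = rr + dr, cc + dc
        ok = (r2 >= 0) & (r2 < L) & (c2 >= 0) & (c2 < L)
        j = r2[ok] * L + c2[ok]
        i = support[ok]
        both = mask[j]
        i, j = i[both], j[both]
        pairs.append(np.column_stack([i, j]))
        weights.append(np.full(i.size, 1.0 / np.hypot(dr, dc)))
    pairs = np.concatenate(pairs, axis=0) if pairs else np.empty((0, 2), int)
    weights = np.concatenate(weights) if weights else np.empty(0)
    n_pairs = pairs.shape[0]
    rows = np.repeat(np.arange(n_pairs), 2)
    cols = pairs.ravel()
    vals = np.column_stack([-weights, weights]).ravel()
    D = sp.csr_matrix((vals, (rows, cols)), shape=(n_pairs, L * L))
    return SupportGradient(support=support, pairs=pairs, matrix=D, grid_size=L)


def coarse_gradient(M: int) -> sp.csr_matrix:
    """Standard 2-point forward-difference gradient, Neumann boundaries."""
    from .support import tv_operator

    return tv_operator(M)


def phi_penalty(v: np.ndarray) -> float:
    """One-sided quadratic: ``sum_t t^2`` over the negative entries."""
    v = np.asarray(v, dtype=float)
    neg = np.minimum(v, 0.0)
    return float(np.sum(neg * neg))


def phi_gradient(v: np.ndarray) -> np.ndarray:
    """Gradient of :func:`phi_penalty`: ``2 min(t, 0)`` elementwise."""
    return 2.0 * np.minimum(np.asarray(v, dtype=float), 0.0)


def prox_intensity(v: np.ndarray, step: float, iota: float, on_mask: np.ndarray) -> np.ndarray:
    """Prox of ``iota * (phi(u) + u^2 off-support)`` scaled by ``step``.

    Elementwise: on-support entries keep nonnegative values and shrink
    negative ones by ``1 / (1 + 2 step iota)``; off-support entries
    shrink by ``1 / (1 + 2 step iota)`` when nonnegative and by
    ``1 / (1 + 4 step iota)`` when negative (both penalties active).
    As ``iota -> inf`` this is the projection onto
    ``{u >= 0, u = 0 off the support}``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    v = np.asarray(v, dtype=float)
    on_mask = np.asarray(on_mask, dtype=bool)
    a = 2.0 * step * iota
    out = np.where(v >= 0, v, v / (1.0 + a))  # on-support rule
    off = ~on_mask
    out = np.where(off & (v >= 0), v / (1.0 + a), out)
    out = np.where(off & (v < 0), v / (1.0 + 2.0 * a), out)
    return out


def prox_background(v: np.ndarray, step: float, iota: float) -> np.ndarray:
    """Prox of ``iota * phi(u)``: shrink negative entries toward zero."""
    if step <= 0:
        raise ValueError("step must be positive")
    v = np.asarray(v, dtype=float)
    return np.where(v >= 0, v, v / (1.0 + 2.0 * step * iota))


def _power_norm(matvec, n: int, iters: int = 50, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(iters):
        w = matvec(v)
        lam = float(v @ w)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 1.0
        v = w / nw
    return lam * 1.02


def default_iota(ybar: np.ndarray) -> float:
    """Penalty weight making the soft constraints effectively hard."""
    return 1e5 * max(1.0, float(np.max(np.abs(ybar))))


def _fista(x0, smooth, prox, step, max_iter, tol):
    """Monotone FISTA: accelerated proximal gradient with restart on increase.

    ``smooth(x)`` returns ``(value, gradient)`` of the smooth part and
    ``prox(v, step)`` the proximal map of the nonsmooth part, whose value
    ``prox.value(x)`` completes the objective for the restart test.
    """
    x = np.asarray(x0, dtype=float).copy()
    z = x.copy()
    t = 1.0
    fx, _ = smooth(x)
    obj = fx + prox.value(x)
    for _ in range(max_iter):
        _, gz = smooth(z)
        x_new = prox(z - step * gz, step)
        f_new, _ = smooth(x_new)
        obj_new = f_new + prox.value(x_new)
        if obj_new > obj:  # restart momentum from the last monotone iterate
            t = 1.0
            z = x.copy()
            _, gz = smooth(z)
            x_new = prox(z - step * gz, step)
            f_new, _ = smooth(x_new)
            obj_new = f_new + prox.value(x_new)
            if obj_new > obj:  # cannot decrease further at this step size
                break
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        rel = abs(obj - obj_new) / max(abs(obj), 1e-30)
        x, t, obj = x_new, t_new, obj_new
        if rel < tol:
            break
    return x


class _SeparableProx:
    """Proximal map plus the value of the separable penalty it represents."""

    def __init__(self, prox_fn, value_fn):
        self._prox = prox_fn
        self._value = value_fn

    def __call__(self, v, step):
        return self._prox(v, step)

    def value(self, x):
        return self._value(x)


def solve_intensity(
    ybar: np.ndarray,
    support: np.ndarray,
    op: ForwardOperator,
    mu: float,
    beta: float = 100.0,
    iota: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 40,
    inner_iter: int = 1000,
    inner_tol: float = 1e-6,
) -> IntensitySolution:
    """Alternate proximal-gradient minimization of the Step-II objective.

    Parameters
    ----------
    ybar : array
        Temporal mean frame, ``M x M`` or flat ``M^2``.
    support : array of int
        Fine-grid support from Step I.
    mu, beta : float
        Smoothness weights for the on-support intensity and for the
        coarse-grid background.
    iota : float, optional
        Constraint-penalty weight; defaults to ``1e5 * max|ybar|``.
    max_iter : int
        Outer alternations; ``inner_iter`` caps each subproblem.
    """
    ybar = np.asarray(ybar, dtype=float).ravel()
    M = op.grid.coarse_size
    L = op.grid.fine_size
    if ybar.size != M * M:
        raise ValueError("ybar has wrong size")
    if mu < 0 or beta < 0:
        raise ValueError("mu and beta must be nonnegative")
    if iota is None:
        iota = default_iota(ybar)
    support = np.asarray(support, dtype=int).ravel()
    on_mask = np.zeros(L * L, dtype=bool)
    on_mask[support] = True

    if support.size == 0:
        # degenerate case: no emitters localized, only a background to fit
        D = sp.csr_matrix((0, L * L))
    else:
        D = build_support_gradient(support, L).matrix
    DtD = (D.T @ D).tocsr()
    Dc = coarse_gradient(M)
    DctDc = (Dc.T @ Dc).tocsr()
    A = op.matrix()

    lip_x = _power_norm(lambda v: A.T @ (A @ v) + 2.0 * mu * (DtD @ v), L * L)
    step_x = 1.0 / max(lip_x, 1e-12)
    lip_b = _power_norm(lambda v: v + 2.0 * beta * (DctDc @ v), M * M)
    step_b = 1.0 / max(lip_b, 1e-12)

    def objective(x, b):
        r = ybar - A @ x - b
        pen = iota * (phi_penalty(x) + float(x[~on_mask] @ x[~on_mask]) + phi_penalty(b))
        return (
            0.5 * float(r @ r)
            + mu * float((D @ x) @ (D @ x))
            + beta * float((Dc @ b) @ (Dc @ b))
            + pen
        )

    off_mask = ~on_mask

    def x_penalty(xv):
        return iota * (phi_penalty(xv) + float(xv[off_mask] @ xv[off_mask]))

    def b_penalty(bv):
        return iota * phi_penalty(bv)

    prox_x = _SeparableProx(
        lambda v, st: prox_intensity(v, st, iota, on_mask), x_penalty
    )
    prox_b = _SeparableProx(lambda v, st: prox_background(v, st, iota), b_penalty)

    x = np.zeros(L * L)
    b = np.full(M * M, float(ybar.min()))
    obj = objective(x, b)
    trace = [obj]
    converged = False
    for _ in range(max_iter):
        # x-subproblem: accelerated proximal gradient on the smooth part
        resid_b = ybar - b

        def smooth_x(xv):
            r = A @ xv - resid_b
            dx = DtD @ xv
            return 0.5 * float(r @ r) + mu * float(xv @ dx), A.T @ r + 2.0 * mu * dx

        x = _fista(x, smooth_x, prox_x, step_x, inner_iter, inner_tol)
        # b-subproblem
        resid_x = ybar - A @ x

        def smooth_b(bv):
            r = bv - resid_x
            db = DctDc @ bv
            return 0.5 * float(r @ r) + beta * float(bv @ db), r + 2.0 * beta * db

        b = _fista(b, smooth_b, prox_b, step_b, inner_iter, inner_tol)
        obj_new = objective(x, b)
        rel = abs(obj - obj_new) / max(abs(obj), 1e-30)
        obj = obj_new
        trace.append(obj)
        if rel < tol:
            converged = True
            break
    return IntensitySolution(
        intensity=x,
        background=b,
        mu=mu,
        beta=beta,
        iota=iota,
        objective_trace=trace,
        converged=converged,
    )
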