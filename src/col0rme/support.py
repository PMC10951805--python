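"""Step I: sparse support estimation in the covariance domain.

Solves, for a frame-stack covariance ``R_y``,

    min_{x >= 0, s >= 0}  F(x, s) + lambda R(x),
    F(x, s) = 1/2 || vec(R_y) - (A (.) A) x - s vec(I) ||^2,

by alternating a regularized solve in the fine-grid variance image ``x``
with the closed-form update of the noise variance ``s`` (the minimizer
of the quadratic fidelity in ``s`` is ``trace(R_y - A diag(x) A^T) / M^2``
projected onto ``s >= 0``).  The sparsity penalty ``R`` is one of

* CEL0 - continuous exact relaxation of the l0 penalty, minimized by
  iteratively reweighted l1 (IRL1) with FISTA inner solves;
* L1   - nonnegative l1, minimized by FISTA;
* TV   - isotropic total variation, minimized by a Condat-Vu
  primal-dual splitting (smooth fidelity handled by its gradient).

The support of the recovered variance image localizes the emitters on
the fine grid and is the input of the Step-II intensity estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .covariance import AcquisitionStack, EmpiricalCovariance, empirical_covariance
from .operators import ForwardOperator

__all__ = [
    "RegularizerSpec",
    "SupportSolution",
    "fidelity_value",
    "noise_variance_update",
    "prox_nonneg_l1",
    "cel0_penalty",
    "irl1_weights",
    "lambda_max",
    "solve_variance_l1",
    "solve_variance_cel0",
    "solve_variance_tv",
    "solve_support",
    "restarted_support",
    "extract_support",
]


@dataclass(frozen=True)
class RegularizerSpec:
    """Sparsity penalty choice with either an absolute or relative weight.

    Exactly one of ``lambda_value`` (absolute) and ``gamma_fraction``
    (fraction of ``lambda_max``) must be given.
    """

    kind: str  # "cel0" | "l1" | "tv"
    lambda_value: float | None = None
    gamma_fraction: float | None = None

    def __post_init__(self) -> None:
        kind = self.kind.lower()
        object.__setattr__(self, "kind", kind)
        if kind not in ("cel0", "l1", "tv"):
            raise ValueError("kind must be one of 'cel0', 'l1', 'tv'")
        if (self.lambda_value is None) == (self.gamma_fraction is None):
            raise ValueError("set exactly one of lambda_value / gamma_fraction")
        if self.lambda_value is not None and self.lambda_value < 0:
            raise ValueError("lambda_value must be nonnegative")
        if self.gamma_fraction is not None and not 0 < self.gamma_fraction <= 1:
            raise ValueError("gamma_fraction must lie in (0, 1]")


@dataclass
class SupportSolution:
    """Result of Step I."""

    variance_image: np.ndarray = field(repr=False)  # flat, length L^2
    noise_variance: float = 0.0
    support: np.ndarray = field(default=None, repr=False)  # sorted flat indices
    objective_trace: list = field(default_factory=list, repr=False)
    restarts_used: int = 0
    lambda_value: float = 0.0
    lambda_max: float = 0.0
    converged: bool = True
    n_frames: int | None = None

    @property
    def support_mask(self) -> np.ndarray:
        mask = np.zeros(self.variance_image.size, dtype=bool)
        mask[self.support] = True
        return mask


# --------------------------------------------------------------------------
# precomputed covariance-domain quantities shared by all Step-I solvers


class _StepIContext:
    """Dense precomputations for the covariance-domain fidelity.

    With ``K = A (.) A`` (self Khatri-Rao product), the fidelity only
    enters the iterations through ``G = K^T K = (A^T A)^{.2}``,
    ``c = K^T vec(R_y) = (a_i^T R_y a_i)_i`` and the column norms
    ``eta_i = ||k_i|| = ||a_i||^2``; all are formed once per problem.
    """

    def __init__(self, op: ForwardOperator, R: np.ndarray) -> None:
        self.op = op
        self.R = R
        A = op.matrix()
        self.G = op.gram_kr()
        self.c = ((A.T @ R) * A.T).sum(axis=1)  # a_i^T R a_i
        a_norms = np.linalg.norm(A, axis=0)
        self.eta = a_norms**2  # Khatri-Rao column norms
        self.M2 = op.grid.n_coarse
        self.tr_R = float(np.trace(R))
        self.ryry = float(np.sum(R * R))
        self._lip: float | None = None

    def fidelity(self, x: np.ndarray, s: float) -> float:
        quad = x @ (self.G @ x)
        return 0.5 * (
            self.ryry
            + quad
            + s * s * self.M2
            + 2.0 * s * (x @ self.eta)
            - 2.0 * (x @ self.c)
            - 2.0 * s * self.tr_R
        )

    def grad_x(self, x: np.ndarray, s: float) -> np.ndarray:
        return self.G @ x + s * self.eta - self.c

    def s_update(self, x: np.ndarray) -> float:
        return max(0.0, (self.tr_R - x @ self.eta) / self.M2)

    def lipschitz(self) -> float:
        """Largest eigenvalue of G by a seeded 50-step power iteration."""
        if self._lip is None:
            rng = np.random.default_rng(0)
            v = rng.standard_normal(self.G.shape[0])
            v /= np.linalg.norm(v)
            lam = 1.0
            for _ in range(50):
                w = self.G @ v
                lam = float(v @ w)
                nw = np.linalg.norm(w)
                if nw == 0:
                    return 1.0
                v = w / nw
            self._lip = lam * 1.02  # small safety margin
        return self._lip


def _as_covariance(data, op: ForwardOperator, ddof: int = 1):
    """Normalize the stack/covariance input; returns (R, T_or_None)."""
    if isinstance(data, EmpiricalCovariance):
        return data.matrix, data.n_frames
    if isinstance(data, AcquisitionStack) or (
        isinstance(data, np.ndarray) and data.ndim == 3
    ):
        cov = empirical_covariance(data, ddof=ddof)
        return cov.matrix, cov.n_frames
    R = np.asarray(data, dtype=float)
    n_c = op.grid.n_coarse
    if R.shape != (n_c, n_c):
        raise ValueError("expected a (T, M, M) stack or an M^2 x M^2 covariance")
    return R, None


# --------------------------------------------------------------------------
# public building blocks (matrix-free versions of the context quantities)


def fidelity_value(x, s: float, R_y: np.ndarray, op: ForwardOperator) -> float:
    """``1/2 || vec(R_y) - (A (.) A) x - s vec(I) ||^2``."""
    x = np.asarray(x, dtype=float).ravel()
    resid = R_y - op.covariance_forward(x) - s * np.eye(op.grid.n_coarse)
    return 0.5 * float(np.sum(resid * resid))


def noise_variance_update(x, R_y: np.ndarray, op: ForwardOperator) -> float:
    """Closed-form minimizer of the fidelity over ``s >= 0`` at fixed ``x``."""
    x = np.asarray(x, dtype=float).ravel()
    _, eta = op.column_norms()
    return max(0.0, (float(np.trace(R_y)) - x @ eta) / op.grid.n_coarse)


def prox_nonneg_l1(v: np.ndarray, threshold) -> np.ndarray:
    """Prox of ``t |u|`` restricted to ``u >= 0``: ``max(0, v - t)``.

    ``threshold`` may be a scalar or a per-entry weight vector.
    """
    threshold = np.asarray(threshold, dtype=float)
    if np.any(threshold < 0):
        raise ValueError("threshold must be nonnegative")
    return np.maximum(0.0, v - threshold)


def cel0_penalty(x, lambda_value: float, kr_norms: np.ndarray) -> float:
    """CEL0 penalty value.

    Per component, a concave quadratic rising from 0 that saturates at
    ``lambda`` for ``|x_i| >= sqrt(2 lambda) / eta_i`` (``eta_i`` the
    Khatri-Rao column norm), so that far from the origin it counts
    ``lambda`` per nonzero exactly like the l0 penalty.
    """
    x = np.abs(np.asarray(x, dtype=float).ravel())
    eta = np.asarray(kr_norms, dtype=float).ravel()
    if np.any(eta <= 0):
        raise ValueError("column norms must be positive")
    thresh = np.sqrt(2.0 * lambda_value) / eta
    inside = x <= thresh
    vals = np.full(x.shape, float(lambda_value))
    vals[inside] = lambda_value - 0.5 * eta[inside] ** 2 * (x[inside] - thresh[inside]) ** 2
    return float(np.maximum(vals, 0.0).sum())


def irl1_weights(x_current, lambda_value: float, kr_norms: np.ndarray) -> np.ndarray:
    """IRL1 majorization weights: slope of the CEL0 branch at ``|x_i|``.

    ``eta_i sqrt(2 lambda) - eta_i^2 |x_i|`` inside the quadratic branch,
    zero beyond the saturation point.
    """
    x = np.abs(np.asarray(x_current, dtype=float).ravel())
    eta = np.asarray(kr_norms, dtype=float).ravel()
    return np.maximum(0.0, eta * np.sqrt(2.0 * lambda_value) - eta**2 * x)


def lambda_max(R_y: np.ndarray, op: ForwardOperator, kind: str) -> float:
    """Smallest penalty weight for which ``x = 0`` solves Step I.

    With ``c_i = a_i^T R_y a_i`` (the fidelity gradient magnitude at the
    origin, ``s = 0``) and ``eta_i = ||a_i||^2``:

    * l1 (nonnegative):  ``max_i (c_i)_+``
    * CEL0:              ``max_i (c_i)_+^2 / (2 eta_i^2)``
    """
    kind = kind.lower()
    if kind not in ("cel0", "l1"):
        raise ValueError("lambda_max is defined for 'cel0' and 'l1' only")
    ctx = _StepIContext(op, np.asarray(R_y, dtype=float))
    c_pos = np.maximum(ctx.c, 0.0)
    if kind == "l1":
        return float(c_pos.max())
    return float((c_pos**2 / (2.0 * ctx.eta**2)).max())


# --------------------------------------------------------------------------
# solvers


def _fista_weighted_l1(
    ctx: _StepIContext,
    weights: np.ndarray,
    s: float,
    x0: np.ndarray,
    tol: float,
    max_iter: int,
):
    """FISTA for ``F(., s) + <w, .>`` over ``x >= 0`` with restart on increase."""
    step = 1.0 / ctx.lipschitz()
    x = x0.copy()
    z = x.copy()
    t = 1.0
    obj = ctx.fidelity(x, s) + float(weights @ x)
    converged = False
    for _ in range(max_iter):
        x_new = prox_nonneg_l1(z - step * ctx.grad_x(z, s), step * weights)
        obj_new = ctx.fidelity(x_new, s) + float(weights @ x_new)
        if obj_new > obj:  # restart momentum at the last good point
            t = 1.0
            z = x.copy()
            x_new = prox_nonneg_l1(z - step * ctx.grad_x(z, s), step * weights)
            obj_new = ctx.fidelity(x_new, s) + float(weights @ x_new)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        rel = abs(obj - obj_new) / max(abs(obj), 1e-30)
        x, t, obj = x_new, t_new, obj_new
        if rel < tol:
            converged = True
            break
    return x, obj, converged


def solve_variance_l1(
    R_y: np.ndarray,
    op: ForwardOperator,
    lambda_value: float,
    s_fixed: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    x0: np.ndarray | None = None,
):
    """Nonnegative-l1 solve of the ``x`` subproblem at fixed ``s`` (FISTA)."""
    if lambda_value <= 0:
        raise ValueError("lambda_value must be positive")
    ctx = R_y if isinstance(R_y, _StepIContext) else _StepIContext(op, np.asarray(R_y, float))
    if x0 is None:
        x0 = np.zeros(op.grid.n_fine)
    w = np.full(op.grid.n_fine, float(lambda_value))
    x, _, converged = _fista_weighted_l1(ctx, w, s_fixed, x0, tol, max_iter)
    return x, converged


def solve_variance_cel0(
    R_y: np.ndarray,
    op: ForwardOperator,
    lambda_value: float,
    s_fixed: float = 0.0,
    tol: float = 1e-6,
    outer_iters: int = 10,
    max_inner: int = 500,
    x0: np.ndarray | None = None,
):
    """CEL0 solve of the ``x`` subproblem by IRL1 with FISTA inner solves.

    The CEL0 objective is nonincreasing across outer iterations by the
    majorize-minimize construction (each weighted-l1 inner problem
    majorizes CEL0 at the current iterate up to a constant).
    """
    if lambda_value <= 0:
        raise ValueError("lambda_value must be positive")
    ctx = R_y if isinstance(R_y, _StepIContext) else _StepIContext(op, np.asarray(R_y, float))
    x = np.zeros(op.grid.n_fine) if x0 is None else x0.copy()
    converged = True

    def cel0_obj(xv):
        return ctx.fidelity(xv, s_fixed) + cel0_penalty(xv, lambda_value, ctx.eta)

    obj = cel0_obj(x)
    for _ in range(outer_iters):
        w = irl1_weights(x, lambda_value, ctx.eta)
        x_new, _, conv = _fista_weighted_l1(ctx, w, s_fixed, x, tol, max_inner)
        obj_new = cel0_obj(x_new)
        if obj_new > obj + 1e-9 * max(1.0, abs(obj)):
            break  # numerically stalled; keep the monotone iterate
        converged = conv
        rel = abs(obj - obj_new) / max(abs(obj), 1e-30)
        x, obj = x_new, obj_new
        if rel < tol:
            break
    return x, converged


def tv_operator(L: int) -> sp.csr_matrix:
    """Forward-difference gradient with Neumann boundaries on an L x L grid.

    Rows 0..L^2-1 are horizontal differences, rows L^2..2L^2-1 vertical;
    differences across the boundary are zero.
    """
    n = L * L
    idx = np.arange(n).reshape(L, L)
    rows, cols, vals = [], [], []
    # horizontal: x[r, c+1] - x[r, c]
    r0 = idx[:, :-1].ravel()
    rows += [r0, r0]
    cols += [idx[:, 1:].ravel(), idx[:, :-1].ravel()]
    vals += [np.ones(r0.size), -np.ones(r0.size)]
    # vertical: x[r+1, c] - x[r, c], offset by n
    r1 = idx[:-1, :].ravel() + n
    rows += [r1, r1]
    cols += [idx[1:, :].ravel(), idx[:-1, :].ravel()]
    vals += [np.ones(r1.size), -np.ones(r1.size)]
    D = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(2 * n, n),
    )
    return D


def tv_value(x: np.ndarray, L: int) -> float:
    """Isotropic discrete TV with one-sided differences and Neumann BCs."""
    D = tv_operator(L)
    g = (D @ np.asarray(x, dtype=float).ravel()).reshape(2, -1)
    return float(np.sqrt(g[0] ** 2 + g[1] ** 2).sum())


def solve_variance_tv(
    R_y: np.ndarray,
    op: ForwardOperator,
    lambda_value: float,
    s_fixed: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    x0: np.ndarray | None = None,
):
    """Isotropic-TV solve of the ``x`` subproblem (Condat-Vu primal-dual).

    The smooth fidelity enters through its gradient; the nonnegativity
    constraint is the primal prox and the TV dual ball projection is the
    dual prox.  Step sizes satisfy ``1/tau - sigma ||D||^2 >= Lf / 2``.
    """
    if lambda_value <= 0:
        raise ValueError("lambda_value must be positive")
    ctx = R_y if isinstance(R_y, _StepIContext) else _StepIContext(op, np.asarray(R_y, float))
    L = op.grid.fine_size
    n = L * L
    D = tv_operator(L)
    norm_D2 = 8.0  # ||D||^2 <= 8 for the forward-difference gradient
    Lf = ctx.lipschitz()
    sigma = 1.0 / np.sqrt(norm_D2)
    tau = 1.0 / (Lf / 2.0 + sigma * norm_D2)
    x = np.zeros(n) if x0 is None else x0.copy()
    y = np.zeros(2 * n)

    def objective(xv):
        return ctx.fidelity(xv, s_fixed) + lambda_value * tv_value(xv, L)

    obj = objective(x)
    best_x, best_obj = x.copy(), obj
    converged = False
    for _ in range(max_iter):
        x_new = np.maximum(0.0, x - tau * (ctx.grad_x(x, s_fixed) + D.T @ y))
        yb = y + sigma * (D @ (2.0 * x_new - x))
        g = yb.reshape(2, -1)
        mag = np.sqrt(g[0] ** 2 + g[1] ** 2)
        scale = np.maximum(1.0, mag / lambda_value)
        y = (g / scale).ravel()
        rel = np.linalg.norm(x_new - x) / max(np.linalg.norm(x), 1e-30)
        x = x_new
        obj = objective(x)
        if obj < best_obj:
            best_obj, best_x = obj, x.copy()
        if rel < tol:
            converged = True
            break
    return best_x, converged


def extract_support(x: np.ndarray, rel_threshold: float = 0.0) -> np.ndarray:
    """Indices with ``x_i > rel_threshold * max(x)`` (flat, sorted)."""
    x = np.asarray(x, dtype=float).ravel()
    if np.any(x < 0):
        x = np.maximum(x, 0.0)
    mx = x.max(initial=0.0)
    if mx <= 0:
        import warnings

        warnings.warn("variance image is identically zero; empty support", stacklevel=2)
        return np.array([], dtype=int)
    return np.flatnonzero(x > rel_threshold * mx)


def solve_support(
    data,
    op: ForwardOperator,
    reg: RegularizerSpec,
    tol: float = 1e-5,
    max_alt_iters: int = 20,
    inner_tol: float = 1e-6,
    max_inner: int = 500,
    x0: np.ndarray | None = None,
    ddof: int = 1,
) -> SupportSolution:
    """Alternate minimization in ``(x, s)`` (the Step-I algorithm).

    ``data`` may be a ``(T, M, M)`` stack, an :class:`AcquisitionStack`,
    an :class:`EmpiricalCovariance` or a dense ``M^2 x M^2`` covariance.
    Initialization is ``x = 0``, ``s = 0`` unless ``x0`` is given.
    """
    R, T = _as_covariance(data, op, ddof=ddof)
    ctx = _StepIContext(op, R)
    lam_max = lambda_max(R, op, reg.kind) if reg.kind != "tv" else 0.0
    if reg.lambda_value is not None:
        lam = reg.lambda_value
    else:
        if reg.kind == "tv":
            raise ValueError("gamma_fraction requires a CEL0 or l1 regularizer")
        lam = reg.gamma_fraction * lam_max

    def penalty(xv):
        if reg.kind == "cel0":
            return cel0_penalty(xv, lam, ctx.eta)
        if reg.kind == "l1":
            return lam * float(np.sum(xv))  # x >= 0
        return lam * tv_value(xv, op.grid.fine_size)

    x = np.zeros(op.grid.n_fine) if x0 is None else np.asarray(x0, float).ravel().copy()
    s = 0.0
    obj = ctx.fidelity(x, s) + penalty(x)
    trace = [obj]
    converged = True
    for _ in range(max_alt_iters):
        if reg.kind == "cel0":
            x_new, conv = solve_variance_cel0(
                ctx, op, lam, s_fixed=s, tol=inner_tol, max_inner=max_inner, x0=x
            )
        elif reg.kind == "l1":
            x_new, conv = solve_variance_l1(
                ctx, op, lam, s_fixed=s, tol=inner_tol, max_iter=max_inner, x0=x
            )
        else:
            x_new, conv = solve_variance_tv(
                ctx, op, lam, s_fixed=s, tol=inner_tol, max_iter=max_inner, x0=x
            )
        # monotone safeguard: keep the previous iterate if the inner solver
        # failed to decrease the joint objective (can happen for the
        # primal-dual TV iterations at loose tolerances)
        if ctx.fidelity(x_new, s) + penalty(x_new) <= trace[-1] + 1e-12 * max(1.0, abs(trace[-1])):
            x = x_new
            converged = conv
        s = ctx.s_update(x)
        obj = ctx.fidelity(x, s) + penalty(x)
        rel = abs(trace[-1] - obj) / max(abs(trace[-1]), 1e-30)
        trace.append(obj)
        if rel < tol:
            break
    thresh = 1e-2 if reg.kind == "tv" else 0.0
    sol = SupportSolution(
        variance_image=x,
        noise_variance=s,
        support=extract_support(x, thresh) if x.max(initial=0.0) > 0 else np.array([], int),
        objective_trace=trace,
        lambda_value=lam,
        lambda_max=lam_max,
        converged=converged,
        n_frames=T,
    )
    return sol


def _adjacent_pixels(support: np.ndarray, L: int) -> np.ndarray:
    """Fine pixels 8-adjacent to the support but not in it."""
    mask = np.zeros((L, L), dtype=bool)
    mask.flat[support] = True
    grown = mask.copy()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.zeros_like(mask)
            rs = slice(max(dr, 0), L + min(dr, 0))
            rd = slice(max(-dr, 0), L + min(-dr, 0))
            cs = slice(max(dc, 0), L + min(dc, 0))
            cd = slice(max(-dc, 0), L + min(-dc, 0))
            shifted[rd, cd] = mask[rs, cs]
            grown |= shifted
    ring = grown & ~mask
    return np.flatnonzero(ring.ravel())


def restarted_support(
    data,
    op: ForwardOperator,
    reg: RegularizerSpec,
    max_restarts: int = 10,
    **solve_kwargs,
) -> SupportSolution:
    """Algorithmic restarting for the nonconvex CEL0 penalty.

    Runs the alternate minimization repeatedly at a fixed ``lambda``,
    re-initializing each restart on the pixels adjacent to (but outside)
    the union support found so far, at magnitude equal to the mean of
    the current nonzero variances.  New local minimizers enrich the
    support; the final variance image is the elementwise maximum over
    restarts and the final support their union.  Stops when a restart
    adds no new pixels or after ``max_restarts`` runs.
    """
    if reg.kind != "cel0":
        raise ValueError("restarting is defined for the CEL0 regularizer")
    L = op.grid.fine_size
    R, T = _as_covariance(data, op)
    sol = solve_support(R, op, reg, **solve_kwargs)
    union = set(sol.support.tolist())
    x_acc = sol.variance_image.copy()
    trace = list(sol.objective_trace)
    restarts = 1
    reg_fixed = RegularizerSpec(kind="cel0", lambda_value=sol.lambda_value)
    while restarts < max_restarts:
        if len(union) == 0:
            break
        ring = _adjacent_pixels(np.fromiter(union, int), L)
        if ring.size == 0:
            break
        nz = x_acc[x_acc > 0]
        mag = float(nz.mean()) if nz.size else 0.0
        x0 = np.zeros(op.grid.n_fine)
        x0[ring] = mag
        sol_r = solve_support(R, op, reg_fixed, x0=x0, **solve_kwargs)
        new = set(sol_r.support.tolist()) - union
        x_acc = np.maximum(x_acc, sol_r.variance_image)
        trace += list(sol_r.objective_trace)
        restarts += 1
        if not new:
            break
        union |= new
    support = np.array(sorted(union), dtype=int)
    return SupportSolution(
        variance_image=x_acc,
        noise_variance=sol.noise_variance,
        support=support,
        objective_trace=trace,
        restarts_used=restarts,
        lambda_value=sol.lambda_value,
        lambda_max=sol.lambda_max,
        converged=sol.converged,
        n_frames=T,
    )
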