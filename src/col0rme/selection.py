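"""Automatic regularization-parameter selection.

Two strategies are provided:

* the support penalty weight ``lambda`` is set as a fraction ``gamma``
  of the closed-form ``lambda_max`` (smallest weight producing an empty
  support);
* the intensity smoothness weight ``mu`` is chosen by the discrepancy
  principle: the residual of the Step-II solution should match the
  expected energy of the noise on the temporal mean frame,
  ``E = nu * M^2 * s_hat / T`` for i.i.d. Gaussian noise of variance
  ``s_hat`` (estimated in Step I) averaged over ``T`` frames.  The
  scalar equation ``h(mu) = ||ybar - A x(mu) - b(mu)||^2 - E = 0`` is
  solved by safeguarded Newton iterations, with ``h'(mu)`` obtained by
  differentiating the Step-II optimality conditions: ``dx/dmu`` solves
  a quadratic auxiliary problem handled by the same proximal-gradient
  machinery as Step II itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intensity import (
    IntensitySolution,
    _SeparableProx,
    _fista,
    _power_norm,
    build_support_gradient,
    coarse_gradient,
    default_iota,
    solve_intensity,
)
from .operators import ForwardOperator

__all__ = [
    "DiscrepancyResult",
    "DiscrepancyBracketError",
    "expected_noise_energy",
    "discrepancy_h",
    "solution_derivative",
    "select_mu_newton",
    "lambda_from_gamma",
]


class DiscrepancyBracketError(RuntimeError):
    """No sign change of h(mu): the support cannot reach the noise level.

    Carries the sampled ``(mu, h)`` curve for diagnostics.
    """

    def __init__(self, trace):
        super().__init__(
            f"no sign change of h(mu) found; sampled curve: {trace}"
        )
        self.trace = list(trace)


@dataclass
class DiscrepancyResult:
    """Outcome of the discrepancy-principle search for ``mu``."""

    mu: float
    h_value: float
    target: float
    solution: IntensitySolution = field(repr=False)
    trace: list = field(default_factory=list, repr=False)  # (mu, h) pairs
    converged: bool = True


def expected_noise_energy(s_hat: float, T: int, M: int, nu: float = 1.0) -> float:
    """Expected squared norm of the temporal-mean noise, times ``nu``.

    For i.i.d. zero-mean Gaussian noise of variance ``s_hat`` per pixel,
    the mean over ``T`` frames has per-pixel variance ``s_hat / T`` and
    ``E ||eta_bar||^2 = M^2 s_hat / T``.  The safety factor ``nu``
    (default 1, appropriate when ``s_hat`` is precise) scales the
    discrepancy target.
    """
    if s_hat < 0:
        raise ValueError("s_hat must be nonnegative")
    if T < 1:
        raise ValueError("T must be positive")
    return nu * M * M * s_hat / T


def discrepancy_h(
    mu: float,
    ybar: np.ndarray,
    support: np.ndarray,
    op: ForwardOperator,
    beta: float,
    iota: float,
    E: float,
    **solve_kwargs,
):
    """``h(mu) = ||ybar - A x(mu) - b(mu)||^2 - E`` and the Step-II solution."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    sol = solve_intensity(ybar, support, op, mu=mu, beta=beta, iota=iota, **solve_kwargs)
    ybar = np.asarray(ybar, dtype=float).ravel()
    r = ybar - op.matrix() @ sol.intensity - sol.background
    h = float(r @ r) - E
    return h, sol


def solution_derivative(
    mu: float,
    sol: IntensitySolution,
    support: np.ndarray,
    op: ForwardOperator,
    iota: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> np.ndarray:
    """``dx/dmu`` of the Step-II intensity at a converged solution.

    Differentiating the stationarity condition of the (smoothly
    penalized) x-subproblem at fixed background gives the quadratic
    problem

        min_u 1/2 ||A u||^2 + mu ||D_Omega u||^2 + <z, u>
              + iota/2 u^T H u,
        z = 2 D_Omega^T D_Omega x(mu),

    where ``H`` collects the second derivatives of the active soft
    constraints (``2`` per active one-sided/off-support quadratic).  It
    is solved by proximal-gradient iterations with the ``iota`` term in
    the prox, mirroring the Step-II solver.
    """
    L = op.grid.fine_size
    x = sol.intensity
    iota = sol.iota if iota is None else iota
    support = np.asarray(support, dtype=int).ravel()
    on_mask = np.zeros(L * L, dtype=bool)
    on_mask[support] = True
    D = build_support_gradient(support, L).matrix
    DtD = (D.T @ D).tocsr()
    A = op.matrix()
    z = 2.0 * (DtD @ x)
    # active-set curvature of the iota-penalties at x(mu)
    H = 2.0 * ((~on_mask).astype(float) + (x < 0).astype(float))
    lip = _power_norm(lambda v: A.T @ (A @ v) + 2.0 * mu * (DtD @ v), L * L, seed=1)
    step = 1.0 / max(lip, 1e-12)

    def smooth(u):
        r = A @ u
        du = DtD @ u
        val = 0.5 * float(r @ r) + mu * float(u @ du) + float(z @ u)
        return val, A.T @ r + 2.0 * mu * du + z

    prox = _SeparableProx(
        lambda v, st: v / (1.0 + st * iota * H),
        lambda u: 0.5 * iota * float((H * u) @ u),
    )
    return _fista(np.zeros(L * L), smooth, prox, step, max_iter, tol)


def select_mu_newton(
    ybar: np.ndarray,
    support: np.ndarray,
    op: ForwardOperator,
    s_hat: float,
    T: int,
    beta: float = 100.0,
    iota: float | None = None,
    nu: float = 1.0,
    mu0: float | None = None,
    tol: float = 1e-3,
    max_iter: int = 30,
    **solve_kwargs,
) -> DiscrepancyResult:
    """Discrepancy-principle choice of ``mu`` by safeguarded Newton.

    Newton steps on ``h(mu) = 0`` use ``h'(mu) = -2 r^T A dx/dmu`` with
    ``dx/dmu`` from :func:`solution_derivative`; whenever a step leaves
    the current sign-change bracket (established by a log-spaced scan)
    or fails to reduce ``|h|``, a bisection step is taken instead.
    Stops at ``|h(mu)| <= tol * E``.
    """
    ybar = np.asarray(ybar, dtype=float).ravel()
    M = op.grid.coarse_size
    E = expected_noise_energy(s_hat, T, M, nu)
    if E <= 0:
        raise ValueError("discrepancy target is zero; no noise to match")
    if iota is None:
        iota = default_iota(ybar)
    if mu0 is None:
        mu0 = max(E / max(float(ybar @ ybar), 1e-30), 1e-8)

    A = op.matrix()
    trace: list = []

    def h_at(mu):
        h, sol = discrepancy_h(mu, ybar, support, op, beta, iota, E, **solve_kwargs)
        trace.append((mu, h))
        return h, sol

    h0, sol0 = h_at(mu0)
    if abs(h0) <= tol * E:
        return DiscrepancyResult(mu0, h0, E, sol0, trace)
    # establish a bracket with a log-spaced scan around mu0 (h nondecreasing
    # in mu: larger smoothing -> larger residual); scan the monotone
    # direction first, then the other side if mu0 was badly placed
    lo, hi = None, None
    h_lo = h_hi = None
    if h0 < 0:
        lo, h_lo = mu0, h0
    else:
        hi, h_hi = mu0, h0
    direction = 1.0 if h0 < 0 else -1.0
    for direc in (direction, -direction):
        for k in range(1, 13):
            if lo is not None and hi is not None:
                break
            mu_try = mu0 * 10.0 ** (direc * k)
            h_try, sol_try = h_at(mu_try)
            if abs(h_try) <= tol * E:
                return DiscrepancyResult(mu_try, h_try, E, sol_try, trace)
            if h_try < 0:
                if lo is None or mu_try > lo:
                    lo, h_lo = mu_try, h_try
            else:
                if hi is None or mu_try < hi:
                    hi, h_hi = mu_try, h_try
        if lo is not None and hi is not None:
            break
    if lo is None or hi is None:
        raise DiscrepancyBracketError(trace)

    mu, h, sol = (lo, h_lo, None) if abs(h_lo) < abs(h_hi) else (hi, h_hi, None)
    if sol is None:
        _, sol = discrepancy_h(mu, ybar, support, op, beta, iota, E, **solve_kwargs)
    converged = False
    for _ in range(max_iter):
        if abs(h) <= tol * E:
            converged = True
            break
        dx = solution_derivative(mu, sol, support, op, iota=iota)
        r = ybar - A @ sol.intensity - sol.background
        hp = -2.0 * float(r @ (A @ dx))
        mu_newton = mu - h / hp if hp != 0 else -1.0
        if not (lo < mu_newton < hi):
            mu_newton = np.sqrt(lo * hi)  # geometric bisection
        h_new, sol_new = h_at(mu_newton)
        if abs(h_new) > abs(h):  # Newton failed to improve: bisect
            mu_newton = np.sqrt(lo * hi)
            h_new, sol_new = h_at(mu_newton)
        mu, h, sol = mu_newton, h_new, sol_new
        if h < 0:
            lo = mu
        else:
            hi = mu
    return DiscrepancyResult(mu, h, E, sol, trace, converged=converged)


def lambda_from_gamma(gamma: float, lam_max: float) -> float:
    """``lambda = gamma * lambda_max`` for ``gamma`` in ``(0, 1]``."""
    if not 0 < gamma <= 1:
        raise ValueError("gamma must lie in (0, 1]")
    return gamma * lam_max
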