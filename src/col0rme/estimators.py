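"""scikit-learn style estimators wrapping the two-step reconstruction.

The method is fit-shaped: a frame stack goes in, a super-resolved
intensity image (plus support, noise variance and background) comes
out.  :class:`SupportEstimator` performs Step I, :class:`IntensityEstimator`
Step II on a given support, and :class:`Col0rme` chains the two.  All
follow the scikit-learn conventions (constructor parameters, ``fit``,
trailing-underscore fitted attributes, ``get_params`` / ``set_params``),
so they compose with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .covariance import AcquisitionStack, empirical_covariance, temporal_mean
from .grid import GridSpec, gaussian_psf_kernel
from .intensity import default_iota, solve_intensity
from .operators import ForwardOperator
from .selection import DiscrepancyBracketError, select_mu_newton
from .support import RegularizerSpec, restarted_support, solve_support

__all__ = ["SupportEstimator", "IntensityEstimator", "Col0rme"]


def _stack_frames(X) -> np.ndarray:
    frames = X.frames if isinstance(X, AcquisitionStack) else np.asarray(X, dtype=float)
    if frames.ndim != 3 or frames.shape[1] != frames.shape[2]:
        raise ValueError("X must be a (T, M, M) frame stack")
    return frames


def _build_operator(M: int, q: int, fwhm_nm: float, pixel_size_nm: float, boundary: str):
    grid = GridSpec(M, q, pixel_size_nm)
    psf = gaussian_psf_kernel(fwhm_nm, grid.fine_pitch_nm)
    return ForwardOperator(grid, psf=psf, boundary=boundary)


class SupportEstimator(BaseEstimator):
    """Step I: covariance-domain sparse support and noise-variance fit.

    Parameters
    ----------
    regularizer : {"cel0", "l1", "tv"}
        Sparsity penalty on the fine-grid variance image.
    gamma : float
        Penalty weight as a fraction of ``lambda_max`` (ignored when
        ``lambda_value`` is set; not available for TV).
    lambda_value : float, optional
        Absolute penalty weight.
    q : int
        Super-resolution factor.
    fwhm_nm, pixel_size_nm : float
        Gaussian PSF width and camera pixel pitch.
    restarts : int
        Algorithmic restarts (CEL0 only); 1 disables restarting.
    """

    def __init__(
        self,
        regularizer: str = "cel0",
        gamma: float = 0.1,
        lambda_value: float | None = None,
        q: int = 4,
        fwhm_nm: float = 229.0,
        pixel_size_nm: float = 100.0,
        boundary: str = "reflect",
        restarts: int = 1,
        tol: float = 1e-5,
        max_alt_iters: int = 20,
        inner_tol: float = 1e-6,
        max_inner: int = 500,
        ddof: int = 1,
    ) -> None:
        self.regularizer = regularizer
        self.gamma = gamma
        self.lambda_value = lambda_value
        self.q = q
        self.fwhm_nm = fwhm_nm
        self.pixel_size_nm = pixel_size_nm
        self.boundary = boundary
        self.restarts = restarts
        self.tol = tol
        self.max_alt_iters = max_alt_iters
        self.inner_tol = inner_tol
        self.max_inner = max_inner
        self.ddof = ddof

    def fit(self, X, y=None):
        frames = _stack_frames(X)
        M = frames.shape[1]
        op = _build_operator(M, self.q, self.fwhm_nm, self.pixel_size_nm, self.boundary)
        if self.lambda_value is not None:
            reg = RegularizerSpec(self.regularizer, lambda_value=self.lambda_value)
        else:
            if self.regularizer == "tv":
                raise ValueError("TV requires an explicit lambda_value")
            reg = RegularizerSpec(self.regularizer, gamma_fraction=self.gamma)
        cov = empirical_covariance(frames, ddof=self.ddof)
        kwargs = dict(
            tol=self.tol,
            max_alt_iters=self.max_alt_iters,
            inner_tol=self.inner_tol,
            max_inner=self.max_inner,
        )
        if self.restarts > 1 and reg.kind == "cel0":
            sol = restarted_support(cov, op, reg, max_restarts=self.restarts, **kwargs)
        else:
            sol = solve_support(cov, op, reg, **kwargs)
        L = op.grid.fine_size
        self.operator_ = op
        self.solution_ = sol
        self.variance_image_ = sol.variance_image.reshape(L, L)
        self.noise_variance_ = sol.noise_variance
        self.support_ = sol.support
        self.lambda_ = sol.lambda_value
        self.lambda_max_ = sol.lambda_max
        self.objective_trace_ = sol.objective_trace
        self.n_frames_ = frames.shape[0]
        self.mean_frame_ = frames.mean(axis=0)
        return self

    def transform(self, X=None):
        """Return the fitted fine-grid variance image."""
        return self.variance_image_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()


class IntensityEstimator(BaseEstimator):
    """Step II: intensity and smooth background on a known support.

    ``mu="auto"`` selects the intensity smoothness weight by the
    discrepancy principle (requires the Step-I noise variance and the
    number of frames, passed to :meth:`fit`).
    """

    def __init__(
        self,
        mu: float | str = "auto",
        beta: float = 100.0,
        iota: float | None = None,
        nu: float = 1.0,
        tol: float = 1e-6,
        max_iter: int = 40,
        inner_iter: int = 1000,
    ) -> None:
        self.mu = mu
        self.beta = beta
        self.iota = iota
        self.nu = nu
        self.tol = tol
        self.max_iter = max_iter
        self.inner_iter = inner_iter

    def fit(self, X, y=None, *, support, operator, noise_variance=None, n_frames=None):
        frames = _stack_frames(X)
        ybar = temporal_mean(frames)
        iota = self.iota if self.iota is not None else default_iota(ybar)
        if self.mu == "auto":
            if noise_variance is None or n_frames is None:
                raise ValueError("mu='auto' needs noise_variance and n_frames")
            try:
                res = select_mu_newton(
                    ybar,
                    support,
                    operator,
                    s_hat=noise_variance,
                    T=n_frames,
                    beta=self.beta,
                    iota=iota,
                    nu=self.nu,
                    tol=1e-3,
                    max_iter=self.max_iter,
                    inner_iter=self.inner_iter,
                )
                sol = res.solution
                self.discrepancy_ = res
            except DiscrepancyBracketError as err:
                # the support cannot reach the noise level: fall back to the
                # sampled mu with the smallest |h| (least-misfit compromise)
                mu_fb = min(err.trace, key=lambda mh: abs(mh[1]))[0]
                sol = solve_intensity(
                    ybar, support, operator, mu=mu_fb, beta=self.beta,
                    iota=iota, tol=self.tol, max_iter=self.max_iter,
                    inner_iter=self.inner_iter,
                )
                self.discrepancy_ = None
        else:
            sol = solve_intensity(
                ybar,
                support,
                operator,
                mu=float(self.mu),
                beta=self.beta,
                iota=iota,
                tol=self.tol,
                max_iter=self.max_iter,
                inner_iter=self.inner_iter,
            )
        L = operator.grid.fine_size
        M = operator.grid.coarse_size
        self.solution_ = sol
        self.intensity_image_ = sol.intensity.reshape(L, L)
        self.background_ = sol.background.reshape(M, M)
        self.mu_ = sol.mu
        self.objective_trace_ = sol.objective_trace
        return self


class Col0rme(BaseEstimator):
    """Full two-step reconstruction: support then intensity/background.

    Examples
    --------
    >>> model = Col0rme(regularizer="cel0", gamma=0.1, q=4, mu=1.0)
    >>> model.fit(stack)                          # doctest: +SKIP
    >>> model.intensity_image_                    # doctest: +SKIP
    """

    def __init__(
        self,
        regularizer: str = "cel0",
        gamma: float = 0.1,
        lambda_value: float | None = None,
        q: int = 4,
        fwhm_nm: float = 229.0,
        pixel_size_nm: float = 100.0,
        boundary: str = "reflect",
        restarts: int = 1,
        mu: float | str = "auto",
        beta: float = 100.0,
        iota: float | None = None,
        nu: float = 1.0,
        tol: float = 1e-5,
    ) -> None:
        self.regularizer = regularizer
        self.gamma = gamma
        self.lambda_value = lambda_value
        self.q = q
        self.fwhm_nm = fwhm_nm
        self.pixel_size_nm = pixel_size_nm
        self.boundary = boundary
        self.restarts = restarts
        self.mu = mu
        self.beta = beta
        self.iota = iota
        self.nu = nu
        self.tol = tol

    def fit(self, X, y=None):
        step1 = SupportEstimator(
            regularizer=self.regularizer,
            gamma=self.gamma,
            lambda_value=self.lambda_value,
            q=self.q,
            fwhm_nm=self.fwhm_nm,
            pixel_size_nm=self.pixel_size_nm,
            boundary=self.boundary,
            restarts=self.restarts,
            tol=self.tol,
        ).fit(X)
        step2 = IntensityEstimator(
            mu=self.mu, beta=self.beta, iota=self.iota, nu=self.nu
        ).fit(
            X,
            support=step1.support_,
            operator=step1.operator_,
            noise_variance=step1.noise_variance_,
            n_frames=step1.n_frames_,
        )
        self.support_estimator_ = step1
        self.intensity_estimator_ = step2
        self.operator_ = step1.operator_
        self.support_ = step1.support_
        self.variance_image_ = step1.variance_image_
        self.noise_variance_ = step1.noise_variance_
        self.lambda_ = step1.lambda_
        self.lambda_max_ = step1.lambda_max_
        self.intensity_image_ = step2.intensity_image_
        self.background_ = step2.background_
        self.mu_ = step2.mu_
        return self

    def transform(self, X=None):
        """Return the fitted fine-grid intensity image."""
        return self.intensity_image_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()
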