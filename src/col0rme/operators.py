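"""Acquisition operators and their covariance-domain counterparts.

The camera model is ``y = S(Psi(x)) + b + noise`` where ``Psi`` is
convolution with the PSF on the fine grid and ``S`` sums every ``q x q``
block of fine pixels into one camera pixel, so ``A = S o Psi`` maps the
``L x L`` fine grid to the ``M x M`` camera grid.

Working with second-order statistics of the frames requires the induced
covariance-domain operator ``x -> A diag(x) A^T`` (equivalently the self
Khatri-Rao product ``A (.) A`` acting on the vectorized variance image)
and its adjoint ``R -> (a_i^T R a_i)_i``.  Both are provided matrix-free
(impulse-response convolutions); solvers additionally cache a dense ``A``
and the Gram matrix ``(A^T A)^{.2}`` behind size guards, because every
quantity the covariance-domain iterations touch is at least as large as
``A`` itself.

Vectorization is row-major (C order) throughout: fine pixel ``(r, c)``
maps to index ``r * L + c``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import fftconvolve

from .grid import GridSpec, PSFModel, gaussian_psf_kernel

__all__ = [
    "ForwardOperator",
    "downsample_sum",
    "downsample_adjoint",
    "covariance_forward",
    "covariance_adjoint",
    "column_norms",
]

# largest fine-grid pixel count for which a dense A (M^2 x L^2) is cached
_MAX_DENSE_FINE = 16384
# largest fine-grid pixel count for which the L^2 x L^2 Gram is formed
_MAX_GRAM_FINE = 8200


def downsample_sum(fine_image: np.ndarray, q: int) -> np.ndarray:
    """Sum every ``q x q`` block of fine pixels (flux-conserving binning)."""
    fine_image = np.asarray(fine_image)
    if fine_image.ndim != 2:
        raise ValueError("expected a 2-D image")
    L0, L1 = fine_image.shape
    if L0 % q or L1 % q:
        raise ValueError(f"image shape {fine_image.shape} not divisible by q={q}")
    return fine_image.reshape(L0 // q, q, L1 // q, q).sum(axis=(1, 3))


def downsample_adjoint(coarse_image: np.ndarray, q: int) -> np.ndarray:
    """Adjoint of :func:`downsample_sum`: replicate each value into its block."""
    coarse_image = np.asarray(coarse_image)
    if coarse_image.ndim != 2:
        raise ValueError("expected a 2-D image")
    return np.repeat(np.repeat(coarse_image, q, axis=0), q, axis=1)


def _fold2(padded: np.ndarray, h: int) -> np.ndarray:
    """Exact adjoint of 2-D symmetric (Neumann) padding by ``h`` per side."""
    q0 = padded[h:-h, :].copy()
    q0[:h, :] += padded[:h, :][::-1, :]
    q0[-h:, :] += padded[-h:, :][::-1, :]
    out = q0[:, h:-h].copy()
    out[:, :h] += q0[:, :h][:, ::-1]
    out[:, -h:] += q0[:, -h:][:, ::-1]
    return out


class ForwardOperator:
    """Linear acquisition operator ``A = S o Psi`` with exact adjoints.

    Parameters
    ----------
    grid : GridSpec
        Coarse/fine grid geometry.
    psf : PSFModel, optional
        Sampled PSF; built from ``fwhm_nm`` if omitted.
    fwhm_nm : float, optional
        Gaussian PSF FWHM in nm (used when ``psf`` is None).
    boundary : {"reflect", "periodic"}
        Convolution boundary handling.  Reflective (Neumann) is the
        default; with periodic boundaries all columns of ``A`` are
        translates of one another, so the column norms degenerate to a
        constant.
    """

    def __init__(
        self,
        grid: GridSpec,
        psf: PSFModel | None = None,
        fwhm_nm: float | None = None,
        boundary: str = "reflect",
    ) -> None:
        if psf is None:
            if fwhm_nm is None:
                raise ValueError("provide either psf or fwhm_nm")
            psf = gaussian_psf_kernel(fwhm_nm, grid.fine_pitch_nm)
        if boundary not in ("reflect", "periodic"):
            raise ValueError("boundary must be 'reflect' or 'periodic'")
        L = grid.fine_size
        kernel = np.asarray(psf.kernel, dtype=float)
        max_side = 2 * L - 1 if boundary == "reflect" else L
        if kernel.shape[0] > max_side:
            # crop an oversized kernel to the largest usable support
            side = max_side if max_side % 2 == 1 else max_side - 1
            c = kernel.shape[0] // 2
            half = side // 2
            kernel = kernel[c - half : c + half + 1, c - half : c + half + 1]
            kernel = kernel / kernel.sum()
            psf = PSFModel(psf.fwhm_nm, psf.fine_pitch_nm, kernel)
        self.grid = grid
        self.psf = psf
        self.boundary = boundary
        self._kernel = kernel
        self._half = kernel.shape[0] // 2
        self._matrix: np.ndarray | None = None
        self._gram_kr: np.ndarray | None = None
        if boundary == "periodic":
            k = np.zeros((L, L))
            side = kernel.shape[0]
            k[:side, :side] = kernel
            k = np.roll(k, (-self._half, -self._half), axis=(0, 1))
            self._khat = np.fft.rfft2(k)

    # ---------------------------------------------------------------- PSF

    def psf_convolve(self, x: np.ndarray) -> np.ndarray:
        """Apply ``Psi`` (PSF convolution) on the fine grid."""
        if self.boundary == "periodic":
            return np.fft.irfft2(np.fft.rfft2(x) * self._khat, s=x.shape)
        h = self._half
        if h == 0:
            return x * self._kernel[0, 0]
        padded = np.pad(x, h, mode="symmetric")
        return fftconvolve(padded, self._kernel, mode="valid")

    def psf_adjoint(self, y: np.ndarray) -> np.ndarray:
        """Apply ``Psi^T`` exactly (fold-back of the symmetric padding)."""
        if self.boundary == "periodic":
            return np.fft.irfft2(np.fft.rfft2(y) * np.conj(self._khat), s=y.shape)
        h = self._half
        if h == 0:
            return y * self._kernel[0, 0]
        full = fftconvolve(y, self._kernel[::-1, ::-1], mode="full")
        return _fold2(full, h)

    # ------------------------------------------------------------ forward

    def apply(self, x: np.ndarray) -> np.ndarray:
        """``A x``: convolve with the PSF then block-sum to the camera grid."""
        x = self._as_fine(x)
        return downsample_sum(self.psf_convolve(x), self.grid.factor)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """``A^T y``: replicate camera pixels then apply ``Psi^T``."""
        y = self._as_coarse(y)
        return self.psf_adjoint(downsample_adjoint(y, self.grid.factor))

    def apply_vec(self, x: np.ndarray) -> np.ndarray:
        L = self.grid.fine_size
        return self.apply(np.asarray(x, dtype=float).reshape(L, L)).ravel()

    def adjoint_vec(self, y: np.ndarray) -> np.ndarray:
        M = self.grid.coarse_size
        return self.adjoint(np.asarray(y, dtype=float).reshape(M, M)).ravel()

    def _as_fine(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        L = self.grid.fine_size
        if x.shape != (L, L):
            raise ValueError(f"expected fine image of shape {(L, L)}, got {x.shape}")
        return x

    def _as_coarse(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        M = self.grid.coarse_size
        if y.shape != (M, M):
            raise ValueError(f"expected coarse image of shape {(M, M)}, got {y.shape}")
        return y

    # ----------------------------------------------------- dense caches

    def matrix(self) -> np.ndarray:
        """Dense ``A`` (``M^2 x L^2``), cached; rows built as ``A^T e_c``."""
        if self._matrix is None:
            n = self.grid.n_fine
            if n > _MAX_DENSE_FINE:
                raise ValueError(
                    f"fine grid has {n} pixels; dense A is limited to "
                    f"{_MAX_DENSE_FINE} fine pixels (crop or tile the input)"
                )
            M = self.grid.coarse_size
            rows = np.empty((self.grid.n_coarse, n))
            e = np.zeros((M, M))
            for c in range(self.grid.n_coarse):
                e.flat[c] = 1.0
                rows[c] = self.adjoint(e).ravel()
                e.flat[c] = 0.0
            self._matrix = rows
        return self._matrix

    def gram_kr(self) -> np.ndarray:
        """Gram of the self Khatri-Rao operator: ``(A^T A)`` squared elementwise."""
        if self._gram_kr is None:
            if self.grid.n_fine > _MAX_GRAM_FINE:
                raise ValueError(
                    "fine grid too large for the dense covariance-domain Gram; "
                    "crop or tile the input"
                )
            A = self.matrix()
            G = A.T @ A
            self._gram_kr = G**2
        return self._gram_kr

    # ------------------------------------------------- covariance domain

    def covariance_forward(self, x: np.ndarray) -> np.ndarray:
        """``A diag(x) A^T`` as a dense ``M^2 x M^2`` matrix (matrix-free).

        Column ``d`` is computed as ``A (x .* A^T e_d)``; ``A`` is never
        materialized.  ``x`` may be an ``L x L`` image or a flat vector.
        """
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.grid.n_fine:
            raise ValueError("variance image has wrong size")
        if x.size and x.min() < -1e-12 * max(1.0, float(np.abs(x).max())):
            warnings.warn("negative entries in variance image", stacklevel=2)
        M = self.grid.coarse_size
        n_c = self.grid.n_coarse
        R = np.empty((n_c, n_c))
        e = np.zeros((M, M))
        for d in range(n_c):
            e.flat[d] = 1.0
            R[:, d] = self.apply_vec(x * self.adjoint(e).ravel())
            e.flat[d] = 0.0
        return 0.5 * (R + R.T)

    def covariance_adjoint(self, R: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`covariance_forward`: ``(a_i^T R a_i)_i``."""
        R = np.asarray(R, dtype=float)
        n_c = self.grid.n_coarse
        if R.shape != (n_c, n_c):
            raise ValueError("covariance matrix has wrong shape")
        if np.abs(R - R.T).max() > 1e-6 * max(1.0, float(np.abs(R).max())):
            warnings.warn("covariance matrix is not symmetric", stacklevel=2)
        M = self.grid.coarse_size
        z = np.zeros(self.grid.n_fine)
        e = np.zeros((M, M))
        for d in range(n_c):
            e.flat[d] = 1.0
            z += self.adjoint_vec(R[:, d]) * self.adjoint(e).ravel()
            e.flat[d] = 0.0
        return z

    def column_norms(self) -> tuple[np.ndarray, np.ndarray]:
        """Norms ``||a_i||`` and ``||(A (.) A)_i|| = ||a_i||^2`` per column."""
        A = self.matrix()
        a = np.linalg.norm(A, axis=0)
        return a, a**2


# module-level functional wrappers -------------------------------------------


def covariance_forward(op: ForwardOperator, x: np.ndarray) -> np.ndarray:
    return op.covariance_forward(x)


def covariance_adjoint(op: ForwardOperator, R: np.ndarray) -> np.ndarray:
    return op.covariance_adjoint(R)


def column_norms(op: ForwardOperator) -> tuple[np.ndarray, np.ndarray]:
    return op.column_norms()
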