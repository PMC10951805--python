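import numpy as np
import pytest

from col0rme.grid import GridSpec, gaussian_psf_kernel
from col0rme.operators import ForwardOperator


@pytest.fixture(scope="session")
def small_op():
    """4x4 coarse grid, q=2 (8x8 fine), modest Gaussian PSF."""
    grid = GridSpec(4, 2, 100.0)
    psf = gaussian_psf_kernel(120.0, grid.fine_pitch_nm, side=5)
    return ForwardOperator(grid, psf=psf, boundary="reflect")


@pytest.fixture(scope="session")
def small_op_periodic():
    grid = GridSpec(4, 2, 100.0)
    psf = gaussian_psf_kernel(120.0, grid.fine_pitch_nm, side=5)
    return ForwardOperator(grid, psf=psf, boundary="periodic")


@pytest.fixture(scope="session")
def dense_A(small_op):
    """Independent dense oracle: A built column-by-column from impulses."""
    n = small_op.grid.n_fine
    m = small_op.grid.n_coarse
    A = np.zeros((m, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        A[:, i] = small_op.apply_vec(e)
    return A


def make_operator(M=4, q=2, fwhm_nm=120.0, side=5, boundary="reflect", pixel=100.0):
    grid = GridSpec(M, q, pixel)
    psf = gaussian_psf_kernel(fwhm_nm, grid.fine_pitch_nm, side=side)
    return ForwardOperator(grid, psf=psf, boundary=boundary)
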