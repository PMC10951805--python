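"""Grid geometry and Gaussian PSF models.

The method reconstructs on a grid ``q`` times finer than the camera grid:
an ``M x M`` camera frame corresponds to an ``L x L`` reconstruction grid
with ``L = q * M``.  Emitters are assumed to sit at fine-pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: FWHM of a Gaussian equals ``2 sqrt(2 ln 2)`` standard deviations.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class GridSpec:
    """Coarse (camera) / fine (reconstruction) grid geometry.

    Parameters
    ----------
    coarse_size : int
        Camera frame side length ``M`` in pixels.
    factor : int
        Super-resolution factor ``q`` (fine grid is ``q`` times finer).
    pixel_size_nm : float
        Camera pixel pitch in nanometres.
    """

    coarse_size: int
    factor: int
    pixel_size_nm: float = 100.0

    def __post_init__(self) -> None:
        if self.coarse_size < 1 or self.factor < 1:
            raise ValueError("coarse_size and factor must be positive integers")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def fine_size(self) -> int:
        """Side length ``L = q * M`` of the fine grid."""
        return self.factor * self.coarse_size

    @property
    def fine_pitch_nm(self) -> float:
        """Fine-grid pixel pitch in nanometres."""
        return self.pixel_size_nm / self.factor

    @property
    def n_coarse(self) -> int:
        return self.coarse_size**2

    @property
    def n_fine(self) -> int:
        return self.fine_size**2


@dataclass(frozen=True)
class PSFModel:
    """Sampled, normalized point-spread function on the fine grid."""

    fwhm_nm: float
    fine_pitch_nm: float
    kernel: np.ndarray = field(repr=False)

    @property
    def sigma_fine_px(self) -> float:
        """Gaussian standard deviation in fine-pixel units."""
        return self.fwhm_nm * FWHM_TO_SIGMA / self.fine_pitch_nm


def default_kernel_side(fwhm_nm: float, fine_pitch_nm: float) -> int:
    """Smallest odd kernel side covering ~8 sigma (<1e-4 truncated mass)."""
    sigma = fwhm_nm * FWHM_TO_SIGMA / fine_pitch_nm
    side = int(np.ceil(8.0 * sigma))
    side = max(side, 3)
    if side % 2 == 0:
        side += 1
    return side


def gaussian_psf_kernel(
    fwhm_nm: float, fine_pitch_nm: float, side: int | None = None
) -> PSFModel:
    """Sample an isotropic Gaussian PSF at fine-pixel centers.

    Parameters
    ----------
    fwhm_nm : float
        Full width at half maximum of the PSF, in nanometres.
    fine_pitch_nm : float
        Fine-grid pixel pitch in nanometres.
    side : int, optional
        Odd kernel side length; defaults to the smallest odd integer
        covering 8 standard deviations.

    Returns
    -------
    PSFModel
        Kernel normalized to unit sum (flux conservation).
    """
    if fwhm_nm <= 0:
        raise ValueError("fwhm_nm must be positive")
    if fine_pitch_nm <= 0:
        raise ValueError("fine_pitch_nm must be positive")
    if side is None:
        side = default_kernel_side(fwhm_nm, fine_pitch_nm)
    if side < 3 or side % 2 == 0:
        raise ValueError("side must be an odd integer >= 3")
    sigma = fwhm_nm * FWHM_TO_SIGMA / fine_pitch_nm
    half = side // 2
    coords = np.arange(-half, half + 1, dtype=float)
    # delta-function limit for vanishing width
    if sigma < 1e-8:
        kernel = np.zeros((side, side))
        kernel[half, half] = 1.0
    else:
        g = np.exp(-0.5 * (coords / sigma) ** 2)
        kernel = np.outer(g, g)
        kernel /= kernel.sum()
    return PSFModel(fwhm_nm=fwhm_nm, fine_pitch_nm=fine_pitch_nm, kernel=kernel)
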