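"""Temporal statistics of an acquisition stack.

Frames are treated as i.i.d. realizations of a random camera image whose
covariance carries the emitter-fluctuation signal: uncorrelated emitters
make the fine-grid variance image appear through ``A diag(x) A^T`` while
any temporally constant background cancels out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionStack", "EmpiricalCovariance", "temporal_mean", "empirical_covariance"]


@dataclass
class AcquisitionStack:
    """A ``(T, M, M)`` stack of camera frames plus acquisition metadata."""

    frames: np.ndarray
    frame_rate_fps: float = 100.0
    pixel_size_nm: float = 100.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("frames must have shape (T, M, M)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frame_rate_fps <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("frame_rate_fps and pixel_size_nm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def coarse_size(self) -> int:
        return self.frames.shape[1]


@dataclass
class EmpiricalCovariance:
    """Empirical covariance ``R_y`` (``M^2 x M^2``) and temporal mean."""

    matrix: np.ndarray = field(repr=False)
    mean: np.ndarray = field(repr=False)
    n_frames: int = 0


def _frames_array(stack) -> np.ndarray:
    frames = stack.frames if isinstance(stack, AcquisitionStack) else np.asarray(stack, dtype=float)
    if frames.ndim != 3:
        raise ValueError("expected a (T, M, M) stack")
    return frames


def temporal_mean(stack) -> np.ndarray:
    """Vectorized temporal mean of the stack (length ``M^2``)."""
    frames = _frames_array(stack)
    if frames.shape[0] < 1:
        raise ValueError("stack is empty")
    return frames.mean(axis=0).ravel()


def empirical_covariance(stack, ddof: int = 1) -> EmpiricalCovariance:
    """Empirical covariance of the vectorized frames.

    Uses the unbiased ``1/(T-1)`` normalization by default (``ddof=1``);
    ``ddof=0`` gives the ``1/T`` variant.
    """
    frames = _frames_array(stack)
    T = frames.shape[0]
    if T < 2:
        raise ValueError("at least two frames are required")
    Y = frames.reshape(T, -1)
    mean = Y.mean(axis=0)
    D = Y - mean
    R = (D.T @ D) / (T - ddof)
    R = 0.5 * (R + R.T)
    return EmpiricalCovariance(matrix=R, mean=mean, n_frames=T)
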