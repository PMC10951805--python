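"""TIFF / CSV / JSON input-output helpers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .covariance import AcquisitionStack

__all__ = ["read_stack", "write_stack", "write_image", "write_json", "write_positions_csv"]


def read_stack(path, frame_rate_fps: float = 100.0, pixel_size_nm: float = 100.0) -> AcquisitionStack:
    """Read a multi-page TIFF stack into an :class:`AcquisitionStack`."""
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    return AcquisitionStack(
        frames=np.asarray(frames, dtype=float),
        frame_rate_fps=frame_rate_fps,
        pixel_size_nm=pixel_size_nm,
    )


def write_stack(path, frames: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(frames, dtype=np.float32))


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def write_positions_csv(path, positions: np.ndarray, grid_size: int) -> None:
    """Emitter fine-grid positions as ``index,row,col`` CSV."""
    positions = np.asarray(positions, dtype=int).ravel()
    r, c = np.divmod(positions, grid_size)
    lines = ["index,row,col"] + [f"{p},{rr},{cc}" for p, rr, cc in zip(positions, r, c)]
    Path(path).write_text("\n".join(lines) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
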