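"""Quantitative assessment of localizations and reconstructions.

Localization quality is measured by the Jaccard index with a spatial
tolerance: estimated and true emitter pixels are matched one-to-one by
the Gale-Shapley stable-matching algorithm with preferences ordered by
Euclidean distance (pairs farther than the tolerance are forbidden),
and ``JI = CD / (CD + FP + FN)``.  Image quality uses the peak
signal-to-noise ratio against the ground-truth intensity image, and
raw-sequence quality the plain signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchResult",
    "jaccard_index",
    "default_tolerance_nm",
    "psnr",
    "snr",
    "noise_variance_error",
]


@dataclass
class MatchResult:
    """One-to-one matching between estimated and true emitter pixels."""

    pairs: list = field(default_factory=list)  # (est_index, gt_index)
    n_correct: int = 0
    n_false_positive: int = 0
    n_false_negative: int = 0
    tolerance_nm: float = 0.0

    @property
    def jaccard(self) -> float:
        denom = self.n_correct + self.n_false_positive + self.n_false_negative
        return self.n_correct / denom if denom else 0.0


def _to_coords(support, grid_size: int | None) -> np.ndarray:
    arr = np.asarray(support)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr.astype(float)
    if arr.ndim == 1:
        if grid_size is None:
            raise ValueError("grid_size is required for flat-index supports")
        r, c = np.divmod(arr.astype(int), grid_size)
        return np.column_stack([r, c]).astype(float)
    raise ValueError("support must be flat indices or (n, 2) coordinates")


def default_tolerance_nm(fine_pitch_nm: float) -> float:
    """Tolerance admitting matches in the 8-neighborhood: ``sqrt(2) * pitch``."""
    return np.sqrt(2.0) * fine_pitch_nm


def jaccard_index(
    est_support,
    gt_support,
    tolerance_nm: float | None = None,
    fine_pitch_nm: float = 25.0,
    grid_size: int | None = None,
):
    """Tolerance Jaccard index with Gale-Shapley one-to-one matching.

    Parameters
    ----------
    est_support, gt_support : array
        Flat fine-grid indices (with ``grid_size``) or ``(n, 2)`` pixel
        coordinates of estimated and true emitter pixels.
    tolerance_nm : float, optional
        Maximum matching distance; defaults to ``sqrt(2)`` fine pixels
        (correct detections allowed in the 8-neighborhood).
    fine_pitch_nm : float
        Fine-grid pixel pitch, converts pixels to nanometres.

    Returns
    -------
    (float, MatchResult)
        The Jaccard index ``CD / (CD + FP + FN)`` and the matching.
    """
    gt = _to_coords(gt_support, grid_size)
    if gt.shape[0] == 0:
        raise ValueError("ground-truth support is empty; JI undefined")
    est = _to_coords(est_support, grid_size)
    if tolerance_nm is None:
        tolerance_nm = default_tolerance_nm(fine_pitch_nm)
    tol_px = tolerance_nm / fine_pitch_nm

    n_e, n_g = est.shape[0], gt.shape[0]
    pairs: list[tuple[int, int]] = []
    if n_e:
        diff = est[:, None, :] - gt[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        # Gale-Shapley: estimates propose in ascending distance order,
        # ground-truth pixels hold the closest proposal; ties broken by
        # lowest index for determinism.
        prefs = []
        for i in range(n_e):
            ok = np.flatnonzero(dist[i] <= tol_px + 1e-12)
            order = ok[np.lexsort((ok, dist[i, ok]))]
            prefs.append(list(order[::-1]))  # pop() from the end
        held = -np.ones(n_g, dtype=int)
        free = list(range(n_e - 1, -1, -1))
        while free:
            i = free.pop()
            while prefs[i]:
                j = prefs[i].pop()
                cur = held[j]
                if cur < 0:
                    held[j] = i
                    break
                if (dist[i, j], i) < (dist[cur, j], cur):
                    held[j] = i
                    free.append(cur)
                    break
            # no acceptable partner left: emitter stays unmatched
        pairs = [(int(held[j]), int(j)) for j in range(n_g) if held[j] >= 0]
    cd = len(pairs)
    result = MatchResult(
        pairs=pairs,
        n_correct=cd,
        n_false_positive=n_e - cd,
        n_false_negative=n_g - cd,
        tolerance_nm=float(tolerance_nm),
    )
    return result.jaccard, result


def psnr(x_hat: np.ndarray, x_ref: np.ndarray) -> float:
    """Peak signal-to-noise ratio, ``10 log10(max(x_ref)^2 / MSE)`` in dB."""
    x_hat = np.asarray(x_hat, dtype=float).ravel()
    x_ref = np.asarray(x_ref, dtype=float).ravel()
    if x_hat.shape != x_ref.shape:
        raise ValueError("shapes differ")
    mse = float(np.mean((x_hat - x_ref) ** 2))
    if mse == 0.0:
        return np.inf
    peak = float(np.max(x_ref))
    return 10.0 * np.log10(peak * peak / mse)


def snr(y_hat, y_ref) -> float:
    """Signal-to-noise ratio ``10 log10(||ref||^2 / ||ref - hat||^2)`` in dB."""
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    if y_hat.shape != y_ref.shape:
        raise ValueError("shapes differ")
    err = float(np.sum((y_ref - y_hat) ** 2))
    if err == 0.0:
        return np.inf
    return 10.0 * np.log10(float(np.sum(y_ref**2)) / err)


def noise_variance_error(s_hat: float, s_true: float) -> float:
    """Relative error ``|s_hat - s_true| / s_true`` of the noise variance."""
    if s_true <= 0:
        raise ValueError("s_true must be positive")
    return abs(s_hat - s_true) / s_true
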