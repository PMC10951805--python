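"""Synthetic fluctuation-microscopy data with known ground truth.

The generator emulates a standard widefield/TIRF acquisition of blinking
fluorophores on tubular (filament) structures:

1. a filament phantom is drawn as smooth random spline curves rasterized
   one fine pixel wide, and emitters are placed along the curves at a
   configured density (emitters sit at fine-pixel centers);
2. each emitter blinks independently as a continuous-time two-state
   telegraph process with exponential on/off dwell times and an
   absorbing exponential bleaching clock, integrated over each frame
   interval to a fractional on-time;
3. each frame is formed as PSF convolution + ``q x q`` block binning of
   the fine-grid photon image, plus a constant background; Poisson shot
   noise is drawn, counts are converted to camera units by the
   effective gain (quantum efficiency x gain), and i.i.d. Gaussian read
   noise is added.

Defaults follow a realistic high-density configuration: 500 photons per
fully-on emitter per frame, 10.7 emitters per camera pixel, quantum
efficiency 0.7 and camera gain 6 (overall gain 4.2), 100 fps, NA 1.4
optics at 525 nm emission (FWHM 229 nm), with a high-background preset
at 2500 background photons/pixel/frame and a low-background preset at
50.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import splev, splprep

from .covariance import AcquisitionStack
from .grid import GridSpec, gaussian_psf_kernel
from .operators import ForwardOperator

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "preset_config",
    "generate_filament_phantom",
    "simulate_blinking",
    "render_stack",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition, optics, fluorophore and camera parameters."""

    grid: GridSpec
    fwhm_nm: float = 229.0
    frame_rate_fps: float = 100.0
    photons_per_frame_mean: float = 500.0
    tau_on_ms: float = 20.0
    tau_off_ms: float = 40.0
    tau_bleach_s: float = 20.0
    emitter_density_per_pixel: float = 10.7
    background_photons: float = 2500.0
    quantum_efficiency: float = 0.7
    camera_gain: float = 6.0
    gaussian_read_noise_sd: float | None = None  # derived from gaussian_snr_db
    gaussian_snr_db: float = 16.0
    numerical_aperture: float = 1.4
    wavelength_nm: float = 525.0
    n_filaments: int = 3
    binary_states: bool = False

    @property
    def effective_gain(self) -> float:
        return self.quantum_efficiency * self.camera_gain

    def operator(self, boundary: str = "reflect") -> ForwardOperator:
        psf = gaussian_psf_kernel(self.fwhm_nm, self.grid.fine_pitch_nm)
        return ForwardOperator(self.grid, psf=psf, boundary=boundary)


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated stack."""

    positions: np.ndarray = field(repr=False)  # flat fine-grid index per emitter
    states: np.ndarray = field(repr=False)  # (n_emitters, T) on-fractions
    x_gt: np.ndarray = field(repr=False)  # fine-grid mean intensity (camera units)
    b_gt: np.ndarray = field(repr=False)  # coarse-grid background (camera units)
    noise_variance: float = 0.0  # Gaussian read-noise variance (camera units^2)
    config: SimulationConfig | None = None
    photon_stack: np.ndarray | None = field(default=None, repr=False)

    @property
    def support(self) -> np.ndarray:
        """Sorted unique fine-grid pixels containing at least one emitter."""
        return np.unique(self.positions)


def preset_config(name: str, coarse_size: int = 16, factor: int = 4) -> SimulationConfig:
    """Low-background (``LB``) or high-background (``HB``) acquisition preset."""
    grid = GridSpec(coarse_size, factor, pixel_size_nm=100.0)
    name = name.upper()
    if name == "HB":
        return SimulationConfig(grid=grid, background_photons=2500.0)
    if name == "LB":
        return SimulationConfig(grid=grid, background_photons=50.0)
    raise ValueError("preset name must be 'LB' or 'HB'")


def generate_filament_phantom(
    grid: GridSpec, n_filaments: int = 3, seed: int = 0, density: float | None = None
):
    """Random smooth filaments with emitters placed along them.

    Returns ``(mask, positions)``: a binary ``L x L`` fine-grid mask of
    the rasterized curves and the flat fine-grid index of each emitter
    (``round(density * M^2)`` emitters sampled uniformly along the
    curves, several emitters may share a pixel).
    """
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    rng = np.random.default_rng(seed)
    L = grid.fine_size
    mask = np.zeros((L, L), dtype=bool)
    curve_pixels = []
    for _ in range(n_filaments):
        # spline through random control points spanning the field of view
        n_ctrl = 4
        ctrl = rng.uniform(0.05 * L, 0.95 * L, size=(2, n_ctrl))
        try:
            tck, _ = splprep(ctrl, s=0, k=min(3, n_ctrl - 1))
        except Exception:
            continue
        t = np.linspace(0.0, 1.0, 20 * L)
        xs, ys = splev(t, tck)
        rr = np.clip(np.round(xs).astype(int), 0, L - 1)
        cc = np.clip(np.round(ys).astype(int), 0, L - 1)
        mask[rr, cc] = True
        curve_pixels.append(rr * L + cc)
    pixels = np.unique(np.concatenate(curve_pixels))
    if density is None:
        density = 10.7
    n_emitters = int(round(density * grid.n_coarse))
    positions = rng.choice(pixels, size=n_emitters, replace=True)
    return mask, positions


def simulate_blinking(
    config: SimulationConfig, n_emitters: int, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame fractional on-times of independent blinking emitters.

    Each emitter follows a stationary two-state telegraph process with
    exponential dwell times (means ``tau_on``, ``tau_off``) and an
    independent exponential bleaching clock (mean ``tau_bleach``,
    absorbing).  The state is integrated over each frame interval, so
    entries lie in ``[0, 1]``; with ``binary_states`` the fraction is
    thresholded at 1/2 to mimic simulators with per-frame on/off states.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    dt = 1.0 / config.frame_rate_fps
    total = T * dt
    tau_on = config.tau_on_ms / 1000.0
    tau_off = config.tau_off_ms / 1000.0
    p_on = tau_on / (tau_on + tau_off)
    frames = np.arange(T + 1) * dt
    out = np.zeros((n_emitters, T))
    bleach = rng.exponential(config.tau_bleach_s, size=n_emitters)
    start_on = rng.random(n_emitters) < p_on
    mean_dwell = min(tau_on, tau_off)
    for e in range(n_emitters):
        horizon = min(total, bleach[e])
        if horizon <= 0:
            continue
        # alternating dwells, drawn in chunks until the horizon is covered
        n_guess = max(8, int(3 * horizon / mean_dwell) + 8)
        on_first = start_on[e]
        dwells = np.empty(0)
        while dwells.sum() < horizon:
            k = dwells.size
            # an even index is an on-dwell iff the emitter starts on
            means = np.where(
                ((np.arange(k, k + n_guess) % 2) == 0),
                tau_on if on_first else tau_off,
                tau_off if on_first else tau_on,
            )
            dwells = np.concatenate([dwells, rng.exponential(means)])
        edges = np.concatenate([[0.0], np.cumsum(dwells)])
        edges = np.clip(edges, 0.0, horizon)
        # cumulative on-time at the event edges (slope 1 during on-dwells)
        on_dwell = (np.arange(dwells.size) % 2 == 0) if on_first else (
            np.arange(dwells.size) % 2 == 1
        )
        seg = np.diff(edges) * on_dwell
        cum_on = np.concatenate([[0.0], np.cumsum(seg)])
        cum = np.interp(frames, edges, cum_on, left=0.0, right=cum_on[-1])
        out[e] = np.diff(cum) / dt
    if config.binary_states:
        out = (out >= 0.5).astype(float)
    return out


def render_stack(
    positions: np.ndarray,
    states: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    keep_photons: bool = False,
):
    """Render camera frames from emitter positions and on-fractions.

    Per frame: fine-grid expected photon image -> PSF convolution and
    block binning -> add background -> Poisson draw -> effective gain ->
    additive Gaussian read noise.  If ``gaussian_read_noise_sd`` is
    unset, its value is derived from ``gaussian_snr_db`` relative to the
    clean (gain-scaled, background-free) signal energy.

    Returns ``(AcquisitionStack, SimulationTruth)``.
    """
    positions = np.asarray(positions, dtype=int).ravel()
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[0] != positions.size:
        raise ValueError("states must have shape (n_emitters, T)")
    T = states.shape[1]
    grid = config.grid
    L, M = grid.fine_size, grid.coarse_size
    op = config.operator()
    gain = config.effective_gain

    clean = np.empty((T, M, M))
    for t in range(T):
        fine = np.zeros(L * L)
        np.add.at(fine, positions, config.photons_per_frame_mean * states[:, t])
        clean[t] = op.apply(fine.reshape(L, L))
    signal_energy = float(np.mean((gain * clean) ** 2))
    if config.gaussian_read_noise_sd is None:
        sd = np.sqrt(signal_energy / 10.0 ** (config.gaussian_snr_db / 10.0))
    else:
        sd = float(config.gaussian_read_noise_sd)

    lam = np.maximum(clean, 0.0) + config.background_photons
    photons = rng.poisson(lam).astype(float)
    frames = gain * photons + rng.normal(0.0, sd, size=photons.shape)

    x_gt = np.zeros(L * L)
    np.add.at(
        x_gt, positions, gain * config.photons_per_frame_mean * states.mean(axis=1)
    )
    truth = SimulationTruth(
        positions=positions,
        states=states,
        x_gt=x_gt,
        b_gt=np.full(M * M, gain * config.background_photons),
        noise_variance=sd * sd,
        config=config,
        photon_stack=photons if keep_photons else None,
    )
    stack = AcquisitionStack(
        frames=frames,
        frame_rate_fps=config.frame_rate_fps,
        pixel_size_nm=grid.pixel_size_nm,
    )
    return stack, truth


def simulate_dataset(
    config: SimulationConfig, T: int, seed: int = 0, keep_photons: bool = False
):
    """Phantom + blinking + rendering with all randomness from one seed."""
    rng = np.random.default_rng(seed)
    _, positions = generate_filament_phantom(
        config.grid,
        config.n_filaments,
        seed=int(rng.integers(2**31 - 1)),
        density=config.emitter_density_per_pixel,
    )
    states = simulate_blinking(config, positions.size, T, rng)
    return render_stack(positions, states, config, rng, keep_photons=keep_photons)
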