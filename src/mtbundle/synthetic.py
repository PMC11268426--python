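"""Synthetic data for motor-driven microtubule bundles.

Generates every input the analysis pipeline consumes, from known ground
truth: filament/tracer kinematics in the sliding, extension and mixed
regimes, photobleached kymographs with Poisson photon noise, tracer track
tables, and noisy SAXS curves/detector frames.

Kinematics.  Filament i at axial position x moves with

    v_i = alpha * p_i * V + (1 - alpha) * gamma_par * x~ + noise

where ``alpha`` interpolates between pure antiparallel sliding (alpha = 1:
half the filaments at +V, half at -V) and pure telescoping extension
(alpha = 0).  ``x~`` is the position relative to the bundle centre, frozen
at t = 0 in linear growth mode or instantaneous in exponential mode; the
polarity p_i = +/-1 flips as a Poisson process at the reversal rate k.
Filament lengths are log-normal (default mean 4.9 um, mode 2.8 um).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bleach import Kymograph
from .saxs_model import (BundleLatticeModel, DetectorGeometry, Q_RANGE_NM,
                         ScatteringCurve, bundle_intensity)

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Default filament-length distribution (um): log-normal mean and mode.
LENGTH_MEAN_UM = 4.9
LENGTH_MODE_UM = 2.8


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KinematicParams:
    """Ground-truth bundle motion parameters."""

    v_slide: float = 22.5        # filament speed magnitude V, nm/s
    alpha: float = 1.0           # sliding fraction: 1 pure sliding, 0 pure extension
    gamma_par: float = 8.5e-4    # axial strain rate, 1/s
    gamma_perp: float = -2.5e-4  # transverse strain rate, 1/s
    reversal_rate: float = 0.0   # polarity flip rate k, 1/s
    growth_mode: str = "linear"  # {"linear", "exponential"}
    noise_sigma: float = 0.0     # velocity jitter, nm/s
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.reversal_rate < 0 or self.v_slide < 0 or self.noise_sigma < 0:
            raise ValueError("rates and speeds must be >= 0")
        if self.growth_mode not in ("linear", "exponential"):
            raise ValueError(f"unknown growth_mode {self.growth_mode!r}")


@dataclass
class FilamentEnsemble:
    """Axial filament trajectories: arrays shaped (n_filaments, n_frames)."""

    positions: np.ndarray    # um
    polarity: np.ndarray     # +/- 1
    lengths: np.ndarray      # um, per filament
    times: np.ndarray        # s
    params: KinematicParams | None = None

    def __post_init__(self):
        n, t = self.positions.shape
        if self.polarity.shape != (n, t) or self.lengths.shape != (n,) \
                or self.times.shape != (t,):
            raise ValueError("inconsistent ensemble array shapes")
        if np.any(self.lengths <= 0):
            raise ValueError("lengths must be > 0")

    @property
    def n_filaments(self) -> int:
        return self.positions.shape[0]

    def at_time(self, t: float) -> np.ndarray:
        """Linearly interpolated positions at time t."""
        times = self.times
        if t <= times[0]:
            return self.positions[:, 0]
        if t >= times[-1]:
            return self.positions[:, -1]
        i = int(np.searchsorted(times, t, side="right")) - 1
        f = (t - times[i]) / (times[i + 1] - times[i])
        return (1 - f) * self.positions[:, i] + f * self.positions[:, i + 1]


@dataclass(frozen=True)
class RenderConfig:
    """Imaging, bleaching and tracer-export settings for rendering."""

    pixel_size: float = 0.325          # um / px
    frame_interval: float = 2.0        # s
    psf_sigma: float = 0.30            # um
    bleach_time: float = 20.0          # s
    bleach_positions: tuple[float, float] = (32.5, 47.5)  # um
    bleach_width: float = 1.5          # FWHM of each Gaussian notch, um
    bleach_depth: float = 0.6          # fraction of label removed at notch centre
    photons_per_px: float | None = 2000.0  # None -> noiseless float rendering
    tracer_fraction: float = 1e-4      # labelled-filament fraction (1 in 10^4)
    field_um: float = 80.0             # rendered field of view
    seed: int = 0

    def __post_init__(self):
        if abs(self.bleach_positions[1] - self.bleach_positions[0]) \
                <= 4.0 * self.bleach_width:
            raise ValueError("bleach positions must be > 4 bleach widths apart")
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth in [0, 1]")
        if self.photons_per_px is not None and self.photons_per_px <= 0:
            raise ValueError("photons_per_px must be > 0")


# --------------------------------------------------------------------------
# filament lengths
# --------------------------------------------------------------------------

def lognormal_params(mean_um: float, mode_um: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given mean and mode.

    Closed form: sigma^2 = (2/3) ln(mean/mode), mu = ln(mode) + sigma^2,
    from mean = exp(mu + sigma^2/2) and mode = exp(mu - sigma^2).
    """
    if not 0.0 < mode_um < mean_um:
        raise ValueError("need 0 < mode < mean for a log-normal")
    sigma2 = (2.0 / 3.0) * math.log(mean_um / mode_um)
    mu = math.log(mode_um) + sigma2
    return mu, math.sqrt(sigma2)


def sample_lengths(n: int, mean_um: float = LENGTH_MEAN_UM,
                   mode_um: float = LENGTH_MODE_UM, seed: int = 0) -> np.ndarray:
    """Draw n filament lengths (um) from the log-normal length distribution."""
    if n < 1:
        raise ValueError("n >= 1 required")
    mu, sigma = lognormal_params(mean_um, mode_um)
    rng = np.random.default_rng(seed)
    return rng.lognormal(mu, sigma, size=n)


# --------------------------------------------------------------------------
# bundle kinematics
# --------------------------------------------------------------------------

def simulate_bundle(params: KinematicParams, n_filaments: int, duration: float,
                    dt: float, *, extent_um: float = 100.0,
                    initial_positions: np.ndarray | None = None,
                    lengths: np.ndarray | float | None = None,
                    placement: str = "grid") -> FilamentEnsemble:
    """Integrate the bundle kinematics for ``duration`` seconds.

    Initial positions are evenly spaced over ``extent_um`` centred on 0
    (``placement="grid"``, with alternating polarity so each population is
    itself uniform) or uniform random (``placement="random"``); explicit
    ``initial_positions`` override both.  Polarities are split exactly half
    +1 / half -1 (odd count: one extra +1).  The deterministic part of each
    step is integrated exactly (the velocity field is affine in x), so the
    pure-sliding and pure-extension limits are free of time-discretisation
    error.
    """
    if n_filaments < 2:
        raise ValueError("n_filaments >= 2 required")
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be > 0")
    k = params.reversal_rate
    if k > 0 and dt > 0.1 / k:
        warnings.warn("dt larger than 0.1/reversal_rate: reversals undersampled")

    rng = np.random.default_rng(params.seed)
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt

    if initial_positions is not None:
        x0 = np.asarray(initial_positions, dtype=float).copy()
        if x0.size != n_filaments:
            raise ValueError("initial_positions length mismatch")
    elif placement == "grid":
        x0 = (np.arange(n_filaments) + 0.5) / n_filaments * extent_um \
            - extent_um / 2.0
    elif placement == "random":
        x0 = rng.uniform(-extent_um / 2.0, extent_um / 2.0, size=n_filaments)
    else:
        raise ValueError(f"unknown placement {placement!r}")

    # exactly half/half polarity, interleaved so the pure-sliding limit is
    # spatially uniform for grid placement; odd count gets an extra +1
    pol0 = np.where(np.arange(n_filaments) % 2 == 0, 1, -1).astype(np.int8)

    if lengths is None:
        L = sample_lengths(n_filaments, seed=params.seed)
    elif np.isscalar(lengths):
        L = np.full(n_filaments, float(lengths))
    else:
        L = np.asarray(lengths, dtype=float).copy()

    center0 = float(np.mean(x0))
    g = (1.0 - params.alpha) * params.gamma_par          # 1/s
    v_units = 1e-3                                       # nm/s -> um/s
    flip_p = 1.0 - math.exp(-k * dt) if k > 0 else 0.0

    positions = np.empty((n_filaments, n_steps + 1))
    polarity = np.empty((n_filaments, n_steps + 1), dtype=np.int8)
    positions[:, 0] = x0
    polarity[:, 0] = pol0

    x = x0.copy()
    p = pol0.copy()
    exp_g = math.exp(g * dt) if g != 0.0 else 1.0
    for i in range(n_steps):
        c = params.alpha * p * params.v_slide * v_units  # um/s
        if params.growth_mode == "linear":
            x = x + (c + g * (x0 - center0)) * dt
        else:
            if g != 0.0:
                # exact step of x' = c + g (x - center0)
                rel = x - center0
                x = center0 + rel * exp_g + c * (exp_g - 1.0) / g
            else:
                x = x + c * dt
        if params.noise_sigma > 0:
            x = x + rng.normal(0.0, params.noise_sigma * v_units,
                               size=n_filaments) * dt
        if flip_p > 0:
            flips = rng.random(n_filaments) < flip_p
            p = np.where(flips, -p, p).astype(np.int8)
        positions[:, i + 1] = x
        polarity[:, i + 1] = p

    return FilamentEnsemble(positions=positions, polarity=polarity,
                            lengths=L, times=times, params=params)


# --------------------------------------------------------------------------
# kymograph rendering
# --------------------------------------------------------------------------

def render_kymograph(ensemble: FilamentEnsemble, cfg: RenderConfig,
                     origin_um: float | None = None) -> Kymograph:
    """Render a bleached-bundle kymograph from filament trajectories.

    Each frame's profile is the sum over filaments of a box of the filament
    length, convolved with a Gaussian PSF.  At ``cfg.bleach_time`` the label
    density along each filament is multiplied by ``1 - depth * G(x)`` with G
    two Gaussian notches at the bleach positions; the notch pattern is
    imprinted in material coordinates and is carried along by the filament
    afterwards.  With ``photons_per_px`` set, pixel values are Poisson counts
    whose expectation is ``photons_per_px`` at the unbleached plateau.

    ``origin_um`` maps simulation coordinate 0 into the image; by default the
    bundle centre is placed at the centre of the field of view.
    """
    if not ensemble.times[0] <= cfg.bleach_time <= ensemble.times[-1]:
        raise ValueError("ensemble time span must cover the bleach time")
    field = cfg.field_um
    for b in cfg.bleach_positions:
        if not 0.0 < b < field:
            raise ValueError(f"bleach position {b} um outside the field")

    if origin_um is None:
        origin_um = field / 2.0

    n_px = int(round(field / cfg.pixel_size))
    oversample = 4
    n_fine = n_px * oversample
    dx = cfg.pixel_size / oversample

    # static material grid: sample points along each filament
    ds = dx
    counts = np.maximum((ensemble.lengths / ds).astype(int), 1)
    fil_idx = np.repeat(np.arange(ensemble.n_filaments), counts)
    s_off = np.concatenate([
        (np.arange(c) + 0.5) / c * L - L / 2.0
        for c, L in zip(counts, ensemble.lengths)])
    pt_w = np.repeat(ensemble.lengths / counts, counts)  # um of filament per point

    # imprint the bleach notches in material coordinates
    xb = ensemble.at_time(cfg.bleach_time)[fil_idx] + s_off + origin_um
    sig_b = cfg.bleach_width / _FWHM
    notch = np.zeros_like(xb)
    for b in cfg.bleach_positions:
        notch += np.exp(-0.5 * ((xb - b) / sig_b) ** 2)
    w_bleached = pt_w * (1.0 - cfg.bleach_depth * np.clip(notch, 0.0, 1.0))

    n_frames = int(np.floor(ensemble.times[-1] / cfg.frame_interval)) + 1
    frame_times = np.arange(n_frames) * cfg.frame_interval
    bleach_frame = int(np.searchsorted(frame_times, cfg.bleach_time))

    psf_fine = cfg.psf_sigma / dx
    image = np.empty((n_frames, n_px))
    from scipy.ndimage import gaussian_filter1d
    for fi, t in enumerate(frame_times):
        pos = ensemble.at_time(t)[fil_idx] + s_off + origin_um
        wts = pt_w if t < cfg.bleach_time else w_bleached
        # linear-interpolation deposit onto the fine grid
        u = pos / dx - 0.5
        i0 = np.floor(u).astype(int)
        f = u - i0
        inside = (i0 >= -1) & (i0 < n_fine)
        i0c = np.clip(i0, 0, n_fine - 1)
        i1c = np.clip(i0 + 1, 0, n_fine - 1)
        lo_ok = (i0 >= 0) & inside
        hi_ok = (i0 + 1 < n_fine) & inside
        fine = np.bincount(i0c[lo_ok], weights=(wts * (1 - f))[lo_ok],
                           minlength=n_fine)
        fine += np.bincount(i1c[hi_ok], weights=(wts * f)[hi_ok],
                            minlength=n_fine)
        fine = gaussian_filter1d(fine, psf_fine, mode="constant")
        image[fi] = fine.reshape(n_px, oversample).sum(axis=1)

    # scale so the unbleached plateau sits at photons_per_px
    core = image[0, n_px // 4: 3 * n_px // 4]
    plateau = float(np.median(core))
    if plateau <= 0:
        raise ValueError("empty field: no filament coverage in the image core")
    scale = (cfg.photons_per_px or 1.0) / plateau
    expected = image * scale
    if cfg.photons_per_px is not None:
        rng = np.random.default_rng(cfg.seed)
        expected = rng.poisson(expected).astype(float)

    meta = {
        "pixel_size_um": cfg.pixel_size,
        "frame_interval_s": cfg.frame_interval,
        "bleach_time_s": cfg.bleach_time,
        "bleach_frame": bleach_frame,
        "seed": cfg.seed,
        "ground_truth": _ground_truth_dict(ensemble.params),
    }
    return Kymograph(intensity=expected, pixel_size=cfg.pixel_size,
                     frame_interval=cfg.frame_interval,
                     bleach_frame=bleach_frame, meta=meta)


def _ground_truth_dict(params: KinematicParams | None) -> dict:
    if params is None:
        return {}
    return {
        "v_slide_nm_s": params.v_slide,
        "alpha": params.alpha,
        "gamma_par_per_s": params.gamma_par,
        "gamma_perp_per_s": params.gamma_perp,
        "reversal_rate_per_s": params.reversal_rate,
        "growth_mode": params.growth_mode,
        "noise_sigma_nm_s": params.noise_sigma,
        "seed": params.seed,
    }


# --------------------------------------------------------------------------
# tracer tracks
# --------------------------------------------------------------------------

def emit_tracer_tracks(ensemble: FilamentEnsemble, cfg: RenderConfig):
    """Export a random filament subset as a tracer-track table.

    Returns a pandas DataFrame with columns ``track, t_s, x_um, y_um``.
    Localisation noise uses the sigma_PSF/sqrt(photons) heuristic; the
    transverse coordinate is a small static per-tracer offset plus the same
    localisation noise.  Deterministic under ``cfg.seed``.
    """
    import pandas as pd

    if not 0.0 < cfg.tracer_fraction <= 1.0:
        raise ValueError("tracer_fraction in (0, 1]")
    n = ensemble.n_filaments
    n_tracers = int(round(n * cfg.tracer_fraction))
    if n_tracers < 1:
        raise ValueError(
            "no tracers selected: increase n_filaments or tracer_fraction")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    chosen = np.sort(rng.choice(n, size=n_tracers, replace=False))
    sigma_loc = (cfg.psf_sigma / math.sqrt(cfg.photons_per_px)
                 if cfg.photons_per_px else 0.0)
    y0 = rng.normal(0.0, 0.2, size=n_tracers)
    rows = []
    t = ensemble.times
    for tid, (fi, y) in enumerate(zip(chosen, y0)):
        x = ensemble.positions[fi]
        if sigma_loc > 0:
            x = x + rng.normal(0.0, sigma_loc, size=x.size)
            yy = y + rng.normal(0.0, sigma_loc, size=x.size)
        else:
            yy = np.full(x.size, y)
        rows.append(pd.DataFrame({"track": tid, "t_s": t, "x_um": x,
                                  "y_um": yy}))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# SAXS synthesis
# --------------------------------------------------------------------------

def default_q_grid(n: int = 500) -> np.ndarray:
    """Instrument q grid, [0.075, 2.185] nm^-1."""
    return np.linspace(Q_RANGE_NM[0], Q_RANGE_NM[1], n)


def exposure_for_peak_snr(model: BundleLatticeModel, snr: float,
                          q_grid: np.ndarray | None = None) -> float:
    """Exposure scale giving Poisson SNR ``snr`` at the intensity maximum."""
    q = q_grid if q_grid is not None else default_q_grid()
    I = bundle_intensity(model, q).I
    return snr ** 2 / float(I.max())


def synthesize_saxs(model: BundleLatticeModel, exposure: float | None,
                    seed: int = 0, q_grid: np.ndarray | None = None,
                    n_psi: int = 720) -> ScatteringCurve:
    """Noisy scattering curve from the forward model.

    Counts are Poisson with expectation ``exposure * I_model`` and
    sigma = sqrt(counts).  ``exposure=None`` (or inf) returns the noiseless
    model curve with the corresponding Poisson sigma at unit exposure.
    """
    q = q_grid if q_grid is not None else default_q_grid()
    I = bundle_intensity(model, q, n_psi=n_psi).I
    if exposure is None or np.isinf(exposure):
        return ScatteringCurve(q=q, I=I, sigma=np.sqrt(np.maximum(I, 1e-300)),
                               label="model")
    if exposure <= 0:
        raise ValueError("exposure must be > 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(exposure * I).astype(float)
    sigma = np.sqrt(np.maximum(counts, 1.0))
    return ScatteringCurve(q=q, I=counts, sigma=sigma, label="synthetic")


def synthesize_detector_image(curve: ScatteringCurve, geom: DetectorGeometry,
                              shape: tuple[int, int], exposure: float = 1.0,
                              seed: int = 0, beamstop_px: float = 10.0):
    """Paint an isotropic detector frame from a 1D curve.

    Pixel expectations interpolate the curve at each pixel's q; a central
    circular beamstop is masked.  Returns (image, mask) with nonzero mask
    marking excluded pixels.
    """
    if exposure <= 0:
        raise ValueError("exposure must be > 0")
    rows, cols = np.indices(shape)
    r = np.hypot(rows - geom.center_px[0], cols - geom.center_px[1])
    qpix = geom.q_of_radius_px(r)
    expected = exposure * np.interp(qpix, curve.q, curve.I,
                                    left=0.0, right=0.0)
    rng = np.random.default_rng(seed)
    image = rng.poisson(expected).astype(float)
    mask = (r <= beamstop_px).astype(np.uint8)
    image[mask != 0] = 0.0
    return image, mask
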