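"""Velocity statistics of tracer microtubules and bundle strain rates.

Sparse labelled tracer filaments report the microscopic motion inside a
bundle.  From their trajectories this module computes finite-difference
velocity series, the velocity-velocity temporal autocorrelation

    C(tau) = < V(t) V(t + tau) >_{t, tracks} / < V^2 >

(no per-track mean subtraction by default: reversal-rich tracks have
near-zero mean and the negative lobe of C is the reversal signature), the
"slowness" exponent S_c — the exponential rate of the distribution of
absolute velocity deviations |V(t) - Vbar|, estimated by the maximum
likelihood rate 1/mean — and the bundle strain rates gamma_par / gamma_perp
from linear fits of normalised extent L(t)/L_o versus time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TracerTrack:
    """One tracer trajectory projected on its principal displacement axis."""

    track_id: int
    times: np.ndarray
    positions: np.ndarray    # axial, um

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("track times must be strictly increasing")
        if self.times.shape != self.positions.shape:
            raise ValueError("times/positions shape mismatch")

    def velocities(self, lag: int = 1) -> np.ndarray:
        return velocities(self.positions, self.times, lag=lag)

    @property
    def mean_velocity(self) -> float:
        """Per-track time-average velocity Vbar (um/s)."""
        return float(np.mean(self.velocities()))


@dataclass
class VelocityStats:
    """Autocorrelation and slowness summary over a set of tracks."""

    lags: np.ndarray
    C: np.ndarray
    ci95: np.ndarray          # (2, n_lags) bootstrap band
    n_tracks: int
    S_c: float | None = None
    S_c_ci: tuple[float, float] | None = None


@dataclass
class StrainSeries:
    """Normalised bundle extents and fitted strain rates."""

    times_par: np.ndarray
    L_par_norm: np.ndarray
    gamma_par: float
    gamma_par_se: float
    gamma_par_pi95: np.ndarray      # (2, n) prediction interval on L/L_o
    times_perp: np.ndarray | None = None
    L_perp_norm: np.ndarray | None = None
    gamma_perp: float | None = None
    gamma_perp_se: float | None = None
    gamma_perp_pi95: np.ndarray | None = None


def velocities(positions, times, lag: int = 1) -> np.ndarray:
    """Finite-difference velocities V(t_i) = (x_{i+lag} - x_i)/(t_{i+lag} - t_i)."""
    x = np.asarray(positions, dtype=float)
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if x.size < lag + 2:
        raise ValueError(f"need at least lag+2 = {lag + 2} points")
    return (x[lag:] - x[:-lag]) / (t[lag:] - t[:-lag])


def principal_axis_projection(x, y) -> np.ndarray:
    """Project 2D positions onto the dominant axis of the displacement.

    The axis is the principal eigenvector of the position covariance; the
    sign is chosen so the net displacement along the axis is non-negative.
    """
    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    proj = pts @ axis
    if proj[-1] < proj[0]:
        proj = -proj
    return proj


def tracks_from_dataframe(df) -> list[TracerTrack]:
    """Build :class:`TracerTrack` objects from a (track, t_s, x_um, y_um) table."""
    tracks = []
    for tid, g in df.groupby("track"):
        g = g.sort_values("t_s")
        pos = principal_axis_projection(g["x_um"].to_numpy(),
                                        g["y_um"].to_numpy())
        tracks.append(TracerTrack(track_id=int(tid),
                                  times=g["t_s"].to_numpy(), positions=pos))
    return tracks


# --------------------------------------------------------------------------
# autocorrelation
# --------------------------------------------------------------------------

def _corr_sums(vel_list: list[np.ndarray], n_lags: int):
    """Per-track sums of V(t) V(t+m) and pair counts for m = 0..n_lags-1."""
    sums = np.zeros((len(vel_list), n_lags))
    counts = np.zeros((len(vel_list), n_lags))
    for i, v in enumerate(vel_list):
        for m in range(min(n_lags, v.size)):
            prod = v[: v.size - m] * v[m:]
            sums[i, m] = prod.sum()
            counts[i, m] = prod.size
    return sums, counts


def autocorrelation(tracks: list[TracerTrack], max_lag: float,
                    n_boot: int = 1000, seed: int = 0,
                    subtract_mean: bool = False) -> VelocityStats:
    """Normalised velocity autocorrelation with a bootstrap 95% band.

    Lags are multiples of the (common) frame interval up to ``max_lag``
    seconds; C(0) = 1 by construction.  The confidence band resamples whole
    tracks (``n_boot`` draws, seeded).
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    if n_boot < 100:
        warnings.warn("n_boot < 100: confidence band will be unreliable")
    dt = float(np.median(np.diff(tracks[0].times)))
    span = min(t.times[-1] - t.times[0] for t in tracks)
    if max_lag >= span:
        raise ValueError("max_lag must be shorter than the shortest track")
    n_lags = int(math.floor(max_lag / dt)) + 1
    vel = []
    for t in tracks:
        v = t.velocities()
        if subtract_mean:
            v = v - v.mean()
        vel.append(v)
    sums, counts = _corr_sums(vel, n_lags)

    def ratio(idx):
        s = sums[idx].sum(axis=0)
        c = counts[idx].sum(axis=0)
        mean = np.divide(s, c, out=np.full(n_lags, np.nan), where=c > 0)
        return mean / mean[0]

    C = ratio(np.arange(len(vel)))
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_lags))
    for b in range(n_boot):
        boots[b] = ratio(rng.integers(0, len(vel), size=len(vel)))
    ci = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return VelocityStats(lags=np.arange(n_lags) * dt, C=C, ci95=ci,
                         n_tracks=len(tracks))


# --------------------------------------------------------------------------
# slowness
# --------------------------------------------------------------------------

def fit_exponential_rate(deviations) -> float:
    """Maximum-likelihood rate of an exponential sample: 1/mean."""
    d = np.asarray(deviations, dtype=float)
    m = d.mean()
    return float(np.inf) if m == 0 else 1.0 / float(m)


def slowness(tracks: list[TracerTrack], n_boot: int = 1000, seed: int = 0):
    """Slowness exponent S_c (s/um) of the |V - Vbar| spectrum, with CI.

    Pools the absolute deviations of each track's velocity from its own mean
    velocity; S_c is the exponential ML rate 1/mean, the CI comes from a
    bootstrap over tracks.  A log-linear histogram fit is returned alongside
    for comparison.  All-constant velocities give S_c = inf.
    """
    devs_per_track = []
    for t in tracks:
        v = t.velocities()
        devs_per_track.append(np.abs(v - v.mean()))
    pooled = np.concatenate(devs_per_track)
    if pooled.size < 50:
        raise ValueError("need at least 50 pooled velocity samples")
    vscale = max(float(np.max(np.abs(np.concatenate(
        [t.velocities() for t in tracks])))), 1e-300)
    if float(pooled.max()) <= 1e-9 * vscale:  # constant-velocity tracks
        S_c = float("inf")
    else:
        S_c = fit_exponential_rate(pooled)
    if not np.isfinite(S_c):
        return {"S_c": float("inf"), "S_c_ci": (float("inf"), float("inf")),
                "S_c_hist": float("inf"), "n_samples": pooled.size,
                "degenerate": True}
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(devs_per_track), size=len(devs_per_track))
        boots.append(fit_exponential_rate(
            np.concatenate([devs_per_track[i] for i in idx])))
    lo, hi = np.percentile(boots, [2.5, 97.5])

    # log-linear histogram fit for comparison with the MLE
    hist, edges = np.histogram(pooled, bins=30, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = hist > 0
    slope = stats.linregress(centers[keep], np.log(hist[keep])).slope
    return {"S_c": S_c, "S_c_ci": (float(lo), float(hi)),
            "S_c_hist": float(-slope), "n_samples": int(pooled.size),
            "degenerate": False}


# --------------------------------------------------------------------------
# strain rates
# --------------------------------------------------------------------------

def _fit_norm_slope(t, L):
    t = np.asarray(t, dtype=float)
    L = np.asarray(L, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 time points")
    L0 = L[0]
    if L0 <= 0:
        raise ValueError("initial dimension L_o must be > 0")
    y = L / L0
    res = stats.linregress(t, y)
    yhat = res.intercept + res.slope * t
    n = t.size
    resid = y - yhat
    s = math.sqrt(float(np.sum(resid ** 2)) / (n - 2)) if n > 2 else 0.0
    tcrit = stats.t.ppf(0.975, max(n - 2, 1))
    sxx = float(np.sum((t - t.mean()) ** 2))
    half = tcrit * s * np.sqrt(1.0 + 1.0 / n + (t - t.mean()) ** 2 / sxx)
    pi = np.vstack([yhat - half, yhat + half])
    return y, float(res.slope), float(res.stderr), pi


def strain_rates(times_par, L_par, times_perp=None, L_perp=None) -> StrainSeries:
    """Strain rates from normalised axial/transverse extents.

    gamma is the OLS slope of L(t)/L_o versus t; a 95% prediction interval
    on the normalised extent is reported with each fit.
    """
    y_par, g_par, se_par, pi_par = _fit_norm_slope(times_par, L_par)
    out = StrainSeries(times_par=np.asarray(times_par, float),
                       L_par_norm=y_par, gamma_par=g_par,
                       gamma_par_se=se_par, gamma_par_pi95=pi_par)
    if times_perp is not None and L_perp is not None:
        y_perp, g_perp, se_perp, pi_perp = _fit_norm_slope(times_perp, L_perp)
        out.times_perp = np.asarray(times_perp, float)
        out.L_perp_norm = y_perp
        out.gamma_perp = g_perp
        out.gamma_perp_se = se_perp
        out.gamma_perp_pi95 = pi_perp
    return out


def transverse_fwhm(profile, pixel_size: float) -> float:
    """Bundle width L_perp as the FWHM of a transverse intensity profile."""
    p = np.asarray(profile, dtype=float)
    base = float(np.min(p))
    half = base + 0.5 * (float(np.max(p)) - base)
    above = np.where(p >= half)[0]
    if above.size < 2:
        raise ValueError("profile has no resolvable width at half maximum")
    return float((above[-1] - above[0] + 1) * pixel_size)
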