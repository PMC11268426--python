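"""Photobleach-line tracking in bundle kymographs.

Two thin lines are bleached across a fluorescent microtubule bundle; their
space-time evolution distinguishes coherent antiparallel filament sliding
(each bleached stripe splits into two counter-moving dips) from telescoping
extension (stripes broaden and drift apart without splitting).  This module
detects the bleach marks in each kymograph frame, tracks them, decides
splitting with a two-vs-one Gaussian BIC test, and extracts

* ``L_cen``: distance between the two marks' intensity-weighted centres of
  mass, with extension speed ``V_cen`` as its ordinary-least-squares slope;
* ``L_split``: mean intra-mark separation of the split sub-bands, with
  splitting speed ``V_split`` as its slope over the post-onset frames.

A mark's centre of mass weighs the split band positions L1, L2 by their
integrated bleach deficits I1, I2 (fitted amplitude x width):
COM = (L1 I1 + L2 I2) / (I1 + I2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths
from scipy.stats import linregress
from statsmodels.stats.proportion import proportion_confint

_SQRT2PI = math.sqrt(2.0 * math.pi)
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> FWHM factor


@dataclass
class Kymograph:
    """Space-time fluorescence image: axis 0 = time, axis 1 = space."""

    intensity: np.ndarray
    pixel_size: float          # um / px
    frame_interval: float      # s
    bleach_frame: int          # first frame at/after the bleach
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph must be 2D (time x space)")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be >= 0")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("calibrations must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.intensity.shape[0]) * self.frame_interval

    @property
    def x(self) -> np.ndarray:
        """Pixel-centre coordinates in um from the left image edge."""
        return (np.arange(self.intensity.shape[1]) + 0.5) * self.pixel_size


@dataclass
class Dip:
    """One detected bleach dip in a single profile."""

    position_um: float
    weight: float        # integrated deficit, amplitude x sigma x sqrt(2 pi)
    fwhm_um: float
    amplitude: float


@dataclass
class BleachMarkTrack:
    """Per-frame state of one bleach mark over the post-bleach frames.

    For unsplit frames ``l1 == l2`` (the single dip position) and the two
    weights each carry half of the dip deficit, so the COM formula applies
    uniformly and reduces to the dip position exactly.
    """

    mark_id: int
    times: np.ndarray
    l1: np.ndarray
    l2: np.ndarray
    i1: np.ndarray
    i2: np.ndarray
    com: np.ndarray
    is_split: np.ndarray       # per-frame boolean
    split_flag: bool = False
    split_onset: int | None = None   # index into the post-bleach frames
    coexist_flag: bool = False
    valid: np.ndarray | None = None

    @property
    def separation(self) -> np.ndarray:
        """Intra-mark split distance, 0 where the mark is unsplit."""
        return np.where(self.is_split, np.abs(self.l2 - self.l1), 0.0)


@dataclass
class BleachKinetics:
    """Kinetic summary of one kymograph."""

    times: np.ndarray
    L_cen: np.ndarray
    L_split: np.ndarray
    V_cen: float               # nm/s
    V_cen_se: float
    V_split: float | None      # nm/s, None when not measurable
    V_split_se: float | None
    classification: str        # {"split", "broadened", "coexisting"}
    n_frames: int
    v_split_reason: str = ""


@dataclass
class BleachConfig:
    """Tunable pipeline thresholds."""

    min_depth_mad: float = 5.0       # dip threshold in MAD units
    smooth_sigma_px: float = 1.0
    max_step_um: float = 1.0         # frame-to-frame association gate
    delta_bic: float = 10.0          # two-vs-one Gaussian evidence gate
    split_fwhm_factor: float = 2.0   # required child separation in FWHM
    confirm_frames: int = 5          # consecutive frames to declare a split
    max_lost_frames: int = 3
    min_child_amp_frac: float = 0.15


# --------------------------------------------------------------------------
# profiles and dip detection
# --------------------------------------------------------------------------

def weighted_com(l1, l2, i1, i2):
    """Intensity-weighted centre of mass (l1*i1 + l2*i2)/(i1 + i2)."""
    return (np.asarray(l1) * np.asarray(i1) + np.asarray(l2) * np.asarray(i2)) \
        / (np.asarray(i1) + np.asarray(i2))


def extract_profiles(kymo: Kymograph, normalize: bool = True) -> np.ndarray:
    """Per-frame 1D intensity profiles, optionally flat-fielded.

    Normalisation divides every frame by the mean pre-bleach profile, which
    removes static labelling inhomogeneity; it requires at least 3 pre-bleach
    frames.
    """
    I = kymo.intensity
    if np.any(I.sum(axis=1) == 0):
        raise ValueError("kymograph contains an all-zero frame")
    if not normalize:
        return I.copy()
    if kymo.bleach_frame < 3:
        raise ValueError("normalization requires >= 3 pre-bleach frames")
    ref = I[:kymo.bleach_frame].mean(axis=0)
    if np.any(ref <= 0):
        raise ValueError("pre-bleach reference profile has non-positive pixels")
    return I / ref[None, :]


def _gauss1(x, a, x0, s, c):
    return c + a * np.exp(-0.5 * ((x - x0) / s) ** 2)


def _gauss2(x, a1, x1, s1, a2, x2, s2, c):
    return (c + a1 * np.exp(-0.5 * ((x - x1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - x2) / s2) ** 2))


def _detection_threshold(profile: np.ndarray, min_depth_mad: float) -> float:
    med = float(np.median(profile))
    mad = 1.4826 * float(np.median(np.abs(profile - med)))
    # absolute floor keeps numerically flat profiles from yielding dips
    return max(min_depth_mad * mad, 0.02 * max(med, 1e-12))


def detect_dips(profile: np.ndarray, pixel_size: float,
                min_depth_mad: float = 5.0,
                smooth_sigma_px: float = 1.0) -> list[Dip]:
    """Detect bleach dips in one profile and refine each by a Gaussian fit.

    The profile is inverted about its median, smoothed, and local maxima of
    the deficit above ``min_depth_mad`` robust noise units are kept.  Each
    dip's weight is its integrated deficit (fitted amplitude x width).  An
    empty list (no dip above threshold) is not an error.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 20:
        raise ValueError("profile too short (< 20 px)")
    x = (np.arange(profile.size) + 0.5) * pixel_size
    med = float(np.median(profile))
    deficit = med - profile
    smooth = gaussian_filter1d(deficit, smooth_sigma_px)
    thr = _detection_threshold(profile, min_depth_mad)
    peaks, props = find_peaks(smooth, height=thr, prominence=0.5 * thr,
                              distance=max(2, int(round(0.5 / pixel_size))))
    dips: list[Dip] = []
    if peaks.size == 0:
        return dips
    widths_px = peak_widths(smooth, peaks, rel_height=0.5)[0]
    for pk, wpx in zip(peaks, widths_px):
        half = max(4, int(round(1.5 * max(wpx, 2.0))))
        lo, hi = max(0, pk - half), min(profile.size, pk + half + 1)
        xs, ys = x[lo:hi], deficit[lo:hi]
        s0 = max(wpx / _FWHM, 0.6) * pixel_size
        p0 = (max(smooth[pk], thr), x[pk], s0, 0.0)
        try:
            popt, _ = curve_fit(
                _gauss1, xs, ys, p0=p0,
                bounds=([0.0, xs[0], 0.3 * pixel_size, -np.inf],
                        [np.inf, xs[-1], (xs[-1] - xs[0]), np.inf]),
                maxfev=2000)
            a, x0, s, _ = popt
        except RuntimeError:
            a, x0, s = p0[0], p0[1], s0
        dips.append(Dip(position_um=float(x0),
                        weight=float(a * s * _SQRT2PI),
                        fwhm_um=float(_FWHM * s),
                        amplitude=float(a)))
    dips.sort(key=lambda d: d.position_um)
    return dips


# --------------------------------------------------------------------------
# mark tracking
# --------------------------------------------------------------------------

def _fit_window(xs, ys, single_guess, pair_guess):
    """Fit one- and two-Gaussian models in a window; return both with BICs."""
    n = xs.size
    out = {}
    try:
        p1, _ = curve_fit(_gauss1, xs, ys, p0=single_guess,
                          bounds=([0.0, xs[0], 1e-3, -np.inf],
                                  [np.inf, xs[-1], xs[-1] - xs[0], np.inf]),
                          maxfev=4000)
        rss1 = float(np.sum((ys - _gauss1(xs, *p1)) ** 2))
    except RuntimeError:
        p1, rss1 = None, np.inf
    try:
        p2, _ = curve_fit(_gauss2, xs, ys, p0=pair_guess,
                          bounds=([0.0, xs[0], 1e-3, 0.0, xs[0], 1e-3, -np.inf],
                                  [np.inf, xs[-1], xs[-1] - xs[0],
                                   np.inf, xs[-1], xs[-1] - xs[0], np.inf]),
                          maxfev=4000)
        rss2 = float(np.sum((ys - _gauss2(xs, *p2)) ** 2))
    except RuntimeError:
        p2, rss2 = None, np.inf
    eps = 1e-300
    out["p1"], out["p2"] = p1, p2
    out["bic1"] = n * math.log(max(rss1, eps) / n) + 4 * math.log(n) \
        if p1 is not None else np.inf
    out["bic2"] = n * math.log(max(rss2, eps) / n) + 7 * math.log(n) \
        if p2 is not None else np.inf
    return out


def _first_run(flags: np.ndarray, run: int) -> int | None:
    count = 0
    for i, f in enumerate(flags):
        count = count + 1 if f else 0
        if count >= run:
            return i - run + 1
    return None


def track_marks(profiles: np.ndarray, pixel_size: float, bleach_frame: int,
                frame_interval: float = 1.0,
                cfg: BleachConfig | None = None) -> tuple[BleachMarkTrack, BleachMarkTrack]:
    """Track the two bleach marks through the post-bleach frames.

    The first post-bleach frame must contain exactly two dips (the freshly
    bleached lines); extra weak detections are discarded with a warning.  A
    mark is declared split when the two-Gaussian description of its window
    beats the single Gaussian by delta-BIC > ``cfg.delta_bic`` with children
    separated by at least ``cfg.split_fwhm_factor`` FWHM, for
    ``cfg.confirm_frames`` consecutive frames.  A persistent third residual
    dip between the split children flags regime coexistence.
    """
    cfg = cfg or BleachConfig()
    post = np.asarray(profiles, dtype=float)[bleach_frame:]
    n_frames, n_px = post.shape
    x = (np.arange(n_px) + 0.5) * pixel_size

    first = detect_dips(post[0], pixel_size, cfg.min_depth_mad,
                        cfg.smooth_sigma_px)
    if len(first) < 2:
        raise ValueError("first post-bleach frame must contain two bleach dips")
    if len(first) > 2:
        warnings.warn(f"{len(first)} dips in first post-bleach frame; "
                      "keeping the two deepest")
        first.sort(key=lambda d: -d.weight)
        first = sorted(first[:2], key=lambda d: d.position_um)
    fwhm0 = float(np.mean([d.fwhm_um for d in first]))
    amp0 = float(np.mean([d.amplitude for d in first]))

    marks = []
    for mid, d in enumerate(first, start=1):
        marks.append({
            "id": mid, "com": d.position_um, "sep": 0.0, "children": None,
            "children_frame": 0, "rec": [], "two_better": np.zeros(n_frames, dtype=bool),
            "valid": np.zeros(n_frames, dtype=bool),
            "resid_central": np.zeros(n_frames, dtype=bool),
            "lost": 0, "truncated_at": None,
        })

    for i in range(n_frames):
        profile = post[i]
        baseline = float(np.median(profile))
        deficit = baseline - profile
        thr = _detection_threshold(profile, cfg.min_depth_mad)
        mids = 0.5 * (marks[0]["com"] + marks[1]["com"])
        for m in marks:
            if m["truncated_at"] is not None:
                continue
            half = max(3.0 * fwhm0, m["sep"] / 2.0 + 3.0 * fwhm0)
            lo_x, hi_x = m["com"] - half, m["com"] + half
            # keep the window on this mark's side of the midline
            if m["com"] < mids:
                hi_x = min(hi_x, mids)
            else:
                lo_x = max(lo_x, mids)
            lo = max(0, int(lo_x / pixel_size))
            hi = min(n_px, int(np.ceil(hi_x / pixel_size)))
            xs, ys = x[lo:hi], deficit[lo:hi]
            if xs.size < 8:
                m["lost"] += 1
                continue
            s0 = fwhm0 / _FWHM
            off = max(m["sep"] / 2.0, 0.5 * fwhm0)
            guess1 = (max(ys.max(), thr), m["com"], max(s0, m["sep"] / 2.0), 0.0)
            guess2 = (max(ys.max(), thr), np.clip(m["com"] - off, xs[0], xs[-1]), s0,
                      max(ys.max(), thr), np.clip(m["com"] + off, xs[0], xs[-1]), s0, 0.0)
            fit = _fit_window(xs, ys, guess1, guess2)
            p1, p2 = fit["p1"], fit["p2"]
            if p1 is None and p2 is None:
                m["lost"] += 1
                if m["lost"] > cfg.max_lost_frames:
                    m["truncated_at"] = i
                    warnings.warn(f"mark {m['id']} lost for more than "
                                  f"{cfg.max_lost_frames} frames; track truncated")
                continue

            two_ok = False
            if p2 is not None and p1 is not None:
                a1, x1, s1, a2, x2, s2, _ = p2
                sep = abs(x2 - x1)
                child_fwhm = _FWHM * 0.5 * (s1 + s2)
                amp_ok = min(a1, a2) >= cfg.min_child_amp_frac * max(p1[0], 1e-12)
                two_ok = (fit["bic1"] - fit["bic2"] > cfg.delta_bic
                          and sep >= cfg.split_fwhm_factor * child_fwhm
                          and amp_ok)
            if two_ok and m["children"] is not None:
                # nearest-neighbour association gate: reject two-Gaussian fits
                # whose children jump from the last accepted positions; the
                # tolerance grows with the gap so a bad lock can recover
                lo_c, hi_c = sorted((p2[1], p2[4]))
                jump = max(abs(lo_c - m["children"][0]),
                           abs(hi_c - m["children"][1]))
                gap = max(1, i - m["children_frame"])
                if jump > cfg.max_step_um * gap:
                    m["valid"][i] = False
                    m["lost"] += 1
                    continue
            m["two_better"][i] = two_ok
            if two_ok:
                m["children"] = tuple(sorted((p2[1], p2[4])))
                m["children_frame"] = i

            # a mark counts as lost when its deficit has faded well below the
            # initial bleach amplitude (per-frame MAD is inflated by moving
            # labelling inhomogeneity, so it is not used here)
            amp_now = p1[0] if p1 is not None else max(p2[0], p2[3])
            if amp_now < 0.2 * amp0:
                m["lost"] += 1
                if m["lost"] > cfg.max_lost_frames:
                    m["truncated_at"] = i
                    warnings.warn(f"mark {m['id']} lost for more than "
                                  f"{cfg.max_lost_frames} frames; track truncated")
                continue
            m["lost"] = 0
            m["valid"][i] = True
            m["rec"].append((i, p1, p2, two_ok))

            if two_ok:
                a1, x1, s1, a2, x2, s2, _ = p2
                w1, w2 = a1 * s1 * _SQRT2PI, a2 * s2 * _SQRT2PI
                com = (x1 * w1 + x2 * w2) / (w1 + w2)
                step_gate = cfg.max_step_um + m["sep"] / 2.0
                if abs(com - m["com"]) <= step_gate:
                    m["com"], m["sep"] = com, abs(x2 - x1)
                # third residual dip between the children -> coexistence
                resid = ys - _gauss2(xs, *p2)
                central = np.abs(xs - com) < max(fwhm0, 0.5 * abs(x2 - x1))
                if central.any() and resid[central].max() > max(thr, 0.4 * amp0):
                    m["resid_central"][i] = True
            elif p1 is not None:
                if abs(p1[1] - m["com"]) <= cfg.max_step_um + m["sep"] / 2.0:
                    m["com"] = float(p1[1])

    tracks = []
    for m in marks:
        onset = _first_run(m["two_better"], cfg.confirm_frames)
        l1 = np.full(n_frames, np.nan)
        l2 = np.full(n_frames, np.nan)
        i1 = np.full(n_frames, np.nan)
        i2 = np.full(n_frames, np.nan)
        com = np.full(n_frames, np.nan)
        is_split = np.zeros(n_frames, dtype=bool)
        for i, p1, p2, two_accept in m["rec"]:
            use_two = onset is not None and i >= onset and two_accept
            if use_two:
                a1, x1, s1, a2, x2, s2, _ = p2
                if x1 > x2:
                    a1, x1, s1, a2, x2, s2 = a2, x2, s2, a1, x1, s1
                l1[i], l2[i] = x1, x2
                i1[i], i2[i] = a1 * s1 * _SQRT2PI, a2 * s2 * _SQRT2PI
                is_split[i] = True
            elif p1 is not None:
                a, x0, s, _ = p1
                w = a * s * _SQRT2PI
                l1[i] = l2[i] = x0
                i1[i] = i2[i] = w / 2.0
            else:
                continue
            com[i] = weighted_com(l1[i], l2[i], i1[i], i2[i])
        coexist = _first_run(m["resid_central"], cfg.confirm_frames) is not None
        tracks.append(BleachMarkTrack(
            mark_id=m["id"],
            times=np.arange(n_frames) * frame_interval,
            l1=l1, l2=l2, i1=i1, i2=i2, com=com, is_split=is_split,
            split_flag=onset is not None, split_onset=onset,
            coexist_flag=coexist, valid=m["valid"]))
    return tracks[0], tracks[1]


# --------------------------------------------------------------------------
# kinetics
# --------------------------------------------------------------------------

def _ols_nm_per_s(t, y):
    res = linregress(t, y)
    return float(res.slope * 1e3), float(res.stderr * 1e3)


def compute_kinetics(track1: BleachMarkTrack, track2: BleachMarkTrack,
                     frame_interval: float,
                     min_fit_frames: int = 5) -> BleachKinetics:
    """Combine two mark tracks into L_cen(t), L_split(t), V_cen and V_split."""
    n = min(track1.com.size, track2.com.size)
    t = np.arange(n) * frame_interval
    both = np.isfinite(track1.com[:n]) & np.isfinite(track2.com[:n])
    if both.sum() < min_fit_frames:
        raise ValueError("fewer than 5 analyzable frames")
    L_cen = np.abs(track2.com[:n] - track1.com[:n])
    V_cen, V_cen_se = _ols_nm_per_s(t[both], L_cen[both])

    sep1 = track1.separation[:n]
    sep2 = track2.separation[:n]
    n_split_marks = int(track1.split_flag) + int(track2.split_flag)
    if n_split_marks == 2:
        L_split = 0.5 * (sep1 + sep2)
    elif n_split_marks == 1:
        L_split = sep1 if track1.split_flag else sep2
    else:
        L_split = np.zeros(n)

    V_split = V_split_se = None
    reason = ""
    if n_split_marks == 2:
        onset = max(track1.split_onset, track2.split_onset)
        sel = (np.arange(n) >= onset) & track1.is_split[:n] & track2.is_split[:n]
        if sel.sum() >= min_fit_frames:
            V_split, V_split_se = _ols_nm_per_s(t[sel], L_split[sel])
        else:
            reason = "fewer than 5 post-onset frames"
    elif n_split_marks == 1:
        reason = "only one mark split"
    else:
        reason = "no mark split"

    if track1.coexist_flag or track2.coexist_flag:
        classification = "coexisting"
    elif n_split_marks >= 1:
        classification = "split"
    else:
        classification = "broadened"

    return BleachKinetics(times=t, L_cen=L_cen, L_split=L_split,
                          V_cen=V_cen, V_cen_se=V_cen_se,
                          V_split=V_split, V_split_se=V_split_se,
                          classification=classification,
                          n_frames=int(both.sum()), v_split_reason=reason)


def splitting_fraction(kinetics_list) -> tuple[float, tuple[float, float]]:
    """Fraction of bundles classified as splitting, with Wilson 95% CI.

    Counts classifications "split" and "coexisting" (a coexisting bundle has
    at least one splitting mark).
    """
    if not kinetics_list:
        raise ValueError("empty kinetics list")
    items = [getattr(k, "classification", k) for k in kinetics_list]
    count = sum(1 for c in items if c in ("split", "coexisting"))
    n = len(items)
    lo, hi = proportion_confint(count, n, alpha=0.05, method="wilson")
    return count / n, (float(lo), float(hi))


def process_kymograph(kymo: Kymograph, cfg: BleachConfig | None = None,
                      normalize: bool = True):
    """Full pipeline: profiles -> mark tracks -> kinetics for one kymograph."""
    cfg = cfg or BleachConfig()
    profiles = extract_profiles(kymo, normalize=normalize)
    t1, t2 = track_marks(profiles, kymo.pixel_size, kymo.bleach_frame,
                         kymo.frame_interval, cfg)
    kin = compute_kinetics(t1, t2, kymo.frame_interval)
    return (t1, t2), kin
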