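"""Weighted least-squares fitting of the bundle scattering model.

Candidate models are a hexagonal-lattice bundle, a rectangular-lattice bundle
of elliptically deformed rods, and an incoherent two-phase coexistence.  The
intensity is linear in the per-phase scale factors and in the background
(constant + power law A*q^-p), so those amplitudes are profiled out by
non-negative linear least squares at every evaluation of the nonlinear
parameters (lattice constants, Debye-Waller disorder, background exponent).
The nonlinear minimisation is bounded trust-region least squares with a
seeded Latin-hypercube multi-start.

Model selection uses BIC = chi^2 + k ln n; the extra-parameter coexistence
model must beat both single-phase models by delta-BIC > 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.stats import qmc

from .saxs_model import (BundleLatticeModel, CrossSection, ScatteringCurve,
                         bundle_intensity)

MODEL_LABELS = ("hex", "rect", "coexist")


@dataclass
class FitConfig:
    """Bounds and search settings for curve fitting."""

    lh_bounds: tuple[float, float] = (30.0, 60.0)
    la_bounds: tuple[float, float] = (15.0, 35.0)
    lb_bounds: tuple[float, float] = (15.0, 35.0)
    disorder_bounds: tuple[float, float] = (0.0, 5.0)
    bg_exponent_bounds: tuple[float, float] = (0.0, 4.0)
    n_starts: int = 6
    n_psi: int = 96           # azimuthal quadrature nodes during fitting
                              # (spectrally exact here; see bundle_intensity)
    n_rods_hex: int = 7
    n_rods_rect: int = 6
    seed: int = 0

    def __post_init__(self):
        for b in (self.lh_bounds, self.la_bounds, self.lb_bounds,
                  self.disorder_bounds, self.bg_exponent_bounds):
            if b[0] > b[1]:
                raise ValueError(f"unordered bounds {b}")
        if self.n_starts < 1:
            raise ValueError("n_starts >= 1")


@dataclass
class FitResult:
    """Best-fit parameters of one model with local 1-sigma uncertainties."""

    model_label: str
    params: dict
    stderr: dict
    chi2: float
    redchi: float
    bic: float
    n_points: int
    n_free: int
    model_I: np.ndarray
    mixture_weight: float | None = None

    def __post_init__(self):
        if self.redchi < 0:
            raise ValueError("reduced chi^2 must be >= 0")


def _param_spec(label: str, cfg: FitConfig):
    """Names and bounds of the nonlinear parameters of a model."""
    if label == "hex":
        names = ["L_h", "disorder_sigma", "bg_exponent"]
        bounds = [cfg.lh_bounds, cfg.disorder_bounds, cfg.bg_exponent_bounds]
    elif label == "rect":
        names = ["L_a", "L_b", "disorder_sigma", "bg_exponent"]
        bounds = [cfg.la_bounds, cfg.lb_bounds, cfg.disorder_bounds,
                  cfg.bg_exponent_bounds]
    elif label == "coexist":
        names = ["L_h", "L_a", "L_b", "disorder_sigma", "bg_exponent"]
        bounds = [cfg.lh_bounds, cfg.la_bounds, cfg.lb_bounds,
                  cfg.disorder_bounds, cfg.bg_exponent_bounds]
    else:
        raise ValueError(f"unknown model label {label!r}")
    return names, np.array(bounds, dtype=float)


def _phase_curves(label: str, theta: dict, q: np.ndarray, cfg: FitConfig):
    """Unit-scale phase intensity curves for the current nonlinear params."""
    curves = []
    if label in ("hex", "coexist"):
        m = BundleLatticeModel(lattice="hexagonal", L_h=theta["L_h"],
                               n_rods=cfg.n_rods_hex,
                               disorder_sigma=theta["disorder_sigma"],
                               cross_section=CrossSection.microtubule())
        curves.append(bundle_intensity(m, q, n_psi=cfg.n_psi).I)
    if label in ("rect", "coexist"):
        la, lb = sorted((theta["L_a"], theta["L_b"]))
        m = BundleLatticeModel(lattice="rectangular", L_a=la, L_b=lb,
                               n_rods=cfg.n_rods_rect,
                               disorder_sigma=theta["disorder_sigma"],
                               cross_section=CrossSection.deformed_microtubule(la, lb))
        curves.append(bundle_intensity(m, q, n_psi=cfg.n_psi).I)
    return curves


def _design_matrix(label, theta, q, cfg):
    cols = _phase_curves(label, theta, q, cfg)
    cols.append(np.ones_like(q))                      # constant background
    cols.append(q ** (-theta["bg_exponent"]))         # power-law background
    return np.column_stack(cols)


def _profiled_residual(x, names, label, q, I, w, cfg):
    theta = dict(zip(names, x))
    B = _design_matrix(label, theta, q, cfg)
    amp, _ = nnls(B * w[:, None], I * w)
    return (B @ amp - I) * w, amp


def fit_curve(curve: ScatteringCurve, model_label: str,
              cfg: FitConfig | None = None) -> FitResult:
    """Fit one lattice model to a measured or synthetic scattering curve.

    Requires positive uncertainties on at least 50 points; points with
    sigma = 0 (or a curve without sigma) fall back to unit weights.
    Multi-start bounded least squares; returns the best start.
    """
    cfg = cfg or FitConfig()
    q, I = curve.q, curve.I
    good = np.isfinite(I)
    if curve.sigma is not None and np.count_nonzero(curve.sigma > 0) >= 50:
        sig = np.where(curve.sigma > 0, curve.sigma, np.inf)
    else:
        sig = np.ones_like(q)
    q, I, sig = q[good], I[good], sig[good]
    if q.size < 50:
        raise ValueError("need >= 50 valid points to fit")
    w = 1.0 / sig

    names, bounds = _param_spec(model_label, cfg)
    sampler = qmc.LatinHypercube(d=len(names), seed=cfg.seed)
    starts = qmc.scale(sampler.random(cfg.n_starts), bounds[:, 0], bounds[:, 1])

    best = None
    failures = []
    for x0 in starts:
        try:
            res = least_squares(
                lambda x: _profiled_residual(x, names, model_label, q, I, w, cfg)[0],
                x0, bounds=(bounds[:, 0], bounds[:, 1]), method="trf",
                xtol=1e-10, ftol=1e-10)
        except Exception as exc:  # pragma: no cover - diagnostics path
            failures.append(str(exc))
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("no fit start converged: " + "; ".join(failures))

    theta = dict(zip(names, best.x))
    _, amp = _profiled_residual(best.x, names, model_label, q, I, w, cfg)
    B = _design_matrix(model_label, theta, q, cfg)
    model_I = B @ amp

    n = q.size
    n_phase = len(amp) - 2
    k = len(names) + len(amp)
    chi2 = float(2.0 * best.cost)
    redchi = chi2 / max(n - k, 1)
    bic = chi2 + k * math.log(n)

    # local quadratic (Gauss-Newton) uncertainties for the nonlinear params
    stderr = {}
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * max(redchi, np.finfo(float).tiny)
        for i, name in enumerate(names):
            stderr[name] = float(np.sqrt(max(cov[i, i], 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        stderr = {name: float("nan") for name in names}

    params = dict(theta)
    if model_label in ("rect", "coexist"):
        la, lb = sorted((params["L_a"], params["L_b"]))
        params["L_a"], params["L_b"] = la, lb
    for i in range(n_phase):
        params[f"scale_{i}"] = float(amp[i])
    params["bg_const"] = float(amp[-2])
    params["bg_amplitude"] = float(amp[-1])

    wmix = None
    if model_label == "coexist":
        tot = amp[0] + amp[1]
        wmix = float(amp[0] / tot) if tot > 0 else float("nan")

    return FitResult(model_label=model_label, params=params, stderr=stderr,
                     chi2=chi2, redchi=redchi, bic=bic, n_points=n,
                     n_free=k, model_I=model_I, mixture_weight=wmix)


def select_model(curve: ScatteringCurve, cfg: FitConfig | None = None,
                 delta_bic_coexist: float = 10.0,
                 delta_bic_tie: float = 2.0):
    """Fit hex, rect and coexistence models and pick the best by BIC.

    The coexistence model is selected only if it beats both single phases by
    more than ``delta_bic_coexist``.  Single-phase candidates within
    ``delta_bic_tie`` of each other set the ``ambiguous`` flag.

    Returns (best_label, results_dict, ambiguous).
    """
    cfg = cfg or FitConfig()
    results = {label: fit_curve(curve, label, cfg) for label in MODEL_LABELS}
    bic_hex = results["hex"].bic
    bic_rect = results["rect"].bic
    best_single = "hex" if bic_hex <= bic_rect else "rect"
    ambiguous = abs(bic_hex - bic_rect) < delta_bic_tie
    best = best_single
    if results["coexist"].bic < min(bic_hex, bic_rect) - delta_bic_coexist:
        best = "coexist"
        ambiguous = False
    return best, results, ambiguous
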