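"""Ground-truth recovery workflows on synthetic data.

Each function generates synthetic data at stated kinematic or structural
parameters, runs the corresponding analysis stage, and returns the recovered
quantity next to the ground truth.  They are the building blocks of the CLI
demo reports and of the reproducibility checks.
"""

from __future__ import annotations

import warnings

import numpy as np

from .bleach import process_kymograph
from .saxs_fit import FitConfig, fit_curve
from .saxs_model import BundleLatticeModel, CrossSection
from .synthetic import (KinematicParams, RenderConfig,
                        exposure_for_peak_snr, lognormal_params,
                        render_kymograph, sample_lengths, simulate_bundle,
                        synthesize_saxs)
from .tracers import strain_rates

#: Pure-sliding per-filament speed used in the splitting-speed recovery:
#: half the measured 0% PEG splitting speed of ~45 nm/s.
V_SLIDE_0PEG = 22.5

#: Measured axial strain rates (1/s) at 0% and 1% PEG.
GAMMA_PAR_0PEG = 8.5e-4
GAMMA_PAR_1PEG = 1.1e-3

#: Measured lattice parameters (nm).
L_H_HEX = 45.8
L_RECT = (20.2, 27.2)


def sliding_identity(v_slide: float = V_SLIDE_0PEG, seed: int = 1) -> dict:
    """Noiseless pure-sliding bundle: recover V_split/V and V_cen.

    Uses an idealised uniform bundle (grid placement, equal lengths, no
    photon noise) so the identities V_split = 2V and V_cen = 0 are tested
    free of sampling artefacts.
    """
    params = KinematicParams(alpha=1.0, v_slide=v_slide, reversal_rate=0.0,
                             noise_sigma=0.0, seed=seed)
    ens = simulate_bundle(params, 800, 260.0, 2.0, extent_um=100.0,
                          lengths=4.9, placement="grid")
    kymo = render_kymograph(ens, RenderConfig(photons_per_px=None, seed=seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, kin = process_kymograph(kymo)
    return {"v_slide": v_slide,
            "V_split": kin.V_split,
            "V_cen": kin.V_cen,
            "ratio": None if kin.V_split is None else kin.V_split / v_slide,
            "classification": kin.classification}


def splitting_speed_recovery(seeds=(1, 2, 3, 4, 5),
                             v_slide: float = V_SLIDE_0PEG,
                             photons_per_px: float = 2000.0) -> dict:
    """Noisy pure-sliding renderings: mean recovered V_split over seeds."""
    per_seed = []
    for seed in seeds:
        params = KinematicParams(alpha=1.0, v_slide=v_slide,
                                 reversal_rate=0.0, noise_sigma=0.0,
                                 seed=seed)
        ens = simulate_bundle(params, 12000, 260.0, 2.0, extent_um=100.0,
                              placement="random")
        kymo = render_kymograph(
            ens, RenderConfig(photons_per_px=photons_per_px, seed=seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, kin = process_kymograph(kymo)
        per_seed.append(kin.V_split)
    good = [v for v in per_seed if v is not None]
    return {"v_slide": v_slide, "expected_V_split": 2.0 * v_slide,
            "per_seed": per_seed, "n_recovered": len(good),
            "mean_V_split": float(np.mean(good)) if good else None}


def strain_rate_recovery(gamma_par: float, duration: float = 900.0,
                         dt: float = 100.0, marker_sep_um: float = 10.0,
                         seed: int = 0) -> dict:
    """Linear-growth marker pair: recover gamma from L(t)/L_o OLS slope."""
    params = KinematicParams(alpha=0.0, gamma_par=gamma_par,
                             growth_mode="linear", noise_sigma=0.0, seed=seed)
    half = marker_sep_um / 2.0
    ens = simulate_bundle(params, 2, duration, dt,
                          initial_positions=np.array([-half, half]),
                          lengths=4.9)
    sep = ens.positions[1] - ens.positions[0]
    fit = strain_rates(ens.times, sep)
    return {"gamma_true": gamma_par, "gamma_fit": fit.gamma_par,
            "gamma_se": fit.gamma_par_se}


def hex_spacing_recovery(seed: int = 0, L_h: float = L_H_HEX,
                         peak_snr: float = 30.0,
                         cfg: FitConfig | None = None) -> dict:
    """Noisy hexagonal-bundle curve: recover the centre-to-centre spacing."""
    model = BundleLatticeModel(lattice="hexagonal", L_h=L_h, n_rods=7,
                               disorder_sigma=1.0)
    exposure = exposure_for_peak_snr(model, peak_snr)
    curve = synthesize_saxs(model, exposure, seed=seed)
    res = fit_curve(curve, "hex", cfg or FitConfig(seed=seed))
    return {"L_h_true": L_h, "L_h_fit": res.params["L_h"],
            "L_h_se": res.stderr["L_h"], "redchi": res.redchi}


def rect_spacing_recovery(seed: int = 0, L_a: float = L_RECT[0],
                          L_b: float = L_RECT[1], peak_snr: float = 30.0,
                          cfg: FitConfig | None = None) -> dict:
    """Noisy rectangular-bundle curve: recover both lattice constants."""
    model = BundleLatticeModel(
        lattice="rectangular", L_a=L_a, L_b=L_b, n_rods=6, disorder_sigma=1.0,
        cross_section=CrossSection.deformed_microtubule(L_a, L_b))
    exposure = exposure_for_peak_snr(model, peak_snr)
    curve = synthesize_saxs(model, exposure, seed=seed)
    res = fit_curve(curve, "rect", cfg or FitConfig(seed=seed))
    return {"L_a_true": L_a, "L_b_true": L_b,
            "L_a_fit": res.params["L_a"], "L_b_fit": res.params["L_b"],
            "smaller_fit": min(res.params["L_a"], res.params["L_b"]),
            "redchi": res.redchi}


def length_distribution_stats(n: int = 100_000, seed: int = 0) -> dict:
    """Sample the length distribution and report mean and closed-form mode."""
    mu, sigma = lognormal_params(4.9, 2.8)
    lengths = sample_lengths(n, seed=seed)
    return {"sample_mean_um": float(np.mean(lengths)),
            "closed_form_mode_um": float(np.exp(mu - sigma ** 2)),
            "mu": mu, "sigma": sigma, "n": n}
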