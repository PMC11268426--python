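import warnings

import numpy as np
import pytest

from mtbundle.bleach import process_kymograph
from mtbundle.synthetic import (KinematicParams, RenderConfig,
                                render_kymograph, simulate_bundle)

V_SLIDE = 22.5          # nm/s, half the measured 0% PEG splitting speed
GAMMA_1PEG = 1.1e-3     # 1/s, measured 1% PEG axial strain rate


def binned_expectation(curve, geom, shape, n_bins, exposure,
                       q_range=(0.075, 2.185)):
    """Expected per-bin mean counts for an isotropic frame of ``curve``.

    Replicates the radial-average binning and averages the continuous
    intensity over each bin's actual pixels, so the comparison is free of
    intra-bin smearing bias.
    """
    rows, cols = np.indices(shape)
    r = np.hypot(rows - geom.center_px[0], cols - geom.center_px[1])
    q = geom.q_of_radius_px(r)
    keep = np.ones(shape, dtype=bool)
    if geom.mask is not None:
        keep &= geom.mask == 0
    lo, hi = q_range
    keep &= (q >= lo) & (q < hi)
    idx = np.clip(np.floor((q[keep] - lo) / (hi - lo) * n_bins).astype(int),
                  0, n_bins - 1)
    expect = exposure * np.interp(q[keep], curve.q, curve.I,
                                  left=0.0, right=0.0)
    n = np.bincount(idx, minlength=n_bins).astype(float)
    tot = np.bincount(idx, weights=expect, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        return tot / n


@pytest.fixture(scope="session")
def sliding_noiseless():
    """Idealised noiseless pure-sliding bundle, rendered and analysed."""
    params = KinematicParams(alpha=1.0, v_slide=V_SLIDE, reversal_rate=0.0,
                             noise_sigma=0.0, seed=1)
    ens = simulate_bundle(params, 800, 260.0, 2.0, extent_um=100.0,
                          lengths=4.9, placement="grid")
    kymo = render_kymograph(ens, RenderConfig(photons_per_px=None, seed=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tracks, kin = process_kymograph(kymo)
    return {"params": params, "ensemble": ens, "kymo": kymo,
            "tracks": tracks, "kinetics": kin}


@pytest.fixture(scope="session")
def extension_noiseless():
    """Idealised noiseless pure-extension (linear growth) bundle."""
    params = KinematicParams(alpha=0.0, gamma_par=GAMMA_1PEG,
                             growth_mode="linear", noise_sigma=0.0, seed=1)
    ens = simulate_bundle(params, 800, 260.0, 2.0, extent_um=100.0,
                          lengths=4.9, placement="grid")
    kymo = render_kymograph(ens, RenderConfig(photons_per_px=None, seed=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tracks, kin = process_kymograph(kymo)
    return {"params": params, "ensemble": ens, "kymo": kymo,
            "tracks": tracks, "kinetics": kin}


@pytest.fixture(scope="session")
def telegraph_tracks():
    """Reversal-rich constant-speed tracks (telegraph velocity process)."""
    from mtbundle.tracers import TracerTrack

    params = KinematicParams(alpha=1.0, v_slide=100.0, reversal_rate=0.05,
                             noise_sigma=0.0, seed=3)
    ens = simulate_bundle(params, 200, 200.0, 1.0, extent_um=400.0,
                          lengths=4.9, placement="grid")
    return [TracerTrack(track_id=i, times=ens.times,
                        positions=ens.positions[i])
            for i in range(ens.n_filaments)]
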