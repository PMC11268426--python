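"""Tests of the synthetic-data generator: lengths, kinematics, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtbundle.synthetic import (KinematicParams, RenderConfig,
                                default_q_grid, emit_tracer_tracks,
                                lognormal_params, render_kymograph,
                                sample_lengths, simulate_bundle,
                                synthesize_saxs)
from mtbundle.saxs_model import BundleLatticeModel, bundle_intensity


class TestLengths:
    def test_closed_form_parameters(self):
        mu, sigma = lognormal_params(4.9, 2.8)
        assert mu == pytest.approx(1.4027, abs=1e-4)
        assert sigma == pytest.approx(0.6108, abs=1e-4)
        # round trip: mean and mode of the parameterised log-normal
        assert np.exp(mu + sigma ** 2 / 2) == pytest.approx(4.9, rel=1e-12)
        assert np.exp(mu - sigma ** 2) == pytest.approx(2.8, rel=1e-12)

    def test_sample_mean_and_mode(self):
        lengths = sample_lengths(100_000, seed=0)
        assert np.mean(lengths) == pytest.approx(4.9, rel=0.01)
        hist, edges = np.histogram(lengths, bins=np.arange(0, 20, 0.5))
        mode_bin = np.argmax(hist)
        assert edges[mode_bin] <= 2.8 <= edges[mode_bin + 1]

    def test_determinism(self):
        assert np.array_equal(sample_lengths(1000, seed=5),
                              sample_lengths(1000, seed=5))

    def test_narrow_limit_collapses_to_mode(self):
        # mean -> mode from above is the sigma -> 0 limit
        lengths = sample_lengths(1000, mean_um=2.8 * (1 + 1e-9),
                                 mode_um=2.8, seed=0)
        assert np.allclose(lengths, 2.8, rtol=1e-3)

    @pytest.mark.parametrize("mean,mode", [(2.8, 4.9), (4.9, 4.9), (4.9, 0.0)])
    def test_invalid_parameterisation(self, mean, mode):
        with pytest.raises(ValueError):
            lognormal_params(mean, mode)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(mean=st.floats(1.0, 20.0), ratio=st.floats(1.01, 3.0))
    def test_parameterisation_solves_constraints(self, mean, ratio):
        mode = mean / ratio
        mu, sigma = lognormal_params(mean, mode)
        assert np.exp(mu + sigma ** 2 / 2) == pytest.approx(mean, rel=1e-9)
        assert np.exp(mu - sigma ** 2) == pytest.approx(mode, rel=1e-9)


class TestKinematics:
    def test_pure_sliding_speeds(self):
        p = KinematicParams(alpha=1.0, v_slide=22.5, reversal_rate=0.0,
                            noise_sigma=0.0)
        ens = simulate_bundle(p, 4, 10.0, 1.0, lengths=4.9,
                              initial_positions=np.arange(4.0))
        v = np.diff(ens.positions, axis=1) / 1.0 * 1e3  # nm/s
        assert np.allclose(np.abs(v), 22.5)
        assert np.allclose(v[::2], 22.5) and np.allclose(v[1::2], -22.5)

    def test_pure_sliding_conserves_extent(self):
        p = KinematicParams(alpha=1.0, v_slide=22.5, reversal_rate=0.0,
                            noise_sigma=0.0)
        ens = simulate_bundle(p, 100, 100.0, 2.0, extent_um=50.0, lengths=4.9)
        plus = ens.positions[ens.polarity[:, 0] == 1]
        extent0 = plus[:, 0].max() - plus[:, 0].min()
        assert np.allclose(plus.max(axis=0) - plus.min(axis=0), extent0)

    def test_linear_marker_separation(self):
        p = KinematicParams(alpha=0.0, gamma_par=8.5e-4, growth_mode="linear",
                            noise_sigma=0.0)
        ens = simulate_bundle(p, 2, 900.0, 1.0, lengths=4.9,
                              initial_positions=np.array([-5.0, 5.0]))
        sep = ens.positions[1] - ens.positions[0]
        assert sep[-1] == pytest.approx(10 * (1 + 0.765), rel=1e-12)
        # affine in t: perfect linear fit
        resid = np.polyfit(ens.times, sep, 1, full=True)[1]
        assert resid[0] == pytest.approx(0.0, abs=1e-18)

    def test_exponential_marker_separation(self):
        p = KinematicParams(alpha=0.0, gamma_par=8.5e-4,
                            growth_mode="exponential", noise_sigma=0.0)
        ens = simulate_bundle(p, 2, 900.0, 1.0, lengths=4.9,
                              initial_positions=np.array([-5.0, 5.0]))
        sep = ens.positions[1] - ens.positions[0]
        assert sep[-1] == pytest.approx(10 * np.exp(0.765), rel=1e-9)

    def test_polarity_half_half(self):
        p = KinematicParams()
        for n in (10, 11):
            ens = simulate_bundle(p, n, 2.0, 1.0, lengths=4.9)
            pos = int(np.sum(ens.polarity[:, 0] == 1))
            assert pos == (n + 1) // 2

    def test_reversal_flip_counts(self):
        k, T = 0.05, 200.0
        p = KinematicParams(alpha=1.0, v_slide=10.0, reversal_rate=k,
                            noise_sigma=0.0, seed=2)
        ens = simulate_bundle(p, 400, T, 1.0, extent_um=100.0, lengths=4.9)
        flips = np.sum(np.diff(ens.polarity.astype(int), axis=1) != 0, axis=1)
        # Poisson(k*T) per track up to discretisation: mean 10 +- a few SE
        assert np.mean(flips) == pytest.approx(k * T, rel=0.1)
        assert np.var(flips) == pytest.approx(k * T, rel=0.25)

    def test_seed_determinism(self):
        p = KinematicParams(alpha=0.5, v_slide=20.0, reversal_rate=0.02,
                            noise_sigma=3.0, seed=7)
        a = simulate_bundle(p, 50, 50.0, 1.0, placement="random")
        b = simulate_bundle(p, 50, 50.0, 1.0, placement="random")
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.polarity, b.polarity)

    def test_undersampled_reversals_warn(self):
        p = KinematicParams(reversal_rate=1.0)
        with pytest.warns(UserWarning, match="undersampled"):
            simulate_bundle(p, 4, 2.0, 1.0, lengths=4.9)


class TestRendering:
    def test_no_op_bleach(self):
        # static bundle: zero-depth bleach must leave every frame unchanged
        p = KinematicParams(alpha=1.0, v_slide=0.0, noise_sigma=0.0)
        ens = simulate_bundle(p, 400, 60.0, 2.0, extent_um=100.0, lengths=4.9)
        cfg = RenderConfig(bleach_depth=0.0, photons_per_px=None, seed=0)
        kymo = render_kymograph(ens, cfg)
        pre = kymo.intensity[kymo.bleach_frame - 1]
        post = kymo.intensity[kymo.bleach_frame + 1]
        assert np.allclose(pre, post, rtol=1e-10)

    def test_poisson_noise_level(self):
        p = KinematicParams(alpha=1.0, v_slide=0.0, noise_sigma=0.0)
        ens = simulate_bundle(p, 2000, 60.0, 2.0, extent_um=120.0, lengths=4.9)
        cfg = RenderConfig(photons_per_px=10_000.0, bleach_depth=0.0, seed=0)
        kymo = render_kymograph(ens, cfg)
        core = kymo.intensity[:, 60:180]
        rel = np.std(core, axis=0) / np.mean(core, axis=0)
        assert np.median(rel) == pytest.approx(0.01, rel=0.25)

    def test_bleach_outside_field_raises(self):
        p = KinematicParams()
        ens = simulate_bundle(p, 10, 40.0, 2.0, lengths=4.9)
        cfg = RenderConfig(bleach_positions=(32.5, 95.0), seed=0)
        with pytest.raises(ValueError, match="outside"):
            render_kymograph(ens, cfg)

    def test_sliding_kymograph_shows_split(self, sliding_noiseless):
        kin = sliding_noiseless["kinetics"]
        assert kin.classification == "split"


class TestTracerExport:
    def _ens(self, **kw):
        p = KinematicParams(alpha=1.0, v_slide=22.5, noise_sigma=0.0,
                            reversal_rate=0.0, **kw)
        return simulate_bundle(p, 20, 20.0, 2.0, extent_um=50.0, lengths=4.9)

    def test_fraction_one_exports_all(self):
        df = emit_tracer_tracks(self._ens(), RenderConfig(tracer_fraction=1.0,
                                                          photons_per_px=None))
        assert df["track"].nunique() == 20

    def test_noiseless_tracks_have_constant_velocity(self):
        df = emit_tracer_tracks(self._ens(), RenderConfig(tracer_fraction=1.0,
                                                          photons_per_px=None))
        for _, g in df.groupby("track"):
            v = np.diff(g["x_um"].to_numpy()) / np.diff(g["t_s"].to_numpy())
            assert np.allclose(v, v[0])

    def test_zero_tracers_raises(self):
        with pytest.raises(ValueError, match="tracer"):
            emit_tracer_tracks(self._ens(), RenderConfig(tracer_fraction=1e-4))


class TestSaxsSynthesis:
    def test_q_grid_endpoints(self):
        q = default_q_grid()
        assert q[0] == pytest.approx(0.075) and q[-1] == pytest.approx(2.185)

    def test_infinite_exposure_is_noiseless(self):
        m = BundleLatticeModel()
        c = synthesize_saxs(m, None)
        ref = bundle_intensity(m, c.q)
        assert np.allclose(c.I, ref.I)

    def test_invalid_exposure(self):
        with pytest.raises(ValueError):
            synthesize_saxs(BundleLatticeModel(), -1.0)

    def test_noise_shrinks_with_exposure(self):
        m = BundleLatticeModel()
        ref = bundle_intensity(m, default_q_grid()).I
        e_lo, e_hi = 1e2 / ref.max(), 1e6 / ref.max()
        lo = synthesize_saxs(m, e_lo, seed=0)
        hi = synthesize_saxs(m, e_hi, seed=0)
        rel_lo = np.median(np.abs(lo.I / e_lo - ref) / ref)
        rel_hi = np.median(np.abs(hi.I / e_hi - ref) / ref)
        assert rel_hi < 0.1 * rel_lo
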