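"""Tests of the SAXS forward model against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.signal import find_peaks
from scipy.special import j0

from mtbundle.saxs_model import (AGBH_D_NM, BundleLatticeModel, CrossSection,
                                 DetectorGeometry,
                                 ScatteringCurve, a_inv_to_nm_inv,
                                 bundle_intensity, cross_section_amplitude,
                                 d_to_q, lattice_positions, mix_phases,
                                 q_to_d, radial_average, structure_average,
                                 subtract_background)
from mtbundle.synthetic import synthesize_detector_image, synthesize_saxs

Q = np.linspace(0.075, 2.185, 400)
CS = CrossSection.microtubule()


def _fft_annulus_amplitude(r_out, r_in, n=4096, extent=512.0):
    """Brute-force oracle: 2D FFT of a rasterised annulus, sampled on axis.

    The annulus is rasterised with linear edge coverage (signed distance
    clipped to one pixel) to suppress edge aliasing.  Returns
    (q, amplitude) along the x axis, normalised to 1 at q = 0.
    """
    dx = extent / n
    ax = (np.arange(n) - n / 2 + 0.5) * dx
    r = np.hypot(ax[None, :], ax[:, None])
    img = (np.clip((r_out - r) / dx + 0.5, 0.0, 1.0)
           - np.clip((r_in - r) / dx + 0.5, 0.0, 1.0))
    F = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
    amp = F[n // 2].real
    amp = amp / amp[n // 2]
    q = np.fft.fftshift(np.fft.fftfreq(n, dx)) * 2 * np.pi
    return q[n // 2:], amp[n // 2:]


class TestCrossSection:
    def test_unit_amplitude_at_zero_q(self):
        assert cross_section_amplitude(CS, 0.0) == pytest.approx(1.0)

    def test_ellipse_with_equal_axes_is_circular(self):
        cse = CrossSection(shape="elliptical", a_out=12.5, b_out=12.5,
                           a_in=8.4, b_in=8.4)
        psi = np.linspace(0, np.pi, 9)
        a = cross_section_amplitude(cse, Q[:, None], psi[None, :])
        b = cross_section_amplitude(CS, Q)[:, None]
        assert np.allclose(a, b, atol=1e-12)

    def test_first_zero_matches_fft_oracle(self):
        q_star = brentq(lambda q: cross_section_amplitude(CS, q), 0.15, 0.45)
        qf, amp = _fft_annulus_amplitude(12.5, 8.4)
        # locate the oracle's first sign change; refine the crossing with a
        # local cubic through the surrounding samples
        sign = np.signbit(amp)
        k = np.argmax(sign[1:] != sign[:-1]) + 1
        lin = qf[k - 1] + (qf[k] - qf[k - 1]) * (
            -amp[k - 1] / (amp[k] - amp[k - 1]))
        sl = slice(max(k - 3, 0), k + 3)
        coeff = np.polyfit(qf[sl], amp[sl], 3)
        q_oracle = min(
            (r.real for r in np.roots(coeff)
             if abs(r.imag) < 1e-9 and qf[sl][0] < r.real < qf[sl][-1]),
            key=lambda x: abs(x - lin))
        assert q_star == pytest.approx(q_oracle, rel=1e-3)

    def test_degenerate_wall_rejected(self):
        with pytest.raises(ValueError):
            CrossSection(shape="circular", r_out=10.0, r_in=10.0)

    def test_deformed_cross_section_preserves_wall_area(self):
        d = CrossSection.deformed_microtubule()
        assert d.wall_area() == pytest.approx(CS.wall_area(), rel=1e-12)
        assert d.a_out == pytest.approx(27.2 / 2)
        assert d.b_out == pytest.approx(20.2 / 2)


class TestLattices:
    def test_hexagonal_first_shell(self):
        pos = lattice_positions(BundleLatticeModel(n_rods=7, L_h=45.8))
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert r[0] == pytest.approx(0.0)
        assert np.allclose(sorted(r)[1:], 45.8)

    def test_rectangular_grid(self):
        m = BundleLatticeModel(lattice="rectangular", L_a=20.2, L_b=27.2,
                               n_rods=6,
                               cross_section=CrossSection.deformed_microtubule())
        pos = lattice_positions(m)
        assert pos.shape == (6, 2)
        assert np.ptp(pos[:, 0]) == pytest.approx(20.2)   # 2 columns along a
        assert np.ptp(pos[:, 1]) == pytest.approx(2 * 27.2)


class TestBundleIntensity:
    def test_single_rod_is_pure_form_factor(self):
        m = BundleLatticeModel(lattice="none", n_rods=1, disorder_sigma=0.0)
        c = bundle_intensity(m, Q)
        f2 = cross_section_amplitude(CS, Q) ** 2
        ratio = c.I * Q / f2
        assert np.allclose(ratio, ratio[0], rtol=1e-12)

    def test_two_rod_closed_form(self):
        m = BundleLatticeModel(lattice="hexagonal", L_h=45.8, n_rods=2,
                               disorder_sigma=0.0)
        s = structure_average(m, Q, force_general=True)
        oracle = 2 * cross_section_amplitude(CS, Q) ** 2 * (1 + j0(Q * 45.8))
        assert np.max(np.abs(s - oracle)) / np.abs(oracle).max() < 1e-6

    def test_seven_rod_hexagonal_peak_position(self):
        qf = np.linspace(0.075, 0.6, 2000)
        m = BundleLatticeModel(lattice="hexagonal", L_h=45.8, n_rods=7,
                               disorder_sigma=0.0)
        s = structure_average(m, qf) / cross_section_amplitude(CS, qf) ** 2 / 7
        peaks, _ = find_peaks(s, prominence=0.1)
        q_peak = qf[peaks[0]]
        assert q_peak == pytest.approx(4 * np.pi / (np.sqrt(3) * 45.8),
                                       rel=0.015)

    def test_fast_path_matches_angular_average(self):
        for model in (
            BundleLatticeModel(lattice="hexagonal", L_h=45.8, n_rods=7,
                               disorder_sigma=0.0),
            BundleLatticeModel(lattice="rectangular", L_a=20.2, L_b=27.2,
                               n_rods=6, disorder_sigma=0.0),
        ):
            fast = structure_average(model, Q)
            gen = structure_average(model, Q, force_general=True)
            assert np.max(np.abs(fast - gen)) / fast.max() < 1e-6

    def test_low_q_structure_approaches_coherent_limit(self):
        # S -> n^2 |F|^2 as q -> 0+, so it exceeds 0.95 n |F|^2
        q0 = np.array([1e-4])
        for n in range(1, 10):
            m = BundleLatticeModel(lattice="hexagonal", L_h=45.8, n_rods=n,
                                   disorder_sigma=0.0)
            s = structure_average(m, q0)[0]
            f2 = cross_section_amplitude(CS, q0[0]) ** 2
            assert s > 0.95 * n * f2
            assert s == pytest.approx(n ** 2 * f2, rel=1e-4)

    def test_debye_waller_damping(self):
        base = bundle_intensity(BundleLatticeModel(disorder_sigma=0.0), Q).I
        prev = base
        for sig in (0.5, 1.0, 2.0):
            cur = bundle_intensity(BundleLatticeModel(disorder_sigma=sig), Q).I
            assert np.all(cur <= prev + 1e-12)
            prev = cur
        assert np.allclose(
            bundle_intensity(BundleLatticeModel(disorder_sigma=0.0), Q).I,
            base)

    def test_scale_linearity(self):
        m = BundleLatticeModel()
        assert np.allclose(bundle_intensity(m, Q, scale=2.0).I,
                           2 * bundle_intensity(m, Q).I)

    def test_zero_q_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="q <= 0"):
            c = bundle_intensity(BundleLatticeModel(), np.array([0.0, 0.1, 0.2]))
        assert c.q.size == 2


class TestCurveOps:
    def _curves(self):
        hexc = bundle_intensity(BundleLatticeModel(), Q, label="hex")
        rect = bundle_intensity(
            BundleLatticeModel(lattice="rectangular", L_a=20.2, L_b=27.2,
                               n_rods=6,
                               cross_section=CrossSection.deformed_microtubule()),
            Q, label="rect")
        return hexc, rect

    @pytest.mark.parametrize("w", [0.0, 0.5, 1.0])
    def test_mixture_endpoints_and_midpoint(self, w):
        hexc, rect = self._curves()
        mixed = mix_phases(hexc, rect, w)
        assert np.allclose(mixed.I, w * hexc.I + (1 - w) * rect.I)

    def test_mixture_grid_mismatch_rejected(self):
        hexc, rect = self._curves()
        other = ScatteringCurve(q=rect.q[:-1], I=rect.I[:-1])
        with pytest.raises(ValueError, match="grid"):
            mix_phases(hexc, other, 0.5)

    def test_background_subtraction_identity_and_zero(self):
        hexc, rect = self._curves()
        assert np.allclose(subtract_background(hexc, rect, 0.0).I, hexc.I)
        assert np.allclose(subtract_background(hexc, hexc, 1.0).I, 0.0)

    def test_background_round_trip(self):
        # composite = bundle + free-tubulin-like power-law background
        hexc, _ = self._curves()
        bg = ScatteringCurve(q=Q, I=0.3 * hexc.I.max() * Q ** -2.0)
        comp = ScatteringCurve(q=Q, I=hexc.I + bg.I,
                               sigma=np.sqrt(hexc.I + bg.I))
        rec = subtract_background(comp, bg, 1.0)
        assert np.allclose(rec.I, hexc.I, rtol=1e-12)
        assert np.all(np.abs(rec.I - hexc.I) <= 3 * np.maximum(rec.sigma, 1e-30))

    def test_background_extrapolation_rejected(self):
        hexc, _ = self._curves()
        short = ScatteringCurve(q=Q[10:], I=hexc.I[10:])
        with pytest.raises(ValueError, match="support"):
            subtract_background(hexc, short, 1.0)


class TestDetector:
    GEOM = DetectorGeometry(pixel_mm=0.3, center_px=(256, 256))

    def test_uniform_image_averages_to_constant(self):
        img = np.full((512, 512), 7.0)
        curve = radial_average(img, self.GEOM, n_bins=64)
        good = ~np.isnan(curve.I)
        assert good.sum() > 32
        assert np.allclose(curve.I[good], 7.0)

    def test_calibrant_ring_q(self):
        assert d_to_q(AGBH_D_NM) == pytest.approx(1.0763, abs=1e-3)
        assert q_to_d(d_to_q(AGBH_D_NM)) == pytest.approx(AGBH_D_NM)

    def test_angstrom_conversion_and_peak_to_diameter(self):
        q_nm = a_inv_to_nm_inv(0.028)
        assert q_nm == pytest.approx(0.28)
        assert round(q_to_d(q_nm)) == 22

    def test_radial_round_trip(self):
        from conftest import binned_expectation

        model = BundleLatticeModel()
        curve = synthesize_saxs(model, None)
        img, mask = synthesize_detector_image(curve, self.GEOM, (512, 512),
                                              exposure=50.0, seed=0)
        geom = DetectorGeometry(pixel_mm=0.3, center_px=(256, 256), mask=mask)
        rec = radial_average(img, geom, n_bins=60)
        expect = binned_expectation(curve, geom, (512, 512), 60, 50.0)
        good = (~np.isnan(rec.I)) & (rec.sigma > 0)
        dev = np.abs(rec.I[good] - expect[good]) \
            / np.maximum(rec.sigma[good], 1e-9)
        assert np.mean(dev <= 3.0) > 0.95

    def test_empty_bins_flagged(self):
        img = np.ones((64, 64))
        curve = radial_average(img, DetectorGeometry(pixel_mm=0.3,
                                                     center_px=(32, 32)),
                               n_bins=64)
        assert np.isnan(curve.I[curve.counts == 0]).all()
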