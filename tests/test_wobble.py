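"""Gabor-transform wobble estimation and order-scaled phase correction."""

import numpy as np
import pytest

from spifi import (
    GaborSpec,
    RotationState,
    WobblePhase,
    apply_wobble_correction,
    estimate_wobble,
    fft_line,
    gabor_transform,
    generate_trace,
)
from spifi.metrics import fwhm
from tests.conftest import N_SAMPLES, NU_C

T = 1.0 / NU_C
RECOVERY_AMP = 0.8      # rad, phase-recovery scenario
BLUR_AMP = 2.0          # rad, strongly wobbled mount for PSF-blur scenario


def sine_wobble(amplitude):
    return lambda t: amplitude * np.sin(2 * np.pi * t / T)


@pytest.fixture(scope="module")
def wobbled_trace(std_mask, std_cursor, point_obj):
    rot = RotationState.make(NU_C, N_SAMPLES, wobble=sine_wobble(RECOVERY_AMP))
    return generate_trace(std_mask, rot, std_cursor, point_obj)


@pytest.fixture(scope="module")
def blurred_trace(std_mask, std_cursor, point_obj):
    rot = RotationState.make(NU_C, N_SAMPLES, wobble=sine_wobble(BLUR_AMP))
    return generate_trace(std_mask, rot, std_cursor, point_obj)


def zero_phase(trace):
    tau = np.linspace(trace.t[0], trace.t[-1], 64)
    return WobblePhase(tau=tau, phi=np.zeros(64), centroid=np.zeros(64),
                       mean_freq=0.0, wg=1e-4)


def order1_width(trace, wphase, q=1):
    spec = fft_line(trace)
    img = apply_wobble_correction(spec, q, wphase, pad=8)
    return fwhm(img.amplitude, img.freq)


class TestGaborTransform:
    def test_window_has_requested_fwhm(self):
        """exp[-4 ln2 (t/wg)^2] evaluates to 1/2 at t = +/- wg/2."""
        wg = 0.01
        for t in (-wg / 2, wg / 2):
            assert np.exp(-4 * np.log(2) * (t / wg) ** 2) == pytest.approx(0.5)

    def test_pure_tone_centroid_is_flat(self):
        n = 4096
        t = np.arange(n) / n
        f0 = 512.0
        z = np.exp(2j * np.pi * f0 * t)
        sg = gabor_transform(z, t, GaborSpec(wg=24 / f0, n_tau=64,
                                             f_range=(0.5 * f0, 1.5 * f0)))
        cen = sg.centroid()
        interior = (sg.tau > sg.tau[0] + 24 / f0) & (sg.tau < sg.tau[-1] - 24 / f0)
        assert np.allclose(cen[interior], f0, rtol=1e-3)

    def test_linear_chirp_centroid_slope(self):
        """Chirp rate alpha recovered from the centroid slope within 2%."""
        n = 8192
        t = np.arange(n) / n
        f0, alpha = 1024.0, 512.0
        z = np.exp(2j * np.pi * (f0 * t + 0.5 * alpha * t ** 2))
        sg = gabor_transform(z, t, GaborSpec(wg=16 / f0, n_tau=128,
                                             f_range=(0.5 * f0, 2.0 * f0)))
        interior = (sg.tau > sg.tau[0] + 32 / f0) & (sg.tau < sg.tau[-1] - 32 / f0)
        slope = np.polyfit(sg.tau[interior], sg.centroid()[interior], 1)[0]
        assert slope == pytest.approx(alpha, rel=0.02)

    def test_too_small_window_rejected(self):
        t = np.arange(256) / 256.0
        with pytest.raises(ValueError, match="window width"):
            gabor_transform(np.ones(256), t, GaborSpec(wg=1e-6, n_tau=16))


class TestEstimateWobble:
    def test_null_case_phase_near_zero(self, point_trace):
        wp = estimate_wobble(point_trace, 1)
        assert np.max(np.abs(wp.phi)) <= 0.05

    def test_sine_wobble_recovered_within_5pc_rms(self, wobbled_trace):
        wp = estimate_wobble(wobbled_trace, 1)
        inj = sine_wobble(RECOVERY_AMP)(wp.tau)
        inj = inj - inj.mean()
        sel = wp.interior()
        err = np.sqrt(np.mean((wp.phi[sel] - inj[sel]) ** 2))
        assert err <= 0.05 * np.sqrt(np.mean(inj[sel] ** 2))

    def test_reference_order_two_returns_order1_phase(self, wobbled_trace):
        """Order 2 carries 2 phi; estimating from it must return phi."""
        wp2 = estimate_wobble(wobbled_trace, 2)
        inj = sine_wobble(RECOVERY_AMP)(wp2.tau)
        inj = inj - inj.mean()
        sel = wp2.interior()
        err = np.sqrt(np.mean((wp2.phi[sel] - inj[sel]) ** 2))
        assert err <= 0.05 * np.sqrt(np.mean(inj[sel] ** 2))

    def test_extended_object_rejected(self, std_mask, std_rot, std_cursor):
        from spifi import SampleObject
        flat = SampleObject(r=std_cursor.r, response=np.ones(std_cursor.r.size))
        tr = generate_trace(std_mask, std_rot, std_cursor, flat)
        with pytest.raises(ValueError, match="point-like"):
            estimate_wobble(tr, 1)


class TestApplyCorrection:
    def test_zero_phase_is_identity(self, point_trace):
        spec = fft_line(point_trace)
        from spifi.reconstruct import order_image
        uncorrected = order_image(spec, 1)
        corrected = apply_wobble_correction(spec, 1, zero_phase(point_trace))
        sel = (corrected.freq >= uncorrected.freq[0]) & \
              (corrected.freq <= uncorrected.freq[-1])
        assert np.allclose(corrected.amplitude[sel], uncorrected.amplitude,
                           rtol=1e-12, atol=1e-9)

    def test_correction_is_unitary_on_band(self, blurred_trace):
        spec = fft_line(blurred_trace)
        wp = estimate_wobble(blurred_trace, 1)
        from spifi.reconstruct import isolate_order
        osig = isolate_order(spec, 1)
        before = np.sum(np.abs(osig.z) ** 2)
        after = np.sum(np.abs(osig.z * np.exp(-1j * wp.interp(osig.t))) ** 2)
        assert after == pytest.approx(before, rel=1e-9)

    def test_correction_restores_point_image_width(
        self, point_trace, blurred_trace
    ):
        """Strong wobble blurs the first-order PSF by >= 1.5x; the measured
        correction restores it to within 10% of the wobble-free width."""
        wp = estimate_wobble(blurred_trace, 1)
        w_free = order1_width(point_trace, zero_phase(point_trace))
        w_unc = order1_width(blurred_trace, zero_phase(blurred_trace))
        w_cor = order1_width(blurred_trace, wp)
        assert w_unc >= 1.5 * w_free
        assert w_cor <= 1.1 * w_free

    def test_wrong_sign_phase_broadens(self, wobbled_trace):
        wp = estimate_wobble(wobbled_trace, 1)
        w_unc = order1_width(wobbled_trace, zero_phase(wobbled_trace))
        flipped = WobblePhase(tau=wp.tau, phi=-wp.phi, centroid=wp.centroid,
                              mean_freq=wp.mean_freq, wg=wp.wg)
        assert order1_width(wobbled_trace, flipped) > w_unc

    def test_phase_measured_once_corrects_other_traces(
        self, std_mask, std_cursor, blurred_trace
    ):
        """The system wobble measured from one emitter corrects an
        independently generated trace sharing the same phi."""
        from spifi.fixtures import make_object
        wp = estimate_wobble(blurred_trace, 1)
        other_obj = make_object("point", r_min=0.0, r_max=4.0,
                                n=std_cursor.r.size, position=2.6)
        rot = RotationState.make(NU_C, N_SAMPLES, wobble=sine_wobble(BLUR_AMP))
        rot0 = RotationState.make(NU_C, N_SAMPLES)
        other_w = generate_trace(std_mask, rot, std_cursor, other_obj)
        other_0 = generate_trace(std_mask, rot0, std_cursor, other_obj)
        w_free = order1_width(other_0, zero_phase(other_0))
        w_cor = order1_width(other_w, wp)
        assert w_cor <= 1.1 * w_free

    def test_narrowing_monotone_in_wobble_amplitude(
        self, std_mask, std_cursor, point_obj, point_trace
    ):
        """Uncorrected/corrected width ratio grows with wobble amplitude
        over the stated grid (single-lobe blur regime)."""
        ratios = []
        for amp in (0.5, 1.0, 1.5, 2.0):
            rot = RotationState.make(NU_C, N_SAMPLES, wobble=sine_wobble(amp))
            tr = generate_trace(std_mask, rot, std_cursor, point_obj)
            wp = estimate_wobble(tr, 1)
            ratios.append(order1_width(tr, zero_phase(tr)) / order1_width(tr, wp))
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_second_order_correction_uses_doubled_phase(
        self, point_trace, wobbled_trace
    ):
        """Correcting order 2 with the order-1 phase record restores the
        order-2 image width (the 2 phi scaling is applied internally);
        order 2 is hit twice as hard by the same mount wobble."""
        wp = estimate_wobble(wobbled_trace, 1)
        w_free = order1_width(point_trace, zero_phase(point_trace), q=2)
        w_unc = order1_width(wobbled_trace, zero_phase(wobbled_trace), q=2)
        w_cor = order1_width(wobbled_trace, wp, q=2)
        assert w_unc >= 1.1 * w_free
        assert w_cor <= 1.02 * w_free

    def test_uncovering_phase_grid_rejected(self, point_trace):
        short = WobblePhase(tau=np.linspace(0, T / 4, 32), phi=np.zeros(32),
                            centroid=np.zeros(32), mean_freq=0.0, wg=1e-4)
        spec = fft_line(point_trace)
        with pytest.raises(ValueError, match="cover"):
            apply_wobble_correction(spec, 1, short)
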