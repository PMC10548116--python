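"""FFT reconstruction: spectra, order isolation, averaging, alignment,
calibration, image assembly, and the enhanced-resolution mechanism."""

import numpy as np
import pytest

from spifi import (
    Calibration,
    LineCursor,
    MaskSpec,
    NoiseSpec,
    RotationState,
    TimeTrace,
    align_to_common_grid,
    assemble_image,
    average_ffts,
    calibrate_frequency_axis,
    fft_line,
    generate_trace,
    isolate_order,
    order_image,
)
from spifi.fixtures import make_object
from spifi.metrics import fwhm, is_resolved
from spifi.reconstruct import feature_peak_frequencies
from tests.conftest import N_CURSOR, NU_C


class TestFftLine:
    def test_pure_sinusoid_hits_single_bin(self):
        n, f0 = 4096, 500.0
        t = np.arange(n) / n  # 1 s span -> 1 Hz bins
        tr = TimeTrace(t=t, signal=np.cos(2 * np.pi * f0 * t), nu_c=1.0)
        spec = fft_line(tr)
        assert spec.freq[np.argmax(spec.amplitude)] == pytest.approx(f0)

    def test_parseval_identity(self):
        rng = np.random.default_rng(0)
        n, dt = 4096, 1e-4
        x = rng.normal(size=n)
        tr = TimeTrace(t=np.arange(n) * dt, signal=x, nu_c=1.0)
        spec = fft_line(tr)
        power = (np.abs(spec.complexv[0]) ** 2
                 + 2 * np.sum(np.abs(spec.complexv[1:-1]) ** 2)
                 + np.abs(spec.complexv[-1]) ** 2) / n
        assert power == pytest.approx(np.sum(x ** 2), rel=1e-9)

    def test_nonuniform_grid_refused(self):
        t = np.array([0.0, 1.0, 2.5, 3.0])
        tr = TimeTrace(t=t, signal=np.zeros(4), nu_c=1.0)
        with pytest.raises(ValueError, match="align_to_common_grid"):
            fft_line(tr)


@pytest.fixture(scope="module")
def two_tone():
    n, dt = 8192, 1e-5
    t = np.arange(n) * dt
    f1 = 2000.0
    sig = np.cos(2 * np.pi * f1 * t) + 0.25 * np.cos(2 * np.pi * 2 * f1 * t)
    tr = TimeTrace(t=t, signal=sig, nu_c=1.0,
                   meta={"pixel_freq_median": f1})
    return fft_line(tr), f1


class TestIsolateOrder:

    def test_isolating_first_order_keeps_only_first_tone(self, two_tone):
        spec, f1 = two_tone
        z = isolate_order(spec, 1)
        zspec = np.abs(np.fft.fft(z.z))
        freqs = np.fft.fftfreq(z.z.size, d=z.dt)
        i1 = np.argmin(np.abs(freqs - f1))
        i2 = np.argmin(np.abs(freqs - 2 * f1))
        assert zspec[i2] < 1e-9 * zspec[i1]

    def test_round_trip_equals_band_masked_spectrum(self, two_tone):
        spec, f1 = two_tone
        z = isolate_order(spec, 1)
        back = 0.5 * np.fft.fft(z.z)
        sel = (spec.freq >= z.band[0]) & (spec.freq <= z.band[1])
        assert np.allclose(back[np.where(sel)[0]], spec.complexv[sel], atol=1e-9)

    def test_auto_band_centres_scale_with_order(self, two_tone):
        spec, f1 = two_tone
        b1 = isolate_order(spec, 1).band
        b2 = isolate_order(spec, 2).band
        c1, c2 = np.mean(b1), np.mean(b2)
        assert c2 == pytest.approx(2 * c1, abs=spec.df)

    def test_band_spanning_two_orders_rejected(self, two_tone):
        spec, f1 = two_tone
        with pytest.raises(ValueError, match="unresolvable"):
            isolate_order(spec, 1, band=(0.6 * f1, 2.4 * f1))


class TestAverageFfts:
    def test_noiseless_average_equals_single_spectrum(self, point_trace):
        av = average_ffts([point_trace] * 4)
        single = fft_line(point_trace)
        assert av.n_averaged == 4
        assert np.allclose(av.amplitude, single.amplitude)

    def test_averaging_improves_peak_snr_like_sqrt_n(
        self, std_mask, std_cursor, point_obj, point_freq
    ):
        """30 replicates with additive noise: background-bin SNR gain ~ sqrt(30)."""
        rot = RotationState.make(NU_C, 2 ** 13)
        traces = [
            generate_trace(std_mask, rot, std_cursor, point_obj,
                           noise=NoiseSpec(additive_rms=0.5, seed=100 + i))
            for i in range(30)
        ]

        def peak_snr(freq, amp):
            bg = (freq > 0.3 * point_freq) & (freq < 0.8 * point_freq)
            sig = np.abs(freq - point_freq) < 3 / rot.period
            return (amp[sig].max() - amp[bg].mean()) / amp[bg].std()

        s1 = fft_line(traces[0])
        av = average_ffts(traces)
        gain = peak_snr(av.freq, av.amplitude) / peak_snr(s1.freq, s1.amplitude)
        assert gain == pytest.approx(np.sqrt(30), rel=0.35)

    def test_magnitude_averaging_beats_raw_averaging_sparse_photons(
        self, std_mask, std_cursor, point_obj, point_freq
    ):
        """With sparse Poisson photons and per-trace carrier phase drift
        (inconsistent rotation trigger), averaging FFT magnitudes preserves
        the image peak while raw-signal averaging washes it out."""
        rot = RotationState.make(NU_C, 2 ** 13)
        traces = [
            generate_trace(
                std_mask, rot, std_cursor, point_obj,
                noise=NoiseSpec(photons_per_sample=2.0,
                                carrier_phase_jitter=1.5, seed=200 + i),
            )
            for i in range(30)
        ]

        def peak_snr(freq, amp):
            bg = (freq > 0.3 * point_freq) & (freq < 0.8 * point_freq)
            sig = np.abs(freq - point_freq) < 3 / rot.period
            return (amp[sig].max() - amp[bg].mean()) / amp[bg].std()

        av = average_ffts(traces)
        raw = TimeTrace(t=traces[0].t,
                        signal=np.mean([tr.signal for tr in traces], axis=0),
                        nu_c=NU_C, meta=traces[0].meta)
        raw_spec = fft_line(raw)
        assert peak_snr(av.freq, av.amplitude) > 1.5 * peak_snr(
            raw_spec.freq, raw_spec.amplitude)

    def test_mixed_grids_rejected(self, point_trace, std_mask, std_cursor, point_obj):
        other = generate_trace(std_mask, RotationState.make(NU_C, 2 ** 13),
                               std_cursor, point_obj)
        with pytest.raises(ValueError, match="common time grid"):
            average_ffts([point_trace, other])


class TestAlignment:
    def _order1_width(self, tr):
        spec = fft_line(tr, pad=8)
        img = order_image(spec, 1)
        return fwhm(img.amplitude, img.freq)

    def test_canonical_trace_unchanged(self, point_trace):
        out = align_to_common_grid(point_trace)
        assert np.allclose(out.signal, point_trace.signal, atol=1e-9)

    def test_speed_drift_recovered(self, std_mask, std_cursor, point_obj):
        """1% rotation-speed drift: post-alignment peak width within 5%
        of the drift-free width."""
        rot0 = RotationState.make(NU_C, 2 ** 13)
        rotd = RotationState.make(NU_C, 2 ** 13, speed_drift=0.01)
        clean = generate_trace(std_mask, rot0, std_cursor, point_obj)
        drifted = generate_trace(std_mask, rotd, std_cursor, point_obj)
        aligned = align_to_common_grid(drifted)
        w0 = self._order1_width(clean)
        assert self._order1_width(drifted) > 2 * w0  # drift really blurs
        assert self._order1_width(aligned) == pytest.approx(w0, rel=0.05)

    def test_single_fiducial_rejected(self, point_trace):
        with pytest.raises(ValueError, match="2 timing fiducials"):
            align_to_common_grid(point_trace, fiducials=[0.001])


class TestCalibration:
    def test_two_points_define_exact_slope(self):
        cal = calibrate_frequency_axis([1000.0, 2000.0], [10.0, 30.0])
        assert cal.slope == pytest.approx(0.02)
        assert cal.slope_err == 0.0

    def test_degenerate_features_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_frequency_axis([500.0, 500.0], [1.0, 2.0])

    def test_bar_target_round_trip_within_one_percent(self):
        """USAF-style bars of known 7.81 um pitch, imaged through the
        forward simulator, recover the true um/Hz slope within 1%."""
        mask = MaskSpec(k=500.0, r0=1.0, r_min=0.0, r_max=0.5)
        rot = RotationState.make(NU_C, 2 ** 13)
        cursor = LineCursor.uniform(0.0, 0.5, 1001)
        obj = make_object("bar_triplet", r_min=0.0, r_max=0.5, n=1001,
                          pitch_um=7.81, center=0.25, bar_width=0.2)
        tr = generate_trace(mask, rot, cursor, obj)
        img = order_image(fft_line(tr, window="hann", pad=8), 1)
        peaks = feature_peak_frequencies(img, 3, half_width=8)
        cal = calibrate_frequency_axis(
            peaks, [c * 1000 for c in obj.meta["bar_centers"]])
        true_slope = 1000.0 / (mask.k * NU_C)  # um per Hz
        assert cal.slope == pytest.approx(true_slope, rel=0.01)


class TestAssembleImage:
    def test_single_row_image(self, point_trace):
        img = order_image(fft_line(point_trace), 1)
        im2 = assemble_image([img], [0.0])
        assert im2.data.shape == (1, img.freq.size)

    def test_row_reversal_flips_image(self, point_trace):
        img = order_image(fft_line(point_trace), 1)
        rows = [img, order_image(fft_line(point_trace), 1)]
        rows[1].amplitude = rows[1].amplitude * 2
        a = assemble_image(rows, [0.0, 1.0])
        b = assemble_image(rows[::-1], [1.0, 0.0])
        assert np.array_equal(a.data, b.data[::-1])

    def test_inconsistent_order_rejected(self, point_trace):
        spec = fft_line(point_trace)
        with pytest.raises(ValueError, match="inconsistent"):
            assemble_image([order_image(spec, 1), order_image(spec, 2)], [0, 1])

    def test_end_to_end_delta_object_argmax(self, std_mask, std_cursor):
        """Scanned delta-like bead lands at its true (y, frequency) pixel."""
        from spifi import scan_object
        rot = RotationState.make(NU_C, 2 ** 13)
        obj2d = make_object("bead_field", seed=11, r_min=0.0, r_max=4.0,
                            n=N_CURSOR, ny=24, y_span_um=12.0, n_beads=1,
                            bead_radius_mm=0.02, bead_radius_um=1.0)
        traces = scan_object(std_mask, rot, std_cursor, obj2d, scan_step=0.5)
        rows = [order_image(fft_line(tr), 1) for tr in traces]
        im2 = assemble_image(rows, [tr.meta["y_commanded_um"] for tr in traces])
        iy, ix = np.unravel_index(np.argmax(im2.data), im2.data.shape)
        bead = obj2d.meta["beads"][0]
        f_bead = std_mask.k * (std_mask.r0 + bead["r_mm"]) * NU_C
        assert abs(im2.y[iy] - bead["y_um"]) <= 0.5
        assert abs(im2.x[ix] - f_bead) <= 1.0 / rot.period


@pytest.fixture(scope="module")
def point_images(point_trace_p2):
    spec = fft_line(point_trace_p2, window="hann", pad=8)
    return order_image(spec, 1), order_image(spec, 2)


class TestEnhancedResolution:
    """Order-2 images carry twice the spatial-frequency support."""

    def test_order2_centred_at_twice_order1(self, point_images, point_freq):
        i1, i2 = point_images
        c1 = i1.freq[np.argmax(i1.amplitude)]
        c2 = i2.freq[np.argmax(i2.amplitude)]
        assert c1 == pytest.approx(point_freq, abs=1.0)
        assert c2 == pytest.approx(2 * c1, rel=1e-6)

    def test_order2_position_fwhm_at_most_06_of_order1(self, point_images):
        i1, i2 = point_images
        cal = Calibration(slope=1.0, slope_err=0.0)
        w1 = fwhm(i1.amplitude, i1.with_calibration(cal).position)
        w2 = fwhm(i2.amplitude, i2.with_calibration(cal).position)
        assert w2 <= 0.6 * w1

    def test_two_point_resolved_only_at_order2(
        self, std_mask, std_rot, std_cursor, point_images
    ):
        """A pair separated by 1.2x the order-1 FWHM is separable at the
        half-maximum level only in the order-2 image."""
        i1, _ = point_images
        w1_hz = fwhm(i1.amplitude, i1.freq)
        sep_mm = 1.2 * w1_hz / (std_mask.k * NU_C)
        obj = make_object("two_point", r_min=0.0, r_max=4.0, n=N_CURSOR,
                          center=1.3, separation=sep_mm)
        tr = generate_trace(std_mask, std_rot, std_cursor, obj, p=2)
        spec = fft_line(tr, window="hann", pad=8)
        assert not is_resolved(order_image(spec, 1).amplitude)
        assert is_resolved(order_image(spec, 2).amplitude)
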