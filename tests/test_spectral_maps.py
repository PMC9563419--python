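import numpy as np
import pytest

from laryngotopo.errors import ConfigurationError, DegenerateInputError, InputError
from laryngotopo.roi_geometry import FoldROI
from laryngotopo.spectral_maps import (
    BrightnessSignal,
    build_ltg_maps,
    compute_spectrum,
    detect_pixel_f0,
    estimate_global_f0,
    pixel_brightness_series,
)
from laryngotopo.video_io import ChannelStack

FPS = 2400.0
T = 480  # 5 Hz bins


def sinus(freq, amp=50.0, base=120.0, phase=0.0, t=T, fps=FPS):
    tt = np.arange(t)
    return base + amp * np.sin(2 * np.pi * freq * tt / fps + phase)


def sig(values):
    return BrightnessSignal(values=np.asarray(values, float), fps=FPS, pixel=(0, 0))


def region_stack(regions=(), shape=(16, 16), base=100.0):
    """Stack with per-region time series; regions is a list of
    (row_slice, col_slice, length-T series)."""
    frames = np.full((T,) + shape, base)
    for rs, cs, v in regions:
        frames[:, rs, cs] = np.asarray(v)[:, None, None]
    return ChannelStack(frames=frames, channel_role="fold_contrast", fps=FPS)


class TestBrightnessSeries:
    def test_constant_stack_gives_constant_signal(self):
        stack = region_stack()
        s = pixel_brightness_series(stack, (3, 4))
        assert (s.values == 100.0).all() and len(s.values) == T

    def test_modulated_pixel_matches_closed_form(self):
        v = sinus(150.0)
        stack = region_stack([(slice(2, 4), slice(2, 4), v)])
        np.testing.assert_allclose(
            pixel_brightness_series(stack, (2, 3)).values, v
        )

    def test_pixel_outside_image_rejected(self):
        with pytest.raises(InputError):
            pixel_brightness_series(region_stack(), (99, 0))


class TestSpectrum:
    def test_bin_centered_sinusoid_amplitude_and_frequency(self):
        """A 280 Hz, amplitude-50 sinusoid over 480 frames at 2400 fps
        shows amplitude ~50 exactly at the 280 Hz bin (bin width 5 Hz)."""
        spec = compute_spectrum(sig(sinus(280.0)))
        k = np.argmin(np.abs(spec.freqs - 280.0))
        assert spec.freqs[k] == 280.0
        assert spec.amplitudes[k] == pytest.approx(50.0, abs=1e-9)
        assert np.argmax(spec.amplitudes) == k

    def test_constant_signal_has_empty_spectrum(self):
        spec = compute_spectrum(sig(np.full(T, 42.0)))
        assert spec.amplitudes.max() < 1e-9

    def test_two_bin_centered_sinusoids_match_direct_dft_oracle(self):
        v = sinus(150.0, amp=7.0) + sinus(300.0, amp=3.0, base=0.0)
        spec = compute_spectrum(sig(v))
        # independent oracle: project onto the complex exponentials
        tt = np.arange(T)
        for f, amp in [(150.0, 7.0), (300.0, 3.0)]:
            k = int(round(f * T / FPS))
            coef = np.abs(np.sum((v - v.mean()) * np.exp(-2j * np.pi * k * tt / T)))
            assert spec.amplitudes[k] == pytest.approx(2 * coef / T, abs=1e-9)
            assert spec.amplitudes[k] == pytest.approx(amp, abs=1e-6)

    def test_phases_lie_in_half_open_pi_interval(self):
        spec = compute_spectrum(sig(sinus(150.0, phase=2.5)))
        assert (spec.phases > -np.pi).all() and (spec.phases <= np.pi).all()

    def test_parseval_power_equals_time_domain_variance(self):
        rng = np.random.default_rng(5)
        v = rng.normal(100, 20, 481)  # odd length: no Nyquist bin
        spec = compute_spectrum(BrightnessSignal(values=v, fps=FPS, pixel=(0, 0)))
        power = (spec.amplitudes[1:] ** 2).sum() / 2
        assert power == pytest.approx(v.var(), rel=1e-9)

    def test_short_signal_rejected(self):
        with pytest.raises(InputError):
            compute_spectrum(sig(np.arange(8.0)))


class TestPixelF0Detection:
    def test_bin_centered_peak_detected_exactly(self):
        assert detect_pixel_f0(compute_spectrum(sig(sinus(280.0)))) == 280.0

    def test_constant_signal_yields_none(self):
        assert detect_pixel_f0(compute_spectrum(sig(np.full(T, 7.0)))) is None

    def test_strongest_band_peak_wins(self):
        v = sinus(150.0, amp=40.0) + sinus(300.0, amp=5.0, base=0.0)
        assert detect_pixel_f0(compute_spectrum(sig(v))) == 150.0

    def test_empty_band_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_pixel_f0(compute_spectrum(sig(sinus(150.0))), band=(400, 70))

    @pytest.mark.parametrize("f_true", [132.0, 217.3, 281.0])
    def test_off_bin_frequency_recovered_within_one_bin(self, f_true):
        f_est = detect_pixel_f0(compute_spectrum(sig(sinus(f_true))))
        assert abs(f_est - f_true) <= FPS / T


def full_roi(shape):
    mask = np.ones(shape, dtype=bool)
    return mask


class TestGlobalF0:
    def test_uniformly_vibrating_roi(self):
        stack = region_stack([(slice(0, 16), slice(0, 16), sinus(150.0))])
        assert estimate_global_f0(stack, full_roi((16, 16))) == 150.0

    def test_amplitude_weighted_mode_matches_histogram_oracle(self):
        """Half the pixels at 150 Hz / amplitude 50, half at 300 Hz /
        amplitude 5: the strong frequency wins the weighted vote."""
        stack = region_stack(
            [
                (slice(0, 8), slice(0, 16), sinus(150.0, amp=50.0)),
                (slice(8, 16), slice(0, 16), sinus(300.0, amp=5.0)),
            ]
        )
        roi = full_roi((16, 16))
        f0 = estimate_global_f0(stack, roi)
        # oracle: per-pixel peaks and amplitudes accumulated by hand
        votes = {150.0: 8 * 16 * 50.0, 300.0: 8 * 16 * 5.0}
        assert f0 == max(votes, key=votes.get) == 150.0

    def test_static_stack_degenerate(self):
        with pytest.raises(DegenerateInputError):
            estimate_global_f0(region_stack(), full_roi((16, 16)))


class TestLTGMaps:
    @pytest.fixture()
    def two_region_stack(self):
        """Region A amplitude 50 (normalizes to 1.0), region B amplitude
        4 (normalizes to 0.08), region C amplitude 6 (0.12)."""
        return region_stack(
            [
                (slice(0, 4), slice(0, 16), sinus(150.0, amp=50.0)),
                (slice(6, 10), slice(0, 16), sinus(150.0, amp=4.0)),
                (slice(12, 16), slice(0, 16), sinus(150.0, amp=6.0)),
            ]
        )

    def test_threshold_semantics_at_0p1(self, two_region_stack):
        """Normalized amplitude 0.08 is below the 0.1 vibrating cutoff,
        0.12 is above it."""
        maps = build_ltg_maps(two_region_stack, full_roi((16, 16)), 150.0)
        assert maps.amp_map[0, 0] == pytest.approx(1.0)
        assert maps.amp_map[6, 0] == pytest.approx(0.08, abs=1e-9)
        assert maps.amp_map[12, 0] == pytest.approx(0.12, abs=1e-9)
        assert maps.vibrating_mask[0, 0]
        assert not maps.vibrating_mask[6, 0]
        assert maps.vibrating_mask[12, 0]

    def test_uniform_vibration_marks_entire_roi(self):
        stack = region_stack([(slice(0, 16), slice(0, 16), sinus(150.0))])
        maps = build_ltg_maps(stack, full_roi((16, 16)), 150.0)
        assert maps.vibrating_mask.all()

    def test_amplitude_normalization_max_is_exactly_one(self, two_region_stack):
        maps = build_ltg_maps(two_region_stack, full_roi((16, 16)), 150.0)
        assert np.nanmax(maps.amp_map) == 1.0

    def test_amplitude_map_invariant_to_brightness_scaling(self, two_region_stack):
        maps1 = build_ltg_maps(two_region_stack, full_roi((16, 16)), 150.0)
        scaled = ChannelStack(
            frames=two_region_stack.frames * 2.0,
            channel_role="fold_contrast",
            fps=FPS,
        )
        maps2 = build_ltg_maps(scaled, full_roi((16, 16)), 150.0)
        np.testing.assert_allclose(maps2.amp_map, maps1.amp_map, rtol=1e-9)

    def test_phase_difference_between_regions(self):
        stack = region_stack(
            [
                (slice(0, 8), slice(0, 16), sinus(150.0, phase=0.0)),
                (slice(8, 16), slice(0, 16), sinus(150.0, phase=np.pi / 2)),
            ]
        )
        maps = build_ltg_maps(stack, full_roi((16, 16)), 150.0)
        diff = maps.phase_map[8, 0] - maps.phase_map[0, 0]
        assert diff == pytest.approx(np.pi / 2, abs=1e-9)
        valid = ~np.isnan(maps.phase_map)
        assert (maps.phase_map[valid] > -np.pi).all()
        assert (maps.phase_map[valid] <= np.pi).all()

    def test_glare_pixels_excluded_from_maps_and_mask(self, two_region_stack):
        glare = np.zeros((16, 16), dtype=bool)
        glare[0, 0] = True
        maps = build_ltg_maps(two_region_stack, full_roi((16, 16)), 150.0, glare=glare)
        assert np.isnan(maps.amp_map[0, 0])
        assert not maps.vibrating_mask[0, 0]
        assert maps.vibrating_mask[0, 1]

    def test_per_pixel_f0_map_carries_own_peaks(self):
        stack = region_stack(
            [
                (slice(0, 8), slice(0, 16), sinus(150.0)),
                (slice(8, 16), slice(0, 16), sinus(280.0)),
            ]
        )
        maps = build_ltg_maps(stack, full_roi((16, 16)), 150.0)
        assert maps.f0_map[0, 0] == 150.0
        assert maps.f0_map[8, 0] == 280.0

    def test_strict_mode_drops_pixels_at_other_frequencies(self):
        """A pixel oscillating strongly at 280 Hz leaks little into the
        150 Hz bin, but a strong off-frequency pixel within one bin
        stays; strict mode additionally requires the pixel's own peak
        near the global F0."""
        stack = region_stack(
            [
                (slice(0, 8), slice(0, 16), sinus(150.0)),
                (slice(8, 16), slice(0, 16), sinus(280.0, amp=50.0)),
            ]
        )
        loose = build_ltg_maps(stack, full_roi((16, 16)), 150.0)
        strict = build_ltg_maps(stack, full_roi((16, 16)), 150.0, strict_f0=True)
        assert strict.vibrating_mask[0:8].all()
        assert not strict.vibrating_mask[8:16].any()
        assert strict.vibrating_mask.sum() <= loose.vibrating_mask.sum()

    def test_static_roi_degenerate(self):
        with pytest.raises(DegenerateInputError):
            build_ltg_maps(region_stack(), full_roi((16, 16)), 150.0)

    def test_threshold_outside_unit_interval_rejected(self, two_region_stack):
        with pytest.raises(ConfigurationError):
            build_ltg_maps(
                two_region_stack, full_roi((16, 16)), 150.0, amp_threshold=1.5
            )
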