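import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmoct import BandSpec, DynamicImage, ValidationError
from dmoct.dyncontrast import (
    average_repeats,
    band_bin_indices,
    band_integrals,
    histogram_match,
    moving_std_reference,
    normalize_channels,
    projection,
    spectrum_frequencies,
    temporal_spectrum,
)

from conftest import make_series


def dft_magnitude_oracle(signal):
    """Direct O(n^2) DFT magnitude summation, independent of numpy's FFT."""
    n = len(signal)
    ks = np.arange(n // 2 + 1)
    mags = []
    for k in ks:
        re = sum(signal[t] * np.cos(-2 * np.pi * k * t / n) for t in range(n))
        im = sum(signal[t] * np.sin(-2 * np.pi * k * t / n) for t in range(n))
        mags.append(np.hypot(re, im))
    return np.array(mags)


class TestTemporalSpectrum:
    def test_constant_series_is_dc_only(self):
        series = make_series(np.full((16, 2, 2), 3.5))
        spec, freqs = temporal_spectrum(series)
        assert spec[0, 0, 0] == pytest.approx(3.5 * 16)
        assert np.allclose(spec[1:], 0.0, atol=1e-9)
        assert freqs[0] == 0.0

    def test_bin_centered_sinusoid_closed_form(self):
        # amplitude-b sinusoid at bin 14 of a 150-frame series -> magnitude b*n/2
        n, rate, k, b = 150, 111.0, 14, 0.25
        t = np.arange(n) / rate
        f = k * rate / n  # ~10.36 Hz
        sig = 2.0 + b * np.cos(2 * np.pi * f * t + 0.7)
        series = make_series(np.tile(sig[:, None, None], (1, 1, 1)))
        spec, freqs = temporal_spectrum(series)
        assert freqs[k] == pytest.approx(10.36, abs=0.01)
        assert spec[k, 0, 0] == pytest.approx(b * n / 2, rel=1e-9)
        ac = spec[1:, 0, 0].copy()
        ac[k - 1] = 0.0
        assert np.all(ac < 1e-9 * b * n)

    def test_frequency_axis_tops_out_at_nyquist(self):
        freqs = spectrum_frequencies(150, 111.0)
        assert freqs[-1] == pytest.approx(55.5)

    def test_agrees_with_direct_dft_oracle(self, rng):
        data = rng.uniform(0.1, 2.0, size=(16, 8, 8))
        series = make_series(data)
        spec, _ = temporal_spectrum(series)
        for (z, x) in [(0, 0), (3, 5), (7, 7)]:
            oracle = dft_magnitude_oracle(data[:, z, x])
            ref = np.abs(oracle).max()
            assert np.all(np.abs(spec[:, z, x] - oracle) <= 1e-6 * ref)

    def test_rejects_single_frame(self):
        with pytest.raises(ValidationError):
            temporal_spectrum(make_series(np.ones((1, 2, 2))))


class TestBandIntegrals:
    def test_default_bin_assignment_150_frames_111hz(self, default_bands):
        freqs = spectrum_frequencies(150, 111.0)
        slow, med, fast = band_bin_indices(freqs, default_bands)
        # brute-force bin-center arithmetic oracle
        df = 111.0 / 150
        expect = {"slow": [], "med": [], "fast": []}
        for k in range(len(freqs)):
            f = k * df
            if 0 <= f < 0.5:
                expect["slow"].append(k)
            elif 0.5 <= f < 5:
                expect["med"].append(k)
            elif 5 <= f < 25:
                expect["fast"].append(k)
        assert list(slow) == expect["slow"] == [0]
        assert list(med) == expect["med"] == list(range(1, 7))
        assert list(fast) == expect["fast"] == list(range(7, 34))

    def test_dc_only_signal_zero_green_red(self, default_bands):
        series = make_series(np.full((150, 2, 2), 2.0))
        spec, freqs = temporal_spectrum(series)
        img = band_integrals(spec, freqs, default_bands)
        assert np.allclose(img.rgb[..., 0], 0.0, atol=1e-9)  # red
        assert np.allclose(img.rgb[..., 1], 0.0, atol=1e-9)  # green
        assert np.all(img.rgb[..., 2] > 0)  # blue holds DC

    def test_bin_centered_fast_sinusoid_all_in_red(self, default_bands):
        n, rate = 150, 111.0
        t = np.arange(n) / rate
        f = 14 * rate / n
        sig = 1.0 + 0.3 * np.cos(2 * np.pi * f * t)
        series = make_series(np.tile(sig[:, None, None], (1, 2, 2)))
        spec, freqs = temporal_spectrum(series)
        img = band_integrals(spec, freqs, default_bands)
        red, green = img.rgb[0, 0, 0], img.rgb[0, 0, 1]
        assert red == pytest.approx(0.3 * n / 2, rel=1e-9)
        assert green <= 1e-6 * red

    def test_band_completeness(self, rng, default_bands):
        data = rng.uniform(0.1, 1.0, size=(50, 6, 6))
        series = make_series(data)
        spec, freqs = temporal_spectrum(series)
        img = band_integrals(spec, freqs, default_bands)
        covered = spec[freqs < default_bands.fast[1]].sum(axis=0)
        assert np.allclose(img.rgb.sum(axis=-1), covered, rtol=1e-12)

    def test_empty_band_raises_with_name(self):
        freqs = spectrum_frequencies(10, 111.0)  # df = 11.1 Hz, medium band empty
        with pytest.raises(ValidationError, match="medium"):
            band_bin_indices(freqs, BandSpec())


class TestNormalizeChannels:
    def _image(self, arr):
        return DynamicImage(rgb=arr, bands=BandSpec(), n_frames_used=10)

    def test_affine_midpoint(self):
        ch = np.array([[2.0, 6.0], [10.0, 2.0]])
        img = self._image(np.stack([ch, ch, ch], axis=-1))
        out = normalize_channels(img)
        assert out.rgb[0, 1, 0] == pytest.approx(0.5)
        assert out.normalization_state == "normalized"

    def test_constant_channel_maps_to_zero(self):
        rgb = np.ones((3, 3, 3)) * 4.2
        out = normalize_channels(self._image(rgb))
        assert np.all(out.rgb == 0.0)

    @settings(max_examples=25, deadline=None)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-5.0, 5.0),
           seed=st.integers(0, 2**16))
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        rgb = rng.uniform(0.0, 3.0, size=(5, 4, 3))
        base = normalize_channels(self._image(rgb))
        scaled = normalize_channels(self._image(a * rgb + b))
        assert np.allclose(base.rgb, scaled.rgb, atol=1e-9)

    def test_attains_zero_and_one(self, rng):
        rgb = rng.uniform(1.0, 7.0, size=(6, 6, 3))
        out = normalize_channels(self._image(rgb))
        for c in range(3):
            assert out.rgb[..., c].min() == 0.0
            assert out.rgb[..., c].max() == 1.0


class TestMovingStdReference:
    def test_constant_stack_gives_zero(self):
        series = make_series(np.full((30, 4, 4), 2.0))
        assert np.allclose(moving_std_reference(series, 25), 0.0)

    def test_window_equal_n_frames_is_global_sd(self, rng):
        data = rng.uniform(0.1, 2.0, size=(20, 5, 5))
        series = make_series(data)
        ref = moving_std_reference(series, window=20)
        assert np.allclose(ref, data.std(axis=0, ddof=1), rtol=1e-10)

    def test_iid_gaussian_recovers_sigma(self):
        rng = np.random.default_rng(42)
        sigma = 0.35
        data = np.abs(10.0 + rng.normal(0, sigma, size=(60, 100, 120)))
        series = make_series(data)
        ref = moving_std_reference(series, window=25)
        # mean windowed sample SD is slightly below sigma (SD bias); 5% covers it
        assert abs(ref.mean() - sigma) / sigma < 0.05

    def test_brute_force_window_oracle(self, rng):
        data = rng.uniform(0.1, 3.0, size=(12, 3, 4))
        series = make_series(data)
        window = 5
        ref = moving_std_reference(series, window)
        expect = np.mean(
            [data[i:i + window].std(axis=0, ddof=1)
             for i in range(12 - window + 1)], axis=0)
        assert np.allclose(ref, expect, rtol=1e-6)

    @pytest.mark.parametrize("window", [1, 0, 31])
    def test_window_out_of_range(self, window):
        series = make_series(np.ones((30, 2, 2)))
        with pytest.raises(ValidationError):
            moving_std_reference(series, window)


class TestHistogramMatch:
    def _normalized(self, rng, shape=(40, 40)):
        rgb = rng.uniform(0, 1, size=shape + (3,))
        img = DynamicImage(rgb=rgb, bands=BandSpec(), n_frames_used=10,
                           normalization_state="normalized")
        return img

    def test_self_match_is_near_identity(self, rng):
        img = self._normalized(rng)
        out = histogram_match(img, img.rgb[..., 0])
        assert np.allclose(out.rgb[..., 0], img.rgb[..., 0], atol=1.5 / 256)

    def test_matches_bimodal_reference_ks(self, rng):
        img = self._normalized(rng, shape=(120, 120))  # >= 10^4 pixels
        ref = np.concatenate([
            rng.normal(0.25, 0.03, 7200), rng.normal(0.75, 0.03, 7200)
        ]).reshape(120, 120)
        out = histogram_match(img, ref)
        # KS distance between matched channel and reference (oracle: empirical CDFs)
        a = np.sort(out.rgb[..., 1].ravel())
        ref_scaled = (ref - ref.min()) / (ref.max() - ref.min())
        b = np.sort(ref_scaled.ravel())
        grid = np.linspace(0, 1, 2001)
        cdf_a = np.searchsorted(a, grid, side="right") / a.size
        cdf_b = np.searchsorted(b, grid, side="right") / b.size
        assert np.abs(cdf_a - cdf_b).max() < 0.02

    def test_rank_order_never_inverted(self, rng):
        img = self._normalized(rng)
        ref = rng.normal(0.5, 0.2, size=(40, 40))
        out = histogram_match(img, ref)
        for c in range(3):
            x = img.rgb[..., c].ravel()
            y = out.rgb[..., c].ravel()
            order = np.argsort(x, kind="stable")
            assert np.all(np.diff(y[order]) >= -1e-12)

    def test_grid_mismatch_raises(self, rng):
        img = self._normalized(rng)
        with pytest.raises(ValidationError):
            histogram_match(img, np.zeros((10, 10)))

    def test_requires_normalized_state(self, rng):
        img = DynamicImage(rgb=rng.uniform(0, 5, (4, 4, 3)), bands=BandSpec(),
                           n_frames_used=10)
        with pytest.raises(ValidationError):
            histogram_match(img, np.zeros((4, 4)))


class TestAverageRepeats:
    def _img(self, rgb, state="normalized"):
        return DynamicImage(rgb=rgb, bands=BandSpec(), n_frames_used=10,
                            normalization_state=state)

    def test_five_identical_images(self, rng):
        rgb = rng.uniform(0, 1, (5, 5, 3))
        out = average_repeats([self._img(rgb.copy()) for _ in range(5)])
        assert np.allclose(out.rgb, rgb)
        assert out.normalization_state == "averaged"

    def test_order_invariance(self, rng):
        imgs = [self._img(rng.uniform(0, 1, (4, 4, 3))) for _ in range(4)]
        a = average_repeats(imgs)
        b = average_repeats(imgs[::-1])
        assert np.allclose(a.rgb, b.rgb)

    def test_elementwise_mean_oracle(self, rng):
        stacks = [rng.uniform(0, 1, (3, 3, 3)) for _ in range(3)]
        out = average_repeats([self._img(s) for s in stacks])
        expect = (stacks[0] + stacks[1] + stacks[2]) / 3.0
        assert np.allclose(out.rgb, expect)

    def test_mixed_states_rejected(self, rng):
        a = self._img(rng.uniform(0, 1, (4, 4, 3)), "normalized")
        b = self._img(rng.uniform(0, 1, (4, 4, 3)), "histogram_matched")
        with pytest.raises(ValidationError):
            average_repeats([a, b])


class TestProjection:
    def test_constant_stack(self):
        series = make_series(np.full((10, 3, 3), 1.5))
        assert np.allclose(projection(series, "max"), 1.5)
        assert np.allclose(projection(series, "std"), 0.0)

    def test_single_bright_frame(self):
        data = np.ones((10, 4, 4))
        data[3, 2, 2] = 9.0
        series = make_series(data)
        assert projection(series, "max")[2, 2] == 9.0

    def test_std_equals_full_window_moving_std(self, rng):
        data = rng.uniform(0.1, 2.0, size=(15, 4, 4))
        series = make_series(data)
        assert np.allclose(projection(series, "std"),
                           moving_std_reference(series, window=15), rtol=1e-10)

    def test_unknown_method(self):
        with pytest.raises(ValidationError):
            projection(make_series(np.ones((5, 2, 2))), "median")


class TestBandSpec:
    def test_default_edges(self, default_bands):
        assert default_bands.intervals == ((0.0, 0.5), (0.5, 5.0), (5.0, 25.0))

    def test_rejects_overlapping_bands(self):
        with pytest.raises(ValidationError):
            BandSpec(slow=(0, 1.0), medium=(0.5, 5.0))

    def test_rejects_fast_band_above_nyquist(self, default_bands):
        with pytest.raises(ValidationError):
            default_bands.validate_against_rate(40.0)
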