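import numpy as np
import pytest

from pxafkit.sigproc import (DenoiseConfig, PipelineConfig, envelope,
                             normalize_maxabs, preprocess_segment,
                             recurrence_image, shannon_energy,
                             wavelet_denoise)
from pxafkit.types import (DegenerateInputError, ECGSegment,
                           InvalidParameterError)

FS = 128.0


class TestWaveletDenoise:
    def test_perfect_reconstruction_when_keeping_all_bands(self, rng):
        x = rng.standard_normal(512)
        cfg = DenoiseConfig(detail_levels_kept=frozenset(range(1, 11)),
                            keep_final_approximation=True)
        y = wavelet_denoise(x, FS, cfg)
        assert np.linalg.norm(y - x) / np.linalg.norm(x) < 1e-8

    def test_zero_input_gives_zero_output(self):
        y = wavelet_denoise(np.zeros(512), FS)
        assert np.allclose(y, 0.0)

    def test_output_length_preserved(self, rng):
        for n in (500, 512, 1000):
            assert wavelet_denoise(rng.standard_normal(n), FS).size == n

    def test_high_frequency_tone_suppressed(self, sinus_segment_4s):
        # a 55 Hz tone lives in the first detail band (32-64 Hz at 128 Hz),
        # which the default configuration discards
        from scipy.signal import periodogram
        clean = sinus_segment_4s.signals[0]
        t = np.arange(clean.size) / FS
        tone = 0.5 * np.sin(2 * np.pi * 55.0 * t)
        den = wavelet_denoise(clean + tone, FS)

        def band_power(x, lo=50.0, hi=60.0):
            f, p = periodogram(x, fs=FS)
            return p[(f >= lo) & (f <= hi)].sum()

        assert band_power(den) / band_power(clean + tone) < 0.05

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(InvalidParameterError):
            DenoiseConfig(wavelet_name="not-a-wavelet")

    def test_invalid_detail_levels_rejected(self):
        with pytest.raises(InvalidParameterError):
            DenoiseConfig(detail_levels_kept=frozenset({11}))


class TestNormalize:
    def test_definition(self):
        np.testing.assert_allclose(normalize_maxabs([2.0, -4.0, 1.0]),
                                   [0.5, -1.0, 0.25])

    def test_idempotent(self):
        x = np.array([0.5, -1.0, 0.25])
        np.testing.assert_allclose(normalize_maxabs(x), x)

    def test_single_negative(self):
        np.testing.assert_allclose(normalize_maxabs([-3.0]), [-1.0])

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_maxabs(np.zeros(10))


class TestShannonEnergy:
    def test_unit_amplitude_maps_near_zero(self):
        y = shannon_energy(np.array([1.0, -1.0]), bias=1e-12).values
        assert np.abs(y).max() < 1e-10

    def test_closed_form_at_exp_minus_half(self):
        y = shannon_energy(np.array([np.exp(-0.5)]), bias=1e-15).values
        assert abs(y[0] - (-np.exp(-1.0))) < 1e-9

    def test_zero_input_finite(self):
        y = shannon_energy(np.zeros(4), bias=1e-6).values
        assert np.isfinite(y).all()
        np.testing.assert_allclose(y, 1e-6 * np.log(1e-6))

    def test_nonpositive_bias_rejected(self):
        with pytest.raises(InvalidParameterError):
            shannon_energy(np.zeros(4), bias=0.0)


class TestEnvelope:
    def test_512_samples_40_windows(self, rng):
        env = envelope(rng.standard_normal(512), 40)
        assert env.values.size == 40

    def test_constant_series(self):
        env = envelope(np.full(512, 3.25), 40)
        np.testing.assert_allclose(env.values, 3.25)

    def test_window_means_match_brute_force(self, rng):
        y = rng.standard_normal(512)
        env = envelope(y, 40)
        bounds = np.round(np.arange(41) * 512 / 40).astype(int)
        expected = [y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        np.testing.assert_allclose(env.values, expected)

    def test_too_many_windows_rejected(self):
        with pytest.raises(InvalidParameterError):
            envelope(np.zeros(10), 11)


class TestRecurrenceImage:
    def test_two_point_distance(self):
        img = recurrence_image(np.array([0.0, 1.0]))
        np.testing.assert_allclose(img.matrix, [[0, 1], [1, 0]])

    def test_symmetry_and_zero_diagonal(self, rng):
        img = recurrence_image(rng.standard_normal(40))
        assert np.array_equal(img.matrix, img.matrix.T)
        assert np.all(img.matrix.diagonal() == 0.0)
        assert np.all(img.matrix >= 0.0)

    def test_binary_mode_brute_force(self):
        img = recurrence_image(np.array([1.0, 2.0, 4.0]), mode="binary",
                               threshold_frac=0.4)
        expected = [[1, 1, 0], [1, 1, 0], [0, 0, 1]]
        np.testing.assert_allclose(img.matrix, expected)

    def test_constant_envelope_binary_all_ones(self):
        img = recurrence_image(np.full(5, 2.0), mode="binary",
                               threshold_frac=0.5)
        assert np.all(img.matrix == 1.0)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidParameterError):
            recurrence_image(np.array([1.0]))


class TestPipeline:
    def test_4s_segment_yields_40x40(self, sinus_segment_4s):
        img = preprocess_segment(sinus_segment_4s)
        assert img.matrix.shape == (40, 40)

    def test_deterministic(self, sinus_segment_4s):
        a = preprocess_segment(sinus_segment_4s)
        b = preprocess_segment(sinus_segment_4s)
        assert np.array_equal(a.matrix, b.matrix)

    def test_amplitude_invariance(self, sinus_segment_4s):
        scaled = ECGSegment(5.0 * sinus_segment_4s.signals, FS)
        a = preprocess_segment(sinus_segment_4s,
                               cfg=PipelineConfig(scale_to_unit=False))
        b = preprocess_segment(scaled, cfg=PipelineConfig(scale_to_unit=False))
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)

    def test_lead_selection(self, sinus_segment_4s):
        a = preprocess_segment(sinus_segment_4s, lead=0)
        b = preprocess_segment(sinus_segment_4s, lead=1)
        assert not np.array_equal(a.matrix, b.matrix)
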