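import itertools

import numpy as np
import pytest
from scipy.signal import butter, freqz, periodogram

from pxafkit.evalkit import (ConfusionCounts, NoiseSpec, add_noise,
                             confusion_from_labels, metrics, noise_sweep,
                             roc_curve)
from pxafkit.types import (DegenerateInputError, ECGSegment,
                           InvalidParameterError)


def mann_whitney_auc(labels, scores):
    """Oracle: concordance probability over all positive/negative pairs."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_classifier(self):
        acc, sens, spec = metrics(ConfusionCounts(1, 1, 0, 0))
        assert (acc, sens, spec) == (1.0, 1.0, 1.0)

    def test_worked_counts(self):
        acc, sens, spec = metrics(ConfusionCounts(tp=27, tn=22, fp=0, fn=1))
        assert acc == pytest.approx(49 / 50)
        assert sens == pytest.approx(27 / 28)
        assert spec == 1.0

    def test_missing_sensitivity(self):
        acc, sens, spec = metrics(ConfusionCounts(tp=0, tn=5, fp=2, fn=0))
        assert np.isnan(sens) and spec == pytest.approx(5 / 7)

    def test_weighted_identity(self, rng):
        # (TP+TN) = sens*(TP+FN) + spec*(TN+FP) whenever both are defined
        for _ in range(50):
            c = ConfusionCounts(*(int(v) for v in rng.integers(1, 30, 4)))
            acc, sens, spec = metrics(c)
            lhs = c.tp + c.tn
            rhs = sens * (c.tp + c.fn) + spec * (c.tn + c.fp)
            assert lhs == pytest.approx(rhs)
            assert min(sens, spec) - 1e-12 <= acc <= max(sens, spec) + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_confusion_from_labels(self):
        c = confusion_from_labels([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)


class TestRocCurve:
    def test_perfect_separation(self):
        _, auc = roc_curve([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_uninformative_scores(self):
        _, auc = roc_curve([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_four_point_hand_example(self):
        _, auc = roc_curve([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidParameterError):
            roc_curve([1, 1], [0.1, 0.2])

    def test_equals_mann_whitney_on_exhaustive_small_inputs(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 13))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
            _, auc = roc_curve(labels, scores)
            assert auc == pytest.approx(mann_whitney_auc(labels, scores))

    def test_points_monotone(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        points, _ = roc_curve(labels, rng.random(50))
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)


class TestAddNoise:
    def make_segment(self, rng):
        return ECGSegment(rng.standard_normal((2, 1280)), 128.0)

    def test_realized_snr_exact(self, rng):
        seg = self.make_segment(rng)
        noisy = add_noise(seg, NoiseSpec(kind="white", snr_db=10.0, seed=1))
        noise = noisy.signals - seg.signals
        snr = 10 * np.log10(np.mean(seg.signals ** 2, axis=1)
                            / np.mean(noise ** 2, axis=1))
        np.testing.assert_allclose(snr, 10.0, atol=0.01)

    def test_high_snr_limit(self, rng):
        seg = self.make_segment(rng)
        noisy = add_noise(seg, NoiseSpec(kind="white", snr_db=120.0, seed=2))
        rel = np.linalg.norm(noisy.signals - seg.signals) \
            / np.linalg.norm(seg.signals)
        assert rel < 1e-5

    def test_color_noise_suppresses_top_band(self, rng):
        seg = self.make_segment(rng)
        white = add_noise(seg, NoiseSpec("white", 0.0, seed=3)).signals \
            - seg.signals
        color = add_noise(seg, NoiseSpec("color", 0.0, seed=3)).signals \
            - seg.signals

        def band_power(x, lo=60.0):
            f, p = periodogram(x[0], fs=128.0)
            return p[f >= lo].sum()

        # zero-phase order-4 filter at 50 Hz: >= 10 dB down above 60 Hz
        ratio_db = 10 * np.log10(band_power(white) / band_power(color))
        assert ratio_db >= 10.0

    def test_zero_power_rejected(self):
        seg = ECGSegment(np.zeros((2, 128)), 128.0)
        with pytest.raises(DegenerateInputError):
            add_noise(seg, NoiseSpec("white", 10.0))

    def test_butterworth_definition(self):
        # unit DC gain and -3 dB at the 50 Hz cutoff (single pass)
        b, a = butter(4, 50.0 / 64.0, btype="low")
        w, h = freqz(b, a, worN=[0.0, 50.0 / 64.0 * np.pi])
        assert abs(h[0]) == pytest.approx(1.0, abs=1e-9)
        assert abs(h[1]) == pytest.approx(1 / np.sqrt(2), abs=1e-9)


class TestNoiseSweep:
    def test_empty_snr_list(self):
        assert noise_sweep(lambda segs: [], [], [], "white") == {}

    def test_perfect_oracle_classifier_at_high_snr(self, rng):
        from pxafkit.ecg_synth import synth_dataset
        segs = synth_dataset(4, 4, 4.0, seed=8)

        def oracle(noisy):
            # label-aware stand-in classifier: exercises only the harness
            return [1 if s.label == "pxaf" else 0 for s in noisy]

        sweep = noise_sweep(oracle, segs, [120.0, 0.0], "white", seed=0)
        assert sweep[120.0] == 1.0 and sweep[0.0] == 1.0
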