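import numpy as np
import pytest

from pxafkit.ecg_synth import (DefectSpec, Morphology, SynthParams,
                               inject_defect, r_peak_times, synth_dataset,
                               synth_pxaf, synth_sinus)
from pxafkit.features import detect_r_peaks
from pxafkit.types import ECGSegment, InvalidParameterError

from conftest import record_to_segment


class TestSinusGeneration:
    def test_sample_count(self):
        rec = synth_sinus(SynthParams(duration_s=60.0, fs=128.0,
                                      mean_hr_bpm=75.0, seed=0))
        assert rec.signals.shape == (2, 7680)

    def test_two_leads_always(self):
        rec = synth_sinus(SynthParams(duration_s=4.0, seed=5))
        assert rec.n_leads == 2

    def test_fixed_rate_spacing(self):
        params = SynthParams(duration_s=10.0, mean_hr_bpm=60.0,
                             hr_variation_bpm=0.0, rr_irregularity=0.0,
                             noise_std_mv=0.0, seed=0)
        spacings = np.diff(r_peak_times(params, "sinus"))
        assert np.all(np.abs(spacings - 1.0) <= 1.0 / params.fs)

    def test_deterministic(self):
        p = SynthParams(duration_s=5.0, seed=11)
        a = synth_sinus(p)
        b = synth_sinus(p)
        assert np.array_equal(a.signals, b.signals)

    def test_bounded_amplitude_and_finite(self):
        rec = synth_sinus(SynthParams(duration_s=20.0, noise_std_mv=0.5,
                                      seed=7))
        assert np.isfinite(rec.signals).all()
        assert np.abs(rec.signals).max() <= 2.0

    @pytest.mark.parametrize("bad", [
        dict(duration_s=0.0), dict(duration_s=4.0, fs=-1.0),
        dict(duration_s=4.0, mean_hr_bpm=0.0),
        dict(duration_s=4.0, rr_irregularity=-0.1),
    ])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            SynthParams(**bad)


class TestPxafGeneration:
    def test_rr_cv_matches_request(self):
        params = SynthParams(duration_s=60.0, mean_hr_bpm=90.0,
                             hr_variation_bpm=0.0, rr_irregularity=0.2,
                             seed=3)
        rr = np.diff(r_peak_times(params, "pxaf"))
        cv = rr.std() / rr.mean()
        assert abs(cv - 0.2) <= 0.05

    def test_p_wave_suppression(self):
        base = dict(duration_s=10.0, mean_hr_bpm=75.0, hr_variation_bpm=0.0,
                    noise_std_mv=0.0, seed=4)
        sinus = synth_sinus(SynthParams(**base))
        gone = synth_pxaf(SynthParams(**base, rr_irregularity=0.0,
                                      p_wave_gain=0.0))
        peaks = r_peak_times(SynthParams(**base), "sinus")
        fs = 128.0

        def p_window_max(sig, r_times):
            vals = []
            for r in r_times[1:]:
                lo, hi = int((r - 0.25) * fs), int((r - 0.15) * fs)
                if 0 <= lo < hi <= sig.shape[1]:
                    vals.append(np.abs(sig[0, lo:hi]).max())
            return max(vals)

        assert p_window_max(gone.signals, peaks) <= \
            0.10 * p_window_max(sinus.signals, peaks) + 1e-9

    def test_degenerate_equals_sinus(self):
        base = dict(duration_s=8.0, mean_hr_bpm=80.0, seed=9)
        sinus = synth_sinus(SynthParams(**base))
        pxaf = synth_pxaf(SynthParams(**base, rr_irregularity=0.0,
                                      p_wave_gain=1.0))
        assert np.array_equal(sinus.signals, pxaf.signals)


class TestDefectInjection:
    def make_segment(self, seed=0, dur=10.0):
        params = SynthParams(duration_s=dur, mean_hr_bpm=90.0,
                             rr_irregularity=0.2, p_wave_gain=0.2, seed=seed)
        return record_to_segment(synth_pxaf(params))

    def test_directive4_adds_detectable_peaks(self):
        # 5-beat segment: spacing ~0.8 s at 75 BPM over 4.3 s
        params = SynthParams(duration_s=4.3, mean_hr_bpm=75.0,
                             hr_variation_bpm=0.0, seed=1)
        seg = record_to_segment(synth_sinus(params))
        n_before = detect_r_peaks(seg).size
        assert n_before == 5
        bad = inject_defect(seg, DefectSpec(4, severity=1.0, seed=3))
        assert detect_r_peaks(bad).size >= 6

    @pytest.mark.parametrize("directive", [1, 2, 3, 4, 5])
    def test_severity_zero_limit_is_identity(self, directive):
        seg = self.make_segment(seed=directive)
        out = inject_defect(seg, DefectSpec(directive, severity=1e-6, seed=1))
        noise_budget = 3 * 0.02 + 1e-3
        assert np.abs(out.signals - seg.signals).max() <= noise_budget

    def test_unknown_directive_rejected(self):
        with pytest.raises(InvalidParameterError):
            DefectSpec(directive_id=6)

    def test_deterministic(self):
        seg = self.make_segment(seed=5)
        a = inject_defect(seg, DefectSpec(2, 0.8, seed=9))
        b = inject_defect(seg, DefectSpec(2, 0.8, seed=9))
        assert np.array_equal(a.signals, b.signals)


class TestDatasetSynthesis:
    def test_counts_shapes_labels(self):
        segs = synth_dataset(100, 100, 4.0, seed=1)
        assert len(segs) == 200
        assert all(s.n_samples == 512 for s in segs)
        assert sum(s.label == "normal" for s in segs) == 100
        assert sum(s.label == "pxaf" for s in segs) == 100

    def test_pxaf_only(self):
        segs = synth_dataset(0, 5, 4.0, seed=2)
        assert [s.label for s in segs] == ["pxaf"] * 5

    def test_reproducible(self):
        a = synth_dataset(3, 3, 4.0, seed=7)
        b = synth_dataset(3, 3, 4.0, seed=7)
        assert all(np.array_equal(x.signals, y.signals)
                   for x, y in zip(a, b))
        assert [s.label for s in a] == [s.label for s in b]
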