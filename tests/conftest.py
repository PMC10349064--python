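import numpy as np
import pytest

from pxafkit.ecg_synth import SynthParams, synth_pxaf, synth_sinus
from pxafkit.types import ECGSegment


def record_to_segment(rec) -> ECGSegment:
    return ECGSegment(rec.signals, rec.fs, label=rec.label,
                      source_record=rec.record_id)


@pytest.fixture(scope="session")
def sinus_segment_10s() -> ECGSegment:
    """Regular 75-BPM sinus fixture, 10 s, no rate modulation."""
    params = SynthParams(duration_s=10.0, mean_hr_bpm=75.0,
                         hr_variation_bpm=0.0, seed=1)
    return record_to_segment(synth_sinus(params))


@pytest.fixture(scope="session")
def pxaf_segment_10s() -> ECGSegment:
    """Irregular PxAF fixture (CV 0.2, suppressed P-waves), 10 s."""
    params = SynthParams(duration_s=10.0, mean_hr_bpm=90.0,
                         hr_variation_bpm=0.0, rr_irregularity=0.2,
                         p_wave_gain=0.2, seed=2)
    return record_to_segment(synth_pxaf(params))


@pytest.fixture(scope="session")
def sinus_segment_4s() -> ECGSegment:
    params = SynthParams(duration_s=4.0, mean_hr_bpm=75.0,
                         hr_variation_bpm=0.0, seed=3)
    return record_to_segment(synth_sinus(params))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
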