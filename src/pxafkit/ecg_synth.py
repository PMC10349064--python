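"""Synthetic 2-lead ECG generation: sinus rhythm, PxAF, and defect variants.

The generator builds each cardiac cycle from five Gaussian wave kernels
(P, Q, R, S, T) placed relative to the R-peak time — the standard
synthetic-ECG construction based on a quasi-periodic dynamical model.
It provides controllable ground truth (R-peak times, RR intervals, QRS
width, P-wave amplitude) for every downstream stage:

* sinus rhythm: smooth respiratory heart-rate modulation, full P-waves,
  regular RR intervals;
* paroxysmal atrial fibrillation (PxAF): multiplicative log-normal RR
  jitter with a requested coefficient of variation, and attenuated /
  time-jittered P-waves;
* defect variants emulating the five rejection directives used to screen
  generative-model outputs (bizarre shape, distorted sub-interval,
  inconsistent QRS, spurious R-peaks, partial PxAF).

All randomness flows through one ``numpy`` Generator seeded per call, so
identical parameters and seed give bit-identical signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .types import ECGRecord, ECGSegment, InvalidParameterError

__all__ = [
    "SynthParams",
    "Morphology",
    "DefectSpec",
    "synth_sinus",
    "synth_pxaf",
    "inject_defect",
    "synth_dataset",
]


@dataclass
class SynthParams:
    """Parameters of the quasi-periodic ECG generator.

    duration_s : total record duration (s), > 0.
    fs : sampling frequency (Hz), default 128.
    mean_hr_bpm : mean heart rate (beats/min), > 0.
    hr_variation_bpm : amplitude of the respiratory sinus modulation; the
        instantaneous rate stays within ``mean_hr_bpm +- hr_variation_bpm``.
    rr_irregularity : coefficient of variation of the RR intervals in
        [0, 1]; 0 gives metronomic beats, PxAF fixtures use ~0.15-0.3.
    p_wave_gain : P-wave amplitude multiplier in [0, 1]; 1 = full P-wave,
        0 = absent (atrial-fibrillation-like).
    noise_std_mv : additive white measurement noise (mV).
    seed : integer seed; all randomness derives from it.
    amp_limit_mv : hard amplitude bound; output is clipped to +- this.
    """

    duration_s: float
    fs: float = 128.0
    mean_hr_bpm: float = 75.0
    hr_variation_bpm: float = 3.0
    rr_irregularity: float = 0.0
    p_wave_gain: float = 1.0
    noise_std_mv: float = 0.02
    seed: int = 0
    amp_limit_mv: float = 2.0

    def __post_init__(self) -> None:
        if not self.duration_s > 0 or not self.fs > 0:
            raise InvalidParameterError("duration_s and fs must be positive")
        if round(self.duration_s * self.fs) < 1:
            raise InvalidParameterError("duration_s * fs must round to >= 1 sample")
        if not self.mean_hr_bpm > 0:
            raise InvalidParameterError("mean_hr_bpm must be positive")
        if self.rr_irregularity < 0:
            raise InvalidParameterError("rr_irregularity must be >= 0")
        if not 0.0 <= self.p_wave_gain <= 1.0:
            raise InvalidParameterError("p_wave_gain must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class Morphology:
    """Wave-kernel shape parameters for one cardiac cycle (lead 0).

    Offsets are seconds relative to the R-peak; amplitudes in mV; widths
    are Gaussian sigmas in seconds.  ``qrs_duration_s`` sets the total
    Q-to-S extent; Q/S placement and widths scale with it.  The second
    lead is the same template scaled by ``lead2_scale`` with a slightly
    larger T-wave, mimicking a two-channel recording.
    """

    p_offset_s: float = 0.20
    p_amp_mv: float = 0.15
    p_sigma_s: float = 0.025
    qrs_duration_s: float = 0.08
    q_amp_mv: float = -0.12
    r_amp_mv: float = 1.0
    s_amp_mv: float = -0.18
    t_offset_s: float = 0.30
    t_amp_mv: float = 0.35
    t_sigma_s: float = 0.06
    lead2_scale: float = 0.65
    lead2_t_boost: float = 1.3

    def wave_table(self, rr_s: float, p_gain: float, lead: int) -> list[tuple[float, float, float]]:
        """(offset, amplitude, sigma) triples for one beat at a given RR."""
        q = self.qrs_duration_s
        # collision guards at high heart rate: pull P and T toward the R-peak
        p_off = min(self.p_offset_s, 0.40 * rr_s)
        t_off = min(self.t_offset_s, 0.50 * rr_s)
        scale = 1.0 if lead == 0 else self.lead2_scale
        t_scale = scale * (1.0 if lead == 0 else self.lead2_t_boost)
        return [
            (-p_off, p_gain * self.p_amp_mv * scale, self.p_sigma_s),
            (-0.32 * q, self.q_amp_mv * scale, 0.11 * q),
            (0.0, self.r_amp_mv * scale, 0.16 * q),
            (+0.32 * q, self.s_amp_mv * scale, 0.11 * q),
            (+t_off, self.t_amp_mv * t_scale, self.t_sigma_s),
        ]


@dataclass
class DefectSpec:
    """Which rejection directive to emulate, how strongly, and the seed."""

    directive_id: int
    severity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.directive_id not in (1, 2, 3, 4, 5):
            raise InvalidParameterError(
                f"directive_id must be in 1..5, got {self.directive_id}"
            )
        if not 0.0 < self.severity <= 1.0:
            raise InvalidParameterError("severity must be in (0, 1]")


# ---------------------------------------------------------------------------
# rhythm generation

def _rr_sequence(params: SynthParams, rng: np.random.Generator,
                 irregular: bool) -> np.ndarray:
    """RR interval sequence (s) covering the record duration plus margin."""
    rrs = []
    t = 0.0
    phase0 = rng.uniform(0, 2 * np.pi)
    cv = params.rr_irregularity if irregular else 0.0
    sigma = np.sqrt(np.log1p(cv * cv))  # log-normal CV -> sigma
    while t < params.duration_s + 2.0:
        hr = params.mean_hr_bpm + params.hr_variation_bpm * np.sin(
            2 * np.pi * 0.25 * t + phase0
        )
        rr = 60.0 / hr
        # multiplicative log-normal jitter with unit mean; sigma=0 -> factor 1
        z = rng.standard_normal()
        rr = rr * np.exp(sigma * z - 0.5 * sigma * sigma)
        rrs.append(rr)
        t += rr
    return np.asarray(rrs)


def _render(params: SynthParams, rng: np.random.Generator,
            irregular: bool, p_gain: float,
            morphology: Morphology | None) -> tuple[np.ndarray, np.ndarray]:
    """Render the 2-lead signal; returns (signals, r_peak_times)."""
    morph = morphology or Morphology()
    n = params.n_samples
    t_axis = np.arange(n) / params.fs
    sig = np.zeros((2, n))

    rrs = _rr_sequence(params, rng, irregular)
    r_times = 0.35 + np.concatenate([[0.0], np.cumsum(rrs)])
    # P-wave timing jitter grows as the P-wave is suppressed (fibrillatory
    # atrial activity); one draw per beat, consumed even when gain = 1 so
    # that degenerate PxAF parameters reproduce the sinus signal exactly.
    p_jit = rng.normal(0.0, 0.02 * (1.0 - p_gain), size=r_times.size)

    for k, (r_t, rr) in enumerate(zip(r_times, np.append(rrs, rrs[-1]))):
        if r_t - 0.5 > params.duration_s:
            break
        lo = max(0, int((r_t - 0.45) * params.fs))
        hi = min(n, int((r_t + 0.6) * params.fs) + 1)
        if lo >= hi:
            continue
        tt = t_axis[lo:hi]
        for lead in (0, 1):
            for off, amp, sg in morph.wave_table(rr, p_gain, lead):
                if amp == 0.0:
                    continue
                center = r_t + off + (p_jit[k] if off < -0.05 else 0.0)
                sig[lead, lo:hi] += amp * np.exp(-0.5 * ((tt - center) / sg) ** 2)

    if params.noise_std_mv > 0:
        sig += rng.normal(0.0, params.noise_std_mv, size=sig.shape)
    np.clip(sig, -params.amp_limit_mv, params.amp_limit_mv, out=sig)
    keep = r_times < params.duration_s
    return sig, r_times[keep]


def synth_sinus(params: SynthParams, morphology: Morphology | None = None) -> ECGRecord:
    """Generate a 2-lead sinus-rhythm record.

    Heart rate follows a slow sinusoidal (respiratory) modulation within
    ``mean_hr_bpm +- hr_variation_bpm``; P-waves are at full amplitude and
    RR intervals are regular (irregularity is ignored for sinus rhythm).
    """
    rng = np.random.default_rng(params.seed)
    sig, _ = _render(params, rng, irregular=False, p_gain=1.0,
                     morphology=morphology)
    return ECGRecord(sig, params.fs, record_id=f"synth-sinus-{params.seed}",
                     label="normal")


def synth_pxaf(params: SynthParams, morphology: Morphology | None = None) -> ECGRecord:
    """Generate a 2-lead PxAF record.

    RR intervals receive multiplicative log-normal jitter with coefficient
    of variation ``rr_irregularity``; P-waves are scaled by ``p_wave_gain``
    and time-jittered in proportion to the suppression.  With
    ``rr_irregularity=0`` and ``p_wave_gain=1`` the output is bit-identical
    to :func:`synth_sinus` at the same seed.
    """
    rng = np.random.default_rng(params.seed)
    sig, _ = _render(params, rng, irregular=True, p_gain=params.p_wave_gain,
                     morphology=morphology)
    return ECGRecord(sig, params.fs, record_id=f"synth-pxaf-{params.seed}",
                     label="pxaf")


def r_peak_times(params: SynthParams, kind: str = "sinus",
                 morphology: Morphology | None = None) -> np.ndarray:
    """Ground-truth R-peak times (s) for a fixture, without rendering noise."""
    rng = np.random.default_rng(params.seed)
    _, rt = _render(params, rng, irregular=(kind == "pxaf"),
                    p_gain=params.p_wave_gain if kind == "pxaf" else 1.0,
                    morphology=morphology)
    return rt


# ---------------------------------------------------------------------------
# defect injection

def _matched_noise(x: np.ndarray, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited white noise with the same per-lead power as ``x``."""
    noise = rng.standard_normal(x.shape)
    nyq = fs / 2.0
    b, a = butter(4, min(40.0, 0.9 * nyq) / nyq, btype="low")
    noise = filtfilt(b, a, noise, axis=-1)
    p_x = np.mean(x ** 2, axis=-1, keepdims=True)
    p_n = np.mean(noise ** 2, axis=-1, keepdims=True)
    return noise * np.sqrt(np.maximum(p_x, 1e-12) / np.maximum(p_n, 1e-12))


def _detect_beats_for_defect(segment: ECGSegment) -> np.ndarray:
    # local import: features depends on sigproc, not on this module
    from .features import detect_r_peaks
    return detect_r_peaks(segment, lead=0)


def inject_defect(segment: ECGSegment, defect: DefectSpec) -> ECGSegment:
    """Return a corrupted copy of ``segment`` implementing one directive.

    1. bizarre shape: blend the whole waveform toward matched-power
       band-limited noise (peaks become undetectable at full severity);
    2. distorted sub-interval: same replacement but over a random
       sub-interval covering >= 25% of the segment;
    3. inconsistent QRS: alternating beats have their QRS widened by
       ``1 + 2.5*severity`` and rescaled by ``1 + 2*severity``;
    4. spurious R-peaks: R-like spikes of amplitude ``~0.9*severity`` times
       the median R amplitude inserted between true beats;
    5. partial PxAF: one random half replaced by a regular sinus rendering
       at the segment's median rate (PxAF pattern survives only partially).

    Severity -> 0 approaches the identity for every directive.
    """
    rng = np.random.default_rng(defect.seed)
    out = segment.copy()
    x = out.signals
    n = out.n_samples
    fs = out.fs
    s = defect.severity
    d = defect.directive_id

    if d == 1:
        noise = _matched_noise(x, fs, rng)
        out.signals = (1.0 - s) * x + s * noise
    elif d == 2:
        # capped at half the segment so the intact remainder stays dominant
        frac = 0.25 + 0.25 * s * rng.uniform(0.5, 1.0)
        length = max(1, int(frac * n))
        start = int(rng.integers(0, max(1, n - length + 1)))
        noise = _matched_noise(x[:, start:start + length], fs, rng)
        y = x.copy()
        y[:, start:start + length] = (
            (1.0 - s) * x[:, start:start + length] + s * noise
        )
        out.signals = y
    elif d in (3, 4, 5):
        peaks = _detect_beats_for_defect(out)
        if peaks.size < 2:
            raise InvalidParameterError(
                f"directive {d} needs a segment with >= 2 beats"
            )
        if d == 3:
            width_f = 1.0 + 2.5 * s
            amp_f = 1.0 + 2.0 * s
            w = int(0.12 * fs)
            y = x.copy()
            for bi, p in enumerate(peaks):
                if bi % 2 == 0:
                    continue
                lo, hi = max(0, p - w), min(n, p + w + 1)
                idx = np.arange(lo, hi)
                # evaluate the original at a compressed argument -> widened QRS
                src = p + (idx - p) / width_f
                for lead in range(y.shape[0]):
                    y[lead, lo:hi] = amp_f * np.interp(src, np.arange(n), x[lead])
            out.signals = np.clip(y, -4.0, 4.0)
        elif d == 4:
            r_amp = np.median(np.abs(x[0, peaks]))
            y = x.copy()
            sigma = 0.010  # 10 ms spike, R-like
            t_axis = np.arange(n) / fs
            # a random ~60% of gaps (at least one) get a near-mid-gap spike
            gaps = list(zip(peaks[:-1], peaks[1:]))
            chosen = [g for g in gaps if rng.random() < 0.6]
            if not chosen:
                chosen = [gaps[int(rng.integers(0, len(gaps)))]]
            for a, b in chosen:
                u = rng.uniform(0.35, 0.65)
                mid = (a + u * (b - a)) / fs
                # R-like but template-foreign: narrow, with jittered height;
                # vanishes with severity -> 0
                amp = s * (0.35 + 0.55 * rng.uniform(0.4, 1.0)) * r_amp
                lo = max(0, int((mid - 0.05) * fs))
                hi = min(n, int((mid + 0.05) * fs) + 1)
                bump = amp * np.exp(-0.5 * ((t_axis[lo:hi] - mid) / sigma) ** 2)
                y[0, lo:hi] += bump
                y[1, lo:hi] += 0.65 * bump
            out.signals = y
        else:  # d == 5
            # replace a contiguous run at one end with a regular sinus
            # rendering; the run grows with severity, reaching half the
            # segment at severity 0.6 and saturating there
            at_start = bool(rng.integers(0, 2))
            rr = np.diff(peaks) / fs
            hr = 60.0 / np.median(rr)
            clean = synth_sinus(SynthParams(
                duration_s=n / fs, fs=fs, mean_hr_bpm=hr,
                hr_variation_bpm=0.0, noise_std_mv=0.0,
                seed=int(rng.integers(0, 2 ** 31)),
            ))
            amp_ratio = (np.percentile(np.abs(x[0]), 99)
                         / max(np.percentile(np.abs(clean.signals[0]), 99), 1e-9))
            clean_sig = clean.signals * amp_ratio
            y = x.copy()
            run = int(round(min(1.0, s / 0.6) * n / 2))
            sl = slice(0, run) if at_start else slice(n - run, n)
            y[:, sl] = clean_sig[:, sl]
            out.signals = y
    return out


# ---------------------------------------------------------------------------
# dataset synthesis

#: default study conditions for the two rhythm classes
SINUS_HR_RANGE = (60.0, 100.0)
PXAF_HR_RANGE = (75.0, 125.0)
PXAF_IRREGULARITY_RANGE = (0.15, 0.30)
PXAF_P_GAIN_RANGE = (0.0, 0.30)


def synth_dataset(n_normal: int, n_pxaf: int, seg_dur_s: float,
                  seed: int = 0, fs: float = 128.0) -> list[ECGSegment]:
    """Generate a labeled collection of sinus and PxAF segments.

    Sinus segments draw their mean rate uniformly from 60-100 BPM (regular
    RR, full P-waves); PxAF segments draw a faster mean rate (75-125 BPM),
    an RR coefficient of variation in 0.15-0.30 and a P-wave gain in
    0-0.3.  Reproducible given ``seed``; normals come first.
    """
    if n_normal < 0 or n_pxaf < 0:
        raise InvalidParameterError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    segments: list[ECGSegment] = []
    for i in range(n_normal + n_pxaf):
        sub = int(rng.integers(0, 2 ** 31))
        if i < n_normal:
            params = SynthParams(
                duration_s=seg_dur_s, fs=fs,
                mean_hr_bpm=rng.uniform(*SINUS_HR_RANGE),
                hr_variation_bpm=3.0, seed=sub,
            )
            rec = synth_sinus(params)
        else:
            params = SynthParams(
                duration_s=seg_dur_s, fs=fs,
                mean_hr_bpm=rng.uniform(*PXAF_HR_RANGE),
                hr_variation_bpm=3.0,
                rr_irregularity=rng.uniform(*PXAF_IRREGULARITY_RANGE),
                p_wave_gain=rng.uniform(*PXAF_P_GAIN_RANGE),
                seed=sub,
            )
            rec = synth_pxaf(params)
        segments.append(ECGSegment(
            rec.signals, fs=fs, label=rec.label,
            source_record=rec.record_id, offset_samples=0,
        ))
    return segments
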