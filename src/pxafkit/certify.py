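"""Automated screening of synthetic ECG segments.

Generative models produce many segments whose morphology a physician
would reject.  This module encodes the five rejection directives used to
screen such outputs as reproducible heuristics:

1. bizarre shape — no detectable beats, or an energy envelope without
   clear peaks (peak-to-median ratio too low);
2. distorted sub-interval — part of the segment is noise-like (large
   high-frequency power fraction) while the rest is not;
3. inconsistent QRS — per-beat QRS durations or R amplitudes vary far
   more than physiology allows;
4. spurious R-peaks — extra detected events split RR intervals into
   consecutive pairs of implausibly short intervals, or halving the
   detection threshold reveals many sub-threshold R-like events;
5. partial PxAF — splitting the RR sequence at some change point leaves
   one side metronomically regular and the other clearly irregular.

A segment is *certified* when no directive raises a flag.  Every
threshold lives in :class:`CertifyConfig`; tightening any of them can
only shrink the certified set.  The thresholds were calibrated on the
package's own synthetic fixtures (clean PxAF vs single-directive
defects) for wide separation between the two populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .features import DetectorConfig, detect_r_peaks, qrs_durations, shannon_envelope
from .types import ECGSegment, InvalidParameterError

__all__ = ["CertifyConfig", "DirectiveVerdict", "check_directives",
           "filter_certified"]


@dataclass
class CertifyConfig:
    """Thresholds of the five directive heuristics (see module docstring)."""

    min_beats: int = 2
    d1_ratio: float = 8.0        # envelope peak-to-median floor
    d2_hf_band_hz: float = 30.0  # start of the "noise" band
    d2_hf_hi: float = 0.10       # a window above this fraction is noise-like
    d2_hf_lo: float = 0.05       # ... while some window must stay below this
    d2_window_frac: float = 0.25
    d3_cv: float = 0.35          # QRS-duration coefficient of variation cap
    d3_amp_cv: float = 0.5       # R-amplitude coefficient of variation cap
    d4_corr_thr: float = 0.8     # beats below this template correlation are alien
    d4_lowcorr_frac: float = 0.1 # tolerated fraction of template-foreign beats
    d4_template_halfw_s: float = 0.15
    d4_pair_frac: float = 0.3    # tolerated fraction of double-short RR pairs
    d4_short_rr: float = 0.6     # "short" = below this fraction of the 85th-pct RR
    d4_excess: float = 0.15      # tolerated extra-peak fraction at half threshold
    d5_min_side_rr: int = 4      # RR intervals required on each side of a split
    d5_delta: float = 0.08       # required CV gap between the two sides
    d5_floor: float = 0.05       # sinus-regularity floor
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    lead: int = 0


@dataclass
class DirectiveVerdict:
    """Outcome of the five directive checks for one segment."""

    flags: dict[int, bool]
    evidence: dict[int, float]

    @property
    def certified(self) -> bool:
        return not any(self.flags.values())

    def first_violation(self) -> int | None:
        for d in sorted(self.flags):
            if self.flags[d]:
                return d
        return None


def _hf_fraction(x: np.ndarray, fs: float, band_hz: float) -> float:
    """Fraction of (non-DC) periodogram power at or above ``band_hz``."""
    f, pxx = periodogram(x, fs=fs, detrend="constant")
    total = pxx[1:].sum()
    if total <= 0:
        return 0.0
    return float(pxx[f >= band_hz].sum() / total)


def check_directives(segment: ECGSegment,
                     cfg: CertifyConfig | None = None) -> DirectiveVerdict:
    """Evaluate all five directives on one segment.

    Directives are evaluated in order 1..5; a segment may raise several
    flags.  Requires at least 2 s of signal.
    """
    cfg = cfg or CertifyConfig()
    if segment.duration_s < 2.0:
        raise InvalidParameterError("check_directives requires >= 2 s of signal")
    fs = segment.fs
    x = segment.signals[cfg.lead]
    det = cfg.detector
    peaks = detect_r_peaks(segment, cfg.lead, det)
    env = shannon_envelope(x, fs, det)

    flags: dict[int, bool] = {}
    evidence: dict[int, float] = {}

    # D1 — bizarre shape: few beats or a flat, peak-less envelope.
    # Clean fixtures sit at ratios > 25, matched-power noise near 3.
    med = float(np.median(env))
    ratio = float(env.max() / med) if med > 0 else float("inf")
    evidence[1] = min(ratio, 1e6)
    flags[1] = peaks.size < cfg.min_beats or ratio < cfg.d1_ratio

    # D2 — distorted sub-interval: some window is noise-like (high-band
    # power fraction above d2_hf_hi) while another stays clean (below
    # d2_hf_lo).  Globally noise-like signals fail D1, not D2.
    n = x.size
    w = max(int(cfg.d2_window_frac * n), 16)
    stride = max(w // 4, 1)
    starts = range(0, n - w + 1, stride)
    hf = np.array([_hf_fraction(x[s:s + w], fs, cfg.d2_hf_band_hz)
                   for s in starts])
    evidence[2] = float(hf.max() - hf.min()) if hf.size else 0.0
    flags[2] = bool(hf.size and hf.max() > cfg.d2_hf_hi
                    and hf.min() < cfg.d2_hf_lo)

    # D3 — inconsistent QRS: duration or amplitude dispersion across beats
    if peaks.size >= 2:
        qrs = qrs_durations(segment, peaks, fs, cfg.lead, det)
        cv_qrs = float(qrs.std() / qrs.mean()) if qrs.mean() > 0 else 0.0
        amps = np.abs(x[peaks])
        cv_amp = float(amps.std() / amps.mean()) if amps.mean() > 0 else 0.0
    else:
        qrs = np.asarray([])
        cv_qrs = cv_amp = 0.0
    evidence[3] = max(cv_qrs, cv_amp * cfg.d3_cv / cfg.d3_amp_cv)
    flags[3] = cv_qrs > cfg.d3_cv or cv_amp > cfg.d3_amp_cv

    # D4 — spurious R-peaks, three complementary signals: (a) detected
    # beats whose waveform does not match the segment's median beat
    # template, (b) RR intervals split into consecutive short-short
    # pairs, (c) extra sub-threshold events revealed at half threshold.
    halfw = max(1, int(round(cfg.d4_template_halfw_s * fs)))
    windows = [x[p - halfw:p + halfw + 1] for p in peaks
               if p - halfw >= 0 and p + halfw + 1 <= n]
    low_corr_frac = 0.0
    if len(windows) >= 3:
        beats = np.asarray(windows)
        template = np.median(beats, axis=0)
        t0 = template - template.mean()
        t_norm = float(np.linalg.norm(t0))
        cors = []
        for b in beats:
            b0 = b - b.mean()
            denom = float(np.linalg.norm(b0)) * t_norm
            cors.append(float(b0 @ t0 / denom) if denom > 0 else 0.0)
        low_corr_frac = float(np.mean(np.asarray(cors) < cfg.d4_corr_thr))
    rr = np.diff(peaks) / fs
    if rr.size >= 2:
        # reference = upper-quantile RR, robust to many split intervals
        ref_rr = float(np.percentile(rr, 85))
        short = rr < cfg.d4_short_rr * ref_rr
        pair_frac = float(np.mean(short[:-1] & short[1:]))
    else:
        pair_frac = 0.0
    half_det = DetectorConfig(**{**det.__dict__,
                                 "threshold_frac": det.threshold_frac / 2})
    n_half = detect_r_peaks(segment, cfg.lead, half_det).size
    excess = (n_half - peaks.size) / peaks.size if peaks.size else 0.0
    evidence[4] = max(low_corr_frac / cfg.d4_lowcorr_frac,
                      pair_frac / cfg.d4_pair_frac, excess / cfg.d4_excess)
    flags[4] = bool(low_corr_frac > cfg.d4_lowcorr_frac or
                    pair_frac > cfg.d4_pair_frac or
                    (peaks.size and excess > cfg.d4_excess))

    # D5 — partial PxAF: some change point splits the RR sequence into a
    # metronomically regular side and a clearly irregular side
    best_spread = 0.0
    flag5 = False
    m = cfg.d5_min_side_rr
    for cut in range(m, rr.size - m + 1):
        sides = (rr[:cut], rr[cut:])
        cvs = [float(sd.std() / sd.mean()) if sd.mean() > 0 else 0.0
               for sd in sides]
        spread = abs(cvs[0] - cvs[1])
        if min(cvs) < cfg.d5_floor and spread > cfg.d5_delta:
            flag5 = True
            best_spread = max(best_spread, spread)
        else:
            best_spread = max(best_spread, spread)
    evidence[5] = best_spread
    flags[5] = flag5

    return DirectiveVerdict(flags=flags, evidence=evidence)


def filter_certified(segments: list[ECGSegment],
                     cfg: CertifyConfig | None = None
                     ) -> tuple[list[ECGSegment], list[dict]]:
    """Partition segments into certified ones and a rejection log.

    The log records, per rejected segment, its input index and the first
    violated directive (plus all raised flags).  Order is preserved.
    """
    cfg = cfg or CertifyConfig()
    certified: list[ECGSegment] = []
    log: list[dict] = []
    for i, seg in enumerate(segments):
        verdict = check_directives(seg, cfg)
        if verdict.certified:
            certified.append(seg)
        else:
            log.append({
                "index": i,
                "source_record": seg.source_record,
                "offset_samples": int(seg.offset_samples),
                "directive": verdict.first_violation(),
                "flags": {str(k): bool(v) for k, v in verdict.flags.items()},
            })
    return certified, log


def defect_suite(n_per_directive: int = 100, n_clean: int = 100,
                 duration_s: float = 10.0, seed: int = 0,
                 severity_range: tuple[float, float] = (0.6, 1.0)):
    """Labeled benchmark suite for the directive heuristics.

    Returns ``(clean_segments, {directive: [segments]})`` built from PxAF
    fixtures drawn from the study's default parameter ranges, with
    moderate-to-severe defects injected per directive.  Used by the
    certification acceptance checks (per-directive recall and clean pass
    rate).
    """
    from .ecg_synth import (DefectSpec, PXAF_HR_RANGE,
                            PXAF_IRREGULARITY_RANGE, PXAF_P_GAIN_RANGE,
                            SynthParams, synth_pxaf)

    rng = np.random.default_rng(seed)

    def one_clean():
        sub = int(rng.integers(0, 2 ** 31))
        r = np.random.default_rng(sub)
        params = SynthParams(
            duration_s=duration_s,
            mean_hr_bpm=r.uniform(*PXAF_HR_RANGE),
            rr_irregularity=r.uniform(*PXAF_IRREGULARITY_RANGE),
            p_wave_gain=r.uniform(*PXAF_P_GAIN_RANGE),
            seed=sub,
        )
        rec = synth_pxaf(params)
        return ECGSegment(rec.signals, rec.fs, label="pxaf",
                          source_record=rec.record_id)

    clean = [one_clean() for _ in range(n_clean)]
    defects: dict[int, list[ECGSegment]] = {}
    for d in (1, 2, 3, 4, 5):
        defects[d] = []
        for _ in range(n_per_directive):
            seg = one_clean()
            spec = DefectSpec(d, severity=float(rng.uniform(*severity_range)),
                              seed=int(rng.integers(0, 2 ** 31)))
            from .ecg_synth import inject_defect
            defects[d].append(inject_defect(seg, spec))
    return clean, defects
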