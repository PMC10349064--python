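"""Core domain containers shared across the toolkit.

All signal amplitudes are in millivolts, times in seconds, sampling rates
in Hz.  Arrays are ``numpy`` throughout; signals are stored as
``(leads, samples)`` float64 matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Label = Literal["normal", "pxaf", "unknown"]


class InvalidParameterError(ValueError):
    """A parameter violates its documented domain."""


class DegenerateInputError(ValueError):
    """An input is formally valid but degenerate for the operation."""


def _validate_signals(signals: np.ndarray) -> np.ndarray:
    signals = np.asarray(signals, dtype=np.float64)
    if signals.ndim != 2:
        raise InvalidParameterError(
            f"signals must be a (leads, samples) matrix, got shape {signals.shape}"
        )
    if signals.shape[0] < 1 or signals.shape[1] < 1:
        raise InvalidParameterError("signals must have >= 1 lead and >= 1 sample")
    if not np.isfinite(signals).all():
        raise InvalidParameterError("signals contain non-finite values")
    return signals


@dataclass
class ECGRecord:
    """A multi-lead ECG recording.

    Attributes
    ----------
    signals : ndarray, shape (leads, samples)
        Amplitudes in millivolts.
    fs : float
        Sampling frequency in Hz.
    record_id : str
        Free-form identifier (file stem for on-disk records).
    label : {"normal", "pxaf", "unknown"}
        Rhythm class of the whole record.
    """

    signals: np.ndarray
    fs: float
    record_id: str = ""
    label: Label = "unknown"

    def __post_init__(self) -> None:
        self.signals = _validate_signals(self.signals)
        if not self.fs > 0:
            raise InvalidParameterError("fs must be positive")

    @property
    def n_leads(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ECGSegment:
    """A contiguous window cut from an :class:`ECGRecord`.

    ``offset_samples`` is the 0-based start index of the window in its
    source record; windows are half-open ``[offset, offset + n)``.
    """

    signals: np.ndarray
    fs: float
    label: Label = "unknown"
    source_record: str = ""
    offset_samples: int = 0

    def __post_init__(self) -> None:
        self.signals = _validate_signals(self.signals)
        if not self.fs > 0:
            raise InvalidParameterError("fs must be positive")
        if self.offset_samples < 0:
            raise InvalidParameterError("offset_samples must be >= 0")

    @property
    def n_leads(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "ECGSegment":
        return replace(self, signals=self.signals.copy())


@dataclass
class BeatFeatures:
    """Per-segment beat-level features: R-peaks, RR intervals, HR, QRS widths.

    ``heart_rate_bpm`` is ``nan`` when fewer than two R-peaks were found
    (RR undefined).  QRS durations are quantized to 1/fs by construction.
    """

    r_peaks: np.ndarray          # int sample indices, strictly increasing
    rr_intervals_s: np.ndarray   # len = max(0, len(r_peaks) - 1)
    heart_rate_bpm: float        # 60 / mean(rr), nan if undefined
    qrs_durations_s: np.ndarray  # one per detected beat

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        self.rr_intervals_s = np.asarray(self.rr_intervals_s, dtype=np.float64)
        self.qrs_durations_s = np.asarray(self.qrs_durations_s, dtype=np.float64)
        if self.r_peaks.size > 1 and not np.all(np.diff(self.r_peaks) > 0):
            raise InvalidParameterError("r_peaks must be strictly increasing")


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test segment collections."""

    train: list
    validation: list
    test: list
    seed: int = 0

    def __iter__(self):
        yield from (self.train, self.validation, self.test)
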