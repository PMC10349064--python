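"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, noise robustness.

Accuracy, specificity and sensitivity follow the standard confusion-count
definitions

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity =  TN / (TN + FP)
    sensitivity =  TP / (TP + FN)

with a metric reported as ``nan`` when its denominator is zero.  The ROC
curve sweeps thresholds over the unique scores (sensitivity against
1 - specificity) and integrates AUC with the trapezoid rule, which equals
the Mann-Whitney concordance probability.

The robustness harness adds noise at a controlled signal-to-noise ratio:
white Gaussian noise, or "color" noise obtained by low-pass filtering
white noise with a zero-phase order-4 Butterworth filter cut off at
50 Hz.  SNR is defined on per-segment average power; noise is scaled so
the realized power ratio matches the request exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .types import DegenerateInputError, ECGSegment, InvalidParameterError

__all__ = ["ConfusionCounts", "NoiseSpec", "metrics", "confusion_from_labels",
           "roc_curve", "add_noise", "noise_sweep"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidParameterError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class NoiseSpec:
    """Noise kind, target SNR and (for color noise) the shaping filter."""

    kind: str = "white"            # "white" | "color"
    snr_db: float = 10.0
    filter_order: int = 4
    cutoff_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "color"):
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); ``nan`` marks an undefined one."""
    acc = (c.tp + c.tn) / c.total if c.total else float("nan")
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    return acc, sens, spec


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray
                          ) -> ConfusionCounts:
    """Counts with class 1 (PxAF) as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise InvalidParameterError("label arrays must have the same shape")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_curve(labels: np.ndarray, scores: np.ndarray
              ) -> tuple[np.ndarray, float]:
    """ROC points and trapezoid AUC.

    Thresholds sweep the unique scores; points are (1-specificity,
    sensitivity) sorted by the first coordinate, including (0,0) and
    (1,1).  Requires both classes to be present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidParameterError("roc_curve needs both classes present")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep the last point of each tied-score run
    keep = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    return points, auc


def add_noise(segment: ECGSegment, spec: NoiseSpec) -> ECGSegment:
    """Additive noise at an exact per-segment SNR (dB).

    White: standard-normal samples.  Color: the same, low-pass filtered
    (zero-phase Butterworth, order/cutoff from ``spec``) before scaling.
    The noise is rescaled per lead so that
    ``10 log10(P_signal / P_noise)`` equals ``spec.snr_db`` exactly.
    """
    x = segment.signals
    p_sig = np.mean(x ** 2, axis=1, keepdims=True)
    if np.any(p_sig <= 0):
        raise DegenerateInputError("cannot set an SNR for a zero-power lead")
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(x.shape)
    if spec.kind == "color":
        nyq = segment.fs / 2.0
        cutoff = min(spec.cutoff_hz, 0.99 * nyq)
        b, a = butter(spec.filter_order, cutoff / nyq, btype="low")
        noise = filtfilt(b, a, noise, axis=1)
    p_noise = np.mean(noise ** 2, axis=1, keepdims=True)
    target = p_sig / (10.0 ** (spec.snr_db / 10.0))
    noise *= np.sqrt(target / p_noise)
    out = segment.copy()
    out.signals = x + noise
    return out


def noise_sweep(classifier, segments: list[ECGSegment],
                snr_list: list[float], kind: str = "white",
                seed: int = 0) -> dict[float, float]:
    """Accuracy of ``classifier`` under increasing noise.

    ``classifier`` maps a list of segments to predicted labels (0 =
    normal, 1 = PxAF).  Every segment is corrupted at each SNR (one
    seeded noise draw per segment) and re-classified; returns
    ``{snr_db: accuracy}`` in the order given.
    """
    y_true = np.array([1 if s.label == "pxaf" else 0 for s in segments])
    out: dict[float, float] = {}
    for snr in snr_list:
        noisy = [add_noise(s, NoiseSpec(kind=kind, snr_db=snr,
                                        seed=seed + 7919 * i))
                 for i, s in enumerate(segments)]
        y_pred = np.asarray(classifier(noisy), dtype=int)
        c = confusion_from_labels(y_true, y_pred)
        out[snr] = metrics(c)[0]
    return out
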