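"""Population-level fidelity comparison of real vs synthetic ECG features.

Synthetic-data fidelity is judged on the distributions of three rhythm
parameters pooled across each population — heart rate (BPM), RR interval
(s) and QRS interval (s) — via descriptive statistics (mean, unbiased
standard deviation, 2.5% and 97.5% percentiles), the two-sample
Kolmogorov-Smirnov test, and paired quantiles for Q-Q plots.

The K-S statistic is computed directly as the supremum of the absolute
ECDF difference over the pooled sample points; the p-value uses the
asymptotic Kolmogorov distribution with effective sample size
``n1*n2/(n1+n2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import kolmogorov

from .features import DetectorConfig, extract_features
from .types import ECGSegment, InvalidParameterError

__all__ = ["DescriptiveStats", "KSResult", "FidelityReport",
           "descriptive_stats", "ks_two_sample", "qq_points",
           "fidelity_report", "pooled_features"]

FEATURE_NAMES = ("hr_bpm", "rr_s", "qrs_s")


@dataclass
class DescriptiveStats:
    mean: float
    std: float       # unbiased (n-1); 0 for a single observation
    p2_5: float
    p97_5: float
    n: int

    def as_dict(self) -> dict:
        return {"mean": self.mean, "std": self.std,
                "p2_5": self.p2_5, "p97_5": self.p97_5, "n": self.n}


@dataclass
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int


@dataclass
class FidelityReport:
    """Per-feature statistics for two populations plus their comparison."""

    real_stats: dict[str, DescriptiveStats]
    synth_stats: dict[str, DescriptiveStats]
    ks: dict[str, KSResult]
    qq: dict[str, np.ndarray]        # (n_quantiles, 2) arrays
    real_values: dict[str, np.ndarray] | None = None
    synth_values: dict[str, np.ndarray] | None = None


def descriptive_stats(values: np.ndarray) -> DescriptiveStats:
    """Mean, unbiased std and 2.5/97.5 percentiles (linear interpolation)."""
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise InvalidParameterError("descriptive_stats requires a non-empty sample")
    std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    p_lo, p_hi = np.percentile(v, [2.5, 97.5], method="linear")
    return DescriptiveStats(mean=float(np.mean(v)), std=std,
                            p2_5=float(p_lo), p97_5=float(p_hi), n=int(v.size))


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    The statistic is ``sup_x |F_a(x) - F_b(x)|`` with right-continuous
    empirical CDFs, evaluated over the pooled sample points; the p-value
    is the asymptotic Kolmogorov survival function at
    ``sqrt(n1*n2/(n1+n2)) * statistic``.
    """
    a = np.sort(np.asarray(a, dtype=np.float64))
    b = np.sort(np.asarray(b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("ks_two_sample requires non-empty samples")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    stat = float(np.max(np.abs(cdf_a - cdf_b)))
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(np.clip(kolmogorov(np.sqrt(n_eff) * stat), 0.0, 1.0))
    return KSResult(statistic=stat, p_value=p, n1=int(a.size), n2=int(b.size))


def qq_points(a: np.ndarray, b: np.ndarray, n_quantiles: int = 100) -> np.ndarray:
    """Paired quantiles of two samples at probabilities ``(k+0.5)/n``.

    Returns an ``(n_quantiles, 2)`` array of ``(q_a, q_b)`` points; equal
    distributions put every point on the identity line.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("qq_points requires non-empty samples")
    if n_quantiles < 1:
        raise InvalidParameterError("n_quantiles must be >= 1")
    probs = (np.arange(n_quantiles) + 0.5) / n_quantiles * 100.0
    qa = np.percentile(a, probs, method="linear")
    qb = np.percentile(b, probs, method="linear")
    return np.column_stack([qa, qb])


def pooled_features(segments: list[ECGSegment],
                    cfg: DetectorConfig | None = None) -> dict[str, np.ndarray]:
    """Pool per-beat features across a segment population.

    Heart rate contributes one value per segment (when defined); RR and
    QRS contribute one value per interval/beat.
    """
    hr, rr, qrs = [], [], []
    for seg in segments:
        f = extract_features(seg, cfg=cfg)
        if np.isfinite(f.heart_rate_bpm):
            hr.append(f.heart_rate_bpm)
        rr.extend(f.rr_intervals_s.tolist())
        qrs.extend(f.qrs_durations_s.tolist())
    return {"hr_bpm": np.asarray(hr), "rr_s": np.asarray(rr),
            "qrs_s": np.asarray(qrs)}


def fidelity_report(real_segments: list[ECGSegment],
                    synth_segments: list[ECGSegment],
                    n_quantiles: int = 100,
                    cfg: DetectorConfig | None = None) -> FidelityReport:
    """Compare feature distributions of a real and a synthetic population."""
    if not real_segments or not synth_segments:
        raise InvalidParameterError("both populations must be non-empty")
    real = pooled_features(real_segments, cfg)
    synth = pooled_features(synth_segments, cfg)
    report = FidelityReport(real_stats={}, synth_stats={}, ks={}, qq={},
                            real_values=real, synth_values=synth)
    for name in FEATURE_NAMES:
        report.real_stats[name] = descriptive_stats(real[name])
        report.synth_stats[name] = descriptive_stats(synth[name])
        report.ks[name] = ks_two_sample(real[name], synth[name])
        report.qq[name] = qq_points(real[name], synth[name], n_quantiles)
    return report


def report_as_dict(report: FidelityReport) -> dict:
    """JSON-serializable form of a :class:`FidelityReport`."""
    return {
        name: {
            "real": report.real_stats[name].as_dict(),
            "synthetic": report.synth_stats[name].as_dict(),
            "ks": {"statistic": report.ks[name].statistic,
                   "p_value": report.ks[name].p_value,
                   "n1": report.ks[name].n1, "n2": report.ks[name].n2},
            "qq": report.qq[name].tolist(),
        }
        for name in FEATURE_NAMES
    }


def save_fidelity_plots(report: FidelityReport, directory) -> list:
    """Histogram and Q-Q plots per feature (PNG files in ``directory``)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in FEATURE_NAMES:
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3))
        qq = report.qq[name]
        ax2.plot(qq[:, 0], qq[:, 1], "o", ms=2)
        lims = [qq.min(), qq.max()]
        ax2.plot(lims, lims, "k--", lw=0.8)
        ax2.set_title(f"Q-Q {name}")
        ax1.set_title(f"{name} (KS={report.ks[name].statistic:.3f})")
        if report.real_values is not None and report.synth_values is not None:
            ax1.hist(report.real_values[name], bins=30, alpha=0.5,
                     density=True, label="real")
            ax1.hist(report.synth_values[name], bins=30, alpha=0.5,
                     density=True, label="synthetic")
            ax1.legend(fontsize=7)
        out = directory / f"fidelity_{name}.png"
        fig.savefig(out, dpi=100)
        plt.close(fig)
        paths.append(out)
    return paths
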