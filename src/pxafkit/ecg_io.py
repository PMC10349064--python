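"""Record I/O, segmentation and dataset splitting.

Records are exchanged in the WFDB convention used by PhysioNet archives:
a text header ``<record>.hea`` plus a binary ``<record>.dat`` holding
interleaved 16-bit little-endian samples (format 16), with a per-lead
gain in A/D units per millivolt.  A CSV writer/reader (one column per
lead) is provided as a plain-text alternative.

Segmentation cuts non-overlapping, contiguous windows from offset 0; a
trailing remainder shorter than the window is discarded.  With the
defaults used throughout this package — 128 Hz sampling and 4-s windows —
each segment holds exactly 512 samples and a 30-min record yields 450
segments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import DatasetSplit, ECGRecord, ECGSegment, InvalidParameterError

__all__ = [
    "read_wfdb_record", "write_wfdb_record",
    "read_csv_record", "write_csv_record",
    "segment_record", "split_dataset",
    "write_split_manifest", "read_split_manifest",
]

DEFAULT_GAIN = 200.0  # A/D units per millivolt, the PhysioNet PAF convention


# ---------------------------------------------------------------------------
# WFDB (.hea + .dat, format 16)

def write_wfdb_record(record: ECGRecord, directory: str | Path,
                      gain: float = DEFAULT_GAIN) -> Path:
    """Write ``record`` as ``<record_id>.hea`` + ``.dat`` (format 16).

    Samples are quantized to ``round(mv * gain)`` and clipped to the int16
    range; the quantization step is ``1/gain`` mV.  Returns the header path.
    """
    if gain <= 0:
        raise InvalidParameterError("gain must be positive")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id or "record"
    n_leads, n_samples = record.signals.shape
    digital = np.clip(np.round(record.signals * gain), -32768, 32767).astype("<i2")
    dat_path = directory / f"{name}.dat"
    # interleave leads sample-by-sample: frame = one sample per lead
    digital.T.reshape(-1).tofile(dat_path)
    lines = [f"{name} {n_leads} {record.fs:g} {n_samples}"]
    for lead in range(n_leads):
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 lead{lead}")
    lines.append(f"# label {record.label}")
    hea_path = directory / f"{name}.hea"
    hea_path.write_text("\n".join(lines) + "\n")
    return hea_path


def read_wfdb_record(path: str | Path) -> ECGRecord:
    """Read a WFDB record from ``<name>.hea`` (or the bare record path).

    Supports single-.dat format-16 records; signals are returned in
    millivolts using the per-lead gains from the header.
    """
    path = Path(path)
    hea_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea_path.exists():
        raise FileNotFoundError(f"header not found: {hea_path}")
    lines = [ln.strip() for ln in hea_path.read_text().splitlines() if ln.strip()]
    head = lines[0].split()
    name, n_leads = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    gains = []
    dat_name = None
    label = "unknown"
    for ln in lines[1:]:
        if ln.startswith("#"):
            parts = ln[1:].split()
            if len(parts) >= 2 and parts[0] == "label":
                label = parts[1]
            continue
        parts = ln.split()
        dat_name = parts[0]
        fmt = parts[1].split("x")[0]
        if fmt != "16":
            raise InvalidParameterError(f"unsupported WFDB format: {fmt}")
        gain = DEFAULT_GAIN
        if len(parts) > 2:
            gain_field = parts[2].split("(")[0].split("/")[0]
            gain = float(gain_field) if gain_field else DEFAULT_GAIN
        if gain == 0:
            raise InvalidParameterError(f"zero gain in header {hea_path}")
        gains.append(gain)
    if dat_name is None or len(gains) != n_leads:
        raise InvalidParameterError(f"malformed header: {hea_path}")
    dat_path = hea_path.parent / dat_name
    if not dat_path.exists():
        raise FileNotFoundError(f"signal file not found: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if n_samples:
        raw = raw[: n_samples * n_leads]
    if raw.size % n_leads:
        raise InvalidParameterError(f"signal length not divisible by leads: {dat_path}")
    digital = raw.reshape(-1, n_leads).T.astype(np.float64)
    signals = digital / np.asarray(gains)[:, None]
    if label not in ("normal", "pxaf", "unknown"):
        label = "unknown"
    return ECGRecord(signals, fs=fs, record_id=name, label=label)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# CSV

def write_csv_record(record: ECGRecord, path: str | Path) -> Path:
    """One column per lead; header row carries fs, id and label."""
    path = Path(path)
    header = (f"# fs={record.fs:g} id={record.record_id} label={record.label}\n"
              + ",".join(f"lead{i}" for i in range(record.n_leads)))
    np.savetxt(path, record.signals.T, delimiter=",", header=header, comments="")
    return path


def read_csv_record(path: str | Path) -> ECGRecord:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fs, rec_id, label = 128.0, path.stem, "unknown"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                if k == "fs":
                    fs = float(v)
                elif k == "id":
                    rec_id = v
                elif k == "label" and v in ("normal", "pxaf", "unknown"):
                    label = v
    data = np.loadtxt(path, delimiter=",", skiprows=2 if first.startswith("#") else 1,
                      ndmin=2)
    return ECGRecord(data.T, fs=fs, record_id=rec_id, label=label)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# segmentation and splits

def segment_record(record: ECGRecord, seg_dur_s: float = 4.0) -> list[ECGSegment]:
    """Cut ``record`` into non-overlapping windows of ``seg_dur_s`` seconds.

    Windows are contiguous from offset 0, half-open in samples; a trailing
    remainder shorter than one window is discarded.  Labels are inherited
    from the record.
    """
    n_per = int(round(seg_dur_s * record.fs))
    if n_per < 1:
        raise InvalidParameterError("seg_dur_s * fs must be >= 1")
    out = []
    for start in range(0, record.n_samples - n_per + 1, n_per):
        out.append(ECGSegment(
            record.signals[:, start:start + n_per].copy(),
            fs=record.fs, label=record.label,
            source_record=record.record_id, offset_samples=start,
        ))
    return out


def split_dataset(segments: list[ECGSegment], counts: tuple[int, int, int],
                  seed: int = 0) -> DatasetSplit:
    """Sample disjoint train/validation/test sets without replacement.

    ``counts`` gives the exact sizes, e.g. ``(4231, 906, 906)`` for the
    full-scale study design.  Membership is uniform over the input and
    reproducible from ``seed``; the three sets are disjoint by
    ``(source_record, offset_samples)`` identity.
    """
    n_train, n_val, n_test = counts
    if min(counts) < 0:
        raise InvalidParameterError("counts must be >= 0")
    total = n_train + n_val + n_test
    if total > len(segments):
        raise InvalidParameterError(
            f"requested {total} segments but only {len(segments)} available"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(segments))
    idx_train = perm[:n_train]
    idx_val = perm[n_train:n_train + n_val]
    idx_test = perm[n_train + n_val:total]
    return DatasetSplit(
        train=[segments[i] for i in idx_train],
        validation=[segments[i] for i in idx_val],
        test=[segments[i] for i in idx_test],
        seed=seed,
    )


def write_split_manifest(split: DatasetSplit, path: str | Path) -> Path:
    """Persist split membership as JSON keyed by (source_record, offset)."""
    path = Path(path)
    doc = {"seed": split.seed}
    for part, segs in zip(("train", "validation", "test"), split):
        doc[part] = [[s.source_record, int(s.offset_samples)] for s in segs]
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_split_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
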