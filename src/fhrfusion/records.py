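"""Reading, cleaning, windowing and labelling of fetal-heart-rate records.

A record is a 4 Hz fetal-heart-rate (FHR) trace in beats per minute, with an
optional uterine-contraction (UC) channel of the same length and optional
umbilical-artery pH metadata.  The value 0 bpm encodes a dropped/missing
sample, following the WFDB convention used by intrapartum CTG databases.

Two on-disk dialects are supported:

* plain CSV — one sample per row, columns ``fhr[,uc]``, preceded by a single
  comment line ``# {"record_id": ..., "ph": ..., "label": ...}``;
* WFDB format-16 record pairs (``.hea`` text header + ``.dat`` int16 signal
  file), the layout used by open intrapartum CTG archives.  pH is taken from
  a ``#pH <value>`` comment line in the header.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FHRRecord",
    "SAMPLING_RATE_HZ",
    "WINDOW_SAMPLES",
    "PH_THRESHOLD",
    "MIN_EFFECTIVE_LENGTH",
    "PHYSIOLOGICAL_RANGE_BPM",
    "read_record",
    "write_record_csv",
    "effective_length",
    "clean_signal",
    "extract_window",
    "label_from_ph",
    "filter_dataset",
]

SAMPLING_RATE_HZ = 4.0
#: 30 minutes at 4 Hz.
WINDOW_SAMPLES = 7200
#: Umbilical-artery pH below this value is labelled pathological (acidosis).
PH_THRESHOLD = 7.15
#: Records with fewer valid samples than this are considered severely
#: incomplete and discarded.
MIN_EFFECTIVE_LENGTH = 10_000
#: Samples outside this bpm window are treated as signal loss.
PHYSIOLOGICAL_RANGE_BPM = (50.0, 240.0)

LABEL_NORMAL = 0
LABEL_PATHOLOGICAL = 1


@dataclass
class FHRRecord:
    """One FHR trace at a fixed 4 Hz sampling rate.

    Attributes
    ----------
    fhr : ndarray
        Heart-rate samples in bpm; 0 encodes a missing sample.
    uc : ndarray, optional
        Uterine-contraction channel, same length as ``fhr``.
    ph : float, optional
        Umbilical-artery pH.
    label : int, optional
        0 = normal, 1 = pathological; derivable from ``ph``.
    """

    fhr: np.ndarray
    uc: Optional[np.ndarray] = None
    ph: Optional[float] = None
    record_id: str = ""
    label: Optional[int] = None
    fs: float = SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        if self.fhr.ndim != 1:
            raise ValueError("fhr must be one-dimensional")
        if np.any(self.fhr < 0):
            raise ValueError("fhr samples must be >= 0 (0 encodes missing)")
        if self.uc is not None:
            self.uc = np.asarray(self.uc, dtype=float)
            if self.uc.shape != self.fhr.shape:
                raise ValueError(
                    f"uc length {self.uc.shape} does not match fhr {self.fhr.shape}"
                )

    def __len__(self) -> int:
        return self.fhr.size

    def with_label(self, threshold: float = PH_THRESHOLD) -> "FHRRecord":
        """Return a copy labelled from its pH (see :func:`label_from_ph`)."""
        return replace(self, label=label_from_ph(self.ph, threshold))


def effective_length(record: FHRRecord) -> int:
    """Number of valid (non-missing, i.e. non-zero) FHR samples."""
    return int(np.count_nonzero(record.fhr))


def label_from_ph(ph: Optional[float], threshold: float = PH_THRESHOLD) -> int:
    """Binary acidosis label from umbilical-artery pH.

    pH below ``threshold`` is pathological; at or above is normal.
    """
    if ph is None or not np.isfinite(ph):
        raise ValueError("record has no pH; supply labels explicitly")
    return LABEL_PATHOLOGICAL if ph < threshold else LABEL_NORMAL


def clean_signal(record: FHRRecord) -> FHRRecord:
    """Replace missing and non-physiological samples by linear interpolation.

    Samples equal to 0 or outside ``PHYSIOLOGICAL_RANGE_BPM`` are treated as
    missing.  Interior gaps are linearly interpolated between the nearest
    valid neighbours; leading/trailing gaps take the nearest valid value.
    Idempotent: cleaning a clean record returns an identical signal.
    """
    x = record.fhr
    lo, hi = PHYSIOLOGICAL_RANGE_BPM
    valid = (x >= lo) & (x <= hi)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError(f"record {record.record_id!r} has no valid samples")
    if n_valid == x.size:
        return replace(record, fhr=x.copy())
    idx = np.arange(x.size)
    # np.interp holds endpoint values flat outside the valid support, which
    # implements the nearest-valid extension for leading/trailing gaps.
    filled = np.interp(idx, idx[valid], x[valid])
    return replace(record, fhr=filled)


def extract_window(record: FHRRecord, n_samples: int = WINDOW_SAMPLES) -> FHRRecord:
    """Return the final ``n_samples`` samples (the last 30 minutes at 4 Hz).

    Fetal distress concentrates before delivery, so classification uses the
    trailing window.  Records shorter than the window are rejected; filter
    them out first (:func:`filter_dataset`).
    """
    if len(record) < n_samples:
        raise ValueError(
            f"record {record.record_id!r} has {len(record)} samples < {n_samples}; "
            "filter short records before windowing"
        )
    fhr = record.fhr[-n_samples:].copy()
    uc = record.uc[-n_samples:].copy() if record.uc is not None else None
    return replace(record, fhr=fhr, uc=uc)


def filter_dataset(
    records: Sequence[FHRRecord],
    min_effective_length: int = MIN_EFFECTIVE_LENGTH,
) -> list:
    """Keep records with at least ``min_effective_length`` valid samples."""
    return [r for r in records if effective_length(r) >= min_effective_length]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_record(path, format: Optional[str] = None) -> FHRRecord:
    """Read a record from ``path`` in the ``csv`` or ``wfdb`` dialect.

    ``format`` defaults from the file suffix (``.csv`` vs ``.hea``/``.dat``
    or bare record name).  Missing pH leaves the label unset.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "wfdb"
    if format == "csv":
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown record format {format!r}")


def _read_csv(path: Path) -> FHRRecord:
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    meta = {}
    lines = text.splitlines()
    data_lines = []
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("{"):
                meta = json.loads(body)
            continue
        data_lines.append(stripped)
    if data_lines and re.match(r"^[A-Za-z]", data_lines[0]):
        header = [c.strip().lower() for c in data_lines[0].split(",")]
        data_lines = data_lines[1:]
    else:
        header = None
    fhr, uc = [], []
    for i, line in enumerate(data_lines):
        cells = line.split(",")
        try:
            vals = [float(c) for c in cells]
        except ValueError:
            raise ValueError(f"{path}: non-numeric sample at data row {i}: {line!r}")
        fhr.append(vals[0])
        if len(vals) > 1:
            uc.append(vals[1])
    if header is not None and header[0] != "fhr":
        raise ValueError(f"{path}: first CSV column must be 'fhr', got {header[0]!r}")
    ph = meta.get("ph")
    ph = float(ph) if ph is not None else None
    label = meta.get("label")
    label = int(label) if label is not None else None
    return FHRRecord(
        fhr=np.array(fhr, dtype=float),
        uc=np.array(uc, dtype=float) if uc else None,
        ph=ph,
        record_id=str(meta.get("record_id", path.stem)),
        label=label,
    )


def write_record_csv(record: FHRRecord, path) -> None:
    """Serialize a record to the CSV dialect with a JSON header comment."""
    path = Path(path)
    meta = {"record_id": record.record_id, "ph": record.ph, "label": record.label}
    with path.open("w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("fhr,uc\n" if record.uc is not None else "fhr\n")
        if record.uc is not None:
            for f, u in zip(record.fhr, record.uc):
                fh.write(f"{f:.6g},{u:.6g}\n")
        else:
            for f in record.fhr:
                fh.write(f"{f:.6g}\n")


def _read_wfdb(path: Path) -> FHRRecord:
    """Minimal WFDB reader for format-16 single-file records.

    Covers the subset used by intrapartum CTG archives: one ``.dat`` holding
    interleaved little-endian int16 samples for all channels, gains/baselines
    per the header signal lines, pH in a ``#pH <value>`` header comment.
    """
    hea = path.with_suffix(".hea") if path.suffix != ".hea" else path
    if not hea.exists():
        raise IOError(f"WFDB header not found: {hea}")
    lines = [ln.rstrip() for ln in hea.read_text().splitlines() if ln.strip()]
    first = lines[0].split()
    name = first[0]
    n_sig = int(first[1])
    sig_lines = [ln for ln in lines[1:] if not ln.startswith("#")][:n_sig]
    comments = [ln for ln in lines if ln.startswith("#")]

    gains, baselines, fmts, fnames, descs = [], [], [], [], []
    for ln in sig_lines:
        parts = ln.split()
        fnames.append(parts[0])
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        fmts.append(fmt)
        gain_field = parts[2] if len(parts) > 2 else "200"
        m = re.match(r"([-+0-9.eE]+)(?:\(([-+0-9]+)\))?(?:/.*)?", gain_field)
        gain = float(m.group(1)) if m else 200.0
        baseline = int(m.group(2)) if m and m.group(2) else None
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        gains.append(gain if gain != 0 else 200.0)
        baselines.append(baseline if baseline is not None else adc_zero)
        descs.append(parts[8] if len(parts) > 8 else f"sig{len(descs)}")
    if any(f != "16" for f in fmts):
        raise IOError(f"{hea}: only WFDB format 16 is supported, got {fmts}")

    dat = hea.parent / fnames[0]
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    raw = raw[: (raw.size // n_sig) * n_sig].reshape(-1, n_sig)
    signals = (raw.astype(float) - np.array(baselines)) / np.array(gains)

    ph = None
    for c in comments:
        m = re.match(r"#\s*pH\s+([-+0-9.eE]+)", c, flags=re.IGNORECASE)
        if m:
            ph = float(m.group(1))
            break
    # Channel assignment: FHR first unless descriptions say otherwise.
    fhr_col, uc_col = 0, (1 if n_sig > 1 else None)
    for j, d in enumerate(descs):
        if d.upper().startswith("FHR"):
            fhr_col = j
        elif d.upper().startswith("UC"):
            uc_col = j
    fhr = np.clip(signals[:, fhr_col], 0.0, None)
    uc = signals[:, uc_col] if uc_col is not None else None
    return FHRRecord(fhr=fhr, uc=uc, ph=ph, record_id=name)
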