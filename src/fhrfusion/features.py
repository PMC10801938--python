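"""The 45 expert features of a cleaned 30-minute FHR window.

Three groups, concatenated in a fixed order:

* 21 morphological time-domain features — baseline statistics, acceleration/
  deceleration counts, moment statistics of the beat-interval (RR) series and
  the classical HRV variability indices (SDNN, RMSSD, NN50, pNN50, STV, LTV,
  triangular index, TINN);
* 14 frequency-domain features — absolute and relative band powers, peak
  frequencies of the four fetal HRV bands (VLF 0–0.03, LF 0.03–0.15,
  MF 0.15–0.5, HF 0.5–1 Hz) and the LF/(MF+HF) ratio, from an FFT
  periodogram of the uniformly resampled RR series;
* 10 nonlinear features — Poincaré SD1/SD2/ratio, approximate/sample/
  Shannon/fuzzy entropies, Lempel–Ziv complexity, Higuchi fractal dimension
  and the Hurst exponent.

The RR series is derived samplewise from the 4 Hz bpm trace as
RR = 60000 / FHR (ms); NN denotes its successive differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from sklearn.base import BaseEstimator, TransformerMixin

from . import _entropy
from .records import FHRRecord, SAMPLING_RATE_HZ

__all__ = [
    "RRSeries",
    "BaselineEstimate",
    "TIME_DOMAIN_NAMES",
    "FREQUENCY_DOMAIN_NAMES",
    "NONLINEAR_NAMES",
    "FEATURE_NAMES",
    "FREQUENCY_BANDS_HZ",
    "fhr_to_rr",
    "estimate_baseline",
    "time_domain_features",
    "frequency_domain_features",
    "nonlinear_features",
    "extract_features",
    "ExpertFeatureExtractor",
]

TIME_DOMAIN_NAMES = [
    "mean_baseline", "max_baseline", "min_baseline", "std_baseline",
    "nACC", "nDEC",
    "max_rr", "min_rr", "mean_rr", "median_rr", "std_rr", "skew_rr", "kurt_rr",
    "SDNN", "RMSSD", "NN50", "pNN50", "STV", "LTV", "Tri", "TINN",
]
FREQUENCY_DOMAIN_NAMES = [
    "rr_VLF", "rr_LF", "rr_MF", "rr_HF", "rr_Total_Power",
    "rr_percent_VLF", "rr_percent_LF", "rr_percent_MF", "rr_percent_HF",
    "rr_peak_VLF", "rr_peak_LF", "rr_peak_MF", "rr_peak_HF", "rr_ratio",
]
NONLINEAR_NAMES = [
    "SD1", "SD2", "SD_Ratio", "ApEn", "SampEn", "ShannEn", "FuzzyEn",
    "LZC", "FD", "Hurst",
]
FEATURE_NAMES = TIME_DOMAIN_NAMES + FREQUENCY_DOMAIN_NAMES + NONLINEAR_NAMES
#: Historical alias kept for the nonlinear ratio's original spelling.
FEATURE_NAME_ALIASES = {"SD_Ration": "SD_Ratio"}

#: Fetal HRV bands in Hz: very-low, low, medium, high frequency.
FREQUENCY_BANDS_HZ = {
    "VLF": (0.0, 0.03),
    "LF": (0.03, 0.15),
    "MF": (0.15, 0.5),
    "HF": (0.5, 1.0),
}

#: HRV histogram bin width for Tri/TINN, 1/128 s.
HIST_BIN_MS = 7.8125


@dataclass
class RRSeries:
    """Beat-interval series rr (ms) and successive differences nn (ms)."""

    rr: np.ndarray
    nn: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if np.any(self.rr <= 0):
            raise ValueError("rr intervals must be positive")
        self.nn = np.diff(self.rr)


@dataclass
class BaselineEstimate:
    """Running FHR baseline (bpm) plus detected accel/decel events."""

    baseline: np.ndarray
    events: List[Tuple[str, int, int]]

    @property
    def n_accelerations(self) -> int:
        return sum(1 for t, *_ in self.events if t == "acceleration")

    @property
    def n_decelerations(self) -> int:
        return sum(1 for t, *_ in self.events if t == "deceleration")


def fhr_to_rr(fhr: np.ndarray) -> RRSeries:
    """Samplewise conversion RR = 60000 / FHR (bpm -> ms)."""
    fhr = np.asarray(fhr, dtype=float)
    if np.any(fhr <= 0):
        raise ValueError("fhr contains non-positive samples; clean the signal first")
    return RRSeries(rr=60000.0 / fhr)


def estimate_baseline(
    fhr: np.ndarray,
    fs: float = SAMPLING_RATE_HZ,
    window_minutes: float = 10.0,
    trim_bpm: float = 15.0,
    n_iter: int = 3,
    event_threshold_bpm: float = 15.0,
    event_min_seconds: float = 15.0,
) -> BaselineEstimate:
    """Iterated trimmed moving-median baseline with FIGO-style event detection.

    The baseline starts as a centred moving median (default 10 min window)
    and is refined by re-computing the median with samples further than
    ``trim_bpm`` from the current estimate excluded, so accelerations and
    decelerations do not drag the baseline.  Events are excursions of at
    least ``event_threshold_bpm`` from the baseline sustained for at least
    ``event_min_seconds`` (FIGO convention: 15 bpm / 15 s).
    """
    fhr = np.asarray(fhr, dtype=float)
    if fhr.size < int(2 * 60 * fs):
        raise ValueError("baseline estimation needs at least 2 minutes of signal")
    win = max(3, int(round(window_minutes * 60 * fs)))
    s = pd.Series(fhr)
    baseline = s.rolling(win, center=True, min_periods=1).median().to_numpy()
    for _ in range(n_iter):
        masked = s.where(np.abs(fhr - baseline) <= trim_bpm)
        est = masked.rolling(win, center=True, min_periods=1).median()
        est = est.interpolate(limit_direction="both")
        baseline = est.to_numpy()
        if np.any(~np.isfinite(baseline)):  # everything trimmed: keep previous
            baseline = s.rolling(win, center=True, min_periods=1).median().to_numpy()
            break
    baseline = np.clip(baseline, 50.0, 240.0)

    min_run = int(round(event_min_seconds * fs))
    dev = fhr - baseline
    events: List[Tuple[str, int, int]] = []
    for kind, mask in (
        ("acceleration", dev >= event_threshold_bpm),
        ("deceleration", dev <= -event_threshold_bpm),
    ):
        events.extend((kind, s0, s1) for s0, s1 in _runs(mask, min_run))
    return BaselineEstimate(baseline=baseline, events=events)


def _runs(mask: np.ndarray, min_len: int) -> List[Tuple[int, int]]:
    """Half-open [start, end) index ranges of True runs of length >= min_len."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [
        (int(a), int(b))
        for a, b in zip(edges[::2], edges[1::2])
        if b - a >= min_len
    ]


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------


def time_domain_features(
    rr: RRSeries,
    base: BaselineEstimate,
    fs: float = SAMPLING_RATE_HZ,
) -> dict:
    if rr.rr.size < 2:
        raise ValueError("need at least 2 beat intervals")
    r, nn = rr.rr, rr.nn
    out = {
        "mean_baseline": float(base.baseline.mean()),
        "max_baseline": float(base.baseline.max()),
        "min_baseline": float(base.baseline.min()),
        "std_baseline": float(base.baseline.std()),
        "nACC": float(base.n_accelerations),
        "nDEC": float(base.n_decelerations),
        "max_rr": float(r.max()),
        "min_rr": float(r.min()),
        "mean_rr": float(r.mean()),
        "median_rr": float(np.median(r)),
        "std_rr": float(r.std()),
        "skew_rr": float(sp_stats.skew(r)) if r.std() > 0 else 0.0,
        "kurt_rr": float(sp_stats.kurtosis(r)) if r.std() > 0 else 0.0,
        "SDNN": float(nn.std()),
        "RMSSD": float(np.sqrt(np.mean(nn**2))),
        "NN50": float(np.count_nonzero(np.abs(nn) > 50.0)),
    }
    out["pNN50"] = 100.0 * out["NN50"] / nn.size
    epoch = max(1, int(round(2.5 * fs)))  # 2.5 s epochs
    n_ep = r.size // epoch
    em = r[: n_ep * epoch].reshape(n_ep, epoch).mean(axis=1)
    out["STV"] = float(np.mean(np.abs(np.diff(em)))) if n_ep >= 2 else 0.0
    per_min = int(round(60 * fs)) // epoch  # epochs per minute
    n_min = n_ep // per_min
    if n_min >= 1:
        mins = em[: n_min * per_min].reshape(n_min, per_min)
        out["LTV"] = float(np.mean(mins.max(axis=1) - mins.min(axis=1)))
    else:
        out["LTV"] = 0.0
    tri, tinn = _triangular_indices(r)
    out["Tri"] = tri
    out["TINN"] = tinn
    return out


def _triangular_indices(r: np.ndarray) -> Tuple[float, float]:
    """HRV triangular index and TINN on a fixed-width interval histogram.

    Tri = n / max bin count.  TINN is the base width (ms) of the least-
    squares triangle fitted to the histogram: zero outside [M, N], linear up
    to the mode and back down, searched over candidate (M, N) bin edges.
    """
    lo = np.floor(r.min() / HIST_BIN_MS) * HIST_BIN_MS
    hi = np.ceil(r.max() / HIST_BIN_MS) * HIST_BIN_MS
    n_bins = max(1, int(round((hi - lo) / HIST_BIN_MS)))
    edges = lo + HIST_BIN_MS * np.arange(n_bins + 1)
    counts, _ = np.histogram(r, bins=edges)
    peak = int(counts.argmax())
    tri = float(r.size / counts.max())
    if n_bins < 3:
        return tri, float(HIST_BIN_MS * n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    x_mode, y = centers[peak], float(counts[peak])
    best, best_err = (centers[0], centers[-1]), np.inf
    for mi in range(0, peak + 1):
        for ni in range(peak, n_bins):
            m_ms, n_ms = centers[mi], centers[ni]
            q = np.zeros(n_bins)
            left = (centers >= m_ms) & (centers <= x_mode)
            right = (centers > x_mode) & (centers <= n_ms)
            if x_mode > m_ms:
                q[left] = y * (centers[left] - m_ms) / (x_mode - m_ms)
            else:
                q[left] = y
            if n_ms > x_mode:
                q[right] = y * (n_ms - centers[right]) / (n_ms - x_mode)
            err = float(((counts - q) ** 2).sum())
            if err < best_err:
                best_err, best = err, (m_ms, n_ms)
    return tri, float(best[1] - best[0])


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------


def frequency_domain_features(rr: RRSeries, fs: float = SAMPLING_RATE_HZ) -> dict:
    """Band powers/percentages/peaks of the FFT periodogram of rr.

    The rr series is mean-detrended and linearly resampled onto a uniform
    4 Hz grid against cumulative beat time, then a one-sided periodogram is
    integrated over the four bands (powers in ms^2).  Total power is the sum
    of the four band powers, so the percentages sum to 100.
    """
    r = rr.rr
    if r.sum() < 5 * 60 * 1000.0:
        raise ValueError("rr series must span at least 5 minutes")
    t = np.cumsum(r) / 1000.0  # cumulative beat time, s
    t = t - t[0]
    grid = np.arange(0.0, t[-1], 1.0 / fs)
    u = np.interp(grid, t, r)
    u = u - u.mean()
    freqs, psd = sp_signal.periodogram(u, fs=fs, window="boxcar", detrend=False)
    df = freqs[1] - freqs[0]
    out = {}
    for name, (f0, f1) in FREQUENCY_BANDS_HZ.items():
        band = (freqs >= f0) & (freqs < f1) if name != "HF" else (
            (freqs >= f0) & (freqs <= f1)
        )
        if band.any():
            out[f"rr_{name}"] = float(psd[band].sum() * df)
            out[f"rr_peak_{name}"] = float(freqs[band][psd[band].argmax()])
        else:
            out[f"rr_{name}"] = 0.0
            out[f"rr_peak_{name}"] = 0.0
    total = sum(out[f"rr_{n}"] for n in FREQUENCY_BANDS_HZ)
    out["rr_Total_Power"] = total
    for name in FREQUENCY_BANDS_HZ:
        out[f"rr_percent_{name}"] = (
            100.0 * out[f"rr_{name}"] / total if total > 0 else 0.0
        )
    denom = out["rr_MF"] + out["rr_HF"]
    out["rr_ratio"] = out["rr_LF"] / denom if denom > 0 else 0.0
    return {k: out[k] for k in FREQUENCY_DOMAIN_NAMES}


# ---------------------------------------------------------------------------
# Nonlinear
# ---------------------------------------------------------------------------


def nonlinear_features(
    rr: RRSeries,
    m: int = 2,
    r_fraction: float = 0.2,
    shannon_bins: int = 16,
    higuchi_kmax: int = 10,
) -> dict:
    """Poincaré, entropy, complexity and fractal statistics of rr.

    SD1 uses the uncentered second moment of successive differences so the
    classical identity SD1 = RMSSD / sqrt(2) holds exactly; SD2 is the
    centred dispersion along the line of identity.  Degenerate constant
    series return 0 for the entropies and ratio.
    """
    x = rr.rr
    if x.size < 100:
        raise ValueError("nonlinear features need at least 100 beat intervals")
    d = np.diff(x)
    s = (x[1:] + x[:-1]) / np.sqrt(2.0)
    sd1 = float(np.sqrt(np.mean(d**2) / 2.0))
    sd2 = float(s.std())
    tol = r_fraction * x.std()
    return {
        "SD1": sd1,
        "SD2": sd2,
        "SD_Ratio": sd2 / sd1 if sd1 > 0 else 0.0,
        "ApEn": _entropy.approximate_entropy(x, m=m, r=tol),
        "SampEn": _entropy.sample_entropy(x, m=m, r=tol),
        "ShannEn": _entropy.shannon_entropy(x, bins=shannon_bins),
        "FuzzyEn": _entropy.fuzzy_entropy(x, m=m, r=tol),
        "LZC": _entropy.lempel_ziv_complexity(x),
        "FD": _entropy.higuchi_fd(x, kmax=higuchi_kmax),
        "Hurst": _entropy.hurst_rs(x),
    }


def extract_features(record: FHRRecord) -> np.ndarray:
    """The ordered 45-feature vector of a cleaned, windowed record."""
    fhr = record.fhr
    if np.any(fhr <= 0):
        raise ValueError("record contains missing samples; clean it first")
    rr = fhr_to_rr(fhr)
    base = estimate_baseline(fhr, fs=record.fs)
    vals = {}
    vals.update(time_domain_features(rr, base, fs=record.fs))
    vals.update(frequency_domain_features(rr, fs=record.fs))
    vals.update(nonlinear_features(rr))
    vec = np.array([vals[name] for name in FEATURE_NAMES], dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [n for n, v in zip(FEATURE_NAMES, vec) if not np.isfinite(v)]
        raise AssertionError(f"non-finite features: {bad}")
    return vec


class ExpertFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping (n, 7200) cleaned FHR windows to (n, 45) features.

    Stateless: ``fit`` only validates input.  Use
    :func:`get_feature_names_out` for the column names.
    """

    def __init__(self, fs: float = SAMPLING_RATE_HZ):
        self.fs = fs

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (n_records, n_samples)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.stack(
            [extract_features(FHRRecord(fhr=row, fs=self.fs)) for row in X]
        )

    def get_feature_names_out(self, input_features=None):
        return np.array(FEATURE_NAMES, dtype=object)
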