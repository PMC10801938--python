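"""Seeded synthetic cardiotocogram generator.

Emulates the statistical structure the classifier assumes in 4 Hz FHR
traces: a slowly drifting baseline in the normal 110–160 bpm range,
band-structured variability (sinusoidal components in the four fetal HRV
bands plus Gaussian noise), Poisson-placed acceleration/deceleration ramps,
contiguous missing-sample dropouts (encoded as 0), and class-conditional
umbilical-artery pH.  Pathological traces (acidosis) have reduced
variability and more decelerations, mirroring the clinical picture of
fetal hypoxia; effect sizes are configurable.

Raw traces are generated at 12 000 samples (50 min) so that records with
modest dropout still clear the 10 000-valid-sample completeness filter
before the last-30-minute window is taken.

Also provides :func:`make_fixture` — signals with analytically known
feature values used as oracles in unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats as sp_stats

from .records import (
    FHRRecord,
    LABEL_NORMAL,
    LABEL_PATHOLOGICAL,
    PH_THRESHOLD,
    SAMPLING_RATE_HZ,
    WINDOW_SAMPLES,
)

__all__ = ["SimConfig", "simulate_fhr", "simulate_dataset", "make_fixture"]

#: Raw samples generated before windowing (50 min at 4 Hz).
RAW_SAMPLES = 12_000


@dataclass
class SimConfig:
    """Generative parameters of the synthetic CTG model.

    Rates are events per 30 minutes; amplitudes in bpm; the pathological
    class multiplies variability by ``variability_multiplier`` (< 1) and
    adds ``decel_rate_shift`` (> 0) decelerations per 30 minutes.
    """

    baseline_mean_bpm: float = 135.0
    baseline_spread_bpm: float = 10.0   # per-record baseline draw, uniform +-
    drift_amplitude_bpm: float = 5.0
    drift_period_s: float = 1200.0
    variability_sd_bpm: float = 2.0
    #: sinusoidal amplitude (bpm) per HRV band, at band-centre frequencies
    band_amplitudes_bpm: Tuple[float, float, float, float] = (4.0, 3.0, 1.5, 0.8)
    band_freqs_hz: Tuple[float, float, float, float] = (0.01, 0.08, 0.3, 0.7)
    accel_rate: float = 3.0
    decel_rate: float = 1.0
    event_amplitude_bpm: float = 20.0
    event_duration_s: float = 60.0
    dropout_fraction: float = 0.05
    dropout_run_s: float = 15.0
    variability_multiplier: float = 0.5
    decel_rate_shift: float = 3.0
    ph_normal: Tuple[float, float] = (7.25, 0.05)        # mean, sd (>= 7.15)
    ph_pathological: Tuple[float, float] = (7.05, 0.05)  # mean, sd (< 7.15)
    deterministic_events: bool = False
    raw_samples: int = RAW_SAMPLES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accel_rate < 0 or self.decel_rate < 0:
            raise ValueError("event rates must be nonnegative")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")
        if not 0 < self.variability_multiplier <= 1:
            raise ValueError("pathological variability multiplier must be in (0, 1]")
        if self.decel_rate_shift < 0:
            raise ValueError("pathological decel-rate shift must be >= 0")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float,
    lo: float = -np.inf, hi: float = np.inf,
) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(
        sp_stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    )


def _event_profile(n: int, fs: float, duration_s: float) -> np.ndarray:
    """Trapezoidal excursion profile: 25% ramp up, 50% plateau, 25% down."""
    m = max(4, int(round(duration_s * fs)))
    ramp = max(1, m // 4)
    prof = np.ones(m)
    prof[:ramp] = np.linspace(0, 1, ramp, endpoint=False)
    prof[m - ramp :] = np.linspace(1, 0, ramp)
    return prof[:n]


def simulate_fhr(
    cfg: SimConfig, label: int, rng: Optional[np.random.Generator] = None,
    record_id: str = "",
) -> FHRRecord:
    """Generate one labelled synthetic raw record (12 000 samples at 4 Hz).

    The record passes through the same pipeline as real data: completeness
    filter, cleaning, then windowing to the last 7200 samples.  The trace
    is baseline drift + band sinusoids (random phase) + Gaussian
    variability + accel/decel ramps, clipped to [50, 240] bpm; a
    ``dropout_fraction`` of samples is then zeroed in contiguous runs.  pH
    is drawn from the class-conditional truncated normal so the labelling
    rule reproduces ``label``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    path = label == LABEL_PATHOLOGICAL
    n = cfg.raw_samples
    fs = SAMPLING_RATE_HZ
    t = np.arange(n) / fs

    base = cfg.baseline_mean_bpm + rng.uniform(
        -cfg.baseline_spread_bpm, cfg.baseline_spread_bpm
    )
    drift = cfg.drift_amplitude_bpm * np.sin(
        2 * np.pi * t / cfg.drift_period_s + rng.uniform(0, 2 * np.pi)
    )
    mult = cfg.variability_multiplier if path else 1.0
    x = base + drift
    for amp, f in zip(cfg.band_amplitudes_bpm, cfg.band_freqs_hz):
        x = x + mult * amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    x = x + rng.normal(0.0, mult * cfg.variability_sd_bpm, size=n)

    minutes = n / fs / 60.0
    accel_mean = cfg.accel_rate * minutes / 30.0
    decel_mean = (cfg.decel_rate + (cfg.decel_rate_shift if path else 0.0)) * (
        minutes / 30.0
    )
    if cfg.deterministic_events:
        n_acc, n_dec = int(round(accel_mean)), int(round(decel_mean))
    else:
        n_acc = int(rng.poisson(accel_mean))
        n_dec = int(rng.poisson(decel_mean))
    dur = int(round(cfg.event_duration_s * fs))
    occupied = np.zeros(n, dtype=bool)
    for sign, count in ((+1.0, n_acc), (-1.0, n_dec)):
        placed = 0
        for _ in range(200):  # rejection sampling of non-overlapping slots
            if placed >= count:
                break
            start = int(rng.integers(0, max(1, n - dur)))
            pad = dur // 2  # keep events separated so detection is unambiguous
            s0, s1 = max(0, start - pad), min(n, start + dur + pad)
            if occupied[s0:s1].any():
                continue
            prof = _event_profile(n - start, fs, cfg.event_duration_s)
            x[start : start + prof.size] += sign * cfg.event_amplitude_bpm * prof
            occupied[s0:s1] = True
            placed += 1
    x = np.clip(x, 50.0, 240.0)

    if cfg.dropout_fraction > 0:
        target = int(round(cfg.dropout_fraction * n))
        run = max(1, int(round(cfg.dropout_run_s * fs)))
        dropped = 0
        guard = 0
        while dropped < target and guard < 1000:
            guard += 1
            start = int(rng.integers(0, n - 1))
            length = min(run, target - dropped, n - start)
            seg = x[start : start + length]
            fresh = int(np.count_nonzero(seg))
            seg[:] = 0.0
            dropped += fresh
    mean_ph, sd_ph = cfg.ph_pathological if path else cfg.ph_normal
    if path:
        ph = _truncated_normal(rng, mean_ph, sd_ph, hi=PH_THRESHOLD - 1e-9)
    else:
        ph = _truncated_normal(rng, mean_ph, sd_ph, lo=PH_THRESHOLD)
    return FHRRecord(fhr=x, ph=ph, record_id=record_id or f"sim-{cfg.seed}",
                     label=int(label))


def simulate_dataset(
    n: int,
    balance: float = 0.5,
    cfg: Optional[SimConfig] = None,
    seed: Optional[int] = None,
) -> List[FHRRecord]:
    """Generate ``n`` records with the requested pathological fraction.

    Per-record seeds are spawned from the dataset seed, so records are
    independent and the whole dataset is reproducible.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < balance < 1:
        raise ValueError("balance must be strictly between 0 and 1")
    cfg = cfg or SimConfig()
    seed = cfg.seed if seed is None else seed
    n_path = int(round(n * balance))
    n_path = min(max(n_path, 1), n - 1)
    labels = np.array(
        [LABEL_PATHOLOGICAL] * n_path + [LABEL_NORMAL] * (n - n_path)
    )
    ss = np.random.SeedSequence(seed)
    np.random.default_rng(ss.spawn(1)[0]).shuffle(labels)
    records = []
    for i, (child, lab) in enumerate(zip(np.random.SeedSequence((seed, 1)).spawn(n), labels)):
        rng = np.random.default_rng(child)
        records.append(
            simulate_fhr(cfg, int(lab), rng=rng, record_id=f"sim-{seed}-{i:04d}")
        )
    return records


def make_fixture(kind: str, n: int = WINDOW_SAMPLES, **kwargs) -> FHRRecord:
    """Analytic test signals with known feature values.

    Kinds
    -----
    ``constant``
        Flat trace at ``bpm`` (default 140): zero variability, no events.
    ``band_sinusoid``
        rr(t) = ``rr_mean`` + ``rr_amplitude`` * sin(2 pi f t) with ``freq``
        in Hz: the rr spectral peak falls in the band containing ``freq``.
    ``alternating_rr``
        rr alternates (a, b) ms: RMSSD = |b - a| exactly.
    ``white_noise``
        rr = ``rr_mean`` + N(0, ``rr_sd``), seeded: Hurst exponent near 0.5.
    """
    t = np.arange(n) / SAMPLING_RATE_HZ
    if kind == "constant":
        bpm = kwargs.get("bpm", 140.0)
        fhr = np.full(n, float(bpm))
    elif kind == "band_sinusoid":
        # The spectral estimator resamples rr against cumulative rr time, so
        # the oracle sinusoid is generated in that time base: each sample's
        # phase advances by its own interval.
        freq = kwargs.get("freq", 0.1)
        mean = kwargs.get("rr_mean", 430.0)
        amp = kwargs.get("rr_amplitude", 40.0)
        rr = np.empty(n)
        tcum = 0.0
        for i in range(n):
            rr[i] = mean + amp * np.sin(2 * np.pi * freq * tcum)
            tcum += rr[i] / 1000.0
        fhr = 60000.0 / rr
    elif kind == "alternating_rr":
        a, b = kwargs.get("a", 500.0), kwargs.get("b", 560.0)
        rr = np.where(np.arange(n) % 2 == 0, a, b).astype(float)
        fhr = 60000.0 / rr
    elif kind == "white_noise":
        rng = np.random.default_rng(kwargs.get("seed", 0))
        rr = kwargs.get("rr_mean", 430.0) + rng.normal(
            0.0, kwargs.get("rr_sd", 20.0), size=n
        )
        fhr = 60000.0 / rr
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return FHRRecord(fhr=fhr, record_id=f"fixture-{kind}")
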