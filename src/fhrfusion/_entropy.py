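"""Entropy, complexity and fractal estimators for beat-interval series.

ApEn / SampEn / FuzzyEn are O(n^2) template-matching statistics; the pairwise
loops are compiled with numba so full-rate 7200-sample windows stay cheap.
All estimators take the series in its natural units (ms) and return
dimensionless values.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "approximate_entropy",
    "sample_entropy",
    "fuzzy_entropy",
    "shannon_entropy",
    "lempel_ziv_complexity",
    "lz76_word_count",
    "higuchi_fd",
    "hurst_rs",
]


@njit(cache=True)
def _apen_phis(x, m, r):
    n = x.size
    nm = n - m  # number of (m+1)-templates; m-templates = nm + 1
    cm = np.ones(nm + 1)   # self-match included
    cm1 = np.ones(nm)
    for i in range(nm + 1):
        for j in range(i + 1, nm + 1):
            d = 0.0
            for t in range(m):
                diff = abs(x[i + t] - x[j + t])
                if diff > d:
                    d = diff
            if d <= r:
                cm[i] += 1.0
                cm[j] += 1.0
                if i < nm and j < nm:
                    d1 = d
                    diff = abs(x[i + m] - x[j + m])
                    if diff > d1:
                        d1 = diff
                    if d1 <= r:
                        cm1[i] += 1.0
                        cm1[j] += 1.0
    phi_m = 0.0
    for i in range(nm + 1):
        phi_m += np.log(cm[i] / (nm + 1))
    phi_m /= nm + 1
    phi_m1 = 0.0
    for i in range(nm):
        phi_m1 += np.log(cm1[i] / nm)
    phi_m1 /= nm
    return phi_m, phi_m1


@njit(cache=True)
def _sampen_counts(x, m, r):
    n = x.size
    nm = n - m
    b = 0.0  # m-template matches (i < j), last m-template excluded as usual
    a = 0.0  # (m+1)-template matches
    for i in range(nm - 1):
        for j in range(i + 1, nm):
            d = 0.0
            for t in range(m):
                diff = abs(x[i + t] - x[j + t])
                if diff > d:
                    d = diff
            if d <= r:
                b += 1.0
                diff = abs(x[i + m] - x[j + m])
                if diff <= r and d <= r:
                    if max(d, diff) <= r:
                        a += 1.0
    return a, b


@njit(cache=True)
def _fuzzyen_phis(x, m, r):
    # Templates are mean-centred; membership exp(-(d/r)^2), fuzziness
    # exponent 2.  Self-matches excluded.
    n = x.size
    nm = n - m
    mu_m = np.empty(nm + 1)
    mu_m1 = np.empty(nm)
    for i in range(nm + 1):
        s = 0.0
        for t in range(m):
            s += x[i + t]
        mu_m[i] = s / m
    for i in range(nm):
        s = 0.0
        for t in range(m + 1):
            s += x[i + t]
        mu_m1[i] = s / (m + 1)
    phi_m = 0.0
    phi_m1 = 0.0
    for i in range(nm + 1):
        for j in range(i + 1, nm + 1):
            d = 0.0
            for t in range(m):
                diff = abs((x[i + t] - mu_m[i]) - (x[j + t] - mu_m[j]))
                if diff > d:
                    d = diff
            phi_m += 2.0 * np.exp(-((d / r) ** 2))
    for i in range(nm):
        for j in range(i + 1, nm):
            d = 0.0
            for t in range(m + 1):
                diff = abs((x[i + t] - mu_m1[i]) - (x[j + t] - mu_m1[j]))
                if diff > d:
                    d = diff
            phi_m1 += 2.0 * np.exp(-((d / r) ** 2))
    phi_m /= (nm + 1) * nm
    phi_m1 /= nm * (nm - 1)
    return phi_m, phi_m1


def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy (regularity statistic, self-matches included)."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if r is None:
        r = 0.2 * x.std()
    if x.size < m + 2 or r <= 0:
        return 0.0
    phi_m, phi_m1 = _apen_phis(x, m, r)
    return float(max(phi_m - phi_m1, 0.0))

def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Sample entropy -ln(A/B) with tolerance ``r`` (default 0.2*std)."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if r is None:
        r = 0.2 * x.std()
    if x.size < m + 2 or r <= 0:
        return 0.0
    a, b = _sampen_counts(x, m, r)
    if a == 0 or b == 0:
        return 0.0
    return float(-np.log(a / b))

def fuzzy_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Fuzzy entropy with Gaussian-like membership exp(-(d/r)^2)."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if r is None:
        r = 0.2 * x.std()
    if x.size < m + 3 or r <= 0:
        return 0.0
    phi_m, phi_m1 = _fuzzyen_phis(x, m, r)
    if phi_m <= 0 or phi_m1 <= 0:
        return 0.0
    return float(max(np.log(phi_m) - np.log(phi_m1), 0.0))


def shannon_entropy(x, bins: int = 16) -> float:
    """Shannon entropy (bits) of the amplitude histogram."""
    x = np.asarray(x, dtype=float)
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


@njit(cache=True)
def _lz76_count(s: np.ndarray) -> int:
    n = s.size
    if n == 0:
        return 0
    c, i, k, l = 1, 0, 1, 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def lz76_word_count(bits: np.ndarray) -> int:
    """Number of distinct phrases in the Lempel–Ziv 1976 parsing."""
    return int(_lz76_count(np.ascontiguousarray(bits, dtype=np.uint8)))


def lempel_ziv_complexity(x) -> float:
    """Normalized LZ complexity of the median-binarized series.

    The raw phrase count c is normalized by n / log2(n), the asymptotic
    phrase count of a random binary sequence.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 0.0
    bits = x >= np.median(x)
    c = lz76_word_count(bits)
    return float(c / (n / np.log2(n)))


def higuchi_fd(x, kmax: int = 10) -> float:
    """Higuchi fractal dimension (slope of log curve length vs log 1/k)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    lk = []
    ks = []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            seg = x[m::k]
            if seg.size < 2:
                continue
            lm = np.abs(np.diff(seg)).sum() * (n - 1) / (seg.size - 1) / k / k
            lengths.append(lm)
        if lengths:
            mean_l = np.mean(lengths)
            if mean_l > 0:
                lk.append(np.log(mean_l))
                ks.append(np.log(1.0 / k))
    if len(lk) < 2:
        return 1.0  # degenerate (e.g. constant) series: a flat curve
    slope = np.polyfit(ks, lk, 1)[0]
    return float(slope)


def hurst_rs(x, min_window: int = 10) -> float:
    """Hurst exponent by rescaled-range (R/S) analysis.

    Window sizes are log-spaced between ``min_window`` and n/2; the exponent
    is the slope of log(R/S) against log(window).  White noise gives ~0.5,
    persistent series > 0.5.  Degenerate constant input returns 0.5.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 * min_window or np.ptp(x) == 0:
        return 0.5
    sizes = np.unique(
        np.floor(np.logspace(np.log10(min_window), np.log10(n // 2), 12)).astype(int)
    )
    log_rs, log_n = [], []
    for w in sizes:
        n_chunks = n // w
        if n_chunks < 1:
            continue
        rs_vals = []
        for c in range(n_chunks):
            seg = x[c * w : (c + 1) * w]
            dev = seg - seg.mean()
            z = np.cumsum(dev)
            r = np.ptp(z)
            s = seg.std()
            if s > 0:
                rs_vals.append(r / s)
        if rs_vals:
            log_rs.append(np.log(np.mean(rs_vals)))
            log_n.append(np.log(w))
    if len(log_rs) < 2:
        return 0.5
    return float(np.polyfit(log_n, log_rs, 1)[0])
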