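"""Empirical mode decomposition and its ensemble variant.

EMD decomposes a signal into intrinsic mode functions (IMFs) by iterative
"sifting": at each step the mean of the upper and lower cubic-spline envelopes
(through local maxima and minima respectively) is subtracted until the result
is approximately symmetric around zero.  Ensemble EMD (EEMD) repeats the
decomposition on noise-perturbed copies of the signal and averages the IMFs
index-wise, which alleviates mode mixing; here the perturbation is white
Gaussian noise scaled to ``noise_level`` times the signal standard deviation.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

__all__ = ["emd", "eemd", "instantaneous_frequency", "mean_imf_frequency"]


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (plateau-safe)."""
    dx = np.diff(x)
    # sign of slope, carrying the previous sign across flat runs
    s = np.sign(dx)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    turn = np.diff(s)
    idx = np.nonzero(turn)[0] + 1
    maxima = idx[turn[idx - 1] < 0]
    minima = idx[turn[idx - 1] > 0]
    return maxima, minima


def _envelope(x: np.ndarray, extrema: np.ndarray, kind: str) -> np.ndarray | None:
    """Cubic-spline envelope through extrema, with mirrored boundary extrema."""
    n = len(x)
    if len(extrema) < 2:
        return None
    # mirror the two outermost extrema beyond each boundary to tame end swings
    left_t = [-extrema[1], -extrema[0]]
    right_t = [2 * (n - 1) - extrema[-1], 2 * (n - 1) - extrema[-2]]
    t = np.concatenate([left_t, extrema, right_t])
    v = np.concatenate([[x[extrema[1]], x[extrema[0]]], x[extrema],
                        [x[extrema[-1]], x[extrema[-2]]]])
    order = np.argsort(t)
    t, v = t[order], v[order]
    keep = np.concatenate([[True], np.diff(t) > 0])
    cs = CubicSpline(t[keep], v[keep])
    return cs(np.arange(n))


def _sift(x: np.ndarray, max_siftings: int = 10, sd_tol: float = 0.2) -> np.ndarray | None:
    """Extract one IMF from ``x``; None when too few extrema remain."""
    h = x
    for _ in range(max_siftings):
        maxima, minima = _local_extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            return None if h is x else h
        upper = _envelope(h, maxima, "max")
        lower = _envelope(h, minima, "min")
        if upper is None or lower is None:
            return None if h is x else h
        mean = 0.5 * (upper + lower)
        h_new = h - mean
        denom = np.sum(h * h)
        if denom > 0 and np.sum(mean * mean) / denom < sd_tol ** 2:
            return h_new
        h = h_new
    return h


def emd(signal: np.ndarray, n_imfs: int = 10, max_siftings: int = 10) -> np.ndarray:
    """Decompose ``signal`` into up to ``n_imfs`` IMFs.

    Returns an ``(n_imfs, n)`` array; trailing rows are zero when the residual
    becomes monotone before ``n_imfs`` modes are found.  The residual is
    ``signal - imfs.sum(axis=0)`` by construction, so reconstruction is exact.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    imfs = np.zeros((n_imfs, len(x)))
    resid = x.copy()
    for k in range(n_imfs):
        imf = _sift(resid, max_siftings=max_siftings)
        if imf is None:
            break
        imfs[k] = imf
        resid = resid - imf
    return imfs


def eemd(
    signal: np.ndarray,
    n_imfs: int = 10,
    n_realizations: int = 2000,
    noise_level: float = 0.3,
    rng: np.random.Generator | int | None = None,
    max_siftings: int = 10,
) -> np.ndarray:
    """Ensemble EMD: average of EMDs of noise-perturbed copies.

    ``noise_level`` scales the added white-noise standard deviation relative to
    the signal's.  ``n_realizations=1`` or ``noise_level=0`` degrade to plain
    EMD.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if n_realizations <= 1 or noise_level == 0:
        return emd(x, n_imfs=n_imfs, max_siftings=max_siftings)
    rng = np.random.default_rng(rng)
    sd = noise_level * np.std(x)
    acc = np.zeros((n_imfs, len(x)))
    for _ in range(n_realizations):
        noisy = x + rng.normal(0.0, sd, size=len(x))
        acc += emd(noisy, n_imfs=n_imfs, max_siftings=max_siftings)
    return acc / n_realizations


def instantaneous_frequency(imf: np.ndarray, fs: float, smooth_ms: float = 10.0) -> np.ndarray:
    """Instantaneous frequency (Hz) from the analytic-signal phase derivative."""
    phase = np.unwrap(np.angle(hilbert(imf)))
    freq = np.gradient(phase) * fs / (2.0 * np.pi)
    w = max(1, int(round(smooth_ms * fs / 1000.0)))
    if w > 1:
        kernel = np.ones(w) / w
        freq = np.convolve(freq, kernel, mode="same")
    return freq


def mean_imf_frequency(imf: np.ndarray, fs: float, stat: str = "mean") -> float:
    """Mean (or median) instantaneous frequency of one IMF, edges trimmed 5%."""
    if not np.any(imf):
        return 0.0
    freq = instantaneous_frequency(imf, fs)
    n = len(freq)
    lo, hi = int(0.05 * n), n - int(0.05 * n)
    core = freq[lo:hi] if hi > lo else freq
    if stat == "median":
        return float(np.median(core))
    if stat == "mean":
        return float(np.mean(core))
    raise ValueError(f"unknown stat {stat!r}")
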