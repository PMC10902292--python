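"""Theta-cycle segmentation, waveform phase, selection, and cycle snippets.

Cycles are delimited peak-to-peak on the fissure theta composite; the trough
is the minimum between peaks and the flanks the half-amplitude points between
trough and each peak.  Phase is assigned by piecewise-linear interpolation
over the four quadrants (start peak 0, descending flank 90, trough 180,
ascending flank 270, end peak 360 deg) rather than by the Hilbert transform,
which respects the asymmetry of real theta waves.

A cycle is accepted when its duration is theta-compatible (83-250 ms), the
theta-composite envelope exceeds the 1-4 Hz infra-theta envelope at the cycle
start, mid and end points, and at least one behavior-track sample falls inside
the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, hilbert

DUR_MIN_MS = 83.0
DUR_MAX_MS = 250.0


@dataclass
class ThetaCycle:
    """One candidate theta cycle with landmarks (sample indices) and features."""

    start_peak: int
    desc_flank: int
    trough: int
    asc_flank: int
    end_peak: int
    fs: float = 1000.0
    accepted: bool = True
    reject_reason: str = ""

    # derived features, filled by detect_candidate_cycles
    amplitude: float = np.nan
    duration_ms: float = np.nan
    frequency: float = np.nan
    asymmetry: float = np.nan

    @property
    def mid(self) -> int:
        return (self.start_peak + self.end_peak) // 2


def _half_crossing(signal: np.ndarray, peak: int, trough: int, descending: bool) -> int:
    """Sample index of the half-amplitude point between a peak and the trough."""
    level = 0.5 * (signal[peak] + signal[trough])
    if descending:
        seg = signal[peak:trough + 1]
        below = np.nonzero(seg <= level)[0]
        off = below[0] if len(below) else len(seg) - 1
        return peak + int(off)
    seg = signal[trough:peak + 1]
    above = np.nonzero(seg >= level)[0]
    off = above[0] if len(above) else len(seg) - 1
    return trough + int(off)


def detect_candidate_cycles(theta: np.ndarray, fs: float = 1000.0,
                            min_peak_distance_ms: float = 80.0) -> list[ThetaCycle]:
    """Segment the theta composite into consecutive peak-to-peak candidate cycles.

    Peak detection enforces a minimum inter-peak distance just below the
    shortest admissible cycle (80 ms) to suppress ripple-induced double peaks.
    Returns an empty list when fewer than two peaks exist.
    """
    x = np.asarray(theta, dtype=float)
    if np.ptp(x) == 0:
        return []
    peaks, _ = find_peaks(x, distance=max(1, int(min_peak_distance_ms * fs / 1000)))
    cycles = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        trough = p0 + int(np.argmin(x[p0:p1 + 1]))
        if trough <= p0 or trough >= p1:
            continue
        desc = _half_crossing(x, p0, trough, descending=True)
        asc = _half_crossing(x, p1, trough, descending=False)
        if not (p0 < desc < trough < asc < p1):
            # flat or degenerate shoulders; nudge flanks to quadrant midpoints
            desc = (p0 + trough) // 2
            asc = (trough + p1) // 2
            if not (p0 < desc < trough < asc < p1):
                continue
        dur_ms = (p1 - p0) / fs * 1000.0
        cyc = ThetaCycle(
            start_peak=int(p0), desc_flank=int(desc), trough=int(trough),
            asc_flank=int(asc), end_peak=int(p1), fs=fs,
            amplitude=float(0.5 * ((x[p0] - x[trough]) + (x[p1] - x[trough]))),
            duration_ms=dur_ms,
            frequency=1000.0 / dur_ms,
            asymmetry=float((p1 - trough) / max(1, trough - p0)),
        )
        cycles.append(cyc)
    return cycles


def waveform_phase(cycle: ThetaCycle, t: np.ndarray | int) -> np.ndarray | float:
    """Waveform phase (deg) at sample index/indices ``t`` within the cycle.

    Piecewise linear over the quadrants: 0 at the start peak, 90 at the
    descending flank, 180 at the trough, 270 at the ascending flank, 360 at
    the end peak.
    """
    scalar = np.isscalar(t)
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if tt.min() < cycle.start_peak or tt.max() > cycle.end_peak:
        raise ValueError("sample index outside cycle span")
    xp = [cycle.start_peak, cycle.desc_flank, cycle.trough, cycle.asc_flank,
          cycle.end_peak]
    fp = [0.0, 90.0, 180.0, 270.0, 360.0]
    out = np.interp(tt, xp, fp)
    return float(out[0]) if scalar else out


def envelope(signal: np.ndarray) -> np.ndarray:
    """Analytic-signal magnitude."""
    return np.abs(hilbert(np.asarray(signal, dtype=float)))


def select_cycles(
    cycles: list[ThetaCycle],
    theta_env: np.ndarray,
    infra_env: np.ndarray,
    behavior_times: np.ndarray | None = None,
    mid_point: str = "temporal",
) -> list[ThetaCycle]:
    """Apply the selection criteria in place and return the accepted cycles.

    ``mid_point`` chooses the cycle "mid" sample for the power criterion:
    "temporal" (midpoint of the span, default) or "trough".
    """
    accepted = []
    for c in cycles:
        mid = c.mid if mid_point == "temporal" else c.trough
        if not (DUR_MIN_MS <= c.duration_ms <= DUR_MAX_MS):
            c.accepted, c.reject_reason = False, "duration"
        elif not all(theta_env[i] > infra_env[i]
                     for i in (c.start_peak, mid, c.end_peak)):
            c.accepted, c.reject_reason = False, "power"
        elif behavior_times is not None and not np.any(
                (behavior_times >= c.start_peak / c.fs)
                & (behavior_times <= c.end_peak / c.fs)):
            c.accepted, c.reject_reason = False, "no_video"
        else:
            c.accepted, c.reject_reason = True, ""
            accepted.append(c)
    return accepted


N_PHASE_BINS = 36  # 10 deg bins


def build_cycle_snippet(spectrogram: np.ndarray, cycle: ThetaCycle) -> np.ndarray:
    """Average the spectrogram per 10-deg waveform-phase bin -> (38, 36) matrix.

    ``spectrogram`` is (n_freqs, n_samples) covering the cycle span.  Phase
    bins left empty by short cycles are filled by linear interpolation across
    phase (circularly at the edges).
    """
    if cycle.end_peak >= spectrogram.shape[1]:
        raise ValueError("cycle extends beyond the spectrogram")
    idx = np.arange(cycle.start_peak, cycle.end_peak + 1)
    phases = waveform_phase(cycle, idx)
    bins = np.minimum((phases / 10.0).astype(int), N_PHASE_BINS - 1)
    nf = spectrogram.shape[0]
    out = np.full((nf, N_PHASE_BINS), np.nan)
    for b in range(N_PHASE_BINS):
        m = bins == b
        if m.any():
            out[:, b] = spectrogram[:, idx[m]].mean(axis=1)
    # interpolate empty bins circularly across phase
    empty = np.isnan(out[0])
    if empty.any() and not empty.all():
        filled = np.nonzero(~empty)[0]
        for row in range(nf):
            out[row, empty] = np.interp(
                np.nonzero(empty)[0], filled, out[row, filled],
                period=N_PHASE_BINS)
    return out
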