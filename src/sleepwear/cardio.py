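"""R-peak detection (Pan-Tompkins) and R-R interval series.

The detector follows the classic real-time QRS recipe — 5–15 Hz bandpass,
differentiation, squaring, 150-ms moving-window integration, adaptive dual
thresholds with a 200-ms refractory period and search-back — applied
offline with zero-phase filtering so detected fiducials keep their raw
timing. Each fiducial is finally localized to the raw-signal maximum
within ±50 ms.

Physiologically implausible R-R intervals (outside 300–2000 ms) are
rejected before any feature computation via :func:`plausible_rr`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

RR_PLAUSIBLE_MS = (300.0, 2000.0)

_REFRACTORY_S = 0.200
_INTEGRATION_S = 0.150
_SEARCHBACK_FACTOR = 1.66
_LOCALIZE_S = 0.050


@dataclass
class RRSeries:
    """Ascending R-peak times (s) and the successive R-R intervals (ms)."""

    rpeak_times: np.ndarray
    rr_intervals: np.ndarray

    def __post_init__(self) -> None:
        self.rpeak_times = np.asarray(self.rpeak_times, dtype=float)
        self.rr_intervals = np.asarray(self.rr_intervals, dtype=float)
        if len(self.rpeak_times) > 1 and np.any(np.diff(self.rpeak_times) <= 0):
            raise ValueError("rpeak_times must be strictly increasing")
        if np.any(self.rr_intervals <= 0):
            raise ValueError("rr_intervals must be positive")
        expected = max(len(self.rpeak_times) - 1, 0)
        if len(self.rr_intervals) != expected:
            raise ValueError("len(rr_intervals) must equal len(rpeak_times) - 1")

    @classmethod
    def from_times(cls, times) -> "RRSeries":
        times = np.asarray(times, dtype=float)
        return cls(times, np.diff(times) * 1000.0)

    def __len__(self) -> int:
        return len(self.rpeak_times)


def detect_r_peaks(ecg, fs: float) -> RRSeries:
    """Pan-Tompkins QRS detection on a (highpass-filtered) ECG trace."""
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError("Pan-Tompkins requires fs >= 100 Hz")
    if len(ecg) < 10 * fs:
        raise ValueError("signal shorter than 10 s")
    if np.ptp(ecg) == 0:
        return RRSeries(np.array([]), np.array([]))

    # 1) bandpass 5-15 Hz (zero-phase keeps fiducial timing)
    sos = signal.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, ecg)
    # 2) derivative, 3) squaring, 4) moving-window integration (150 ms)
    deriv = np.gradient(bp) * fs
    squared = deriv**2
    win = max(int(round(_INTEGRATION_S * fs)), 1)
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    fiducials = _adaptive_threshold(mwi, fs)
    if len(fiducials) == 0:
        return RRSeries(np.array([]), np.array([]))

    # localize to the raw-signal maximum within +-50 ms
    half = int(round(_LOCALIZE_S * fs))
    peaks = []
    for i in fiducials:
        lo, hi = max(i - half, 0), min(i + half + 1, len(ecg))
        peaks.append(lo + int(np.argmax(ecg[lo:hi])))
    peaks = np.unique(peaks)
    return RRSeries.from_times(peaks / fs)


def _adaptive_threshold(mwi: np.ndarray, fs: float) -> np.ndarray:
    """Adaptive dual-threshold peak picking with refractory and search-back."""
    refractory = int(round(_REFRACTORY_S * fs))
    cand, _ = signal.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        return np.array([], dtype=int)

    # initialize running estimates from the first 2 s
    lead = mwi[: int(2 * fs)] if len(mwi) >= int(2 * fs) else mwi
    spki = 0.5 * float(np.max(lead))
    npki = float(np.mean(lead)) * 0.5
    accepted: list[int] = []
    rr_recent: list[float] = []

    for i in cand:
        thr1 = npki + 0.25 * (spki - npki)
        if mwi[i] > thr1:
            _accept(accepted, rr_recent, i, fs)
            spki = 0.125 * mwi[i] + 0.875 * spki
        else:
            # search-back: if too long since the last beat, retry at thr/2
            if accepted and rr_recent:
                rr_avg = float(np.mean(rr_recent[-8:]))
                if (i - accepted[-1]) / fs > _SEARCHBACK_FACTOR * rr_avg and mwi[i] > thr1 / 2:
                    _accept(accepted, rr_recent, i, fs)
                    spki = 0.25 * mwi[i] + 0.75 * spki
                    continue
            npki = 0.125 * mwi[i] + 0.875 * npki
    return np.asarray(accepted, dtype=int)


def _accept(accepted: list[int], rr_recent: list[float], i: int, fs: float) -> None:
    if accepted:
        rr_recent.append((i - accepted[-1]) / fs)
    accepted.append(i)


def rr_in_window(series: RRSeries, t0: float, t1: float) -> RRSeries:
    """Sub-series of intervals whose *terminating* peak lies in ``[t0, t1)``."""
    if t0 >= t1:
        raise ValueError("t0 must be < t1")
    if len(series) < 2:
        return RRSeries(np.array([]), np.array([]))
    term = series.rpeak_times[1:]
    mask = (term >= t0) & (term < t1)
    if not mask.any():
        return RRSeries(np.array([]), np.array([]))
    idx = np.flatnonzero(mask)
    # peaks: predecessor of the first terminating peak, then the terminators
    first = idx[0]
    peaks = np.concatenate(([series.rpeak_times[first]], term[mask]))
    return RRSeries(peaks, series.rr_intervals[mask])


def plausible_rr(rr_ms: np.ndarray) -> np.ndarray:
    """Drop R-R intervals outside the physiologically plausible 300-2000 ms."""
    rr_ms = np.asarray(rr_ms, dtype=float)
    lo, hi = RR_PLAUSIBLE_MS
    return rr_ms[(rr_ms >= lo) & (rr_ms <= hi)]
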