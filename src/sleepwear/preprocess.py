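"""Cleaning and alignment of raw sensor streams.

Resampling to nominal rates, fifth-order Butterworth highpass filtering
(1 Hz cutoff, zero-phase), ECG-based time synchronization by normalized
cross-correlation, and the per-epoch physiological validity screen
(minimum SpO2 < 50% or minimum heart rate < 40 bpm excludes the epoch).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal


class SyncError(ValueError):
    """Raised when ECG-based synchronization cannot be computed."""


@dataclass(frozen=True)
class FilterSpec:
    """Highpass Butterworth filter specification."""

    kind: str = "highpass"
    order: int = 5
    cutoff_hz: float = 1.0
    design: str = "butterworth"


DEFAULT_FILTER = FilterSpec()
DEFAULT_SYNC_RATE_HZ = 128.0
DEFAULT_MAX_LAG_S = 300.0


def resample_channel(samples, fs_in: float, fs_out: float) -> np.ndarray:
    """Band-limited (polyphase) resampling; output length = round(n·fs_out/fs_in)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot resample an empty sequence")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_in == fs_out:
        return samples.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    # work mean-removed: constants map to constants exactly, edges behave
    mu = samples.mean()
    out = signal.resample_poly(samples - mu, frac.numerator, frac.denominator,
                               padtype="line") + mu
    n_target = int(round(len(samples) * fs_out / fs_in))
    if len(out) > n_target:
        out = out[:n_target]
    elif len(out) < n_target:
        out = np.pad(out, (0, n_target - len(out)), mode="edge")
    return out


def highpass_filter(samples, fs: float, spec: FilterSpec = DEFAULT_FILTER) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth highpass; removes DC exactly."""
    samples = np.asarray(samples, dtype=float)
    if spec.cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz >= Nyquist {fs / 2} Hz")
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, samples)


def synchronize_by_ecg(
    ref_ecg,
    ref_fs: float,
    target_ecg,
    target_fs: float,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    common_rate_hz: float = DEFAULT_SYNC_RATE_HZ,
) -> float:
    """Lag (s) of ``target`` relative to ``ref`` by normalized cross-correlation.

    Both signals are resampled to ``common_rate_hz``; the returned lag is the
    argmax of the normalized cross-correlation within ``±max_lag_s``.
    Positive lag means the target stream starts later than the reference
    (its content is delayed).
    """
    ref = resample_channel(ref_ecg, ref_fs, common_rate_hz)
    tgt = resample_channel(target_ecg, target_fs, common_rate_hz)
    ref = ref - ref.mean()
    tgt = tgt - tgt.mean()
    if np.std(ref) == 0 or np.std(tgt) == 0:
        raise SyncError("flat ECG signal: cannot synchronize")
    # full cross-correlation; lag k means tgt[t] ~ ref[t - k]
    corr = signal.correlate(tgt, ref, mode="full", method="fft")
    lags = signal.correlation_lags(len(tgt), len(ref), mode="full")
    max_lag = int(round(max_lag_s * common_rate_hz))
    keep = np.abs(lags) <= max_lag
    corr, lags = corr[keep], lags[keep]
    return float(lags[np.argmax(corr)] / common_rate_hz)


def validity_screen(
    epoch_spo2_min: float | None, epoch_hr_min: float | None
) -> tuple[bool, str | None]:
    """Per-epoch physiological plausibility screen.

    Invalid iff minimum SpO2 < 50 % or minimum heart rate < 40 bpm
    (strict inequalities); missing inputs mark the epoch invalid with
    reason ``"missing"``. Returns ``(valid, reason)``.
    """
    if (
        epoch_spo2_min is None
        or epoch_hr_min is None
        or not np.isfinite(epoch_spo2_min)
        or not np.isfinite(epoch_hr_min)
    ):
        return False, "missing"
    if epoch_spo2_min < 50.0:
        return False, "spo2_min<50"
    if epoch_hr_min < 40.0:
        return False, "hr_min<40"
    return True, None
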