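"""Per-epoch feature extraction: 73 features over four sensor modalities.

Recordings are segmented into non-overlapping 30-s epochs aligned with the
hypnogram. Each valid epoch yields exactly 73 features:

* ACC (33): mean, min, max, range, IQR, SD, kurtosis, RMS, variance per
  axis (9×3), plus pairwise Pearson rho and p-value for (x,y), (x,z),
  (y,z). The z axis (416 Hz) is decimated to the common 52 Hz grid with
  anti-alias filtering first. Variance/SD use the population (n)
  convention; kurtosis is Pearson (non-excess), so a Gaussian gives 3.
* ECG (19): HR mean/min/max, SDNN, RMSSD, NN50, NN20, PNN50, PNN20, VLF/LF/HF
  band power and peak frequency, LF/HF ratio, R-R mean/min/max. Band powers
  come from an FFT periodogram of the 4-Hz-interpolated, mean-removed R-R
  tachogram, zero-padded to 4096 points; VLF = 0.0033–0.04 Hz,
  LF = 0.04–0.15 Hz, HF = 0.15–0.4 Hz. On a 30-s epoch the VLF band is
  below the spectral resolution and is near-degenerate; it is computed
  literally anyway.
* TEMP (6): distal-to-proximal gradient (DPG = limb − chest) mean, min,
  max, range; chest mean; limb mean.
* SpO2 (15): mean, min, variance, lag-1 autocorrelation (rho),
  zero-crossing rate, desaturation index (DI: mean absolute difference of
  successive 10-s window means), TSA95/90/85/80/70 (seconds below each
  threshold), ODI2/3/4/5 (desaturation events reaching at least x points
  below the previous epoch's mean; see :func:`_count_runs`).

Epochs failing the physiological validity screen (min SpO2 < 50 % or min
HR < 40 bpm) or with insufficient data are excluded, with reasons logged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cardio, preprocess
from .recording import EPOCH_LENGTH_S, STAGES, Hypnogram, SensorRecording

# ---------------------------------------------------------------------------
# Canonical 73-column feature order

_ACC_STATS = ("mean", "min", "max", "range", "iqr", "sd", "kurtosis", "rms", "variance")
ACC_FEATURES = [f"acc_{stat}_{ax}" for stat in _ACC_STATS for ax in "xyz"] + [
    "acc_rho_xy", "acc_rho_xz", "acc_rho_yz", "acc_p_xy", "acc_p_xz", "acc_p_yz",
]
ECG_FEATURES = [
    "hr_mean", "hr_min", "hr_max", "sdnn", "rmssd", "nn50", "nn20", "pnn50", "pnn20",
    "vlf_power", "vlf_peak", "lf_power", "lf_peak", "hf_power", "hf_peak",
    "lf_hf_ratio", "rr_mean", "rr_min", "rr_max",
]
TEMP_FEATURES = ["dpg_mean", "dpg_min", "dpg_max", "dpg_range", "temp_chest_mean", "temp_limb_mean"]
SPO2_FEATURES = [
    "spo2_mean", "spo2_min", "spo2_variance", "spo2_rho", "spo2_zcr", "spo2_di",
    "tsa95", "tsa90", "tsa85", "tsa80", "tsa70", "odi2", "odi3", "odi4", "odi5",
]
FEATURE_COLUMNS = ACC_FEATURES + ECG_FEATURES + TEMP_FEATURES + SPO2_FEATURES
FEATURE_MODALITY = (
    {f: "acc" for f in ACC_FEATURES}
    | {f: "ecg" for f in ECG_FEATURES}
    | {f: "temp" for f in TEMP_FEATURES}
    | {f: "spo2" for f in SPO2_FEATURES}
)
assert len(FEATURE_COLUMNS) == 73

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
_TACHO_FS = 4.0
_NFFT = 4096


# ---------------------------------------------------------------------------
# Stage label collapsing

_MAPPINGS = {
    2: {"Wake": "Wake", "N1": "Sleep", "N2": "Sleep", "N3": "Sleep", "REM": "Sleep"},
    3: {"Wake": "Wake", "N1": "NREM", "N2": "NREM", "N3": "NREM", "REM": "REM"},
    4: {"Wake": "Wake", "N1": "Light", "N2": "Light", "N3": "Deep", "REM": "REM"},
}
COLLAPSED_CLASSES = {
    2: ("Wake", "Sleep"),
    3: ("Wake", "NREM", "REM"),
    4: ("Wake", "Light", "Deep", "REM"),
    5: STAGES,
}


@dataclass(frozen=True)
class StageResolution:
    """Collapsing of the five AASM stages to 2, 3 or 4 classes."""

    n_classes: int

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3, 4, 5):
            raise ValueError("n_classes must be one of 2, 3, 4, 5")

    @property
    def mapping(self) -> dict[str, str]:
        if self.n_classes == 5:
            return {s: s for s in STAGES}
        return dict(_MAPPINGS[self.n_classes])

    @property
    def classes(self) -> tuple[str, ...]:
        return COLLAPSED_CLASSES[self.n_classes]


def map_labels(hypnogram: Hypnogram | np.ndarray, resolution: StageResolution | int):
    """Collapse five-stage labels to the requested resolution."""
    if isinstance(resolution, int):
        resolution = StageResolution(resolution)
    labels = hypnogram.labels if isinstance(hypnogram, Hypnogram) else np.asarray(hypnogram)
    mapping = resolution.mapping
    try:
        return np.array([mapping[l] for l in labels], dtype=object)
    except KeyError as exc:
        raise ValueError(f"unknown stage label {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# Epoch segmentation


def segment_epochs(
    recording: SensorRecording, hypnogram: Hypnogram
) -> list[tuple[int, float, float, str]]:
    """Half-open epoch windows ``[30k, 30(k+1))`` paired with hypnogram labels.

    Returns ``(epoch_index, t0, t1, label)`` tuples; a trailing partial
    epoch is dropped, and if the hypnogram is shorter than the recording the
    overlap is used (with a warning).
    """
    n_rec = int(recording.duration_s // EPOCH_LENGTH_S)
    n_hyp = hypnogram.n_epochs
    if n_hyp < n_rec:
        warnings.warn(
            f"hypnogram ({n_hyp} epochs) shorter than recording ({n_rec}); truncating",
            stacklevel=2,
        )
    n = min(n_rec, n_hyp)
    return [
        (k, k * EPOCH_LENGTH_S, (k + 1) * EPOCH_LENGTH_S, hypnogram.labels[k])
        for k in range(n)
    ]


# ---------------------------------------------------------------------------
# Per-modality feature functions


def _pop_sd(x: np.ndarray) -> float:
    return float(np.std(x))  # ddof=0: population convention


def _pearson_kurtosis(x: np.ndarray) -> float:
    """Non-excess (Pearson) kurtosis; 0-variance input gives 0."""
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((x - x.mean()) ** 4) / m2**2)


def acc_features(acc_x, acc_y, acc_z) -> dict[str, float]:
    """33 accelerometer features on a common 52 Hz epoch grid."""
    axes = {"x": np.asarray(acc_x, float), "y": np.asarray(acc_y, float), "z": np.asarray(acc_z, float)}
    out: dict[str, float] = {}
    for ax, sig in axes.items():
        out[f"acc_mean_{ax}"] = float(sig.mean())
        out[f"acc_min_{ax}"] = float(sig.min())
        out[f"acc_max_{ax}"] = float(sig.max())
        out[f"acc_range_{ax}"] = float(sig.max() - sig.min())
        out[f"acc_iqr_{ax}"] = float(np.percentile(sig, 75) - np.percentile(sig, 25))
        out[f"acc_sd_{ax}"] = _pop_sd(sig)
        out[f"acc_kurtosis_{ax}"] = _pearson_kurtosis(sig)
        out[f"acc_rms_{ax}"] = float(np.sqrt(np.mean(sig**2)))
        out[f"acc_variance_{ax}"] = float(np.var(sig))
    n = min(len(s) for s in axes.values())
    for a, b in (("x", "y"), ("x", "z"), ("y", "z")):
        sa, sb = axes[a][:n], axes[b][:n]
        if np.std(sa) == 0 or np.std(sb) == 0:
            rho, p = 0.0, 1.0  # Pearson undefined for a constant axis
        else:
            rho, p = stats.pearsonr(sa, sb)
        out[f"acc_rho_{a}{b}"] = float(rho)
        out[f"acc_p_{a}{b}"] = float(p)
    return out


def ecg_features(epoch_rr: cardio.RRSeries) -> dict[str, float] | None:
    """19 HR/HRV features from the epoch's R-R series; None if < 3 intervals."""
    rr = cardio.plausible_rr(epoch_rr.rr_intervals)
    if len(rr) < 3:
        return None
    out: dict[str, float] = {}
    hr = 60000.0 / rr
    out["hr_mean"] = float(hr.mean())
    out["hr_min"] = float(hr.min())
    out["hr_max"] = float(hr.max())
    out["rr_mean"] = float(rr.mean())
    out["rr_min"] = float(rr.min())
    out["rr_max"] = float(rr.max())
    out["sdnn"] = _pop_sd(rr)
    d = np.diff(rr)
    out["rmssd"] = float(np.sqrt(np.mean(d**2))) if len(d) else 0.0
    nn20 = int(np.sum(np.abs(d) > 20.0))
    nn50 = int(np.sum(np.abs(d) > 50.0))
    out["nn20"], out["nn50"] = float(nn20), float(nn50)
    npairs = max(len(d), 1)
    out["pnn20"] = 100.0 * nn20 / npairs
    out["pnn50"] = 100.0 * nn50 / npairs
    out.update(_hrv_spectrum(epoch_rr))
    return out


def _hrv_spectrum(epoch_rr: cardio.RRSeries) -> dict[str, float]:
    """FFT periodogram of the 4-Hz-interpolated R-R tachogram, zero-padded."""
    times = epoch_rr.rpeak_times[1:]  # terminating peaks carry the intervals
    rr = epoch_rr.rr_intervals
    keep = (rr >= cardio.RR_PLAUSIBLE_MS[0]) & (rr <= cardio.RR_PLAUSIBLE_MS[1])
    times, rr = times[keep], rr[keep]
    t0, t1 = times[0], times[-1]
    grid = np.arange(t0, t1, 1.0 / _TACHO_FS)
    if len(grid) < 4:
        grid = np.linspace(t0, t1, 4)
    tach = np.interp(grid, times, rr)
    tach = tach - tach.mean()
    spec = np.fft.rfft(tach, n=_NFFT)
    freqs = np.fft.rfftfreq(_NFFT, d=1.0 / _TACHO_FS)
    # one-sided periodogram density (ms^2/Hz), normalized by actual length
    psd = (np.abs(spec) ** 2) / (_TACHO_FS * len(tach))
    psd[1:-1] *= 2.0
    df = freqs[1] - freqs[0]
    out: dict[str, float] = {}
    for name, (lo, hi) in (("vlf", VLF_BAND), ("lf", LF_BAND), ("hf", HF_BAND)):
        band = (freqs >= lo) & (freqs < hi)
        out[f"{name}_power"] = float(psd[band].sum() * df)
        out[f"{name}_peak"] = float(freqs[band][np.argmax(psd[band])]) if band.any() else 0.0
    out["lf_hf_ratio"] = out["lf_power"] / (out["hf_power"] + 1e-12)
    return out


def temp_features(temp_chest, temp_limb) -> dict[str, float]:
    """6 skin-temperature features; DPG = limb − chest on the shared 1-Hz grid."""
    chest = np.asarray(temp_chest, float)
    limb = np.asarray(temp_limb, float)
    n = min(len(chest), len(limb))
    dpg = limb[:n] - chest[:n]
    return {
        "dpg_mean": float(dpg.mean()),
        "dpg_min": float(dpg.min()),
        "dpg_max": float(dpg.max()),
        "dpg_range": float(dpg.max() - dpg.min()),
        "temp_chest_mean": float(chest.mean()),
        "temp_limb_mean": float(limb.mean()),
    }


def spo2_features(
    spo2, prev_epoch_mean: float | None, fs: float = 5.0
) -> dict[str, float]:
    """15 oximetry features for one epoch.

    ``prev_epoch_mean`` is the mean SpO2 of the most recent *valid* epoch
    (None for the first epoch of a night → all ODI features 0).
    """
    s = np.asarray(spo2, float)
    out: dict[str, float] = {
        "spo2_mean": float(s.mean()),
        "spo2_min": float(s.min()),
        "spo2_variance": float(np.var(s)),
    }
    # lag-1 autocorrelation (self-similarity); constant signal -> 0
    if len(s) > 1 and np.std(s[:-1]) > 0 and np.std(s[1:]) > 0:
        out["spo2_rho"] = float(np.corrcoef(s[:-1], s[1:])[0, 1])
    else:
        out["spo2_rho"] = 0.0
    centered = s - s.mean()
    crossings = int(np.sum(np.signbit(centered[:-1]) != np.signbit(centered[1:])))
    out["spo2_zcr"] = crossings / (len(s) / fs)  # crossings per second
    # DI: mean absolute difference between successive 10-s window means
    w = int(round(10.0 * fs))
    means = [s[i : i + w].mean() for i in range(0, len(s) - w + 1, w)]
    out["spo2_di"] = float(np.mean(np.abs(np.diff(means)))) if len(means) > 1 else 0.0
    for thr in (95, 90, 85, 80, 70):
        out[f"tsa{thr}"] = float(np.sum(s < thr) / fs)  # seconds below threshold
    for x in (2, 3, 4, 5):
        out[f"odi{x}"] = float(_count_runs(s, prev_epoch_mean, x))
    return out


def _count_runs(s: np.ndarray, prev_mean: float | None, depth: float) -> int:
    """Desaturation events at least ``depth`` points below ``prev_mean``.

    An event is a maximal excursion at least 2 points below the reference
    (the shallowest ODI threshold); it counts toward ``depth`` if its
    deepest sample reaches ``depth`` below. Segmenting at the shallowest
    threshold keeps the event counts nested (ODI5 <= ODI4 <= ODI3 <= ODI2)
    even when sensor noise fragments a deep excursion.
    """
    if prev_mean is None:
        return 0
    deficit = prev_mean - s
    in_event = deficit >= 2.0
    edges = np.flatnonzero(np.diff(np.concatenate(([False], in_event, [False])).astype(int)))
    count = 0
    for start, stop in zip(edges[::2], edges[1::2]):
        if deficit[start:stop].max() >= depth:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Table assembly


@dataclass
class EpochFeatureTable:
    """Per-epoch feature rows (valid epochs only) plus exclusion bookkeeping."""

    data: pd.DataFrame
    excluded: pd.DataFrame
    feature_columns: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))

    @property
    def n_epochs(self) -> int:
        return len(self.data)

    def features(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EpochFeatureTable":
        df = pd.read_csv(path)
        missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing[:5]}...")
        return cls(data=df, excluded=pd.DataFrame(columns=["subject_id", "epoch_index", "reason"]))


def extract_night(
    recording: SensorRecording,
    hypnogram: Hypnogram,
    filter_spec: preprocess.FilterSpec = preprocess.DEFAULT_FILTER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature rows for one night; returns (valid rows, excluded rows)."""
    fs = recording.fs
    ecg_f = preprocess.highpass_filter(recording.channels["ecg"], fs["ecg"], filter_spec)
    rr_all = cardio.detect_r_peaks(ecg_f, fs["ecg"])
    acc = {
        ax: preprocess.highpass_filter(recording.channels[f"acc_{ax}"], fs[f"acc_{ax}"], filter_spec)
        for ax in "xyz"
    }
    # decimate z (416 Hz) to the common 52 Hz grid, anti-aliased
    acc["z"] = preprocess.resample_channel(acc["z"], fs["acc_z"], 52.0)
    spo2 = recording.channels["spo2"]
    chest, limb = recording.channels["temp_chest"], recording.channels["temp_limb"]
    hr_dev = recording.channels["hr_device"]

    rows, dropped = [], []
    prev_valid_spo2_mean: float | None = None
    for k, t0, t1, label in segment_epochs(recording, hypnogram):
        def sl(sig, rate):
            return sig[int(t0 * rate) : int(t1 * rate)]

        ep_spo2 = sl(spo2, fs["spo2"])
        ep_rr = cardio.rr_in_window(rr_all, t0, t1)
        rr_ms = cardio.plausible_rr(ep_rr.rr_intervals)
        if len(rr_ms) >= 2:
            hr_min: float | None = float(60000.0 / rr_ms.max())
        else:  # fall back to the 1 Hz device HR channel
            ep_hr = sl(hr_dev, fs["hr_device"])
            hr_min = float(ep_hr.min()) if len(ep_hr) else None
        spo2_min = float(ep_spo2.min()) if len(ep_spo2) else None
        valid, reason = preprocess.validity_screen(spo2_min, hr_min)
        if valid:
            ecg_row = ecg_features(ep_rr)
            if ecg_row is None:
                valid, reason = False, "too_few_rr"
        ep_chest, ep_limb = sl(chest, 1.0), sl(limb, 1.0)
        if valid and (len(ep_chest) == 0 or len(ep_limb) == 0):
            valid, reason = False, "missing"
        if not valid:
            dropped.append({"subject_id": recording.subject_id, "epoch_index": k, "reason": reason})
            continue
        row: dict = {"subject_id": recording.subject_id, "epoch_index": k, "label5": label}
        row.update(acc_features(sl(acc["x"], 52.0), sl(acc["y"], 52.0), sl(acc["z"], 52.0)))
        row.update(ecg_row)
        row.update(temp_features(ep_chest, ep_limb))
        row.update(spo2_features(ep_spo2, prev_valid_spo2_mean, fs["spo2"]))
        prev_valid_spo2_mean = row["spo2_mean"]
        rows.append(row)
    return pd.DataFrame(rows), pd.DataFrame(dropped, columns=["subject_id", "epoch_index", "reason"])


def build_feature_table(
    nights: list[tuple[SensorRecording, Hypnogram]],
    resolution: StageResolution | int | None = None,
) -> EpochFeatureTable:
    """Assemble the cohort feature table: one row per valid epoch.

    Adds collapsed label columns ``label2``, ``label3``, ``label4`` alongside
    ``label5``; if ``resolution`` is given, also a ``label`` column at that
    resolution.
    """
    frames, drops = [], []
    for rec, hyp in nights:
        df, dropped = extract_night(rec, hyp)
        frames.append(df)
        drops.append(dropped)
    data = pd.concat(frames, ignore_index=True)
    excluded = pd.concat(drops, ignore_index=True)
    if data.empty:
        raise ValueError("no valid epochs in any night")
    for n in (2, 3, 4):
        data[f"label{n}"] = map_labels(data["label5"].to_numpy(), StageResolution(n))
    if resolution is not None:
        res = StageResolution(resolution) if isinstance(resolution, int) else resolution
        data["label"] = map_labels(data["label5"].to_numpy(), res)
    meta = ["subject_id", "epoch_index", "label5", "label2", "label3", "label4"]
    if resolution is not None:
        meta.append("label")
    data = data[meta + FEATURE_COLUMNS]
    return EpochFeatureTable(data=data, excluded=excluded)
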