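"""Core containers for overnight wearable recordings and hypnograms, plus disk I/O.

The on-disk interchange format is deliberately plain: one CSV per channel
(columns ``t_seconds,value``), a JSON manifest mapping channel names to files
and sampling rates, and a hypnogram CSV (``epoch_index,onset_s,stage``).
An optional EDF importer (requires :mod:`mne`) maps EDF signal labels onto
the canonical channel names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: AASM five-stage vocabulary, in canonical order.
STAGES = ("Wake", "N1", "N2", "N3", "REM")

#: Canonical channel inventory and nominal sampling rates (Hz).
CHANNEL_FS = {
    "ecg": 512.0,
    "acc_x": 52.0,
    "acc_y": 52.0,
    "acc_z": 416.0,
    "spo2": 5.0,
    "temp_chest": 1.0,
    "temp_limb": 1.0,
    "hr_device": 1.0,
}

EPOCH_LENGTH_S = 30.0


class RecordingError(ValueError):
    """Raised for malformed recordings, manifests, or channel files."""


@dataclass
class Hypnogram:
    """Ordered 30-s epoch sleep-stage labels for one night."""

    labels: np.ndarray  # array of str over STAGES
    epoch_length_s: float = EPOCH_LENGTH_S
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(STAGES)
        if bad:
            raise RecordingError(f"unknown stage labels: {sorted(bad)}")
        if self.epoch_length_s != EPOCH_LENGTH_S:
            raise RecordingError("epoch length is fixed at 30 s")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def to_frame(self) -> pd.DataFrame:
        onset = self.start_time + self.epoch_length_s * np.arange(self.n_epochs)
        return pd.DataFrame(
            {"epoch_index": np.arange(self.n_epochs), "onset_s": onset, "stage": self.labels}
        )


@dataclass
class SensorRecording:
    """Multichannel raw streams with per-channel sampling rates.

    ``ground_truth_rpeaks`` (seconds) and ``ground_truth_offset_s`` are
    populated only by the synthetic generator and exist so downstream
    detection / synchronization can be validated against known truth.
    """

    channels: dict[str, np.ndarray]
    fs: dict[str, float]
    start_time: float = 0.0
    subject_id: str = "S0"
    ground_truth_rpeaks: np.ndarray | None = None
    ground_truth_offset_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, samples in self.channels.items():
            if samples.size == 0:
                raise RecordingError(f"channel {name!r} is empty")
            if name not in self.fs or self.fs[name] <= 0:
                raise RecordingError(f"channel {name!r} lacks a positive sampling rate")
        durs = [len(v) / self.fs[k] for k, v in self.channels.items()]
        if max(durs) - min(durs) > EPOCH_LENGTH_S:
            raise RecordingError("channel durations disagree by more than one epoch")
        spo2 = self.channels.get("spo2")
        if spo2 is not None and (spo2.min() < 0 or spo2.max() > 100):
            raise RecordingError("SpO2 outside [0, 100]")
        for name in ("temp_chest", "temp_limb"):
            t = self.channels.get(name)
            if t is not None and (t.min() < 20 or t.max() > 45):
                raise RecordingError(f"{name} outside [20, 45] degC")

    @property
    def duration_s(self) -> float:
        return min(len(v) / self.fs[k] for k, v in self.channels.items())


# ---------------------------------------------------------------------------
# CSV + JSON manifest round trip


def write_recording(
    recording: SensorRecording,
    out_dir: str | Path,
    hypnogram: Hypnogram | None = None,
    seed: int | None = None,
) -> Path:
    """Write per-channel CSVs plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    channel_map = {}
    for name, samples in recording.channels.items():
        fs = recording.fs[name]
        fname = f"{name}.csv"
        t = recording.start_time + np.arange(len(samples)) / fs
        pd.DataFrame({"t_seconds": t, "value": samples}).to_csv(
            out / fname, index=False, float_format="%.10g"
        )
        channel_map[name] = {"file": fname, "fs": fs, "units": _CHANNEL_UNITS.get(name, "")}
    manifest = {
        "subject_id": recording.subject_id,
        "start_time": recording.start_time,
        "channels": channel_map,
        "seed": seed,
    }
    if hypnogram is not None:
        hypnogram.to_frame().to_csv(out / "hypnogram.csv", index=False)
        manifest["hypnogram"] = "hypnogram.csv"
    if recording.ground_truth_rpeaks is not None:
        pd.DataFrame({"t_seconds": recording.ground_truth_rpeaks}).to_csv(
            out / "rpeaks_truth.csv", index=False, float_format="%.10g"
        )
        manifest["rpeaks_truth"] = "rpeaks_truth.csv"
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


_CHANNEL_UNITS = {
    "ecg": "mV",
    "acc_x": "g",
    "acc_y": "g",
    "acc_z": "g",
    "spo2": "%",
    "temp_chest": "degC",
    "temp_limb": "degC",
    "hr_device": "bpm",
}


def read_recording(manifest_path: str | Path) -> tuple[SensorRecording, Hypnogram | None]:
    """Load a recording (and hypnogram, if present) from a JSON manifest."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise RecordingError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    channels, fs = {}, {}
    for name, entry in manifest["channels"].items():
        f = base / entry["file"]
        if not f.exists():
            raise RecordingError(f"channel {name!r}: missing file {f}")
        try:
            df = pd.read_csv(f)
            channels[name] = df["value"].to_numpy(dtype=float)
        except (KeyError, ValueError) as exc:
            raise RecordingError(f"channel {name!r}: malformed CSV {f}: {exc}") from exc
        fs[name] = float(entry["fs"])
    rpeaks = None
    if manifest.get("rpeaks_truth"):
        rpeaks = pd.read_csv(base / manifest["rpeaks_truth"])["t_seconds"].to_numpy()
    rec = SensorRecording(
        channels=channels,
        fs=fs,
        start_time=float(manifest.get("start_time", 0.0)),
        subject_id=manifest.get("subject_id", "S0"),
        ground_truth_rpeaks=rpeaks,
    )
    hyp = None
    if manifest.get("hypnogram"):
        hdf = pd.read_csv(base / manifest["hypnogram"])
        hyp = Hypnogram(
            labels=hdf["stage"].to_numpy(dtype=object),
            start_time=float(hdf["onset_s"].iloc[0]) if len(hdf) else 0.0,
        )
    return rec, hyp


# ---------------------------------------------------------------------------
# Optional EDF import

#: default EDF label -> canonical channel name mapping; override via ``channel_map``
DEFAULT_EDF_MAP = {
    "ECG": "ecg",
    "AccX": "acc_x",
    "AccY": "acc_y",
    "AccZ": "acc_z",
    "SpO2": "spo2",
    "TempChest": "temp_chest",
    "TempLimb": "temp_limb",
    "HR": "hr_device",
}


def read_edf(path: str | Path, channel_map: dict[str, str] | None = None) -> SensorRecording:
    """Import an EDF file as a :class:`SensorRecording` (requires :mod:`mne`)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise RecordingError("EDF import requires the optional dependency 'mne'") from exc
    channel_map = dict(DEFAULT_EDF_MAP if channel_map is None else channel_map)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # mne represents all EDF channels on one common sampling grid
    sfreq = float(raw.info["sfreq"])
    data = raw.get_data()
    channels, fs = {}, {}
    for i, label in enumerate(raw.ch_names):
        name = channel_map.get(label)
        if name is None:
            continue
        channels[name] = data[i]
        fs[name] = sfreq
    if not channels:
        raise RecordingError("no EDF signal labels matched the channel map")
    return SensorRecording(channels=channels, fs=fs)
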