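"""Synthetic overnight multimodal recordings with known ground truth.

Emulates the channel inventory of a chest + finger wearable pair — ECG at
512 Hz, triaxial acceleration (52/52/416 Hz), SpO2 at 5 Hz, proximal and
distal skin temperature at 1 Hz, device heart rate at 1 Hz — driven by a
first-order Markov hypnogram over the five AASM stages at 30-s resolution.

Stage structure enters through autonomic physiology:

* heart rate: per-stage mean rate and RR variability (SDNN), with a
  two-band oscillatory modulation (LF ~0.1 Hz, HF ~0.3 Hz) whose mix is the
  per-stage ``stage_hf_lf_balance`` (HF fraction), so spectral HRV features
  separate stages;
* movement: burst process concentrated in Wake;
* SpO2: ~97% baseline with trapezoidal desaturation events at a Poisson
  rate;
* temperature: distal (limb) temperature rises by ``dpg_sleep_shift``
  during sleep (distal vasodilation), so the distal-to-proximal gradient
  carries stage information.

Subject-specific additive baseline offsets on HR, SpO2 and temperature —
scaled by ``subject_offset_scale`` — reproduce between-subject
heterogeneity; a cohort generator additionally jitters the per-stage
physiology around shared defaults so that, at high heterogeneity, the
stage→feature mapping itself differs between subjects.

All randomness flows from integer seeds; the same config generates
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .recording import CHANNEL_FS, EPOCH_LENGTH_S, STAGES, Hypnogram, SensorRecording

EPOCHS_PER_HOUR = 120  # 3600 / 30

#: default 5x5 row-stochastic transition matrix over STAGES at 30-s steps,
#: tuned for realistic bout lengths (wake bouts ~5 min, N2 dominant).
DEFAULT_TRANSITION = np.array(
    [
        # Wake   N1     N2     N3     REM
        [0.800, 0.150, 0.050, 0.000, 0.000],  # Wake
        [0.080, 0.570, 0.320, 0.015, 0.015],  # N1
        [0.030, 0.040, 0.845, 0.045, 0.040],  # N2
        [0.015, 0.000, 0.110, 0.855, 0.020],  # N3
        [0.050, 0.030, 0.050, 0.000, 0.870],  # REM
    ]
)


def _stage_dict(values) -> dict[str, float]:
    return dict(zip(STAGES, values))


@dataclass
class SyntheticSubjectConfig:
    """All knobs of the per-subject generator; defaults give a clean,
    stage-separable night for a single synthetic subject."""

    subject_id: str = "S0"
    duration_h: float = 8.0
    stage_transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    stage_hr_mean: dict[str, float] = field(
        default_factory=lambda: _stage_dict([78.0, 70.0, 64.0, 57.0, 74.0])
    )  # bpm
    stage_hr_sdnn: dict[str, float] = field(
        default_factory=lambda: _stage_dict([55.0, 45.0, 40.0, 25.0, 60.0])
    )  # ms
    stage_hf_lf_balance: dict[str, float] = field(
        default_factory=lambda: _stage_dict([0.30, 0.40, 0.55, 0.75, 0.25])
    )  # HF fraction of oscillatory RR power, in (0, 1)
    desat_rate: float = 5.0  # events / hour
    desat_depth: float = 4.0  # %-points
    desat_duration_s: float = 30.0
    movement_burst_rate: dict[str, float] = field(
        default_factory=lambda: _stage_dict([60.0, 6.0, 2.0, 0.5, 1.0])
    )  # bursts / hour per stage
    temp_baseline_chest: float = 35.5  # degC
    temp_baseline_limb: float = 33.5  # degC
    dpg_sleep_shift: float = 1.5  # degC added to limb during sleep
    subject_offset_scale: float = 0.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "ecg": 0.02,
            "acc": 0.01,
            "spo2": 0.25,
            "temp": 0.05,
        }
    )
    psg_ecg_offset_s: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        m = np.asarray(self.stage_transition, dtype=float)
        if m.shape != (5, 5) or np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1) > 1e-9):
            raise ValueError("stage_transition must be a 5x5 row-stochastic matrix")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        for name, v in self.stage_hr_mean.items():
            if v <= 40:
                raise ValueError(f"stage_hr_mean[{name}] must exceed 40 bpm")
        for d in (self.stage_hr_sdnn, self.movement_burst_rate):
            if any(v < 0 for v in d.values()):
                raise ValueError("rates and SDs must be non-negative")
        if self.desat_rate < 0 or self.desat_depth < 0 or self.desat_duration_s < 0:
            raise ValueError("desaturation parameters must be non-negative")

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_h * EPOCHS_PER_HOUR))


# ---------------------------------------------------------------------------
# Hypnogram


def generate_hypnogram(config: SyntheticSubjectConfig) -> Hypnogram:
    """First-order Markov stage trajectory at 30-s steps, starting in Wake."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0x5EED])
    m = np.asarray(config.stage_transition, dtype=float)
    n = config.n_epochs
    states = np.empty(n, dtype=int)
    state = 0  # nights begin awake
    for k in range(n):
        states[k] = state
        state = rng.choice(5, p=m[state])
    return Hypnogram(labels=np.array(STAGES, dtype=object)[states])


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix via eigen-decomposition."""
    vals, vecs = np.linalg.eig(np.asarray(transition, dtype=float).T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Recording synthesis

_QRS_WIDTH_S = 0.024  # half-width of the R spike
_T_DELAY_S = 0.16
_T_WIDTH_S = 0.10
_T_AMP = 0.18


def _ecg_template(fs: float) -> np.ndarray:
    """Fixed stylized PQRST-lite template: sharp R spike, small Q/S dips, T bump."""
    t = np.arange(-0.10 * fs, 0.35 * fs) / fs
    r = np.exp(-0.5 * (t / (_QRS_WIDTH_S / 2.5)) ** 2)
    q = -0.12 * np.exp(-0.5 * ((t + 0.030) / 0.008) ** 2)
    s = -0.18 * np.exp(-0.5 * ((t - 0.030) / 0.010) ** 2)
    tw = _T_AMP * np.exp(-0.5 * ((t - _T_DELAY_S) / _T_WIDTH_S) ** 2)
    return r + q + s + tw


def _draw_rpeak_times(
    config: SyntheticSubjectConfig, hyp: Hypnogram, rng, hr_offset: float = 0.0
) -> np.ndarray:
    """Stage-dependent RR point process with two-band oscillatory modulation."""
    duration_s = hyp.duration_s
    stages = hyp.labels
    lf_phase = rng.uniform(0, 2 * np.pi)
    hf_phase = rng.uniform(0, 2 * np.pi)
    hr_off = hr_offset
    times = []
    t = float(rng.uniform(0.0, 0.8))
    while t < duration_s:
        k = min(int(t // EPOCH_LENGTH_S), len(stages) - 1)
        st = stages[k]
        hr = config.stage_hr_mean[st] + hr_off
        sdnn = config.stage_hr_sdnn[st]
        b = config.stage_hf_lf_balance[st]
        base_rr = 60000.0 / hr  # ms
        # sine of amplitude A has SD A/sqrt(2); allocate 80% of the target
        # variance to the two bands, 20% to white jitter
        a_hf = sdnn * np.sqrt(2 * 0.8 * b)
        a_lf = sdnn * np.sqrt(2 * 0.8 * (1 - b))
        rr = (
            base_rr
            + a_lf * np.sin(2 * np.pi * 0.10 * t + lf_phase)
            + a_hf * np.sin(2 * np.pi * 0.30 * t + hf_phase)
            + rng.normal(0.0, sdnn * np.sqrt(0.2))
        )
        rr = float(np.clip(rr, 350.0, 1800.0))
        times.append(t)
        t += rr / 1000.0
    return np.asarray(times)


def generate_recording(
    config: SyntheticSubjectConfig, hypnogram: Hypnogram
) -> SensorRecording:
    """Render all sensor channels for one night given its hypnogram."""
    config.validate()
    if hypnogram.n_epochs != config.n_epochs:
        raise ValueError(
            f"hypnogram has {hypnogram.n_epochs} epochs, config specifies {config.n_epochs}"
        )
    rng = np.random.default_rng([config.seed, 0xB10])
    duration_s = hypnogram.duration_s
    stages = hypnogram.labels
    asleep = np.array([s != "Wake" for s in stages])

    # subject-specific additive baselines, drawn once per subject
    off_rng = np.random.default_rng([config.seed, 0x0FF])
    scale = config.subject_offset_scale
    hr_offset = scale * 8.0 * off_rng.standard_normal()  # bpm
    spo2_offset = scale * 1.5 * off_rng.standard_normal()  # %-points
    temp_chest_offset = scale * 0.8 * off_rng.standard_normal()  # degC
    temp_limb_offset = scale * 0.8 * off_rng.standard_normal()

    # --- ECG ------------------------------------------------------------
    fs_ecg = CHANNEL_FS["ecg"]
    rpeaks = _draw_rpeak_times(config, hypnogram, rng, hr_offset=hr_offset)
    n_ecg = int(round(duration_s * fs_ecg))
    ecg = np.zeros(n_ecg)
    template = _ecg_template(fs_ecg)
    t0 = int(0.10 * fs_ecg)  # template index of the R spike
    placed = []
    for tp in rpeaks:
        i = int(round(tp * fs_ecg))
        lo, hi = i - t0, i - t0 + len(template)
        if lo < 0 or hi > n_ecg:
            continue
        ecg[lo:hi] += template
        placed.append(i / fs_ecg)  # sample-quantized truth
    ecg += rng.normal(0.0, config.noise_sd["ecg"], n_ecg)

    # --- acceleration ----------------------------------------------------
    acc = {}
    gravity = {"acc_x": 0.10, "acc_y": -0.05, "acc_z": 0.98}
    burst_windows = _movement_bursts(config, stages, rng)
    for name in ("acc_x", "acc_y", "acc_z"):
        fs = CHANNEL_FS[name]
        n = int(round(duration_s * fs))
        sig = np.full(n, gravity[name]) + rng.normal(0.0, config.noise_sd["acc"], n)
        for (b0, b1) in burst_windows:
            i0, i1 = int(b0 * fs), min(int(b1 * fs), n)
            if i1 > i0:
                sig[i0:i1] += rng.normal(0.0, 0.30, i1 - i0)
        acc[name] = sig

    # --- SpO2 ------------------------------------------------------------
    fs_spo2 = CHANNEL_FS["spo2"]
    n_spo2 = int(round(duration_s * fs_spo2))
    t_spo2 = np.arange(n_spo2) / fs_spo2
    spo2 = np.full(n_spo2, 97.0 + spo2_offset)
    for onset in _poisson_events(config.desat_rate, duration_s, rng):
        spo2 -= config.desat_depth * _trapezoid(
            t_spo2, onset, config.desat_duration_s
        )
    spo2 += rng.normal(0.0, config.noise_sd["spo2"], n_spo2)
    np.clip(spo2, 0.0, 100.0, out=spo2)

    # --- temperature ------------------------------------------------------
    fs_temp = CHANNEL_FS["temp_chest"]
    n_temp = int(round(duration_s * fs_temp))
    sleep_1hz = np.repeat(asleep.astype(float), int(EPOCH_LENGTH_S * fs_temp))[:n_temp]
    if len(sleep_1hz) < n_temp:
        sleep_1hz = np.pad(sleep_1hz, (0, n_temp - len(sleep_1hz)), mode="edge")
    # smooth the sleep indicator over ~2 min so the distal rise is gradual
    kernel = np.ones(120) / 120.0
    sleep_smooth = np.convolve(sleep_1hz, kernel, mode="same")
    temp_chest = (
        config.temp_baseline_chest
        + temp_chest_offset
        + rng.normal(0.0, config.noise_sd["temp"], n_temp)
    )
    temp_limb = (
        config.temp_baseline_limb
        + temp_limb_offset
        + config.dpg_sleep_shift * sleep_smooth
        + rng.normal(0.0, config.noise_sd["temp"], n_temp)
    )
    np.clip(temp_chest, 20.0, 45.0, out=temp_chest)
    np.clip(temp_limb, 20.0, 45.0, out=temp_limb)

    # --- device heart rate (1 Hz) ----------------------------------------
    t_hr = np.arange(n_temp) / fs_temp
    placed_arr = np.asarray(placed)
    if len(placed_arr) >= 2:
        inst_hr = 60.0 / np.diff(placed_arr)
        hr_device = np.interp(t_hr, placed_arr[1:], inst_hr)
    else:  # degenerate: no beats placed
        hr_device = np.full(n_temp, 60.0)

    return SensorRecording(
        channels={
            "ecg": ecg,
            "acc_x": acc["acc_x"],
            "acc_y": acc["acc_y"],
            "acc_z": acc["acc_z"],
            "spo2": spo2,
            "temp_chest": temp_chest,
            "temp_limb": temp_limb,
            "hr_device": hr_device,
        },
        fs=dict(CHANNEL_FS),
        subject_id=config.subject_id,
        ground_truth_rpeaks=placed_arr,
        meta={"hr_offset_bpm": hr_offset, "spo2_offset": spo2_offset},
    )


def _poisson_events(rate_per_hour: float, duration_s: float, rng) -> list[float]:
    """Exponential inter-arrival event onsets over [0, duration_s)."""
    if rate_per_hour <= 0:
        return []
    onsets = []
    t = rng.exponential(3600.0 / rate_per_hour)
    while t < duration_s:
        onsets.append(t)
        t += rng.exponential(3600.0 / rate_per_hour)
    return onsets


def _trapezoid(t: np.ndarray, onset: float, duration: float) -> np.ndarray:
    """Unit-depth trapezoidal dip profile: ramp down, plateau, ramp up."""
    third = duration / 3.0
    x = t - onset
    prof = np.zeros_like(t)
    ramp_dn = (x >= 0) & (x < third)
    plateau = (x >= third) & (x < 2 * third)
    ramp_up = (x >= 2 * third) & (x < duration)
    prof[ramp_dn] = x[ramp_dn] / third
    prof[plateau] = 1.0
    prof[ramp_up] = (duration - x[ramp_up]) / third
    return prof


def _movement_bursts(
    config: SyntheticSubjectConfig, stages: np.ndarray, rng
) -> list[tuple[float, float]]:
    """(start_s, end_s) windows of movement, Poisson per epoch by stage rate."""
    windows = []
    for k, st in enumerate(stages):
        lam = config.movement_burst_rate[st] / EPOCHS_PER_HOUR
        for _ in range(rng.poisson(lam)):
            start = k * EPOCH_LENGTH_S + rng.uniform(0.0, EPOCH_LENGTH_S - 3.0)
            windows.append((start, start + rng.uniform(1.0, 3.0)))
    return windows


# ---------------------------------------------------------------------------
# PSG ECG copy for synchronization testing


def make_psg_ecg_copy(
    recording: SensorRecording, offset_s: float, snr: float = np.inf
) -> tuple[np.ndarray, float]:
    """A time-shifted, independently noisy copy of the ECG channel.

    Positive ``offset_s`` means the copy *starts later* than the original:
    ``copy[t] = ecg[t - offset_s]`` (zero-padded). Returns ``(samples, fs)``
    and records ``ground_truth_offset_s`` on the recording.
    """
    fs = recording.fs["ecg"]
    ecg = recording.channels["ecg"]
    shift = int(round(offset_s * fs))
    if abs(shift) >= len(ecg):
        raise ValueError("offset exceeds recording duration")
    out = np.zeros_like(ecg)
    if shift >= 0:
        out[shift:] = ecg[: len(ecg) - shift]
    else:
        out[:shift] = ecg[-shift:]
    if np.isfinite(snr):
        power = float(np.mean(ecg**2))
        rng = np.random.default_rng([int(abs(shift)) + 1, 0xC0B])
        out = out + rng.normal(0.0, np.sqrt(power / snr), len(out))
    recording.ground_truth_offset_s = shift / fs
    return out, fs


# ---------------------------------------------------------------------------
# Cohorts


def generate_cohort(
    n_subjects: int = 9,
    heterogeneity: float = 1.0,
    seed: int = 0,
    duration_h: float = 5.4,
    base_config: SyntheticSubjectConfig | None = None,
) -> list[tuple[SensorRecording, Hypnogram]]:
    """Generate ``n_subjects`` nights around shared defaults.

    ``heterogeneity`` scales both the subject-specific additive baselines and
    the jitter of per-stage physiology (HR means, SDNN, HF/LF balance,
    movement rates, DPG shift) around the defaults. ``heterogeneity=0``
    reproduces identical per-subject physiology (only the seeds differ).

    Defaults mimic a small inpatient study: nine usable subjects at ~5.4 h
    of usable data each.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = base_config or SyntheticSubjectConfig(duration_h=duration_h)
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        jrng = np.random.default_rng([sub_seed, 0x1E7])
        h = heterogeneity
        cfg = replace(
            base,
            subject_id=f"S{i + 1}",
            duration_h=duration_h,
            seed=sub_seed,
            subject_offset_scale=h,
            stage_hr_mean={
                s: max(45.0, v + h * 3.0 * jrng.standard_normal())
                for s, v in base.stage_hr_mean.items()
            },
            stage_hr_sdnn={
                s: max(5.0, v * float(np.exp(h * 0.25 * jrng.standard_normal())))
                for s, v in base.stage_hr_sdnn.items()
            },
            stage_hf_lf_balance={
                s: float(np.clip(v + h * 0.12 * jrng.standard_normal(), 0.05, 0.95))
                for s, v in base.stage_hf_lf_balance.items()
            },
            movement_burst_rate={
                s: v * float(np.exp(h * 0.30 * jrng.standard_normal()))
                for s, v in base.movement_burst_rate.items()
            },
            dpg_sleep_shift=max(0.0, base.dpg_sleep_shift + h * 0.4 * jrng.standard_normal()),
            desat_rate=base.desat_rate * float(np.exp(h * 0.3 * jrng.standard_normal())),
        )
        hyp = generate_hypnogram(cfg)
        rec = generate_recording(cfg, hyp)
        out.append((rec, hyp))
    return out
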