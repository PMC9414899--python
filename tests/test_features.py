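"""Feature extraction: the 73-feature inventory, hand-checked values,
ordering invariants, and exclusion bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from sleepwear.cardio import RRSeries
from sleepwear.features import (
    ACC_FEATURES,
    ECG_FEATURES,
    FEATURE_COLUMNS,
    FEATURE_MODALITY,
    SPO2_FEATURES,
    TEMP_FEATURES,
    StageResolution,
    acc_features,
    build_feature_table,
    ecg_features,
    extract_night,
    map_labels,
    segment_epochs,
    spo2_features,
    temp_features,
)
from sleepwear.recording import Hypnogram, SensorRecording
from sleepwear.synth import SyntheticSubjectConfig, generate_hypnogram, generate_recording


class TestInventory:
    def test_column_counts_by_modality(self):
        assert len(FEATURE_COLUMNS) == 73
        assert len(ACC_FEATURES) == 33
        assert len(ECG_FEATURES) == 19
        assert len(TEMP_FEATURES) == 6
        assert len(SPO2_FEATURES) == 15
        counts = pd.Series(FEATURE_MODALITY).value_counts()
        assert counts.to_dict() == {"acc": 33, "ecg": 19, "temp": 6, "spo2": 15}

    def test_every_valid_epoch_emits_all_columns(self, clean_table):
        rows, _ = clean_table
        assert set(FEATURE_COLUMNS) <= set(rows.columns)
        assert rows[FEATURE_COLUMNS].notna().all().all()
        assert np.isfinite(rows[FEATURE_COLUMNS].to_numpy(dtype=float)).all()


class TestAccFeatures:
    def test_constant_axis_statistics(self):
        ones = np.ones(60)
        out = acc_features(ones, np.arange(60.0), np.arange(60.0))
        assert out["acc_mean_x"] == 1.0
        assert out["acc_sd_x"] == 0.0
        assert out["acc_variance_x"] == 0.0
        assert out["acc_range_x"] == 0.0
        assert out["acc_rms_x"] == 1.0
        # pairs involving the constant axis: undefined Pearson -> rho 0, p 1
        assert out["acc_rho_xy"] == 0.0 and out["acc_p_xy"] == 1.0

    def test_proportional_axes_perfectly_correlated(self, rng):
        x = rng.standard_normal(100)
        out = acc_features(x, 2 * x, rng.standard_normal(100))
        assert out["acc_rho_xy"] == pytest.approx(1.0)
        assert out["acc_p_xy"] < 1e-10

    def test_alternating_signal_population_moments(self):
        x = np.tile([0.0, 1.0], 780)  # n = 1560 (one 30-s epoch at 52 Hz)
        out = acc_features(x, x, x)
        assert out["acc_mean_x"] == pytest.approx(0.5)
        assert out["acc_rms_x"] == pytest.approx(np.sqrt(0.5))
        assert out["acc_variance_x"] == pytest.approx(0.25)  # population n convention
        assert out["acc_sd_x"] == pytest.approx(0.5)


class TestEcgFeatures:
    def test_nn_counts_strict_inequality_hand_case(self):
        """RR = [800, 820, 845, 900] ms: diffs {20, 25, 55}; strict '>'
        gives NN20 = 2 (20 excluded), NN50 = 1."""
        times = np.array([0.0, 0.8, 1.62, 2.465, 3.365])
        out = ecg_features(RRSeries(times, np.array([800.0, 820.0, 845.0, 900.0])))
        assert out["nn20"] == 2
        assert out["nn50"] == 1
        assert out["pnn20"] == pytest.approx(200 / 3)
        assert out["pnn50"] == pytest.approx(100 / 3)

    def test_constant_rr_degenerate_variability(self):
        times = np.arange(0.0, 20.0, 1.0)  # RR = 1000 ms
        out = ecg_features(RRSeries.from_times(times))
        assert out["sdnn"] == 0.0
        assert out["rmssd"] == 0.0
        assert out["hr_mean"] == pytest.approx(60.0)
        assert out["rr_mean"] == pytest.approx(1000.0)

    def test_pure_hf_tachogram_peaks_in_hf_band(self):
        """RR modulated at 0.25 Hz: HF peak at 0.25 and HF >> LF power."""
        f0 = 0.25
        times = [0.0]
        while times[-1] < 60.0:
            rr = 1.0 + 0.1 * np.sin(2 * np.pi * f0 * times[-1])
            times.append(times[-1] + rr)
        out = ecg_features(RRSeries.from_times(np.asarray(times)))
        df = 4.0 / 4096  # tachogram rate / FFT length
        assert abs(out["hf_peak"] - f0) <= 2 * df + 1e-9
        assert out["hf_power"] >= 10 * out["lf_power"]

    def test_too_few_intervals_returns_none(self):
        assert ecg_features(RRSeries.from_times([1.0, 2.0])) is None


class TestTempFeatures:
    def test_constant_gradient(self):
        out = temp_features(np.full(30, 35.5), np.full(30, 34.0))
        assert out["dpg_mean"] == pytest.approx(-1.5)
        assert out["dpg_range"] == 0.0

    def test_equal_channels_zero_gradient(self):
        out = temp_features(np.full(30, 34.0), np.full(30, 34.0))
        assert out["dpg_mean"] == 0.0 and out["dpg_min"] == 0.0

    def test_hand_arithmetic(self):
        out = temp_features([35.0, 35.0, 35.0], [33.0, 34.0, 35.0])
        assert out["dpg_mean"] == pytest.approx(-1.0)
        assert out["dpg_min"] == -2.0
        assert out["dpg_max"] == 0.0
        assert out["dpg_range"] == 2.0


class TestSpo2Features:
    def test_constant_epoch_all_zero(self):
        out = spo2_features(np.full(150, 98.0), prev_epoch_mean=98.0)
        for f in ("tsa95", "tsa90", "tsa85", "tsa80", "tsa70",
                  "odi2", "odi3", "odi4", "odi5", "spo2_variance", "spo2_di"):
            assert out[f] == 0.0

    def test_single_dip_hand_count(self):
        """10 samples at 88 (rest 97), previous mean 97: 2.0 s below 90,
        nothing below 85; one run 9 points below -> every ODI threshold 1."""
        s = np.full(150, 97.0)
        s[40:50] = 88.0
        out = spo2_features(s, prev_epoch_mean=97.0)
        assert out["tsa90"] == pytest.approx(2.0)
        assert out["tsa85"] == 0.0
        for x in (2, 3, 4, 5):
            assert out[f"odi{x}"] == 1

    def test_two_separated_dips_run_counting(self):
        s = np.full(150, 97.0)
        s[20:30] = 94.0
        s[100:110] = 94.0
        out = spo2_features(s, prev_epoch_mean=97.0)
        assert out["odi3"] == 2
        assert out["odi5"] == 0

    def test_first_epoch_has_no_odi_reference(self):
        s = np.full(150, 80.0)
        out = spo2_features(s, prev_epoch_mean=None)
        assert all(out[f"odi{x}"] == 0 for x in (2, 3, 4, 5))
        assert out["tsa85"] == pytest.approx(30.0)  # whole epoch below 85


class TestLabels:
    @pytest.mark.parametrize(
        "stage,resolution,expected",
        [
            ("N3", 4, "Deep"),
            ("N1", 2, "Sleep"),
            ("N1", 4, "Light"),
            ("N2", 3, "NREM"),
            ("REM", 3, "REM"),
            ("Wake", 2, "Wake"),
            ("Wake", 3, "Wake"),
            ("Wake", 4, "Wake"),
        ],
    )
    def test_stage_collapsing(self, stage, resolution, expected):
        assert map_labels(np.array([stage]), resolution)[0] == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            map_labels(np.array(["Nap"]), 2)

    def test_invalid_resolution_rejected(self):
        with pytest.raises(ValueError):
            StageResolution(6)


def _minimal_recording(duration_s: float) -> SensorRecording:
    n = int(duration_s)
    return SensorRecording(
        channels={"hr_device": np.full(n, 60.0)}, fs={"hr_device": 1.0}
    )


class TestSegmentation:
    def test_eight_hour_recording_gives_960_epochs(self):
        rec = _minimal_recording(8 * 3600)
        hyp = Hypnogram(labels=np.array(["N2"] * 960, dtype=object))
        wins = segment_epochs(rec, hyp)
        assert len(wins) == 960
        k, t0, t1, label = wins[5]
        assert (k, t0, t1) == (5, 150.0, 180.0)

    def test_trailing_partial_epoch_dropped(self):
        rec = _minimal_recording(100)
        hyp = Hypnogram(labels=np.array(["N2"] * 4, dtype=object))
        assert len(segment_epochs(rec, hyp)) == 3

    def test_short_hypnogram_truncates_with_warning(self):
        rec = _minimal_recording(300)
        hyp = Hypnogram(labels=np.array(["N2"] * 4, dtype=object))
        with pytest.warns(UserWarning, match="truncating"):
            wins = segment_epochs(rec, hyp)
        assert len(wins) == 4


class TestTableInvariants:
    def test_ordering_invariants_on_generated_night(self, clean_table):
        rows, _ = clean_table
        assert (rows["pnn50"] <= rows["pnn20"] + 1e-12).all()
        assert (rows["nn50"] <= rows["nn20"]).all()
        for lo, hi in (("tsa70", "tsa80"), ("tsa80", "tsa85"),
                       ("tsa85", "tsa90"), ("tsa90", "tsa95")):
            assert (rows[lo] <= rows[hi] + 1e-12).all()
        for lo, hi in (("odi5", "odi4"), ("odi4", "odi3"), ("odi3", "odi2")):
            assert (rows[lo] <= rows[hi]).all()
        for ax in "xyz":
            assert np.allclose(rows[f"acc_variance_{ax}"], rows[f"acc_sd_{ax}"] ** 2)
            assert np.allclose(
                rows[f"acc_range_{ax}"], rows[f"acc_max_{ax}"] - rows[f"acc_min_{ax}"]
            )
        assert rows[["tsa95", "tsa90", "tsa85", "tsa80", "tsa70"]].to_numpy().max() <= 30.0

    def test_clean_night_excludes_nothing(self, clean_table):
        _, excluded = clean_table
        assert len(excluded) == 0

    def test_extraction_is_pure(self, clean_night):
        rec, hyp = clean_night
        a, _ = extract_night(rec, hyp)
        b, _ = extract_night(rec, hyp)
        pd.testing.assert_frame_equal(a, b)

    def test_cohort_table_has_collapsed_labels(self, clean_night):
        rec, hyp = clean_night
        table = build_feature_table([(rec, hyp)], resolution=4)
        assert {"label5", "label2", "label3", "label4", "label"} <= set(table.data.columns)
        assert table.data.shape[0] == hyp.n_epochs  # clean night: no exclusions
        assert len([c for c in table.data.columns if c in FEATURE_COLUMNS]) == 73

    def test_spo2_dip_epoch_is_excluded(self):
        cfg = SyntheticSubjectConfig(duration_h=0.25, seed=21)
        hyp = generate_hypnogram(cfg)
        rec = generate_recording(cfg, hyp)
        rec.channels["spo2"][5 * 150 : 6 * 150] = 45.0  # epoch 5 dips below 50%
        table = build_feature_table([(rec, hyp)])
        assert 5 not in set(table.data["epoch_index"])
        assert list(table.excluded.itertuples(index=False)) == [
            (rec.subject_id, 5, "spo2_min<50")
        ]
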