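"""Feature pruning, normalization, rebalancing and nested cross-validation."""

import logging

import numpy as np
import pandas as pd
import pytest

from sleepwear.features import FEATURE_COLUMNS
from sleepwear.modeling import (
    ModelSpec,
    FittedModel,
    class_weights,
    drop_correlated_features,
    nested_cv,
    random_undersample,
    rebalance,
    smote,
    train_final,
    zscore_within_subject,
)

FEATS = FEATURE_COLUMNS[:8]  # small named subset keeps model tests fast


def _toy_table(n_per_subject=120, subjects=("S1",), seed=0, sep=3.0):
    """Separable two-class table on a handful of named feature columns."""
    rng = np.random.default_rng(seed)
    frames = []
    for j, s in enumerate(subjects):
        n = n_per_subject
        y = np.where(rng.uniform(size=n) < 0.25, "Wake", "Sleep")
        X = rng.standard_normal((n, len(FEATS)))
        X[y == "Wake", :2] += sep  # first two features carry the signal
        X += j * 0.5  # subject baseline shift
        df = pd.DataFrame(X, columns=FEATS)
        df.insert(0, "subject_id", s)
        df["label2"] = y
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestCorrelationPruning:
    def test_duplicated_column_dropped_once(self, rng):
        df = pd.DataFrame(rng.standard_normal((50, 3)), columns=FEATS[:3])
        df[FEATS[1]] = df[FEATS[0]]
        kept, dropped = drop_correlated_features(df, feature_columns=FEATS[:3])
        assert dropped == [FEATS[1]]  # later column of the pair goes
        assert FEATS[0] in kept

    def test_exact_threshold_pair_kept(self):
        """|r| = 0.95 exactly is not 'greater than 0.95': both stay."""
        n = 400
        u = np.tile([1.0, -1.0], n // 2)
        v = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        x = u
        y = 0.95 * u + np.sqrt(1 - 0.95**2) * v
        df = pd.DataFrame({FEATS[0]: x, FEATS[1]: y})
        r = df.corr().iloc[0, 1]
        assert r == pytest.approx(0.95, abs=1e-12)
        kept, dropped = drop_correlated_features(df, feature_columns=FEATS[:2])
        assert dropped == []

    def test_independent_columns_untouched(self, rng):
        df = pd.DataFrame(rng.standard_normal((500, 5)), columns=FEATS[:5])
        kept, dropped = drop_correlated_features(df, feature_columns=FEATS[:5])
        assert kept == FEATS[:5] and dropped == []


class TestZScore:
    def test_normalized_moments(self):
        df = _toy_table(subjects=("S1", "S2"), seed=1)
        out = zscore_within_subject(df, feature_columns=FEATS)
        for _, g in out.groupby("subject_id"):
            assert np.allclose(g[FEATS].mean(), 0.0, atol=1e-9)
            assert np.allclose(g[FEATS].std(ddof=0), 1.0, atol=1e-9)

    def test_constant_feature_becomes_zero(self):
        df = _toy_table(seed=2)
        df[FEATS[0]] = 7.0
        out = zscore_within_subject(df, feature_columns=FEATS)
        assert (out[FEATS[0]] == 0.0).all()

    def test_baseline_shifts_removed(self):
        """Two subjects with identical dynamics but different raw baselines
        normalize to identical columns."""
        base = _toy_table(subjects=("S1",), seed=3)
        shifted = base.copy()
        shifted["subject_id"] = "S2"
        shifted[FEATS] = base[FEATS] * 2.5 + 40.0
        df = pd.concat([base, shifted], ignore_index=True)
        out = zscore_within_subject(df, feature_columns=FEATS)
        a = out[out.subject_id == "S1"][FEATS].to_numpy()
        b = out[out.subject_id == "S2"][FEATS].to_numpy()
        assert np.allclose(a, b, atol=1e-9)


class TestRebalancing:
    def test_undersampling_to_minority_count(self, rng):
        X = rng.standard_normal((120, 4))
        y = np.array(["A"] * 100 + ["B"] * 20)
        Xr, yr = random_undersample(X, y, seed=5)
        counts = pd.Series(yr).value_counts()
        assert counts["A"] == counts["B"] == 20

    def test_smote_grows_minority_on_segments(self, rng):
        """Synthetic B rows are convex combinations of original B rows, so a
        linear relation among B features is preserved exactly."""
        Xa = rng.standard_normal((100, 2))
        Xb = rng.standard_normal((20, 1))
        Xb = np.hstack([Xb, 2 * Xb])  # feature2 = 2 * feature1 on class B
        X = np.vstack([Xa, Xb])
        y = np.array(["A"] * 100 + ["B"] * 20)
        Xr, yr = smote(X, y, seed=6)
        counts = pd.Series(yr).value_counts()
        assert counts["A"] == counts["B"] == 100
        newB = Xr[len(X):]
        assert np.allclose(newB[:, 1], 2 * newB[:, 0], atol=1e-9)

    def test_balanced_input_unchanged(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.array(["A", "B"] * 20)
        for fn in (random_undersample, smote):
            Xr, yr = fn(X, y, seed=1)
            assert len(yr) == 40

    def test_tiny_class_falls_back_to_oversampling(self, rng, caplog):
        X = rng.standard_normal((11, 2))
        y = np.array(["A"] * 10 + ["B"])
        with caplog.at_level(logging.WARNING):
            Xr, yr = smote(X, y, seed=2)
        assert (yr == "B").sum() == 10
        assert any("SMOTE" in r.message for r in caplog.records)

    def test_class_weights_inverse_frequency(self):
        w = class_weights(np.array(["A"] * 75 + ["B"] * 25))
        assert w["A"] == pytest.approx(100 / (2 * 75))
        assert w["B"] == pytest.approx(100 / (2 * 25))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            rebalance(rng.standard_normal((5, 2)), np.array(["A"] * 5),
                      ModelSpec(algorithm="xgboost"), seed=0)

    def test_strategy_pairing(self):
        assert ModelSpec(algorithm="balanced_bagging").imbalance_strategy == \
            "class_weights+undersampling"
        assert ModelSpec(algorithm="xgboost").imbalance_strategy == "smote"


def _fast_spec(algorithm="balanced_random_forest", seed=0):
    return ModelSpec(
        algorithm=algorithm,
        hyperparameter_grid={"n_estimators": [30], "max_depth": [4]},
        rfe_ladder=[8, 4],
        inner_folds=3,
        seed=seed,
    )


class TestNestedCV:
    def test_personal_folds_partition_and_stratify(self):
        df = _toy_table(n_per_subject=200, seed=7)
        res = nested_cv(df, _fast_spec(), framework="personal", resolution=2)
        idx = np.concatenate([f.test_index for f in res.folds])
        assert sorted(idx) == list(range(200))
        assert len(res.folds) == 10
        wake_frac = (df["label2"] == "Wake").mean()
        for f in res.folds:
            n_wake = (df.iloc[f.test_index]["label2"] == "Wake").sum()
            assert abs(n_wake - wake_frac * len(f.test_index)) <= 1.0

    def test_population_losocv_structure(self):
        df = _toy_table(n_per_subject=60, subjects=tuple(f"S{i}" for i in range(5)), seed=8)
        res = nested_cv(df, _fast_spec(), framework="population", resolution=2)
        assert len(res.folds) == 5
        tested_subjects = {f.fold_id for f in res.folds}
        assert tested_subjects == set(df["subject_id"].unique())
        for f in res.folds:
            assert (df.iloc[f.test_index]["subject_id"] == f.fold_id).all()

    def test_determinism_end_to_end(self):
        df = _toy_table(n_per_subject=100, seed=9)
        a = nested_cv(df, _fast_spec(seed=3), framework="personal", resolution=2)
        b = nested_cv(df, _fast_spec(seed=3), framework="personal", resolution=2)
        assert np.array_equal(a.predictions, b.predictions)
        for fa, fb in zip(a.folds, b.folds):
            assert fa.selected_features == fb.selected_features
            assert fa.hyperparameters == fb.hyperparameters

    def test_separable_signal_is_learned(self):
        df = _toy_table(n_per_subject=200, seed=10, sep=4.0)
        res = nested_cv(df, _fast_spec(), framework="personal", resolution=2)
        acc = np.mean(res.truths == res.predictions)
        assert acc > 0.9

    def test_population_needs_three_subjects(self):
        df = _toy_table(subjects=("S1", "S2"), seed=11)
        with pytest.raises(ValueError, match="3 subjects"):
            nested_cv(df, _fast_spec(), framework="population", resolution=2)

    def test_selected_features_are_named_subset(self):
        df = _toy_table(n_per_subject=100, seed=12)
        res = nested_cv(df, _fast_spec(), framework="personal", resolution=2)
        for f in res.folds:
            assert set(f.selected_features) <= set(FEATS)
            assert len(f.selected_features) <= 8


class TestFinalModel:
    def test_save_load_predict_round_trip(self, tmp_path):
        df = _toy_table(n_per_subject=150, seed=13)
        fitted = train_final(df, _fast_spec(), resolution=2)
        norm = zscore_within_subject(df, feature_columns=FEATS)
        before = fitted.predict(norm)
        path = tmp_path / "model.pkl"
        fitted.save(path)
        after = FittedModel.load(path).predict(norm)
        assert np.array_equal(before, after)

    def test_metadata_lists_selected_features(self, tmp_path):
        import json

        df = _toy_table(n_per_subject=150, seed=14)
        fitted = train_final(df, _fast_spec(), resolution=2)
        fitted.save(tmp_path / "m.pkl")
        meta = json.loads((tmp_path / "m.json").read_text())
        assert meta["selected_features"] == fitted.selected_features
        assert meta["algorithm"] == "balanced_random_forest"

    def test_load_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            FittedModel.load(tmp_path / "nope.pkl")
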