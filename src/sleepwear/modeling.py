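"""Sleep-stage classifier training under personal and population frameworks.

Two evaluation frameworks mirror the study design:

* **population** — leave-one-subject-out cross-validation (LOSOCV): each
  subject is one outer test fold, training on everyone else;
* **personal** — stratified 10-fold cross-validation within one subject's
  night.

Within each outer training set: features with pairwise Pearson |r| > 0.95
are pruned (greedy, fixed column order), features are z-scored within
subject over the full night, and an inner 10-fold loop selects the feature
subset (recursive-feature-elimination ranking, scored at a ladder of
subset sizes) and hyperparameters (grid search) by maximum weighted F1.
The winning configuration is refit on the full outer training set with
class rebalancing and evaluated on the held-out fold.

Class imbalance handling is paired to the algorithm: bagging and random
forest use class weights plus random undersampling; gradient boosting and
XGBoost use SMOTE. Both resamplers are implemented here (seeded) —
undersampling reduces every class to the minority count; SMOTE interpolates
synthetic minority rows between k=5 same-class nearest neighbors until all
classes match the majority count.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import RFE
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import LabelEncoder
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS, EpochFeatureTable, StageResolution

logger = logging.getLogger(__name__)

ALGORITHMS = ("balanced_bagging", "balanced_random_forest", "gradient_boosting", "xgboost")
_UNDERSAMPLE_ALGOS = {"balanced_bagging", "balanced_random_forest"}

DEFAULT_GRIDS = {
    "balanced_bagging": {"n_estimators": [100, 300]},
    "balanced_random_forest": {"n_estimators": [100, 300], "max_depth": [3, 6]},
    "gradient_boosting": {"n_estimators": [100, 300], "max_depth": [3, 6], "learning_rate": [0.05, 0.1]},
    "xgboost": {"n_estimators": [100, 300], "max_depth": [3, 6], "learning_rate": [0.05, 0.1]},
}


@dataclass
class ModelSpec:
    """Algorithm + imbalance strategy + search space for one model family."""

    algorithm: str = "xgboost"
    hyperparameter_grid: dict[str, list] | None = None
    rfe_ladder: list[int] | None = None  # feature-count ladder; None -> halving to 8
    inner_folds: int = 10
    correlation_threshold: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.hyperparameter_grid is None:
            self.hyperparameter_grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.algorithm].items()}
        if not self.hyperparameter_grid:
            raise ValueError("hyperparameter grid must be non-empty")

    @property
    def imbalance_strategy(self) -> str:
        return "class_weights+undersampling" if self.algorithm in _UNDERSAMPLE_ALGOS else "smote"

    def grid_points(self) -> list[dict]:
        keys = sorted(self.hyperparameter_grid)
        pts = [{}]
        for k in keys:
            pts = [{**p, k: v} for p in pts for v in self.hyperparameter_grid[k]]
        return pts

    def ladder(self, n_features: int) -> list[int]:
        if self.rfe_ladder is not None:
            return sorted({min(k, n_features) for k in self.rfe_ladder}, reverse=True)
        out, k = [], n_features
        while k >= 8:  # halving steps down to 8 features
            out.append(k)
            k //= 2
        return out or [n_features]

    @classmethod
    def desk_scale(cls, algorithm: str = "balanced_random_forest", seed: int = 0) -> "ModelSpec":
        """A small, fast search space for demonstration-sized cohorts."""
        grids = {
            "balanced_bagging": {"n_estimators": [60]},
            "balanced_random_forest": {"n_estimators": [60], "max_depth": [6]},
            "gradient_boosting": {"n_estimators": [60], "max_depth": [3], "learning_rate": [0.1]},
            "xgboost": {"n_estimators": [60], "max_depth": [3], "learning_rate": [0.1]},
        }
        return cls(algorithm=algorithm, hyperparameter_grid=grids[algorithm],
                   rfe_ladder=[73, 16], inner_folds=5, seed=seed)


@dataclass
class FoldResult:
    fold_id: str
    truths: np.ndarray
    predictions: np.ndarray
    selected_features: list[str]
    hyperparameters: dict
    test_index: np.ndarray


@dataclass
class CVResult:
    """Per-fold test predictions and selections for one cross-validated run."""

    folds: list[FoldResult]
    framework: str
    resolution: int
    algorithm: str

    @property
    def truths(self) -> np.ndarray:
        return np.concatenate([f.truths for f in self.folds])

    @property
    def predictions(self) -> np.ndarray:
        return np.concatenate([f.predictions for f in self.folds])

    def validate(self) -> None:
        idx = np.concatenate([f.test_index for f in self.folds])
        if len(idx) != len(np.unique(idx)):
            raise AssertionError("an epoch appears in more than one test fold")
        for f in self.folds:
            if len(f.truths) != len(f.predictions):
                raise AssertionError("predictions not aligned with truths")


# ---------------------------------------------------------------------------
# Feature pruning and normalization


def drop_correlated_features(
    table: pd.DataFrame,
    threshold: float = 0.95,
    feature_columns: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Greedy correlation pruning in fixed column order.

    Scanning features in order, a feature is dropped iff its absolute
    Pearson correlation with any *already kept* feature strictly exceeds
    ``threshold``. Returns (kept, dropped) feature names; deterministic.
    """
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    if len(table) < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    corr = table[cols].corr().abs().fillna(0.0).to_numpy()
    kept_idx: list[int] = []
    dropped: list[str] = []
    eps = 1e-12  # strict ">": a pair at exactly the threshold is kept
    for j in range(len(cols)):
        if any(corr[j, i] > threshold + eps for i in kept_idx):
            dropped.append(cols[j])
        else:
            kept_idx.append(j)
    return [cols[i] for i in kept_idx], dropped


def zscore_within_subject(
    table: pd.DataFrame, feature_columns: list[str] | None = None
) -> pd.DataFrame:
    """Per-subject, per-feature z-scoring over each subject's full night.

    A feature with zero within-subject SD becomes all zeros for that
    subject. Population (n) SD convention.
    """
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    out = table.copy()

    def _z(g: pd.DataFrame) -> pd.DataFrame:
        mu = g.mean()
        sd = g.std(ddof=0)
        z = (g - mu) / sd.replace(0.0, np.nan)
        return z.fillna(0.0)

    out[cols] = table.groupby("subject_id", group_keys=False)[cols].apply(_z)
    return out


# ---------------------------------------------------------------------------
# Rebalancing


def random_undersample(X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Reduce every class to the minority-class count (without replacement)."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    keep = np.sort(np.concatenate(keep))
    return X[keep], y[keep]


def smote(X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0):
    """Synthetic minority oversampling: grow every class to the majority count.

    Synthetic rows are convex interpolations between a minority row and one
    of its ``k`` nearest same-class neighbors. A class with < 2 members
    falls back to random oversampling with replacement (logged).
    """
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    Xs, ys = [X], [y]
    for c, n_c in zip(classes, counts):
        need = n_max - n_c
        if need == 0:
            continue
        rows = X[y == c]
        if n_c < 2:
            logger.warning("SMOTE: class %r has <2 members; random oversampling", c)
            pick = rng.integers(0, n_c, size=need)
            synth = rows[pick]
        else:
            nn = NearestNeighbors(n_neighbors=min(k, n_c - 1) + 1).fit(rows)
            _, nbrs = nn.kneighbors(rows)  # col 0 is the point itself
            base = rng.integers(0, n_c, size=need)
            nbr_col = rng.integers(1, nbrs.shape[1], size=need)
            partner = nbrs[base, nbr_col]
            u = rng.uniform(0.0, 1.0, size=(need, 1))
            synth = rows[base] + u * (rows[partner] - rows[base])
        Xs.append(synth)
        ys.append(np.full(need, c, dtype=y.dtype))
    return np.concatenate(Xs), np.concatenate(ys)


def class_weights(y: np.ndarray) -> dict:
    """Inverse-frequency weights, normalized as n / (n_classes * count)."""
    classes, counts = np.unique(y, return_counts=True)
    n = len(y)
    return {c: n / (len(classes) * cnt) for c, cnt in zip(classes, counts)}


def rebalance(X: np.ndarray, y: np.ndarray, spec: ModelSpec, seed: int):
    """Apply the spec's imbalance strategy to one training split."""
    if len(np.unique(y)) < 2:
        raise ValueError("rebalancing requires at least 2 classes")
    if spec.algorithm in _UNDERSAMPLE_ALGOS:
        return random_undersample(X, y, seed=seed)
    return smote(X, y, seed=seed)


# ---------------------------------------------------------------------------
# Estimators


def make_estimator(spec: ModelSpec, params: dict, seed: int):
    if spec.algorithm == "balanced_bagging":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(class_weight="balanced", random_state=seed),
            random_state=seed,
            **params,
        )
    if spec.algorithm == "balanced_random_forest":
        return RandomForestClassifier(
            class_weight="balanced_subsample", random_state=seed, n_jobs=1, **params
        )
    if spec.algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    from xgboost import XGBClassifier

    return XGBClassifier(
        random_state=seed, n_jobs=1, verbosity=0, eval_metric="mlogloss", **params
    )


def _rfe_estimator(spec: ModelSpec, params: dict, seed: int):
    """A lighter estimator with feature_importances_ for the RFE ranking."""
    if spec.algorithm == "balanced_bagging":
        return DecisionTreeClassifier(class_weight="balanced", random_state=seed)
    est = make_estimator(spec, dict(params), seed)
    if hasattr(est, "set_params") and "n_estimators" in est.get_params():
        est.set_params(n_estimators=min(est.get_params()["n_estimators"], 100))
    return est


class _Encoded:
    """String-label adapter (XGBoost needs integer classes)."""

    def __init__(self, est, classes: np.ndarray):
        self.est = est
        self.le = LabelEncoder().fit(classes)

    def fit(self, X, y):
        self.est.fit(X, self.le.transform(y))
        return self

    def predict(self, X):
        return self.le.inverse_transform(np.asarray(self.est.predict(X), dtype=int))


# ---------------------------------------------------------------------------
# Nested cross-validation


def nested_cv(
    table: EpochFeatureTable | pd.DataFrame,
    spec: ModelSpec,
    framework: str = "personal",
    resolution: int | StageResolution = 2,
    subject: str | None = None,
) -> CVResult:
    """Nested CV per the study design; returns per-fold test predictions.

    population: LOSOCV outer folds over subjects (requires >= 3 subjects).
    personal: stratified 10-fold outer CV on one subject (``subject`` may
    select one subject from a cohort table; defaults to the only subject).
    """
    df = table.data if isinstance(table, EpochFeatureTable) else table
    res = resolution if isinstance(resolution, StageResolution) else StageResolution(resolution)
    label_col = f"label{res.n_classes}" if f"label{res.n_classes}" in df.columns else "label"
    df = df.reset_index(drop=True)

    if framework == "personal":
        subjects = df["subject_id"].unique()
        if subject is None:
            if len(subjects) > 1:
                raise ValueError("personal framework needs a single subject (pass subject=...)")
            subject = subjects[0]
        df = df[df["subject_id"] == subject].reset_index(drop=True)
        outer = _stratified_outer_folds(df[label_col].to_numpy(), 10, spec.seed)
    elif framework == "population":
        subjects = df["subject_id"].unique()
        if len(subjects) < 3:
            raise ValueError("population framework requires >= 3 subjects")
        outer = [
            (s, np.flatnonzero((df["subject_id"] != s).to_numpy()),
             np.flatnonzero((df["subject_id"] == s).to_numpy()))
            for s in subjects
        ]
    else:
        raise ValueError("framework must be 'personal' or 'population'")

    # per-subject z-scoring over the full night (per-subject normalization)
    norm = zscore_within_subject(df)
    y_all = df[label_col].to_numpy()
    folds = []
    for f, (fold_id, train_idx, test_idx) in enumerate(outer):
        fold_seed = int(np.random.default_rng([spec.seed, 7, f]).integers(2**31 - 1))
        kept, _ = drop_correlated_features(norm.iloc[train_idx], spec.correlation_threshold)
        Xtr = norm.iloc[train_idx][kept].to_numpy(dtype=float)
        ytr = y_all[train_idx]
        Xte = norm.iloc[test_idx][kept].to_numpy(dtype=float)

        if len(np.unique(ytr)) < 2:
            # degenerate outer fold: every training epoch shares one label
            logger.warning("outer fold %s: single-class training set", fold_id)
            only = ytr[0]
            preds = np.full(len(test_idx), only, dtype=object)
            best = {"params": {}, "feature_idx": np.arange(len(kept))}
        else:
            best = _inner_select(Xtr, ytr, kept, spec, fold_seed)
            sel_idx = best["feature_idx"]
            Xb, yb = rebalance(Xtr[:, sel_idx], ytr, spec, fold_seed)
            model = _Encoded(make_estimator(spec, best["params"], fold_seed), np.unique(ytr))
            model.fit(Xb, yb)
            preds = model.predict(Xte[:, sel_idx])
        sel_idx = best["feature_idx"]
        folds.append(
            FoldResult(
                fold_id=str(fold_id),
                truths=y_all[test_idx],
                predictions=np.asarray(preds, dtype=object),
                selected_features=[kept[i] for i in sel_idx],
                hyperparameters=dict(best["params"]),
                test_index=test_idx,
            )
        )
    result = CVResult(folds=folds, framework=framework, resolution=res.n_classes,
                      algorithm=spec.algorithm)
    result.validate()
    return result


def _stratified_outer_folds(y: np.ndarray, n_folds: int, seed: int):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31 - 1))
    return [(f"fold{i}", tr, te) for i, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y))]


def _inner_select(
    Xtr: np.ndarray, ytr: np.ndarray, kept: list[str], spec: ModelSpec, seed: int
) -> dict:
    """Inner 10-fold selection of hyperparameters and RFE feature count.

    The RFE elimination ranking is computed once per outer fold on the
    rebalanced outer-training set; inner folds score prefix subsets of that
    ranking (the ladder) for each grid point by weighted F1.
    """
    ladder = spec.ladder(Xtr.shape[1])
    Xb, yb = rebalance(Xtr, ytr, spec, seed)
    ranker = RFE(
        _rfe_estimator(spec, spec.grid_points()[0], seed),
        n_features_to_select=min(ladder[-1], Xtr.shape[1]),
        step=0.5,
    )
    with np.errstate(all="ignore"):
        ranker.fit(Xb, LabelEncoder().fit_transform(yb))
    order = np.argsort(ranker.ranking_, kind="stable")  # best features first

    classes, counts = np.unique(ytr, return_counts=True)
    n_splits = int(min(spec.inner_folds, counts.min(), len(ytr) // 2))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**31 - 1))
    inner = list(skf.split(Xtr, ytr))

    best = {"score": -np.inf, "params": None, "feature_idx": None}
    for params in spec.grid_points():
        for n_feat in ladder:
            idx = np.sort(order[:n_feat])
            scores = []
            for j, (itr, ival) in enumerate(inner):
                if len(np.unique(ytr[itr])) < 2:
                    # a class is absent from this inner training split
                    logger.warning("inner fold %d: single-class split skipped", j)
                    continue
                Xi, yi = rebalance(Xtr[itr][:, idx], ytr[itr], spec, seed + 1000 + j)
                m = _Encoded(make_estimator(spec, params, seed), classes)
                m.fit(Xi, yi)
                pv = m.predict(Xtr[ival][:, idx])
                scores.append(f1_score(ytr[ival], pv, average="weighted", zero_division=0))
            score = float(np.mean(scores)) if scores else 0.0
            # ties: prefer fewer features, then earlier grid point
            if score > best["score"] + 1e-12 or (
                abs(score - best["score"]) <= 1e-12
                and best["feature_idx"] is not None
                and n_feat < len(best["feature_idx"])
            ):
                best = {"score": score, "params": params, "feature_idx": idx}
    return best


# ---------------------------------------------------------------------------
# Final model persistence


def train_final(
    table: EpochFeatureTable | pd.DataFrame,
    spec: ModelSpec,
    resolution: int | StageResolution = 2,
) -> "FittedModel":
    """Fit one deployable model on the full table (prune → normalize →
    inner selection → rebalance → fit); reload gives identical predictions."""
    df = table.data if isinstance(table, EpochFeatureTable) else table
    if df.empty:
        raise ValueError("empty feature table")
    res = resolution if isinstance(resolution, StageResolution) else StageResolution(resolution)
    label_col = f"label{res.n_classes}" if f"label{res.n_classes}" in df.columns else "label"
    df = df.reset_index(drop=True)
    stats = (
        df.groupby("subject_id")[[c for c in FEATURE_COLUMNS if c in df.columns]]
        .agg(["mean", "std"])
    )
    norm = zscore_within_subject(df)
    kept, _ = drop_correlated_features(norm, spec.correlation_threshold)
    X = norm[kept].to_numpy(dtype=float)
    y = df[label_col].to_numpy()
    best = _inner_select(X, y, kept, spec, spec.seed)
    idx = best["feature_idx"]
    Xb, yb = rebalance(X[:, idx], y, spec, spec.seed)
    model = _Encoded(make_estimator(spec, best["params"], spec.seed), np.unique(y))
    model.fit(Xb, yb)
    return FittedModel(
        model=model,
        selected_features=[kept[i] for i in idx],
        hyperparameters=dict(best["params"]),
        spec=spec,
        resolution=res.n_classes,
        normalization_stats=stats,
    )


@dataclass
class FittedModel:
    """A persisted final model: estimator + selections + normalization stats."""

    model: _Encoded
    selected_features: list[str]
    hyperparameters: dict
    spec: ModelSpec
    resolution: int
    normalization_stats: pd.DataFrame

    def predict(self, normalized_features: pd.DataFrame) -> np.ndarray:
        X = normalized_features[self.selected_features].to_numpy(dtype=float)
        return self.model.predict(X)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        meta = {
            "algorithm": self.spec.algorithm,
            "resolution": self.resolution,
            "selected_features": self.selected_features,
            "hyperparameters": self.hyperparameters,
            "seed": self.spec.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no saved model at {path}")
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError("file does not contain a FittedModel")
        return obj
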