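"""Top-level modelling interface: build a model from a feature table,
``fit()`` it under a cross-validation framework, and inspect the results.

.. code-block:: python

    table = build_feature_table(generate_cohort(5, heterogeneity=0, seed=1))
    model = SleepStageModel(table, framework="population", resolution=2,
                            algorithm="balanced_random_forest", seed=1)
    res = model.fit()
    print(res.summary())
    res.pooled_kappa, res.per_class, res.sleep_architecture()
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, modeling
from .features import EpochFeatureTable, StageResolution


class SleepStageModel:
    """A sleep-stage classification design over an epoch feature table.

    Parameters
    ----------
    table : EpochFeatureTable or DataFrame
        Per-epoch features with ``subject_id`` and label columns.
    framework : {'personal', 'population'}
        Personal: stratified 10-fold CV within one subject. Population:
        leave-one-subject-out CV across subjects.
    resolution : int
        Number of collapsed stage classes (2, 3 or 4).
    algorithm : str
        One of ``balanced_bagging``, ``balanced_random_forest``,
        ``gradient_boosting``, ``xgboost``.
    spec : ModelSpec, optional
        Full search-space control; overrides ``algorithm``/``seed``.
    subject : str, optional
        Subject for the personal framework (required if the table holds
        several subjects).
    """

    def __init__(
        self,
        table: EpochFeatureTable | pd.DataFrame,
        framework: str = "personal",
        resolution: int = 2,
        algorithm: str = "xgboost",
        spec: modeling.ModelSpec | None = None,
        subject: str | None = None,
        seed: int = 0,
    ):
        self.table = table
        self.framework = framework
        self.resolution = StageResolution(resolution) if isinstance(resolution, int) else resolution
        self.spec = spec or modeling.ModelSpec(algorithm=algorithm, seed=seed)
        self.subject = subject

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "SleepStageModel":
        return cls(EpochFeatureTable.from_csv(path), **kwargs)

    def fit(self) -> "SleepStageResults":
        cv = modeling.nested_cv(
            self.table, self.spec, framework=self.framework,
            resolution=self.resolution, subject=self.subject,
        )
        return SleepStageResults(self, cv)

    def fit_final(self) -> modeling.FittedModel:
        """Fit one deployable model on all rows (no held-out evaluation)."""
        return modeling.train_final(self.table, self.spec, self.resolution)


class SleepStageResults:
    """Cross-validated results: pooled metrics, per-fold detail, reports."""

    def __init__(self, model: SleepStageModel, cv: modeling.CVResult):
        self.model = model
        self.cv = cv
        self.metrics = evaluation.per_class_metrics(cv)

    # -- primary quantities -------------------------------------------------
    @property
    def pooled_kappa(self) -> float:
        return self.metrics.pooled_kappa

    @property
    def kappa_band(self) -> str:
        return evaluation.kappa_band(self.pooled_kappa)

    @property
    def balanced_accuracy(self) -> float:
        return self.metrics.balanced_accuracy

    @property
    def per_class(self) -> pd.DataFrame:
        return self.metrics.per_class

    @property
    def confusion_matrix(self) -> pd.DataFrame:
        return self.metrics.confusion

    def sleep_architecture(self, predicted: bool = True) -> evaluation.SleepArchitecture:
        labels = self.cv.predictions if predicted else self.cv.truths
        # restore epoch order so awakening runs are temporal, not fold order
        idx = np.concatenate([f.test_index for f in self.cv.folds])
        return evaluation.sleep_architecture(np.asarray(labels, dtype=object)[np.argsort(idx)])

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Sleep-stage classification results",
            "=" * 56,
            f"framework:          {self.cv.framework}",
            f"resolution:         {self.cv.resolution}-stage",
            f"algorithm:          {self.cv.algorithm}",
            f"epochs (pooled):    {m.n_epochs}",
            f"folds:              {len(self.cv.folds)}",
            f"pooled kappa:       {m.pooled_kappa:.3f} ({self.kappa_band})",
            f"balanced accuracy:  {m.balanced_accuracy:.3f}",
            "",
            "Per-class (pooled):",
            m.per_class.round(3).to_string(),
        ]
        if m.fold_summary is not None:
            lines += ["", "Across folds (mean / SEM):", m.fold_summary.round(3).to_string()]
        return "\n".join(lines)

    def report(self, out_dir: str | Path, **kwargs) -> dict:
        arch = kwargs.pop("architecture", self.sleep_architecture())
        return evaluation.report(self.cv, out_dir, architecture=arch, **kwargs)

    def plot_hypnogram(self, path: str | Path) -> None:
        idx = np.argsort(np.concatenate([f.test_index for f in self.cv.folds]))
        evaluation.plot_hypnogram_comparison(
            np.asarray(self.cv.truths, dtype=object)[idx],
            np.asarray(self.cv.predictions, dtype=object)[idx],
            list(self.metrics.confusion.index),
            path,
        )
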