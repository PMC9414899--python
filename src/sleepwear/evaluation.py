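"""Performance metrics and reports for sleep-stage classifiers.

Pooled Cohen's kappa (one confusion matrix aggregated over all test folds,
chance agreement from the pooled marginals), one-vs-rest per-class
specificity / precision / sensitivity / F1, balanced accuracy (arithmetic
mean of per-class recall), sleep-architecture summaries, hypnogram
comparison plots, and tSNE feature-space embedding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import COLLAPSED_CLASSES
from .modeling import CVResult

KAPPA_BANDS = [
    (-1.0, "worse-than-chance"),  # < 0
    (0.0, "slight"),  # 0 - 0.20
    (0.20, "fair"),  # 0.21 - 0.40
    (0.40, "moderate"),  # 0.41 - 0.60
    (0.60, "substantial"),  # 0.61 - 0.80
    (0.80, "near-perfect"),  # 0.81 - 1
]


def confusion_matrix(
    truths, predictions, labels: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Confusion counts; rows = truth, columns = predicted."""
    truths = np.asarray(truths)
    predictions = np.asarray(predictions)
    if labels is None:
        labels = tuple(sorted(set(truths) | set(predictions)))
    n = len(labels)
    pos = {c: i for i, c in enumerate(labels)}
    m = np.zeros((n, n), dtype=int)
    for t, p in zip(truths, predictions):
        m[pos[t], pos[p]] += 1
    return pd.DataFrame(m, index=list(labels), columns=list(labels))


def kappa_from_confusion(cm: pd.DataFrame | np.ndarray) -> float:
    """Cohen's kappa = (p_o - p_e)/(1 - p_e) from a confusion matrix."""
    m = np.asarray(cm, dtype=float)
    n = m.sum()
    if n == 0:
        return float("nan")
    p_o = np.trace(m) / n
    p_e = float(np.sum(m.sum(axis=0) * m.sum(axis=1)) / n**2)
    if p_e == 1.0:  # degenerate single-class pool
        return float("nan")
    return float((p_o - p_e) / (1 - p_e))


def pooled_kappa(results: CVResult | tuple) -> float:
    """Cohen's kappa on the single confusion matrix pooled over all folds."""
    truths, preds = _pooled(results)
    if len(set(truths)) < 2:
        return float("nan")  # flagged sentinel: kappa undefined
    return kappa_from_confusion(confusion_matrix(truths, preds))


def _pooled(results) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(results, CVResult):
        return results.truths, results.predictions
    truths, preds = results
    return np.asarray(truths), np.asarray(preds)


def kappa_band(value: float) -> str:
    """Agreement label for a kappa value; band edges belong to the lower band."""
    if not -1.0 <= value <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    if value < 0:
        return "worse-than-chance"
    label = KAPPA_BANDS[1][1]
    for lo, name in KAPPA_BANDS[1:]:
        if value > lo:
            label = name
    return label


def f1_from_pr(precision: float, sensitivity: float, beta: float = 1.0) -> float:
    """F_beta = (1+b^2)·precision·sensitivity / (b^2·precision + sensitivity)."""
    denom = beta**2 * precision + sensitivity
    if denom == 0:
        return 0.0
    return (1 + beta**2) * precision * sensitivity / denom


@dataclass
class MetricsReport:
    """Pooled metrics for one cross-validated model."""

    pooled_kappa: float
    per_class: pd.DataFrame  # index class; specificity/precision/sensitivity/f1
    balanced_accuracy: float
    confusion: pd.DataFrame
    confusion_row_pct: pd.DataFrame
    n_epochs: int
    fold_summary: pd.DataFrame | None = None  # mean and SEM across folds
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pooled_kappa": self.pooled_kappa,
            "kappa_band": kappa_band(self.pooled_kappa)
            if np.isfinite(self.pooled_kappa)
            else "undefined",
            "balanced_accuracy": self.balanced_accuracy,
            "n_epochs": self.n_epochs,
            "per_class": {
                c: {k: float(v) for k, v in row.items()}
                for c, row in self.per_class.iterrows()
            },
            "confusion": {
                str(t): {str(p): int(v) for p, v in row.items()}
                for t, row in self.confusion.iterrows()
            },
            "flags": list(self.flags),
        }


def per_class_metrics(
    results: CVResult | tuple, labels: tuple[str, ...] | None = None
) -> MetricsReport:
    """One-vs-rest per-class metrics plus pooled kappa and balanced accuracy."""
    truths, preds = _pooled(results)
    if labels is None and isinstance(results, CVResult):
        labels = COLLAPSED_CLASSES.get(results.resolution)
        if labels is not None:
            labels = tuple(c for c in labels if c in set(truths) | set(preds))
    cm = confusion_matrix(truths, preds, labels)
    m = cm.to_numpy(dtype=float)
    n = m.sum()
    flags = []
    rows = {}
    for i, c in enumerate(cm.index):
        tp = m[i, i]
        fn = m[i].sum() - tp
        fp = m[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn > 0 else 0.0
        spec = tn / (tn + fp) if tn + fp > 0 else 0.0
        if tp + fp > 0:
            prec = tp / (tp + fp)
        else:
            prec = 0.0
            flags.append(f"precision undefined for empty predicted class {c!r}; set to 0")
        rows[c] = {
            "specificity": spec,
            "precision": prec,
            "sensitivity": sens,
            "f1": f1_from_pr(prec, sens),
        }
    per_class = pd.DataFrame(rows).T
    bal_acc = float(per_class["sensitivity"].mean())
    # identity check: micro-averaged recall equals overall accuracy
    assert abs(np.trace(m) / n - float(np.sum(truths == preds)) / len(truths)) < 1e-12
    fold_summary = None
    if isinstance(results, CVResult) and len(results.folds) > 1:
        fold_summary = _fold_summary(results, cm.index)
    row_sums = m.sum(axis=1, keepdims=True)
    row_pct = pd.DataFrame(
        np.divide(m, row_sums, out=np.zeros_like(m), where=row_sums > 0) * 100.0,
        index=cm.index,
        columns=cm.columns,
    )
    return MetricsReport(
        pooled_kappa=kappa_from_confusion(cm) if len(set(truths)) > 1 else float("nan"),
        per_class=per_class,
        balanced_accuracy=bal_acc,
        confusion=cm,
        confusion_row_pct=row_pct,
        n_epochs=int(n),
        fold_summary=fold_summary,
        flags=flags,
    )


def _fold_summary(results: CVResult, classes) -> pd.DataFrame:
    """Mean and SEM of per-class metrics across folds (table-style reporting)."""
    per_fold = []
    for f in results.folds:
        rep = per_class_metrics((f.truths, f.predictions), labels=tuple(classes))
        per_fold.append(rep.per_class)
    stacked = pd.concat(per_fold, keys=range(len(per_fold)))
    grouped = stacked.groupby(level=1, sort=False)
    mean = grouped.mean()
    sem = grouped.sem(ddof=1).fillna(0.0)
    out = mean.add_suffix("_mean").join(sem.add_suffix("_sem"))
    return out.loc[[c for c in classes if c in out.index]]


# ---------------------------------------------------------------------------
# Sleep architecture


@dataclass
class SleepArchitecture:
    total_sleep_time_min: float
    stage_percentages: dict[str, float]  # % of total recording time
    n_awakenings: int

    def to_dict(self) -> dict:
        return {
            "total_sleep_time_min": self.total_sleep_time_min,
            "stage_percentages": dict(self.stage_percentages),
            "n_awakenings": self.n_awakenings,
        }


def sleep_architecture(labels) -> SleepArchitecture:
    """Summary of a per-epoch label sequence (any stage resolution).

    TST = 0.5 min per non-Wake epoch; stage percentages are of total
    recording time; an awakening is a maximal Wake run strictly inside the
    sleep period (after the first and before the last non-Wake epoch).
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    n = len(labels)
    wake = labels == "Wake"
    tst = 0.5 * float(np.sum(~wake))
    pct = {str(c): 100.0 * float(np.sum(labels == c)) / n for c in pd.unique(labels)}
    sleep_idx = np.flatnonzero(~wake)
    awakenings = 0
    if len(sleep_idx) > 0:
        first, last = sleep_idx[0], sleep_idx[-1]
        inside = wake[first : last + 1]
        awakenings = int(inside[0]) + int(np.sum(~inside[:-1] & inside[1:]))
    return SleepArchitecture(tst, pct, awakenings)


# ---------------------------------------------------------------------------
# tSNE embedding


def tsne_embedding(
    features: pd.DataFrame | np.ndarray,
    perplexity: float = 40.0,
    iterations: int = 300,
    seed: int = 0,
) -> np.ndarray:
    """2-D stochastic-neighbor embedding of the feature matrix.

    Uses perplexity 40 and 300 iterations by default; if the table has
    fewer than 3x perplexity rows the perplexity is shrunk (with a warning).
    """
    import warnings

    from sklearn.manifold import TSNE

    X = np.asarray(features, dtype=float)
    if len(X) < 3 * perplexity:
        new_p = max(5.0, (len(X) - 1) / 3.0)
        warnings.warn(
            f"{len(X)} rows < 3x perplexity {perplexity}; shrinking perplexity to {new_p:.0f}",
            stacklevel=2,
        )
        perplexity = new_p
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max(int(iterations), 250),
        random_state=seed % (2**31 - 1),
        init="random",
        n_jobs=1,
    )
    return tsne.fit_transform(X)


# ---------------------------------------------------------------------------
# Report bundle


def plot_hypnogram_comparison(truth_labels, pred_labels, classes, path) -> None:
    """Predicted vs. truth step-line hypnogram (Wake on top, deep at bottom)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = {c: len(classes) - 1 - i for i, c in enumerate(classes)}
    t = np.arange(len(truth_labels)) * 0.5  # minutes
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.step(t, [order[l] for l in truth_labels], where="post", color="k", lw=1.2, label="PSG")
    ax.step(t, [order[l] for l in pred_labels], where="post", color="g", lw=1.0,
            alpha=0.75, label="model")
    ax.set_yticks([order[c] for c in classes])
    ax.set_yticklabels(classes)
    ax.set_xlabel("time (min)")
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def report(
    results: CVResult,
    out_dir: str | Path,
    architecture: SleepArchitecture | None = None,
    embedding: np.ndarray | None = None,
) -> dict:
    """Write the report bundle: metrics JSON, confusion CSVs, hypnogram plot,
    markdown summary. Deterministic (sorted keys) so regeneration is
    byte-identical. Returns the metrics dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rep = per_class_metrics(results)
    metrics = rep.to_dict()
    metrics["framework"] = results.framework
    metrics["resolution"] = results.resolution
    metrics["algorithm"] = results.algorithm
    if architecture is not None:
        metrics["sleep_architecture"] = architecture.to_dict()
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    rep.confusion.to_csv(out / "confusion_counts.csv")
    rep.confusion_row_pct.to_csv(out / "confusion_row_pct.csv", float_format="%.4f")
    if rep.fold_summary is not None:
        rep.fold_summary.to_csv(out / "per_fold_metrics.csv", float_format="%.6f")
    classes = list(rep.confusion.index)
    plot_hypnogram_comparison(results.truths, results.predictions, classes,
                              out / "hypnogram.png")
    if embedding is not None:
        np.savetxt(out / "tsne.csv", embedding, delimiter=",", header="dim1,dim2", comments="")
    lines = [
        "# Sleep staging report",
        "",
        f"- framework: {results.framework}, resolution: {results.resolution}-stage, "
        f"algorithm: {results.algorithm}",
        f"- epochs: {metrics['n_epochs']}",
        f"- pooled Cohen's kappa: {metrics['pooled_kappa']:.3f} ({metrics['kappa_band']})",
        f"- balanced accuracy: {metrics['balanced_accuracy']:.3f}",
    ]
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    return metrics
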