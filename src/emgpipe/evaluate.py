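"""Classifier benchmark: stratified k-fold cross-validation of LR, linear and
RBF SVMs, kNN and RF with per-class precision/recall/F1/accuracy and
one-vs-rest AUC, plus table emitters.

Conventions: confusion matrices are pooled across folds for the count-based
metrics (stable for small classes) while AUC is averaged per fold; the
per-class "accuracy" row mirrors the recall row, the genuinely distinct
micro accuracy (trace/total) appears only in the overall summary.  kNN ties
resolve to the lowest class id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .exceptions import ConfigurationError, ShapeError, UndefinedMetricError
from .feateng import pca_fit_transform, zscore_fit_transform

MODEL_NAMES = ("LR", "SVM-1", "SVM-2", "kNN", "RF")

METRIC_ROWS = ("Precision", "Recall", "F1-score", "Accuracy", "AUC")


@dataclass
class ModelSpec:
    """A named classifier with documented default hyperparameters and an
    optional inner-3-fold hyperparameter grid."""

    name: str
    hyperparams: dict = field(default_factory=dict)
    grid: dict | None = None

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ConfigurationError(f"model name must be one of {MODEL_NAMES}, got {self.name!r}")

    def build(self, seed: int = 0):
        hp = dict(self.hyperparams)
        if self.name == "LR":
            est = LogisticRegression(C=hp.pop("C", 1.0), max_iter=hp.pop("max_iter", 2000), **hp)
        elif self.name == "SVM-1":
            est = SVC(kernel="linear", C=hp.pop("C", 1.0), random_state=seed, **hp)
        elif self.name == "SVM-2":
            est = SVC(kernel="rbf", C=hp.pop("C", 1.0), gamma=hp.pop("gamma", "scale"), random_state=seed, **hp)
        elif self.name == "kNN":
            est = KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5), **hp)
        else:  # RF
            est = RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 100),
                max_depth=hp.pop("max_depth", None),
                random_state=seed,
                **hp,
            )
        if self.grid:
            est = GridSearchCV(est, self.grid, cv=3, n_jobs=1)
        return est


def default_model_specs(names=MODEL_NAMES) -> list[ModelSpec]:
    return [ModelSpec(name=n) for n in names]


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified folds: a partition of the index set in which each
    class's per-fold count is within one sample of its global share."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ConfigurationError(
            f"every class needs >= {k} members for {k}-fold CV (smallest has {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(labels.size), labels)]


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    """Counts matrix, rows = true class, columns = predicted class."""
    classes = np.asarray(classes)
    index = {c: i for i, c in enumerate(classes.tolist())}
    cm = np.zeros((classes.size, classes.size), dtype=np.int64)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        cm[index[t], index[p]] += 1
    return cm


def precision_recall_f1_acc(cm: np.ndarray, class_index: int) -> tuple[float, float, float, float]:
    """One-vs-rest precision, recall, F1 and per-class accuracy for one row.

    Per-class accuracy is reported as recall (the tables' convention); any
    zero-division yields 0 with a warning.
    """
    cm = np.asarray(cm)
    tp = cm[class_index, class_index]
    fp = cm[:, class_index].sum() - tp
    fn = cm[class_index, :].sum() - tp

    def _ratio(num, den, what):
        if den == 0:
            warnings.warn(f"{what} undefined for class index {class_index}: reported as 0")
            return 0.0
        return float(num / den)

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2.0 * precision * recall, precision + recall, "F1") if (precision + recall) else 0.0
    if precision + recall == 0:
        warnings.warn(f"F1 undefined for class index {class_index}: reported as 0")
    return precision, recall, f1, recall


def overall_accuracy(cm: np.ndarray) -> float:
    """Micro accuracy: trace(cm) / total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return float(np.trace(cm) / total)


def roc_auc_ovr(scores: np.ndarray, labels, class_id, classes=None) -> float:
    """One-vs-rest AUC for ``class_id`` as the Mann-Whitney statistic: the
    fraction of positive-negative pairs where the positive outranks the
    negative, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ShapeError("scores must be finite")
    if classes is None:
        classes = np.unique(labels)
    classes = np.asarray(classes)
    col = int(np.nonzero(classes == class_id)[0][0])
    s = scores[:, col] if scores.ndim == 2 else scores
    pos = labels == class_id
    n_pos = int(pos.sum())
    n_neg = int(s.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined for class {class_id}: needs both positives and negatives"
        )
    ranks = rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class MetricsReport:
    """Cross-validated metrics for one model: per-class arrays (fractions in
    [0, 1]), macro/overall summary, per-fold raw values and warnings."""

    model: str
    classes: np.ndarray
    confusion: np.ndarray
    per_class: dict[str, np.ndarray]
    overall: dict[str, float]
    fold_accuracy: list[float]
    fold_auc: list[np.ndarray]
    warnings: list[str] = field(default_factory=list)
    error: str | None = None

    def per_class_percent_frame(self) -> pd.DataFrame:
        rows = {
            "Precision": self.per_class["precision"],
            "Recall": self.per_class["recall"],
            "F1-score": self.per_class["f1"],
            "Accuracy": self.per_class["accuracy"],
            "AUC": self.per_class["auc"],
        }
        frame = pd.DataFrame(rows).T * 100.0
        frame.columns = [f"Class {c}" for c in self.classes]
        frame.index.name = "Metric/Class"
        return frame


def _score_matrix(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))
    return np.asarray(model.decision_function(X))


def _fold_views(values, labels, folds, retention, paper_mode):
    """Per-fold (train, test) design matrices with fold-internal feature
    engineering unless ``paper_mode`` fits globally (leaky, for comparison)."""
    if retention is None:
        return [(values[tr], values[te]) for tr, te in folds]
    if paper_mode:
        z, _ = zscore_fit_transform(values)
        proj = pca_fit_transform(z, retention).projected
        return [(proj[tr], proj[te]) for tr, te in folds]
    views = []
    for tr, te in folds:
        z_tr, params = zscore_fit_transform(values[tr])
        ds = pca_fit_transform(z_tr, retention)
        views.append((ds.projected, ds.transform(params.transform(values[te]))))
    return views


def run_benchmark(
    values,
    labels,
    models: list[ModelSpec] | None = None,
    k: int = 5,
    seed: int = 0,
    retention: float | None = None,
    paper_mode: bool = False,
) -> list[MetricsReport]:
    """Cross-validate every model on the same seeded folds.

    Per fold: fit on training rows (with fold-internal z-score + PCA when
    ``retention`` is given), score and classify the test rows, pool the
    confusion matrix and collect per-class fold AUCs.  A model that fails to
    train yields a report carrying the error; the others are unaffected.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.size:
        raise ShapeError("values and labels must have the same number of rows")
    models = models if models is not None else default_model_specs()
    classes = np.unique(labels)
    folds = stratified_kfold(labels, k=k, seed=seed)
    views = _fold_views(values, labels, folds, retention, paper_mode)

    reports: list[MetricsReport] = []
    for spec in models:
        try:
            reports.append(
                _benchmark_one(spec, values, labels, classes, folds, views, seed)
            )
        except Exception as exc:  # noqa: BLE001 - per-model isolation is the contract
            reports.append(
                MetricsReport(
                    model=spec.name,
                    classes=classes,
                    confusion=np.zeros((classes.size, classes.size), dtype=np.int64),
                    per_class={},
                    overall={},
                    fold_accuracy=[],
                    fold_auc=[],
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return reports


def _benchmark_one(spec, values, labels, classes, folds, views, seed) -> MetricsReport:
    cm = np.zeros((classes.size, classes.size), dtype=np.int64)
    fold_auc: list[np.ndarray] = []
    fold_accuracy: list[float] = []
    notes: list[str] = []

    for (tr, te), (X_tr, X_te) in zip(folds, views):
        model = spec.build(seed=seed)
        model.fit(X_tr, labels[tr])
        pred = model.predict(X_te)
        scores = _score_matrix(model, X_te)
        cm_fold = confusion_matrix(labels[te], pred, classes)
        cm += cm_fold
        fold_accuracy.append(overall_accuracy(cm_fold))
        aucs = np.full(classes.size, np.nan)
        for ci, cid in enumerate(classes):
            try:
                aucs[ci] = roc_auc_ovr(scores, labels[te], cid, classes=model.classes_)
            except UndefinedMetricError as exc:
                notes.append(str(exc))
        fold_auc.append(aucs)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        prf = np.array([precision_recall_f1_acc(cm, ci) for ci in range(classes.size)])
    notes.extend(str(w.message) for w in caught)

    auc_stack = np.vstack(fold_auc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        auc_mean = np.nanmean(auc_stack, axis=0)
    auc_mean = np.nan_to_num(auc_mean, nan=0.0)

    per_class = {
        "precision": prf[:, 0],
        "recall": prf[:, 1],
        "f1": prf[:, 2],
        "accuracy": prf[:, 3],
        "auc": auc_mean,
    }
    overall = {
        "precision": float(prf[:, 0].mean()),
        "recall": float(prf[:, 1].mean()),
        "f1": float(prf[:, 2].mean()),
        "accuracy": float(overall_accuracy(cm)),
        "auc": float(auc_mean.mean()),
    }
    return MetricsReport(
        model=spec.name,
        classes=classes,
        confusion=cm,
        per_class=per_class,
        overall=overall,
        fold_accuracy=fold_accuracy,
        fold_auc=fold_auc,
        warnings=notes,
    )


def _slug(name: str) -> str:
    return name.lower().replace("-", "")


def emit_tables(reports: list[MetricsReport], out_dir) -> dict[str, object]:
    """Write one per-class table per model plus an overall summary, as CSV and
    aligned text.  Values are percentages rounded half-even to 2 decimals."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, object] = {}
    ok = [r for r in reports if r.error is None]
    for rep in ok:
        frame = rep.per_class_percent_frame().round(2)
        base = out_dir / f"table_{_slug(rep.model)}"
        frame.to_csv(base.with_suffix(".csv"), float_format="%.2f")
        base.with_suffix(".txt").write_text(frame.to_string(float_format=lambda v: f"{v:.2f}") + "\n")
        written[rep.model] = frame

    overall = pd.DataFrame(
        {rep.model: [rep.overall[m] * 100.0 for m in ("precision", "recall", "f1", "accuracy", "auc")] for rep in ok},
        index=list(METRIC_ROWS),
    ).round(2)
    overall.index.name = "Metric/Model"
    overall.to_csv(out_dir / "table_overall.csv", float_format="%.2f")
    (out_dir / "table_overall.txt").write_text(
        overall.to_string(float_format=lambda v: f"{v:.2f}") + "\n"
    )
    written["overall"] = overall
    return written
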