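"""SVM classification of selected deep features, with repeated stratified
10-fold cross-validation and full per-class confusion-matrix metrics.

Per repeat, every sample is predicted exactly once (as the validation member
of its fold) and the fold predictions are pooled into one confusion matrix;
accuracy mean and standard deviation are reported over repeats.  Metrics
follow the usual binary definitions — sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), F1 the harmonic mean of precision and
recall — printed as percentages rounded half-up to two decimals, and in the
binary case the sensitivity of one class equals the specificity of the
other by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ramm import FeatureMatrix, encode_labels

logger = logging.getLogger(__name__)

CLASS_NAMES = ("healthy", "unhealthy")


@dataclass
class SVMConfig:
    kernel: str = "poly"  # "poly" | "rbf" | "linear"
    poly_degree: int = 3
    C: float = 1.0
    coef0: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")
        if self.kernel not in ("poly", "rbf", "linear"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")


def _make_svm(cfg: SVMConfig):
    svc = SVC(
        kernel=cfg.kernel,
        degree=cfg.poly_degree,
        C=cfg.C,
        coef0=cfg.coef0,
        gamma="scale",
    )
    return make_pipeline(StandardScaler(), svc) if cfg.standardize else svc


@dataclass
class ConfusionMatrix:
    """2x2 counts indexed (true class, predicted class), order CLASS_NAMES."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 2x2 with counts >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        counts = np.zeros((2, 2), dtype=np.int64)
        np.add.at(counts, (y_true, y_pred), 1)
        return cls(counts)


def round2(x: float) -> float:
    """Half-up rounding to two decimals, as metric tables are printed."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion_metrics(cm: ConfusionMatrix, positive: str) -> dict[str, float | None]:
    """Per-class sensitivity/specificity/precision/F1 in percent (2 d.p.).

    A zero denominator yields ``None`` (undefined, not zero) and a warning.
    """
    p = CLASS_NAMES.index(positive)
    n = 1 - p
    tp = int(cm.counts[p, p])
    fn = int(cm.counts[p, n])
    fp = int(cm.counts[n, p])
    tn = int(cm.counts[n, n])

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            logger.warning("%s undefined for class %r (zero denominator)", name, positive)
            return None
        return 100.0 * num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    if sens is None or prec is None or (prec + sens) == 0:
        f1 = None
        logger.warning("F1 undefined for class %r", positive)
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    out = {"sensitivity": sens, "specificity": spec, "precision": prec, "f1": f1}
    return {k: (round2(v) if v is not None else None) for k, v in out.items()}


@dataclass
class MetricReport:
    per_class: dict[str, dict[str, float | None]]
    accuracy: float  # percent, over all pooled predictions
    per_run_accuracy: list[float]  # percent, one per repeat
    mean_accuracy: float
    std_accuracy: float
    confusions: list[ConfusionMatrix] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "per_run_accuracy": self.per_run_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "confusions": [cm.counts.tolist() for cm in self.confusions],
        }


def _report_from_confusions(cms: list[ConfusionMatrix]) -> MetricReport:
    pooled = ConfusionMatrix(sum(cm.counts for cm in cms))
    per_run = [round2(100.0 * cm.accuracy) for cm in cms]
    return MetricReport(
        per_class={c: confusion_metrics(pooled, c) for c in CLASS_NAMES},
        accuracy=round2(100.0 * pooled.accuracy),
        per_run_accuracy=per_run,
        mean_accuracy=round2(float(np.mean(per_run))),
        std_accuracy=round2(float(np.std(per_run, ddof=1))) if len(per_run) > 1 else 0.0,
        confusions=cms,
    )


def cross_validate(
    features: FeatureMatrix | np.ndarray,
    labels=None,
    cfg: SVMConfig | None = None,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    feature_indices: np.ndarray | None = None,
) -> MetricReport:
    """Repeated stratified k-fold CV of the SVM on (selected) features.

    Each repeat reshuffles the stratified folds with its own derived seed;
    within a repeat every sample is predicted exactly once.
    """
    cfg = cfg or SVMConfig()
    if isinstance(features, FeatureMatrix):
        X = features.values
        y = encode_labels(features.labels)
    else:
        X = np.asarray(features, dtype=np.float64)
        y = np.asarray(labels)
        if y.dtype.kind not in "iu":
            y = encode_labels(list(y))
    if feature_indices is not None:
        X = X[:, np.asarray(feature_indices, dtype=int)]
    # canonical sample order (label, then feature values): fold membership
    # then depends only on the data multiset and the seed, so the report is
    # invariant to the order samples arrive in
    canon = np.lexsort(tuple(X.T[::-1]) + (y,))
    X, y = X[canon], y[canon]
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"stratified {folds}-fold CV needs >= {folds} samples per class "
            f"(smallest class has {counts.min()})"
        )
    cms = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        y_pred = np.empty_like(y)
        for train_ix, test_ix in skf.split(X, y):
            clf = _make_svm(cfg)
            clf.fit(X[train_ix], y[train_ix])
            y_pred[test_ix] = clf.predict(X[test_ix])
        cms.append(ConfusionMatrix.from_predictions(y, y_pred))
    return _report_from_confusions(cms)


def ablation_suite(
    features: FeatureMatrix,
    selections: dict[str, np.ndarray | None],
    cfg: SVMConfig | None = None,
    folds: int = 10,
    seed: int = 0,
) -> dict[str, MetricReport]:
    """Paired comparison of feature-selection arms.

    ``selections`` maps arm name -> column index array (or None for all
    features).  Every arm uses identical fold assignments (same seed, same
    stratification), so differences are attributable to the selection alone.
    """
    return {
        name: cross_validate(
            features, cfg=cfg, folds=folds, repeats=1, seed=seed,
            feature_indices=idx,
        )
        for name, idx in selections.items()
    }


def format_metric_table(report: MetricReport) -> str:
    """Per-class metric table in the standard 4-column layout."""
    lines = ["Class       Sensitivity (%)  Specificity (%)  Precision (%)  F1-Score (%)"]
    for cls in CLASS_NAMES:
        m = report.per_class[cls]
        cells = [
            f"{m[k]:.2f}" if m[k] is not None else "undef"
            for k in ("sensitivity", "specificity", "precision", "f1")
        ]
        lines.append(f"{cls.capitalize():<12}{cells[0]:>15}{cells[1]:>17}{cells[2]:>15}{cells[3]:>14}")
    return "\n".join(lines)


def format_run_table(report: MetricReport, per_column: int = 10) -> str:
    """Per-run accuracies in columns of ten, with mean and s.d."""
    accs = report.per_run_accuracy
    cols = [accs[i : i + per_column] for i in range(0, len(accs), per_column)]
    header = "\t".join(
        f"{i * per_column + 1}-{i * per_column + len(c)}" for i, c in enumerate(cols)
    )
    lines = [header]
    for r in range(max(len(c) for c in cols)):
        lines.append("\t".join(f"{c[r]:.2f}%" if r < len(c) else "" for c in cols))
    lines.append(f"mean {report.mean_accuracy:.2f}%  sd {report.std_accuracy:.2f}")
    return "\n".join(lines)
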