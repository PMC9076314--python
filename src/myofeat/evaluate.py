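"""Classification, trial-wise cross-validation, confusion-matrix metrics,
Bonferroni-corrected ANOVA comparisons, and the window-size / SNR
robustness sweeps.

Cross-validation is leave-one-trial-out: with T repetitions per movement
the evaluation runs T folds, fold t training on every movement's trials
except t and testing on trial t, so train and test windows never share a
contraction.  ULDA is refitted inside every fold on training windows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .dimred import ulda_fit, ulda_transform
from .features import FeatureMatrix, FeatureSetSpec, feature_set, extract
from .preprocess import add_awgn, preprocess, segment_disjoint
from .synthio import TrialRecording

__all__ = [
    "MetricSet",
    "EvaluationReport",
    "SweepPoint",
    "SweepResult",
    "make_classifier",
    "classify",
    "metrics_from_confusion",
    "trialwise_cv",
    "cv_from_features",
    "extract_dataset",
    "compare_bonferroni",
    "sweep_window",
    "sweep_snr",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


def make_classifier(model: str, quadratic: bool = True):
    """Instantiate one of the three evaluation classifiers.

    * ``lda`` — Gaussian discriminant with per-class covariance (quadratic
      boundary); ``quadratic=False`` selects the pooled-covariance linear
      variant.
    * ``svm`` — RBF-kernel SVM with kernel ``exp(−‖u−v‖²/(2σ²))``, σ = 1
      (i.e. gamma = 0.5).
    * ``knn`` — 3-nearest-neighbours with cityblock (L1) distance.
    """
    model = model.lower()
    if model == "lda":
        if quadratic:
            # tiny shrinkage + low rank tolerance: keeps per-class covariances
            # invertible when ULDA leaves near-zero within-class variance
            return QuadraticDiscriminantAnalysis(reg_param=1e-6, tol=1e-12)
        return LinearDiscriminantAnalysis()
    if model == "svm":
        return SVC(kernel="rbf", gamma=0.5)
    if model == "knn":
        return KNeighborsClassifier(n_neighbors=3, metric="manhattan")
    raise ValueError(f"unknown model {model!r}; choose lda, svm or knn")


def classify(
    train: FeatureMatrix,
    test: FeatureMatrix,
    model: str = "lda",
    quadratic: bool = True,
) -> np.ndarray:
    """Fit a classifier on ``train`` and predict labels for ``test``."""
    if list(train.columns) != list(test.columns):
        raise ValueError("train and test feature columns differ")
    clf = make_classifier(model, quadratic=quadratic)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinearity warnings on separable data
        clf.fit(train.values, train.labels)
        return np.asarray(clf.predict(test.values))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSet:
    """Accuracy, sensitivity, specificity, precision and F1, in percent."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics_from_confusion(
    confusion: np.ndarray, classes: Sequence | None = None
) -> tuple[dict, MetricSet]:
    """Per-movement (one-vs-rest) and macro-averaged metrics, in percent.

    For movement m: TP = C[m,m]; FN = row-sum minus TP; FP = column-sum
    minus TP; TN = everything else.  Then accuracy = (TP+TN)/total,
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    precision = TP/(TP+FP), and F1 the harmonic mean of precision and
    sensitivity.  Zero-denominator metrics report 0 with a warning.
    """
    C = np.asarray(confusion)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(C < 0) or not np.all(C == np.round(C)):
        raise ValueError("confusion matrix must hold nonnegative integers")
    K = C.shape[0]
    names = list(classes) if classes is not None else list(range(K))
    total = float(C.sum())
    per: dict = {}
    for m in range(K):
        tp = float(C[m, m])
        fn = float(C[m].sum()) - tp
        fp = float(C[:, m].sum()) - tp
        tn = total - tp - fn - fp
        sens = _safe_ratio(tp, tp + fn, f"sensitivity[{names[m]}]")
        prec = _safe_ratio(tp, tp + fp, f"precision[{names[m]}]")
        per[names[m]] = MetricSet(
            accuracy=100.0 * _safe_ratio(tp + tn, total, "accuracy"),
            sensitivity=100.0 * sens,
            specificity=100.0 * _safe_ratio(tn, tn + fp, f"specificity[{names[m]}]"),
            precision=100.0 * prec,
            f1=100.0 * _safe_ratio(2 * prec * sens, prec + sens, f"f1[{names[m]}]"),
        )
    macro = MetricSet(
        **{
            m: float(np.mean([getattr(per[c], m) for c in names]))
            for m in METRIC_NAMES
        }
    )
    return per, macro


# ---------------------------------------------------------------------------
# trial-wise cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-fold and aggregate results of one trial-wise CV run."""

    classes: tuple
    fold_confusions: list[np.ndarray]
    fold_macro: list[MetricSet]
    per_movement: dict                      # movement -> MetricSet (pooled)
    macro_mean: MetricSet
    macro_sd: MetricSet
    spec_name: str = ""
    model: str = ""

    @property
    def pooled_confusion(self) -> np.ndarray:
        return np.sum(self.fold_confusions, axis=0)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "spec": self.spec_name,
            "model": self.model,
            "macro_mean": self.macro_mean.as_dict(),
            "macro_sd": self.macro_sd.as_dict(),
            "per_movement": {str(k): v.as_dict() for k, v in self.per_movement.items()},
            "pooled_confusion": self.pooled_confusion.tolist(),
        }


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    C = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        C[idx[t], idx[p]] += 1
    return C


def cv_from_features(
    fm: FeatureMatrix, model: str = "lda", quadratic: bool = True
) -> EvaluationReport:
    """Leave-one-trial-out CV on an already-extracted feature matrix.

    Every movement must carry the same trial indices.  ULDA is fitted per
    fold on the training rows only and applied to both splits before
    classification.
    """
    classes = tuple(sorted(set(fm.labels.tolist())))
    trial_sets = {
        c: tuple(sorted(set(fm.trial_index[fm.labels == c].tolist()))) for c in classes
    }
    trials = trial_sets[classes[0]]
    if any(ts != trials for ts in trial_sets.values()):
        raise ValueError("unequal trial sets across movements")
    fold_confusions, fold_macro = [], []
    for t in trials:
        test_mask = fm.trial_index == t
        train = _subset(fm, ~test_mask)
        test = _subset(fm, test_mask)
        proj = ulda_fit(train)
        y_pred = classify(
            ulda_transform(proj, train), ulda_transform(proj, test),
            model=model, quadratic=quadratic,
        )
        C = _confusion(test.labels, y_pred, classes)
        fold_confusions.append(C)
        _, macro = metrics_from_confusion(C, classes)
        fold_macro.append(macro)
    per_movement, _ = metrics_from_confusion(
        np.sum(fold_confusions, axis=0), classes
    )
    macro_mean = MetricSet(**{
        m: float(np.mean([getattr(f, m) for f in fold_macro])) for m in METRIC_NAMES
    })
    macro_sd = MetricSet(**{
        m: float(np.std([getattr(f, m) for f in fold_macro], ddof=1))
        for m in METRIC_NAMES
    })
    return EvaluationReport(
        classes=classes,
        fold_confusions=fold_confusions,
        fold_macro=fold_macro,
        per_movement=per_movement,
        macro_mean=macro_mean,
        macro_sd=macro_sd,
        spec_name=fm.spec_name,
        model=model,
    )


def _subset(fm: FeatureMatrix, mask: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        values=fm.values[mask],
        columns=fm.columns,
        labels=fm.labels[mask],
        trial_index=fm.trial_index[mask],
        window_index=fm.window_index[mask],
        spec_name=fm.spec_name,
    )


def extract_dataset(
    recordings: Sequence[TrialRecording],
    spec: FeatureSetSpec | str,
    window_ms: float = 250.0,
    do_preprocess: bool = True,
) -> FeatureMatrix:
    """Front half of the pipeline: filter, window and featurize a dataset."""
    windows = []
    for rec in recordings:
        if do_preprocess:
            rec = preprocess(rec)
        windows.extend(segment_disjoint(rec, window_ms))
    return extract(windows, spec)


def trialwise_cv(
    recordings: Sequence[TrialRecording],
    spec: FeatureSetSpec | str,
    model: str = "lda",
    window_ms: float = 250.0,
    quadratic: bool = True,
    do_preprocess: bool = True,
) -> EvaluationReport:
    """Full pipeline evaluation: preprocess → window → features → per-fold
    ULDA → classifier → Eq.-style confusion metrics, leave-one-trial-out."""
    fm = extract_dataset(recordings, spec, window_ms, do_preprocess)
    return cv_from_features(fm, model=model, quadratic=quadratic)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def compare_bonferroni(
    scores_a: Sequence[float], scores_b: Sequence[float], n_comparisons: int = 1
) -> float:
    """One-way ANOVA between two score vectors, Bonferroni-corrected.

    Returns ``min(1, p · n_comparisons)``.  Degenerate zero-variance groups
    report 0 when the means differ and 1 otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("score vectors must share length >= 2")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if np.var(a) == 0 and np.var(b) == 0:
        return 0.0 if a.mean() != b.mean() else 1.0
    _, p = stats.f_oneway(a, b)
    return float(min(1.0, p * n_comparisons))


# ---------------------------------------------------------------------------
# robustness sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepPoint:
    """One axis point: metrics with and without the {LMAV, NSV} pair."""

    axis_value: float
    base: EvaluationReport
    augmented: EvaluationReport


@dataclass
class SweepResult:
    axis_name: str                       # "window_ms" or "snr_db"
    points: list[SweepPoint] = field(default_factory=list)

    @property
    def axis(self) -> list[float]:
        return [p.axis_value for p in self.points]

    def f1_curves(self) -> dict[str, list[float]]:
        return {
            "base": [p.base.macro_mean.f1 for p in self.points],
            "augmented": [p.augmented.macro_mean.f1 for p in self.points],
        }

    def to_dict(self) -> dict:
        return {
            "axis_name": self.axis_name,
            "axis": self.axis,
            "base": [p.base.to_dict() for p in self.points],
            "augmented": [p.augmented.to_dict() for p in self.points],
        }


def _augmented(spec: FeatureSetSpec | str) -> FeatureSetSpec:
    if isinstance(spec, str):
        spec = feature_set(spec)
    return spec.with_extra(["LMAV", "NSV"])


DEFAULT_WINDOW_GRID = tuple(range(50, 351, 50))   # 50..350 ms step 50
DEFAULT_SNR_GRID = tuple(range(0, 21))            # 0..20 dB step 1


def sweep_window(
    recordings: Sequence[TrialRecording],
    base_spec: FeatureSetSpec | str = "PROPOSED11",
    model: str = "lda",
    grid: Sequence[float] = DEFAULT_WINDOW_GRID,
) -> SweepResult:
    """Window-size robustness sweep: evaluate the base feature set and
    base ∪ {LMAV, NSV} at each window length (default 50-350 ms, step 50)."""
    if isinstance(base_spec, str):
        base_spec = feature_set(base_spec)
    aug = _augmented(base_spec)
    result = SweepResult(axis_name="window_ms")
    for w in grid:
        result.points.append(SweepPoint(
            axis_value=float(w),
            base=trialwise_cv(recordings, base_spec, model, window_ms=w),
            augmented=trialwise_cv(recordings, aug, model, window_ms=w),
        ))
    return result


def sweep_snr(
    recordings: Sequence[TrialRecording],
    base_spec: FeatureSetSpec | str = "PROPOSED11",
    model: str = "lda",
    seed: int = 0,
    grid: Sequence[float] = DEFAULT_SNR_GRID,
    window_ms: float = 250.0,
) -> SweepResult:
    """SNR robustness sweep: contaminate the *raw* trials with AWGN at each
    requested SNR (one seeded realization per trial per point), then run the
    full pipeline for the base set and base ∪ {LMAV, NSV}."""
    if isinstance(base_spec, str):
        base_spec = feature_set(base_spec)
    aug = _augmented(base_spec)
    result = SweepResult(axis_name="snr_db")
    for j, snr in enumerate(grid):
        noisy = [add_awgn(rec, snr, seed=seed + 1000 * j) for rec in recordings]
        result.points.append(SweepPoint(
            axis_value=float(snr),
            base=trialwise_cv(noisy, base_spec, model, window_ms=window_ms),
            augmented=trialwise_cv(noisy, aug, model, window_ms=window_ms),
        ))
    return result
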