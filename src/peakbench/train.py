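"""Supervised threshold calibration and evaluation.

Training is grid search: evaluate the total label error E at every threshold
on the grid and keep the minimizer

    lambda_hat = argmin_lambda  sum_i E[c_lambda(x_i), L_i],

breaking ties toward the *largest* minimizing threshold (the most conservative
call set — over-calling is the dominant failure mode of default parameters).
Test evaluation scores a fixed threshold's calls against held-out labels.
Cross-validation resamples labeled *windows* (each window was labeled as a
unit, so labels within a window are not independent), never individual labels
or samples.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

from .exceptions import PeakBenchError, ValidationError
from .io import ThresholdedCallSet
from .model import (
    FP_CAPABLE_LABEL_TYPES,
    POSITIVE_LABEL_TYPES,
    Window,
    labels_of,
)
from .peak_error import ErrorSummary, error_by_type, evaluate_labels, summarize

logger = logging.getLogger(__name__)


@dataclass
class TrainedModel:
    """The result of grid-search calibration on a training label set."""

    algorithm: str
    chosen_threshold: float
    train_error: ErrorSummary
    per_threshold_errors: dict[float, ErrorSummary] = field(default_factory=dict)


@dataclass(frozen=True)
class FoldAssignment:
    """A seeded assignment of windows to K folds (sizes differ by at most 1)."""

    k: int
    seed: int
    assignment: Mapping[str, int]  # window_id -> fold in {1..k}

    def windows_in_fold(self, windows: Iterable[Window], fold: int) -> list[Window]:
        return [w for w in windows if self.assignment[w.id] == fold]

    def windows_not_in_fold(self, windows: Iterable[Window], fold: int) -> list[Window]:
        return [w for w in windows if self.assignment[w.id] != fold]


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    tpr: float
    fpr: float


@dataclass(frozen=True)
class RocCurve:
    """ROC-like threshold sweep.

    Axis definitions (one consistent reading of "ROC-like"): the true positive
    rate is 1 - FN / (#positive labels: peaks, peakStart, peakEnd); the false
    positive rate is FP / (#fp-capable labels: noPeaks, peakStart, peakEnd).
    "peaks" labels are excluded from the FPR denominator because they can
    never be false positives under the error rules.
    """

    points: tuple[RocPoint, ...]


@dataclass(frozen=True)
class FoldResult:
    fold: int
    chosen_threshold: float
    trained: ErrorSummary
    default: ErrorSummary | None


@dataclass
class CrossValidationResult:
    folds: list[FoldResult]

    def _percents(self, which: str) -> np.ndarray:
        vals = [getattr(f, which) for f in self.folds]
        if any(v is None for v in vals):
            raise PeakBenchError(f"no {which} evaluation in cross-validation result")
        return np.array([v.percent_error for v in vals])

    @property
    def trained_mean(self) -> float:
        return float(self._percents("trained").mean())

    @property
    def trained_sd(self) -> float:
        """Sample standard deviation over test folds."""
        return float(self._percents("trained").std(ddof=1))

    @property
    def default_mean(self) -> float:
        return float(self._percents("default").mean())

    @property
    def default_sd(self) -> float:
        return float(self._percents("default").std(ddof=1))


@dataclass(frozen=True)
class LearningCurvePoint:
    n_windows_trained: int
    per_order: tuple[float, ...]  # test percent error for each ordering

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_order))

    @property
    def min(self) -> float:
        return float(np.min(self.per_order))

    @property
    def max(self) -> float:
        return float(np.max(self.per_order))


def train(
    call_set: ThresholdedCallSet,
    train_windows: Iterable[Window],
    groups: Mapping[str, str] | None = None,
) -> TrainedModel:
    """Grid-search the threshold minimizing total label error on the training windows."""
    train_windows = list(train_windows)
    if not call_set.thresholds:
        raise ValidationError("call set has an empty threshold grid")
    if not train_windows:
        raise ValidationError("training requires at least one labeled window")
    labels = labels_of(train_windows)
    per_threshold: dict[float, ErrorSummary] = {}
    best_t = None
    best: ErrorSummary | None = None
    for t in call_set.thresholds:  # ascending; <= keeps the largest minimizer
        summary = summarize(evaluate_labels(call_set.calls_at(t), labels, groups))
        per_threshold[t] = summary
        if best is None or summary.errors <= best.errors:
            best, best_t = summary, t
    logger.info(
        "trained %s: lambda_hat=%g, train error %d/%d (%.1f%%) over %d grid points",
        call_set.algorithm, best_t, best.errors, best.n_labels,
        best.percent_error, len(call_set.thresholds),
    )
    return TrainedModel(call_set.algorithm, best_t, best, per_threshold)


def evaluate(
    call_set: ThresholdedCallSet,
    threshold: float,
    test_windows: Iterable[Window],
    groups: Mapping[str, str] | None = None,
) -> ErrorSummary:
    """Label error of the calls at one grid threshold on held-out windows."""
    calls = call_set.calls_at(threshold)  # raises ThresholdError off-grid
    return summarize(evaluate_labels(calls, labels_of(test_windows), groups))


def assign_folds(windows: Iterable[Window], k: int, seed: int) -> FoldAssignment:
    """Seeded shuffle then round-robin: fold sizes differ by at most 1."""
    windows = list(windows)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if len(windows) < k:
        raise ValidationError(f"{len(windows)} windows is fewer than k={k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(windows))
    assignment = {windows[int(j)].id: (pos % k) + 1 for pos, j in enumerate(order)}
    return FoldAssignment(k, seed, assignment)


def cross_validate(
    call_set: ThresholdedCallSet,
    windows: Iterable[Window],
    k: int,
    seed: int,
    groups: Mapping[str, str] | None = None,
    compare_default: bool = True,
) -> CrossValidationResult:
    """Window-based K-fold cross-validation of trained vs default thresholds.

    For each fold: train on all other folds, then evaluate the trained
    threshold (and, when the call set has one, the default threshold) on the
    held-out fold.
    """
    windows = list(windows)
    if compare_default and call_set.default_threshold is None:
        raise PeakBenchError("call set has no default threshold to compare against")
    fa = assign_folds(windows, k, seed)
    folds = []
    for fold in range(1, k + 1):
        model = train(call_set, fa.windows_not_in_fold(windows, fold), groups)
        test = fa.windows_in_fold(windows, fold)
        trained = evaluate(call_set, model.chosen_threshold, test, groups)
        default = (
            evaluate(call_set, call_set.default_threshold, test, groups)
            if compare_default
            else None
        )
        folds.append(FoldResult(fold, model.chosen_threshold, trained, default))
    return CrossValidationResult(folds)


def roc_like_curve(
    call_set: ThresholdedCallSet,
    windows: Iterable[Window],
    groups: Mapping[str, str] | None = None,
) -> RocCurve:
    """True/false positive rates for every threshold on the grid."""
    labels = labels_of(list(windows))
    points = []
    for t in call_set.thresholds:
        by_type = error_by_type(evaluate_labels(call_set.calls_at(t), labels, groups))
        n_pos = sum(by_type[t_].n_labels for t_ in POSITIVE_LABEL_TYPES)
        n_fpc = sum(by_type[t_].n_labels for t_ in FP_CAPABLE_LABEL_TYPES)
        if n_pos == 0 or n_fpc == 0:
            raise ValidationError(
                "ROC-like rates undefined: need at least one positive and one "
                "fp-capable label"
            )
        fn = sum(by_type[t_].fn_total for t_ in POSITIVE_LABEL_TYPES)
        fp = sum(by_type[t_].fp_total for t_ in FP_CAPABLE_LABEL_TYPES)
        points.append(RocPoint(t, 1.0 - fn / n_pos, fp / n_fpc))
    return RocCurve(tuple(points))


def learning_curve(
    call_set: ThresholdedCallSet,
    windows: Iterable[Window],
    folds: FoldAssignment,
    test_fold: int,
    max_train: int,
    n_orders: int,
    seed: int,
    groups: Mapping[str, str] | None = None,
) -> list[LearningCurvePoint]:
    """Test error as a function of training-set size.

    For each of ``n_orders`` random orderings of the training windows, train
    on nested prefixes of sizes 0..max_train and evaluate on the fixed test
    fold.  Size 0 means no labels: the default threshold is used.
    """
    windows = list(windows)
    if n_orders < 1:
        raise ValidationError("n_orders must be >= 1")
    test = folds.windows_in_fold(windows, test_fold)
    pool = folds.windows_not_in_fold(windows, test_fold)
    if max_train > len(pool):
        raise ValidationError(
            f"max_train={max_train} exceeds the {len(pool)} available training windows"
        )
    if call_set.default_threshold is None:
        raise PeakBenchError("learning curve size 0 requires a default threshold")
    per_size: dict[int, list[float]] = {s: [] for s in range(max_train + 1)}
    for o in range(n_orders):
        rng = np.random.default_rng((seed, o))
        ordering = [pool[int(j)] for j in rng.permutation(len(pool))]
        for s in range(max_train + 1):
            if s == 0:
                summary = evaluate(call_set, call_set.default_threshold, test, groups)
            else:
                model = train(call_set, ordering[:s], groups)
                summary = evaluate(call_set, model.chosen_threshold, test, groups)
            per_size[s].append(summary.percent_error)
    return [
        LearningCurvePoint(s, tuple(per_size[s])) for s in range(max_train + 1)
    ]
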