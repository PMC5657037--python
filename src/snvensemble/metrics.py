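"""Confusion counts, sensitivity/precision/F1, cross-validation and
strategy comparison.

Definitions: TP are truth sites that were predicted somatic, FN truth
sites that were not, FP predicted-somatic sites outside the truth set,
and TN the remaining sites of the evaluated universe.  Sensitivity =
TP/(TP+FN), precision = TP/(TP+FP), F1 = 2PR/(P+R); a metric whose
denominator is zero is reported as 0 with a logged warning so degenerate
cross-validation folds do not abort a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .features import FeatureSchema
from .labeling import LabeledExample
from .sites import GenomicSite
from .tree import TrainParams, fit_arrays, predict_matrix, _examples_to_arrays

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricSet:
    counts: ConfusionCounts
    sensitivity: float
    precision: float
    f1: float


@dataclass
class StrategyResult:
    strategy: str  # single | union | intersection | ensemble
    caller: str
    metrics: MetricSet

    def __post_init__(self) -> None:
        if self.strategy not in ("single", "union", "intersection", "ensemble"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def confusion_counts(
    predicted: Iterable[GenomicSite],
    truth: Iterable[GenomicSite],
    universe: Iterable[GenomicSite],
) -> ConfusionCounts:
    """Set-based confusion counts over an explicit evaluation universe."""
    pred, tru, uni = set(predicted), set(truth), set(universe)
    if not pred <= uni or not tru <= uni:
        raise ValueError("predicted and truth sets must lie within the universe")
    tp = len(pred & tru)
    fp = len(pred - tru)
    fn = len(tru - pred)
    tn = len(uni) - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", what)
        return 0.0
    return num / den


def metric_set(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, precision and F1 from confusion counts."""
    sens = _safe_ratio(c.tp, c.tp + c.fn, "sensitivity")
    prec = _safe_ratio(c.tp, c.tp + c.fp, "precision")
    f1 = _safe_ratio(2 * prec * sens, prec + sens, "F1")
    return MetricSet(c, sens, prec, f1)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    return _safe_ratio(2 * precision * recall, precision + recall, "F1")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _stratified_folds(y: np.ndarray, k: int, seed: int, stratified: bool) -> np.ndarray:
    """Fold index per example; per-class round-robin after a seeded shuffle."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    if not stratified:
        perm = rng.permutation(len(y))
        folds[perm] = np.arange(len(y)) % k
        return folds
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(idx)) % k
    return folds


def cross_validate(
    examples: Sequence[LabeledExample],
    schema: FeatureSchema,
    k: int = 10,
    seed: int = 0,
    params: Optional[TrainParams] = None,
    stratified: bool = True,
) -> tuple[MetricSet, list[MetricSet]]:
    """k-fold cross-validation; pooled held-out confusion counts.

    Folds are stratified by class by default (class sizes per fold differ
    by at most one).  ``k == n`` with ``stratified=False`` is
    leave-one-out.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    params = params or TrainParams()
    X, y = _examples_to_arrays(examples, schema)
    if stratified:
        for cls in np.unique(y):
            if (y == cls).sum() < k:
                raise ValueError(
                    f"class {cls} has fewer than k={k} examples; use a smaller k"
                )
    folds = _stratified_folds(y, k, seed, stratified)
    per_fold: list[MetricSet] = []
    pooled = np.zeros(4)  # tp, fp, fn, tn
    for fold in range(k):
        test = folds == fold
        model = fit_arrays(X[~test], y[~test], schema, params)
        scores = predict_matrix(model, X[test])
        pred = scores >= 0.5
        truth = y[test] == 1
        tp = int(np.sum(pred & truth))
        fp = int(np.sum(pred & ~truth))
        fn = int(np.sum(~pred & truth))
        tn = int(np.sum(~pred & ~truth))
        pooled += (tp, fp, fn, tn)
        per_fold.append(metric_set(ConfusionCounts(tp, fp, fn, tn)))
    summary = metric_set(ConfusionCounts(*pooled))
    return summary, per_fold


# ---------------------------------------------------------------------------
# strategy comparison
# ---------------------------------------------------------------------------

def combine_strategy(
    platform_calls: Mapping[str, Iterable[GenomicSite]], strategy: str
) -> set[GenomicSite]:
    """Union or intersection of one caller's per-platform call sets."""
    sets = [set(s) for s in platform_calls.values()]
    if not sets:
        raise ValueError("need at least one platform call set")
    if strategy == "union":
        return set().union(*sets)
    if strategy == "intersection":
        return set.intersection(*sets)
    raise ValueError(f"unknown strategy {strategy!r}")


def compare_report(
    truth: Iterable[GenomicSite],
    universe: Iterable[GenomicSite],
    caller_calls: Mapping[str, Mapping[str, Iterable[GenomicSite]]],
    ensemble_predictions: Iterable[GenomicSite],
) -> list[StrategyResult]:
    """Per-caller union/intersection baselines plus the ensemble.

    ``caller_calls`` maps caller name -> platform name -> called sites.
    Returns 2·(number of callers) + 1 rows.
    """
    truth = set(truth)
    universe = set(universe) | truth
    results: list[StrategyResult] = []
    for caller, platform_calls in caller_calls.items():
        for strategy in ("union", "intersection"):
            pred = combine_strategy(platform_calls, strategy) & universe
            results.append(
                StrategyResult(strategy, caller, metric_set(confusion_counts(pred, truth, universe)))
            )
    pred = set(ensemble_predictions) & universe
    results.append(StrategyResult("ensemble", "J48-style tree", metric_set(confusion_counts(pred, truth, universe))))
    return results


def report_to_tsv(results: Sequence[StrategyResult], path) -> None:
    """Tab-delimited report: strategy, caller, counts and metrics."""
    with open(path, "wt") as fh:
        fh.write("strategy\tcaller\ttp\tfp\tfn\ttn\tsensitivity\tprecision\tf1\n")
        for r in results:
            c = r.metrics.counts
            fh.write(
                f"{r.strategy}\t{r.caller}\t{c.tp:.9g}\t{c.fp:.9g}\t{c.fn:.9g}\t{c.tn:.9g}"
                f"\t{r.metrics.sensitivity:.4f}\t{r.metrics.precision:.4f}\t{r.metrics.f1:.4f}\n"
            )
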