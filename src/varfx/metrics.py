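"""Performance measures: per-class accuracy/coverage, F, Q2, MCC, ROC/AUC,
bootstrap errors, accuracy-coverage and reliability curves, difficulty triage.

Conventions: 'effect' is the positive class.  TP = correctly predicted
effect, FP = neutral predicted effect, TN = correctly predicted neutral,
FN = effect predicted neutral.

* accuracy_effect  = precision_effect = TP / (TP + FP)
* coverage_effect  = recall_effect    = TP / (TP + FN)
* accuracy_neutral = NPV              = TN / (TN + FN)
* coverage_neutral = specificity      = TN / (TN + FP)
* F per class = harmonic mean of its precision and recall
* Q2  = (TP + TN) / total
* MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Any quantity with a zero denominator is reported as None (an explicit
undefined marker), never silently as 0.

Bootstrap errors are estimated over n sets, each a random 50% subsample of
the test set drawn without replacement: SD = sqrt(mean((x_i − ⟨x⟩)²)) and
SE = SD / sqrt(n − 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .io import EFFECT, NEUTRAL, UNLABELED, PredictionResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_counts(predictions: Iterable[tuple[str, str]]) -> ConfusionCounts:
    """Counts from (predicted_class, label) pairs; unlabeled rows are excluded."""
    tp = fp = tn = fn = 0
    skipped = 0
    for predicted, label in predictions:
        if label == UNLABELED:
            skipped += 1
            continue
        if label not in (NEUTRAL, EFFECT) or predicted not in (NEUTRAL, EFFECT):
            raise ValueError(f"unexpected class pair ({predicted!r}, {label!r})")
        if label == EFFECT:
            if predicted == EFFECT:
                tp += 1
            else:
                fn += 1
        else:
            if predicted == EFFECT:
                fp += 1
            else:
                tn += 1
    if skipped:
        logger.info("confusion_counts: excluded %d unlabeled rows", skipped)
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def class_metrics(c: ConfusionCounts) -> tuple[float | None, float | None,
                                               float | None, float | None]:
    """(accuracy_effect, coverage_effect, accuracy_neutral, coverage_neutral)."""
    return (
        _ratio(c.TP, c.TP + c.FP),
        _ratio(c.TP, c.TP + c.FN),
        _ratio(c.TN, c.TN + c.FN),
        _ratio(c.TN, c.TN + c.FP),
    )


def f_measures(c: ConfusionCounts) -> tuple[float | None, float | None]:
    """(F_effect, F_neutral); undefined when a component rate is undefined."""
    acc_e, cov_e, acc_n, cov_n = class_metrics(c)

    def f(p, r):
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)

    return f(acc_e, cov_e), f(acc_n, cov_n)


def q2(c: ConfusionCounts) -> float:
    """Two-state accuracy (TP + TN) / total."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    return (c.TP + c.TN) / c.total


def mcc(c: ConfusionCounts) -> float | None:
    """Matthews correlation coefficient; None when any marginal is zero."""
    denom = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    if denom == 0:
        return None
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)


def _binary_labels(labels: Sequence[str]) -> np.ndarray:
    y = np.array([1 if lab == EFFECT else 0 for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    return y


def roc_auc(scores: Sequence[float], labels: Sequence[str]):
    """ROC points (fpr, tpr) from a threshold sweep and the trapezoid AUC.

    Equals the tie-corrected Mann–Whitney rank statistic (ties count 1/2).
    """
    y = _binary_labels(labels)
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass(frozen=True)
class BootstrapEstimate:
    mean: float
    sd: float
    se: float
    n_sets: int
    n_skipped: int
    values: tuple[float, ...]


def bootstrap_errors(test_set: Sequence, metric: Callable[[Sequence], float | None],
                     n_sets: int = 1000, seed: int = 0,
                     fraction: float = 0.5) -> BootstrapEstimate:
    """SD/SE of a metric over random 50% subsamples drawn without replacement.

    Subsamples on which the metric is undefined (None) are skipped and
    counted.  SD = sqrt(mean squared deviation from the bootstrap mean);
    SE = SD / sqrt(n_sets − 1).
    """
    items = list(test_set)
    if len(items) < 2:
        raise ValueError("bootstrap requires at least 2 items")
    rng = np.random.default_rng(seed)
    size = max(1, int(round(fraction * len(items))))
    values = []
    skipped = 0
    for _ in range(n_sets):
        idx = rng.choice(len(items), size=size, replace=False)
        x = metric([items[i] for i in idx])
        if x is None:
            skipped += 1
            continue
        values.append(float(x))
    if not values:
        raise ValueError("metric undefined on every bootstrap set")
    arr = np.array(values)
    mean = float(arr.mean())
    sd = float(np.sqrt(np.mean((arr - mean) ** 2)))
    se = sd / math.sqrt(n_sets - 1)
    return BootstrapEstimate(mean=mean, sd=sd, se=se, n_sets=n_sets,
                             n_skipped=skipped, values=tuple(values))


@dataclass(frozen=True)
class MetricReport:
    """All scalar measures for one prediction set (None = undefined)."""

    accuracy_effect: float | None
    coverage_effect: float | None
    accuracy_neutral: float | None
    coverage_neutral: float | None
    f_effect: float | None
    f_neutral: float | None
    q2: float
    mcc: float | None
    auc: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def metric_report(predicted: Sequence[str], labels: Sequence[str],
                  scores: Sequence[float] | None = None) -> MetricReport:
    c = confusion_counts(zip(predicted, labels))
    acc_e, cov_e, acc_n, cov_n = class_metrics(c)
    f_e, f_n = f_measures(c)
    auc = None
    if scores is not None:
        try:
            _, auc = roc_auc(scores, labels)
        except ValueError:
            auc = None
    return MetricReport(acc_e, cov_e, acc_n, cov_n, f_e, f_n, q2(c), mcc(c), auc)


def accuracy_coverage_curve(scores: Sequence[float], labels: Sequence[str],
                            thresholds: Sequence[float]) -> list[dict]:
    """Per threshold: per-class accuracy (precision) and coverage (recall).

    A variant is predicted 'effect' when its score exceeds the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    out = []
    for t in thresholds:
        predicted = [EFFECT if s > t else NEUTRAL for s in scores]
        c = confusion_counts(zip(predicted, labels))
        acc_e, cov_e, acc_n, cov_n = class_metrics(c)
        out.append({"threshold": float(t),
                    "accuracy_effect": acc_e, "coverage_effect": cov_e,
                    "accuracy_neutral": acc_n, "coverage_neutral": cov_n})
    return out


def reliability_curve(results: Sequence[PredictionResult],
                      labels: Sequence[str]) -> list[dict]:
    """Cumulative per-class accuracy/coverage for predictions with RI >= r.

    Coverage is measured against all labeled variants of the class, so it is
    non-increasing in r; accuracy is the precision within the retained set.
    """
    if len(results) != len(labels):
        raise ValueError("results and labels differ in length")
    total_e = sum(1 for lab in labels if lab == EFFECT)
    total_n = sum(1 for lab in labels if lab == NEUTRAL)
    rows = []
    for r in range(11):
        retained = [(res.predicted_class, lab)
                    for res, lab in zip(results, labels) if res.ri >= r]
        c = confusion_counts(retained)
        acc_e, _, acc_n, _ = class_metrics(c)
        rows.append({
            "ri": r,
            "n_retained": c.total,
            "accuracy_effect": acc_e,
            "accuracy_neutral": acc_n,
            "coverage_effect": _ratio(c.TP, total_e) if total_e else None,
            "coverage_neutral": _ratio(c.TN, total_n) if total_n else None,
            "accuracy_overall": _ratio(c.TP + c.TN, c.total) if c.total else None,
        })
    return rows


def random_baseline_q2(n_effect: int, n_neutral: int,
                       p_effect_background: float = 0.6) -> float:
    """Expected Q2 of a predictor that calls 'effect' with fixed probability.

    Closed form: p_bg · f_effect + (1 − p_bg) · (1 − f_effect), where
    f_effect is the effect fraction of the evaluated set.
    """
    total = n_effect + n_neutral
    if total == 0:
        raise ValueError("empty set")
    f_effect = n_effect / total
    return p_effect_background * f_effect + (1 - p_effect_background) * (1 - f_effect)


def simulate_random_baseline_q2(n_effect: int, n_neutral: int,
                                p_effect_background: float = 0.6,
                                n_replicates: int = 1000,
                                seed: int = 0) -> BootstrapEstimate:
    """Monte-Carlo estimate of the random-baseline Q2 (mean over replicates)."""
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(n_effect, dtype=int), np.zeros(n_neutral, dtype=int)])
    values = []
    for _ in range(n_replicates):
        predicted = rng.random(labels.shape[0]) < p_effect_background
        correct = int(np.sum(predicted == (labels == 1)))
        values.append(correct / labels.shape[0])
    arr = np.array(values)
    mean = float(arr.mean())
    sd = float(np.sqrt(np.mean((arr - mean) ** 2)))
    return BootstrapEstimate(mean=mean, sd=sd, se=sd / math.sqrt(n_replicates - 1),
                             n_sets=n_replicates, n_skipped=0, values=tuple(values))


EASY = "easy"
UNSOLVABLE = "unsolvable"
DIFFICULT = "difficult"


def triage_difficulty(per_method_predictions: Mapping[str, Mapping],
                      labels: Mapping, p_effect_background: float = 0.6) -> dict:
    """Partition variants into easy / unsolvable / difficult across methods.

    easy = all methods agree and are correct; unsolvable = all agree and are
    wrong; difficult = any disagreement.  Variants missing from any method are
    excluded with a logged count.  Reports each method's Q2 on the difficult
    subset plus the closed-form random baseline for the stated background.
    """
    methods = list(per_method_predictions)
    if len(methods) < 2:
        raise ValueError("triage requires at least two methods")
    partition = {EASY: [], UNSOLVABLE: [], DIFFICULT: []}
    excluded = 0
    for key, label in labels.items():
        calls = []
        missing = False
        for m in methods:
            call = per_method_predictions[m].get(key)
            if call is None:
                missing = True
                break
            calls.append(call)
        if missing:
            excluded += 1
            continue
        if all(c == calls[0] for c in calls):
            partition[EASY if calls[0] == label else UNSOLVABLE].append(key)
        else:
            partition[DIFFICULT].append(key)
    if excluded:
        logger.info("triage: excluded %d variants missing from some method", excluded)
    difficult = partition[DIFFICULT]
    per_method_q2 = {}
    for m in methods:
        if difficult:
            c = confusion_counts(
                (per_method_predictions[m][k], labels[k]) for k in difficult)
            per_method_q2[m] = q2(c)
        else:
            per_method_q2[m] = None
    n_eff = sum(1 for k in difficult if labels[k] == EFFECT)
    n_neu = len(difficult) - n_eff
    baseline = (random_baseline_q2(n_eff, n_neu, p_effect_background)
                if difficult else None)
    return {"partition": partition, "difficult_q2": per_method_q2,
            "random_baseline_q2": baseline, "n_excluded": excluded}
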