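"""Evaluation: accuracy, mean average precision, improvement statistics,
class-proportional subsampling, and the labeled-fraction ablation.

mAP here is the macro mean over classes of one-vs-rest average precision
with step interpolation (the area under each class's precision-recall
curve, averaged over all classes, unweighted).  Accuracy is the headline
metric because validation and test sets are class-balanced; mAP is kept
for comparability with the re-identification literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score

from ._seeds import derive_seed
from .errors import ArgumentError, UndefinedMetricError


@dataclass
class MetricReport:
    accuracy: float
    mAP: float
    per_class_ap: list[float]
    n_evaluated: int


@dataclass
class AblationRow:
    """One labeled-fraction condition, before vs after pseudo-labeling."""

    fraction: float
    baseline_train_size: int
    baseline_test_accuracy: float  # percent
    final_train_size: int
    final_test_accuracy: float  # percent
    pct_accuracy_increase: float  # relative, percent
    initial_pct_utilized: float
    final_pct_utilized: float


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Proportion of correctly classified images over the total."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ArgumentError("predicted and true label vectors differ in length")
    if predicted.size == 0:
        raise ArgumentError("cannot compute accuracy of an empty set")
    return float(np.mean(predicted == truth))


def mean_average_precision(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[float, list[float]]:
    """Macro mAP: mean over classes of one-vs-rest average precision.

    ``scores`` is an (n, K) matrix of per-class confidences; images are
    ranked by the class-c column, and AP_c is the step-interpolated area
    under the resulting precision-recall curve.  Every class must occur in
    ``truth`` at least once, otherwise its AP is undefined.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ArgumentError("scores must be an (n, K) matrix with K >= 2")
    if scores.shape[0] != truth.shape[0]:
        raise ArgumentError("scores and truth lengths differ")
    k = scores.shape[1]
    present = set(np.unique(truth).tolist())
    missing = [c for c in range(k) if c not in present]
    if missing:
        raise UndefinedMetricError(
            f"average precision undefined: class {missing[0]} absent from truth"
        )
    per_class = [
        float(average_precision_score((truth == c).astype(int), scores[:, c]))
        for c in range(k)
    ]
    return float(np.mean(per_class)), per_class


def metric_report(scores: np.ndarray, truth: np.ndarray) -> MetricReport:
    """Accuracy + mAP of an (n, K) score matrix against true labels."""
    preds = np.argmax(np.asarray(scores), axis=1)
    m, per_class = mean_average_precision(scores, truth)
    return MetricReport(
        accuracy=accuracy(preds, truth),
        mAP=m,
        per_class_ap=per_class,
        n_evaluated=len(truth),
    )


def improvement_stats(
    baseline_accuracy: float, final_accuracy: float
) -> tuple[float, float]:
    """(absolute percentage-point gain, relative percent gain) of an accuracy pair.

    Inputs are on the percent scale (e.g. 77.54); the relative gain is
    100 * (final - baseline) / baseline.
    """
    if baseline_accuracy <= 0:
        raise ArgumentError("baseline accuracy must be > 0")
    absolute = float(final_accuracy - baseline_accuracy)
    relative = float(100.0 * absolute / baseline_accuracy)
    return absolute, relative


def subsample_labeled(
    records: list[tuple[str, int]], fraction: float, seed: int = 0
) -> list[tuple[str, int]]:
    """Class-proportional subsample of labeled records.

    Per-class targets are floor(fraction * n_c) plus largest-remainder
    top-up so the global total equals round(fraction * N) exactly.  A class
    whose target would be zero keeps one image (with a warning) — every
    individual must stay representable.  Deterministic given ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ArgumentError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return list(records)
    by_class: dict[int, list[tuple[str, int]]] = {}
    for rec in records:
        by_class.setdefault(rec[1], []).append(rec)
    classes = sorted(by_class)
    counts = {c: len(by_class[c]) for c in classes}
    total_target = int(round(fraction * len(records)))
    floors = {c: int(np.floor(fraction * counts[c])) for c in classes}
    remainders = {c: fraction * counts[c] - floors[c] for c in classes}
    short = total_target - sum(floors.values())
    # ties in the remainder broken by class index for determinism
    for c in sorted(classes, key=lambda c: (-remainders[c], c))[: max(short, 0)]:
        floors[c] += 1
    empty = [c for c in classes if floors[c] == 0]
    if empty:
        warnings.warn(
            f"fraction {fraction} yields zero images for classes {empty}; "
            "keeping one image each",
            stacklevel=2,
        )
        for c in empty:
            floors[c] = 1
    rng = np.random.default_rng(seed)
    out: list[tuple[str, int]] = []
    for c in classes:
        recs = sorted(by_class[c])
        take = rng.choice(len(recs), size=min(floors[c], len(recs)), replace=False)
        out.extend(recs[i] for i in sorted(take))
    return out


def labeled_fraction_ablation(
    data,
    fractions=(0.10, 0.25, 0.50, 0.75, 0.90),
    n_rounds: int = 4,
    grid=None,
    spec=None,
    schedule=None,
    aug=None,
    master_seed: int = 0,
) -> list[AblationRow]:
    """Repeat the full pseudo-labeling run from reduced labeled pools.

    For each fraction the manually labeled training pool is subsampled
    class-proportionally, the baseline and ``n_rounds`` rounds are run,
    and the row records train sizes, test accuracies (percent), the
    relative accuracy gain, and the share of all training-side images
    (full labeled pool + unlabeled pool) utilized before and after.
    """
    from .pseudolabel import run_pseudo_labeling  # local: avoids an import cycle

    denom = len(data.labeled_pool) + len(data.unlabeled_ids)
    rows: list[AblationRow] = []
    for fraction in fractions:
        reduced = subsample_labeled(
            data.labeled_pool, fraction, seed=derive_seed(master_seed, "subsample", float(fraction))
        )
        result = run_pseudo_labeling(
            data.with_labeled_pool(reduced),
            n_rounds=n_rounds,
            grid=grid,
            spec=spec,
            schedule=schedule,
            aug=aug,
            master_seed=derive_seed(master_seed, "fraction", float(fraction)),
        )
        base, final = result.baseline, result.final
        base_acc = 100.0 * base.test_accuracy
        final_acc = 100.0 * final.test_accuracy
        base_size = base.n_manual
        final_size = final.n_manual + final.n_pseudo
        rel = improvement_stats(base_acc, final_acc)[1] if base_acc > 0 else float("nan")
        rows.append(
            AblationRow(
                fraction=float(fraction),
                baseline_train_size=base_size,
                baseline_test_accuracy=base_acc,
                final_train_size=final_size,
                final_test_accuracy=final_acc,
                pct_accuracy_increase=rel,
                initial_pct_utilized=100.0 * base_size / denom,
                final_pct_utilized=100.0 * final_size / denom,
            )
        )
    return rows


def utilization_percent(train_size: int, labeled_pool: int, unlabeled_pool: int) -> float:
    """Share (percent) of all training-side images present in a training set."""
    denom = labeled_pool + unlabeled_pool
    if denom <= 0:
        raise ArgumentError("pool sizes must be positive")
    return 100.0 * train_size / denom
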