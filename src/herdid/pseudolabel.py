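"""The pseudo-labeling engine.

One round = train on everything currently labeled, predict softmax
confidences on the remaining unlabeled pool, and for each candidate
threshold train a fresh classifier on labeled + previously promoted +
newly filtered records; the threshold whose model scores highest on the
validation set wins, its records are promoted (frozen — a pseudo-label
never changes and its snapshot leaves the unlabeled pool), and its model
carries into the next round.  Up to four rounds in the reference study;
the engine stops early if the winning threshold promotes nothing.

Filtering is strict (confidence > threshold), so threshold 0 admits every
prediction (softmax confidences are strictly positive) and threshold 1
admits none.  Ties in the sweep are broken toward the largest threshold:
fewer, higher-confidence pseudo-labels are the conservative choice
against label noise.

Training seeds are derived from the training-set contents, so two
thresholds that filter identical training sets provably train identical
models (the sweep caches those duplicates instead of retraining).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from ._seeds import derive_seed
from .classify import (
    AugmentationParams,
    ClassifierSpec,
    ConfidenceVector,
    TrainedClassifier,
    TrainingSchedule,
    predict_batch,
    predict_labels,
    train_two_stage,
)
from .data import ExperimentData
from .errors import ArgumentError
from .evaluate import accuracy

#: Candidate confidence thresholds of the reference study: 0 admits all
#: unlabeled data; the upper tail probes the extreme of the softmax scale.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = (
    0.0, 0.5, 0.75, 0.90, 0.95, 0.98, 0.99, 0.995,
    0.999, 0.9999, 0.99999, 0.999999, 0.9999999,
)


@dataclass(frozen=True)
class ThresholdGrid:
    values: tuple[float, ...] = DEFAULT_THRESHOLD_GRID

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise ArgumentError("threshold grid must be non-empty")
        if any(not 0 <= v < 1 for v in vals):
            raise ArgumentError("thresholds must lie in [0, 1)")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ArgumentError("thresholds must be strictly increasing")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class PseudoLabelRecord:
    """An unlabeled snapshot promoted into the training set."""

    snapshot_id: str
    assigned_label: int
    confidence: float
    round_assigned: int


@dataclass(frozen=True)
class SweepRow:
    threshold: float
    train_size: int
    n_new: int
    validation_accuracy: float


@dataclass
class RoundResult:
    round_index: int
    chosen_threshold: float | None
    n_manual: int
    n_pseudo: int
    validation_accuracy: float
    test_accuracy: float
    sweep: list[SweepRow] = field(default_factory=list)
    n_promoted: int = 0
    stopped_early: bool = False


@dataclass
class EngineState:
    """Pools partitioning the training-side snapshots, plus the current model."""

    labeled_pool: list[tuple[str, int]]
    pseudo_pool: list[PseudoLabelRecord]
    unlabeled_ids: list[str]
    model: TrainedClassifier | None = None
    history: list[RoundResult] = field(default_factory=list)

    def training_pairs(self) -> list[tuple[str, int]]:
        return list(self.labeled_pool) + [
            (r.snapshot_id, r.assigned_label) for r in self.pseudo_pool
        ]


def filter_confident(
    predictions: list[tuple[str, ConfidenceVector]],
    threshold: float,
    round_assigned: int = 1,
) -> list[PseudoLabelRecord]:
    """Keep exactly the predictions with confidence strictly above ``threshold``."""
    if not 0 <= threshold <= 1:
        raise ArgumentError("threshold must lie in [0, 1]")
    return [
        PseudoLabelRecord(
            snapshot_id=sid,
            assigned_label=cv.predicted_label,
            confidence=cv.confidence,
            round_assigned=round_assigned,
        )
        for sid, cv in predictions
        if cv.confidence > threshold
    ]


def _content_digest(pairs: list[tuple[str, int]]) -> str:
    token = "|".join(f"{sid}:{lab}" for sid, lab in sorted(pairs))
    return hashlib.sha256(token.encode()).hexdigest()[:16]


def _train_on_pairs(
    pairs: list[tuple[str, int]],
    data: ExperimentData,
    spec: ClassifierSpec,
    schedule: TrainingSchedule,
    aug: AugmentationParams | None,
    master_seed: int,
    cache: dict[str, TrainedClassifier] | None,
) -> TrainedClassifier:
    digest = _content_digest(pairs)
    if cache is not None and digest in cache:
        return cache[digest]
    seed = derive_seed(master_seed, "train", digest)
    images = data.images([sid for sid, _ in pairs])
    labels = np.array([lab for _, lab in pairs], dtype=int)
    model = train_two_stage(spec, images, labels, schedule.with_seed(seed), aug)
    if cache is not None:
        cache[digest] = model
    return model


def run_threshold_sweep(
    labeled_pool: list[tuple[str, int]],
    pseudo_pool: list[PseudoLabelRecord],
    unlabeled_predictions: list[tuple[str, ConfidenceVector]],
    grid: ThresholdGrid,
    data: ExperimentData,
    spec: ClassifierSpec,
    schedule: TrainingSchedule,
    aug: AugmentationParams | None = None,
    master_seed: int = 0,
    round_index: int = 1,
    cache: dict[str, TrainedClassifier] | None = None,
) -> tuple[list[SweepRow], dict[float, TrainedClassifier]]:
    """Train one model per threshold and score each on the validation set.

    Returns the sweep table plus the trained model per threshold.  Training
    sizes are weakly decreasing in the threshold (filtering is nested).
    """
    if not labeled_pool:
        raise ArgumentError("labeled pool must be non-empty")
    if cache is None:
        cache = {}
    frozen = [(r.snapshot_id, r.assigned_label) for r in pseudo_pool]
    val_images = data.images(data.val_ids)

    rows: list[SweepRow] = []
    models: dict[float, TrainedClassifier] = {}
    for t in grid.values:
        new_records = filter_confident(unlabeled_predictions, t, round_index)
        pairs = list(labeled_pool) + frozen + [
            (r.snapshot_id, r.assigned_label) for r in new_records
        ]
        model = _train_on_pairs(pairs, data, spec, schedule, aug, master_seed, cache)
        val_acc = accuracy(predict_labels(model, val_images), data.val_labels)
        rows.append(
            SweepRow(
                threshold=t,
                train_size=len(pairs),
                n_new=len(new_records),
                validation_accuracy=val_acc,
            )
        )
        models[t] = model
    return rows, models


def select_best_threshold(sweep: list[SweepRow]) -> float:
    """Argmax of validation accuracy; ties broken toward the largest threshold."""
    if not sweep:
        raise ArgumentError("sweep table must be non-empty")
    best = max(sweep, key=lambda r: (r.validation_accuracy, r.threshold))
    return best.threshold


def run_round(
    state: EngineState,
    grid: ThresholdGrid,
    data: ExperimentData,
    spec: ClassifierSpec,
    schedule: TrainingSchedule,
    aug: AugmentationParams | None = None,
    master_seed: int = 0,
    round_index: int = 1,
    cache: dict[str, TrainedClassifier] | None = None,
) -> tuple[EngineState, RoundResult]:
    """One full pseudo-labeling round starting from ``state.model``."""
    if state.model is None:
        raise ArgumentError("state has no trained model; run the baseline first")
    preds = list(
        zip(
            state.unlabeled_ids,
            predict_batch(state.model, data.images(state.unlabeled_ids)),
        )
    )
    sweep, models = run_threshold_sweep(
        state.labeled_pool, state.pseudo_pool, preds, grid, data, spec, schedule,
        aug=aug, master_seed=master_seed, round_index=round_index, cache=cache,
    )
    best = select_best_threshold(sweep)
    promoted = filter_confident(preds, best, round_index)
    promoted_ids = {r.snapshot_id for r in promoted}
    model = models[best]

    new_state = EngineState(
        labeled_pool=list(state.labeled_pool),
        pseudo_pool=list(state.pseudo_pool) + promoted,
        unlabeled_ids=[sid for sid in state.unlabeled_ids if sid not in promoted_ids],
        model=model,
        history=list(state.history),
    )
    test_acc = accuracy(
        predict_labels(model, data.images(data.test_ids)), data.test_labels
    )
    row = next(r for r in sweep if r.threshold == best)
    result = RoundResult(
        round_index=round_index,
        chosen_threshold=best,
        n_manual=len(state.labeled_pool),
        n_pseudo=len(new_state.pseudo_pool),
        validation_accuracy=row.validation_accuracy,
        test_accuracy=test_acc,
        sweep=sweep,
        n_promoted=len(promoted),
        stopped_early=len(promoted) == 0,
    )
    new_state.history.append(result)
    return new_state, result


@dataclass
class PseudoLabelingResult:
    history: list[RoundResult]
    final_model: TrainedClassifier
    state: EngineState

    @property
    def baseline(self) -> RoundResult:
        return self.history[0]

    @property
    def final(self) -> RoundResult:
        return self.history[-1]


def run_pseudo_labeling(
    data: ExperimentData,
    n_rounds: int = 4,
    grid: ThresholdGrid | None = None,
    spec: ClassifierSpec | None = None,
    schedule: TrainingSchedule | None = None,
    aug: AugmentationParams | None = None,
    master_seed: int = 0,
) -> PseudoLabelingResult:
    """Baseline (round 0, manual labels only) plus up to ``n_rounds`` rounds.

    Deterministic given ``master_seed`` with the reference backbone (and
    with the CNN backbone under a fixed BLAS).  Stops early when the
    winning threshold promotes no new images.
    """
    if n_rounds < 0:
        raise ArgumentError("n_rounds must be >= 0")
    grid = grid or ThresholdGrid()
    spec = spec or ClassifierSpec(n_classes=data.n_classes)
    schedule = schedule or TrainingSchedule()
    if spec.n_classes != data.n_classes:
        spec = replace(spec, n_classes=data.n_classes)

    cache: dict[str, TrainedClassifier] = {}
    baseline_model = _train_on_pairs(
        list(data.labeled_pool), data, spec, schedule, aug, master_seed, cache
    )
    val_acc = accuracy(
        predict_labels(baseline_model, data.images(data.val_ids)), data.val_labels
    )
    test_acc = accuracy(
        predict_labels(baseline_model, data.images(data.test_ids)), data.test_labels
    )
    state = EngineState(
        labeled_pool=list(data.labeled_pool),
        pseudo_pool=[],
        unlabeled_ids=list(data.unlabeled_ids),
        model=baseline_model,
        history=[
            RoundResult(
                round_index=0,
                chosen_threshold=None,
                n_manual=len(data.labeled_pool),
                n_pseudo=0,
                validation_accuracy=val_acc,
                test_accuracy=test_acc,
            )
        ],
    )
    for rnd in range(1, int(n_rounds) + 1):
        state, result = run_round(
            state, grid, data, spec, schedule,
            aug=aug, master_seed=master_seed, round_index=rnd, cache=cache,
        )
        if result.stopped_early:
            break
    return PseudoLabelingResult(
        history=state.history, final_model=state.model, state=state
    )


def pseudo_label_precision(
    records: list[PseudoLabelRecord], true_labels: dict[str, int]
) -> float:
    """Fraction of promoted records whose assigned label matches the hidden truth."""
    if not records:
        raise ArgumentError("no records to score")
    hits = sum(1 for r in records if true_labels.get(r.snapshot_id) == r.assigned_label)
    return hits / len(records)
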