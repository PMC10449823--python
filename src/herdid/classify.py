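"""Probabilistic classifier contract: softmax confidences, augmentation,
and the two-stage (feature-extraction then fine-tuning) training schedule.

Identification is closed-set: one softmax unit per animal, and the
maximum output is the prediction's confidence — the quantity the
pseudo-labeling engine thresholds on.  Two backbones are provided behind
a common interface (``initialize`` / ``set_trainable_scope`` / ``fit`` /
``logits``): a small numpy CNN, and a deterministic nearest-centroid
reference classifier whose logits are negative mean-squared distances to
class centroids scaled by a temperature, used where tests need exactly
reproducible engine behaviour with no gradient noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seeds import derive_seed
from .errors import ArgumentError, DataError
from .smallcnn import SmallCNN

BACKBONES = ("small-cnn", "nearest-centroid-reference")


# ---------------------------------------------------------------------------
# softmax and confidences


@dataclass(frozen=True)
class ConfidenceVector:
    """Softmax output over the K identities for one image."""

    p: np.ndarray
    predicted_label: int
    confidence: float

    @property
    def k(self) -> int:
        return len(self.p)


def softmax(z: Sequence[float] | np.ndarray) -> ConfidenceVector:
    """Normalize logits into class probabilities, sigma(z)_i = e^{z_i} / sum_j e^{z_j}.

    Shift-by-max keeps the computation stable for large-magnitude logits;
    the result is invariant to adding a constant to every logit.
    """
    p = softmax_matrix(np.asarray(z, dtype=float)[None, :])[0]
    label = int(np.argmax(p))
    return ConfidenceVector(p=p, predicted_label=label, confidence=float(p[label]))


def softmax_matrix(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax of an (n, K) logit matrix."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[1] < 1:
        raise ArgumentError("expected an (n, K) logit matrix with K >= 1")
    if not np.all(np.isfinite(z)):
        raise ArgumentError("logits must be finite")
    zs = z - z.max(axis=1, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentationParams:
    """On-the-fly training augmentation (never applied at prediction time).

    Defaults: zoom in/out by up to 10%, brightness scaled to 20-150% of
    the original, 50% chance of horizontal and of vertical flip, nearest
    (edge-clamp) fill for pixels exposed by zooming out.
    """

    zoom_range: float = 0.1
    brightness_range: tuple[float, float] = (0.2, 1.5)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    fill_mode: str = "nearest"

    def __post_init__(self) -> None:
        if not 0 <= self.zoom_range < 1:
            raise ArgumentError("zoom_range must be in [0, 1)")
        lo, hi = self.brightness_range
        if not 0 < lo <= hi:
            raise ArgumentError("brightness_range must satisfy 0 < low <= high")
        if self.fill_mode != "nearest":
            raise ArgumentError("only fill_mode='nearest' is supported")


@dataclass(frozen=True)
class AugmentationDraw:
    zoom: float
    brightness: float
    hflip: bool
    vflip: bool


def draw_augmentation(params: AugmentationParams, rng: np.random.Generator) -> AugmentationDraw:
    """Sample one realization of the augmentation parameters."""
    return AugmentationDraw(
        zoom=float(rng.uniform(1 - params.zoom_range, 1 + params.zoom_range)),
        brightness=float(rng.uniform(*params.brightness_range)),
        hflip=bool(params.horizontal_flip and rng.random() < 0.5),
        vflip=bool(params.vertical_flip and rng.random() < 0.5),
    )


def augment(image: np.ndarray, params: AugmentationParams, rng_seed: int) -> np.ndarray:
    """Randomly zoom, brightness-scale and flip one image; deterministic per seed."""
    image = np.asarray(image)
    out = augment_batch(image[None].astype(float), params, np.random.default_rng(rng_seed))[0]
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return out.astype(image.dtype)


def augment_batch(
    batch: np.ndarray, params: AugmentationParams, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized per-image augmentation of an (n, h, w) float batch.

    Zoom is about the image centre with nearest-neighbour sampling and
    edge-clamp fill; intensities are clipped to the image's value scale
    ([0, 1] for float batches) after brightness scaling, matching 8-bit
    sensor saturation.
    """
    batch = np.asarray(batch, dtype=float)
    n, h, w = batch.shape
    if n == 0:
        return batch
    zooms = rng.uniform(1 - params.zoom_range, 1 + params.zoom_range, size=n)
    brightness = rng.uniform(*params.brightness_range, size=n)
    hflips = (rng.random(n) < 0.5) if params.horizontal_flip else np.zeros(n, bool)
    vflips = (rng.random(n) < 0.5) if params.vertical_flip else np.zeros(n, bool)

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rr = np.arange(h)[None, :]  # (1, h)
    cc = np.arange(w)[None, :]
    src_r = np.clip(np.rint(cy + (rr - cy) / zooms[:, None]), 0, h - 1).astype(int)
    src_c = np.clip(np.rint(cx + (cc - cx) / zooms[:, None]), 0, w - 1).astype(int)
    src_r = np.where(vflips[:, None], src_r[:, ::-1], src_r)
    src_c = np.where(hflips[:, None], src_c[:, ::-1], src_c)
    out = batch[np.arange(n)[:, None, None], src_r[:, :, None], src_c[:, None, :]]
    out *= brightness[:, None, None]
    limit = 255.0 if batch.max() > 1.5 else 1.0
    return np.clip(out, 0.0, limit)


# ---------------------------------------------------------------------------
# training schedule and classifier spec


@dataclass(frozen=True)
class TrainingSchedule:
    """Two-stage schedule: head-only feature extraction, then fine-tuning.

    The defaults suit a randomly initialized backbone: a short head-only
    warm-up, then full training at the same rate.  Dropping the stage-2
    rate by ~100x (1e-3 -> 1e-5) is the right regime only when stage 2
    merely adjusts pretrained features; with no pretraining, stage 2 *is*
    the main fit and needs a full-strength rate.
    """

    stage1_epochs: int = 10
    stage2_epochs: int = 60
    stage1_lr: float = 2e-3
    stage2_lr: float = 2e-3
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage1_epochs < 0 or self.stage2_epochs < 0:
            raise ArgumentError("epoch counts must be >= 0")
        if self.stage1_lr <= 0 or self.stage2_lr <= 0:
            raise ArgumentError("learning rates must be > 0")

    def with_seed(self, seed: int) -> "TrainingSchedule":
        return TrainingSchedule(
            self.stage1_epochs, self.stage2_epochs, self.stage1_lr,
            self.stage2_lr, self.optimizer, int(seed),
        )


@dataclass(frozen=True)
class ClassifierSpec:
    """Which backbone to build, at what input geometry, for how many classes."""

    backbone: str = "small-cnn"
    input_hw: tuple[int, int] = (16, 32)
    n_classes: int = 2
    centroid_temperature: float = 100.0  # reference backbone logit scale

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ArgumentError(
                f"unknown backbone '{self.backbone}'; expected one of {BACKBONES}"
            )
        if self.n_classes < 1:
            raise ArgumentError("n_classes must be >= 1")


class NearestCentroidBackbone:
    """Deterministic reference classifier: logits = -tau * MSE to class centroids.

    Exists so engine tests are exactly reproducible without gradient
    noise: fitting just computes per-class mean images (augmentation and
    epoch counts are irrelevant to the fit and ignored), and both training
    stages are degenerate, so the two-stage contract holds trivially.
    """

    def __init__(self, input_hw: tuple[int, int], n_classes: int, temperature: float = 100.0):
        self.input_hw = tuple(input_hw)
        self.n_classes = int(n_classes)
        self.temperature = float(temperature)
        self.centroids: np.ndarray | None = None

    def initialize(self, seed: int) -> None:  # noqa: ARG002 - deterministic
        self.centroids = np.zeros((self.n_classes,) + self.input_hw)

    def set_trainable_scope(self, scope: str) -> None:
        if scope not in ("head", "all"):
            raise ArgumentError("scope must be 'head' or 'all'")

    def fit(self, x: np.ndarray, y: np.ndarray) -> None:
        cents = np.zeros((self.n_classes,) + self.input_hw)
        for c in range(self.n_classes):
            sel = y == c
            if sel.any():
                cents[c] = x[sel].mean(axis=0)
        self.centroids = cents

    def logits(self, x: np.ndarray) -> np.ndarray:
        if self.centroids is None:
            raise ArgumentError("backbone not initialized")
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.input_hw:
            raise ArgumentError(
                f"input geometry {x.shape[1:]} does not match model {self.input_hw}"
            )
        flat = x.reshape(len(x), -1)
        cf = self.centroids.reshape(self.n_classes, -1)
        d2 = ((flat[:, None, :] - cf[None, :, :]) ** 2).mean(axis=2)
        return -self.temperature * d2


def build_backbone(spec: ClassifierSpec):
    if spec.backbone == "small-cnn":
        return SmallCNN(input_hw=spec.input_hw, n_classes=spec.n_classes)
    return NearestCentroidBackbone(
        spec.input_hw, spec.n_classes, temperature=spec.centroid_temperature
    )


# ---------------------------------------------------------------------------
# training and prediction


@dataclass
class TrainedClassifier:
    """A frozen trained model plus the provenance needed to reproduce it."""

    spec: ClassifierSpec
    schedule: TrainingSchedule
    backbone: object = field(repr=False, default=None)

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        return self.backbone.logits(images)


def _validate_train_set(images: np.ndarray, labels: np.ndarray, k: int) -> None:
    if len(images) == 0:
        raise ArgumentError("training set must be non-empty")
    if len(images) != len(labels):
        raise ArgumentError("images and labels lengths differ")
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= k:
        bad = labels[(labels < 0) | (labels >= k)][0]
        raise DataError(f"label {bad} outside [0, {k})")


def train_two_stage(
    spec: ClassifierSpec,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    schedule: TrainingSchedule,
    aug: AugmentationParams | None = None,
) -> TrainedClassifier:
    """Feature-extraction (head-only) then fine-tuning (all layers).

    Stage 1 trains only the two FC head layers at ``stage1_lr``; stage 2
    unfreezes all earlier layers and continues at ``stage2_lr``.  A fresh
    backbone is initialized from ``schedule.seed`` every call (no warm
    starts), and the result is deterministic for a fixed seed.
    """
    labels = np.asarray(train_labels, dtype=int)
    images = np.asarray(train_images, dtype=float)
    _validate_train_set(images, labels, spec.n_classes)

    backbone = build_backbone(spec)
    backbone.initialize(schedule.seed)
    if isinstance(backbone, NearestCentroidBackbone):
        backbone.fit(images, labels)
        return TrainedClassifier(spec=spec, schedule=schedule, backbone=backbone)

    rng = np.random.default_rng(derive_seed(schedule.seed, "fit"))
    augment_fn = None
    if aug is not None:
        augment_fn = lambda xb, r: augment_batch(xb, aug, r)  # noqa: E731
    backbone.set_trainable_scope("head")
    backbone.fit_epochs(images, labels, schedule.stage1_epochs, schedule.stage1_lr, rng, augment_fn)
    backbone.set_trainable_scope("all")
    backbone.fit_epochs(images, labels, schedule.stage2_epochs, schedule.stage2_lr, rng, augment_fn)
    return TrainedClassifier(spec=spec, schedule=schedule, backbone=backbone)


def predict_batch(classifier: TrainedClassifier, images: np.ndarray) -> list[ConfidenceVector]:
    """One ConfidenceVector per image, in input order; no augmentation."""
    images = np.asarray(images, dtype=float)
    if len(images) == 0:
        return []
    probs = softmax_matrix(classifier.predict_logits(images))
    out = []
    for row in probs:
        label = int(np.argmax(row))
        out.append(ConfidenceVector(p=row, predicted_label=label, confidence=float(row[label])))
    return out


def predict_labels(classifier: TrainedClassifier, images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    if len(images) == 0:
        return np.zeros(0, dtype=int)
    return np.argmax(classifier.predict_logits(images), axis=1)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: TrainedClassifier, path: str | Path) -> None:
    """Single-file checkpoint: spec + schedule + weights (npz)."""
    path = Path(path)
    header = json.dumps({"spec": asdict(model.spec), "schedule": asdict(model.schedule)})
    arrays: dict[str, np.ndarray] = {}
    bb = model.backbone
    if isinstance(bb, SmallCNN):
        arrays = {f"param_{k}": v for k, v in bb.params.items()}
    elif isinstance(bb, NearestCentroidBackbone):
        arrays = {"centroids": bb.centroids}
    np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> TrainedClassifier:
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["header"]).decode())
        spec_d = header["spec"]
        spec_d["input_hw"] = tuple(spec_d["input_hw"])
        sched_d = header["schedule"]
        sched_d["stage1_lr"] = float(sched_d["stage1_lr"])
        spec = ClassifierSpec(**spec_d)
        schedule = TrainingSchedule(**sched_d)
        backbone = build_backbone(spec)
        backbone.initialize(schedule.seed)
        if isinstance(backbone, SmallCNN):
            for k in backbone.params:
                backbone.params[k] = data[f"param_{k}"]
        else:
            backbone.centroids = data["centroids"]
    return TrainedClassifier(spec=spec, schedule=schedule, backbone=backbone)
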