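"""Bridging layer: turn a dataset (manifest + snapshots) into model-ready pools.

Applies the preprocessing chain (mask -> crop + rotate -> resize to the
classifier input geometry, scaled to [0, 1]) to every snapshot once, and
partitions snapshot ids into the four experiment pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

from .errors import ConfigurationError
from .preprocess import apply_mask, crop_rotate
from .synth import SyntheticDataset


@dataclass
class ExperimentData:
    """Preprocessed images plus the labeled/unlabeled/val/test structure."""

    store: dict[str, np.ndarray]  # snapshot_id -> float32 (h, w) in [0, 1]
    labeled_pool: list[tuple[str, int]]  # manually labeled training records
    unlabeled_ids: list[str]
    val_ids: list[str]
    val_labels: np.ndarray
    test_ids: list[str]
    test_labels: np.ndarray
    n_classes: int
    true_labels: dict[str, int] = field(default_factory=dict)  # hidden ledger

    def images(self, ids) -> np.ndarray:
        return np.stack([self.store[i] for i in ids]) if len(ids) else np.zeros((0, 1, 1))

    def with_labeled_pool(self, pool: list[tuple[str, int]]) -> "ExperimentData":
        return replace(self, labeled_pool=list(pool))


def preprocess_snapshot(
    snapshot, input_hw: tuple[int, int] = (16, 32), padding: int = 2
) -> np.ndarray:
    """Mask, crop + rotate horizontal, resize to the model geometry, [0, 1]."""
    mask = snapshot.mask
    if mask is None:
        mask = (snapshot.depth < 0.9 * snapshot.depth.max()).astype(np.uint8)
    masked = apply_mask(snapshot.infrared, mask)
    proc = crop_rotate(masked, mask, padding=padding, source_snapshot_id=snapshot.snapshot_id)
    img = resize(proc.image.astype(float) / 255.0, input_hw, anti_aliasing=True)
    return img.astype(np.float32)


def prepare_experiment(
    dataset: SyntheticDataset,
    input_hw: tuple[int, int] = (16, 32),
    padding: int = 2,
) -> ExperimentData:
    """Preprocess every snapshot and assemble the experiment pools."""
    present = set(dataset.manifest["split"])
    for split in ("train", "validation", "test", "unlabeled"):
        if split not in present:
            raise ConfigurationError(f"manifest is missing the '{split}' split")

    store = {
        sid: preprocess_snapshot(snap, input_hw=input_hw, padding=padding)
        for sid, snap in dataset.snapshots.items()
    }
    train_ids = dataset.split_ids("train")
    val_ids = dataset.split_ids("validation")
    test_ids = dataset.split_ids("test")
    labels = dataset.manifest.set_index("snapshot_id")["label"]
    labeled_pool = [(sid, int(labels[sid])) for sid in train_ids]
    k = int(max(int(labels[sid]) for sid in train_ids + val_ids + test_ids)) + 1
    return ExperimentData(
        store=store,
        labeled_pool=labeled_pool,
        unlabeled_ids=dataset.split_ids("unlabeled"),
        val_ids=val_ids,
        val_labels=dataset.labels_for(val_ids),
        test_ids=test_ids,
        test_labels=dataset.labels_for(test_ids),
        n_classes=k,
        true_labels=dataset.true_labels(),
    )
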