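"""Synthetic herd and capture-session generator.

Emulates a top-down infrared + depth camera mounted above a milking-parlor
exit lane: each individual has a fixed black/white coat pattern painted on
an elongated (elliptical) body, and walks under the camera with a random
heading, zoom (height above ground), lateral offset and brightness.  Depth
maps are in millimetres with the empty-lane background exactly at the
camera mounting height.  Capture sessions span multiple days with
day-disjoint train/validation/test/unlabeled splits, class-balanced
validation and test sets, and a hidden ground-truth ledger for the
unlabeled split so pseudo-label quality is scoreable.

Everything is deterministic given the master seed: per-snapshot seeds are
derived from (master_seed, individual, day, index), so any manifest can be
re-rendered bit-exactly from its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from ._seeds import derive_seed
from .errors import ArgumentError, ConfigurationError, RenderError

SPLITS = ("train", "validation", "test", "unlabeled")

# Infrared reflectance levels for the two coat colours (8-bit scale).
_LIGHT_COAT = 190.0
_DARK_COAT = 70.0
# Peak height of the body above the lane floor used for the depth dome, mm.
_BODY_RELIEF_MM = 150.0

_PATTERN_SHAPE = (48, 96)  # body-local (across, along) pattern grid


@dataclass(frozen=True)
class CoatTemplate:
    """A fixed per-individual coat pattern on an elongated body.

    ``pattern`` is a binary grid in body-local coordinates (rows across the
    body, columns along it); 1 marks dark coat. The pattern never changes
    between renders of the same individual — it is the identity signal.
    """

    individual_id: int
    pattern: np.ndarray
    body_aspect: float

    def __post_init__(self) -> None:
        if self.individual_id < 0:
            raise ArgumentError("individual_id must be >= 0")
        if self.body_aspect <= 1.0:
            raise ArgumentError("body_aspect must be > 1 (elongated body)")


@dataclass(frozen=True)
class CaptureConfig:
    """Geometry and noise levels of the simulated capture rig.

    Defaults are desk-scale: 96x128 frames instead of the rig's 640x480,
    camera at 3500 mm, cow surface around 2000 mm from the camera (well
    under a 3000 mm presence threshold).
    """

    n_individuals: int = 15
    image_height: int = 96
    image_width: int = 128
    camera_height_mm: float = 3500.0
    cow_depth_mm: float = 2000.0
    days: tuple[int, ...] = tuple(range(8))
    snapshots_per_day_per_individual: int = 2
    angle_jitter_deg: float = 30.0
    zoom_jitter: float = 0.08
    brightness_jitter: tuple[float, float] = (0.85, 1.15)
    offset_jitter_px: float = 8.0
    pixel_noise_std: float = 8.0
    depth_noise_std_mm: float = 20.0
    day_illumination_range: tuple[float, float] = (0.8, 1.2)
    pattern_complexity: int = 6
    body_length_px: float = 88.0
    body_aspect: float = 2.2
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ArgumentError("n_individuals must be >= 0")
        if self.cow_depth_mm >= self.camera_height_mm:
            raise ArgumentError("cow_depth_mm must be < camera_height_mm")
        if self.snapshots_per_day_per_individual < 0:
            raise ArgumentError("snapshot counts must be non-negative")
        if min(self.image_height, self.image_width) < 16:
            raise ArgumentError("frame must be at least 16x16 pixels")


@dataclass(frozen=True)
class Pose:
    """One realization of how a body sits in the frame."""

    angle_deg: float = 0.0
    zoom: float = 1.0
    brightness: float = 1.0
    offset: tuple[float, float] = (0.0, 0.0)  # (row, col) pixels


@dataclass
class Snapshot:
    """One capture event: infrared + depth (+ mask, + optional identity)."""

    snapshot_id: str
    infrared: np.ndarray  # uint8, 0-255
    depth: np.ndarray  # uint16, millimetres
    mask: np.ndarray | None  # uint8 {0,1}, 1 = body
    capture_day: int
    identity: int | None


@dataclass(frozen=True)
class SplitPlan:
    """Day-disjoint split design with per-split image budgets.

    ``val_total``/``test_total`` are split across individuals equally (the
    validation and test sets are class-balanced); an indivisible budget is
    a configuration error.  ``n_unlabeled`` is spread as evenly as possible
    over (individual, day) cells and the identities are withheld from the
    manifest but kept in the hidden ledger.
    """

    train_days: tuple[int, ...] = (0, 1)
    val_days: tuple[int, ...] = (2, 3)
    unlabeled_days: tuple[int, ...] = (4, 5)
    test_days: tuple[int, ...] = (6, 7)
    train_per_individual: int = 2
    val_total: int = 60
    test_total: int = 60
    n_unlabeled: int = 400

    def day_sets(self) -> dict[str, tuple[int, ...]]:
        return {
            "train": self.train_days,
            "validation": self.val_days,
            "test": self.test_days,
            "unlabeled": self.unlabeled_days,
        }

    def validate(self, config: CaptureConfig) -> None:
        sets = self.day_sets()
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                shared = set(sets[a]) & set(sets[b])
                if shared:
                    raise ConfigurationError(
                        f"splits '{a}' and '{b}' share capture days {sorted(shared)}"
                    )
        k = config.n_individuals
        if k > 0:
            for label, total in (("val_total", self.val_total), ("test_total", self.test_total)):
                if total % k != 0:
                    raise ConfigurationError(
                        f"{label}={total} is not divisible by {k} individuals; "
                        "validation and test sets must be class-balanced"
                    )


@dataclass
class SyntheticDataset:
    """A generated study: manifest + in-memory snapshots + hidden ledger."""

    manifest: pd.DataFrame
    snapshots: dict[str, Snapshot]
    ledger: pd.DataFrame  # snapshot_id, true_label — covers every unlabeled snapshot
    config: CaptureConfig
    plan: SplitPlan
    templates: list[CoatTemplate] = field(default_factory=list)

    def split_ids(self, split: str) -> list[str]:
        if split not in SPLITS:
            raise ArgumentError(f"unknown split '{split}'")
        return list(self.manifest.loc[self.manifest["split"] == split, "snapshot_id"])

    def labels_for(self, ids: Sequence[str]) -> np.ndarray:
        lab = self.manifest.set_index("snapshot_id")["label"]
        return np.array([int(lab[i]) for i in ids])

    def true_labels(self) -> dict[str, int]:
        """Hidden ground truth for the unlabeled split (scoring only)."""
        return {r.snapshot_id: int(r.true_label) for r in self.ledger.itertuples()}


# ---------------------------------------------------------------------------
# coat templates


def generate_coat_templates(
    n_individuals: int,
    pattern_complexity: int = 6,
    seed: int = 0,
    body_aspect: float = 2.2,
) -> list[CoatTemplate]:
    """Draw ``n_individuals`` distinguishable coat patterns.

    Each pattern is the union of ``pattern_complexity`` random smooth blobs
    thresholded to a random dark fraction, masked to the body ellipse —
    mimicking Holstein patch statistics without modelling anatomy.  Any
    template whose dark-patch IoU with an earlier one exceeds 0.85 is
    redrawn, so templates are pairwise distinguishable by construction.
    """
    if n_individuals < 0:
        raise ArgumentError("n_individuals must be >= 0")
    if pattern_complexity < 1:
        raise ArgumentError("pattern_complexity must be >= 1")

    templates: list[CoatTemplate] = []
    for ind in range(int(n_individuals)):
        attempt = 0
        while True:
            pat = _draw_pattern(
                derive_seed(seed, "coat", ind, attempt), pattern_complexity
            )
            if all(_pattern_iou(pat, t.pattern) <= 0.85 for t in templates):
                break
            attempt += 1
        templates.append(
            CoatTemplate(individual_id=ind, pattern=pat, body_aspect=body_aspect)
        )
    return templates


def _body_ellipse(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    v, u = np.mgrid[0:h, 0:w]
    vv = (v - (h - 1) / 2) / (h / 2)
    uu = (u - (w - 1) / 2) / (w / 2)
    return vv**2 + uu**2 <= 1.0


def _draw_pattern(seed: int, complexity: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    h, w = _PATTERN_SHAPE
    v, u = np.mgrid[0:h, 0:w]
    fld = np.zeros((h, w), dtype=float)
    for _ in range(complexity):
        cv = rng.uniform(0.1 * h, 0.9 * h)
        cu = rng.uniform(0.1 * w, 0.9 * w)
        sv = rng.uniform(0.08, 0.25) * h
        su = rng.uniform(0.08, 0.25) * w
        fld += np.exp(-0.5 * (((v - cv) / sv) ** 2 + ((u - cu) / su) ** 2))
    dark_frac = rng.uniform(0.30, 0.55)
    thr = np.quantile(fld, 1.0 - dark_frac)
    return ((fld >= thr) & _body_ellipse((h, w))).astype(np.uint8)


def _pattern_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = int(np.logical_and(a, b).sum())
    union = int(np.logical_or(a, b).sum())
    return inter / union if union else 1.0


# ---------------------------------------------------------------------------
# rendering


def render_snapshot(
    template: CoatTemplate,
    pose: Pose,
    config: CaptureConfig,
    seed: int = 0,
    snapshot_id: str = "snap",
    capture_day: int = 0,
    identity: int | None = None,
    day_illumination: float = 1.0,
) -> Snapshot:
    """Render one capture of ``template`` under ``pose``.

    The body is an ellipse of half-length ``zoom * body_length_px / 2``
    rotated by ``angle_deg`` (counter-clockwise positive) about the frame
    centre plus ``offset``; the coat pattern is sampled nearest-neighbour
    in body-local coordinates.  Background depth is exactly
    ``camera_height_mm``; body depth is ``cow_depth_mm`` minus a smooth
    dome (the back rises toward the spine) plus clipped Gaussian jitter.
    """
    h, w = config.image_height, config.image_width
    a = 0.5 * config.body_length_px * pose.zoom  # half-length, px
    b = a / template.body_aspect  # half-width, px

    cy = (h - 1) / 2 + pose.offset[0]
    cx = (w - 1) / 2 + pose.offset[1]
    theta = np.deg2rad(pose.angle_deg)
    # frame-axis extents of the rotated ellipse
    ext_x = np.hypot(a * np.cos(theta), b * np.sin(theta))
    ext_y = np.hypot(a * np.sin(theta), b * np.cos(theta))
    if cx - ext_x < 0 or cx + ext_x > w - 1 or cy - ext_y < 0 or cy + ext_y > h - 1:
        raise RenderError(
            f"body exceeds the {h}x{w} frame under pose "
            f"(angle={pose.angle_deg:.1f} deg, zoom={pose.zoom:.3f}, "
            f"offset={pose.offset})"
        )

    rows, cols = np.mgrid[0:h, 0:w]
    x = cols - cx
    y = -(rows - cy)  # math convention: y up, angles CCW positive
    uu = (x * np.cos(theta) + y * np.sin(theta)) / a  # along-body, [-1, 1]
    vv = (-x * np.sin(theta) + y * np.cos(theta)) / b  # across-body
    inside = uu**2 + vv**2 <= 1.0

    ph, pw = template.pattern.shape
    pi = np.clip(np.rint((vv + 1) / 2 * (ph - 1)), 0, ph - 1).astype(int)
    pj = np.clip(np.rint((uu + 1) / 2 * (pw - 1)), 0, pw - 1).astype(int)
    dark = template.pattern[pi, pj].astype(bool) & inside

    rng = np.random.default_rng(seed)
    coat = np.where(dark, _DARK_COAT, _LIGHT_COAT)
    gain = pose.brightness * day_illumination
    infrared = np.where(inside, coat * gain, 0.0)
    infrared = infrared + rng.normal(0.0, config.pixel_noise_std, size=(h, w))
    infrared = np.clip(infrared, 0, 255).astype(np.uint8)

    dome = np.sqrt(np.clip(1.0 - uu**2 - vv**2, 0.0, None))
    depth = np.full((h, w), config.camera_height_mm, dtype=float)
    body_depth = (
        config.cow_depth_mm
        - _BODY_RELIEF_MM * dome[inside]
        + rng.normal(0.0, config.depth_noise_std_mm, size=int(inside.sum()))
    )
    depth[inside] = np.clip(body_depth, 1.0, config.camera_height_mm)
    depth = np.rint(depth).astype(np.uint16)

    return Snapshot(
        snapshot_id=snapshot_id,
        infrared=infrared,
        depth=depth,
        mask=inside.astype(np.uint8),
        capture_day=capture_day,
        identity=identity,
    )


def _sample_pose(rng: np.random.Generator, config: CaptureConfig) -> Pose:
    heading = 180.0 if rng.random() < 0.5 else 0.0  # cows walk either way
    angle = heading + rng.uniform(-config.angle_jitter_deg, config.angle_jitter_deg)
    if angle > 180.0:
        angle -= 360.0
    zoom = 1.0 + rng.uniform(-config.zoom_jitter, config.zoom_jitter)
    brightness = rng.uniform(*config.brightness_jitter)
    off = rng.uniform(-config.offset_jitter_px, config.offset_jitter_px, size=2)
    return Pose(angle_deg=angle, zoom=zoom, brightness=brightness, offset=(off[0], off[1]))


# ---------------------------------------------------------------------------
# study generation


def _allocate(total: int, cells: int) -> list[int]:
    """Spread ``total`` items over ``cells`` as evenly as possible."""
    base, extra = divmod(total, cells)
    return [base + (1 if i < extra else 0) for i in range(cells)]


def generate_study(config: CaptureConfig, plan: SplitPlan | None = None) -> SyntheticDataset:
    """Generate a full multi-day study with day-disjoint splits.

    Every snapshot's split is determined solely by its capture day;
    validation/test budgets are split equally per individual.  Unlabeled
    snapshots carry no label in the manifest but are fully covered by the
    hidden ground-truth ledger.  Deterministic given ``config.master_seed``.
    """
    plan = plan or SplitPlan()
    plan.validate(config)
    k = config.n_individuals
    templates = generate_coat_templates(
        k,
        pattern_complexity=config.pattern_complexity,
        seed=derive_seed(config.master_seed, "templates"),
        body_aspect=config.body_aspect,
    )

    day_sets = plan.day_sets()
    per_ind_budget = {
        "train": plan.train_per_individual,
        "validation": plan.val_total // k if k else 0,
        "test": plan.test_total // k if k else 0,
    }

    day_gain: dict[int, float] = {}
    for day in config.days:
        lo, hi = config.day_illumination_range
        day_gain[day] = float(
            np.random.default_rng(derive_seed(config.master_seed, "day", day)).uniform(lo, hi)
        )

    rows = []
    snapshots: dict[str, Snapshot] = {}
    ledger_rows = []

    def _render(ind: int, day: int, idx: int, split: str) -> None:
        sid = f"d{day:03d}_i{ind:03d}_{idx:03d}"
        seed = derive_seed(config.master_seed, "snap", ind, day, idx)
        pose = _sample_pose(np.random.default_rng(seed), config)
        snap = render_snapshot(
            templates[ind],
            pose,
            config,
            seed=derive_seed(seed, "pixels"),
            snapshot_id=sid,
            capture_day=day,
            identity=ind,
            day_illumination=day_gain.get(day, 1.0),
        )
        unlabeled = split == "unlabeled"
        rows.append(
            {
                "snapshot_id": sid,
                "infrared_path": "",
                "depth_path": "",
                "mask_path": "",
                "capture_day": day,
                "split": split,
                "label": "" if unlabeled else ind,
            }
        )
        if unlabeled:
            snap.identity = None
            ledger_rows.append({"snapshot_id": sid, "true_label": ind})
        snapshots[sid] = snap

    for split in ("train", "validation", "test"):
        days = day_sets[split]
        if not days:
            continue
        for ind in range(k):
            counts = _allocate(per_ind_budget[split], len(days))
            for day, n in zip(days, counts):
                for idx in range(n):
                    _render(ind, day, idx, split)

    udays = day_sets["unlabeled"]
    if udays and k:
        cells = [(ind, day) for ind in range(k) for day in udays]
        for (ind, day), n in zip(cells, _allocate(plan.n_unlabeled, len(cells))):
            for idx in range(n):
                _render(ind, day, idx, "unlabeled")

    manifest = pd.DataFrame(
        rows,
        columns=[
            "snapshot_id",
            "infrared_path",
            "depth_path",
            "mask_path",
            "capture_day",
            "split",
            "label",
        ],
    ).sort_values("snapshot_id", kind="stable").reset_index(drop=True)
    ledger = pd.DataFrame(ledger_rows, columns=["snapshot_id", "true_label"])
    return SyntheticDataset(
        manifest=manifest,
        snapshots=snapshots,
        ledger=ledger,
        config=config,
        plan=plan,
        templates=templates,
    )


# ---------------------------------------------------------------------------
# disk I/O (PNG images + CSV manifest + CSV hidden ledger)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Materialize a dataset: 8-bit PNGs (infrared, mask), 16-bit PNG depth
    in millimetres, ``manifest.csv`` and the hidden ``ground_truth_ledger.csv``."""
    outdir = Path(outdir)
    img_dir = outdir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest.copy()
    for i, row in manifest.iterrows():
        snap = dataset.snapshots[row["snapshot_id"]]
        sid = snap.snapshot_id
        ir_path = img_dir / f"{sid}_ir.png"
        dp_path = img_dir / f"{sid}_depth.png"
        Image.fromarray(snap.infrared, mode="L").save(ir_path)
        Image.fromarray(snap.depth.astype(np.uint16)).save(dp_path)
        manifest.loc[i, "infrared_path"] = str(ir_path.relative_to(outdir))
        manifest.loc[i, "depth_path"] = str(dp_path.relative_to(outdir))
        if snap.mask is not None:
            mk_path = img_dir / f"{sid}_mask.png"
            Image.fromarray((snap.mask * 255).astype(np.uint8), mode="L").save(mk_path)
            manifest.loc[i, "mask_path"] = str(mk_path.relative_to(outdir))
    manifest.to_csv(outdir / "manifest.csv", index=False)
    dataset.ledger.to_csv(outdir / "ground_truth_ledger.csv", index=False)
    return outdir


def load_dataset(indir: str | Path) -> SyntheticDataset:
    """Load a materialized dataset back into memory."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv", keep_default_na=False)
    ledger_path = indir / "ground_truth_ledger.csv"
    ledger = (
        pd.read_csv(ledger_path)
        if ledger_path.exists()
        else pd.DataFrame(columns=["snapshot_id", "true_label"])
    )
    snapshots: dict[str, Snapshot] = {}
    for row in manifest.itertuples():
        infrared = np.asarray(Image.open(indir / row.infrared_path), dtype=np.uint8)
        depth = np.asarray(Image.open(indir / row.depth_path)).astype(np.uint16)
        mask = None
        if row.mask_path:
            mask = (np.asarray(Image.open(indir / row.mask_path)) > 127).astype(np.uint8)
        label = row.label
        identity = None if label == "" else int(label)
        snapshots[row.snapshot_id] = Snapshot(
            snapshot_id=row.snapshot_id,
            infrared=infrared,
            depth=depth,
            mask=mask,
            capture_day=int(row.capture_day),
            identity=identity,
        )
    return SyntheticDataset(
        manifest=manifest,
        snapshots=snapshots,
        ledger=ledger,
        config=CaptureConfig(),
        plan=SplitPlan(),
    )


def manifest_bytes(dataset: SyntheticDataset) -> bytes:
    """Serialized manifest, used for byte-identity determinism checks."""
    return dataset.manifest.to_csv(index=False).encode()
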