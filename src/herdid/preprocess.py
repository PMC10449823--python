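"""Snapshot preprocessing: presence trigger, background removal, crop + rotate.

The capture rig fires only when something is close enough to the camera
(mean depth over a lane region strictly below a threshold — 3000 mm under
a camera mounted at 3500 mm).  Infrared snapshots are then stripped of
background using the segmentation mask, cropped to the body and rotated so
the body's principal axis is horizontal.  Rotation uses nearest-neighbour
interpolation and re-binarizes the mask, so "background is exactly zero"
is an exact invariant, not an approximate one.

Coordinates are 0-based row-major; boxes are half-open; angles are in
degrees, counter-clockwise positive in standard (x right, y up) axes.
The 180-degree head-left/head-right ambiguity of a principal axis is left
unresolved — horizontal flips during training absorb it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ArgumentError, DegenerateInputError


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open pixel box ``[top, top+height) x [left, left+width)``."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ArgumentError("ROI must have positive area")
        if self.top < 0 or self.left < 0:
            raise ArgumentError("ROI must lie inside the frame")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.top, self.top + self.height), slice(self.left, self.left + self.width)


@dataclass
class ProcessedImage:
    """A background-free, horizontally aligned body crop."""

    image: np.ndarray
    mask: np.ndarray
    source_snapshot_id: str
    rotation_applied: float  # degrees, CCW positive
    crop_box: RegionOfInterest  # in the rotated frame


def detect_presence(depth: np.ndarray, roi: RegionOfInterest, threshold_mm: float) -> bool:
    """True iff the mean depth over ``roi`` is strictly below ``threshold_mm``.

    All ROI pixels participate in the mean (no invalid-pixel masking); the
    empty lane, at exactly the camera height, never triggers. Equality with
    the threshold does not trigger either.
    """
    depth = np.asarray(depth)
    if threshold_mm <= 0:
        raise ArgumentError("threshold_mm must be > 0")
    rs, cs = roi.slices()
    if roi.top + roi.height > depth.shape[0] or roi.left + roi.width > depth.shape[1]:
        raise ArgumentError("ROI extends beyond the depth frame")
    region = depth[rs, cs]
    if region.size == 0:
        raise ArgumentError("ROI selects no pixels")
    return float(region.mean()) < float(threshold_mm)


def apply_mask(infrared: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every background pixel: out = infrared where mask==1 else 0."""
    infrared = np.asarray(infrared)
    mask = np.asarray(mask)
    if infrared.shape != mask.shape:
        raise ArgumentError(
            f"shape mismatch: infrared {infrared.shape} vs mask {mask.shape}"
        )
    return np.where(mask != 0, infrared, np.zeros((), dtype=infrared.dtype))


def principal_axis_angle(mask: np.ndarray) -> float:
    """Orientation of the foreground's major principal axis, degrees in (-90, 90].

    Computed from second central moments of the foreground pixel
    coordinates in (x right, y up) axes. A shape with equal eigenvalues and
    no covariance (e.g. a perfect square) returns 0 by convention.
    """
    mask = np.asarray(mask)
    ys, xs = np.nonzero(mask)
    if len(xs) < 2:
        raise DegenerateInputError("mask needs at least 2 foreground pixels")
    x = xs.astype(float)
    y = -ys.astype(float)  # y up
    x -= x.mean()
    y -= y.mean()
    mu20 = float(np.mean(x * x))
    mu02 = float(np.mean(y * y))
    mu11 = float(np.mean(x * y))
    if mu20 == 0.0 and mu02 > 0.0:  # all pixels on one vertical line
        raise DegenerateInputError("foreground is a single vertical line of pixels")
    angle = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return float(angle)


def crop_rotate(
    masked: np.ndarray,
    mask: np.ndarray,
    padding: int = 0,
    source_snapshot_id: str = "",
) -> ProcessedImage:
    """Rotate the body horizontal, then crop to its bounding box + padding.

    Nearest-neighbour rotation of both image and mask about the frame
    centre; the output image is re-masked so background stays exactly 0.
    The crop box is the tight rotated-foreground bounding box grown by
    ``padding`` on each side, clipped at the rotated frame.
    """
    masked = np.asarray(masked)
    mask = np.asarray(mask)
    if masked.shape != mask.shape:
        raise ArgumentError("image and mask shapes differ")
    if padding < 0:
        raise ArgumentError("padding must be >= 0")
    if not mask.any():
        raise DegenerateInputError("cannot crop an empty mask")

    angle = principal_axis_angle(mask)
    if abs(angle) < 1e-9:
        img_r, mask_r = masked, mask.astype(bool)
        applied = 0.0
    else:
        # ndimage.rotate(a) turns content by +a CCW in (x right, y up)
        # axes, so undoing a +angle orientation needs a -angle rotation.
        img_r = ndimage.rotate(masked, -angle, reshape=True, order=0, prefilter=False)
        mask_r = ndimage.rotate(
            mask.astype(np.uint8), -angle, reshape=True, order=0, prefilter=False
        ).astype(bool)
        applied = float(angle)
        img_r = np.where(mask_r, img_r, np.zeros((), dtype=img_r.dtype))

    ys, xs = np.nonzero(mask_r)
    top = max(int(ys.min()) - padding, 0)
    bottom = min(int(ys.max()) + 1 + padding, mask_r.shape[0])
    left = max(int(xs.min()) - padding, 0)
    right = min(int(xs.max()) + 1 + padding, mask_r.shape[1])
    box = RegionOfInterest(top=top, left=left, height=bottom - top, width=right - left)
    rs, cs = box.slices()
    return ProcessedImage(
        image=img_r[rs, cs],
        mask=mask_r[rs, cs].astype(np.uint8),
        source_snapshot_id=source_snapshot_id,
        rotation_applied=applied,
        crop_box=box,
    )
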