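"""Turning instance-segmentation output into actionable coordinates.

Two kinds of target are produced from a detector's masks:

* **Crystal targets** — the centre of mass of each detected crystal mask, the
  point queued for X-ray data collection.
* **A dispense target** — the point in the drop farthest from both the drop
  edge and every crystal, found by subtracting the union of the crystal masks
  from the drop mask and taking the argmax of the exact Euclidean distance
  transform of what remains.  Compound dispensed there (e.g. a fragment in
  DMSO) diffuses toward the crystals gradually instead of shocking them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import BinaryMask, BoundingBox, EmptyMaskError, bbox_from_mask

__all__ = [
    "Detection",
    "CrystalTarget",
    "DispenseTarget",
    "NoFeasiblePointError",
    "filter_detections",
    "crystal_centroid",
    "distance_transform",
    "dispense_point",
    "make_targets",
]

#: Default minimum detection probability for downstream use.
DEFAULT_PROBABILITY_THRESHOLD = 0.6


class NoFeasiblePointError(ValueError):
    """The drop-minus-crystals region is empty: nowhere left to dispense."""


@dataclass(frozen=True)
class Detection:
    """A predicted object: category, confidence, mask and tight box."""

    category: str
    probability: float
    mask: BinaryMask
    bbox: BoundingBox = None  # type: ignore[assignment]  # derived if omitted

    def __post_init__(self) -> None:
        if self.category not in ("crystal", "drop"):
            raise ValueError(f"unknown category {self.category!r}")
        if not np.isfinite(self.probability):
            raise ValueError("probability must be finite")
        if self.bbox is None:
            object.__setattr__(self, "bbox", bbox_from_mask(self.mask))
        elif bbox_from_mask(self.mask) != self.bbox:
            raise ValueError("bbox is not tight for the mask")


@dataclass(frozen=True)
class CrystalTarget:
    """Continuous data-collection coordinates at a crystal's centre of mass."""

    x: float
    y: float
    inside_mask: bool
    source_detection: Detection | None = field(default=None, repr=False)


@dataclass(frozen=True)
class DispenseTarget:
    """Integer pixel coordinates for compound dispensing, with clearance.

    ``clearance`` is the exact Euclidean distance (in pixels) from the chosen
    pixel to the nearest point outside the drop-minus-crystals region.
    """

    x: int
    y: int
    clearance: float

    def __post_init__(self) -> None:
        if self.clearance <= 0:
            raise ValueError("clearance must be positive")


def filter_detections(
    detections: list[Detection],
    min_probability: float = DEFAULT_PROBABILITY_THRESHOLD,
) -> list[Detection]:
    """Keep detections with ``probability >= min_probability``, in order."""
    return [d for d in detections if d.probability >= min_probability]


def crystal_centroid(
    mask: BinaryMask, source: Detection | None = None
) -> CrystalTarget:
    """Centre of mass of a mask in pixel-centre coordinates.

    ``x`` is the mean foreground column index + 0.5 and ``y`` the mean row
    index + 0.5.  ``inside_mask`` reports whether the pixel containing the
    centroid is itself foreground (false for e.g. ring-shaped masks, where a
    beamline would need a fallback rule).
    """
    if mask.is_empty():
        raise EmptyMaskError("cannot take the centroid of an empty mask")
    rows, cols = np.nonzero(mask.array)
    x = float(cols.mean()) + 0.5
    y = float(rows.mean()) + 0.5
    r = min(int(y), mask.height - 1)
    c = min(int(x), mask.width - 1)
    return CrystalTarget(
        x=x, y=y, inside_mask=bool(mask.array[r, c]), source_detection=source
    )


def distance_transform(mask: BinaryMask) -> np.ndarray:
    """Exact Euclidean distance transform with the image border as background.

    Each foreground pixel maps to its exact Euclidean distance to the nearest
    background pixel; background pixels map to 0.  Pixels outside the frame
    count as background, so a region touching the image edge is not treated as
    infinitely clear there.
    """
    padded = np.pad(mask.array, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded)
    return dist[1:-1, 1:-1]


def dispense_point(
    drop_mask: BinaryMask, crystal_masks: list[BinaryMask]
) -> DispenseTarget:
    """The point in the drop farthest from the drop edge and all crystals.

    Subtracts the union of the crystal masks from the drop mask, applies the
    exact Euclidean distance transform and returns the argmax pixel with its
    distance value as clearance.  Ties are broken deterministically by
    smallest row, then smallest column.
    """
    if drop_mask.is_empty():
        raise EmptyMaskError("drop mask is empty")
    region = drop_mask.array.copy()
    for cm in crystal_masks:
        if cm.shape != drop_mask.shape:
            raise ValueError("crystal mask dimensions differ from the drop mask")
        region &= ~cm.array
    if not region.any():
        raise NoFeasiblePointError("crystal masks cover the entire drop")
    dist = distance_transform(BinaryMask(region))
    flat_idx = int(np.argmax(dist))  # first occurrence: min row, then min col
    r, c = np.unravel_index(flat_idx, dist.shape)
    return DispenseTarget(x=int(c), y=int(r), clearance=float(dist[r, c]))


def make_targets(
    detections: list[Detection],
    min_probability: float = DEFAULT_PROBABILITY_THRESHOLD,
) -> tuple[list[CrystalTarget], DispenseTarget | None]:
    """Filter detections and derive crystal and dispense targets.

    Crystal targets come from every surviving crystal detection.  The
    dispense target uses the highest-probability surviving drop detection and
    the union of all surviving crystal masks; it is ``None`` when no drop was
    detected or when the crystals leave no feasible point.
    """
    kept = filter_detections(detections, min_probability)
    crystals = [d for d in kept if d.category == "crystal"]
    drops = [d for d in kept if d.category == "drop"]

    crystal_targets = [crystal_centroid(d.mask, source=d) for d in crystals]

    dispense: DispenseTarget | None = None
    if drops:
        best_drop = max(drops, key=lambda d: d.probability)
        try:
            dispense = dispense_point(best_drop.mask, [d.mask for d in crystals])
        except NoFeasiblePointError:
            dispense = None
    return crystal_targets, dispense
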