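"""Geometric primitives shared across annotation, targeting and evaluation.

Coordinate convention (used everywhere in this package): 0-based, origin at
the top-left of the image, ``x`` indexes columns and ``y`` indexes rows.
Bounding boxes are half-open: ``[xmin, xmax) x [ymin, ymax)``.  The pixel at
row ``r``, column ``c`` covers the unit square ``[c, c+1) x [r, r+1)`` and has
its centre at ``(c + 0.5, r + 0.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BoundingBox",
    "BinaryMask",
    "Polygon",
    "EmptyMaskError",
    "rasterize_polygon",
    "bbox_from_mask",
]


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty mask and none results."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open pixel box ``[xmin, xmax) x [ymin, ymax)``."""

    xmin: int
    ymin: int
    xmax: int
    ymax: int

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate bounding box: ({self.xmin}, {self.ymin}, "
                f"{self.xmax}, {self.ymax})"
            )

    @property
    def width(self) -> int:
        return self.xmax - self.xmin

    @property
    def height(self) -> int:
        return self.ymax - self.ymin

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersection_area(self, other: "BoundingBox") -> int:
        w = min(self.xmax, other.xmax) - max(self.xmin, other.xmin)
        h = min(self.ymax, other.ymax) - max(self.ymin, other.ymin)
        return max(w, 0) * max(h, 0)

    def as_xywh(self) -> tuple[int, int, int, int]:
        return (self.xmin, self.ymin, self.width, self.height)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean H x W pixel grid.

    The underlying array is stored with ``dtype=bool``; any array-like of
    {0, 1} values is accepted and converted.
    """

    array: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.array)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"mask must be a 2-D grid, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask values must be in {0, 1}")
            arr = arr.astype(bool)
        arr = np.ascontiguousarray(arr)
        arr.setflags(write=False)
        object.__setattr__(self, "array", arr)

    @property
    def height(self) -> int:
        return int(self.array.shape[0])

    @property
    def width(self) -> int:
        return int(self.array.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def area(self) -> int:
        """Number of foreground pixels."""
        return int(self.array.sum())

    def is_empty(self) -> bool:
        return not bool(self.array.any())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.array.shape == other.array.shape and bool(
            (self.array == other.array).all()
        )

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash((self.shape, self.array.tobytes()))


@dataclass(frozen=True)
class Polygon:
    """Ordered vertex list ``[(x, y), ...]`` in image-frame pixel units."""

    vertices: tuple[tuple[float, float], ...]

    def __init__(self, vertices: Iterable[Sequence[float]]):
        verts = tuple((float(x), float(y)) for x, y in vertices)
        if len(verts) < 3:
            raise ValueError(f"polygon needs >= 3 vertices, got {len(verts)}")
        if not all(np.isfinite(v).all() for v in map(np.asarray, verts)):
            raise ValueError("polygon coordinates must be finite")
        object.__setattr__(self, "vertices", verts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


def _points_in_polygon(points: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even–odd (crossing-number) point-in-polygon test, boundary inclusive.

    ``points`` is (N, 2) as (x, y); ``verts`` is (V, 2).  A point exactly on a
    polygon edge counts as inside.  Vectorized over points and edges.
    """
    px = points[:, 0][:, None]
    py = points[:, 1][:, None]
    x1 = verts[:, 0][None, :]
    y1 = verts[:, 1][None, :]
    x2 = np.roll(verts[:, 0], -1)[None, :]
    y2 = np.roll(verts[:, 1], -1)[None, :]

    # Even-odd ray cast towards +x.  Half-open vertical rule avoids double
    # counting at shared vertices.
    crosses = (y1 > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_at = (x2 - x1) * (py - y1) / (y2 - y1) + x1
    inside = (crosses & (px < x_at)).sum(axis=1) % 2 == 1

    # Boundary test: zero cross product and within the edge's span.
    dx = x2 - x1
    dy = y2 - y1
    cross = (px - x1) * dy - (py - y1) * dx
    dot = (px - x1) * dx + (py - y1) * dy
    seg_len2 = dx * dx + dy * dy
    on_edge = (
        (np.abs(cross) <= 1e-9 * np.maximum(1.0, np.sqrt(seg_len2)))
        & (dot >= -1e-12)
        & (dot <= seg_len2 + 1e-12)
    ).any(axis=1)

    return inside | on_edge


def rasterize_polygon(polygon: Polygon, height: int, width: int) -> BinaryMask:
    """Rasterize a polygon onto an ``height x width`` grid.

    Pixel ``(r, c)`` is foreground iff its centre ``(c + 0.5, r + 0.5)`` lies
    inside the polygon, with points on the boundary counting as inside.
    Self-intersecting polygons follow the even–odd fill rule.  Portions of the
    polygon outside the image are clipped away.

    Raises
    ------
    EmptyMaskError
        If no pixel centre falls inside the polygon (degenerate or fully
        off-image polygon).
    """
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be >= 1")
    verts = polygon.as_array()

    # Only pixels whose centres can possibly be covered need testing.
    cmin = max(int(np.floor(verts[:, 0].min() - 0.5)), 0)
    cmax = min(int(np.ceil(verts[:, 0].max() - 0.5)) + 1, width)
    rmin = max(int(np.floor(verts[:, 1].min() - 0.5)), 0)
    rmax = min(int(np.ceil(verts[:, 1].max() - 0.5)) + 1, height)

    grid = np.zeros((height, width), dtype=bool)
    if cmin < cmax and rmin < rmax:
        rr, cc = np.meshgrid(
            np.arange(rmin, rmax), np.arange(cmin, cmax), indexing="ij"
        )
        centres = np.column_stack([cc.ravel() + 0.5, rr.ravel() + 0.5])
        hit = _points_in_polygon(centres, verts)
        grid[rmin:rmax, cmin:cmax] = hit.reshape(rmax - rmin, cmax - cmin)

    if not grid.any():
        raise EmptyMaskError(
            "polygon covers no pixel centre (degenerate or outside the image)"
        )
    return BinaryMask(grid)


def bbox_from_mask(mask: BinaryMask) -> BoundingBox:
    """Tight half-open bounding box of a mask's foreground pixels."""
    if mask.is_empty():
        raise EmptyMaskError("cannot take the bounding box of an empty mask")
    rows = np.flatnonzero(mask.array.any(axis=1))
    cols = np.flatnonzero(mask.array.any(axis=0))
    return BoundingBox(
        xmin=int(cols[0]),
        ymin=int(rows[0]),
        xmax=int(cols[-1]) + 1,
        ymax=int(rows[-1]) + 1,
    )
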