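"""Instance-annotation I/O and image preprocessing.

Converts citizen-science polygon exports (Zooniverse-style CSV with JSON
payloads) and COCO JSON into validated :class:`InstanceAnnotation` objects,
rasterizes polygons into masks, derives bounding boxes, and applies the
standard micrograph preprocessing used upstream of annotation and detection
(integer downscale followed by contrast-limited adaptive histogram
equalization).

Category ids in COCO documents are stable: ``{1: "crystal", 2: "drop"}``.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Union

import numpy as np
from skimage import exposure, transform

from .geometry import (
    BinaryMask,
    BoundingBox,
    EmptyMaskError,
    Polygon,
    bbox_from_mask,
    rasterize_polygon,
)

logger = logging.getLogger(__name__)

CATEGORIES: dict[int, str] = {1: "crystal", 2: "drop"}
_CATEGORY_IDS = {name: cid for cid, name in CATEGORIES.items()}

__all__ = [
    "CATEGORIES",
    "ImageRecord",
    "InstanceAnnotation",
    "ZooniverseParseError",
    "CocoSchemaError",
    "annotation_from_polygon",
    "parse_zooniverse_export",
    "preprocess_image",
    "write_coco",
    "read_coco",
    "rle_encode",
    "rle_decode",
]


class ZooniverseParseError(ValueError):
    """Malformed row in a Zooniverse-style CSV export."""


class CocoSchemaError(ValueError):
    """A COCO document is missing required keys or uses unknown categories."""


@dataclass(frozen=True)
class ImageRecord:
    """An image with its identifier and provenance path."""

    image_id: str
    pixels: np.ndarray = field(repr=False)
    source_path: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim not in (2, 3):
            raise ValueError("pixels must be a 2-D grey or 3-D RGB grid")
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class InstanceAnnotation:
    """A ground-truth object: category, optional polygon, mask and tight box."""

    image_id: str
    category: str
    mask: BinaryMask
    bbox: BoundingBox
    polygon: Polygon | None = None

    def __post_init__(self) -> None:
        if self.category not in _CATEGORY_IDS:
            raise ValueError(
                f"unknown category {self.category!r}; "
                f"expected one of {sorted(_CATEGORY_IDS)}"
            )
        if self.mask.is_empty():
            raise EmptyMaskError("annotation mask is empty")
        if bbox_from_mask(self.mask) != self.bbox:
            raise ValueError("bbox is not the tight bounding box of the mask")


def annotation_from_polygon(
    image_id: str,
    category: str,
    polygon: Polygon,
    height: int,
    width: int,
) -> InstanceAnnotation:
    """Build an annotation by rasterizing ``polygon`` onto the image grid."""
    mask = rasterize_polygon(polygon, height, width)
    return InstanceAnnotation(
        image_id=image_id,
        category=category,
        mask=mask,
        bbox=bbox_from_mask(mask),
        polygon=polygon,
    )


# ---------------------------------------------------------------------------
# Zooniverse CSV dialect
# ---------------------------------------------------------------------------

ShapeSpec = Union[tuple[int, int], Mapping[str, tuple[int, int]]]


def _shape_for(image_id: str, image_shape: ShapeSpec) -> tuple[int, int]:
    if isinstance(image_shape, Mapping):
        try:
            return image_shape[image_id]
        except KeyError:
            raise ZooniverseParseError(
                f"no image shape provided for image {image_id!r}"
            ) from None
    return image_shape


def parse_zooniverse_export(
    csv_stream: IO[str] | str,
    image_shape: ShapeSpec,
) -> dict[str, list[InstanceAnnotation]]:
    """Parse a Zooniverse-style CSV export into per-image annotations.

    The dialect has columns ``subject_ids``, ``subject_data`` (a JSON object
    ``{"<id>": {"Filename": ...}}``) and ``annotations`` (a JSON list of
    tasks, each task a list of ``{"tool_label": "crystal"|"drop",
    "points": [{"x": ..., "y": ...}, ...]}``).  The platform does not record
    image dimensions, so ``image_shape`` supplies them — either one
    ``(height, width)`` for all images or a mapping ``image_id -> (h, w)``.

    Polygons with fewer than three vertices are skipped with a logged warning;
    malformed JSON raises :class:`ZooniverseParseError` citing the row number.
    Images that appear but carry no valid polygons map to empty lists.
    """
    if isinstance(csv_stream, str):
        csv_stream = io.StringIO(csv_stream)
    reader = csv.DictReader(csv_stream)
    required = {"subject_ids", "subject_data", "annotations"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ZooniverseParseError(
            f"CSV must have columns {sorted(required)}, got {reader.fieldnames}"
        )

    out: dict[str, list[InstanceAnnotation]] = {}
    n_skipped = 0
    for row_number, row in enumerate(reader, start=2):  # 1 is the header
        try:
            subject_data = json.loads(row["subject_data"])
            tasks = json.loads(row["annotations"])
        except json.JSONDecodeError as exc:
            raise ZooniverseParseError(
                f"row {row_number}: malformed JSON payload ({exc})"
            ) from exc

        subject_id = str(row["subject_ids"])
        meta = subject_data.get(subject_id, {})
        image_id = str(meta.get("Filename", subject_id))
        anns = out.setdefault(image_id, [])
        height, width = _shape_for(image_id, image_shape)

        for task in tasks:
            for obj in task:
                label = obj.get("tool_label", "")
                if label not in _CATEGORY_IDS:
                    raise ZooniverseParseError(
                        f"row {row_number}: unknown tool_label {label!r}"
                    )
                points = [(p["x"], p["y"]) for p in obj.get("points", [])]
                if len(points) < 3:
                    n_skipped += 1
                    logger.warning(
                        "row %d: skipping polygon with %d < 3 vertices "
                        "(image %s)",
                        row_number,
                        len(points),
                        image_id,
                    )
                    continue
                anns.append(
                    annotation_from_polygon(
                        image_id, label, Polygon(points), height, width
                    )
                )
    if n_skipped:
        logger.warning("skipped %d undersized polygon(s) in export", n_skipped)
    return out


# ---------------------------------------------------------------------------
# Preprocessing: downscale + CLAHE
# ---------------------------------------------------------------------------


def preprocess_image(
    image: ImageRecord,
    downscale_factor: int = 2,
    clahe_grid: int = 12,
    clahe_clip: float = 2.0,
) -> ImageRecord:
    """Downscale an image by an integer factor, then apply CLAHE.

    The output has dimensions ``floor(input / downscale_factor)``.  CLAHE is
    applied tile-wise on a ``clahe_grid x clahe_grid`` tiling of the rescaled
    image.  ``clahe_clip`` uses the OpenCV-style convention in which the
    per-bin histogram ceiling is ``clip * tile_area / 256``; it is converted to
    scikit-image's normalized clip limit internally.  Output pixels are uint8.
    """
    if downscale_factor < 1:
        raise ValueError("downscale_factor must be >= 1")
    if clahe_grid < 1:
        raise ValueError("clahe_grid must be >= 1")
    arr = np.asarray(image.pixels, dtype=float)
    if arr.ndim == 3:  # luminance of RGB; annotation only needs geometry
        arr = arr.mean(axis=2)
    if arr.max() > 1.0:
        arr = arr / 255.0

    out_h = image.height // downscale_factor
    out_w = image.width // downscale_factor
    if out_h < clahe_grid or out_w < clahe_grid:
        raise ValueError(
            f"downscaled image ({out_h} x {out_w}) is smaller than the CLAHE "
            f"grid ({clahe_grid}); use a smaller grid"
        )
    if downscale_factor > 1:
        arr = transform.resize(
            arr, (out_h, out_w), order=1, anti_aliasing=True, mode="reflect"
        )

    if np.ptp(arr) > 0:  # CLAHE of a flat image is (trivially) flat
        kernel = (max(out_h // clahe_grid, 1), max(out_w // clahe_grid, 1))
        arr = exposure.equalize_adapthist(
            np.clip(arr, 0.0, 1.0),
            kernel_size=kernel,
            clip_limit=clahe_clip / 256.0,
        )
    out = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    return ImageRecord(
        image_id=image.image_id, pixels=out, source_path=image.source_path
    )


# ---------------------------------------------------------------------------
# COCO JSON
# ---------------------------------------------------------------------------


def rle_encode(mask: BinaryMask) -> dict:
    """Uncompressed COCO run-length encoding (column-major, starts with 0s)."""
    flat = mask.array.flatten(order="F").astype(np.int8)
    # run boundaries
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate(([0], change, [flat.size]))
    counts = np.diff(starts).tolist()
    if flat.size and flat[0] == 1:  # COCO counts always begin with zeros
        counts = [0] + counts
    return {"size": [mask.height, mask.width], "counts": counts}


def rle_decode(rle: dict) -> BinaryMask:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for count in rle["counts"]:
        if val:
            flat[pos : pos + count] = True
        pos += count
        val = not val
    return BinaryMask(flat.reshape((w, h)).T)


def write_coco(
    annotations: Iterable[InstanceAnnotation],
    images: Iterable[ImageRecord] | Iterable[tuple[str, int, int]],
) -> dict:
    """Serialize annotations to a COCO-format document (a JSON-able dict).

    ``images`` may be :class:`ImageRecord` objects or ``(image_id, height,
    width)`` tuples.  Polygon-native annotations are stored as COCO polygon
    segmentations; mask-native ones as uncompressed RLE.  ``write`` then
    ``read`` is the identity on masks.
    """
    image_entries = []
    image_index: dict[str, int] = {}
    for img in images:
        if isinstance(img, ImageRecord):
            image_id, h, w = img.image_id, img.height, img.width
        else:
            image_id, h, w = img
        idx = len(image_entries) + 1
        image_index[str(image_id)] = idx
        image_entries.append(
            {"id": idx, "file_name": str(image_id), "height": int(h), "width": int(w)}
        )

    ann_entries = []
    for ann in annotations:
        if ann.image_id not in image_index:
            raise CocoSchemaError(
                f"annotation references unknown image {ann.image_id!r}"
            )
        if ann.polygon is not None:
            seg = [
                [coord for xy in ann.polygon.vertices for coord in xy]
            ]
        else:
            seg = rle_encode(ann.mask)
        ann_entries.append(
            {
                "id": len(ann_entries) + 1,
                "image_id": image_index[ann.image_id],
                "category_id": _CATEGORY_IDS[ann.category],
                "segmentation": seg,
                "area": ann.mask.area,
                "bbox": list(ann.bbox.as_xywh()),
                "iscrowd": 0,
            }
        )

    return {
        "images": image_entries,
        "annotations": ann_entries,
        "categories": [
            {"id": cid, "name": name} for cid, name in sorted(CATEGORIES.items())
        ],
    }


def read_coco(
    document: dict,
) -> tuple[dict[str, list[InstanceAnnotation]], list[tuple[str, int, int]]]:
    """Parse a COCO document into annotations grouped by image.

    Returns ``(annotations_by_image_id, [(image_id, height, width), ...])``.
    Polygon segmentations are re-rasterized under the package's pixel-centre
    rule; RLE segmentations are decoded directly.
    """
    for key in ("images", "annotations", "categories"):
        if key not in document:
            raise CocoSchemaError(f"COCO document missing key {key!r}")
    cat_names = {c["id"]: c["name"] for c in document["categories"]}
    images = {
        img["id"]: (str(img["file_name"]), int(img["height"]), int(img["width"]))
        for img in document["images"]
    }
    out: dict[str, list[InstanceAnnotation]] = {
        file_name: [] for file_name, _, _ in images.values()
    }
    for entry in document["annotations"]:
        try:
            image_id, h, w = images[entry["image_id"]]
            category = cat_names[entry["category_id"]]
            seg = entry["segmentation"]
        except KeyError as exc:
            raise CocoSchemaError(f"annotation missing/invalid field: {exc}") from exc
        if category not in _CATEGORY_IDS:
            raise CocoSchemaError(f"unknown category {category!r}")
        if isinstance(seg, dict):
            mask = rle_decode(seg)
            ann = InstanceAnnotation(
                image_id=image_id,
                category=category,
                mask=mask,
                bbox=bbox_from_mask(mask),
            )
        else:
            coords = seg[0]
            points = list(zip(coords[0::2], coords[1::2]))
            ann = annotation_from_polygon(image_id, category, Polygon(points), h, w)
        out[image_id].append(ann)
    return out, list(images.values())
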