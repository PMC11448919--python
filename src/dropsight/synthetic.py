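"""Synthetic crystallization-drop scenes, inspection tables and label panels.

Everything downstream (annotation I/O, curation, targeting, evaluation) is
exercisable without real micrographs or a trained detector: this module draws
sitting-drop-like scenes (one quasi-elliptical drop, a configurable number of
convex polygonal crystals, background noise) with exact ground-truth masks,
emits LIMS-style inspection tables, simulates multi-expert label panels with
tunable confusion, and provides a mock detector whose corruption parameters
(miss rate, spurious-detection rate) are known, so downstream metrics have
closed-form expectations.

All randomness flows from a single user-supplied seed: each generator builds
one ``numpy.random.SeedSequence`` from it and spawns named child streams in a
fixed order, so outputs are bit-reproducible for a fixed seed.

The rendering makes no claim of photometric realism — only the geometry is
consumed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .curation import CLASS_LABELS, InspectionRecord
from .geometry import BinaryMask, Polygon, bbox_from_mask, rasterize_polygon
from .annotations import InstanceAnnotation
from .targeting import Detection, distance_transform

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "ExpertPanelSpec",
    "SceneValidationError",
    "generate_scene",
    "scene_annotations",
    "generate_inspection_table",
    "simulate_expert_panel",
    "mock_predictor",
]

#: Scores assigned to scenes containing at least one crystal.
CRYSTAL_SCORES = (6, 7, 8, 9)
#: Scores available to crystal-free scenes.
NONCRYSTAL_SCORES = (0, 1, 2, 3, 4, 5)


class SceneValidationError(ValueError):
    """A scene specification violates an invariant; the message names the field."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic drop scene.

    Defaults give a modest 256 x 320 scene with a centred elliptical drop and
    zero to six crystals of 10-40 px longest dimension, wholly inside the
    drop — a geometry-faithful, photometrically crude stand-in for a
    sitting-drop micrograph.
    """

    image_height: int = 256
    image_width: int = 320
    drop_axes: tuple[float, float] = (120.0, 95.0)  # (semi-axis-x, semi-axis-y)
    drop_centre: tuple[float, float] | None = None  # default: image centre
    crystal_count_range: tuple[int, int] = (0, 6)
    crystal_size_range: tuple[float, float] = (10.0, 40.0)
    crystal_vertex_count_range: tuple[int, int] = (3, 8)
    crystals_inside_drop: bool = True
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 8 or self.image_width < 8:
            raise SceneValidationError("image_height/image_width must be >= 8")
        ax, ay = self.drop_axes
        if ax <= 0 or ay <= 0:
            raise SceneValidationError("drop_axes must be positive")
        cx, cy = self.centre
        if not (ax <= cx <= self.image_width - ax and ay <= cy <= self.image_height - ay):
            raise SceneValidationError("drop_centre/drop_axes: drop exceeds image bounds")
        lo, hi = self.crystal_count_range
        if lo < 0 or lo > hi:
            raise SceneValidationError("crystal_count_range must satisfy 0 <= min <= max")
        slo, shi = self.crystal_size_range
        if slo <= 0 or slo > shi:
            raise SceneValidationError("crystal_size_range must be positive and ordered")
        vlo, vhi = self.crystal_vertex_count_range
        if vlo < 3 or vlo > vhi:
            raise SceneValidationError("crystal_vertex_count_range min must be >= 3")
        if self.noise_sd < 0:
            raise SceneValidationError("noise_sd must be >= 0")

    @property
    def centre(self) -> tuple[float, float]:
        if self.drop_centre is not None:
            return self.drop_centre
        return (self.image_width / 2.0, self.image_height / 2.0)


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered scene with its exact ground truth."""

    image: np.ndarray = field(repr=False)
    drop_mask: BinaryMask
    crystal_masks: tuple[BinaryMask, ...]
    outcome_score: int
    provenance: SceneSpec

    def __post_init__(self) -> None:
        shape = (self.provenance.image_height, self.provenance.image_width)
        if self.image.shape != shape or self.drop_mask.shape != shape:
            raise SceneValidationError("image/mask dimensions disagree with the spec")
        for m in self.crystal_masks:
            if m.shape != shape:
                raise SceneValidationError("crystal mask dimensions disagree")
            if m.is_empty():
                raise SceneValidationError("crystal mask is empty")


def _ellipse_mask(spec: SceneSpec) -> BinaryMask:
    cx, cy = spec.centre
    ax, ay = spec.drop_axes
    yy, xx = np.mgrid[0 : spec.image_height, 0 : spec.image_width]
    px = xx + 0.5
    py = yy + 0.5
    return BinaryMask(((px - cx) / ax) ** 2 + ((py - cy) / ay) ** 2 <= 1.0)


def _random_convex_polygon(
    rng: np.random.Generator,
    centre: tuple[float, float],
    size: float,
    n_vertices: int,
) -> Polygon:
    """Convex polygon of roughly ``size`` longest dimension around ``centre``."""
    angles = np.sort(rng.uniform(0.0, 2.0 * math.pi, size=n_vertices))
    radii = size / 2.0 * rng.uniform(0.55, 1.0, size=n_vertices)
    pts = np.column_stack(
        [centre[0] + radii * np.cos(angles), centre[1] + radii * np.sin(angles)]
    )
    if n_vertices > 3:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    return Polygon(pts)


def generate_scene(
    spec: SceneSpec,
    crystal_score_weights: Sequence[float] | None = None,
    noncrystal_score_weights: Sequence[float] | None = None,
) -> SyntheticScene:
    """Generate one scene, deterministically for a fixed ``spec.seed``.

    The outcome score mirrors the ten-point scoring semantics: scenes with at
    least one crystal draw a score from {6..9}, crystal-free scenes from
    {0..5}, each under the given (default uniform) weights — so the score maps
    to the 'Crystals' class iff a crystal was drawn.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_layout, rng_render, rng_score = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    drop = _ellipse_mask(spec)
    drop_edt = distance_transform(drop)

    n_crystals = int(
        rng_layout.integers(spec.crystal_count_range[0], spec.crystal_count_range[1] + 1)
    )
    crystal_masks: list[BinaryMask] = []
    polygons: list[Polygon] = []
    for _ in range(n_crystals):
        for _attempt in range(100):
            size = float(rng_layout.uniform(*spec.crystal_size_range))
            k = int(
                rng_layout.integers(
                    spec.crystal_vertex_count_range[0],
                    spec.crystal_vertex_count_range[1] + 1,
                )
            )
            if spec.crystals_inside_drop:
                # centre on a drop pixel comfortably inside the rim
                candidates = np.argwhere(drop_edt >= min(4.0, drop_edt.max()))
            else:
                candidates = np.argwhere(
                    np.ones((spec.image_height, spec.image_width), dtype=bool)
                )
            r, c = candidates[rng_layout.integers(len(candidates))]
            poly = _random_convex_polygon(rng_layout, (c + 0.5, r + 0.5), size, k)
            try:
                mask = rasterize_polygon(poly, spec.image_height, spec.image_width)
            except ValueError:
                continue
            if spec.crystals_inside_drop:
                clipped = mask.array & drop.array
                if not clipped.any():
                    continue
                mask = BinaryMask(clipped)
            crystal_masks.append(mask)
            polygons.append(poly)
            break
        else:  # pragma: no cover - extremely unlikely with sane specs
            raise SceneValidationError("could not place a crystal inside the drop")

    # rendering: flat background, interior gradient, dark rim, bright/dark
    # crystals, Gaussian noise.  Downstream only consumes the geometry.
    img = np.full((spec.image_height, spec.image_width), 150.0)
    if drop_edt.max() > 0:
        interior = 95.0 + 35.0 * (drop_edt / drop_edt.max())
        img = np.where(drop.array, interior, img)
    img = np.where((drop_edt > 0) & (drop_edt <= 2.0), 55.0, img)
    for mask in crystal_masks:
        level = rng_render.choice([45.0, 200.0, 225.0])
        img = np.where(mask.array, level, img)
    if spec.noise_sd > 0:
        img = img + rng_render.normal(0.0, spec.noise_sd, size=img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)

    if n_crystals > 0:
        score = int(rng_score.choice(CRYSTAL_SCORES, p=crystal_score_weights))
    else:
        score = int(rng_score.choice(NONCRYSTAL_SCORES, p=noncrystal_score_weights))

    return SyntheticScene(
        image=image,
        drop_mask=drop,
        crystal_masks=tuple(crystal_masks),
        outcome_score=score,
        provenance=spec,
    )


def scene_annotations(scene: SyntheticScene, image_id: str) -> list[InstanceAnnotation]:
    """Ground-truth annotations (drop first, then crystals) for a scene."""
    anns = [
        InstanceAnnotation(
            image_id=image_id,
            category="drop",
            mask=scene.drop_mask,
            bbox=bbox_from_mask(scene.drop_mask),
        )
    ]
    anns.extend(
        InstanceAnnotation(
            image_id=image_id,
            category="crystal",
            mask=mask,
            bbox=bbox_from_mask(mask),
        )
        for mask in scene.crystal_masks
    )
    return anns


# ---------------------------------------------------------------------------
# Inspection tables
# ---------------------------------------------------------------------------

_WELLS = tuple(f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13))


def generate_inspection_table(
    n_subwells: int,
    inspections_per_subwell: tuple[int, int] = (1, 4),
    score_fraction: float = 1.0,
    seed: int = 0,
) -> list[InspectionRecord]:
    """Emulate a LIMS query result: scored inspection records by subwell.

    Subwells fill 96-well plates (two subwells per well); each subwell gets a
    uniform number of inspections in ``inspections_per_subwell`` (numbered
    from 1), and exactly ``round(score_fraction * n_records)`` records,
    chosen at random, carry a ten-point score.
    """
    if n_subwells < 1:
        raise ValueError("n_subwells must be >= 1")
    lo, hi = inspections_per_subwell
    if lo < 1 or lo > hi:
        raise ValueError("inspections_per_subwell must satisfy 1 <= min <= max")
    if not 0.0 <= score_fraction <= 1.0:
        raise ValueError("score_fraction must be in [0, 1]")

    ss = np.random.SeedSequence(seed)
    rng_counts, rng_scores = (np.random.default_rng(c) for c in ss.spawn(2))

    records: list[InspectionRecord] = []
    per_plate = len(_WELLS) * 2
    for idx in range(n_subwells):
        plate = f"PLATE-{idx // per_plate + 1:04d}"
        well = _WELLS[(idx % per_plate) // 2]
        subwell = idx % 2 + 1
        n_insp = int(rng_counts.integers(lo, hi + 1))
        for insp in range(1, n_insp + 1):
            records.append(
                InspectionRecord(
                    plate_barcode=plate,
                    well=well,
                    subwell=subwell,
                    inspection=insp,
                    image_id=f"{plate}_{well}_{subwell}_insp{insp}.png",
                )
            )

    n_scored = int(round(score_fraction * len(records)))
    scored_idx = set(
        rng_scores.choice(len(records), size=n_scored, replace=False).tolist()
    )
    for i in sorted(scored_idx):
        rec = records[i]
        records[i] = InspectionRecord(
            plate_barcode=rec.plate_barcode,
            well=rec.well,
            subwell=rec.subwell,
            inspection=rec.inspection,
            image_id=rec.image_id,
            score=int(rng_scores.integers(0, 10)),
        )
    return records


# ---------------------------------------------------------------------------
# Expert panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpertPanelSpec:
    """A panel of simulated experts, each with a 4 x 4 confusion matrix.

    ``confusion`` is either one row-stochastic matrix shared by all experts
    or one per expert (shape ``(n_experts, 4, 4)``), rows/columns ordered as
    :data:`dropsight.curation.CLASS_LABELS`.  Entry ``[t, j]`` is the
    probability that an expert labels a class-``t`` image as class ``j``.
    """

    n_experts: int = 3
    confusion: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        conf = (
            np.eye(len(CLASS_LABELS))
            if self.confusion is None
            else np.asarray(self.confusion, dtype=float)
        )
        if conf.ndim == 2:
            conf = np.broadcast_to(conf, (self.n_experts,) + conf.shape).copy()
        if conf.shape != (self.n_experts, len(CLASS_LABELS), len(CLASS_LABELS)):
            raise ValueError(
                f"confusion must be (4, 4) or (n_experts, 4, 4), got {conf.shape}"
            )
        if not np.allclose(conf.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("each confusion row must sum to 1 (+/- 1e-9)")
        if (conf < 0).any():
            raise ValueError("confusion entries must be non-negative")
        conf.setflags(write=False)
        object.__setattr__(self, "confusion", conf)


def simulate_expert_panel(
    true_labels: Sequence[str], panel: ExpertPanelSpec
) -> pd.DataFrame:
    """Simulate independent expert labels for each image.

    Returns a DataFrame indexed by image id (``image_0000`` ...) with one
    column per expert (``expert_1`` ...); each cell is drawn from that
    expert's confusion row for the image's true label.
    """
    if len(true_labels) == 0:
        raise ValueError("true_labels is empty")
    label_index = {lab: i for i, lab in enumerate(CLASS_LABELS)}
    try:
        truth_idx = np.array([label_index[lab] for lab in true_labels])
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc}") from exc

    ss = np.random.SeedSequence(panel.seed)
    columns = {}
    for e, child in enumerate(ss.spawn(panel.n_experts)):
        rng = np.random.default_rng(child)
        probs = panel.confusion[e][truth_idx]  # (n_images, 4)
        cum = probs.cumsum(axis=1)
        u = rng.uniform(size=len(true_labels))[:, None]
        drawn = (u < cum).argmax(axis=1)
        columns[f"expert_{e + 1}"] = [CLASS_LABELS[i] for i in drawn]
    index = [f"image_{i:04d}" for i in range(len(true_labels))]
    return pd.DataFrame(columns, index=pd.Index(index, name="image_id"))


# ---------------------------------------------------------------------------
# Mock detector
# ---------------------------------------------------------------------------

ScoreLaw = Callable[[np.random.Generator, bool], float]


def _resolve_score_law(score_law: float | ScoreLaw | None) -> ScoreLaw:
    if score_law is None:
        return lambda rng, is_spurious: 0.9
    if isinstance(score_law, (int, float)):
        value = float(score_law)
        return lambda rng, is_spurious: value
    return score_law


def mock_predictor(
    scene: SyntheticScene,
    drop_prob: float = 0.0,
    spurious_rate: float = 0.0,
    score_law: float | ScoreLaw | None = None,
    seed: int = 0,
    include_drop: bool = True,
) -> list[Detection]:
    """A stand-in detector with known corruption parameters.

    Each ground-truth crystal is emitted (with its exact mask) with
    probability ``1 - drop_prob``; spurious small-polygon crystal detections
    are added at Poisson rate ``spurious_rate`` per image.  Confidence scores
    come from ``score_law`` — a constant, or a callable
    ``(rng, is_spurious) -> float`` (default: constant 0.9).  When
    ``include_drop`` is true the drop mask is emitted as a 'drop' detection.
    """
    if not 0.0 <= drop_prob <= 1.0:
        raise ValueError("drop_prob must be in [0, 1]")
    if spurious_rate < 0:
        raise ValueError("spurious_rate must be >= 0")
    law = _resolve_score_law(score_law)
    ss = np.random.SeedSequence(seed)
    rng_keep, rng_spurious, rng_scores = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )

    detections: list[Detection] = []
    if include_drop and not scene.drop_mask.is_empty():
        detections.append(
            Detection(
                category="drop",
                probability=law(rng_scores, False),
                mask=scene.drop_mask,
            )
        )
    for mask in scene.crystal_masks:
        if rng_keep.uniform() < drop_prob:
            continue
        detections.append(
            Detection(
                category="crystal",
                probability=law(rng_scores, False),
                mask=mask,
            )
        )

    h = scene.provenance.image_height
    w = scene.provenance.image_width
    for _ in range(int(rng_spurious.poisson(spurious_rate))):
        for _attempt in range(50):
            cx = float(rng_spurious.uniform(2, w - 2))
            cy = float(rng_spurious.uniform(2, h - 2))
            size = float(rng_spurious.uniform(5, 15))
            k = int(rng_spurious.integers(3, 7))
            poly = _random_convex_polygon(rng_spurious, (cx, cy), size, k)
            try:
                mask = rasterize_polygon(poly, h, w)
            except ValueError:
                continue
            detections.append(
                Detection(
                    category="crystal",
                    probability=law(rng_scores, True),
                    mask=mask,
                )
            )
            break
    return detections
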