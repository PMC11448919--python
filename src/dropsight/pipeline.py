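"""Orchestration: configured end-to-end runs with on-disk artefacts.

Each ``run_*`` function is a thin, deterministic composition of the library
modules: it reads/writes the declared CSV/JSON/PNG formats, records a
manifest with the config hash and library versions, and leaves all science to
:mod:`dropsight.synthetic`, :mod:`dropsight.curation`,
:mod:`dropsight.targeting` and :mod:`dropsight.evaluation`.  The ``dropsight``
command-line interface in :mod:`dropsight.cli` wraps these functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .annotations import (
    ImageRecord,
    InstanceAnnotation,
    read_coco,
    rle_decode,
    write_coco,
)
from .curation import (
    CLASS_LABELS,
    InspectionRecord,
    build_consensus_sets,
    map_score_to_class,
    select_scored_images,
    split_train_val,
)
from .evaluation import COCO_THRESHOLDS, SIZE_BINS, classification_report, mean_ap
from .geometry import BinaryMask, Polygon, bbox_from_mask, rasterize_polygon
from .synthetic import (
    ExpertPanelSpec,
    SceneSpec,
    generate_scene,
    generate_inspection_table,
    mock_predictor,
    scene_annotations,
    simulate_expert_panel,
)
from .targeting import Detection, make_targets

__all__ = [
    "PredictorInterface",
    "PredictorContractError",
    "SimulateConfig",
    "run_simulate",
    "run_curate",
    "run_target",
    "run_evaluate_classify",
    "run_evaluate_detect",
    "read_coco_detections",
    "read_inspection_csv",
    "uniform_confusion",
]


class PredictorContractError(RuntimeError):
    """A predictor returned output violating the detection contract."""


@runtime_checkable
class PredictorInterface(Protocol):
    """The seam where a real trained detector can replace the mock one."""

    identity: str

    def __call__(self, image: ImageRecord) -> list[Detection]: ...


def _config_hash(config) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(out_dir: Path, config, extra: dict | None = None) -> None:
    manifest = {
        "dropsight_version": __version__,
        "numpy_version": np.__version__,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
    }
    if extra:
        manifest.update(extra)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )


def uniform_confusion(accuracy: float, n_classes: int = len(CLASS_LABELS)) -> np.ndarray:
    """Row-stochastic confusion matrix with uniform off-diagonal errors."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    off = (1.0 - accuracy) / (n_classes - 1)
    conf = np.full((n_classes, n_classes), off)
    np.fill_diagonal(conf, accuracy)
    return conf


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulateConfig:
    """Parameters of one synthetic-bundle run (all randomness from ``seed``)."""

    out_dir: str
    n_scenes: int = 5
    seed: int = 0
    image_height: int = 256
    image_width: int = 320
    crystal_count_range: tuple[int, int] = (0, 6)
    n_subwells: int = 50
    inspections_per_subwell: tuple[int, int] = (1, 4)
    score_fraction: float = 0.9
    n_experts: int = 3
    expert_accuracy: float = 0.85


def run_simulate(config: SimulateConfig) -> dict[str, Path]:
    """Write a scene bundle: PNGs, COCO ground truth, inspection + panel CSVs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    scene_seeds, table_seed, panel_seed = (
        s.generate_state(1)[0] % (2**31) for s in ss.spawn(3)
    )

    annotations: list[InstanceAnnotation] = []
    images: list[tuple[str, int, int]] = []
    true_labels: list[str] = []
    for i in range(config.n_scenes):
        spec = SceneSpec(
            image_height=config.image_height,
            image_width=config.image_width,
            # drop scaled to the frame so any image size is valid
            drop_axes=(0.38 * config.image_width, 0.37 * config.image_height),
            crystal_count_range=config.crystal_count_range,
            crystal_size_range=(
                0.04 * config.image_width,
                0.15 * config.image_width,
            ),
            seed=int(scene_seeds + i),
        )
        scene = generate_scene(spec)
        image_id = f"scene_{i:04d}.png"
        Image.fromarray(scene.image).save(out / image_id)
        images.append((image_id, spec.image_height, spec.image_width))
        annotations.extend(scene_annotations(scene, image_id))
        true_labels.append(map_score_to_class(scene.outcome_score))

    coco_path = out / "ground_truth.coco.json"
    coco_path.write_text(
        json.dumps(write_coco(annotations, images), sort_keys=True)
    )

    records = generate_inspection_table(
        n_subwells=config.n_subwells,
        inspections_per_subwell=config.inspections_per_subwell,
        score_fraction=config.score_fraction,
        seed=int(table_seed),
    )
    insp_path = out / "inspections.csv"
    pd.DataFrame(
        [
            {
                "plate_barcode": r.plate_barcode,
                "well": r.well,
                "subwell": r.subwell,
                "inspection": r.inspection,
                "score": r.score,
                "image_path": r.image_id,
            }
            for r in records
        ]
    ).to_csv(insp_path, index=False)

    panel_spec = ExpertPanelSpec(
        n_experts=config.n_experts,
        confusion=uniform_confusion(config.expert_accuracy),
        seed=int(panel_seed),
    )
    panel = simulate_expert_panel(true_labels, panel_spec)
    panel.index = pd.Index(
        [img_id for img_id, _, _ in images], name="image_id"
    )
    panel_path = out / "expert_panel.csv"
    panel.to_csv(panel_path)

    _write_manifest(out, config, {"n_annotations": len(annotations)})
    return {
        "coco": coco_path,
        "inspections": insp_path,
        "panel": panel_path,
        "manifest": out / "manifest.json",
    }


# ---------------------------------------------------------------------------
# curate
# ---------------------------------------------------------------------------


def read_inspection_csv(path: str | Path) -> list[InspectionRecord]:
    df = pd.read_csv(path)
    required = {"plate_barcode", "well", "subwell", "inspection", "score", "image_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"inspection CSV missing column(s): {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        score = None if pd.isna(row.score) else int(row.score)
        records.append(
            InspectionRecord(
                plate_barcode=str(row.plate_barcode),
                well=str(row.well),
                subwell=int(row.subwell),
                inspection=int(row.inspection),
                image_id=str(row.image_path),
                score=score,
            )
        )
    return records


def run_curate(
    inspections_csv: str | Path,
    panel_csv: str | Path | None,
    out_dir: str | Path,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
) -> dict:
    """Apply subwell de-duplication, class mapping, split and consensus rules.

    Writes ``split.csv`` (image_id, subset, label), optionally
    ``consensus.csv`` (image_id, set, label), and ``summary.json`` with
    per-class counts per subset.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_inspection_csv(inspections_csv)
    chosen = select_scored_images(records)
    if not chosen:
        raise ValueError("no scored images in the inspection table")
    labels = {sel.image_id: sel.label for sel in chosen.values()}
    split = split_train_val(
        labels.keys(),
        train_fraction=train_fraction,
        seed=seed,
        labels=labels if stratify else None,
    )
    rows = [
        {"image_id": img, "subset": "train" if img in split.train_ids else "val",
         "label": labels[img]}
        for img in sorted(labels)
    ]
    pd.DataFrame(rows).to_csv(out / "split.csv", index=False)

    summary: dict = {
        "n_images": len(labels),
        "n_train": len(split.train_ids),
        "n_val": len(split.val_ids),
        "class_counts": {
            subset: {
                cls: sum(
                    1 for r in rows if r["subset"] == subset and r["label"] == cls
                )
                for cls in CLASS_LABELS
            }
            for subset in ("train", "val")
        },
    }

    if panel_csv is not None:
        panel = pd.read_csv(panel_csv, index_col="image_id")
        consensus = build_consensus_sets(panel)
        crows = [
            {"image_id": img, "set": "unambiguous", "label": lab}
            for img, lab in sorted(consensus.unambiguous.items())
        ] + [
            {"image_id": img, "set": "mostly_unambiguous", "label": lab}
            for img, lab in sorted(consensus.mostly_unambiguous.items())
        ] + [
            {"image_id": img, "set": "discarded", "label": ""}
            for img in sorted(consensus.discarded)
        ]
        pd.DataFrame(crows).to_csv(out / "consensus.csv", index=False)
        summary["consensus_counts"] = {
            "unambiguous": len(consensus.unambiguous),
            "mostly_unambiguous": len(consensus.mostly_unambiguous),
            "discarded": len(consensus.discarded),
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


# ---------------------------------------------------------------------------
# target
# ---------------------------------------------------------------------------


def read_coco_detections(document: dict) -> dict[str, list[Detection]]:
    """Parse detector output in COCO form (annotations carry a ``score``)."""
    for key in ("images", "annotations", "categories"):
        if key not in document:
            raise ValueError(f"detections document missing key {key!r}")
    cat_names = {c["id"]: c["name"] for c in document["categories"]}
    images = {
        img["id"]: (str(img["file_name"]), int(img["height"]), int(img["width"]))
        for img in document["images"]
    }
    out: dict[str, list[Detection]] = {name: [] for name, _, _ in images.values()}
    for entry in document["annotations"]:
        image_id, h, w = images[entry["image_id"]]
        seg = entry["segmentation"]
        if isinstance(seg, dict):
            mask = rle_decode(seg)
        else:
            coords = seg[0]
            poly = Polygon(list(zip(coords[0::2], coords[1::2])))
            mask = rasterize_polygon(poly, h, w)
        out[image_id].append(
            Detection(
                category=cat_names[entry["category_id"]],
                probability=float(entry.get("score", 1.0)),
                mask=mask,
            )
        )
    return out


def _validate_predictor_output(
    image: ImageRecord, detections: Sequence[Detection]
) -> None:
    for det in detections:
        if not 0.0 <= det.probability <= 1.0:
            raise PredictorContractError(
                f"image {image.image_id}: probability {det.probability} "
                "outside [0, 1]"
            )
        if det.mask.shape != (image.height, image.width):
            raise PredictorContractError(
                f"image {image.image_id}: mask shape {det.mask.shape} does not "
                f"match image ({image.height}, {image.width})"
            )


def _overlay(image: ImageRecord, crystal_targets, dispense) -> np.ndarray:
    """Render targets onto the image: red dots for crystals, green cross for
    the dispense point."""
    arr = np.asarray(image.pixels)
    if arr.ndim == 2:
        rgb = np.stack([arr] * 3, axis=2).astype(np.uint8)
    else:
        rgb = arr.astype(np.uint8).copy()
    h, w = rgb.shape[:2]

    def blot(r: int, c: int, colour, radius: int = 3) -> None:
        r0, r1 = max(r - radius, 0), min(r + radius + 1, h)
        c0, c1 = max(c - radius, 0), min(c + radius + 1, w)
        rgb[r0:r1, c0:c1] = colour

    for t in crystal_targets:
        blot(int(t.y), int(t.x), (255, 0, 0), radius=2)
    if dispense is not None:
        arm = 6
        r, c = dispense.y, dispense.x
        rgb[max(r - arm, 0) : min(r + arm + 1, h), c] = (0, 255, 0)
        rgb[r, max(c - arm, 0) : min(c + arm + 1, w)] = (0, 255, 0)
    return rgb


def run_target(
    detections_per_image: dict[str, list[Detection]],
    out_csv: str | Path,
    min_probability: float = 0.6,
    overlay_dir: str | Path | None = None,
    images: dict[str, ImageRecord] | None = None,
) -> pd.DataFrame:
    """Emit crystal-centroid and dispense coordinates for each image.

    The output CSV has columns (image_id, kind, x, y, value) where ``value``
    is the detection probability for crystal targets and the clearance (in
    pixels) for dispense targets.
    """
    rows = []
    for image_id in sorted(detections_per_image):
        dets = detections_per_image[image_id]
        crystal_targets, dispense = make_targets(dets, min_probability)
        for t in crystal_targets:
            rows.append(
                {
                    "image_id": image_id,
                    "kind": "crystal",
                    "x": t.x,
                    "y": t.y,
                    "value": t.source_detection.probability
                    if t.source_detection
                    else float("nan"),
                }
            )
        if dispense is not None:
            rows.append(
                {
                    "image_id": image_id,
                    "kind": "dispense",
                    "x": dispense.x,
                    "y": dispense.y,
                    "value": dispense.clearance,
                }
            )
        if overlay_dir is not None and images is not None and image_id in images:
            overlay_path = Path(overlay_dir)
            overlay_path.mkdir(parents=True, exist_ok=True)
            rgb = _overlay(images[image_id], crystal_targets, dispense)
            Image.fromarray(rgb).save(overlay_path / f"{Path(image_id).stem}_targets.png")
    df = pd.DataFrame(rows, columns=["image_id", "kind", "x", "y", "value"])
    df.to_csv(out_csv, index=False)
    return df


def run_predict_and_target(
    images: Iterable[ImageRecord],
    predictor: PredictorInterface,
    out_csv: str | Path,
    min_probability: float = 0.6,
    overlay_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Predict with any :class:`PredictorInterface`, then derive targets."""
    image_map: dict[str, ImageRecord] = {}
    det_map: dict[str, list[Detection]] = {}
    for image in images:
        dets = predictor(image)
        _validate_predictor_output(image, dets)
        image_map[image.image_id] = image
        det_map[image.image_id] = dets
    return run_target(
        det_map,
        out_csv,
        min_probability=min_probability,
        overlay_dir=overlay_dir,
        images=image_map,
    )


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------


def run_evaluate_classify(
    truth_csv: str | Path, predictions_csv: str | Path, out_json: str | Path | None = None
) -> dict:
    """Per-class precision/recall/F1 and macro mean from two label CSVs.

    Both CSVs need columns ``image_id`` and ``label``; ids must match.
    """
    truth_df = pd.read_csv(truth_csv).set_index("image_id")
    pred_df = pd.read_csv(predictions_csv).set_index("image_id")
    missing = set(truth_df.index) ^ set(pred_df.index)
    if missing:
        raise ValueError(
            f"image-id sets differ between truth and predictions: {sorted(missing)[:10]}"
        )
    ids = sorted(truth_df.index)
    truth = [str(truth_df.loc[i, "label"]) for i in ids]
    pred = [str(pred_df.loc[i, "label"]) for i in ids]
    classes = sorted(set(truth) | set(pred))
    report = classification_report(truth, pred, classes)
    payload = {
        "classes": {
            cls: (
                None
                if m is None
                else {"precision": m.precision, "recall": m.recall, "f1": m.f1}
            )
            for cls, m in report.per_class.items()
        },
        "macro_f1": report.macro_f1,
        "n_images": len(ids),
    }
    if out_json is not None:
        Path(out_json).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload


def run_evaluate_detect(
    ground_truth_coco: dict,
    detections_coco: dict,
    out_csv: str | Path | None = None,
    thresholds: Sequence[float] = COCO_THRESHOLDS,
) -> pd.DataFrame:
    """mAP table (geometry, threshold, size, score) for COCO GT + detections."""
    gt_by_image, _ = read_coco(ground_truth_coco)
    det_by_image = read_coco_detections(detections_coco)
    rows = []
    for geometry in ("box", "mask"):
        result = mean_ap(gt_by_image, det_by_image, thresholds, geometry=geometry)
        for thr in thresholds:
            score = result.mean(thresholds=[float(thr)], size_bin="all")
            rows.append(
                {
                    "geometry": geometry,
                    "threshold": float(thr),
                    "size": "all",
                    "score": score,
                }
            )
        for size_bin in SIZE_BINS:
            rows.append(
                {
                    "geometry": geometry,
                    "threshold": "mean",
                    "size": size_bin,
                    "score": result.mean(size_bin=size_bin),
                }
            )
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
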