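"""Dataset-curation rules for scored crystallization-drop images.

Implements the bookkeeping that turns raw LIMS inspection records into a
classification dataset: the ten-score -> four-class outcome mapping, subwell
de-duplication (one image per time course), random train/validation splits,
inverse-frequency balancing weights, loss-ranked relabel flagging, balanced
test-pool sampling, and multi-expert consensus label construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "TEN_CLASS_NAMES",
    "InspectionRecord",
    "DatasetSplit",
    "ConsensusSets",
    "SelectedImage",
    "map_score_to_class",
    "select_scored_images",
    "split_train_val",
    "class_balance_weights",
    "flag_for_relabel",
    "stratified_sample",
    "sample_one_inspection_per_subwell",
    "build_consensus_sets",
    "pairwise_agreement",
]

#: The four-class outcome system used for classification.
CLASS_LABELS: tuple[str, ...] = ("Crystals", "Precipitate", "Clear", "Other")

#: Names of the ten-point in-house scoring system.
TEN_CLASS_NAMES: dict[int, str] = {
    0: "Clear",
    1: "Contaminated",
    2: "Light Precipitate",
    3: "Heavy Precipitate",
    4: "Phase Separation",
    5: "Spherulites",
    6: "Microcrystals",
    7: "1D Crystals",
    8: "2D Crystals",
    9: "3D Crystals",
}

_SCORE_TO_CLASS: dict[int, str] = {
    0: "Clear",
    1: "Other",
    2: "Precipitate",
    3: "Precipitate",
    4: "Other",
    5: "Other",
    6: "Crystals",
    7: "Crystals",
    8: "Crystals",
    9: "Crystals",
}


def map_score_to_class(score: int) -> str:
    """Map a ten-point outcome score (0-9) to its four-class label.

    0 -> Clear; {2, 3} -> Precipitate; {1, 4, 5} -> Other;
    {6, 7, 8, 9} -> Crystals.
    """
    try:
        return _SCORE_TO_CLASS[int(score)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(f"score must be an integer in 0-9, got {score!r}") from None


@dataclass(frozen=True)
class InspectionRecord:
    """One imaging pass of one subwell, optionally carrying an outcome score."""

    plate_barcode: str
    well: str
    subwell: int
    inspection: int
    image_id: str
    score: int | None = None

    def __post_init__(self) -> None:
        if self.inspection < 1:
            raise ValueError("inspection numbers start at 1")
        if self.score is not None and not 0 <= self.score <= 9:
            raise ValueError(f"score must be in 0-9, got {self.score}")

    @property
    def subwell_key(self) -> tuple[str, str, int]:
        return (self.plate_barcode, self.well, self.subwell)


@dataclass(frozen=True)
class SelectedImage:
    """The image chosen to represent a subwell, with its score and label."""

    image_id: str
    inspection: int
    score: int

    @property
    def label(self) -> str:
        return map_score_to_class(self.score)


def select_scored_images(
    records: Iterable[InspectionRecord],
) -> dict[tuple[str, str, int], SelectedImage]:
    """Choose one scored image per subwell to remove time-course redundancy.

    Per subwell: a single scored inspection is taken as-is; with two or more
    scored inspections, the one with the second-lowest inspection number is
    taken (the first inspection often pre-dates any outcome of interest).
    Unscored records are ignored; subwells with no scored image are absent
    from the result.
    """
    grouped: dict[tuple[str, str, int], list[InspectionRecord]] = {}
    for rec in records:
        if rec.score is None:
            continue
        grouped.setdefault(rec.subwell_key, []).append(rec)

    chosen: dict[tuple[str, str, int], SelectedImage] = {}
    for key, recs in grouped.items():
        recs.sort(key=lambda r: r.inspection)
        pick = recs[0] if len(recs) == 1 else recs[1]
        chosen[key] = SelectedImage(
            image_id=pick.image_id, inspection=pick.inspection, score=pick.score
        )
    return chosen


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validation id sets covering the input set."""

    train_ids: frozenset[str]
    val_ids: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.train_ids & self.val_ids:
            raise ValueError("train and validation sets overlap")


def split_train_val(
    image_ids: Iterable[str],
    train_fraction: float = 0.8,
    seed: int = 0,
    labels: Mapping[str, str] | None = None,
) -> DatasetSplit:
    """Randomly split ids into train/validation sets.

    The training set has ``round(train_fraction * N)`` members.  If
    ``labels`` is given the split is stratified per class, with the same
    rounding applied within each class (largest classes first absorb the
    rounding remainder so the global size is preserved).
    """
    ids = sorted(set(map(str, image_ids)))
    n = len(ids)
    if n == 0:
        raise ValueError("cannot split an empty id set")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))

    if labels is None:
        perm = rng.permutation(n)
        train = frozenset(ids[i] for i in perm[:n_train])
    else:
        train_list: list[str] = []
        by_class: dict[str, list[str]] = {}
        for i in ids:
            by_class.setdefault(labels[i], []).append(i)
        # deterministic class order: biggest first, ties by name
        ordered = sorted(by_class.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        remaining = n_train
        for k, (cls, members) in enumerate(ordered):
            if k == len(ordered) - 1:
                take = remaining
            else:
                take = min(int(round(train_fraction * len(members))), remaining)
            perm = rng.permutation(len(members))
            train_list.extend(members[i] for i in perm[:take])
            remaining -= take
        train = frozenset(train_list)

    val = frozenset(ids) - train
    return DatasetSplit(train_ids=train, val_ids=val, seed=seed)


def class_balance_weights(labels: Sequence[str]) -> np.ndarray:
    """Per-item sampling weights inversely proportional to class frequency.

    Weighted sampling with replacement under these weights draws every
    observed class with equal expected frequency.  Weights sum to 1.
    """
    if len(labels) == 0:
        raise ValueError("label list is empty")
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    n_classes = len(counts)
    weights = np.array([1.0 / (n_classes * counts[lab]) for lab in labels])
    return weights


def flag_for_relabel(
    losses: Mapping[str, float], fraction: float = 0.05
) -> set[str]:
    """Flag the highest-loss ``ceil(fraction * N)`` images for expert review.

    Ties at the cut are broken by ascending image id so the flagged set is
    deterministic.
    """
    if not losses:
        raise ValueError("loss map is empty")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(losses))
    ranked = sorted(losses.items(), key=lambda kv: (-kv[1], kv[0]))
    return {image_id for image_id, _ in ranked[:k]}


def stratified_sample(
    pool: Mapping[str, str],
    targets: Mapping[str, int],
    seed: int = 0,
) -> set[str]:
    """Draw exact per-class counts uniformly without replacement.

    Raises a ``ValueError`` naming the class and shortfall if the pool cannot
    satisfy any requested count.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for image_id in sorted(pool):
        by_class.setdefault(pool[image_id], []).append(image_id)

    picked: set[str] = set()
    for cls in sorted(targets):
        want = targets[cls]
        if want < 0:
            raise ValueError(f"negative target for class {cls!r}")
        if want == 0:
            continue
        members = by_class.get(cls, [])
        if len(members) < want:
            raise ValueError(
                f"class {cls!r} has {len(members)} candidates, "
                f"{want - len(members)} short of the target {want}"
            )
        idx = rng.choice(len(members), size=want, replace=False)
        picked.update(members[i] for i in idx)
    return picked


def sample_one_inspection_per_subwell(
    records: Iterable[InspectionRecord],
    inspection_range: tuple[int, int] = (2, 7),
    seed: int = 0,
) -> dict[tuple[str, str, int], str]:
    """Pick one image per subwell time course, uniformly within a window.

    Subwells with fewer than two inspections in total are excluded first
    (single-inspection subwells tend to be one-off experiments, not monitored
    time courses).  Among the rest, one image with inspection number inside
    ``inspection_range`` (inclusive) is chosen uniformly at random per
    subwell; subwells with no inspection in the window are omitted.
    """
    lo, hi = inspection_range
    if lo > hi:
        raise ValueError("inspection_range must satisfy lo <= hi")
    rng = np.random.default_rng(seed)
    grouped: dict[tuple[str, str, int], list[InspectionRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.subwell_key, []).append(rec)

    out: dict[tuple[str, str, int], str] = {}
    for key in sorted(grouped):
        recs = grouped[key]
        if len({r.inspection for r in recs}) < 2:
            continue
        eligible = sorted(
            (r for r in recs if lo <= r.inspection <= hi),
            key=lambda r: r.inspection,
        )
        if not eligible:
            continue
        out[key] = eligible[rng.integers(len(eligible))].image_id
    return out


@dataclass(frozen=True)
class ConsensusSets:
    """Expert-consensus label sets.

    ``unambiguous`` holds unanimously labelled images, ``mostly_unambiguous``
    additionally holds majority-labelled ones (so the unambiguous ids are a
    subset), and ``discarded`` holds images with no majority label.
    """

    unambiguous: dict[str, str]
    mostly_unambiguous: dict[str, str]
    discarded: frozenset[str]

    def __post_init__(self) -> None:
        if not set(self.unambiguous) <= set(self.mostly_unambiguous):
            raise ValueError("unambiguous ids must be in the mostly-unambiguous set")


def _panel_rows(panel) -> Iterable[tuple[str, list]]:
    if isinstance(panel, pd.DataFrame):
        for image_id, row in panel.iterrows():
            yield str(image_id), list(row.values)
    else:
        for image_id, labels in panel.items():
            yield str(image_id), list(labels)


def build_consensus_sets(panel) -> ConsensusSets:
    """Partition panel-labelled images by expert agreement.

    ``panel`` is a mapping ``image_id -> [label per expert]`` or a DataFrame
    with one column per expert, indexed by image id.  Unanimous images enter
    both consensus sets; images where a strict majority (> n/2) of experts
    agree enter the mostly-unambiguous set with the modal label; the rest are
    discarded.  A missing label raises a ``ValueError``.
    """
    unambiguous: dict[str, str] = {}
    mostly: dict[str, str] = {}
    discarded: set[str] = set()
    for image_id, labels in _panel_rows(panel):
        if len(labels) == 0 or any(lab is None or lab != lab for lab in labels):
            raise ValueError(f"image {image_id!r} has a missing expert label")
        counts: dict[str, int] = {}
        for lab in labels:
            counts[str(lab)] = counts.get(str(lab), 0) + 1
        modal, modal_count = max(counts.items(), key=lambda kv: kv[1])
        if modal_count == len(labels):
            unambiguous[image_id] = modal
            mostly[image_id] = modal
        elif modal_count > len(labels) / 2:
            mostly[image_id] = modal
        else:
            discarded.add(image_id)
    return ConsensusSets(
        unambiguous=unambiguous,
        mostly_unambiguous=mostly,
        discarded=frozenset(discarded),
    )


def pairwise_agreement(labels_a: Sequence, labels_b: Sequence) -> float:
    """Fraction of positions at which two label vectors agree."""
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"length mismatch: {len(labels_a)} vs {len(labels_b)}"
        )
    if len(labels_a) == 0:
        raise ValueError("label vectors are empty")
    same = sum(1 for a, b in zip(labels_a, labels_b) if a == b)
    return same / len(labels_a)
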