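"""Ellipse-ROI annotations and labelled-pixel sampling.

Training supervision is drawn by hand as rotated ellipses, each carrying one
of three class labels:

1. empty/bright background (unstained white space),
2. isolated endomysial microvessels (small dark blobs),
3. perimysial vessel agglomerates (large dark clusters).

An annotation selects every pixel whose centre lies strictly inside the
ellipse. Pixel (x, y) is identified with the continuous point (x, y) — array
index coordinates are pixel centres — so a circle of radius 1.4 centred on a
pixel selects the 5-pixel plus shape around it.

Annotations are serialised as a JSON list of objects
``{"image": str, "class": 1|2|3, "cx": float, "cy": float, "a": float,
"b": float, "theta_deg": float}``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptySelectionError, FormatError, IncompleteTrainingSetError
from .image_io import GrayImage

__all__ = [
    "CLASS_LABELS",
    "EllipseAnnotation",
    "TrainingSet",
    "pixels_in_ellipse",
    "build_training_set",
    "load_annotations",
    "save_annotations",
]

logger = logging.getLogger(__name__)

#: The fixed three-class scheme: background / isolated microvessel / agglomerate.
CLASS_LABELS = (1, 2, 3)


@dataclass(frozen=True)
class EllipseAnnotation:
    """A rotated elliptical ROI with a class label.

    ``cx, cy`` are the centre in pixel-index coordinates (x = column,
    y = row); ``a, b`` are the semi-axes in pixels; ``theta`` is the
    counter-clockwise rotation of the a-axis in radians.
    """

    image_id: str
    class_label: int
    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise FormatError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        if not (self.a > 0 and self.b > 0):
            raise FormatError(f"semi-axes must be strictly positive, got a={self.a}, b={self.b}")


def pixels_in_ellipse(ann: EllipseAnnotation, shape: tuple[int, int]) -> np.ndarray:
    """All pixel coordinates strictly inside the ellipse, clipped to bounds.

    Parameters
    ----------
    ann : EllipseAnnotation
    shape : (height, width) of the target image.

    Returns
    -------
    (n, 2) int array of (row, col) pairs in row-major order. May be empty
    for an ellipse too small to contain any pixel centre.

    Raises
    ------
    EmptySelectionError
        If the ellipse's bounding box lies entirely outside the image.
    """
    h, w = shape
    r = max(ann.a, ann.b)
    if ann.cx + r < 0 or ann.cx - r > w - 1 or ann.cy + r < 0 or ann.cy - r > h - 1:
        raise EmptySelectionError(
            f"ellipse at ({ann.cx}, {ann.cy}) with semi-axes ({ann.a}, {ann.b}) "
            f"lies entirely outside a {w}x{h} image"
        )
    x0 = max(0, int(math.floor(ann.cx - r)))
    x1 = min(w - 1, int(math.ceil(ann.cx + r)))
    y0 = max(0, int(math.floor(ann.cy - r)))
    y1 = min(h - 1, int(math.ceil(ann.cy + r)))
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    dx = xs - ann.cx
    dy = ys - ann.cy
    ct, st = math.cos(ann.theta), math.sin(ann.theta)
    u = (dx * ct + dy * st) / ann.a
    v = (-dx * st + dy * ct) / ann.b
    inside = u * u + v * v < 1.0  # strict: tiny ellipses select nothing
    coords = np.column_stack([ys[inside], xs[inside]])
    return coords.astype(np.intp)


@dataclass(frozen=True)
class TrainingSet:
    """Labelled pixel samples ready for forest training.

    ``X`` is the (n_samples, n_features) feature matrix; ``y`` the class
    labels; ``pixel_keys`` identifies each sample as (image_id, row, col) so
    train/eval leakage can be detected.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    image_ids: tuple[str, ...]
    pixel_keys: frozenset = field(repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts)}


def build_training_set(
    annotations: Sequence[EllipseAnnotation],
    images: Mapping[str, GrayImage],
    extractor,
) -> TrainingSet:
    """Extract one feature-vector sample per annotated pixel.

    Multiple ellipses of the same class pool (and deduplicate) their pixels.
    A pixel claimed by two *different* classes is dropped with a logged
    warning: ambiguous supervision is worse than less supervision.

    Raises
    ------
    IncompleteTrainingSetError
        If any of the three classes ends up with zero samples.
    KeyError
        If an annotation references an image that was not supplied.
    """
    by_image: dict[str, list[EllipseAnnotation]] = {}
    for ann in annotations:
        if ann.image_id not in images:
            raise KeyError(f"annotation references unknown image {ann.image_id!r}")
        by_image.setdefault(ann.image_id, []).append(ann)

    X_parts: list[np.ndarray] = []
    y_parts: list[np.ndarray] = []
    keys: set[tuple[str, int, int]] = set()
    n_conflicts = 0
    for image_id in sorted(by_image):
        img = images[image_id]
        h, w = img.pixels.shape
        # claim[y, x]: 0 unclaimed, 1..3 single class, -1 conflicting classes
        claim = np.zeros((h, w), dtype=np.int8)
        for ann in by_image[image_id]:
            coords = pixels_in_ellipse(ann, (h, w))
            if len(coords) == 0:
                continue
            cur = claim[coords[:, 0], coords[:, 1]]
            conflict = (cur != 0) & (cur != ann.class_label)
            claim[coords[:, 0], coords[:, 1]] = np.where(
                conflict, -1, ann.class_label
            ).astype(np.int8)
        n_img_conflicts = int((claim == -1).sum())
        if n_img_conflicts:
            n_conflicts += n_img_conflicts
            logger.warning(
                "%s: %d pixel(s) claimed by conflicting classes were dropped",
                image_id,
                n_img_conflicts,
            )
        feats = extractor.transform(img)
        for label in CLASS_LABELS:
            rows, cols = np.nonzero(claim == label)
            if len(rows) == 0:
                continue
            X_parts.append(feats[rows, cols, :])
            y_parts.append(np.full(len(rows), label, dtype=np.int64))
            keys.update((image_id, int(r), int(c)) for r, c in zip(rows, cols))

    y = np.concatenate(y_parts) if y_parts else np.empty(0, dtype=np.int64)
    missing = set(CLASS_LABELS) - set(np.unique(y).tolist())
    if missing:
        raise IncompleteTrainingSetError(missing)
    X = np.concatenate(X_parts, axis=0)
    return TrainingSet(
        X=X,
        y=y,
        feature_names=tuple(extractor.feature_names),
        image_ids=tuple(sorted(by_image)),
        pixel_keys=frozenset(keys),
    )


def _validate_entry(obj: dict, index: int) -> EllipseAnnotation:
    required = {"image", "class", "cx", "cy", "a", "b"}
    missing = required - obj.keys()
    if missing:
        raise FormatError(
            f"annotation entry {index}: missing field(s) {sorted(missing)}"
        )
    cls = obj["class"]
    if cls not in CLASS_LABELS:
        raise FormatError(f"annotation entry {index}: class must be 1, 2 or 3, got {cls!r}")
    try:
        return EllipseAnnotation(
            image_id=str(obj["image"]),
            class_label=int(cls),
            cx=float(obj["cx"]),
            cy=float(obj["cy"]),
            a=float(obj["a"]),
            b=float(obj["b"]),
            theta=math.radians(float(obj.get("theta_deg", 0.0))),
        )
    except (TypeError, ValueError) as exc:
        raise FormatError(f"annotation entry {index}: {exc}") from exc


def load_annotations(path: str | Path) -> list[EllipseAnnotation]:
    """Read annotations from a JSON file, validating every entry.

    Errors name the zero-based entry index at fault.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except OSError as exc:
        raise FormatError(f"cannot read annotations {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(data, list):
        raise FormatError(f"{path}: top level must be a JSON list")
    return [_validate_entry(obj, i) for i, obj in enumerate(data)]


def save_annotations(annotations: Iterable[EllipseAnnotation], path: str | Path) -> None:
    records = [
        {
            "image": a.image_id,
            "class": a.class_label,
            "cx": a.cx,
            "cy": a.cy,
            "a": a.a,
            "b": a.b,
            "theta_deg": math.degrees(a.theta),
        }
        for a in annotations
    ]
    Path(path).write_text(json.dumps(records, indent=1))
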