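"""Threshold filtering of probability maps and percent-area quantification.

The microvessel density readout is the fraction of image pixels whose
class-2 (isolated microvessel) posterior, rendered on the 8-bit gray scale,
falls inside an inclusive intensity band — by default [45, 255], i.e. a
posterior of roughly 0.18 or higher. Retained pixels are painted red in the
overlay rendering, and the statistic reported per image is

    percent_area = 100 * retained_pixels / total_pixels

with the whole image as the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .forest import PixelForestClassifier, ProbabilityMap
from .image_io import DEFAULT_GATE_BOUNDS, GrayImage, brightness_gate

__all__ = [
    "DEFAULT_GRAY_BOUNDS",
    "QuantResult",
    "threshold_filter",
    "render_overlay",
    "extract_mask_from_overlay",
    "batch_quantify",
]

#: Stage-6 default intensity band on the rendered probability map, matching
#: the manual counting procedure's threshold setting.
DEFAULT_GRAY_BOUNDS = (45, 255)

OVERLAY_RED = (255, 0, 0)


@dataclass(frozen=True)
class QuantResult:
    """Filtered-pixel mask and percent-area statistic for one image."""

    image_id: str
    class_label: int
    mask: np.ndarray
    gray_low: int
    gray_high: int

    @property
    def retained_count(self) -> int:
        return int(self.mask.sum())

    @property
    def total_count(self) -> int:
        return int(self.mask.size)

    @property
    def percent_area(self) -> float:
        return 100.0 * self.retained_count / self.total_count


def threshold_filter(
    pmap: ProbabilityMap,
    gray_low: int = DEFAULT_GRAY_BOUNDS[0],
    gray_high: int = DEFAULT_GRAY_BOUNDS[1],
) -> QuantResult:
    """Retain pixels whose rendered gray value lies in [gray_low, gray_high].

    Both bounds are inclusive: white (255) marks the highest posterior and
    must be retained.

    Raises
    ------
    ParameterError
        If the bounds are inverted or outside [0, 255].
    """
    if not (0 <= gray_low <= gray_high <= 255):
        raise ParameterError(
            f"require 0 <= gray_low <= gray_high <= 255, got [{gray_low}, {gray_high}]"
        )
    g = pmap.gray_render
    mask = (g >= gray_low) & (g <= gray_high)
    return QuantResult(
        image_id=pmap.image_id,
        class_label=pmap.class_label,
        mask=mask,
        gray_low=int(gray_low),
        gray_high=int(gray_high),
    )


def render_overlay(img: GrayImage, qr: QuantResult) -> np.ndarray:
    """RGB rendering with retained pixels painted pure red (255, 0, 0).

    Non-retained pixels carry the grayscale value on all three channels, so
    the mask round-trips losslessly: a pixel is red iff it was retained
    (a gray pixel always has equal channels; (255, 0, 0) never does).
    """
    if qr.mask.shape != img.pixels.shape:
        raise ParameterError(
            f"mask shape {qr.mask.shape} does not match image shape {img.pixels.shape}"
        )
    rgb = np.repeat(img.pixels[:, :, None], 3, axis=2)
    rgb[qr.mask] = OVERLAY_RED
    return rgb


def extract_mask_from_overlay(overlay: np.ndarray) -> np.ndarray:
    """Recover the retained-pixel mask from an overlay rendering."""
    return (
        (overlay[:, :, 0] == OVERLAY_RED[0])
        & (overlay[:, :, 1] == OVERLAY_RED[1])
        & (overlay[:, :, 2] == OVERLAY_RED[2])
    )


def batch_quantify(
    model: PixelForestClassifier,
    images: Sequence[GrayImage],
    class_label: int = 2,
    gray_low: int = DEFAULT_GRAY_BOUNDS[0],
    gray_high: int = DEFAULT_GRAY_BOUNDS[1],
    gate_bounds: tuple[float, float] | None = DEFAULT_GATE_BOUNDS,
    overlay_dir: str | Path | None = None,
) -> tuple[list[QuantResult], pd.DataFrame]:
    """Quantify a batch of images, one CSV-ready report row per image.

    Images failing the brightness gate are recorded as skipped with the
    gate's reason, never silently dropped. Pass ``gate_bounds=None`` to
    disable the gate.

    Returns
    -------
    (results, report) where ``results`` holds a :class:`QuantResult` per
    gated-in image and ``report`` has one row per input image with columns
    image_id, status, reason, mean_intensity, retained_count, total_count,
    percent_area.
    """
    results: list[QuantResult] = []
    rows: list[dict] = []
    for img in images:
        if gate_bounds is not None:
            verdict = brightness_gate(img, *gate_bounds)
        else:
            verdict = None
        if verdict is not None and not verdict.passed:
            rows.append(
                {
                    "image_id": img.source_id,
                    "status": "skipped",
                    "reason": verdict.reason,
                    "mean_intensity": img.mean_intensity,
                    "retained_count": pd.NA,
                    "total_count": img.pixels.size,
                    "percent_area": pd.NA,
                }
            )
            continue
        pmap = model.predict_maps(img)[class_label]
        qr = threshold_filter(pmap, gray_low, gray_high)
        results.append(qr)
        rows.append(
            {
                "image_id": img.source_id,
                "status": "ok",
                "reason": "",
                "mean_intensity": img.mean_intensity,
                "retained_count": qr.retained_count,
                "total_count": qr.total_count,
                "percent_area": qr.percent_area,
            }
        )
        if overlay_dir is not None:
            from PIL import Image

            overlay = render_overlay(img, qr)
            out = Path(overlay_dir) / f"{img.source_id}.overlay.png"
            Image.fromarray(overlay, mode="RGB").save(out)
    columns = [
        "image_id",
        "status",
        "reason",
        "mean_intensity",
        "retained_count",
        "total_count",
        "percent_area",
    ]
    report = pd.DataFrame(rows, columns=columns)
    return results, report
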