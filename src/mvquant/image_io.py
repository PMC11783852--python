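"""Raster image input/output, grayscale conversion and brightness gating.

Histology photomicrographs arrive as RGB (or already-gray) TIFF/PNG files.
The pipeline operates on 8-bit grayscale rasters throughout: all probability
renderings and filter thresholds live on a [0, 255] scale, so 16-bit inputs
are reduced to 8 bits on load.

Very dark (under-exposed) or washed-out images make the pixel classifier
unreliable; :func:`brightness_gate` implements the mean-intensity
pre-selection guard applied before batch quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import FormatError, ImageIOError

__all__ = [
    "RawImage",
    "GrayImage",
    "GateVerdict",
    "load_image",
    "to_grayscale",
    "brightness_gate",
    "save_gray_png",
    "DEFAULT_GATE_BOUNDS",
]

# ITU-R BT.601 luma weights.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: Default mean-intensity bounds for the brightness gate. Images with mean
#: gray below 40 are rejected as too dark for reliable classification; above
#: 250 as washed out. Both are configurable everywhere the gate is applied.
DEFAULT_GATE_BOUNDS = (40.0, 250.0)


@dataclass(frozen=True)
class RawImage:
    """An 8-bit RGB raster with provenance metadata.

    ``pixels`` has shape (height, width, 3), dtype uint8, channel order RGB.
    ``pixel_size_um`` is recorded when known but never used for resampling.
    """

    pixels: np.ndarray
    source_id: str
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.dtype != np.uint8:
            raise FormatError(
                f"RawImage requires a (H, W, 3) uint8 array, got shape "
                f"{p.shape} dtype {p.dtype}"
            )
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise FormatError("RawImage must be at least 1x1")
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayImage:
    """A single-channel 8-bit raster, values in [0, 255]."""

    pixels: np.ndarray
    source_id: str
    pixel_size_um: float | None = None
    mean_intensity: float = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.dtype != np.uint8:
            raise FormatError(
                f"GrayImage requires a (H, W) uint8 array, got shape "
                f"{p.shape} dtype {p.dtype}"
            )
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise FormatError("GrayImage must be at least 1x1")
        object.__setattr__(self, "pixels", p)
        object.__setattr__(self, "mean_intensity", float(p.mean()))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GateVerdict:
    """Outcome of the brightness pre-selection gate."""

    passed: bool
    mean_intensity: float
    reason: str | None = None

    def to_json_record(self, image_id: str) -> dict:
        return {
            "image": image_id,
            "gate": "pass" if self.passed else "fail",
            "mean_intensity": self.mean_intensity,
            "reason": self.reason,
        }


def _to_uint8(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        # full-range reduction: 65535 -> 255
        return (arr >> 8).astype(np.uint8)
    if arr.dtype == bool:
        return arr.astype(np.uint8) * 255
    raise FormatError(f"{path}: unsupported pixel dtype {arr.dtype}; expected 8- or 16-bit integer")


def load_image(path: str | Path, pixel_size_um: float | None = None) -> RawImage:
    """Read a TIFF or PNG file into a :class:`RawImage`.

    Grayscale files are replicated across the three channels; an alpha
    channel, if present, is dropped. 16-bit samples are linearly rescaled to
    8-bit (integer division of the full range).
    """
    path = Path(path)
    if not path.is_file():
        raise ImageIOError(f"cannot read image: no such file {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(str(path))
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = _to_uint8(arr, path)
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] in (3, 4):
        arr = _to_uint8(arr, path)[:, :, :3]
    else:
        raise FormatError(f"{path}: unsupported image shape {arr.shape}")
    return RawImage(pixels=arr, source_id=path.stem, pixel_size_um=pixel_size_um)


def to_grayscale(img: RawImage) -> GrayImage:
    """Convert an RGB raster to 8-bit grayscale with BT.601 luma weights.

    gray = round(0.299 R + 0.587 G + 0.114 B), clamped to [0, 255]. Already
    gray inputs (R = G = B = v) map to v exactly.
    """
    wr, wg, wb = GRAY_WEIGHTS
    rgb = img.pixels.astype(np.float64)
    gray = wr * rgb[:, :, 0] + wg * rgb[:, :, 1] + wb * rgb[:, :, 2]
    gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    return GrayImage(pixels=gray, source_id=img.source_id, pixel_size_um=img.pixel_size_um)


def brightness_gate(
    img: GrayImage,
    min_mean: float = DEFAULT_GATE_BOUNDS[0],
    max_mean: float = DEFAULT_GATE_BOUNDS[1],
) -> GateVerdict:
    """Pass/fail verdict on mean intensity.

    Fails with reason ``"too dark"`` when the mean gray level is below
    ``min_mean`` and ``"too bright"`` when above ``max_mean``.
    """
    m = img.mean_intensity
    if m < min_mean:
        return GateVerdict(passed=False, mean_intensity=m, reason="too dark")
    if m > max_mean:
        return GateVerdict(passed=False, mean_intensity=m, reason="too bright")
    return GateVerdict(passed=True, mean_intensity=m)


def save_gray_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write a (H, W) uint8 array as a single-channel 8-bit PNG."""
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.dtype != np.uint8:
        raise FormatError("save_gray_png expects a (H, W) uint8 array")
    Image.fromarray(arr, mode="L").save(Path(path))
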