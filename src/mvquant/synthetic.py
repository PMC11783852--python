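"""Synthetic immunostain-like images with pixel-exact ground truth.

Brightfield immunohistochemistry rendered in grayscale shows stained
vessels as dark structures on a bright background. The generator emulates
that geometry at controllable density:

* class 1 — bright background (slide + unstained tissue),
* class 2 — small isolated dark discs (endomysial microvessels),
* class 3 — large dark multi-blob agglomerates (perimysial vessels).

Every structure is rasterised with an explicit inclusive rule
(dist² <= r²), the label raster is exact, and the true class-2 percent area
is computed from it — so the full pipeline can be scored against known
ground truth without any external data. Identical spec + seed reproduce the
image and labels bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .annotations import EllipseAnnotation, pixels_in_ellipse
from .errors import ParameterError, PlacementError
from .image_io import GrayImage

__all__ = ["SyntheticSpec", "generate", "generate_annotations", "spec_for_density"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic histology image.

    Intensities are on the 8-bit gray scale. ``vessel_intensity_mean`` must
    be darker than ``background_mean`` (stained structures absorb light);
    set ``invert=True`` for fluorescence-like polarity.
    """

    width: int = 512
    height: int = 512
    background_mean: float = 230.0
    background_sd: float = 3.0
    n_microvessels: int = 250
    microvessel_radius_range: tuple[float, float] = (2.0, 4.0)
    n_perimysial_clusters: int = 3
    cluster_blob_count: int = 6
    cluster_blob_radius: float = 12.0
    vessel_intensity_mean: float = 70.0
    vessel_intensity_sd: float = 8.0
    noise_sd: float = 5.0
    seed: int = 0
    invert: bool = False
    image_id: str | None = None

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ParameterError("canvas must be at least 1x1")
        if self.vessel_intensity_mean >= self.background_mean:
            raise ParameterError(
                "vessel_intensity_mean must be below background_mean "
                "(stained structures are darker than the background)"
            )
        lo, hi = self.microvessel_radius_range
        if not (0 < lo <= hi):
            raise ParameterError(f"bad microvessel_radius_range {self.microvessel_radius_range}")
        if min(self.n_microvessels, self.n_perimysial_clusters, self.cluster_blob_count) < 0:
            raise ParameterError("structure counts must be non-negative")


def _disc_coords(cy: float, cx: float, r: float, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pixels with (y-cy)^2 + (x-cx)^2 <= r^2, clipped to bounds."""
    h, w = shape
    y0 = max(0, int(math.floor(cy - r)))
    y1 = min(h - 1, int(math.ceil(cy + r)))
    x0 = max(0, int(math.floor(cx - r)))
    x1 = min(w - 1, int(math.ceil(cx + r)))
    if y0 > y1 or x0 > x1:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = (ys - cy) ** 2 + (xs - cx) ** 2 <= r * r
    return ys[inside], xs[inside]


def _place_clusters(spec: SyntheticSpec, labels: np.ndarray, rng: np.random.Generator) -> list[tuple]:
    """Paint class-3 agglomerates; returns the painted blob geometry."""
    h, w = labels.shape
    blobs: list[tuple] = []
    extent = 2.5 * spec.cluster_blob_radius
    margin = min(extent, (min(h, w) - 1) / 2)
    for _ in range(spec.n_perimysial_clusters):
        ccy = rng.uniform(margin, h - 1 - margin)
        ccx = rng.uniform(margin, w - 1 - margin)
        for _ in range(spec.cluster_blob_count):
            # overlapping blobs jittered around the cluster centre
            by = ccy + rng.normal(0, spec.cluster_blob_radius * 0.8)
            bx = ccx + rng.normal(0, spec.cluster_blob_radius * 0.8)
            br = spec.cluster_blob_radius * rng.uniform(0.6, 1.0)
            ys, xs = _disc_coords(by, bx, br, labels.shape)
            labels[ys, xs] = 3
            blobs.append((by, bx, br))
    return blobs


def _place_microvessels(
    spec: SyntheticSpec, labels: np.ndarray, rng: np.random.Generator, gap: float = 3.0
) -> list[tuple]:
    """Paint isolated class-2 discs, keeping a clear band around each."""
    h, w = labels.shape
    discs: list[tuple] = []
    lo, hi = spec.microvessel_radius_range
    max_attempts = 200 * max(spec.n_microvessels, 1)
    attempts = 0
    while len(discs) < spec.n_microvessels:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {spec.n_microvessels} isolated microvessels "
                f"on a {w}x{h} canvas after {max_attempts} attempts "
                f"({len(discs)} placed); reduce the density"
            )
        attempts += 1
        r = rng.uniform(lo, hi)
        cy = rng.uniform(r + gap, h - 1 - r - gap) if h - 1 > 2 * (r + gap) else (h - 1) / 2
        cx = rng.uniform(r + gap, w - 1 - r - gap) if w - 1 > 2 * (r + gap) else (w - 1) / 2
        gy, gx = _disc_coords(cy, cx, r + gap, labels.shape)
        if np.any(labels[gy, gx] != 1):
            continue
        ys, xs = _disc_coords(cy, cx, r, labels.shape)
        if len(ys) == 0:
            continue
        labels[ys, xs] = 2
        discs.append((cy, cx, r))
    return discs


def generate(spec: SyntheticSpec) -> tuple[GrayImage, np.ndarray, float]:
    """Render one synthetic image.

    Returns
    -------
    (image, labels, true_percent) where ``labels`` is an (H, W) uint8
    raster in {1, 2, 3} and ``true_percent`` is the exact class-2 pixel
    percentage of the whole image.

    Raises
    ------
    PlacementError
        If the requested structures cannot be placed without overlap
        within a bounded number of retries.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    labels = np.ones(shape, dtype=np.uint8)
    blobs = _place_clusters(spec, labels, rng)
    discs = _place_microvessels(spec, labels, rng)

    img = spec.background_mean + rng.normal(0.0, spec.background_sd, shape)
    for by, bx, br in blobs:
        ys, xs = _disc_coords(by, bx, br, shape)
        img[ys, xs] = spec.vessel_intensity_mean + rng.normal(0.0, spec.vessel_intensity_sd)
    for cy, cx, r in discs:
        ys, xs = _disc_coords(cy, cx, r, shape)
        img[ys, xs] = spec.vessel_intensity_mean + rng.normal(0.0, spec.vessel_intensity_sd)
    img = img + rng.normal(0.0, spec.noise_sd, shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if spec.invert:
        img = (255 - img).astype(np.uint8)

    true_percent = 100.0 * float(np.sum(labels == 2)) / labels.size
    image_id = spec.image_id if spec.image_id is not None else f"synthetic-{spec.seed}"
    return GrayImage(pixels=img, source_id=image_id), labels, true_percent


def generate_annotations(
    truth: np.ndarray,
    per_class: int = 3,
    seed: int = 0,
    image_id: str = "synthetic",
    axes_range: tuple[float, float] = (0.9, 2.6),
    boundary_fraction: float = 0.5,
    boundary_dist: float = 3.0,
    max_attempts_per_ellipse: int = 2000,
) -> list[EllipseAnnotation]:
    """Draw pure ellipse annotations on a ground-truth label raster.

    Emulates the manual annotation step: for each class, ``per_class``
    random ellipses are placed so that every selected pixel carries that
    class (100% purity), by rejection sampling centred on random pixels of
    the class. Deterministic under ``seed``.

    Following standard trainable-segmentation practice, a fraction of the
    background (class 1) ellipses is centred within ``boundary_dist``
    pixels of a stained structure: annotators outline background tight
    against vessels so the classifier learns the bright/dark boundary,
    which is what keeps vessel halos out of the positive class.

    Raises
    ------
    PlacementError
        If a class is absent from the raster or too small to host any
        pure ellipse within the attempt budget.
    """
    truth = np.asarray(truth)
    rng = np.random.default_rng(seed)
    dist_to_structure = ndimage.distance_transform_edt(truth == 1)
    brows, bcols = np.nonzero((truth == 1) & (dist_to_structure > 0) & (dist_to_structure <= boundary_dist))
    annotations: list[EllipseAnnotation] = []
    for cls in (1, 2, 3):
        rows, cols = np.nonzero(truth == cls)
        if len(rows) == 0:
            raise PlacementError(f"ground truth contains no class-{cls} pixels")
        placed = 0
        attempts = 0
        while placed < per_class:
            if attempts >= max_attempts_per_ellipse * per_class:
                raise PlacementError(
                    f"could not place {per_class} pure ellipses for class {cls} "
                    f"after {attempts} attempts; the class region is too fragmented"
                )
            attempts += 1
            if cls == 1 and placed < per_class * boundary_fraction and len(brows) > 0:
                i = int(rng.integers(len(brows)))
                cy, cx = brows[i], bcols[i]
            else:
                i = int(rng.integers(len(rows)))
                cy, cx = rows[i], cols[i]
            ann = EllipseAnnotation(
                image_id=image_id,
                class_label=cls,
                cx=float(cx + rng.uniform(-0.4, 0.4)),
                cy=float(cy + rng.uniform(-0.4, 0.4)),
                a=float(rng.uniform(*axes_range)),
                b=float(rng.uniform(*axes_range)),
                theta=float(rng.uniform(0.0, math.pi)),
            )
            coords = pixels_in_ellipse(ann, truth.shape)
            if len(coords) == 0:
                continue
            if np.all(truth[coords[:, 0], coords[:, 1]] == cls):
                annotations.append(ann)
                placed += 1
    return annotations


# mean in-disc pixel count for the default radius range, used only to pick
# how many discs approximate a requested density; the returned truth percent
# is always exact.
def _mean_disc_area(radius_range: tuple[float, float]) -> float:
    lo, hi = radius_range
    # E[pi r^2] for r ~ U(lo, hi)
    return math.pi * (hi**3 - lo**3) / (3.0 * (hi - lo)) if hi > lo else math.pi * lo**2


def spec_for_density(
    target_percent: float,
    seed: int,
    width: int = 512,
    height: int = 512,
    image_id: str | None = None,
    **overrides,
) -> SyntheticSpec:
    """A spec whose class-2 area approximates ``target_percent``.

    The disc count is chosen from the expected disc area; the exact class-2
    percentage still comes from the generated label raster.
    """
    base = SyntheticSpec(width=width, height=height, seed=seed, image_id=image_id, **overrides)
    n = max(1, round(target_percent / 100.0 * width * height / _mean_disc_area(base.microvessel_radius_range)))
    return replace(base, n_microvessels=int(n))
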