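import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mvquant import (
    EllipseAnnotation,
    GrayImage,
    MultiscaleFeatureExtractor,
    build_training_set,
    generate,
    generate_annotations,
    spec_for_density,
    train,
)

settings.register_profile(
    "mvquant",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("mvquant")

# Three uniform horizontal bands with disjoint intensities: bright background
# (class 1), dark microvessel-like (class 2), mid-gray agglomerate-like
# (class 3). Cleanly separable by intensity alone — the canonical sanity
# fixture for the classifier.
BAND_VALUES = {1: 220, 2: 30, 3: 130}
BAND_SIGMAS = (1.0, 2.0)


def make_band_image(image_id: str, size: int = 96) -> tuple[GrayImage, np.ndarray]:
    third = size // 3
    pixels = np.empty((size, size), dtype=np.uint8)
    labels = np.empty((size, size), dtype=np.uint8)
    for i, cls in enumerate((1, 2, 3)):
        pixels[i * third : (i + 1) * third if cls != 3 else size] = BAND_VALUES[cls]
        labels[i * third : (i + 1) * third if cls != 3 else size] = cls
    return GrayImage(pixels=pixels, source_id=image_id), labels


def band_annotations(image_id: str, size: int = 96, x: float = 48.0) -> list[EllipseAnnotation]:
    third = size // 3
    return [
        EllipseAnnotation(image_id=image_id, class_label=cls, cx=x,
                          cy=(cls - 0.5) * third, a=3.0, b=3.0)
        for cls in (1, 2, 3)
    ]


@pytest.fixture(scope="session")
def band_extractor():
    return MultiscaleFeatureExtractor(sigmas=BAND_SIGMAS)


@pytest.fixture(scope="session")
def band_training_set(band_extractor):
    img, _ = make_band_image("band-train")
    anns = band_annotations("band-train")
    return build_training_set(anns, {"band-train": img}, band_extractor)


@pytest.fixture(scope="session")
def band_model(band_training_set):
    return train(band_training_set, n_trees=50, seed=7, sigmas=BAND_SIGMAS)


def train_on_fixtures(n_images=12, size=256, density=4.0, seed=0, n_trees=200, per_class=3):
    """Train a default-feature model on generated fixture images."""
    extractor = MultiscaleFeatureExtractor()
    images, anns = {}, []
    for i in range(n_images):
        image_id = f"train-{seed}-{i}"
        spec = spec_for_density(density, seed=1000 * seed + i, width=size, height=size,
                                image_id=image_id)
        img, truth, _ = generate(spec)
        images[image_id] = img
        anns += generate_annotations(truth, per_class=per_class, seed=1000 * seed + i,
                                     image_id=image_id)
    ts = build_training_set(anns, images, extractor)
    return train(ts, n_trees=n_trees, seed=seed), ts


@pytest.fixture(scope="session")
def fixture_model_256():
    """A model trained on 12 synthetic 256x256 images (seed 0), reused by
    the heavier end-to-end tests."""
    model, _ = train_on_fixtures(seed=0)
    return model
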