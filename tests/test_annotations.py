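import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mvquant import (
    EllipseAnnotation,
    GrayImage,
    MultiscaleFeatureExtractor,
    build_training_set,
    load_annotations,
    pixels_in_ellipse,
    save_annotations,
)
from mvquant.errors import EmptySelectionError, FormatError, IncompleteTrainingSetError


def ellipse(cls=1, cx=5.0, cy=5.0, a=1.4, b=1.4, theta=0.0, image="img"):
    return EllipseAnnotation(image_id=image, class_label=cls, cx=cx, cy=cy, a=a, b=b, theta=theta)


def brute_force_interior(ann, shape):
    """Independent per-pixel point-in-ellipse loop (the test oracle)."""
    h, w = shape
    out = []
    ct, st_ = math.cos(ann.theta), math.sin(ann.theta)
    for y in range(h):
        for x in range(w):
            dx, dy = x - ann.cx, y - ann.cy
            u = (dx * ct + dy * st_) / ann.a
            v = (-dx * st_ + dy * ct) / ann.b
            if u * u + v * v < 1.0:
                out.append((y, x))
    return out


class TestPixelsInEllipse:
    def test_small_circle_selects_plus_shape(self):
        coords = pixels_in_ellipse(ellipse(cx=5, cy=5, a=1.4, b=1.4), (11, 11))
        assert {tuple(c) for c in coords} == {(5, 5), (4, 5), (6, 5), (5, 4), (5, 6)}

    def test_tiny_circle_on_pixel_centre_selects_one_pixel(self):
        coords = pixels_in_ellipse(ellipse(cx=5, cy=5, a=0.4, b=0.4), (11, 11))
        assert [tuple(c) for c in coords] == [(5, 5)]

    def test_fully_outside_raises(self):
        with pytest.raises(EmptySelectionError):
            pixels_in_ellipse(ellipse(cx=-100, cy=-100), (10, 10))

    def test_row_major_ordering(self):
        coords = pixels_in_ellipse(ellipse(cx=4, cy=4, a=2.6, b=1.7, theta=0.5), (12, 12))
        as_tuples = [tuple(c) for c in coords]
        assert as_tuples == sorted(as_tuples)

    def test_clipped_to_image_bounds(self):
        coords = pixels_in_ellipse(ellipse(cx=0, cy=0, a=3, b=3), (8, 8))
        assert (coords >= 0).all()

    @given(
        cx=st.floats(-4, 35), cy=st.floats(-4, 35),
        a=st.floats(0.3, 9), b=st.floats(0.3, 9),
        theta=st.floats(0, math.pi),
        h=st.integers(4, 32), w=st.integers(4, 32),
    )
    def test_agrees_with_bruteforce_oracle(self, cx, cy, a, b, theta, h, w):
        ann = ellipse(cx=cx, cy=cy, a=a, b=b, theta=theta)
        try:
            coords = pixels_in_ellipse(ann, (h, w))
        except EmptySelectionError:
            assert brute_force_interior(ann, (h, w)) == []
            return
        assert [tuple(c) for c in coords] == brute_force_interior(ann, (h, w))


@pytest.fixture(scope="module")
def tiny_setup():
    extractor = MultiscaleFeatureExtractor(sigmas=(1.0,))
    img = GrayImage(pixels=np.full((16, 16), 120, np.uint8), source_id="img")
    return extractor, {"img": img}


class TestBuildTrainingSet:
    def test_one_pixel_per_class(self, tiny_setup):
        extractor, images = tiny_setup
        anns = [ellipse(cls=c, cx=3 * c, cy=3 * c, a=0.4, b=0.4) for c in (1, 2, 3)]
        ts = build_training_set(anns, images, extractor)
        assert ts.n_samples == 3
        assert ts.class_counts == {1: 1, 2: 1, 3: 1}
        assert ts.X.shape == (3, extractor.n_features)

    def test_same_class_ellipses_pool_additively(self, tiny_setup):
        extractor, images = tiny_setup
        anns = [
            ellipse(cls=2, cx=4, cy=4),
            ellipse(cls=2, cx=11, cy=11),
            ellipse(cls=1, cx=4, cy=11, a=0.4, b=0.4),
            ellipse(cls=3, cx=11, cy=4, a=0.4, b=0.4),
        ]
        ts = build_training_set(anns, images, extractor)
        assert ts.class_counts[2] == 10  # two disjoint 5-pixel plus shapes

    def test_same_class_overlap_deduplicated(self, tiny_setup):
        extractor, images = tiny_setup
        anns = [
            ellipse(cls=2, cx=5, cy=5),
            ellipse(cls=2, cx=5, cy=5),  # identical: same 5 pixels
            ellipse(cls=1, cx=11, cy=11, a=0.4, b=0.4),
            ellipse(cls=3, cx=11, cy=4, a=0.4, b=0.4),
        ]
        ts = build_training_set(anns, images, extractor)
        assert ts.class_counts[2] == 5

    def test_cross_class_conflict_dropped_with_warning(self, tiny_setup, caplog):
        extractor, images = tiny_setup
        anns = [
            ellipse(cls=2, cx=5, cy=5),
            ellipse(cls=3, cx=5, cy=5, a=0.4, b=0.4),  # centre pixel claimed twice
            ellipse(cls=1, cx=11, cy=11, a=0.4, b=0.4),
            ellipse(cls=3, cx=11, cy=4, a=0.4, b=0.4),
        ]
        with caplog.at_level("WARNING"):
            ts = build_training_set(anns, images, extractor)
        assert ts.class_counts[2] == 4  # centre pixel dropped
        assert "conflicting classes" in caplog.text

    def test_missing_class_raises_naming_it(self, tiny_setup):
        extractor, images = tiny_setup
        anns = [ellipse(cls=c, cx=3 * c, cy=3 * c) for c in (1, 2)]
        with pytest.raises(IncompleteTrainingSetError, match="3"):
            build_training_set(anns, images, extractor)

    def test_unknown_image_rejected(self, tiny_setup):
        extractor, images = tiny_setup
        with pytest.raises(KeyError, match="ghost"):
            build_training_set([ellipse(image="ghost")], images, extractor)

    def test_sample_count_matches_interior_pixel_sum(self, tiny_setup):
        extractor, images = tiny_setup
        anns = [
            ellipse(cls=1, cx=3, cy=3, a=2.1, b=1.3),
            ellipse(cls=2, cx=10, cy=4, a=1.8, b=1.8),
            ellipse(cls=3, cx=5, cy=11, a=1.1, b=2.4),
        ]
        ts = build_training_set(anns, images, extractor)
        expected = sum(len(pixels_in_ellipse(a, (16, 16))) for a in anns)
        assert ts.n_samples == expected


class TestAnnotationJSON:
    def test_round_trip(self, tmp_path):
        anns = [ellipse(cls=2, cx=3.5, cy=7.25, a=1.5, b=2.5, theta=0.7)]
        path = tmp_path / "ann.json"
        save_annotations(anns, path)
        back = load_annotations(path)
        assert back[0].class_label == 2
        assert back[0].theta == pytest.approx(0.7)

    @pytest.mark.parametrize(
        "payload, message",
        [
            ([{"image": "i", "class": 5, "cx": 1, "cy": 1, "a": 1, "b": 1}], "class must be"),
            ([{"image": "i", "class": 2, "cx": 1, "cy": 1}], "missing field"),
            ({"image": "i"}, "top level"),
        ],
    )
    def test_invalid_entries_report_position(self, tmp_path, payload, message):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(FormatError, match=message):
            load_annotations(path)

    def test_unparseable_json(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("[{")
        with pytest.raises(FormatError, match="not valid JSON"):
            load_annotations(path)


def test_nonpositive_axes_rejected():
    with pytest.raises(FormatError):
        ellipse(a=0.0)
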