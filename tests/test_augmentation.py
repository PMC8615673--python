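"""Counting and geometry of the training-set augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from masscontext.augmentation import (
    AugmentationPlan,
    augment_region,
    build_training_set,
    orientation_variants,
    sliding_window_count,
    sliding_window_crops,
)
from masscontext.datatypes import (
    ROI,
    ROI_SIZE,
    BoundingBox,
    GrayImage,
    Label,
    MassRegion,
    Provenance,
)


def _region(image_shape, bbox, label=Label.BENIGN, seed=0):
    rng = np.random.default_rng(seed)
    pixels = rng.integers(0, 256, image_shape).astype(np.uint8)
    return MassRegion(GrayImage(pixels), BoundingBox(*bbox), label=label)


def _brute_force_count(bbox, image_shape, window, stride):
    """Independent enumeration of every valid stride-spaced placement."""
    win_r, win_c = window
    lo_r = max(0, bbox.row_max - win_r)
    lo_c = max(0, bbox.col_max - win_c)
    count = 0
    for r in range(lo_r, image_shape[0], stride):
        for c in range(lo_c, image_shape[1], stride):
            ok = (
                r <= bbox.row_min
                and c <= bbox.col_min
                and r + win_r >= bbox.row_max
                and c + win_c >= bbox.col_max
                and r + win_r <= image_shape[0]
                and c + win_c <= image_shape[1]
            )
            count += ok
    return count


class TestSlidingWindows:
    def test_nine_crops_on_centered_mass(self):
        # 244x244 image, 200x200 mass centered: offsets 0..20 both axes
        region = _region((244, 244), (22, 22, 222, 222))
        crops = sliding_window_crops(region, (224, 224), stride=10)
        assert len(crops) == 9
        assert all(c.pixels.shape == (ROI_SIZE, ROI_SIZE) for c in crops)

    def test_window_equal_to_image_gives_one_crop(self):
        region = _region((300, 280), (50, 40, 200, 220))
        crops = sliding_window_crops(region, (300, 280), stride=10)
        assert len(crops) == 1

    def test_window_smaller_than_bbox_rejected(self):
        region = _region((300, 300), (50, 50, 250, 250))
        with pytest.raises(ValueError):
            sliding_window_crops(region, (150, 150))

    @given(
        rows=st.integers(230, 400), cols=st.integers(230, 400),
        h=st.integers(30, 180), w=st.integers(30, 180),
        r0=st.integers(0, 60), c0=st.integers(0, 60),
        stride=st.sampled_from([5, 10, 20]),
    )
    @settings(max_examples=100, deadline=None)
    def test_count_matches_brute_force_enumeration(
        self, rows, cols, h, w, r0, c0, stride
    ):
        bbox = BoundingBox(r0, c0, r0 + h, c0 + w)
        window = (224, 224)
        expected = _brute_force_count(bbox, (rows, cols), window, stride)
        region = _region((rows, cols), bbox.as_tuple())
        assert sliding_window_count(bbox, (rows, cols), window, stride) == expected
        crops = sliding_window_crops(region, window, stride)
        assert len(crops) == expected
        # every placement stays inside the image and contains the bbox
        for c in crops:
            rr, cc = map(int, c.provenance.crop_position.split(","))
            assert 0 <= rr <= rows - 224 and 0 <= cc <= cols - 224
            assert rr <= bbox.row_min and rr + 224 >= bbox.row_max
            assert cc <= bbox.col_min and cc + 224 >= bbox.col_max


class TestOrientations:
    def _asymmetric_roi(self):
        rng = np.random.default_rng(4)
        return ROI(rng.uniform(0, 255, (ROI_SIZE, ROI_SIZE)),
                   Provenance("window", 0))

    def test_eight_distinct_variants_on_asymmetric_input(self):
        roi = self._asymmetric_roi()
        variants = orientation_variants(roi)
        assert len(variants) == 8
        flat = [v.pixels.tobytes() for v in variants]
        assert len(set(flat)) == 8  # no accidental symmetry

    def test_identity_and_group_property(self):
        roi = self._asymmetric_roi()
        variants = orientation_variants(roi)
        np.testing.assert_array_equal(variants[0].pixels, roi.pixels)
        # rotating the 90-degree variant by 90 again gives the 180 variant
        again = orientation_variants(
            ROI(variants[1].pixels, Provenance("window", 0)), angles=(90,), flip=False
        )[0]
        np.testing.assert_array_equal(again.pixels, variants[2].pixels)

    def test_flip_is_involution(self):
        roi = self._asymmetric_roi()
        np.testing.assert_array_equal(roi.pixels[:, ::-1][:, ::-1], roi.pixels)


class TestTrainingSet:
    def test_count_composition(self):
        # 9 windows x 8 orientations + 2 scale ROIs = 74
        region = _region((244, 244), (22, 22, 222, 222))
        plan = AugmentationPlan(window_margin=24)  # window 200+24 = 224
        samples = augment_region(region, plan)
        assert len(samples) == 9 * 8 + 2

    def test_labels_inherited_everywhere(self):
        region = _region((260, 260), (40, 40, 200, 200), label=Label.MALIGNANT)
        samples = augment_region(region, AugmentationPlan())
        assert samples and all(s.label == int(Label.MALIGNANT) for s in samples)

    def test_unlabeled_region_rejected(self):
        region = _region((260, 260), (40, 40, 200, 200))
        region.label = None
        with pytest.raises(ValueError):
            augment_region(region)

    def test_empty_input_gives_empty_manifest(self):
        assert build_training_set([]) == []

    def test_deterministic(self):
        region = _region((260, 260), (40, 40, 200, 200))
        a = build_training_set([region])
        b = build_training_set([region])
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.transform == y.transform
            np.testing.assert_array_equal(x.roi.pixels, y.roi.pixels)
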