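"""Geometry of the two context-extraction schemes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from masscontext.datatypes import BoundingBox, GrayImage, MassRegion, ROI_SIZE
from masscontext.roi_context import (
    expand_bbox,
    extract_multicontext_rois,
    extract_multiscale_rois,
    extract_rois,
    isotropic_rescale_to_base,
    n_rois,
)


def _region(image_shape=(400, 400), bbox=(150, 150, 250, 250), seed=0):
    rng = np.random.default_rng(seed)
    pixels = rng.integers(0, 256, image_shape).astype(np.uint8)
    return MassRegion(GrayImage(pixels), BoundingBox(*bbox))


class TestExpandBbox:
    @pytest.mark.parametrize(
        "bbox, percent, expected",
        [
            ((100, 100, 200, 200), 0, (100, 100, 200, 200)),
            ((100, 100, 200, 200), 50, (50, 50, 250, 250)),
            ((0, 0, 100, 100), 50, (0, 0, 150, 150)),  # clamped at origin
        ],
    )
    def test_expansion_arithmetic(self, bbox, percent, expected):
        out = expand_bbox(BoundingBox(*bbox), percent, (1000, 1000))
        assert out.as_tuple() == expected

    def test_negative_percent_rejected(self):
        with pytest.raises(ValueError):
            expand_bbox(BoundingBox(10, 10, 20, 20), -1, (100, 100))

    def test_bbox_outside_image_rejected(self):
        with pytest.raises(ValueError):
            expand_bbox(BoundingBox(10, 10, 200, 200), 10, (100, 100))

    @given(
        r0=st.integers(0, 300), c0=st.integers(0, 300),
        h=st.integers(1, 100), w=st.integers(1, 100),
        percent=st.floats(0, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_result_contains_input(self, r0, c0, h, w, percent):
        bbox = BoundingBox(r0, c0, r0 + h, c0 + w)
        out = expand_bbox(bbox, percent, (500, 500))
        assert out.contains(bbox)
        assert out.within((500, 500))
        if percent == 0:
            assert out == bbox


class TestIsotropicRescale:
    @pytest.mark.parametrize(
        "in_shape, out_shape",
        [
            ((128, 160), (256, 320)),
            ((256, 300), (256, 300)),
            ((300, 512), (256, 437)),  # 512 * 256/300 = 436.9, half-up
            ((512, 300), (437, 256)),
        ],
    )
    def test_output_dimensions(self, in_shape, out_shape):
        out = isotropic_rescale_to_base(np.zeros(in_shape))
        assert out.shape == out_shape
        assert min(out.shape) == 256


class TestMultiScale:
    def test_one_roi_per_scale_ascending(self):
        rois = extract_multiscale_rois(_region(), {50, 60, 70, 80, 100})
        assert len(rois) == 5
        scales = [r.provenance.scale_percent for r in rois]
        assert scales == sorted(scales) == [50, 60, 70, 80, 100]
        assert all(r.pixels.shape == (ROI_SIZE, ROI_SIZE) for r in rois)

    def test_zero_scale_is_tight_crop(self):
        region = _region()
        rois = extract_multiscale_rois(region, {0})
        assert len(rois) == 1
        from masscontext.roi_context import resize_bilinear

        np.testing.assert_allclose(
            rois[0].pixels, resize_bilinear(region.crop(), (ROI_SIZE, ROI_SIZE))
        )

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            extract_multiscale_rois(_region(), set())

    @given(
        a=st.floats(0, 80), b=st.floats(0, 80),
    )
    @settings(max_examples=50, deadline=None)
    def test_crops_nested_by_scale(self, a, b):
        """For an interior bbox, the pre-resize crop window at the smaller
        scale is geometrically contained in the larger one."""
        region = _region()
        lo, hi = sorted([a, b])
        box_lo = expand_bbox(region.bbox, lo, region.image.shape)
        box_hi = expand_bbox(region.bbox, hi, region.image.shape)
        assert box_hi.contains(box_lo)


class TestMultiContext:
    def test_eleven_rois_all_fixed_size(self, benign_region):
        rois = extract_multicontext_rois(benign_region)
        assert len(rois) == 11
        assert all(r.pixels.shape == (ROI_SIZE, ROI_SIZE) for r in rois)

    def test_fixed_order_and_flip_pairing(self):
        region = _region(bbox=(100, 100, 228, 260))  # crop 128x160 -> 256x320
        rois = extract_multicontext_rois(region)
        positions = [r.provenance.crop_position for r in rois]
        assert positions == [
            "full", "top_left", "top_right", "bottom_left", "bottom_right",
            "center",
            "top_left", "top_right", "bottom_left", "bottom_right", "center",
        ]
        assert [r.provenance.flipped for r in rois] == [False] * 6 + [True] * 5
        # each flipped ROI is the exact mirror of its unflipped partner
        for plain, flip in zip(rois[1:6], rois[6:]):
            np.testing.assert_array_equal(flip.pixels, plain.pixels[:, ::-1])

    def test_corner_offsets_on_rectangular_crop(self):
        # crop 128x160 rescales to 256x320; verify crops equal manual slices
        region = _region(bbox=(100, 100, 228, 260))
        rescaled = isotropic_rescale_to_base(region.crop())
        assert rescaled.shape == (256, 320)
        rois = extract_multicontext_rois(region)
        expected_offsets = {
            "top_left": (0, 0), "top_right": (0, 96),
            "bottom_left": (32, 0), "bottom_right": (32, 96),
            "center": (16, 48),
        }
        for roi in rois[1:6]:
            r0, c0 = expected_offsets[roi.provenance.crop_position]
            np.testing.assert_allclose(
                roi.pixels, rescaled[r0 : r0 + 224, c0 : c0 + 224]
            )

    def test_square_crop_emits_duplicated_corners(self):
        region = _region(bbox=(100, 100, 228, 228))  # square -> 256x256
        rois = extract_multicontext_rois(region)
        assert len(rois) == 11
        tl, bl = rois[1].pixels, rois[3].pixels
        rescaled = isotropic_rescale_to_base(region.crop())
        np.testing.assert_allclose(tl, rescaled[:224, :224])
        np.testing.assert_allclose(bl, rescaled[32:, :224])

    def test_three_context_variant(self, benign_region):
        rois = extract_rois(benign_region, "MC1")
        assert len(rois) == 3
        assert [r.provenance.crop_position for r in rois] == [
            "full", "center", "center",
        ]
        np.testing.assert_array_equal(rois[2].pixels, rois[1].pixels[:, ::-1])


class TestSchemes:
    @pytest.mark.parametrize(
        "scheme, expected",
        [("single", 1), ("MS1", 5), ("MS2", 5), ("MS3", 5), ("MC1", 3), ("MC2", 11)],
    )
    def test_scheme_roi_counts(self, benign_region, scheme, expected):
        assert n_rois(scheme) == expected
        assert len(extract_rois(benign_region, scheme)) == expected

    def test_extraction_is_deterministic(self, malignant_region):
        a = extract_rois(malignant_region, "MC2")
        b = extract_rois(malignant_region, "MC2")
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.pixels, y.pixels)
            assert x.provenance == y.provenance
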