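"""Mask products and background subtraction against direct oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import grey_dilation, grey_erosion, uniform_filter
from skimage.filters import threshold_isodata

from chromodyn import (
    GeometryError,
    ParameterError,
    RoiRect,
    TimelapseStack,
    damage_area_mask,
    foci_mask,
    segment_nuclei,
    subtract_background,
)


def dna_stack(frames, pixel_size=0.072):
    frames = np.asarray(frames, dtype=float)
    return TimelapseStack(
        data=frames[:, None],
        time_s=np.arange(len(frames), dtype=float) + 1.0,
        pixel_size_um=pixel_size,
        channel_roles={"dna": 0},
    )


def disk_frame(shape, centers, radius, value=100.0, rng=None):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    frame = np.zeros(shape)
    for cy, cx in centers:
        frame[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    if rng is not None:
        frame = rng.poisson(frame + 1.0).astype(float)
    return frame


class TestSegmentNuclei:
    def test_all_zero_frames_give_empty_masks(self):
        masks = segment_nuclei(dna_stack(np.zeros((3, 64, 64))))
        assert masks.shape == (3, 64, 64)
        assert masks.max() == 0

    def test_single_disk_matches_threshold_oracle(self):
        frame = disk_frame((96, 96), [(48, 48)], 20)
        masks = segment_nuclei(dna_stack([frame]), min_area_px=100)
        assert masks.max() == 1
        oracle = frame > threshold_isodata(frame)
        np.testing.assert_array_equal(masks[0] > 0, oracle)

    def test_two_disks_get_stable_distinct_labels(self):
        frame = disk_frame((96, 96), [(30, 30), (70, 70)], 12)
        masks = segment_nuclei(dna_stack([frame] * 4), min_area_px=100)
        for t in range(4):
            assert set(np.unique(masks[t])) == {0, 1, 2}
            np.testing.assert_array_equal(masks[t], masks[0])
        # the two objects really are disjoint components
        assert not ((masks[0] == 1) & (masks[0] == 2)).any()

    def test_segmentation_is_idempotent(self):
        frame = disk_frame((96, 96), [(30, 30), (70, 70)], 12)
        first = segment_nuclei(dna_stack([frame]), min_area_px=100)
        second = segment_nuclei(
            dna_stack([(first[0] > 0).astype(float)]), min_area_px=100
        )
        np.testing.assert_array_equal(first, second)

    def test_min_area_filters_debris(self):
        frame = disk_frame((96, 96), [(48, 48)], 20)
        frame[5, 5] = 500.0  # hot pixel
        masks = segment_nuclei(dna_stack([frame]), min_area_px=100)
        assert masks[0][5, 5] == 0
        assert masks.max() == 1


class TestDamageAreaMask:
    def test_full_frame_roi_is_identity(self):
        labels = np.zeros((2, 32, 32), dtype=int)
        labels[:, 5:20, 5:20] = 1
        out = damage_area_mask(labels, RoiRect(0, 0, 32, 32))
        np.testing.assert_array_equal(out, labels)

    def test_disjoint_roi_gives_empty(self):
        labels = np.zeros((1, 32, 32), dtype=int)
        labels[0, :10, :10] = 1
        out = damage_area_mask(labels, RoiRect(20, 20, 10, 10))
        assert out.max() == 0

    def test_half_overlap_pixel_count_matches_set_intersection(self):
        labels = np.zeros((1, 64, 64), dtype=int)
        labels[0, 10:40, 10:40] = 1
        roi = RoiRect(0, 0, 25, 64)
        out = damage_area_mask(labels, roi)
        brute = {
            (y, x)
            for y in range(64)
            for x in range(64)
            if labels[0, y, x] and 0 <= x < 25
        }
        assert (out > 0).sum() == len(brute)

    def test_output_is_subset_of_input(self, rng):
        labels = (rng.random((3, 48, 48)) > 0.6).astype(int)
        out = damage_area_mask(labels, RoiRect(5, 7, 20, 13))
        assert np.all((out > 0) <= (labels > 0))

    def test_roi_outside_frame_raises(self):
        with pytest.raises(GeometryError):
            damage_area_mask(np.zeros((1, 32, 32), int), RoiRect(20, 20, 20, 20))


class TestFociMask:
    def test_eighty_percent_of_max(self):
        frame = np.arange(64, dtype=float).reshape(8, 8) + 37  # max 100
        mask = foci_mask(frame, fraction=0.8)
        np.testing.assert_array_equal(mask, frame >= 80)

    def test_constant_frame_selects_everything(self):
        assert foci_mask(np.full((8, 8), 7.0)).all()

    def test_fraction_one_selects_only_argmax(self):
        frame = np.zeros((8, 8))
        frame[3, 4] = 10
        mask = foci_mask(frame, fraction=1.0)
        assert mask.sum() == 1 and mask[3, 4]

    def test_all_zero_frame_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            mask = foci_mask(np.zeros((8, 8)))
        assert not mask.any()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        lo=st.floats(0.05, 0.5),
        hi=st.floats(0.55, 1.0),
        seed=st.integers(0, 100),
    )
    def test_raising_fraction_never_adds_pixels(self, lo, hi, seed):
        frame = np.random.default_rng(seed).random((16, 16)) + 0.01
        assert np.all(foci_mask(frame, hi) <= foci_mask(frame, lo))


class TestSubtractBackground:
    def test_constant_frame_goes_to_zero(self):
        out = subtract_background(
            dna_stack([np.full((64, 64), 42.0)]), rolling_ball_radius_px=20
        )
        assert np.allclose(out.channel("dna")[0], 0.0)

    def test_blob_preserved_offset_removed_vs_opening_oracle(self):
        """A compact blob on a flat offset survives (within 5% of the
        smoothed peak); the offset is fully removed; the whole image agrees
        with a grey-opening (ball structuring element) oracle."""
        yy, xx = np.mgrid[0:64, 0:64]
        blob = 50.0 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 3.0**2))
        frame = blob + 20.0
        out = subtract_background(
            dna_stack([frame]), smooth_radius_px=1, rolling_ball_radius_px=30
        ).channel("dna")[0]

        smoothed = uniform_filter(frame, 3)
        r = 30
        by, bx = np.mgrid[-r : r + 1, -r : r + 1]
        d2 = (by**2 + bx**2) / r**2
        ball = np.where(d2 <= 1, r * np.sqrt(np.clip(1 - d2, 0, 1)), -np.inf)
        oracle = np.clip(
            smoothed - grey_dilation(grey_erosion(smoothed, structure=ball), structure=ball),
            0,
            None,
        )

        assert out[2, 2] == pytest.approx(0.0, abs=1e-6)  # offset removed
        assert out.max() == pytest.approx(smoothed.max() - 20.0, rel=0.05)
        assert np.abs(out - oracle).max() < 2.0  # 4% of blob height

    def test_never_increases_and_stays_nonnegative(self, rng):
        frames = rng.poisson(30.0, size=(2, 64, 64)).astype(float)
        stack = dna_stack(frames)
        out = subtract_background(stack, rolling_ball_radius_px=15).channel("dna")
        smoothed = np.stack([uniform_filter(f, 3) for f in frames])
        assert np.all(out >= 0)
        assert np.all(out <= smoothed + 1e-9)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ParameterError):
            subtract_background(
                dna_stack([np.ones((32, 32))]), rolling_ball_radius_px=100
            )
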