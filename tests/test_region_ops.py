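"""Flattening, search regions, biasing, masking, down-sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octseg.errors import InputError
from octseg.gradient_maps import compute_gradient
from octseg.graph_search import shortest_path_boundary
from octseg.region_ops import (
    Boundary,
    FlattenRecord,
    apply_lower_bias,
    downsample_search_upsample,
    flatten,
    interframe_region,
    intraframe_region,
    mask_relative,
    moving_average,
    unflatten_boundary,
)


class TestFlatten:
    def test_already_flat_reference_is_identity(self):
        rng = np.random.default_rng(0)
        frame = rng.random((20, 10))
        flat, rec = flatten(frame, np.full(10, 7.0))
        assert np.array_equal(flat, frame)
        assert np.all(rec.shifts == 0)
        assert rec.target_row == 7

    def test_tilted_reference_shift_arithmetic(self):
        frame = np.zeros((20, 10))
        _, rec = flatten(frame, np.arange(10, dtype=float))
        assert rec.target_row == 9
        assert np.array_equal(rec.shifts, np.arange(9, -1, -1))

    def test_unflatten_restores_frame_rows_and_boundary(self):
        rng = np.random.default_rng(1)
        frame = rng.random((30, 8))
        ref = 10.0 + 3 * np.sin(np.arange(8))
        flat, rec = flatten(frame, ref)
        # rows untouched by fill round-trip exactly
        for x in range(8):
            s = rec.shifts[x]
            assert np.array_equal(flat[s:, x], frame[:30 - s, x])
            assert np.all(flat[:s, x] == frame[0, x])
        b = Boundary(z=np.linspace(12, 14, 8), label="ILM")
        restored = unflatten_boundary(
            Boundary(z=rec.apply_to(b.z)), rec)
        assert np.allclose(restored.z, b.z)

    def test_reference_outside_frame_rejected(self):
        with pytest.raises(InputError):
            flatten(np.zeros((10, 4)), np.array([0.0, 2.0, 11.0, 3.0]))
        with pytest.raises(InputError):
            flatten(np.zeros((10, 4)), np.zeros(3))

    def test_record_length_mismatch_rejected(self):
        rec = FlattenRecord(shifts=np.zeros(4, dtype=int), target_row=5)
        with pytest.raises(InputError):
            rec.invert(np.zeros(5))


class TestRegions:
    def test_interframe_band_from_prev_boundary(self):
        prev = np.linspace(100, 120, 50)
        r = interframe_region(prev, frame_height=496, margin=10)
        assert (r.z_top, r.z_bottom) == (90, 130)

    def test_interframe_band_clamps_to_image(self):
        r = interframe_region(np.full(5, 5.0), frame_height=496, margin=10)
        assert r.z_top == 0
        r = interframe_region(np.full(5, 490.0), frame_height=496, margin=10)
        assert r.z_bottom == 495

    def test_interframe_margin_zero_is_exact_band(self):
        r = interframe_region(np.array([30.0, 40.0]), 100, margin=0)
        assert (r.z_top, r.z_bottom) == (30, 40)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 400), min_size=2, max_size=30))
    def test_interframe_band_contains_previous_boundary(self, zs):
        z = np.array(zs)
        r = interframe_region(z, frame_height=496, margin=10)
        assert r.z_top <= z.min() and r.z_bottom >= z.max()

    def test_rect_below_height(self):
        r = intraframe_region(300, None, "rect_below", height=40,
                              frame_height=496)
        assert (r.z_top, r.z_bottom) == (300, 339)
        assert r.n_rows == 40

    def test_rect_between_extremes(self):
        upper = np.array([45.0, 50.0, 40.0])
        lower = np.full(3, 300.0)
        r = intraframe_region(upper, lower, "rect_between_extremes")
        assert (r.z_top, r.z_bottom) == (50, 300)

    def test_degenerate_single_row_region(self):
        r = intraframe_region(np.full(3, 10.0), np.full(3, 10.0),
                              "rect_between_extremes")
        assert r.n_rows == 1

    def test_inverted_bounds_rejected(self):
        with pytest.raises(InputError):
            intraframe_region(np.full(3, 50.0), np.full(3, 20.0),
                              "rect_between_extremes")


class TestBiasAndMask:
    def test_bias_rows_scale_zero_to_one(self):
        g = np.ones((3, 1))
        assert np.allclose(apply_lower_bias(g), [[0.0], [0.5], [1.0]])

    def test_bottom_row_unchanged(self):
        rng = np.random.default_rng(2)
        g = rng.random((7, 5))
        assert np.array_equal(apply_lower_bias(g)[-1], g[-1])

    def test_bias_monotone_in_depth(self):
        g = apply_lower_bias(np.ones((10, 2)))
        assert np.all(np.diff(g, axis=0) >= 0)

    def test_single_row_region_rejected(self):
        with pytest.raises(InputError):
            apply_lower_bias(np.ones((1, 5)))

    def test_bias_makes_search_select_lower_of_equal_edges(self):
        g = np.zeros((10, 12))
        g[2] = 0.8
        g[8] = 0.8
        plain = shortest_path_boundary(g)
        biased = shortest_path_boundary(apply_lower_bias(g))
        assert np.all(plain.rows == 2)  # smaller-row tie-break
        assert np.all(biased.rows == 8)

    def test_mask_below_flat_boundary(self):
        g = np.ones((10, 4))
        out = mask_relative(g, np.full(4, 4.0), "below")
        assert np.all(out[:5] == 1) and np.all(out[5:] == 0)

    def test_mask_above_and_outside_pair(self):
        g = np.ones((10, 4))
        out = mask_relative(g, np.full(4, 4.0), "above")
        assert np.all(out[:4] == 0) and np.all(out[4:] == 1)
        out = mask_relative(g, np.full(4, 6.0), "outside_pair",
                            upper=np.full(4, 6.0))
        assert np.all(out[6] == 1)
        assert out.sum() == 4  # touching boundaries leave one row

    def test_mask_idempotent(self):
        rng = np.random.default_rng(3)
        g = rng.random((12, 6))
        b = rng.uniform(2, 9, size=6)
        once = mask_relative(g, b, "below")
        assert np.array_equal(mask_relative(once, b, "below"), once)

    def test_mask_boundary_outside_region_rejected(self):
        with pytest.raises(InputError):
            mask_relative(np.ones((5, 3)), np.full(3, 7.0), "below")

    def test_two_pass_masked_search_finds_upper_edge(self):
        # detect the lower of two edges, mask below it (with a clearance for
        # its response spread), re-search: the second pass must return the
        # upper edge strictly above the first
        frame = np.zeros((60, 30))
        frame[20:40] = 0.5   # bright band: b2d edge at 40 (strong via depth)
        frame[40:] = 0.05
        g = compute_gradient(frame, "bright_to_dark").values
        first = shortest_path_boundary(apply_lower_bias(g))
        masked = mask_relative(g, np.maximum(first.rows - 8, 0), "below")
        second = shortest_path_boundary(masked)
        assert np.all(second.rows < first.rows)


class TestDownsample:
    def test_factor_one_window_one_equals_plain_search(self):
        rng = np.random.default_rng(4)
        g = rng.random((15, 20))
        z = downsample_search_upsample(g, factor=1, smooth_window=1)
        assert np.array_equal(z, shortest_path_boundary(g).rows.astype(float))

    @pytest.mark.parametrize("factor", [1, 2, 4])
    def test_flat_bright_row_recovered_exactly(self, factor):
        g = np.zeros((12, 24))
        g[5] = 1.0
        z = downsample_search_upsample(g, factor=factor, smooth_window=5)
        assert np.allclose(z, 5.0)

    def test_sinusoidal_edge_recovered_within_one_pixel(self):
        cols = 120
        rows = 40
        truth = 20 + 3 * np.sin(2 * np.pi * np.arange(cols) / 60)
        frame = np.zeros((rows, cols))
        for x in range(cols):
            frame[:, x] = np.clip(np.arange(rows) + 0.5 - truth[x], 0, 1)
        g = compute_gradient(frame, "dark_to_bright").values
        z = downsample_search_upsample(g, factor=2, smooth_window=5)
        assert np.abs(z - truth).max() <= 1.0

    def test_downsampled_path_close_to_full_resolution_path(self):
        cols = 80
        truth = 15 + np.linspace(0, 20, cols) * 0.8  # slope < 1 px/col
        frame = np.zeros((50, cols))
        for x in range(cols):
            frame[:, x] = np.clip(np.arange(50) + 0.5 - truth[x], 0, 1)
        g = compute_gradient(frame, "dark_to_bright").values
        z1 = downsample_search_upsample(g, factor=1, smooth_window=1)
        z2 = downsample_search_upsample(g, factor=2, smooth_window=1)
        assert np.abs(z1 - z2).max() <= 1.0

    def test_region_too_narrow_rejected(self):
        with pytest.raises(InputError):
            downsample_search_upsample(np.zeros((5, 3)), factor=2)


def test_moving_average_edge_truncation():
    z = np.array([0.0, 0.0, 10.0, 0.0, 0.0])
    sm = moving_average(z, 3)
    assert sm[0] == 0.0 and sm[2] == pytest.approx(10 / 3)
    assert np.array_equal(moving_average(z, 1), z)
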