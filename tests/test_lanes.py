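"""Lane geometry, profile integration, baselines and bounded measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelquant import (
    Baseline,
    LanePath,
    MeasurementRegion,
    Raster,
    ValidationError,
    baseline_at,
    lane_center,
    lane_profile,
    measure,
    validate_path,
)


def brute_force_profile(raster, path):
    """Independent per-row pixel loop implementing the inclusion rule."""
    h, w = raster.shape
    y0, y1 = path.row_span
    ys = range(int(np.ceil(y0)), int(np.floor(y1)) + 1)
    values = []
    for y in ys:
        xc, hw = lane_center(path, y)
        total = 0.0
        for x in range(w):
            if abs(x - xc) <= hw:
                total += raster.pixels[y, x]
        values.append(total)
    return list(ys)[0], values


class TestLanePath:
    def test_straight_vertical_lane_is_valid(self):
        p = LanePath([(0, 10, 3), (99, 10, 3)])
        assert validate_path(p, (100, 50)) is p

    def test_equal_rows_are_a_horizontal_segment(self):
        with pytest.raises(ValidationError, match="horizontal"):
            LanePath([(0, 10, 3), (0, 20, 3)])

    def test_decreasing_rows_rejected(self):
        with pytest.raises(ValidationError, match="horizontal"):
            LanePath([(0, 10, 3), (50, 12, 3), (40, 14, 3)])

    def test_single_node_rejected(self):
        with pytest.raises(ValidationError, match="2 nodes"):
            LanePath([(0, 10, 3)])

    def test_non_positive_half_width_rejected(self):
        with pytest.raises(ValidationError, match="half-width"):
            LanePath([(0, 10, 0.0), (10, 10, 3)])

    def test_path_outside_image_rows_rejected(self):
        p = LanePath([(0, 10, 3), (150, 10, 3)])
        with pytest.raises(ValidationError, match="outside image rows"):
            validate_path(p, (100, 50))

    def test_edge_clipped_lane_allowed_but_logged(self, caplog):
        p = LanePath([(0, 2, 5), (99, 2, 5)])
        with caplog.at_level("WARNING", logger="gelquant.lanes"):
            validate_path(p, (100, 50))
        assert any("clip" in rec.message for rec in caplog.records)


class TestLaneCenter:
    def test_midpoint_interpolation(self):
        p = LanePath([(0, 0, 2), (10, 10, 4)])
        assert lane_center(p, 5) == (5.0, 3.0)

    def test_exact_at_nodes(self):
        p = LanePath([(0, 0, 2), (10, 10, 4)])
        assert lane_center(p, 0) == (0.0, 2.0)
        assert lane_center(p, 10) == (10.0, 4.0)

    def test_outside_span_rejected(self):
        p = LanePath([(0, 0, 2), (10, 10, 4)])
        with pytest.raises(ValidationError):
            lane_center(p, 11)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_two_point_interpolation_oracle(self, data):
        rows = sorted(data.draw(st.lists(
            st.floats(0, 99, allow_nan=False), min_size=2, max_size=6,
            unique=True)))
        nodes = [(y, data.draw(st.floats(0, 50)), data.draw(st.floats(0.5, 8)))
                 for y in rows]
        p = LanePath(nodes)
        y = data.draw(st.floats(rows[0], rows[-1]))
        # oracle: find the bracketing pair, interpolate by hand
        for (y0, x0, w0), (y1, x1, w1) in zip(nodes, nodes[1:]):
            if y0 <= y <= y1:
                t = (y - y0) / (y1 - y0)
                x, w = lane_center(p, y)
                assert x == pytest.approx(x0 + t * (x1 - x0), abs=1e-9)
                assert w == pytest.approx(w0 + t * (w1 - w0), abs=1e-9)
                break


class TestLaneProfile:
    def test_constant_raster_counts_columns(self):
        r = Raster(np.full((30, 40), 2.0))
        p = LanePath([(0, 20, 3), (29, 20, 3)])  # 7 integer columns
        prof = lane_profile(r, p)
        assert prof.y_start == 0
        np.testing.assert_array_equal(prof.values, 14.0)

    def test_zero_raster_gives_zero_profile(self):
        r = Raster(np.zeros((30, 40)))
        prof = lane_profile(r, LanePath([(0, 20, 3), (29, 20, 3)]))
        np.testing.assert_array_equal(prof.values, 0.0)

    def test_curved_lane_equals_pixel_loop(self, rng):
        r = Raster(rng.uniform(0, 100, (60, 50)))
        ys = np.array([0.0, 20.0, 40.0, 59.0])
        xs = 25 + 8e-3 * (ys - 30) ** 2
        p = LanePath([(y, x, 4.2) for y, x in zip(ys, xs)])
        prof = lane_profile(r, p)
        y0, expected = brute_force_profile(r, p)
        assert prof.y_start == y0
        np.testing.assert_allclose(prof.values, expected, atol=1e-9)

    def test_random_paths_equal_pixel_loop(self, rng):
        for _ in range(25):
            r = Raster(rng.uniform(0, 100, (40, 30)))
            rows = np.sort(rng.uniform(0, 39, 4))
            while len(np.unique(rows)) < 4:
                rows = np.sort(rng.uniform(0, 39, 4))
            p = LanePath([(y, rng.uniform(0, 29), rng.uniform(0.5, 9))
                          for y in rows])
            prof = lane_profile(r, p)
            y0, expected = brute_force_profile(r, p)
            assert prof.y_start == y0
            np.testing.assert_allclose(prof.values, expected, atol=1e-9)

    def test_width_monotonicity(self, rng):
        r = Raster(rng.uniform(0, 100, (40, 30)))
        narrow = lane_profile(r, LanePath([(0, 15, 3), (39, 15, 3)]))
        wide = lane_profile(r, LanePath([(0, 15, 6), (39, 15, 6)]))
        assert np.all(wide.values >= narrow.values)

    def test_linear_in_intensity(self, rng):
        r = Raster(rng.uniform(0, 100, (40, 30)))
        p = LanePath([(0, 15, 4), (39, 18, 4)])
        base = lane_profile(r, p).values
        scaled = lane_profile(Raster(3.0 * r.pixels), p).values
        np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-12)


class TestBaseline:
    def test_linear_between_anchors(self):
        b = Baseline([(0, 0), (10, 10)])
        assert baseline_at(b, 5) == 5.0

    def test_default_is_zero_everywhere(self):
        b = Baseline()
        assert baseline_at(b, 0) == 0.0
        assert baseline_at(b, 1234) == 0.0

    def test_constant_extrapolation(self):
        b = Baseline([(0, 4)])
        assert baseline_at(b, 100) == 4.0
        b2 = Baseline([(10, 2), (20, 8)])
        assert baseline_at(b2, 0) == 2.0
        assert baseline_at(b2, 99) == 8.0

    def test_invalid_anchors_rejected(self):
        with pytest.raises(ValidationError):
            Baseline([(0, 1), (0, 2)])
        with pytest.raises(ValidationError):
            Baseline([(0, -1)])


class TestMeasure:
    def test_constant_profile_times_rows(self):
        r = Raster(np.full((30, 40), 2.0))
        prof = lane_profile(r, LanePath([(0, 20, 3), (29, 20, 3)]))
        m = measure(prof, Baseline(), MeasurementRegion(0, 10))
        assert m.value == 140.0
        assert m.success is True

    def test_profile_equal_to_baseline_gives_zero(self):
        r = Raster(np.full((30, 40), 2.0))
        prof = lane_profile(r, LanePath([(0, 20, 3), (29, 20, 3)]))
        b = Baseline([(0, 14.0)])
        assert measure(prof, b, MeasurementRegion(0, 30)).value == 0.0

    def test_region_outside_profile_rejected(self):
        r = Raster(np.full((30, 40), 2.0))
        prof = lane_profile(r, LanePath([(5, 20, 3), (25, 20, 3)]))
        with pytest.raises(ValidationError):
            measure(prof, Baseline(), MeasurementRegion(0, 10))

    def test_negative_value_allowed_with_warning(self, caplog):
        r = Raster(np.full((30, 40), 2.0))
        prof = lane_profile(r, LanePath([(0, 20, 3), (29, 20, 3)]))
        b = Baseline([(0, 100.0)])
        with caplog.at_level("WARNING", logger="gelquant.lanes"):
            m = measure(prof, b, MeasurementRegion(0, 10))
        assert m.value < 0
        assert any("baseline above signal" in rec.message for rec in caplog.records)

    def test_additivity_over_adjacent_regions(self, rng):
        # integer intensities and a dyadic baseline slope keep every
        # partial sum exact in float64, so equality is bitwise
        r = Raster(rng.integers(0, 1000, (60, 30)).astype(float))
        prof = lane_profile(r, LanePath([(0, 15, 5), (59, 15, 5)]))
        b = Baseline([(0, 3.0), (56, 10.0)])  # slope 0.125/row
        a, mid, c = 5, 22, 50
        v_left = measure(prof, b, MeasurementRegion(a, mid)).value
        v_right = measure(prof, b, MeasurementRegion(mid, c)).value
        v_full = measure(prof, b, MeasurementRegion(a, c)).value
        assert v_left + v_right == v_full

    def test_linearity_in_intensity_scale(self, rng):
        r = Raster(rng.uniform(0, 100, (60, 30)))
        p = LanePath([(0, 15, 5), (59, 15, 5)])
        b = Baseline([(0, 3.0), (59, 7.0)])
        region = MeasurementRegion(5, 50)
        v = measure(lane_profile(r, p), b, region).value
        k = 7.0
        bk = Baseline([(0, 3.0 * k), (59, 7.0 * k)])
        vk = measure(lane_profile(Raster(k * r.pixels), p), bk, region).value
        assert vk == pytest.approx(k * v, rel=1e-12)

    def test_lateral_shift_invariance_for_contained_band(self):
        """Nudging a straight lane sideways keeps the band's value (<1%)."""
        from tests.conftest import single_band_spec
        from gelquant import generate

        spec = single_band_spec(amount=30000.0, sigma=2.0, half_width=9.0,
                                x0=30.0, width=61)
        raster, _ = generate(spec)
        region = MeasurementRegion(45, 76)
        values = []
        for delta in (-2.0, 0.0, 2.0):
            p = LanePath([(0, 30.0 + delta, 9.0), (119, 30.0 + delta, 9.0)])
            values.append(measure(lane_profile(raster, p), Baseline(),
                                  region).value)
        ref = values[1]
        assert all(abs(v / ref - 1) < 0.01 for v in values)

    def test_recovers_injected_band_amount(self):
        from tests.conftest import single_band_spec
        from gelquant import generate

        spec = single_band_spec(amount=25000.0, sigma=2.5)
        raster, truth = generate(spec)
        p = LanePath([(0, 30, 8), (119, 30, 8)])
        m = measure(lane_profile(raster, p), Baseline(),
                    MeasurementRegion(40, 81))
        assert m.value == pytest.approx(25000.0, rel=0.02)
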