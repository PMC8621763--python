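"""Tests of the tangent-launch interval segmentation and its linear table."""

import json

import numpy as np
import pytest

import doseline as dl
from doseline.errors import ConfigurationError, DomainError


class TestFindBoundaries:
    def test_four_intervals_with_defaults(self, seg_config):
        boundaries = dl.find_boundaries(seg_config)
        assert len(boundaries) == 4
        assert boundaries[-1] == pytest.approx(dl.prhe_inverse(0.10), rel=1e-12)

    def test_matches_grid_scan_oracle(self, seg_config, curve):
        """Brute-force scan of the same discrepancy criterion on a fine
        dose grid agrees with the root-found boundaries to one grid step."""
        step = 1e-5
        factor = seg_config.discrepancy_factor
        x_max = dl.prhe_inverse(seg_config.p_max, curve)
        oracle = []
        x_k = dl.prhe_inverse(seg_config.p_min, curve)
        while True:
            slope = dl.prhe_derivative(x_k, curve)
            y_k = dl.prhe_nonlinear(x_k, curve)
            xs = np.arange(x_k + step, x_max + step, step)
            ratios = np.array(
                [dl.prhe_nonlinear(x, curve) / (y_k + slope * (x - x_k)) for x in xs]
            )
            hits = np.nonzero(ratios >= factor)[0]
            if len(hits) == 0:
                oracle.append(x_max)
                break
            oracle.append(float(xs[hits[0]]))
            x_k = oracle[-1]
        boundaries = dl.find_boundaries(seg_config)
        assert len(boundaries) == len(oracle)
        # The oracle's launch points are grid-snapped, so its one-step error
        # propagates (amplified by the curve's steepness) into later
        # boundaries; allow a few steps of slack there.
        for b, o in zip(boundaries, oracle):
            assert abs(b - o) <= 10 * step

    def test_self_consistent_discrepancy_at_boundaries(self, seg_config, curve):
        boundaries = dl.find_boundaries(seg_config)
        x_k = dl.prhe_inverse(seg_config.p_min, curve)
        for b in boundaries[:-1]:
            tangent = dl.prhe_nonlinear(x_k, curve) + dl.prhe_derivative(x_k, curve) * (
                b - x_k
            )
            ratio = dl.prhe_nonlinear(b, curve) / tangent
            assert ratio == pytest.approx(seg_config.discrepancy_factor, rel=1e-3)
            x_k = b

    def test_unattainable_factor_gives_single_interval(self):
        config = dl.SegmentationConfig(discrepancy_factor=1e9)
        boundaries = dl.find_boundaries(config)
        assert len(boundaries) == 1
        assert boundaries[0] == pytest.approx(dl.prhe_inverse(config.p_max), rel=1e-12)

    def test_tolerance_insensitive(self, seg_config):
        coarse = dl.find_boundaries(seg_config, xtol=1e-6)
        fine = dl.find_boundaries(seg_config, xtol=1e-13)
        assert np.allclose(coarse, fine, atol=1e-5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            dl.SegmentationConfig(p_min=0.2, p_max=0.1)
        with pytest.raises(ConfigurationError):
            dl.SegmentationConfig(discrepancy_factor=1.0)


class TestBuildSecantTable:
    def test_continuous_and_monotone(self, segment_table):
        for left, right in zip(segment_table.segments, segment_table.segments[1:]):
            assert left.end_prhe == pytest.approx(right.base_prhe, rel=1e-10)
        xs = np.linspace(0, segment_table.x_max, 2001)
        ys = [dl.evaluate_piecewise(x, segment_table) for x in xs]
        assert np.all(np.diff(ys) >= -1e-15)

    def test_first_segment_anchored_at_origin(self, segment_table):
        first = segment_table.segments[0]
        assert first.x_start == 0.0
        assert first.base_prhe == 0.0

    def test_reproduces_published_table_from_published_boundaries(self, curve):
        """Secant parameters over the published boundaries agree with the
        published table within one unit in the last printed digit."""
        table = dl.build_secant_table([0.090, 0.153, 0.334, 0.464])
        slopes = [seg.slope for seg in table]
        bases = [seg.base_prhe for seg in table]
        for got, printed, ulp in zip(
            slopes, [0.00031, 0.013, 0.18, 0.51], [1e-5, 1e-3, 1e-2, 1e-2]
        ):
            assert abs(got - printed) <= 1.1 * ulp
        for got, printed, ulp in zip(
            bases, [0.0, 0.000028, 0.00085, 0.034], [0.0, 1e-6, 1e-5, 1e-3]
        ):
            assert abs(got - printed) <= 1.1 * ulp

    def test_secant_never_below_curve(self, segment_table, curve):
        """Convexity makes every secant a conservative (over-)estimate."""
        for seg in segment_table:
            xs = np.linspace(max(seg.x_start, 1e-6), seg.x_end, 500)
            for x in xs:
                assert seg(x) >= dl.prhe_nonlinear(x, curve) * (1 - 1e-12)

    def test_rejects_bad_boundaries(self):
        with pytest.raises(DomainError):
            dl.build_secant_table([0.2, 0.1])
        with pytest.raises(DomainError):
            dl.build_secant_table([-0.1, 0.2])
        with pytest.raises(DomainError):
            dl.build_secant_table([])


class TestEvaluatePiecewise:
    def test_zero_dose(self, segment_table):
        assert dl.evaluate_piecewise(0.0, segment_table) == 0.0

    def test_worked_example_with_published_table(self, published_table):
        assert dl.evaluate_piecewise(0.279, published_table) == pytest.approx(
            2.35e-2, rel=2e-3  # printed to 3 significant figures
        )

    def test_boundary_value_equals_nonlinear(self, segment_table, curve):
        b1 = segment_table.segments[0].x_end
        assert dl.evaluate_piecewise(b1, segment_table) == pytest.approx(
            dl.prhe_nonlinear(b1, curve), rel=1e-10
        )
        assert dl.prhe_nonlinear(b1, curve) == pytest.approx(2.9e-5, rel=0.1)

    def test_beyond_range_falls_back_with_warning(self, segment_table, curve):
        with pytest.warns(UserWarning, match="exceeds the linearized range"):
            value = dl.evaluate_piecewise(0.9, segment_table)
        assert value == pytest.approx(dl.prhe_nonlinear(0.9, curve), rel=1e-12)

    def test_negative_dose_rejected(self, segment_table):
        with pytest.raises(DomainError):
            dl.evaluate_piecewise(-0.1, segment_table)


class TestEd10Line:
    def test_passes_through_anchors(self, seg_config):
        x_ed10 = dl.prhe_inverse(seg_config.p_max)
        assert dl.ed10_linear_prhe(0.0, seg_config) == 0.0
        assert dl.ed10_linear_prhe(x_ed10, seg_config) == pytest.approx(0.10, rel=1e-12)

    def test_overestimates_by_thousands_at_low_dose(self, seg_config, curve):
        ratio = dl.ed10_linear_prhe(0.063, seg_config) / dl.prhe_nonlinear(0.063, curve)
        assert ratio == pytest.approx(7000, rel=0.05)


class TestMaxRelativeDifference:
    def test_degenerate_segment(self, curve):
        seg = dl.LinearSegment(0.1, 0.1 + 1e-13, 0.01, dl.prhe_nonlinear(0.1, curve))
        assert dl.max_relative_difference(seg, curve) == pytest.approx(0.0, abs=1e-4)

    def test_first_interval_overestimate_shrinks_past_six_percent(
        self, segment_table, curve
    ):
        """Above 6.3% of ED50 the first secant over-predicts by less than an
        order of magnitude."""
        first = segment_table.segments[0]
        ratio = first(0.063) / dl.prhe_nonlinear(0.063, curve)
        assert 1.0 < ratio < 10.5
        assert ratio == pytest.approx(10, rel=0.05)

    def test_later_interval_bounds(self, segment_table, curve):
        diffs = [
            dl.max_relative_difference(seg, curve) for seg in segment_table.segments[1:]
        ]
        assert diffs[0] <= 175.0
        assert diffs[1] <= 176.0
        assert diffs[2] <= 10.0
        assert all(d >= 0 for d in diffs)


class TestSerialization:
    def test_json_round_trip(self, segment_table):
        text = segment_table.to_json()
        back = dl.SegmentTable.from_json(text)
        assert back == segment_table
        payload = json.loads(text)
        assert payload["config"]["discrepancy_factor"] == 5.0

    def test_records_schema(self, segment_table):
        records = segment_table.to_records()
        assert [r["interval_label"] for r in records] == ["I", "II", "III", "IV"]
        assert set(records[0]) == {
            "interval_label",
            "x_start",
            "x_end",
            "slope",
            "base_prhe",
        }
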