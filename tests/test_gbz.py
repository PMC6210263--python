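"""Grading index, Level 0–III banding, refined exposure-ratio weight, fuzzy bands."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from workrisk import (
    DEFAULT_WEIGHT_TABLES,
    GradingLevel,
    LaborIntensity,
    WeightMode,
    WeightTables,
    classify_grading,
    exposure_ratio,
    fuzzy_classify,
    grade_agent,
    grading_index,
    weight_for_exposure_ratio,
)
from workrisk.exposure import MeasurementRecord
from workrisk.registry import ChemicalAgent, HazardClass


class TestExposureRatio:
    @pytest.mark.parametrize(
        "measured, limit, expected", [(7.6, 20, 0.38), (5.0, 5.0, 1.0), (0.0, 2.0, 0.0)]
    )
    def test_is_plain_ratio(self, measured, limit, expected):
        assert exposure_ratio(measured, limit) == pytest.approx(expected)

    def test_nonpositive_limit_rejected(self):
        with pytest.raises(ValueError, match="limit"):
            exposure_ratio(1.0, 0.0)


class TestExposureRatioWeight:
    def test_standard_mode_zeroes_below_limit(self):
        assert weight_for_exposure_ratio(0.38, mode=WeightMode.STANDARD) == 0.0
        assert weight_for_exposure_ratio(1.0, mode=WeightMode.STANDARD) == 0.0

    def test_refined_mode_is_identity_below_one(self):
        assert weight_for_exposure_ratio(0.38, mode=WeightMode.REFINED) == pytest.approx(0.38)

    def test_both_modes_zero_at_zero(self):
        for mode in WeightMode:
            assert weight_for_exposure_ratio(0.0, mode=mode) == 0.0

    @pytest.mark.parametrize("b, expected", [(1.5, 1.0), (3.0, 1.0), (4.0, 2.0), (7.0, 3.0)])
    def test_table_lookup_above_one_in_both_modes(self, b, expected):
        for mode in WeightMode:
            assert weight_for_exposure_ratio(b, mode=mode) == expected

    @given(b=st.floats(0, 20, allow_nan=False))
    def test_refined_never_below_standard(self, b):
        assert weight_for_exposure_ratio(b, mode=WeightMode.REFINED) >= weight_for_exposure_ratio(
            b, mode=WeightMode.STANDARD
        )


class TestGradingIndex:
    def test_zero_weight_annihilates(self):
        assert grading_index(8.0, 0.0, 2.5) == 0.0

    @pytest.mark.parametrize("wd, wb, wl, g", [(4, 1, 1.5, 6.0), (8, 3, 2, 48.0)])
    def test_product(self, wd, wb, wl, g):
        assert grading_index(wd, wb, wl) == pytest.approx(g)

    weight = st.one_of(st.just(0.0), st.floats(0.1, 10))

    @given(wd=weight, wb=weight, wl=weight, bump=st.floats(0, 2))
    def test_nondecreasing_in_each_weight_and_zero_iff_a_zero_factor(self, wd, wb, wl, bump):
        g = grading_index(wd, wb, wl)
        assert (g == 0) == (wd == 0 or wb == 0 or wl == 0)
        assert grading_index(wd + bump, wb, wl) >= g
        assert grading_index(wd, wb + bump, wl) >= g
        assert grading_index(wd, wb, wl + bump) >= g


class TestClassifyGrading:
    @pytest.mark.parametrize(
        "g, level",
        [
            (0.0, GradingLevel.LEVEL_0),
            (0.0001, GradingLevel.LEVEL_I),
            (6.0, GradingLevel.LEVEL_I),  # closed upper bound
            (6.0001, GradingLevel.LEVEL_II),
            (24.0, GradingLevel.LEVEL_II),  # closed upper bound
            (25.0, GradingLevel.LEVEL_III),
        ],
    )
    def test_band_edges_exact(self, g, level):
        assert classify_grading(g) is level

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_grading(-1.0)


AMMONIA = ChemicalAgent(name="Ammonia", pc_twa=20.0, rfc=0.5, hazard_class=HazardClass.III)


class TestGradeAgent:
    def test_below_limit_standard_mode_is_level_0(self):
        rec = MeasurementRecord("p", "Ammonia", 7.6)
        result = grade_agent(rec, AMMONIA)
        assert result.b == pytest.approx(0.38)
        assert result.wb == 0.0
        assert result.g == 0.0
        assert result.level is GradingLevel.LEVEL_0

    def test_refined_mode_grades_below_limit_exposure(self):
        tables = WeightTables(
            wd_by_class={HazardClass.III: 4.0},
            wb_breakpoints=DEFAULT_WEIGHT_TABLES.wb_breakpoints,
            wl_by_intensity={LaborIntensity.II: 1.5},
        )
        rec = MeasurementRecord("p", "Ammonia", 7.6)
        result = grade_agent(rec, AMMONIA, tables=tables, mode=WeightMode.REFINED)
        assert result.g == pytest.approx(4 * 0.38 * 1.5)  # 2.28
        assert result.level is GradingLevel.LEVEL_I

    def test_over_limit_uses_weight_table(self):
        rec = MeasurementRecord("p", "Ammonia", 60.0)  # 3× the limit
        tables = WeightTables(
            wd_by_class={HazardClass.III: 8.0},
            wb_breakpoints=DEFAULT_WEIGHT_TABLES.wb_breakpoints,
            wl_by_intensity={LaborIntensity.II: 2.0},
        )
        result = grade_agent(rec, AMMONIA, tables=tables)
        assert result.wb == 1.0  # B = 3 falls in (1, 3]
        assert result.g == pytest.approx(16.0)
        assert result.level is GradingLevel.LEVEL_II

    @given(ca=st.floats(0, 100, allow_nan=False))
    def test_refined_level_never_below_standard_level(self, ca):
        rec = MeasurementRecord("p", "Ammonia", ca)
        std = grade_agent(rec, AMMONIA, mode=WeightMode.STANDARD)
        ref = grade_agent(rec, AMMONIA, mode=WeightMode.REFINED)
        assert std.level <= ref.level


class TestFuzzyClassify:
    def test_interior_point_is_crisp(self):
        m = fuzzy_classify(12.0, bandwidth=0.1)
        assert m[GradingLevel.LEVEL_II] == pytest.approx(1.0)

    def test_edge_point_splits_evenly(self):
        m = fuzzy_classify(6.0, bandwidth=0.25)
        assert m[GradingLevel.LEVEL_I] == pytest.approx(0.5)
        assert m[GradingLevel.LEVEL_II] == pytest.approx(0.5)

    def test_linear_interpolation_within_edge_zone(self):
        # edge zone 5.4–6.6 at bandwidth 0.1; g = 5.8 sits 1/3 of the way up
        m = fuzzy_classify(5.8, bandwidth=0.1)
        assert m[GradingLevel.LEVEL_I] == pytest.approx(2 / 3)
        assert m[GradingLevel.LEVEL_II] == pytest.approx(1 / 3)

    def test_zero_index_stays_crisp_level_0(self):
        assert fuzzy_classify(0.0, bandwidth=0.3)[GradingLevel.LEVEL_0] == 1.0

    @given(g=st.floats(0, 100, allow_nan=False), bw=st.floats(0.01, 0.99))
    def test_memberships_nonnegative_and_sum_to_one(self, g, bw):
        m = fuzzy_classify(g, bandwidth=bw)
        assert all(v >= 0 for v in m.values())
        assert sum(m.values()) == pytest.approx(1.0)

    @given(g=st.floats(0, 100, allow_nan=False), bw=st.floats(0.01, 0.5))
    def test_argmax_agrees_with_crisp_band_when_dominant(self, g, bw):
        m = fuzzy_classify(g, bandwidth=bw)
        dominant_level, dominant = max(m.items(), key=lambda kv: kv[1])
        if dominant > 0.5:
            assert dominant_level is classify_grading(g)

    def test_degenerates_to_crisp_as_bandwidth_shrinks(self):
        for g in (0.5, 5.99, 6.01, 23.9, 24.1, 80.0):
            m = fuzzy_classify(g, bandwidth=1e-9)
            assert m[classify_grading(g)] == pytest.approx(1.0)

    @pytest.mark.parametrize("bw", [0.0, 1.0, -0.1])
    def test_bandwidth_out_of_range_rejected(self, bw):
        with pytest.raises(ValueError, match="bandwidth"):
            fuzzy_classify(5.0, bandwidth=bw)


def test_weight_tables_yaml_round_trip(tmp_path):
    path = tmp_path / "weights.yaml"
    DEFAULT_WEIGHT_TABLES.to_yaml(path)
    again = WeightTables.from_yaml(path)
    assert again == DEFAULT_WEIGHT_TABLES


def test_malformed_weight_yaml_rejected():
    with pytest.raises(ValueError, match="malformed"):
        WeightTables.from_yaml(io.StringIO("wd: {I: 8}\n"))
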