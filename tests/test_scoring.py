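"""Score transforms, radar-area geometry, ranking and convention search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from printability import (AXES, SubstratePanel, SubstrateRecord,
                          TransformConfig, TransformError, ValidationError,
                          convention_search, default_convention_grid,
                          encode_ppa, radar_area, radar_chart_svg,
                          rank_substrates, transform_scores)

REPORTED_AREAS = {"S1": 6.9, "S2": 20.4, "S5": 59.2, "S6": 26.1,
                  "S7": 42.1, "S8": 23.5, "S9": 29.9, "S10": 23.7}


def shoelace_area(scores, n=8):
    """Independent polygon-area oracle: polar vertices + shoelace formula."""
    pts = [(r * math.cos(2 * math.pi * i / n), r * math.sin(2 * math.pi * i / n))
           for i, r in enumerate(scores)]
    a = 0.0
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        a += x1 * y2 - x2 * y1
    a = abs(a) / 2.0
    amax = 0.5 * math.sin(2 * math.pi / n) * n * 100.0 ** 2
    return 100.0 * a / amax


score_vectors = st.lists(st.floats(min_value=0, max_value=100), min_size=8,
                         max_size=8)


class TestEncodePpa:
    @pytest.mark.parametrize("color,edges,expect", [
        ("+", "+", 10), ("-", "-", 0), ("+", "-", 5), ("-", "+", 5)])
    def test_plus_count_mapping(self, color, edges, expect):
        assert encode_ppa(color, edges) == expect

    def test_invalid_mark_rejected(self):
        with pytest.raises(ValidationError):
            encode_ppa("+", "x")


class TestRadarArea:
    def test_full_and_empty_polygons(self):
        assert radar_area([100.0] * 8) == pytest.approx(100.0)
        assert radar_area([0.0] * 8) == 0.0

    def test_single_nonzero_axis_scores_zero(self):
        for i in range(8):
            v = [0.0] * 8
            v[i] = 100.0
            assert radar_area(v) == 0.0

    @given(score_vectors)
    @settings(max_examples=200, deadline=None)
    def test_matches_shoelace_oracle(self, scores):
        assert radar_area(scores) == pytest.approx(shoelace_area(scores),
                                                   abs=1e-9)

    @given(score_vectors, st.integers(min_value=0, max_value=7))
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_rotation_and_reversal(self, scores, k):
        base = radar_area(scores)
        rotated = scores[k:] + scores[:k]
        assert radar_area(rotated) == pytest.approx(base, abs=1e-9)
        assert radar_area(scores[::-1]) == pytest.approx(base, abs=1e-9)

    @given(score_vectors, st.integers(min_value=0, max_value=7),
           st.floats(min_value=0.1, max_value=100))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_coordinate(self, scores, i, bump):
        bumped = list(scores)
        bumped[i] = min(100.0, bumped[i] + bump)
        assert radar_area(bumped) >= radar_area(scores) - 1e-12

    def test_hundred_iff_all_hundred(self):
        v = [100.0] * 8
        v[3] = 99.0
        assert radar_area(v) < 100.0

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValidationError):
            radar_area([101.0] + [0.0] * 7)


class TestTransformScores:
    def test_saturating_clamped_and_self_max_axes(self, panel):
        scores = {v.sample_id: v.scores for v in transform_scores(panel)}
        assert scores["S1"]["EB"] == 100.0      # 272.91% >> 10% target
        assert scores["S3"]["YM"] == 0.0        # 3498 MPa clamps past the bound
        assert scores["S5"]["DL"] == 100.0      # panel-maximum drug load
        assert scores["S9"]["POR"] == 100.0     # panel-maximum porosity
        for v in scores.values():
            assert all(0.0 <= s <= 100.0 for s in v.values())

    def test_incomplete_records_excluded_with_warning(self, panel, caplog):
        with caplog.at_level("WARNING", logger="printability"):
            vectors = transform_scores(panel)
        ids = {v.sample_id for v in vectors}
        assert "S4" not in ids and len(ids) == 9
        assert any("S4" in rec.message for rec in caplog.records)

    def test_scope_idempotence_under_non_maximal_addition(self, panel):
        base = {v.sample_id: v.scores for v in transform_scores(panel)}
        extra = SubstrateRecord(
            "S99", subset="I", weight=10.0, thickness=50.0, drug_load=10.0,
            porosity_exp=0.5, porosity_img=1.0, ppa_color="-", ppa_edges="-",
            eb=1.0, ts=0.1, ym=10.0, g_star=0.1)
        bigger = SubstratePanel(list(panel.records) + [extra])
        after = {v.sample_id: v.scores for v in transform_scores(bigger)}
        for sid, sc in base.items():
            for axis in ("POR", "TH", "G*", "DL"):
                assert after[sid][axis] == sc[axis]

    def test_per_subset_scope_changes_only_max_axes(self, panel):
        g = {v.sample_id: v.scores for v in transform_scores(panel)}
        p = {v.sample_id: v.scores
             for v in transform_scores(panel, TransformConfig(
                 max_scope="per_subset"))}
        for sid in g:
            for axis in ("EB", "TS", "YM", "PPA"):
                assert g[sid][axis] == p[sid][axis]
        assert p["S2"]["POR"] == 100.0  # subset-I maximum porosity

    def test_zero_scope_max_names_axis(self):
        recs = [SubstrateRecord(
            f"A{i}", subset="I", weight=1.0, thickness=10.0, drug_load=0.0,
            porosity_exp=1.0, porosity_img=1.0, ppa_color="+", ppa_edges="+",
            eb=10.0, ts=2.0, ym=100.0, g_star=1.0) for i in range(2)]
        with pytest.raises(TransformError, match="DL"):
            transform_scores(SubstratePanel(recs))


class TestRanking:
    def test_within_subset_orderings_match_reported(self, panel):
        ranking, exclusions = rank_substrates(panel)
        order = [sid for sid, _, _ in ranking]
        assert "S3" in exclusions and "S4" in exclusions
        assert order.index("S2") < order.index("S1")
        assert order.index("S5") < order.index("S7") < order.index("S6")
        subset3 = [s for s in order if s in ("S8", "S9", "S10")]
        assert subset3[0] == "S9"

    def test_single_record_panel(self):
        rec = SubstrateRecord(
            "A", subset="I", weight=1.0, thickness=10.0, drug_load=5.0,
            porosity_exp=1.0, porosity_img=1.0, ppa_color="+", ppa_edges="+",
            eb=10.0, ts=2.0, ym=100.0, g_star=1.0)
        ranking, _ = rank_substrates(SubstratePanel([rec]))
        assert len(ranking) == 1 and ranking[0][0] == "A"

    def test_ties_broken_lexicographically_and_reported(self):
        recs = [SubstrateRecord(
            sid, subset="I", weight=1.0, thickness=10.0, drug_load=5.0,
            porosity_exp=1.0, porosity_img=1.0, ppa_color="+", ppa_edges="+",
            eb=10.0, ts=2.0, ym=100.0, g_star=1.0) for sid in ("B", "A")]
        ranking, _ = rank_substrates(SubstratePanel(recs))
        assert [r[0] for r in ranking] == ["A", "B"]
        assert all(tied for _, _, tied in ranking)

    def test_flag_exclusion_can_be_disabled(self, panel):
        ranking, _ = rank_substrates(panel, exclude_flagged=False)
        assert "S3" in [sid for sid, _, _ in ranking]


class TestConventionSearch:
    def test_residual_report_covers_grid_and_samples(self, panel):
        best, report = convention_search(panel, REPORTED_AREAS)
        assert len(report) == len(default_convention_grid()) == 16
        for entry in report:
            assert set(entry["residuals"]) == set(REPORTED_AREAS)
            assert entry["max_abs_residual"] >= 0

    def test_deterministic_tie_break_first_in_grid(self, panel):
        cfg = TransformConfig()
        # reversal leaves every area unchanged, so residuals tie exactly
        grid = [cfg, cfg.replace(axis_order=cfg.axis_order[::-1])]
        areas = {v.sample_id: v.relative_area
                 for v in transform_scores(panel, cfg)}
        best, report = convention_search(panel, areas, grid)
        assert best is grid[0]
        assert report[0]["max_abs_residual"] == pytest.approx(
            report[1]["max_abs_residual"])

    def test_recovers_generating_config_with_zero_residual(self, panel):
        target_cfg = TransformConfig(max_scope="per_subset", ym_bound=400.0)
        areas = {v.sample_id: v.relative_area
                 for v in transform_scores(panel, target_cfg)}
        best, report = convention_search(panel, areas)
        assert best.max_scope == "per_subset" and best.ym_bound == 400.0
        assert min(e["max_abs_residual"] for e in report) < 1e-9

    def test_empty_inputs_rejected(self, panel):
        with pytest.raises(ValidationError):
            convention_search(panel, {})
        with pytest.raises(ValidationError):
            convention_search(panel, REPORTED_AREAS, grid=[])


class TestRadarSvg:
    def test_svg_contains_polygons_and_labels(self, panel):
        vectors = transform_scores(panel)
        svg = radar_chart_svg(vectors[:2], title="Subset I")
        assert svg.startswith("<svg")
        assert svg.count("<polygon") >= 4 + 2  # rings + sample polygons
        for axis in AXES:
            assert f">{axis}</text>" in svg
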