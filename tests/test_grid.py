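"""Grid construction, the 6.25 m^2 inclusion rule, zone majority labelling,
the activity formula, and stocking arithmetic — each against a brute-force
or closed-form oracle where the behaviour is non-trivial."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import LineString, Polygon, box

from tramplerisk.geometry import MarshGeometry
from tramplerisk.grid import (
    ActivityGrid,
    ZoneCoverageError,
    MissingWeekError,
    assign_zones,
    build_grid,
    cattle_activity,
    distance_to_seawall,
    seasonal_cattle_density,
)
from tramplerisk.telemetry import TrackSet


def square_marsh(side=100.0, zones=None, creeks=()):
    boundary = box(0, 0, side, side)
    return MarshGeometry(
        boundary=boundary,
        seawall=LineString([(0, 0), (0, side)]),
        creeks=list(creeks),
        zones=zones or {"mid_marsh_redshank": boundary},
    )


def tracks_with_fixes(points, herd_size, week=1):
    df = pd.DataFrame(points, columns=["x_m", "y_m"])
    df["collar_id"] = "C1"
    df["timestamp"] = pd.Timestamp("2013-05-19") + pd.to_timedelta(
        np.arange(len(df)), unit="m")
    df["week"] = week
    return TrackSet(fixes=df[["collar_id", "timestamp", "x_m", "y_m", "week"]],
                    herd_size=herd_size)


class TestBuildGrid:
    def test_exact_tiling_of_square_marsh(self):
        cells = build_grid(square_marsh(100.0))
        assert len(cells) == 4
        assert np.allclose(cells["marsh_area_m2"], 2500.0)
        assert cells["included"].all()

    def test_inclusion_threshold_is_strict(self):
        # marsh sliver covering exactly 6.25 m^2 (2.5 x 2.5 m) of the second cell
        marsh = MarshGeometry(
            boundary=box(0, 0, 50, 50).union(box(50, 0, 52.5, 2.5)),
            seawall=LineString([(0, 0), (0, 50)]),
            zones={"mid_marsh_redshank": box(0, 0, 55, 55)},
        )
        cells = build_grid(marsh)
        sliver = cells[(cells["ix"] == 1) & (cells["iy"] == 0)].iloc[0]
        assert sliver["marsh_area_m2"] == pytest.approx(6.25)
        assert not sliver["included"]  # strict >
        grown = build_grid(marsh, inclusion_threshold_m2=6.24)
        assert grown[(grown["ix"] == 1) & (grown["iy"] == 0)]["included"].iloc[0]

    def test_area_conservation_random_polygon(self, rng):
        # irregular marsh: cell areas must sum to area(boundary - creeks)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 12))
        r = rng.uniform(80, 140, 12)
        poly = Polygon(np.column_stack([150 + r * np.cos(angles),
                                        150 + r * np.sin(angles)])).buffer(0)
        creek = box(140, 0, 150, 300).intersection(poly)
        marsh = MarshGeometry(boundary=poly, seawall=LineString([(0, 0), (0, 300)]),
                              creeks=[creek], zones={"mid_marsh_redshank": poly})
        cells = build_grid(marsh)
        assert cells["marsh_area_m2"].sum() == pytest.approx(
            poly.area - creek.area, rel=1e-6)


class TestAssignZones:
    def test_majority_area_rule(self):
        zones = {"mid_marsh_redshank": box(0, 0, 60, 100),
                 "non_redshank": box(60, 0, 100, 100)}
        cells = assign_zones(build_grid(square_marsh(100.0, zones)), square_marsh(100.0, zones))
        right = cells[(cells["ix"] == 1)]
        assert (right["zone"] == "non_redshank").all()  # 40 m vs 10 m split
        left = cells[(cells["ix"] == 0)]
        assert (left["zone"] == "mid_marsh_redshank").all()

    def test_cell_wholly_inside_one_zone(self):
        marsh = square_marsh(100.0, {"elytrigia_redshank": box(0, 0, 100, 100)})
        cells = assign_zones(build_grid(marsh), marsh)
        assert (cells["zone"] == "elytrigia_redshank").all()

    def test_exact_tie_goes_to_zone_nearer_seawall(self):
        zones = {"non_saltmarsh": box(0, 0, 25, 100),
                 "mid_marsh_redshank": box(25, 0, 100, 100)}
        marsh = square_marsh(100.0, zones)
        cells = assign_zones(build_grid(marsh), marsh)
        first_col = cells[cells["ix"] == 0]  # split exactly 25/25 m
        assert (first_col["zone"] == "non_saltmarsh").all()

    def test_uncovered_included_cell_raises(self):
        marsh = square_marsh(100.0, {"non_redshank": box(0, 0, 50, 100)})
        with pytest.raises(ZoneCoverageError, match="1_"):
            assign_zones(build_grid(marsh), marsh)

    def test_matches_monte_carlo_majority_oracle(self, rng):
        """Majority label agrees with dense point-sampling within each cell."""
        zones = {
            "non_saltmarsh": box(0, 0, 37, 150),
            "mid_marsh_redshank": box(37, 0, 81, 150),
            "elytrigia_redshank": box(81, 0, 113, 150),
            "non_redshank": box(113, 0, 150, 150),
        }
        marsh = square_marsh(150.0, zones)
        cells = assign_zones(build_grid(marsh), marsh)
        for rec in cells.itertuples(index=False):
            xs = rng.uniform(rec.x0, rec.x0 + 50, 4000)
            ys = rng.uniform(rec.y0, rec.y0 + 50, 4000)
            pts = shapely.points(np.column_stack([xs, ys]))
            counts = {z: shapely.contains(g, pts).sum() for z, g in zones.items()}
            oracle = max(counts, key=counts.get)
            if max(counts.values()) > 1.05 * sorted(counts.values())[-2]:
                assert rec.zone == oracle


class TestCattleActivity:
    def test_formula_direct_arithmetic(self):
        # H=100, full 0.25-ha cell, 50 of 2,000 fixes -> 10 cattle/ha
        marsh = square_marsh(200.0)
        cells = build_grid(marsh)
        pts = [(10.0 + 0.01 * k, 10.0) for k in range(50)]
        pts += [(60.0, 60.0 + 0.001 * k) for k in range(1950)]
        act = cattle_activity(tracks_with_fixes(pts, herd_size=100), cells)
        a = act.activity_for(1)
        assert a.loc["0_0"] == pytest.approx(100 * (50 / 2000) / 0.25)
        assert a.loc["0_0"] == pytest.approx(10.0)

    def test_concentration_limit(self):
        marsh = square_marsh(100.0)
        cells = build_grid(marsh)
        pts = [(10.0, 10.0 + 0.001 * k) for k in range(500)]
        act = cattle_activity(tracks_with_fixes(pts, herd_size=116), cells)
        assert act.activity_for(1).loc["0_0"] == pytest.approx(116 / 0.25)

    def test_unvisited_cell_has_zero_activity(self):
        marsh = square_marsh(100.0)
        cells = build_grid(marsh)
        act = cattle_activity(tracks_with_fixes([(10, 10)], herd_size=5), cells)
        assert act.activity_for(1).loc["1_1"] == 0.0

    def test_missing_week_reported_missing_not_zero(self):
        marsh = square_marsh(100.0)
        cells = build_grid(marsh)
        act = cattle_activity(tracks_with_fixes([(10, 10)], herd_size=5), cells)
        with pytest.raises(MissingWeekError):
            act.activity_for(2)

    def test_activity_conservation_and_scale_invariance(self, default_season):
        act = default_season["activity"]
        area_ha = act.included.set_index("cell_id")["marsh_area_m2"] / 1e4
        for w in act.weeks[::5]:
            a = act.activity_for(w)
            assert float((a * area_ha).sum()) == pytest.approx(act.herd_size)
        # doubling every count leaves activity unchanged (n/N invariance)
        doubled = ActivityGrid(cells=act.cells,
                               counts=act.counts.assign(n=act.counts["n"] * 2),
                               herd_size=act.herd_size,
                               week_totals=act.week_totals * 2,
                               marsh_id=act.marsh_id)
        w = act.weeks[0]
        pd.testing.assert_series_equal(act.activity_for(w), doubled.activity_for(w))

    def test_gridding_matches_brute_force_point_in_cell(self, rng):
        marsh = square_marsh(200.0)
        cells = build_grid(marsh)
        pts = np.column_stack([rng.uniform(0, 200, 800), rng.uniform(0, 200, 800)])
        act = cattle_activity(tracks_with_fixes(pts.tolist(), herd_size=10), cells)
        # oracle: shapely covers() against each half-open cell box
        oracle_counts = {}
        for rec in cells.itertuples(index=False):
            cell = box(rec.x0, rec.y0, rec.x0 + 50, rec.y0 + 50)
            inside = shapely.contains(cell, shapely.points(pts)) | (
                shapely.touches(cell, shapely.points(pts))
                & (pts[:, 0] >= rec.x0) & (pts[:, 0] < rec.x0 + 50)
                & (pts[:, 1] >= rec.y0) & (pts[:, 1] < rec.y0 + 50))
            oracle_counts[rec.cell_id] = int(inside.sum())
        got = act.counts[act.counts["week"] == 1].set_index("cell_id")["n"]
        for cid, n in oracle_counts.items():
            assert int(got.get(cid, 0)) == n


class TestSeasonalCattleDensity:
    @pytest.mark.parametrize("herd,area,scd", [
        (116, 322, 0.36), (39, 126, 0.31), (100, 201, 0.50), (60, 477, 0.13),
    ])
    def test_reported_scd_values(self, herd, area, scd):
        assert seasonal_cattle_density(herd, area).scd_rounded == scd

    def test_lsu_applies_young_stock_coefficient(self):
        s = seasonal_cattle_density(100, 201)
        assert s.scd_rounded == 0.50
        assert s.lsu_rounded == 0.40
        assert s.lsu_per_ha <= s.scd_per_ha

    def test_zero_area_raises(self):
        with pytest.raises(ValueError):
            seasonal_cattle_density(10, 0)


class TestDistanceToSeawall:
    def test_point_on_polyline_and_perpendicular(self):
        wall = LineString([(0, 0), (0, 1000)])
        d = distance_to_seawall([(0, 500), (500, 250)], wall)
        assert d[0] == 0.0
        assert d[1] == 500.0

    def test_matches_segmentwise_projection_oracle(self, rng):
        wall = LineString([(0, 0), (30, 400), (10, 800), (60, 1200)])
        pts = np.column_stack([rng.uniform(-50, 600, 200), rng.uniform(-50, 1300, 200)])
        got = distance_to_seawall(pts, wall)
        verts = np.asarray(wall.coords)
        expect = np.full(len(pts), np.inf)
        for a, b in zip(verts[:-1], verts[1:]):
            ab = b - a
            t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
            proj = a + t[:, None] * ab
            expect = np.minimum(expect, np.hypot(*(pts - proj).T))
        np.testing.assert_allclose(got, expect, atol=1e-9)

    def test_empty_polyline_raises(self):
        with pytest.raises(Exception):
            distance_to_seawall([(0, 0)], LineString())
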