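"""50-m analysis grid, cell inclusion, zone assignment and cattle activity.

The activity statistic is the field's per-cell mean cattle abundance over an
evaluation window:

    activity (cattle/ha) = H * (n_cell / N_window) / cell_marsh_area_ha

with H the herd size, n_cell the GPS fixes landing in the cell, N_window the
total fixes landing in *included* cells over the window, and the cell's
marsh area the part of the 50 x 50 m square covered by usable marsh. Cells
are included only when they contain more than 6.25 m^2 of marsh (the GPS
chipset accuracy rule). Activity therefore conserves the herd: summing
activity x area over cells returns H whenever no fix falls in an excluded
cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, box

from .geometry import ZONE_ORDER, GeometryError, MarshGeometry
from .telemetry import TrackSet

log = logging.getLogger(__name__)

INCLUSION_THRESHOLD_M2 = 6.25


class ZoneCoverageError(ValueError):
    """Raised when included cells have no habitat-zone coverage."""


class MissingWeekError(KeyError):
    """Raised when activity is requested for a week with no within-marsh fixes."""


@dataclass(frozen=True)
class StockingSummary:
    """Seasonal cattle density (SCD) and livestock units (LSU) per hectare."""

    scd_per_ha: float
    lsu_per_ha: float

    @staticmethod
    def _round2(x: float) -> float:
        return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    @property
    def scd_rounded(self) -> float:
        return self._round2(self.scd_per_ha)

    @property
    def lsu_rounded(self) -> float:
        return self._round2(self.lsu_per_ha)


def seasonal_cattle_density(herd_size: float, marsh_area_ha: float,
                            lsu_coefficient: float = 0.8) -> StockingSummary:
    """SCD = herd size / marsh area; LSU applies the young-stock coefficient.

    The saltmarshes here are grazed by young cattle, counted at 0.8 livestock
    units per head. Values are kept unrounded; 2-decimal half-up rounding is
    available for reporting.
    """
    if marsh_area_ha <= 0:
        raise ValueError("marsh area must be positive")
    if herd_size <= 0:
        raise ValueError("herd size must be positive")
    scd = herd_size / marsh_area_ha
    return StockingSummary(scd_per_ha=scd, lsu_per_ha=scd * lsu_coefficient)


def distance_to_seawall(points, seawall: LineString) -> np.ndarray:
    """Euclidean distance from planar points (n x 2 array) to the seawall line."""
    if seawall.is_empty or len(seawall.coords) < 2:
        raise GeometryError("seawall polyline is empty or degenerate")
    pts = shapely.points(np.asarray(points, dtype=float))
    return shapely.distance(pts, seawall)


def build_grid(marsh: MarshGeometry, cell_size_m: float = 50.0,
               origin: tuple[float, float] | None = None,
               inclusion_threshold_m2: float = INCLUSION_THRESHOLD_M2) -> pd.DataFrame:
    """Lay a half-open square grid over the marsh bounding box.

    Cells are [x0, x0+s) x [y0, y0+s), anchored at the boundary bounding-box
    minimum unless an explicit origin is given. Each cell's marsh area is
    its intersection with the usable marsh (boundary minus creeks); the
    strict > threshold decides inclusion. Distances to the seawall are
    measured from cell centroids.
    """
    if not marsh.boundary.is_valid or marsh.boundary.area <= 0:
        raise GeometryError("degenerate marsh boundary")
    minx, miny, maxx, maxy = marsh.boundary.bounds
    if origin is not None:
        ox, oy = origin
        # shift the anchor down-left so the grid still covers the bbox
        ox -= np.ceil((ox - minx) / cell_size_m) * cell_size_m
        oy -= np.ceil((oy - miny) / cell_size_m) * cell_size_m
        minx, miny = ox, oy
    nx = int(np.ceil((maxx - minx) / cell_size_m - 1e-9))
    ny = int(np.ceil((maxy - miny) / cell_size_m - 1e-9))

    usable = marsh.usable
    rows = []
    for ix in range(nx):
        for iy in range(ny):
            x0 = minx + ix * cell_size_m
            y0 = miny + iy * cell_size_m
            cell = box(x0, y0, x0 + cell_size_m, y0 + cell_size_m)
            area = cell.intersection(usable).area
            rows.append((f"{ix}_{iy}", ix, iy, x0, y0, area))
    cells = pd.DataFrame(rows, columns=["cell_id", "ix", "iy", "x0", "y0", "marsh_area_m2"])
    cells["included"] = cells["marsh_area_m2"] > inclusion_threshold_m2
    centroids = np.column_stack([cells["x0"] + cell_size_m / 2, cells["y0"] + cell_size_m / 2])
    cells["dist_seawall_m"] = distance_to_seawall(centroids, marsh.seawall)
    cells["zone"] = pd.Series([None] * len(cells), dtype=object)
    cells.attrs["cell_size_m"] = cell_size_m
    cells.attrs["origin"] = (minx, miny)
    cells.attrs["nx"], cells.attrs["ny"] = nx, ny
    log.info("grid: %d candidate cells, %d included", len(cells), int(cells["included"].sum()))
    return cells


def assign_zones(cells: pd.DataFrame, marsh: MarshGeometry) -> pd.DataFrame:
    """Label each included cell with its majority habitat zone.

    The zone occupying the largest marsh area of the cell wins; exact ties go
    to the zone nearer the seawall in the fixed zone order. Included cells
    with zero zone coverage are a data error and raise.
    """
    s = cells.attrs["cell_size_m"]
    zone_geoms = [marsh.zones.get(z) for z in ZONE_ORDER]
    out = cells.copy()
    out.attrs.update(cells.attrs)
    labels: list[str | None] = []
    uncovered = []
    for rec in out.itertuples(index=False):
        if not rec.included:
            labels.append(None)
            continue
        cell = box(rec.x0, rec.y0, rec.x0 + s, rec.y0 + s)
        areas = np.array([
            0.0 if g is None or g.is_empty else cell.intersection(g).area
            for g in zone_geoms
        ])
        if areas.max() <= 0:
            uncovered.append(rec.cell_id)
            labels.append(None)
            continue
        labels.append(ZONE_ORDER[int(np.argmax(areas))])  # argmax-first = nearer seawall on ties
    if uncovered:
        raise ZoneCoverageError(f"included cells without zone coverage: {uncovered}")
    out["zone"] = labels
    return out


@dataclass
class ActivityGrid:
    """Per-cell weekly fix counts and cattle activity for one marsh.

    ``counts`` is long-format (cell_id, week, n) over included cells only;
    ``week_totals`` maps week -> N_w (fixes landing in included cells).
    Weeks with no within-marsh fixes are absent (missing, not zero).
    """

    cells: pd.DataFrame
    counts: pd.DataFrame
    herd_size: int
    week_totals: pd.Series
    excluded_fixes: int = 0
    marsh_id: str = "B"

    @property
    def included(self) -> pd.DataFrame:
        return self.cells[self.cells["included"]]

    @property
    def weeks(self) -> list[int]:
        return sorted(self.week_totals.index.tolist())

    def cell_id_at(self, x: float, y: float) -> str | None:
        """Cell id containing a point under the half-open convention."""
        ox, oy = self.cells.attrs["origin"]
        s = self.cells.attrs["cell_size_m"]
        ix = int(np.floor((x - ox) / s))
        iy = int(np.floor((y - oy) / s))
        if not (0 <= ix < self.cells.attrs["nx"] and 0 <= iy < self.cells.attrs["ny"]):
            return None
        return f"{ix}_{iy}"

    def _area_ha(self) -> pd.Series:
        inc = self.included.set_index("cell_id")
        return inc["marsh_area_m2"] / 10_000.0

    def activity_for(self, week: int) -> pd.Series:
        """Activity (cattle/ha) for every included cell in one week."""
        if week not in self.week_totals.index:
            raise MissingWeekError(
                f"week {week} has no within-marsh fixes; activity is undefined"
            )
        n_w = float(self.week_totals.loc[week])
        area_ha = self._area_ha()
        n = (self.counts[self.counts["week"] == week]
             .set_index("cell_id")["n"].reindex(area_ha.index, fill_value=0))
        return self.herd_size * (n / n_w) / area_ha

    def window_activity(self, weeks: list[int] | None = None) -> pd.Series:
        """Pooled activity over a set of weeks (default: all observed weeks).

        The denominator is the total included-cell fix count over the window,
        so the statistic stays the mean cattle abundance over that window.
        """
        if weeks is None:
            weeks = self.weeks
        missing = [w for w in weeks if w not in self.week_totals.index]
        sub = self.counts[self.counts["week"].isin(weeks)]
        n_tot = float(self.week_totals.reindex(weeks).fillna(0).sum())
        if n_tot == 0:
            raise MissingWeekError(f"no within-marsh fixes in weeks {weeks}")
        area_ha = self._area_ha()
        n = sub.groupby("cell_id")["n"].sum().reindex(area_ha.index, fill_value=0)
        return self.herd_size * (n / n_tot) / area_ha

    def activity_table(self) -> pd.DataFrame:
        """Long-format (cell_id, week, n, activity_ha) over included cells."""
        frames = []
        for w in self.weeks:
            a = self.activity_for(w)
            n = (self.counts[self.counts["week"] == w]
                 .set_index("cell_id")["n"].reindex(a.index, fill_value=0))
            frames.append(pd.DataFrame({
                "cell_id": a.index, "week": w, "n": n.to_numpy(dtype=int),
                "activity_ha": a.to_numpy(),
            }))
        return pd.concat(frames, ignore_index=True)


def cattle_activity(tracks: TrackSet, cells: pd.DataFrame,
                    weeks: list[int] | None = None) -> ActivityGrid:
    """Count week-labelled fixes into grid cells and form the activity grid.

    Fixes landing in excluded cells (or off-grid) are logged and dropped from
    both the numerator and the denominator N_w.
    """
    if "week" not in tracks.fixes.columns:
        raise ValueError("fixes must be week-labelled (run assign_weeks first)")
    ox, oy = cells.attrs["origin"]
    s = cells.attrs["cell_size_m"]
    nx, ny = cells.attrs["nx"], cells.attrs["ny"]

    fixes = tracks.fixes
    if weeks is not None:
        fixes = fixes[fixes["week"].isin(weeks)]
    ix = np.floor((fixes["x_m"].to_numpy() - ox) / s).astype(int)
    iy = np.floor((fixes["y_m"].to_numpy() - oy) / s).astype(int)
    on_grid = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    cell_ids = np.array([f"{a}_{b}" for a, b in zip(ix, iy)], dtype=object)

    included_ids = set(cells.loc[cells["included"], "cell_id"])
    in_included = on_grid & np.array([c in included_ids for c in cell_ids])
    n_excluded = int((~in_included).sum())
    if n_excluded:
        log.info("cattle_activity: %d fixes in excluded cells or off-grid dropped "
                 "from numerator and denominator", n_excluded)

    kept = fixes.loc[in_included].assign(cell_id=cell_ids[in_included])
    counts = (kept.groupby(["cell_id", "week"]).size()
              .rename("n").reset_index())
    week_totals = counts.groupby("week")["n"].sum()
    return ActivityGrid(cells=cells, counts=counts, herd_size=tracks.herd_size,
                        week_totals=week_totals, excluded_fixes=n_excluded,
                        marsh_id=tracks.marsh_id)


def activity_over_window(tracks: TrackSet, cells: pd.DataFrame, cal,
                         start, days: int = 24) -> ActivityGrid:
    """Activity grid restricted to a fixed calendar window (e.g. the first 24
    days of grazing, the window used for trampling-risk maps).

    Raises if the tracks do not cover the whole window.
    """
    start = pd.Timestamp(start)
    end = start + pd.Timedelta(days=days)
    last = tracks.fixes["timestamp"].max()
    if last < end - pd.Timedelta(days=1):
        raise ValueError(
            f"activity window [{start.date()}, {end.date()}) extends beyond fix "
            f"coverage (last fix {last})"
        )
    from dataclasses import replace
    sub = tracks.fixes[(tracks.fixes["timestamp"] >= start) & (tracks.fixes["timestamp"] < end)]
    subtracks = replace(tracks, fixes=sub.reset_index(drop=True))
    from .telemetry import assign_weeks
    if "week" not in subtracks.fixes.columns:
        subtracks = assign_weeks(subtracks, cal)
    return cattle_activity(subtracks, cells)


def write_cells_geojson(activity: ActivityGrid, path) -> None:
    """Cells as a GeoJSON FeatureCollection with per-week activity properties."""
    import json

    s = activity.cells.attrs["cell_size_m"]
    act = {w: activity.activity_for(w) for w in activity.weeks}
    features = []
    for rec in activity.cells.itertuples(index=False):
        props = {
            "cell_id": rec.cell_id, "included": bool(rec.included),
            "zone": rec.zone, "marsh_area_m2": rec.marsh_area_m2,
            "dist_seawall_m": rec.dist_seawall_m,
        }
        if rec.included:
            for w, a in act.items():
                props[f"activity_w{w:02d}"] = float(a.get(rec.cell_id, 0.0))
        geom = {
            "type": "Polygon",
            "coordinates": [[
                [rec.x0, rec.y0], [rec.x0 + s, rec.y0], [rec.x0 + s, rec.y0 + s],
                [rec.x0, rec.y0 + s], [rec.x0, rec.y0],
            ]],
        }
        features.append({"type": "Feature", "properties": props, "geometry": geom})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
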