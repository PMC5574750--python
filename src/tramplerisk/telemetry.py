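"""GPS fix ingestion, validation, windowing and collar summaries.

Fix tables are tidy DataFrames with columns ``collar_id, timestamp, x_m,
y_m`` (planar metres, ISO-8601 timestamps at minute precision or finer).
The season calendar anchors weekly bins at 14 April (week 1 of the redshank
nesting season) in half-open 7-day blocks, so week 28 ends on 26 October.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from datetime import date

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FIX_COLUMNS = ["collar_id", "timestamp", "x_m", "y_m"]

# Local equirectangular mapping used only to encode planar metres as GPX
# lat/lon; the origin sits in the Wash estuary. The mapping is linear and
# inverts exactly, so CSV and GPX encodings round-trip.
_LAT0, _LON0 = 52.8, 0.2
_M_PER_DEG_LAT = 111_320.0
_M_PER_DEG_LON = _M_PER_DEG_LAT * math.cos(math.radians(_LAT0))


class FixParseError(ValueError):
    """Raised when a fix file cannot be parsed."""


class CalendarError(ValueError):
    """Raised when fixes fall outside the season calendar."""


@dataclass(frozen=True)
class SeasonCalendar:
    """Half-open weekly bins: week w covers [start + 7(w-1), start + 7w) days.

    Week 1 begins 14 April (start of the redshank nesting season, which runs
    mid-April to mid-July, i.e. through ``nesting_end_week``); a 28-week
    season ends 26 October.
    """

    week1_start: date = date(2013, 4, 14)
    n_weeks: int = 28
    nesting_end_week: int = 12

    def week_of(self, timestamps) -> np.ndarray:
        ts = pd.to_datetime(pd.Series(timestamps))
        start = pd.Timestamp(self.week1_start)
        delta_days = (ts - start) / pd.Timedelta(days=1)
        weeks = 1 + np.floor(delta_days / 7.0).astype("int64")
        return weeks.to_numpy()

    @property
    def season_end(self) -> pd.Timestamp:
        return pd.Timestamp(self.week1_start) + pd.Timedelta(weeks=self.n_weeks)


@dataclass
class TrackSet:
    """Validated collar fixes plus herd metadata.

    Invariants: fixes sorted by collar then time, strictly increasing
    timestamps per collar, all within [grazing_start, grazing_end], and the
    herd size is at least the number of distinct collars.
    """

    fixes: pd.DataFrame
    herd_size: int
    marsh_id: str = "B"
    grazing_start: date | None = None
    grazing_end: date | None = None
    duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in FIX_COLUMNS if c not in self.fixes.columns]
        if missing:
            raise FixParseError(f"fix table missing columns {missing}")
        if self.herd_size < self.fixes["collar_id"].nunique():
            raise ValueError("herd_size smaller than the number of distinct collars")
        if not np.isfinite(self.fixes[["x_m", "y_m"]].to_numpy(dtype=float)).all():
            raise ValueError("non-finite coordinates in fix table")
        if self.grazing_start is None and len(self.fixes):
            self.grazing_start = self.fixes["timestamp"].min().date()
        if self.grazing_end is None and len(self.fixes):
            self.grazing_end = self.fixes["timestamp"].max().date()
        if len(self.fixes):
            days = self.fixes["timestamp"].dt.date
            if days.min() < self.grazing_start or days.max() > self.grazing_end:
                raise ValueError("fixes outside the grazing window")
            per = self.fixes.groupby("collar_id", sort=False)["timestamp"]
            if (per.apply(lambda s: s.is_monotonic_increasing and s.is_unique) == False).any():
                raise ValueError("timestamps not strictly increasing within a collar")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    def collar_spans(self) -> pd.DataFrame:
        """Per-collar first/last fix and counts (the logging-span report)."""
        g = self.fixes.groupby("collar_id")["timestamp"]
        return pd.DataFrame({
            "first_fix": g.min(),
            "last_fix": g.max(),
            "n_fixes": g.size(),
        }).reset_index()


def read_fixes(path, fmt: str = "csv", herd_size: int | None = None,
               marsh_id: str = "B", grazing_start: date | None = None,
               grazing_end: date | None = None) -> TrackSet:
    """Read a fix file (CSV dialect or GPX 1.1 waypoints) into a TrackSet.

    Duplicate (collar, timestamp) pairs are hardware artefacts: the first is
    kept and the count logged. Unparseable timestamps raise with their row
    numbers; an empty file raises.
    """
    if fmt == "csv":
        df = pd.read_csv(path, comment="#")
        if df.empty:
            raise FixParseError(f"{path}: no fixes found")
        missing = [c for c in FIX_COLUMNS if c not in df.columns]
        if missing:
            raise FixParseError(f"{path}: missing columns {missing}")
        ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
        if ts.isna().any():
            bad = (df.index[ts.isna()] + 2).tolist()[:10]  # +2: header + 1-basing
            raise FixParseError(f"{path}: unparseable timestamps at rows {bad}")
        df = df.assign(timestamp=ts)
    elif fmt == "gpx":
        df = _read_gpx(path)
    else:
        raise ValueError(f"unknown fix format {fmt!r}")

    df = df[FIX_COLUMNS].sort_values(["collar_id", "timestamp"], kind="mergesort")
    before = len(df)
    df = df.drop_duplicates(subset=["collar_id", "timestamp"], keep="first")
    dropped = before - len(df)
    if dropped:
        log.info("dropped %d duplicate (collar, timestamp) fixes", dropped)
    df = df.reset_index(drop=True)
    if herd_size is None:
        herd_size = df["collar_id"].nunique()
    return TrackSet(fixes=df, herd_size=herd_size, marsh_id=marsh_id,
                    grazing_start=grazing_start, grazing_end=grazing_end,
                    duplicates_dropped=dropped)


def write_fixes_csv(tracks: TrackSet, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = tracks.fixes.copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(fh, index=False, float_format="%.6f")


def write_fixes_gpx(tracks: TrackSet, path) -> None:
    """Write fixes as GPX 1.1 waypoints, collar id carried in <name>."""
    gpx = ET.Element("gpx", version="1.1", creator="tramplerisk",
                     xmlns="http://www.topografix.com/GPX/1/1")
    for rec in tracks.fixes.itertuples(index=False):
        lat = _LAT0 + rec.y_m / _M_PER_DEG_LAT
        lon = _LON0 + rec.x_m / _M_PER_DEG_LON
        wpt = ET.SubElement(gpx, "wpt", lat=f"{lat:.10f}", lon=f"{lon:.10f}")
        ET.SubElement(wpt, "time").text = rec.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ")
        ET.SubElement(wpt, "name").text = str(rec.collar_id)
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="unicode")


def _read_gpx(path) -> pd.DataFrame:
    ns = {"g": "http://www.topografix.com/GPX/1/1"}
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FixParseError(f"{path}: invalid GPX ({exc})") from exc
    rows = []
    for i, wpt in enumerate(root.findall("g:wpt", ns)):
        name = wpt.find("g:name", ns)
        time = wpt.find("g:time", ns)
        if name is None or time is None:
            raise FixParseError(f"{path}: waypoint {i} missing <name> or <time>")
        ts = pd.to_datetime(time.text, errors="coerce")
        if pd.isna(ts):
            raise FixParseError(f"{path}: unparseable <time> in waypoint {i}")
        if ts.tzinfo is not None:
            ts = ts.tz_localize(None)
        rows.append({
            "collar_id": name.text,
            "timestamp": ts,
            "x_m": (float(wpt.get("lon")) - _LON0) * _M_PER_DEG_LON,
            "y_m": (float(wpt.get("lat")) - _LAT0) * _M_PER_DEG_LAT,
        })
    if not rows:
        raise FixParseError(f"{path}: no waypoints found")
    return pd.DataFrame(rows)


def cattle_days(tracks: TrackSet) -> int:
    """Sum over collars of distinct calendar days with at least one fix."""
    if tracks.n_fixes == 0:
        raise ValueError("cattle_days requires a nonempty TrackSet")
    days = tracks.fixes["timestamp"].dt.normalize()
    return int(days.groupby(tracks.fixes["collar_id"]).nunique().sum())


def assign_weeks(tracks: TrackSet, cal: SeasonCalendar) -> TrackSet:
    """Label every fix with its season week (idempotent).

    Fixes before week 1 or after the season's last week are calendar
    violations and raise, listing the offending timestamps.
    """
    weeks = cal.week_of(tracks.fixes["timestamp"])
    bad = (weeks < 1) | (weeks > cal.n_weeks)
    if bad.any():
        offenders = tracks.fixes.loc[bad, "timestamp"].head(10).tolist()
        raise CalendarError(
            f"{int(bad.sum())} fixes outside the season calendar "
            f"({cal.week1_start} + {cal.n_weeks} weeks); first offenders: {offenders}"
        )
    fixes = tracks.fixes.assign(week=weeks)
    return replace(tracks, fixes=fixes)
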