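"""Weekly herd-spread and habitat-use summaries.

CA100 is the percentage of included grid cells that contain 100% of a week's
cattle activity — because activity is defined on raw fix counts, the minimal
cell set holding all activity is exactly the set of visited cells, so CA100
is the visited-cell fraction. Large CA100 means the herd spreads over more
of the available marsh.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import ZONE_ORDER
from .grid import ActivityGrid
from .telemetry import TrackSet
from .grid import distance_to_seawall

__all__ = [
    "ca100", "never_visited_fraction", "zone_activity_share",
    "zone_area_share", "p95_distance", "weekly_series",
]


def ca100(activity: ActivityGrid, week: int) -> float | None:
    """Percentage of included cells visited (>= 1 fix) in the week.

    Weeks with no within-marsh fixes have no defined spread and return None.
    """
    if week not in activity.week_totals.index:
        return None
    n_included = int(activity.cells["included"].sum())
    visited = activity.counts[(activity.counts["week"] == week) & (activity.counts["n"] >= 1)]
    return 100.0 * visited["cell_id"].nunique() / n_included


def never_visited_fraction(activity: ActivityGrid) -> float:
    """Percentage of included cells with zero fixes over the whole season."""
    n_included = int(activity.cells["included"].sum())
    if n_included == 0:
        raise ValueError("no included cells")
    visited = activity.counts.loc[activity.counts["n"] >= 1, "cell_id"].nunique()
    return 100.0 * (n_included - visited) / n_included


def zone_activity_share(activity: ActivityGrid, week: int) -> dict[str, float]:
    """Percentage of the week's within-marsh fixes in each habitat zone.

    Zones absent from the marsh are omitted. Shares sum to 100 for weeks
    with fixes.
    """
    if activity.cells["zone"].isna().all():
        raise ValueError("zones not assigned; run assign_zones first")
    if week not in activity.week_totals.index:
        return {}
    n_w = float(activity.week_totals.loc[week])
    zone_of = activity.included.set_index("cell_id")["zone"]
    sub = activity.counts[activity.counts["week"] == week]
    by_zone = sub.groupby(sub["cell_id"].map(zone_of))["n"].sum()
    present = [z for z in ZONE_ORDER if (zone_of == z).any()]
    return {z: 100.0 * float(by_zone.get(z, 0)) / n_w for z in present}


def zone_area_share(activity: ActivityGrid) -> dict[str, float]:
    """Percentage of total included marsh area in each zone (the 'Area' bars)."""
    inc = activity.included
    total = inc["marsh_area_m2"].sum()
    by_zone = inc.groupby("zone")["marsh_area_m2"].sum()
    present = [z for z in ZONE_ORDER if z in by_zone.index]
    return {z: 100.0 * float(by_zone.loc[z]) / total for z in present}


def p95_distance(tracks: TrackSet, seawall, week: int | None = None,
                 low_n: int = 20) -> float | None:
    """95th percentile of fix distances to the seawall (pooled over collars).

    The 95th (not the maximum) excludes one-off trips to distant points.
    Linear interpolation between order statistics (the type-7 definition).
    Returns None for an empty week; warns when fewer than ``low_n`` fixes.
    """
    fixes = tracks.fixes
    if week is not None:
        if "week" not in fixes.columns:
            raise ValueError("fixes must be week-labelled to select a week")
        fixes = fixes[fixes["week"] == week]
    if len(fixes) == 0:
        return None
    if len(fixes) < low_n:
        warnings.warn(f"p95_distance: only {len(fixes)} fixes (week={week}); "
                      "estimate is low-precision")
    d = distance_to_seawall(fixes[["x_m", "y_m"]].to_numpy(), seawall)
    return float(np.percentile(d, 95))


def weekly_series(activity: ActivityGrid, tracks: TrackSet, seawall) -> pd.DataFrame:
    """Per-week summary table: CA100, p95 distance, and zone activity shares."""
    rows = []
    zones_present = [z for z in ZONE_ORDER
                     if (activity.included["zone"] == z).any()]
    for w in activity.weeks:
        row = {
            "marsh_id": activity.marsh_id,
            "week": w,
            "ca100_pct": ca100(activity, w),
            "p95_dist_m": p95_distance(tracks, seawall, w),
        }
        shares = zone_activity_share(activity, w)
        for z in zones_present:
            row[f"share_{z}_pct"] = shares.get(z, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
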