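"""Synthetic marsh, herd-movement and dummy-nest data generator.

Emulates the study system the analysis pipeline expects: a rectangular
saltmarsh bounded landward by a seawall, four habitat zones banded by
distance from the wall, a creek network, a free-roaming young-cattle herd
tracked by GPS collars at a 20-minute fix cadence, and clay-disc dummy-nest
plots whose trampling probability rises with local cattle activity.

The movement model is a biased correlated random walk with herd cohesion and
an attraction centre that drifts seaward to a mid-season peak and back — the
simplest mechanism producing the two field phenomena the pipeline must
detect: early-season concentration within a few hundred metres of the
seawall, and a hump-shaped seasonal expansion of the grazed range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, box
from shapely.ops import unary_union

from .geometry import ZONE_ORDER, MarshGeometry

__all__ = [
    "SimConfig",
    "TrueDoseResponse",
    "ConfigurationError",
    "generate_marsh",
    "simulate_herd_tracks",
    "generate_plot_layout",
    "simulate_trampling_trials",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class TrueDoseResponse:
    """Ground-truth logistic dose-response used to simulate disc trampling.

    ``logit(p_period) = beta0 + beta1 * activity`` gives the probability that
    a disc is broken at least once during one exposure period of
    ``horizon_days`` days, at the local cattle activity (cattle/ha) of the
    plot's grid cell. ``beta1 > 0``: trampling risk is non-decreasing in
    activity.
    """

    beta0: float = -4.0
    beta1: float = 2.9
    horizon_days: int = 14

    def __post_init__(self) -> None:
        if not self.beta1 > 0:
            raise ConfigurationError("beta1 must be positive (risk non-decreasing)")
        if self.horizon_days < 1:
            raise ConfigurationError("horizon_days must be >= 1")

    def p_period(self, activity) -> np.ndarray:
        """Per-period trampling probability at the given activity."""
        eta = self.beta0 + self.beta1 * np.asarray(activity, dtype=float)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))

    def p24(self, activity, incubation_days: int = 24) -> np.ndarray:
        """Implied incubation-length trampling probability.

        The per-period probability converts to a daily probability
        ``1 - (1-p)**(1/horizon)`` and then to the incubation horizon, i.e.
        ``1 - (1-p)**(incubation/horizon)``.
        """
        p = self.p_period(activity)
        return 1.0 - (1.0 - p) ** (incubation_days / self.horizon_days)


@dataclass(frozen=True)
class SimConfig:
    """Study-system configuration for the synthetic generator.

    Defaults emulate the marsh on which the dummy-nest experiment ran: a
    126-ha saltmarsh grazed by 39 young cattle from mid-May (week 6 of the
    redshank season, which starts 14 April) to late October (week 28), with
    4 GPS collars logging every 20 minutes. Zone band widths are ordered by
    proximity to the seawall (non-saltmarsh, mid-marsh redshank, Elytrigia
    redshank, non-redshank).
    """

    marsh_area_ha: float = 126.0
    seawall_length_m: float = 1800.0
    zone_band_widths_m: tuple[float, float, float, float] = (100.0, 250.0, 150.0, 200.0)
    creek_density: float = 0.05  # fraction of marsh area occupied by creeks
    herd_size: int = 39
    n_collars: int = 4
    fix_interval_min: float = 20.0
    season_weeks: int = 28
    week1_start_date: date = date(2013, 4, 14)
    grazing_start_week: int = 6
    grazing_end_week: int = 28
    attraction_point: tuple[float, float] | None = None  # default: mid-seawall trough
    expansion_peak_week: int = 20
    range_scale: float = 1.0  # multiplies both roaming range and step noise
    tidal_pulse_amplitude: float = 0.0  # optional periodic pull to the wall, off by default
    collar_dropout: dict[str, date] | None = None  # per-collar truncation (battery failure)
    true_dose_response: TrueDoseResponse = field(default_factory=TrueDoseResponse)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.marsh_area_ha <= 0 or self.seawall_length_m <= 0:
            raise ConfigurationError("marsh area and seawall length must be positive")
        if len(self.zone_band_widths_m) != 4 or any(w <= 0 for w in self.zone_band_widths_m):
            raise ConfigurationError("zone_band_widths_m must be 4 positive widths")
        if self.creek_density < 0 or self.creek_density >= 0.5:
            raise ConfigurationError("creek_density must be in [0, 0.5)")
        if self.herd_size < 1:
            raise ConfigurationError("herd_size must be a positive integer")
        if not (1 <= self.n_collars <= self.herd_size):
            raise ConfigurationError("n_collars must be in [1, herd_size]")
        if self.fix_interval_min <= 0:
            raise ConfigurationError("fix_interval_min must be positive")
        if not (1 <= self.grazing_start_week <= self.grazing_end_week <= self.season_weeks):
            raise ConfigurationError("grazing weeks must satisfy 1 <= start <= end <= season")
        if self.range_scale < 0:
            raise ConfigurationError("range_scale must be >= 0")

    @property
    def boundary_depth_m(self) -> float:
        """Marsh depth (seawall to seaward edge). The boundary is inflated so
        that the usable area (boundary minus creeks) matches marsh_area_ha."""
        boundary_area = self.marsh_area_ha * 10_000.0 / (1.0 - self.creek_density)
        return boundary_area / self.seawall_length_m

    @property
    def attraction_xy(self) -> tuple[float, float]:
        if self.attraction_point is not None:
            return self.attraction_point
        return (0.0, self.seawall_length_m / 2.0)

    @property
    def grazing_start(self) -> datetime:
        d = self.week1_start_date + timedelta(weeks=self.grazing_start_week - 1)
        return datetime(d.year, d.month, d.day)

    @property
    def grazing_end(self) -> datetime:
        d = self.week1_start_date + timedelta(weeks=self.grazing_end_week)
        return datetime(d.year, d.month, d.day)


def _rng(config: SimConfig, stream: int, seed: int | None = None) -> np.random.Generator:
    base = config.rng_seed if seed is None else seed
    return np.random.default_rng([base, stream])


def generate_marsh(config: SimConfig) -> MarshGeometry:
    """Build the rectangular marsh with zone bands and a creek network.

    The seawall runs along the x = 0 edge so that a point's x-coordinate is
    its distance from the wall. Zone bands are laid seaward in
    :data:`ZONE_ORDER`; the outermost (non-redshank) band is extended to the
    seaward edge so the bands tile the marsh. Creeks are narrow rectangles
    reaching in from the seaward edge, covering ``creek_density`` of the
    boundary area; zone polygons exclude creeks so that zones partition the
    usable marsh exactly.
    """
    depth = config.boundary_depth_m
    length = config.seawall_length_m

    cum = 0.0
    edges = [0.0]
    for name, w in zip(ZONE_ORDER, config.zone_band_widths_m):
        cum += w
        if cum > depth + 1e-6 and name != ZONE_ORDER[-1]:
            raise ConfigurationError(
                f"zone band '{name}' ends at {cum:.1f} m, beyond the marsh depth "
                f"{depth:.1f} m implied by area and seawall length"
            )
        edges.append(min(cum, depth))
    if edges[-2] >= depth:
        raise ConfigurationError(
            f"zone band '{ZONE_ORDER[-1]}' has no room: inner bands already reach "
            f"the marsh depth {depth:.1f} m"
        )
    edges[-1] = depth  # outermost band absorbs any remaining depth

    boundary = box(0.0, 0.0, depth, length)
    seawall = LineString([(0.0, 0.0), (0.0, length)])

    creeks: list[Polygon] = []
    if config.creek_density > 0:
        rng = _rng(config, 1)
        target = config.creek_density * boundary.area
        acc = 0.0
        while acc < target:
            width = rng.uniform(3.0, 8.0)
            reach = rng.uniform(0.2, 0.8) * depth
            need = (target - acc) / width
            reach = min(reach, need)
            if reach < 1.0:
                reach = need  # trim the final creek to hit the target area
            y0 = rng.uniform(0.0, length - width)
            creek = box(depth - reach, y0, depth, y0 + width)
            creeks.append(creek)
            acc = unary_union(creeks).area

    creek_union = unary_union(creeks) if creeks else Polygon()
    zones: dict[str, Polygon] = {}
    for name, x0, x1 in zip(ZONE_ORDER, edges[:-1], edges[1:]):
        band = box(x0, 0.0, x1, length)
        zones[name] = band.difference(creek_union)

    return MarshGeometry(boundary=boundary, seawall=seawall, creeks=creeks, zones=zones)


def _range_profile(config: SimConfig, week: np.ndarray, depth: float) -> np.ndarray:
    """Hump-shaped roaming range (m) by (fractional) week: small early, peaking
    at expansion_peak_week, shrinking again toward the season's end."""
    r0, rmax, sigma = 120.0, 0.75 * depth, 5.5
    hump = r0 + (rmax - r0) * np.exp(-0.5 * ((week - config.expansion_peak_week) / sigma) ** 2)
    return config.range_scale * hump


def simulate_herd_tracks(marsh: MarshGeometry, config: SimConfig):
    """Simulate collar fixes over the grazing window.

    One fix per collar every ``fix_interval_min`` minutes. Each collar's
    velocity mixes persistence, attraction toward a drifting herd centre
    (anchored at the water trough early and late, furthest seaward at
    ``expansion_peak_week``), cohesion toward the current herd centroid, and
    Gaussian noise. Walkers are reflected off the boundary and nudged out of
    creeks, never discarded. Identical seed => identical fix table.
    """
    from .telemetry import TrackSet  # local import to avoid a cycle

    rng = _rng(config, 2)
    depth = config.boundary_depth_m
    length = config.seawall_length_m
    ax, ay = config.attraction_xy

    window_min = (config.grazing_end - config.grazing_start).total_seconds() / 60.0
    n_steps = int(math.floor(window_min / config.fix_interval_min))
    times = pd.to_datetime(config.grazing_start) + pd.to_timedelta(
        np.arange(n_steps) * config.fix_interval_min, unit="m"
    )
    week1 = datetime(config.week1_start_date.year, config.week1_start_date.month,
                     config.week1_start_date.day)
    week_frac = 1.0 + (times - week1).total_seconds() / (7 * 86400.0)
    ranges = _range_profile(config, week_frac.to_numpy(), depth)

    n = config.n_collars
    pos = np.tile([ax, ay], (n, 1)).astype(float)
    pos[:, 1] += config.range_scale * rng.normal(0.0, 10.0, size=n)
    pos[:, 1] = np.clip(pos[:, 1], 0.0, length)
    vel = np.zeros((n, 2))

    persist, pull, cohesion = 0.60, 0.06, 0.05
    # wandering scales with the seasonal range: tight clusters near the wall
    # early and late, loose ranging at the mid-season peak
    noise_sds = config.range_scale * (8.0 + 0.035 * ranges / max(config.range_scale, 1e-12)) \
        if config.range_scale > 0 else np.zeros(n_steps)

    xs = np.empty((n_steps, n))
    ys = np.empty((n_steps, n))
    steps_per_day = 86400.0 / (config.fix_interval_min * 60.0)
    for k in range(n_steps):
        r = ranges[k]
        noise_sd = noise_sds[k] if config.range_scale > 0 else 0.0
        cx = min(r, 0.92 * depth)
        cy = ay
        if config.tidal_pulse_amplitude > 0:
            # optional semi-diurnal pull back toward the wall (off by default)
            phase = 2.0 * math.pi * (k / steps_per_day) / 0.5175
            cx *= max(0.0, 1.0 - config.tidal_pulse_amplitude * 0.5 * (1 + math.cos(phase)))
        centre = np.array([cx, cy])
        centroid = pos.mean(axis=0)
        vel = (
            persist * vel
            + pull * (centre - pos)
            + cohesion * (centroid - pos)
            + rng.normal(0.0, noise_sd, size=(n, 2))
        )
        pos = pos + vel
        # reflect at the rectangular boundary
        for dim, hi in ((0, depth), (1, length)):
            low = pos[:, dim] < 0
            pos[low, dim] = -pos[low, dim]
            vel[low, dim] = -vel[low, dim]
            high = pos[:, dim] > hi
            pos[high, dim] = 2 * hi - pos[high, dim]
            vel[high, dim] = -vel[high, dim]
        pos[:, 0] = np.clip(pos[:, 0], 0.0, depth)
        pos[:, 1] = np.clip(pos[:, 1], 0.0, length)
        xs[k] = pos[:, 0]
        ys[k] = pos[:, 1]

    collars = [f"C{i+1}" for i in range(n)]
    frames = []
    for i, collar in enumerate(collars):
        frames.append(pd.DataFrame({
            "collar_id": collar,
            "timestamp": times,
            "x_m": xs[:, i],
            "y_m": ys[:, i],
        }))
    fixes = pd.concat(frames, ignore_index=True)

    fixes = _evict_from_creeks(fixes, marsh)

    if config.collar_dropout:
        keep = np.ones(len(fixes), dtype=bool)
        for collar, last_day in config.collar_dropout.items():
            cutoff = pd.Timestamp(last_day) + pd.Timedelta(days=1)
            keep &= ~((fixes["collar_id"] == collar) & (fixes["timestamp"] >= cutoff))
        fixes = fixes.loc[keep].reset_index(drop=True)

    fixes = fixes.sort_values(["collar_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return TrackSet(
        fixes=fixes,
        herd_size=config.herd_size,
        marsh_id=marsh.marsh_id,
        grazing_start=config.grazing_start.date(),
        grazing_end=(config.grazing_end - timedelta(days=1)).date(),
    )


def _evict_from_creeks(fixes: pd.DataFrame, marsh: MarshGeometry) -> pd.DataFrame:
    """Shift any fix that landed in a creek to the nearest usable ground.

    Creeks are narrow, so offenders are few; each is pushed away from the
    creek in small steps (first alongshore, then landward) until clear.
    """
    if not marsh.creeks:
        return fixes
    import shapely

    creek_union = marsh.creek_union
    pts = shapely.points(fixes[["x_m", "y_m"]].to_numpy())
    inside = shapely.contains(creek_union, pts)
    if not inside.any():
        return fixes
    fixes = fixes.copy()
    length = marsh.boundary.bounds[3]
    for idx in np.flatnonzero(inside):
        x, y = fixes.iloc[idx][["x_m", "y_m"]]
        moved = False
        for dy in np.arange(1.0, 200.0):
            for sign in (1.0, -1.0):
                yy = y + sign * dy
                if 0 <= yy <= length and not creek_union.contains(shapely.Point(x, yy)):
                    fixes.iloc[idx, fixes.columns.get_loc("y_m")] = yy
                    moved = True
                    break
            if moved:
                break
        if not moved:  # pragma: no cover - creeks are never this wide
            for dx in np.arange(1.0, 2000.0):
                if x - dx >= 0 and not creek_union.contains(shapely.Point(x - dx, y)):
                    fixes.iloc[idx, fixes.columns.get_loc("x_m")] = x - dx
                    break
    return fixes


def generate_plot_layout(
    marsh: MarshGeometry,
    n_plots: int = 30,
    min_spacing_m: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified random dummy-nest plot centres.

    Mirrors the field design: plots spread over all habitat zones and the
    full range of distances from the seawall, at least ``min_spacing_m``
    apart. Each plot holds nine discs in a 9 m x 9 m grid (3 m spacing);
    only the centre is needed downstream because local activity is read from
    the 50-m cell containing it.
    """
    import shapely

    rng = np.random.default_rng([seed, 3])
    zones = [z for z in ZONE_ORDER if z in marsh.zones and marsh.zones[z].area > 0]
    per_zone = {z: n_plots // len(zones) for z in zones}
    for z in zones[: n_plots % len(zones)]:
        per_zone[z] += 1

    rows = []
    placed: list[tuple[float, float]] = []
    for zone in zones:
        geom = marsh.zones[zone]
        minx, miny, maxx, maxy = geom.bounds
        got = 0
        attempts = 0
        while got < per_zone[zone] and attempts < 20_000:
            attempts += 1
            x = rng.uniform(minx + 5, maxx - 5)
            y = rng.uniform(miny + 5, maxy - 5)
            if not geom.contains(shapely.Point(x, y)):
                continue
            if any((x - px) ** 2 + (y - py) ** 2 < min_spacing_m**2 for px, py in placed):
                continue
            placed.append((x, y))
            rows.append({"plot_id": f"P{len(rows)+1:02d}", "x_m": x, "y_m": y, "zone": zone})
            got += 1
        if got < per_zone[zone]:
            warnings.warn(
                f"could only place {got}/{per_zone[zone]} plots in zone {zone}; "
                "consider reducing min_spacing_m"
            )
    return pd.DataFrame(rows)


def simulate_trampling_trials(
    activity,
    plots: pd.DataFrame,
    truth: TrueDoseResponse,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate disc-level trampling outcomes for two exposure periods.

    Each plot's nine discs are independent Bernoulli trials per 14-day
    period with ``logit(p) = beta0 + beta1 * local_activity``, where local
    activity is the window activity (cattle/ha) of the grid cell containing
    the plot centre. Broken discs are replaced after period 1, so period 2
    again exposes nine discs. Plots whose centre falls outside an included
    grid cell are flagged and excluded with a warning.

    Returns a tidy disc table: plot_id, disc_id, period, broken,
    local_activity_ha, x_m, y_m.
    """
    rng = np.random.default_rng([seed, 4])
    window = activity.window_activity()
    rows = []
    excluded = []
    for rec in plots.itertuples(index=False):
        cid = activity.cell_id_at(rec.x_m, rec.y_m)
        if cid is None or cid not in window.index:
            excluded.append(rec.plot_id)
            continue
        a = float(window.loc[cid])
        if np.isneginf(truth.beta0):
            p = 0.0
        else:
            p = float(truth.p_period(a))
        for period in (1, 2):
            broken = rng.random(9) < p
            for disc in range(9):
                rows.append({
                    "plot_id": rec.plot_id,
                    "disc_id": disc + 1,
                    "period": period,
                    "broken": int(broken[disc]),
                    "local_activity_ha": a,
                    "x_m": rec.x_m,
                    "y_m": rec.y_m,
                })
    if excluded:
        warnings.warn(
            f"{len(excluded)} plot(s) fell outside included grid cells and were "
            f"excluded: {excluded}"
        )
    return pd.DataFrame(rows)
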