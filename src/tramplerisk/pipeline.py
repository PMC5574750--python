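"""End-to-end stages: simulate a study dataset to disk, and run the full
analysis (activity surfaces -> range metrics -> trend models -> trampling
dose-response -> risk maps) over fix/geometry/trial files.

Every output table carries a header comment with the config hash and seed;
deterministic stages are bit-stable under rerun.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import range_metrics as rm
from .config import RunConfig
from .geometry import read_marsh_geojson, write_marsh_geojson
from .grid import (
    activity_over_window,
    assign_zones,
    build_grid,
    cattle_activity,
    seasonal_cattle_density,
    write_cells_geojson,
)
from .synthetic import (
    generate_marsh,
    generate_plot_layout,
    simulate_herd_tracks,
    simulate_trampling_trials,
)
from .telemetry import SeasonCalendar, assign_weeks, cattle_days, read_fixes, write_fixes_csv
from .trampling import (
    fit_dose_response,
    morans_i,
    plot_probabilities,
    predict_risk_map,
    trials_from_disc_table,
    zone_risk_summary,
)
from .trends import ModelSpec, acf_diagnostic, backward_select, fit_zone_glm

log = logging.getLogger(__name__)


def _stamp(cfg: RunConfig) -> str:
    return f"config={cfg.config_hash()} seed={cfg.seed}"


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_stamp(cfg)}\n")
        df.to_csv(fh, index=False, float_format="%.8g")


def run_simulate(cfg: RunConfig) -> dict[str, Path]:
    """Generate and write a synthetic study dataset (marsh, fixes, trials).

    Deterministic under (config, seed); the seed is recorded in every file
    header. Returns the paths written.
    """
    sim = replace(cfg.sim, rng_seed=cfg.seed)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    marsh = generate_marsh(sim)
    tracks = simulate_herd_tracks(marsh, sim)

    cal = SeasonCalendar(week1_start=sim.week1_start_date, n_weeks=sim.season_weeks)
    tracks = assign_weeks(tracks, cal)
    cells = assign_zones(build_grid(marsh, cfg.cell_size_m,
                                    inclusion_threshold_m2=cfg.inclusion_threshold_m2),
                         marsh)
    window = activity_over_window(tracks, cells, cal, sim.grazing_start,
                                  days=cfg.incubation_days)
    plots = generate_plot_layout(marsh, n_plots=cfg.n_plots, seed=cfg.seed)
    discs = simulate_trampling_trials(window, plots, sim.true_dose_response,
                                      seed=cfg.seed)

    paths = {
        "geometry": cfg.path("geometry"),
        "fixes": cfg.path("fixes"),
        "trials": cfg.path("trials"),
        "plots": outdir / "plots.csv",
        "config": outdir / "config_echo.yaml",
    }
    write_marsh_geojson(marsh, paths["geometry"])
    write_fixes_csv(tracks, paths["fixes"], header_comment=_stamp(cfg))
    _write_csv(discs, paths["trials"], cfg)
    _write_csv(plots, paths["plots"], cfg)
    cfg.to_yaml(paths["config"])
    log.info("simulate: wrote %d fixes, %d disc records", tracks.n_fixes, len(discs))
    return paths


def run_analysis(cfg: RunConfig) -> dict:
    """Run the full analysis over the configured input files.

    Emits activity surfaces, a weekly metrics table, trend-model summaries
    with removal logs, per-zone models, the trampling probability table,
    the dose-response curve and the 24-day risk map. A missing trials file
    skips the trampling stage with a logged notice rather than failing the
    range-metric stages.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "settings": cfg.to_dict(),
                    "config_hash": cfg.config_hash()}

    stage = "read inputs"
    try:
        marsh = read_marsh_geojson(cfg.path("geometry"))
        tracks = read_fixes(cfg.path("fixes"), herd_size=cfg.sim.herd_size,
                            marsh_id=marsh.marsh_id)
        cal = SeasonCalendar(week1_start=cfg.sim.week1_start_date,
                             n_weeks=cfg.sim.season_weeks)
        tracks = assign_weeks(tracks, cal)

        stage = "activity grid"
        cells = assign_zones(
            build_grid(marsh, cfg.cell_size_m,
                       inclusion_threshold_m2=cfg.inclusion_threshold_m2),
            marsh,
        )
        activity = cattle_activity(tracks, cells)
        _write_csv(activity.activity_table(), outdir / "activity_weekly.csv", cfg)
        write_cells_geojson(activity, outdir / "activity_cells.geojson")

        stock = seasonal_cattle_density(tracks.herd_size, marsh.usable_area_ha,
                                        cfg.lsu_coefficient)
        report["stocking"] = {"scd_per_ha": stock.scd_rounded,
                              "lsu_per_ha": stock.lsu_rounded,
                              "cattle_days": cattle_days(tracks),
                              "n_fixes": tracks.n_fixes}

        stage = "range metrics"
        weekly = rm.weekly_series(activity, tracks, marsh.seawall)
        _write_csv(weekly, outdir / "weekly_metrics.csv", cfg)
        report["never_visited_pct"] = rm.never_visited_fraction(activity)
        report["zone_area_share"] = rm.zone_area_share(activity)
        report["weekly"] = weekly

        stage = "trend models"
        trend_data = weekly.rename(columns={"ca100_pct": "ca100"}).dropna(subset=["ca100"])
        multi_marsh = trend_data["marsh_id"].nunique() >= 2
        terms = None if multi_marsh else ("week", "week2")
        ca_spec = ModelSpec(response="ca100", transform="log10",
                            terms=terms or ModelSpec("x").terms, correlation="ar1")
        ca_fit = backward_select(ca_spec, trend_data, alpha=cfg.alpha)
        d_spec = replace(ca_spec, response="p95_dist_m", transform="identity")
        d_fit = backward_select(d_spec, trend_data.dropna(subset=["p95_dist_m"]),
                                alpha=cfg.alpha)
        report["trend_fits"] = {"ca100": ca_fit, "p95_dist": d_fit}
        _write_trend_summary(outdir / "trend_models.txt", cfg,
                             {"CA100 (log10)": ca_fit, "p95 distance": d_fit})
        report["acf"] = {"ca100": acf_diagnostic(ca_fit),
                         "p95_dist": acf_diagnostic(d_fit)}

        stage = "zone models"
        zone_fits = {}
        for zone in activity.included["zone"].dropna().unique():
            zdata = _zone_series(activity, zone)
            fit = fit_zone_glm(zone, zdata, transform="sqrt", alpha=cfg.alpha)
            if fit is not None:
                zone_fits[zone] = fit
        report["zone_fits"] = zone_fits

        stage = "trampling"
        trials_path = cfg.path("trials")
        if not trials_path.exists():
            log.warning("trials file %s missing; trampling stage skipped", trials_path)
            report["stages"].append((stage, "skipped: no trials file"))
        else:
            discs = pd.read_csv(trials_path, comment="#")
            trials = trials_from_disc_table(discs)
            probs = pd.DataFrame([{
                "plot_id": t.plot_id, "local_activity_ha": t.local_activity_ha,
                **plot_probabilities(t, cfg.period_days, cfg.incubation_days).__dict__,
            } for t in trials])
            _write_csv(probs, outdir / "trampling_probabilities.csv", cfg)

            model = fit_dose_response(trials, period_days=cfg.period_days,
                                      incubation_days=cfg.incubation_days)
            report["dose_response"] = model
            _write_csv(model.curve_table(), outdir / "dose_response_curve.csv", cfg)

            resid = probs["p24"].to_numpy() - model.predict(
                probs["local_activity_ha"].to_numpy())
            coords = np.array([t.centre for t in trials])
            report["moran"] = morans_i(resid, coords, seed=cfg.seed)

            window = activity_over_window(tracks, cells, cal,
                                          pd.Timestamp(tracks.grazing_start),
                                          days=cfg.incubation_days)
            risk = predict_risk_map(model, window)
            _write_csv(risk, outdir / "risk_map.csv", cfg)
            _write_csv(zone_risk_summary(risk), outdir / "risk_by_zone.csv", cfg)
            report["risk_map"] = risk
            report["risk_by_zone"] = zone_risk_summary(risk)
            _plot_outputs(outdir, weekly, model, risk)

        report["stages"].append(("complete", "ok"))
    except Exception as exc:
        raise RuntimeError(f"analysis failed at stage '{stage}': {exc}") from exc

    _write_run_log(outdir / "run_log.txt", cfg, report)
    return report


def _zone_series(activity, zone: str) -> pd.DataFrame:
    """Weekly mean cattle density within one habitat zone (cattle/ha)."""
    inc = activity.included.set_index("cell_id")
    zone_cells = inc.index[inc["zone"] == zone]
    area_ha = inc.loc[zone_cells, "marsh_area_m2"].sum() / 10_000.0
    rows = []
    for w in activity.weeks:
        sub = activity.counts[(activity.counts["week"] == w)
                              & activity.counts["cell_id"].isin(zone_cells)]
        n = float(sub["n"].sum())
        n_w = float(activity.week_totals.loc[w])
        rows.append({"marsh_id": activity.marsh_id, "week": w,
                     "activity": activity.herd_size * (n / n_w) / area_ha})
    return pd.DataFrame(rows)


def _write_trend_summary(path: Path, cfg: RunConfig, fits: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_stamp(cfg)}\n")
        for name, fit in fits.items():
            fh.write(f"\n== {name} ==\n")
            fh.write(f"terms: {', '.join(fit.spec.terms) or '(intercept only)'}\n")
            fh.write(f"phi (AR1): {fit.phi:.4f}  logLik: {fit.loglik:.3f}\n")
            fh.write(fit.anova_table.to_string(index=False,
                                               float_format=lambda v: f"{v:.4g}"))
            fh.write("\nremoved: " + (", ".join(
                f"{t} (p={p:.3g})" for t, p in fit.removal_log) or "none") + "\n")


def _plot_outputs(outdir: Path, weekly: pd.DataFrame, model, risk: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    axes[0].plot(weekly["week"], weekly["ca100_pct"], "o-")
    axes[0].set(xlabel="week (1 = 14 April)", ylabel="CA100 (%)",
                title="Spread of cattle activity")
    curve = model.curve_table()
    axes[1].plot(curve["activity_ha"], curve["p24"], "k-")
    axes[1].fill_between(curve["activity_ha"], curve["ci_low"], curve["ci_high"],
                         alpha=0.25)
    axes[1].set(xlabel="cattle activity (ha$^{-1}$)", ylabel="P(trampled in 24 d)",
                title="Dose-response")
    sc = axes[2].scatter(risk["dist_seawall_m"], risk["p24"], c=risk["activity_24d"],
                         s=8, cmap="viridis")
    fig.colorbar(sc, ax=axes[2], label="activity (ha$^{-1}$)")
    axes[2].set(xlabel="distance to seawall (m)", ylabel="P(trampled in 24 d)",
                title="Risk vs distance to wall")
    fig.tight_layout()
    fig.savefig(outdir / "summary_figures.png", dpi=120)
    plt.close(fig)


def _write_run_log(path: Path, cfg: RunConfig, report: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_stamp(cfg)}\n")
        fh.write("settings in force:\n")
        for key in ("cell_size_m", "inclusion_threshold_m2", "alpha",
                    "lsu_coefficient", "incubation_days", "period_days", "seed"):
            fh.write(f"  {key} = {getattr(cfg, key)}\n")
        if "stocking" in report:
            for k, v in report["stocking"].items():
                fh.write(f"  {k} = {v}\n")
        if "never_visited_pct" in report:
            fh.write(f"  never_visited_pct = {report['never_visited_pct']:.2f}\n")
        for stage, status in report["stages"]:
            fh.write(f"stage {stage}: {status}\n")
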