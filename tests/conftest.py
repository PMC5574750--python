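"""Shared fixtures: a full default simulated season (built once per session)
and a small fast marsh for unit-level checks."""

from __future__ import annotations

import numpy as np
import pytest

from tramplerisk.grid import activity_over_window, assign_zones, build_grid, cattle_activity
from tramplerisk.synthetic import (
    SimConfig,
    generate_marsh,
    generate_plot_layout,
    simulate_herd_tracks,
    simulate_trampling_trials,
)
from tramplerisk.telemetry import SeasonCalendar, assign_weeks
from tramplerisk.trampling import fit_dose_response, trials_from_disc_table


def small_config(**overrides) -> SimConfig:
    """A 20-ha marsh with a short grazing window: fast to simulate, same
    statistical structure as the default season."""
    kw = dict(
        marsh_area_ha=20.0,
        seawall_length_m=500.0,
        zone_band_widths_m=(50.0, 150.0, 100.0, 100.0),
        herd_size=10,
        n_collars=2,
        fix_interval_min=60.0,
        grazing_start_week=6,
        grazing_end_week=9,
        expansion_peak_week=7,
        rng_seed=0,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def default_season():
    """Default study conditions, seed 7: marsh, week-labelled tracks, zoned
    cells, season-long activity grid."""
    cfg = SimConfig(rng_seed=7)
    marsh = generate_marsh(cfg)
    cal = SeasonCalendar(week1_start=cfg.week1_start_date, n_weeks=cfg.season_weeks)
    tracks = assign_weeks(simulate_herd_tracks(marsh, cfg), cal)
    cells = assign_zones(build_grid(marsh), marsh)
    activity = cattle_activity(tracks, cells)
    return {"cfg": cfg, "marsh": marsh, "cal": cal, "tracks": tracks,
            "cells": cells, "activity": activity}


@pytest.fixture(scope="session")
def trampling_bundle(default_season):
    """Dummy-nest experiment over the first 24 days of grazing on the default
    season: plots, disc outcomes, fitted dose-response."""
    d = default_season
    cfg = d["cfg"]
    window = activity_over_window(d["tracks"], d["cells"], d["cal"],
                                  cfg.grazing_start, days=24)
    plots = generate_plot_layout(d["marsh"], n_plots=30, seed=7)
    discs = simulate_trampling_trials(window, plots, cfg.true_dose_response, seed=7)
    trials = trials_from_disc_table(discs)
    model = fit_dose_response(trials)
    return {"window": window, "plots": plots, "discs": discs,
            "trials": trials, "model": model, "truth": cfg.true_dose_response}


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
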