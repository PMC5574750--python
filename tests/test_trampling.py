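"""Trampling probability algebra (against exact arithmetic), the smooth
binomial dose-response (against simulation truth and an independent R/mgcv
fit), and risk-map projection."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tramplerisk.synthetic import TrueDoseResponse
from tramplerisk.trampling import (
    PlotTrial,
    daily_probability,
    fit_dose_response,
    incubation_probability,
    morans_i,
    plot_probabilities,
    predict_risk_map,
    trials_from_disc_table,
    zone_risk_summary,
)


class TestProbabilityAlgebra:
    def test_zero_and_one_preserved(self):
        assert daily_probability(0.0) == 0.0
        assert daily_probability(1.0) == 1.0
        assert incubation_probability(0.0) == 0.0
        assert incubation_probability(1.0) == 1.0

    def test_half_period_against_exact_arithmetic(self):
        """1 - 2^(-1/14) and its 24-day compound, to 30 significant digits."""
        import sympy

        daily_exact = float((1 - sympy.Rational(1, 2) ** sympy.Rational(1, 14))
                            .evalf(30))
        assert daily_probability(0.5, 14) == pytest.approx(daily_exact, abs=1e-15)
        assert daily_probability(0.5, 14) == pytest.approx(0.0483, abs=5e-5)
        p24_exact = float((1 - (sympy.Rational(1, 2) ** sympy.Rational(1, 14))
                           ** 24).evalf(30))
        got = incubation_probability(daily_probability(0.5, 14), 24)
        assert got == pytest.approx(p24_exact, abs=1e-14)
        assert got == pytest.approx(0.695, abs=5e-4)

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_incubation_inverts_daily_with_equal_days(self, p):
        assert incubation_probability(daily_probability(p, 14), 14) == pytest.approx(
            p, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6),
           st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(max_examples=100, deadline=None)
    def test_daily_strictly_increasing_in_period_probability(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert daily_probability(lo) < daily_probability(hi)

    def test_daily_decreasing_in_days(self):
        assert daily_probability(0.5, 14) > daily_probability(0.5, 28)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            daily_probability(1.2)
        with pytest.raises(ValueError):
            incubation_probability(-0.1)


class TestPlotProbabilities:
    def test_all_intact_and_all_broken_limits(self):
        zero = plot_probabilities(PlotTrial("P", (0, 0), 0, 0, 1.0))
        assert zero.p24 == 0.0
        one = plot_probabilities(PlotTrial("P", (0, 0), 9, 9, 1.0))
        assert one.p24 == 1.0

    def test_mixed_counts_single_expression_oracle(self):
        t = plot_probabilities(PlotTrial("P", (0, 0), 3, 6, 1.0))
        d1 = 1 - (1 - 1 / 3) ** (1 / 14)
        d2 = 1 - (1 - 2 / 3) ** (1 / 14)
        assert t.p_period1 == pytest.approx(1 / 3)
        assert t.p_period2 == pytest.approx(2 / 3)
        assert t.p24 == pytest.approx(1 - (1 - (d1 + d2) / 2) ** 24, abs=1e-14)
        assert t.d_mean < t.p24  # incubation compounds the daily hazard

    def test_disc_table_aggregation(self):
        rows = []
        for period in (1, 2):
            for disc in range(1, 10):
                rows.append({"plot_id": "P01", "disc_id": disc, "period": period,
                             "broken": int(disc <= (3 if period == 1 else 6)),
                             "local_activity_ha": 1.5, "x_m": 10.0, "y_m": 20.0})
        trials = trials_from_disc_table(pd.DataFrame(rows))
        assert len(trials) == 1
        assert trials[0].broken_p1 == 3 and trials[0].broken_p2 == 6
        assert trials[0].local_activity_ha == 1.5


def simulate_trials(rng, truth, activities):
    trials = []
    for i, a in enumerate(activities):
        p = float(truth.p_period(a))
        trials.append(PlotTrial(f"P{i}", (float(i), 0.0), int(rng.binomial(9, p)),
                                int(rng.binomial(9, p)), float(a)))
    return trials


class TestFitDoseResponse:
    def test_null_data_predicts_near_zero(self, rng):
        trials = [PlotTrial(f"P{i}", (i, 0), 0, 0, float(a))
                  for i, a in enumerate(np.linspace(0, 3, 12))]
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_dose_response(trials)
        assert model.degenerate
        assert model.predict(0.0) < 0.05
        assert np.all(model.predict(np.linspace(0, 3, 20)) < 0.05)

    def test_recovers_logistic_truth_shape(self, rng):
        truth = TrueDoseResponse(beta0=-4.0, beta1=2.9)
        acts = np.concatenate([[0.0], rng.uniform(0, 4.5, 39)])
        model = fit_dose_response(simulate_trials(rng, truth, acts))
        probe = np.array([0.0, 1.0, 2.0, 4.0])
        pred = model.predict(probe)
        true = truth.p24(probe)
        assert np.all(np.abs(pred - true) < 0.25)
        # near-monotone: the unconstrained smooth may wiggle by a few 1e-3
        assert np.all(np.diff(model.predict(np.linspace(0, 4.4, 30))) > -0.01)

    def test_saturating_truth_reaches_high_risk_by_three(self, rng):
        """A monotone saturating truth that hits ~1 above 3 cattle/ha is
        matched by the fit (risk > 0.99 at activity 3)."""
        truth = TrueDoseResponse(beta0=-4.0, beta1=3.5)
        acts = np.concatenate([np.zeros(8), rng.uniform(0.2, 5.5, 30)])
        model = fit_dose_response(simulate_trials(rng, truth, acts))
        assert truth.p24(3.0) > 0.99
        assert model.predict(3.0) > 0.99
        assert model.predict(0.0) < 0.1

    def test_effective_df_near_two_for_logistic_truth(self, rng):
        truth = TrueDoseResponse(beta0=-3.5, beta1=2.0)
        acts = np.concatenate([[0.0], rng.uniform(0, 4, 29)])
        model = fit_dose_response(simulate_trials(rng, truth, acts))
        assert 1.0 <= model.edf <= 3.5

    def test_predictions_bounded_over_observed_activity_range(self, rng):
        truth = TrueDoseResponse(beta0=-2.0, beta1=1.5)
        acts = np.concatenate([[0.0], rng.uniform(0, 12, 29)])
        model = fit_dose_response(simulate_trials(rng, truth, acts))
        grid = np.linspace(0, 12, 241)
        p = model.predict(grid)
        assert np.all((p >= 0) & (p <= 1))

    def test_extrapolation_clamped_with_warning(self, rng):
        truth = TrueDoseResponse(beta0=-2.0, beta1=1.5)
        acts = np.linspace(0, 3, 15)
        model = fit_dose_response(simulate_trials(rng, truth, acts))
        with pytest.warns(UserWarning, match="clamped"):
            far = model.predict(10.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert far == pytest.approx(model.predict(3.0))

    def test_negative_activity_rejected(self):
        trials = [PlotTrial("P", (0, 0), 1, 1, 0.5)]
        object.__setattr__(trials[0], "local_activity_ha", -1.0)
        with pytest.raises(ValueError):
            fit_dose_response(trials * 12)

    def test_curve_table_contains_ci(self, trampling_bundle):
        tab = trampling_bundle["model"].curve_table()
        assert tab["activity_ha"].iloc[0] == 0.0
        assert tab["activity_ha"].iloc[-1] == pytest.approx(12.0)
        assert ((tab["ci_low"] <= tab["p24"]) & (tab["p24"] <= tab["ci_high"])).all()

    def test_period_level_variant_agrees_roughly(self, rng):
        truth = TrueDoseResponse(beta0=-3.0, beta1=2.0)
        acts = np.concatenate([[0.0], rng.uniform(0, 4, 29)])
        trials = simulate_trials(rng, truth, acts)
        m24 = fit_dose_response(trials)
        mper = fit_dose_response(trials, period_level=True)
        probe = np.array([0.5, 1.5, 2.5])
        assert np.all(np.abs(m24.predict(probe) - mper.predict(probe)) < 0.2)

    def test_matches_mgcv_binomial_gam(self, rng):
        """Independent cross-check: R mgcv fit of the same disc-level data
        predicts within 0.08 of this implementation at interior probes."""
        truth = TrueDoseResponse(beta0=-3.0, beta1=2.0)
        acts = np.concatenate([[0.0], rng.uniform(0, 4, 39)])
        trials = simulate_trials(rng, truth, acts)
        model = fit_dose_response(trials)
        df = pd.DataFrame({
            "x": [t.local_activity_ha for t in trials],
            "succ": [round(plot_probabilities(t).p24 * t.n_discs, 6) for t in trials],
            "n": [t.n_discs for t in trials],
        })
        rscript = (
            "suppressMessages(library(mgcv));"
            "d <- read.csv('stdin');"
            "fit <- gam(cbind(succ, n - succ) ~ s(x, k = 4), family = quasibinomial, data = d);"
            "probe <- data.frame(x = c(0.5, 1.5, 2.5, 3.5));"
            "cat(predict(fit, probe, type = 'response'), sep = ',')"
        )
        try:
            out = subprocess.run(["Rscript", "-e", rscript], input=df.to_csv(index=False),
                                 capture_output=True, text=True, timeout=120, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.skip(f"Rscript/mgcv unavailable: {exc}")
        r_pred = np.array([float(v) for v in out.stdout.strip().split(",")])
        py_pred = model.predict(np.array([0.5, 1.5, 2.5, 3.5]))
        np.testing.assert_allclose(py_pred, r_pred, atol=0.08)


class TestRiskMap:
    def test_monotone_model_preserves_activity_ordering(self, trampling_bundle, default_season):
        risk = predict_risk_map(trampling_bundle["model"], trampling_bundle["window"])
        srt = risk.sort_values("activity_24d")
        assert (np.diff(srt["p24"].to_numpy()) >= -1e-9).all()
        assert risk["p24"].between(0, 1).all()
        n_included = int(default_season["cells"]["included"].sum())
        assert len(risk) == n_included

    def test_zero_activity_cells_get_zero_activity_prediction(self, trampling_bundle):
        model = trampling_bundle["model"]
        risk = predict_risk_map(model, trampling_bundle["window"])
        zero_cells = risk[risk["activity_24d"] == 0.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = model.predict(0.0)
        assert np.allclose(zero_cells["p24"], base)

    def test_redshank_zone_risk_exceeds_non_redshank(self, trampling_bundle):
        risk = predict_risk_map(trampling_bundle["model"], trampling_bundle["window"])
        summary = zone_risk_summary(risk).set_index("zone")
        ratio = (summary.loc["mid_marsh_redshank", "mean_p24"]
                 / summary.loc["non_redshank", "mean_p24"])
        assert ratio >= 2.0

    def test_window_beyond_coverage_raises(self, default_season):
        from tramplerisk.grid import activity_over_window

        d = default_season
        late = pd.Timestamp(d["tracks"].grazing_end) - pd.Timedelta(days=3)
        with pytest.raises(ValueError, match="coverage"):
            activity_over_window(d["tracks"], d["cells"], d["cal"], late, days=24)


def test_morans_i_detects_gradient_not_noise(rng):
    coords = rng.uniform(0, 100, size=(40, 2))
    noise = rng.normal(size=40)
    res = morans_i(noise, coords, seed=1)
    assert res["p_value"] > 0.01
    gradient = coords[:, 0] + rng.normal(scale=1.0, size=40)
    res2 = morans_i(gradient, coords, seed=1)
    assert res2["I"] > res["I"]
    assert res2["p_value"] < 0.05
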