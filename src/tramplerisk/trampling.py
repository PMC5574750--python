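"""Dummy-nest trampling: probability algebra, smooth dose-response, risk maps.

Each dummy-nest plot exposes nine clay discs for two 14-day periods (broken
discs replaced after period 1). A period's broken fraction converts to a
daily trampling probability

    d = 1 - (1 - p_period)^(1/14)

and the mean daily probability over the two periods converts to the
probability of at least one trampling event during the redshank incubation,

    p24 = 1 - (1 - d_mean)^24.

The dose-response relating p24 to local cattle activity (cattle/ha) is a
binomial penalized-spline smooth on the logit scale — trampling rises from
zero with no cattle and saturates at high activity — fitted by penalized
IRLS with the smoothing parameter chosen by AIC over a grid, each plot
entering as nine weighted Bernoulli trials at its p24. Projecting the fitted
curve through per-cell activity over the first 24 days of grazing yields the
nest-trampling risk map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import solve
from scipy.special import expit

from .grid import ActivityGrid

log = logging.getLogger(__name__)

__all__ = [
    "daily_probability", "incubation_probability", "PlotTrial",
    "TramplingProbabilities", "plot_probabilities", "trials_from_disc_table",
    "DoseResponse", "fit_dose_response", "predict_risk_map",
    "zone_risk_summary", "morans_i",
]


def _check_unit_interval(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"{name} must lie in [0, 1]; got {x!r}")
    return arr


def daily_probability(p_period, days: int = 14):
    """Per-day trampling probability implied by a period outcome.

    ``1 - (1 - p_period)**(1/days)``: the daily hazard-equivalent under
    independent days. Strictly increasing in p_period and decreasing in
    days for p in (0, 1).
    """
    p = _check_unit_interval(p_period, "p_period")
    if days < 1:
        raise ValueError("days must be >= 1")
    out = 1.0 - (1.0 - p) ** (1.0 / days)
    return float(out) if np.isscalar(p_period) else out


def incubation_probability(d_mean, incubation_days: int = 24):
    """Probability of at least one trampling event over an incubation.

    ``1 - (1 - d_mean)**incubation_days``; with equal day counts this is the
    exact algebraic inverse of :func:`daily_probability`.
    """
    d = _check_unit_interval(d_mean, "d_mean")
    if incubation_days < 1:
        raise ValueError("incubation_days must be >= 1")
    out = 1.0 - (1.0 - d) ** incubation_days
    return float(out) if np.isscalar(d_mean) else out


@dataclass(frozen=True)
class PlotTrial:
    """One nine-disc dummy-nest plot with per-period broken counts."""

    plot_id: str
    centre: tuple[float, float]
    broken_p1: int
    broken_p2: int
    local_activity_ha: float
    n_discs: int = 9

    def __post_init__(self) -> None:
        for b in (self.broken_p1, self.broken_p2):
            if not (0 <= b <= self.n_discs):
                raise ValueError(f"broken count {b} outside [0, {self.n_discs}]")
        if self.local_activity_ha < 0:
            raise ValueError("local activity must be >= 0")


@dataclass(frozen=True)
class TramplingProbabilities:
    p_period1: float
    p_period2: float
    d1: float
    d2: float
    d_mean: float
    p24: float


def plot_probabilities(trial: PlotTrial, period_days: int = 14,
                       incubation_days: int = 24) -> TramplingProbabilities:
    """Convert a plot's two period outcomes to daily and 24-day probabilities.

    The 24-day probability uses the mean of the two daily probabilities.
    """
    p1 = trial.broken_p1 / trial.n_discs
    p2 = trial.broken_p2 / trial.n_discs
    d1 = daily_probability(p1, period_days)
    d2 = daily_probability(p2, period_days)
    d_mean = (d1 + d2) / 2.0
    return TramplingProbabilities(
        p_period1=p1, p_period2=p2, d1=d1, d2=d2, d_mean=d_mean,
        p24=incubation_probability(d_mean, incubation_days),
    )


def trials_from_disc_table(discs: pd.DataFrame) -> list[PlotTrial]:
    """Aggregate a tidy disc table (plot_id, disc_id, period, broken,
    local_activity_ha, x_m, y_m) into per-plot trials."""
    trials = []
    for pid, sub in discs.groupby("plot_id", sort=True):
        counts = sub.groupby("period")["broken"].sum()
        n = int(sub.groupby("period")["disc_id"].nunique().max())
        trials.append(PlotTrial(
            plot_id=str(pid),
            centre=(float(sub["x_m"].iloc[0]), float(sub["y_m"].iloc[0])),
            broken_p1=int(counts.get(1, 0)),
            broken_p2=int(counts.get(2, 0)),
            local_activity_ha=float(sub["local_activity_ha"].iloc[0]),
            n_discs=n,
        ))
    return trials


class DoseResponse:
    """Fitted binomial penalized-spline dose-response: activity -> p24.

    Predictions outside the fitted activity range are clamped to the
    boundary prediction (with a warning) rather than extrapolated.
    """

    def __init__(self, knots: np.ndarray, coefs: np.ndarray, degree: int,
                 lambda_: float, edf: float, deviance: float,
                 null_deviance: float, cov: np.ndarray,
                 x_range: tuple[float, float], degenerate: bool = False):
        self.knots = knots
        self.coefs = coefs
        self.degree = degree
        self.lambda_ = lambda_
        self.edf = edf
        self.deviance = deviance
        self.null_deviance = null_deviance
        self.cov = cov  # Bayesian posterior covariance of the spline coefs
        self.x_range = x_range
        self.degenerate = degenerate

    @property
    def explained_deviance(self) -> float:
        """1 - deviance/null_deviance (the usual pseudo-R^2 for a smooth GLM)."""
        if self.null_deviance <= 0:
            return np.nan
        return 1.0 - self.deviance / self.null_deviance

    def _basis(self, x: np.ndarray) -> np.ndarray:
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def _clamp(self, activity) -> np.ndarray:
        x = np.asarray(activity, dtype=float)
        lo, hi = self.x_range
        if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
            warnings.warn(
                "activity outside the fitted range "
                f"[{lo:.3g}, {hi:.3g}]; predictions clamped to the boundary"
            )
        return np.clip(x, lo, hi)

    def predict(self, activity):
        """Predicted 24-day trampling probability at the given activity."""
        x = self._clamp(activity)
        eta = self._basis(np.atleast_1d(x)) @ self.coefs
        p = expit(eta)
        return float(p[0]) if np.isscalar(activity) else p

    def predict_interval(self, activity, level: float = 0.95):
        """Prediction with a pointwise CI (delta method on the logit scale)."""
        from scipy.stats import norm

        x = np.atleast_1d(self._clamp(activity))
        B = self._basis(x)
        eta = B @ self.coefs
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, self.cov, B), 0.0))
        z = norm.ppf(0.5 + level / 2)
        return expit(eta), expit(eta - z * se), expit(eta + z * se)

    def curve_table(self, a_max: float = 12.0, step: float = 0.05) -> pd.DataFrame:
        """Sampled dose-response curve with CI bounds over [0, a_max]."""
        grid = np.round(np.arange(0.0, a_max + step / 2, step), 10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, lo, hi = self.predict_interval(grid)
        return pd.DataFrame({"activity_ha": grid, "p24": p,
                             "ci_low": lo, "ci_high": hi})


def _binomial_deviance(y: np.ndarray, mu: np.ndarray, m: np.ndarray) -> float:
    """Deviance for (possibly fractional) binomial proportions with weights m."""
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log(np.where(y < 1, 1 - y, 1.0) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(m * (t1 + t2)))


def fit_dose_response(
    trials: list[PlotTrial],
    n_basis: int = 6,
    degree: int = 3,
    lambdas: np.ndarray | None = None,
    period_days: int = 14,
    incubation_days: int = 24,
    period_level: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> DoseResponse:
    """Fit the smooth binomial dose-response of trampling on cattle activity.

    Each plot's observed period outcomes are converted to its 24-day
    probability (mean-daily route) and enter the likelihood as ``n_discs``
    weighted Bernoulli trials at that probability — preserving the binomial
    error structure while modelling the incubation-length response. With
    ``period_level=True`` the two raw period counts are modelled instead and
    the fitted period curve is converted to the 24-day scale.

    The smooth is a cubic B-spline (``n_basis`` functions over the observed
    activity range) with a second-difference penalty; lambda minimises
    AIC = deviance + 2*edf over a log-spaced grid.
    """
    if len(trials) < 3:
        raise ValueError("need at least 3 plots to fit a dose-response")
    if len(trials) < 10:
        warnings.warn(f"only {len(trials)} plots; the smooth will be imprecise")
    x = np.array([t.local_activity_ha for t in trials], dtype=float)
    if np.any(x < 0):
        raise ValueError("negative activity values")
    if len(np.unique(np.round(x, 9))) < 3:
        raise ValueError("need >= 3 distinct activity values to fit a smooth")

    if period_level:
        xs = np.repeat(x, 2)
        y = np.array([[t.broken_p1 / t.n_discs, t.broken_p2 / t.n_discs]
                      for t in trials]).ravel()
        m = np.repeat([float(t.n_discs) for t in trials], 2)
    else:
        xs = x
        y = np.array([plot_probabilities(t, period_days, incubation_days).p24
                      for t in trials])
        m = np.array([float(t.n_discs) for t in trials])

    degenerate = bool(np.allclose(y, y[0]))
    if degenerate:
        warnings.warn("all plot outcomes identical; dose-response fit is degenerate "
                      "(complete separation), predictions near-constant")

    lo, hi = float(xs.min()), float(xs.max())
    n_interior = max(n_basis - degree - 1, 0)
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = BSpline.design_matrix(xs, knots, degree).toarray()
    k = B.shape[1]
    D = np.diff(np.eye(k), n=2, axis=0)
    P = D.T @ D

    if lambdas is None:
        lambdas = np.logspace(-3, 5, 17)

    best = None
    for lam in lambdas:
        beta = np.zeros(k)
        dev_old = np.inf
        ok = True
        for _ in range(max_iter):
            eta = B @ beta
            mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
            w = m * mu * (1 - mu)
            z = eta + (y - mu) / (mu * (1 - mu))
            BtW = B.T * w
            A = BtW @ B + lam * P
            try:
                beta = solve(A, BtW @ z, assume_a="pos")
            except np.linalg.LinAlgError:  # pragma: no cover
                ok = False
                break
            dev = _binomial_deviance(y, expit(B @ beta), m)
            if abs(dev_old - dev) < tol * (abs(dev) + 1):
                break
            dev_old = dev
        if not ok:
            continue
        eta = B @ beta
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        w = m * mu * (1 - mu)
        BtWB = (B.T * w) @ B
        A = BtWB + lam * P
        Ainv = np.linalg.inv(A)
        edf = float(np.trace(Ainv @ BtWB))
        dev = _binomial_deviance(y, mu, m)
        aic = dev + 2.0 * edf
        if best is None or aic < best["aic"]:
            best = {"aic": aic, "lam": float(lam), "beta": beta, "edf": edf,
                    "dev": dev, "cov": Ainv}
    if best is None:  # pragma: no cover
        raise RuntimeError("penalized IRLS failed for every smoothing value")

    ybar = float(np.sum(m * y) / np.sum(m))
    null_dev = _binomial_deviance(y, np.full_like(y, ybar), m)

    model = DoseResponse(
        knots=knots, coefs=best["beta"], degree=degree, lambda_=best["lam"],
        edf=best["edf"], deviance=best["dev"], null_deviance=null_dev,
        cov=best["cov"], x_range=(lo, hi), degenerate=degenerate,
    )
    if period_level:
        model = _PeriodLevelDoseResponse(model, period_days, incubation_days)
    return model


class _PeriodLevelDoseResponse(DoseResponse):
    """Wraps a period-scale fit, converting predictions to the 24-day scale."""

    def __init__(self, inner: DoseResponse, period_days: int, incubation_days: int):
        self.__dict__.update(inner.__dict__)
        self._period_days = period_days
        self._incubation_days = incubation_days

    def predict(self, activity):
        p_period = super().predict(activity)
        d = daily_probability(p_period, self._period_days)
        return incubation_probability(d, self._incubation_days)


def predict_risk_map(model: DoseResponse, window_activity: ActivityGrid | pd.Series,
                     cells: pd.DataFrame | None = None) -> pd.DataFrame:
    """Project the dose-response through per-cell activity to a risk map.

    ``window_activity`` is the activity grid (or per-cell Series) computed
    over the first 24 days of grazing. Returns one row per included cell:
    cell_id, activity_24d, p24, zone, dist_seawall_m. Cells with zero
    activity get the model's zero-activity prediction.
    """
    if isinstance(window_activity, ActivityGrid):
        act = window_activity.window_activity()
        cells = window_activity.cells
    else:
        act = window_activity
        if cells is None:
            raise ValueError("cells table required when passing a raw Series")
    inc = cells[cells["included"]].set_index("cell_id")
    act = act.reindex(inc.index, fill_value=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p24 = model.predict(act.to_numpy())
    out = pd.DataFrame({
        "cell_id": inc.index,
        "activity_24d": act.to_numpy(),
        "p24": p24,
        "zone": inc["zone"].to_numpy(),
        "dist_seawall_m": inc["dist_seawall_m"].to_numpy(),
    }).reset_index(drop=True)
    if not ((out["p24"] >= 0) & (out["p24"] <= 1)).all():  # pragma: no cover
        raise AssertionError("risk predictions escaped [0, 1]")
    return out


def zone_risk_summary(risk_map: pd.DataFrame) -> pd.DataFrame:
    """Mean and max 24-day trampling risk per habitat zone."""
    g = risk_map.groupby("zone", sort=False)["p24"]
    return pd.DataFrame({"mean_p24": g.mean(), "max_p24": g.max(),
                         "n_cells": g.size()}).reset_index()


def morans_i(values: np.ndarray, coords: np.ndarray,
             n_permutations: int = 199, seed: int = 0) -> dict:
    """Moran's I with inverse-distance weights plus a permutation p-value.

    Used as a screen for spatial autocorrelation in plot-level deviance
    residuals; reported, not auto-corrected.
    """
    v = np.asarray(values, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = len(v)
    if n < 4:
        raise ValueError("need >= 4 values for Moran's I")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    z = v - v.mean()
    s0 = w.sum()
    denom = float(z @ z)
    if denom == 0:
        return {"I": 0.0, "expected": -1.0 / (n - 1), "p_value": 1.0}
    observed = n / s0 * float(z @ w @ z) / denom

    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        zp = rng.permutation(z)
        perm[i] = n / s0 * float(zp @ w @ zp) / denom
    p = (1 + np.sum(np.abs(perm) >= abs(observed))) / (n_permutations + 1)
    return {"I": observed, "expected": -1.0 / (n - 1), "p_value": float(p)}
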