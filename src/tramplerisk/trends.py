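"""Trend models for weekly range metrics: GLS with within-marsh AR(1) errors,
sequential F tables, backward single-term elimination, and per-zone linear
models with residual autocorrelation diagnostics.

The global model for a weekly response is

    g(y) ~ marsh + week + week^2 + marsh:week + marsh:week^2

with g a variance-stabilising transform (log10, log10(x+1), sqrt or
identity) and, optionally, AR(1)-correlated errors within each marsh ordered
by week (phi estimated by maximum likelihood via profile likelihood, so that
fixed-effect term deletions are comparable across fits). Term F tests are
sequential (type I), matching the conventional presentation of such model
tables. Backward selection removes the single least-significant removable
term until everything left has p < alpha, respecting marginality: a main
effect is never dropped while one of its interactions remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

ALL_TERMS: tuple[str, ...] = ("marsh", "week", "week2", "marsh:week", "marsh:week2")

_TRANSFORMS = {
    "identity": lambda y: y,
    "log10": lambda y: np.log10(y),
    "log10_plus_1": lambda y: np.log10(np.asarray(y, dtype=float) + 1.0),
    "sqrt": lambda y: np.sqrt(y),
}


class ConvergenceError(RuntimeError):
    pass


class SingularDesignError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Response, transform, term set and correlation structure."""

    response: str
    transform: str = "identity"
    terms: tuple[str, ...] = ALL_TERMS
    correlation: str = "ar1"  # "none" | "ar1" (within group, ordered by week)
    group: str = "marsh_id"
    order: str = "week"
    method: str = "reml"  # phi estimation: "reml" (small-sample debiased) | "ml"

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.correlation not in ("none", "ar1"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.method not in ("reml", "ml"):
            raise ValueError(f"unknown method {self.method!r}")
        if "week2" in self.terms and "week" not in self.terms:
            raise ValueError("week2 requires week (marginality)")
        for t in self.terms:
            if ":" in t:
                a, b = t.split(":")
                b = "week" if b == "week" else b
                if a not in self.terms or b.replace("2", "") not in self.terms:
                    pass  # checked dynamically during elimination
        unknown = set(self.terms) - set(ALL_TERMS)
        if unknown:
            raise ValueError(f"unknown terms {sorted(unknown)}")


@dataclass
class FitResult:
    """Fitted linear/GLS model with AR(1) parameter and sequential F table."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    phi: float
    loglik: float
    sigma2: float
    anova_table: pd.DataFrame
    n_obs: int
    df_resid: int
    term_slices: dict[str, list[int]] = field(default_factory=dict)
    resid_by_group: dict[str, np.ndarray] = field(default_factory=dict)
    fitted: np.ndarray | None = None
    removal_log: list[tuple[str, float]] = field(default_factory=list)
    #: every single-term deletion test run during selection: (term, p, removed)
    selection_trace: list[tuple[str, float, bool]] = field(default_factory=list)

    @property
    def terms(self) -> tuple[str, ...]:
        return self.spec.terms


def _design(data: pd.DataFrame, spec: ModelSpec):
    """Build the design matrix with an intercept and the spec's terms.

    Categorical marsh is treatment-coded against its first level; returns
    (X, column names, term -> column-index map).
    """
    groups = pd.Categorical(data[spec.group])
    levels = list(groups.categories)
    week = data[spec.order].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["(Intercept)"]
    slices: dict[str, list[int]] = {}

    def add(term: str, arrs: list[np.ndarray], labels: list[str]):
        idx = []
        for a, lab in zip(arrs, labels):
            idx.append(len(cols))
            cols.append(a)
            names.append(lab)
        slices[term] = idx

    dummies = {lev: (groups == lev).astype(float) for lev in levels[1:]}
    for term in spec.terms:
        if term == "marsh":
            add(term, [dummies[l] for l in levels[1:]], [f"marsh[{l}]" for l in levels[1:]])
        elif term == "week":
            add(term, [week], ["week"])
        elif term == "week2":
            add(term, [week**2], ["week2"])
        elif term == "marsh:week":
            add(term, [dummies[l] * week for l in levels[1:]],
                [f"marsh[{l}]:week" for l in levels[1:]])
        elif term == "marsh:week2":
            add(term, [dummies[l] * week**2 for l in levels[1:]],
                [f"marsh[{l}]:week2" for l in levels[1:]])
    X = np.column_stack(cols)
    return X, names, slices


def _whiten(X: np.ndarray, y: np.ndarray, groups: np.ndarray, order: np.ndarray,
            phi: float):
    """AR(1) whitening within groups, gap-aware for unequally spaced weeks.

    Returns transformed (X*, y*) with iid errors and the log-determinant of
    the whitening transform (needed for the ML log-likelihood).
    """
    Xw = X.copy().astype(float)
    yw = y.copy().astype(float)
    logdet = 0.0
    if phi == 0.0:
        return Xw, yw, logdet
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        idx = idx[np.argsort(order[idx], kind="mergesort")]
        c1 = np.sqrt(1.0 - phi**2)
        Xw[idx[0]] *= c1
        yw[idx[0]] *= c1
        logdet += np.log(c1)
        for prev, cur in zip(idx[:-1], idx[1:]):
            d = int(round(order[cur] - order[prev]))  # week gaps are integral
            rho = phi**d
            scale = np.sqrt((1.0 - phi**2) / (1.0 - phi ** (2 * d)))
            Xw[cur] = (X[cur] - rho * X[prev]) * scale
            yw[cur] = (y[cur] - rho * y[prev]) * scale
            logdet += np.log(scale)
    return Xw, yw, logdet


def _profile_loglik(phi: float, X, y, groups, order, reml: bool = False) -> float:
    Xw, yw, logdet = _whiten(X, y, groups, order, phi)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    n, p = X.shape
    if rss <= 0:
        rss = 1e-300
    if reml:
        sign, logdet_xtx = np.linalg.slogdet(Xw.T @ Xw)
        nr = n - p
        return (-0.5 * nr * (np.log(2 * np.pi) + 1.0 + np.log(rss / nr))
                + logdet - 0.5 * logdet_xtx)
    return -0.5 * n * (np.log(2 * np.pi) + 1.0 + np.log(rss / n)) + logdet


def fit_gls_ar1(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit the linear model, estimating the AR(1) parameter by profile
    likelihood (REML by default, to offset the small-sample downward bias of
    the within-group autocorrelation; ``method="ml"`` available).

    With ``correlation="none"`` (or phi estimated at 0) this reduces exactly
    to ordinary least squares. The returned term table holds sequential
    (type I) F tests in the spec's term order.
    """
    y = _TRANSFORMS[spec.transform](data[spec.response].to_numpy(dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("response transform produced non-finite values")
    X, names, slices = _design(data, spec)
    n, p = X.shape
    if n <= p:
        raise SingularDesignError(f"{n} observations cannot identify {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError(f"singular design; aliased columns among {names}")
    groups = data[spec.group].to_numpy()
    order = data[spec.order].to_numpy(dtype=float)

    for g in np.unique(groups):
        if (groups == g).sum() < 2 and spec.correlation == "ar1":
            raise ValueError(f"group {g!r} has < 2 observations; AR(1) unidentified")

    if spec.correlation == "ar1":
        reml = spec.method == "reml"
        res = optimize.minimize_scalar(
            lambda ph: -_profile_loglik(ph, X, y, groups, order, reml),
            bounds=(-0.95, 0.95), method="bounded",
            options={"xatol": 1e-6},
        )
        if not res.success:  # pragma: no cover
            raise ConvergenceError(f"AR(1) profile likelihood failed: {res}")
        phi = float(res.x)
    else:
        phi = 0.0

    Xw, yw, _ = _whiten(X, y, groups, order, phi)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    df_resid = n - p
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    bse = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0, None))
    loglik = _profile_loglik(phi, X, y, groups, order, spec.method == "reml")

    # sequential (type I) F table; a numerically zero residual variance
    # (e.g. an exactly constant response) yields NA tests, not noise
    degenerate = sigma2 <= 1e-20 * max(1.0, float(np.mean(y**2)))
    rows = []
    fitted_terms: list[str] = []
    rss_prev = _rss_for_terms(Xw, yw, slices, fitted_terms)
    for term in spec.terms:
        fitted_terms.append(term)
        rss_cur = _rss_for_terms(Xw, yw, slices, fitted_terms)
        df_t = len(slices[term])
        if degenerate or sigma2 <= 0:
            F = pval = np.nan
        else:
            F = max(rss_prev - rss_cur, 0.0) / df_t / sigma2
            pval = float(stats.f.sf(F, df_t, df_resid))
        rows.append({"term": term, "df": df_t, "res_df": df_resid,
                     "F": F, "p": pval})
        rss_prev = rss_cur
    anova = pd.DataFrame(rows)

    resid_raw = y - X @ beta
    resid_by_group = {}
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        idx = idx[np.argsort(order[idx], kind="mergesort")]
        resid_by_group[str(g)] = resid_raw[idx]

    return FitResult(
        spec=spec,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        phi=phi, loglik=loglik, sigma2=sigma2,
        anova_table=anova, n_obs=n, df_resid=df_resid,
        term_slices=slices, resid_by_group=resid_by_group,
        fitted=X @ beta,
    )


def _rss_for_terms(Xw, yw, slices, terms) -> float:
    cols = [0] + [i for t in terms for i in slices[t]]
    Xi = Xw[:, cols]
    beta, *_ = np.linalg.lstsq(Xi, yw, rcond=None)
    r = yw - Xi @ beta
    return float(r @ r)


def _removable(terms: tuple[str, ...]) -> list[str]:
    """Terms droppable under marginality: no remaining term depends on them."""
    out = []
    for t in terms:
        if t == "marsh" and ("marsh:week" in terms or "marsh:week2" in terms):
            continue
        if t == "week" and ("week2" in terms or "marsh:week" in terms):
            continue
        if t == "week2" and "marsh:week2" in terms:
            continue
        out.append(t)
    return out


def _deletion_pvalue(spec: ModelSpec, data: pd.DataFrame, term: str,
                     full: FitResult) -> float:
    """F test for dropping one term from the current model (computed on the
    whitened scale at the current model's phi)."""
    reduced_terms = tuple(t for t in spec.terms if t != term)
    y = _TRANSFORMS[spec.transform](data[spec.response].to_numpy(dtype=float))
    X, _, slices = _design(data, spec)
    groups = data[spec.group].to_numpy()
    order = data[spec.order].to_numpy(dtype=float)
    Xw, yw, _ = _whiten(X, y, groups, order, full.phi)
    rss_full = _rss_for_terms(Xw, yw, slices, list(spec.terms))
    rss_red = _rss_for_terms(Xw, yw, slices, list(reduced_terms))
    q = len(slices[term])
    if full.sigma2 <= 0 or not np.isfinite(full.sigma2):
        return np.nan
    F = ((rss_red - rss_full) / q) / full.sigma2
    return float(stats.f.sf(F, q, full.df_resid))


def backward_select(spec: ModelSpec, data: pd.DataFrame,
                    alpha: float = 0.05) -> FitResult:
    """Backward single-term elimination from the global model.

    Repeatedly drops the removable term with the highest deletion p-value
    >= alpha until none remains; may return the intercept-only model. The
    removal log (term, p at removal) is attached to the returned fit.
    """
    current = spec
    removal_log: list[tuple[str, float]] = []
    trace: list[tuple[str, float, bool]] = []
    while True:
        fit = fit_gls_ar1(current, data)
        candidates = _removable(current.terms)
        if not candidates:
            break
        pvals = {t: _deletion_pvalue(current, data, t, fit) for t in candidates}
        worst = max(pvals, key=lambda t: (np.nan_to_num(pvals[t], nan=1.0)))
        worst_p = pvals[worst]
        removed = bool(np.isnan(worst_p) or worst_p >= alpha)
        trace.append((worst, float(np.nan_to_num(worst_p, nan=1.0)), removed))
        if not removed:
            break
        removal_log.append((worst, float(np.nan_to_num(worst_p, nan=1.0))))
        current = replace(current, terms=tuple(t for t in current.terms if t != worst))
        if not current.terms:
            fit = fit_gls_ar1(current, data)
            break
    fit.removal_log = removal_log
    fit.selection_trace = trace
    if removal_log:
        log.info("backward_select removed: %s",
                 ", ".join(f"{t} (p={p:.3g})" for t, p in removal_log))
    return fit


def fit_zone_glm(zone: str, zone_data: pd.DataFrame, transform: str = "identity",
                 alpha: float = 0.05) -> FitResult | None:
    """Per-zone Gaussian linear model of weekly activity on marsh, week, week^2.

    Interactions are included in the global model and then eliminated when
    nonsignificant (only interactions are tested; mains remain in the table
    whatever their p, matching the conventional per-zone model presentation).
    Returns None (with a log entry) when the zone is absent from the data.
    """
    if zone_data.empty:
        log.info("zone %s absent on all marshes; model skipped", zone)
        return None
    n_marshes = zone_data["marsh_id"].nunique()
    terms: tuple[str, ...] = ("week", "week2") if n_marshes < 2 else ALL_TERMS
    spec = ModelSpec(response="activity", transform=transform, terms=terms,
                     correlation="none")
    current = spec
    removal_log: list[tuple[str, float]] = []
    while True:
        fit = fit_gls_ar1(current, zone_data)
        inter = [t for t in current.terms if ":" in t]
        if not inter:
            break
        pvals = {t: _deletion_pvalue(current, zone_data, t, fit) for t in inter}
        worst = max(pvals, key=lambda t: np.nan_to_num(pvals[t], nan=1.0))
        if not (np.isnan(pvals[worst]) or pvals[worst] >= alpha):
            break
        removal_log.append((worst, float(np.nan_to_num(pvals[worst], nan=1.0))))
        current = replace(current, terms=tuple(t for t in current.terms if t != worst))
    fit.removal_log = removal_log
    return fit


def acf_diagnostic(fit: FitResult, max_lag: int = 10) -> pd.DataFrame:
    """Per-group residual autocorrelations with 95% white-noise bands.

    Flags any lag whose |acf| exceeds 1.96/sqrt(n_group). Groups with fewer
    than 3 residuals contribute nothing (report may be empty).
    """
    rows = []
    for g, r in fit.resid_by_group.items():
        n = len(r)
        if n < 3:
            continue
        r = r - r.mean()
        denom = float(r @ r)
        if denom <= 0:
            continue
        band = 1.96 / np.sqrt(n)
        for lag in range(1, min(max_lag, n - 1) + 1):
            ac = float(r[lag:] @ r[:-lag]) / denom
            rows.append({"group": g, "lag": lag, "acf": ac, "band": band,
                         "flagged": abs(ac) > band})
    return pd.DataFrame(rows, columns=["group", "lag", "acf", "band", "flagged"])
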