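"""Parameter estimation from killing-assay time series.

Stage 1 estimates (rho, K) by fitting logistic growth to each untreated
well; stage 2 fixes those and estimates (kappa1, kappa2, theta) by fitting
the predator-prey solution to each treated well, minimising the RMSE of the
cancer-cell (cell-index) trajectory.  Both stages run over the
post-treatment, below-confluency window chosen by
:func:`carrgo.rtca.select_fit_window`.

Robustness utilities mirror the assay-level checks: multi-start uniqueness
of the optimum, refitting on down-sampled series, and dose/antigen trend
summaries with Pearson correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedR2Error,
)
from .estimators import CarrgoRegressor, LogisticGrowthRegressor
from .model import CarrgoParams
from .rtca import FitWindow, WellSeries, cells_to_ci, downsample, select_fit_window

__all__ = [
    "FitResult",
    "MultiStartReport",
    "fit_logistic",
    "fit_carrgo",
    "goodness_of_fit",
    "multistart_fit",
    "carrgo_problem",
    "downsampling_robustness",
    "downsampling_anova",
    "parameter_trend_summary",
]

logger = logging.getLogger(__name__)

HOURS_PER_DAY = 24.0

#: Death-rate resolution floor (day^-1): fitted theta below this is
#: indistinguishable from zero on a 4-day assay, so relative spreads and
#: deviations of theta are measured against max(|theta|, THETA_FLOOR).
THETA_FLOOR = 1e-3


@dataclass
class FitResult:
    """Outcome of one well-level fit."""

    params: CarrgoParams
    fitted: tuple
    rmse: float
    r2: float
    n_points: int
    converged: bool
    bounds_used: dict = field(default_factory=dict)
    start_point: dict = field(default_factory=dict)
    well_id: str = ""
    message: str = ""

    def as_row(self) -> dict:
        p = self.params
        return {
            "well_id": self.well_id,
            "rho": p.rho,
            "K": p.K,
            "kappa1": p.kappa1,
            "kappa2": p.kappa2,
            "theta": p.theta,
            "rmse": self.rmse,
            "r2": self.r2,
            "n_points": self.n_points,
            "converged": self.converged,
            "fitted": "+".join(self.fitted),
        }


@dataclass
class MultiStartReport:
    """Uniqueness diagnosis from repeated fits with dispersed start points."""

    n_starts: int
    n_converged: int
    best: FitResult | None
    dispersion: dict
    unique: str  # "unique" / "non-unique" / "undetermined"
    results: list = field(default_factory=list)
    seed: int | None = None


def _window_arrays(ws: WellSeries, window: FitWindow):
    t_days = ws.t[window.start : window.end] / HOURS_PER_DAY
    y = ws.ci[window.start : window.end]
    return t_days, y


def fit_logistic(ws: WellSeries, window: FitWindow, **kwargs) -> FitResult:
    """Estimate (rho, K) from an untreated well over the fit window."""
    if ws.meta.treated:
        raise InvalidInputError(
            f"well {ws.meta.well_id or '?'} is treated; logistic fit expects untreated"
        )
    t, y = _window_arrays(ws, window)
    est = LogisticGrowthRegressor(**kwargs).fit(t, y)
    params = CarrgoParams(
        rho=est.rho_, K=est.K_, kappa1=0.0, kappa2=0.0, theta=0.0, unit_label="CI"
    )
    return FitResult(
        params=params,
        fitted=("rho", "K"),
        rmse=est.rmse_,
        r2=est.r2_,
        n_points=est.n_points_,
        converged=est.converged_,
        bounds_used=est.bounds_used_,
        start_point=est.start_point_,
        well_id=ws.meta.well_id,
    )


def dose_in_ci(ws: WellSeries, calibration_slope: float | None) -> float:
    """CAR T-cell inoculum Y0 = seeding_count * et_ratio, in CI units.

    The E:T ratio defines the dose against the seeded target count; the
    calibration slope converts cells to CI-equivalents (intercept omitted:
    it models well-level offset, not per-population density).
    """
    if not ws.meta.treated:
        raise InvalidInputError("untreated well has no CAR T-cell dose")
    cells = ws.meta.seeding_count * ws.meta.et_ratio
    if calibration_slope is None:
        return float(cells)
    return float(cells_to_ci(cells, calibration_slope))


def bridge_mean_ci(
    ws: WellSeries, t0_h: float, spike_halfwidth_h: float = 1.0
) -> float:
    """Time-averaged observed cancer density over [treat_time, t0_h].

    Trapezoid average of the clean samples in the gap between the dose and
    the window start; spike-contaminated samples (within
    ``spike_halfwidth_h`` after the treatment) are skipped and the value at
    the treatment time is linearly interpolated from the straddling clean
    samples (X itself is continuous across the dose).
    """
    treat = ws.meta.treat_time_h
    if t0_h <= treat + 1e-9:
        i = int(np.argmin(np.abs(ws.t - t0_h)))
        return float(ws.ci[i])
    clean = (ws.t < treat - 1e-9) | (ws.t >= treat + spike_halfwidth_h - 1e-9)
    inner = clean & (ws.t > treat) & (ws.t <= t0_h + 1e-9)
    ts = list(ws.t[inner])
    cis = list(ws.ci[inner])
    pre = np.nonzero(clean & (ws.t < treat - 1e-9))[0]
    if pre.size and ts:
        tl, cl = ws.t[pre[-1]], ws.ci[pre[-1]]
        tr, cr = ts[0], cis[0]
        ts.insert(0, treat)
        cis.insert(0, cl + (treat - tl) / (tr - tl) * (cr - cl))
    if not ts:
        i = int(np.argmin(np.abs(ws.t - t0_h)))
        return float(ws.ci[i])
    return float(np.trapezoid(cis, ts) / (ts[-1] - ts[0]))


def fit_carrgo(
    ws: WellSeries,
    window: FitWindow,
    rho: float,
    K: float,
    Y0: float | None = None,
    calibration_slope: float | None = None,
    x_bridge: float | None = None,
    spike_halfwidth_h: float = 1.0,
    **kwargs,
) -> FitResult:
    """Estimate (kappa1, kappa2, theta) from a treated well.

    ``rho`` and ``K`` come from the paired untreated fit.  ``Y0`` is the
    CAR T-cell inoculum in CI units; when omitted it is computed from the
    well's E:T ratio via :func:`dose_in_ci`.  ``x_bridge`` overrides the
    dose-to-window-start mean density (e.g. computed from a
    finer-resolution recording of the same well).
    """
    if not ws.meta.treated:
        raise InvalidInputError(
            f"well {ws.meta.well_id or '?'} is untreated; CARRGO fit expects treated"
        )
    t, y = _window_arrays(ws, window)
    if Y0 is None:
        Y0 = dose_in_ci(ws, calibration_slope)
    if x_bridge is None:
        x_bridge = bridge_mean_ci(ws, ws.t[window.start], spike_halfwidth_h)
    est = CarrgoRegressor(
        rho=rho,
        K=K,
        y0_dose=Y0,
        t_dose=ws.meta.treat_time_h / HOURS_PER_DAY,
        x_bridge=x_bridge,
        **kwargs,
    ).fit(t, y)
    params = CarrgoParams(
        rho=rho, K=K, kappa1=est.kappa1_, kappa2=est.kappa2_, theta=est.theta_
    )
    msg = ""
    if est.bound_pinned_:
        msg = f"bound-pinned: {','.join(est.pinned_params_)}"
        logger.info("well %s %s", ws.meta.well_id, msg)
    return FitResult(
        params=params,
        fitted=("kappa1", "kappa2", "theta"),
        rmse=est.rmse_,
        r2=est.r2_,
        n_points=est.n_points_,
        converged=est.converged_,
        bounds_used=est.bounds_used_,
        start_point=est.start_point_,
        well_id=ws.meta.well_id,
        message=msg,
    )


def goodness_of_fit(predicted, observed) -> float:
    """R^2 as the squared Pearson correlation of observed vs predicted."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise InvalidInputError("predicted and observed must be 1-D of equal length")
    if len(predicted) < 3:
        raise InsufficientDataError("R^2 needs >= 3 points")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise UndefinedR2Error("zero variance in predicted or observed values")
    return float(np.corrcoef(predicted, observed)[0, 1] ** 2)


def carrgo_problem(
    ws: WellSeries,
    window: FitWindow,
    rho: float,
    K: float,
    Y0: float | None = None,
    calibration_slope: float | None = None,
    **kwargs,
):
    """Package a treated-well fit as a start-point -> FitResult callable.

    Also returns the default log-uniform start ranges (three orders of
    magnitude around the natural scale rho/K for the kappas).
    """
    scale = rho / K

    def run(start: dict) -> FitResult:
        return fit_carrgo(
            ws, window, rho, K, Y0=Y0, calibration_slope=calibration_slope,
            start=start, **kwargs,
        )

    ranges = {
        "kappa1": (1e-1 * scale, 1e2 * scale),
        "kappa2": (1e-1 * scale, 1e2 * scale),  # magnitude; sign drawn separately
        "theta": (1e-5, 1.0),
    }
    return run, ranges


def multistart_fit(
    problem,
    n_starts: int = 100,
    ranges: dict | None = None,
    seed: int | None = None,
    dispersion_threshold: float = 0.01,
) -> MultiStartReport:
    """Repeat a fit from dispersed starting points and diagnose uniqueness.

    ``problem`` is either a callable mapping a start dict to a
    :class:`FitResult`, or the (callable, ranges) pair returned by
    :func:`carrgo_problem`.  Starts are drawn log-uniformly within
    ``ranges`` (sign-symmetric for kappa2).  A parameter's dispersion is its
    (max - min) spread among converged runs relative to the median
    magnitude (theta against max(|median|, THETA_FLOOR)); the verdict is
    "unique" when every dispersion is below ``dispersion_threshold``.
    """
    if isinstance(problem, tuple):
        problem, default_ranges = problem
        ranges = ranges or default_ranges
    if ranges is None:
        raise InvalidInputError("multistart_fit needs start ranges")
    for name, (lo, hi) in ranges.items():
        if hi / lo < 1e3 * (1 - 1e-9):
            logger.warning("start range for %s spans < 3 orders of magnitude", name)
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_starts):
        start = {}
        for name, (lo, hi) in ranges.items():
            mag = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
            if name == "kappa2":
                mag *= rng.choice([-1.0, 1.0])
            start[name] = mag
        try:
            results.append(problem(start))
        except Exception as exc:  # a wild start may break the integrator
            logger.info("multistart run failed from %s: %s", start, exc)
    converged = [r for r in results if r.converged]
    if not converged:
        return MultiStartReport(
            n_starts=n_starts,
            n_converged=0,
            best=None,
            dispersion={},
            unique="undetermined",
            results=results,
            seed=seed,
        )
    best = min(converged, key=lambda r: r.rmse)
    dispersion = {}
    for name in ("kappa1", "kappa2", "theta"):
        vals = np.array([getattr(r.params, name) for r in converged])
        med = np.median(np.abs(vals))
        denom = max(med, THETA_FLOOR) if name == "theta" else max(med, 1e-12)
        dispersion[name] = float(np.ptp(vals) / denom)
    unique = (
        "unique"
        if all(d < dispersion_threshold for d in dispersion.values())
        else "non-unique"
    )
    return MultiStartReport(
        n_starts=n_starts,
        n_converged=len(converged),
        best=best,
        dispersion=dispersion,
        unique=unique,
        results=results,
        seed=seed,
    )


def downsampling_robustness(
    ws: WellSeries,
    rho: float,
    K: float,
    intervals=(2.0, 5.0, 10.0),
    Y0: float | None = None,
    calibration_slope: float | None = None,
    confluency_frac: float = 0.8,
    spike_halfwidth_h: float = 1.0,
    ci_max: float | None = None,
    warm_start: bool = True,
    **kwargs,
):
    """Refit a treated well on down-sampled copies and compare parameters.

    Returns a DataFrame with one row per sampling interval (the native
    resolution first) and, in ``DataFrame.attrs["max_rel_dev"]``, the
    maximum deviation of each parameter from the native fit relative to its
    native magnitude (theta against max(|theta|, THETA_FLOOR)).  Coarse
    refits are warm-started at the native estimate by default — refitting a
    sparser view of the same well is a refinement, not a fresh search.
    Failed sub-fits leave a flagged row rather than aborting.
    """
    window = select_fit_window(ws, confluency_frac, spike_halfwidth_h, ci_max=ci_max)
    native = fit_carrgo(
        ws, window, rho, K, Y0=Y0, calibration_slope=calibration_slope, **kwargs
    )
    native_spacing = float(np.median(np.diff(ws.t)))
    rows = [{**native.as_row(), "interval_h": native_spacing}]
    p_nat = native.params
    devs = {"kappa1": 0.0, "kappa2": 0.0, "theta": 0.0}
    warm = (
        {"kappa1": p_nat.kappa1, "kappa2": p_nat.kappa2, "theta": p_nat.theta}
        if warm_start
        else None
    )
    for interval in intervals:
        try:
            ds = downsample(ws, interval)
            win = select_fit_window(ds, confluency_frac, spike_halfwidth_h, ci_max=ci_max)
            # the dose bridge is computed from the native recording: the
            # full-resolution trace exists whenever one down-samples it
            xb = bridge_mean_ci(ws, float(ds.t[win.start]), spike_halfwidth_h)
            fit = fit_carrgo(
                ds, win, rho, K, Y0=Y0, calibration_slope=calibration_slope,
                start=warm, x_bridge=xb, spike_halfwidth_h=spike_halfwidth_h,
                **kwargs,
            )
            row = {**fit.as_row(), "interval_h": interval}
            for name in devs:
                ref = abs(getattr(p_nat, name))
                if name == "theta":
                    ref = max(ref, THETA_FLOOR)
                d = abs(getattr(fit.params, name) - getattr(p_nat, name)) / max(
                    ref, 1e-12
                )
                row[f"rel_dev_{name}"] = d
                devs[name] = max(devs[name], d)
        except Exception as exc:
            logger.warning("down-sampled fit at %s h failed: %s", interval, exc)
            row = {"well_id": ws.meta.well_id, "interval_h": interval,
                   "converged": False, "failed": str(exc)}
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["max_rel_dev"] = devs
    return table


def downsampling_anova(tables: list[pd.DataFrame], param: str = "kappa1"):
    """Repeated-measures ANOVA of a parameter across sampling intervals.

    ``tables`` are per-well outputs of :func:`downsampling_robustness`
    (each well is one subject, interval the within factor).  Returns the
    p-value, or None when fewer than 3 wells are available.  Reported for
    context; the robustness gate is the relative-deviation bound.
    """
    if len(tables) < 3:
        return None
    from statsmodels.stats.anova import AnovaRM

    rows = []
    for i, tab in enumerate(tables):
        for _, r in tab.iterrows():
            if pd.notna(r.get(param)):
                rows.append({"well": i, "interval": r["interval_h"], "value": r[param]})
    df = pd.DataFrame(rows)
    counts = df.groupby("well")["interval"].count()
    if counts.nunique() != 1:  # unbalanced -> AnovaRM not applicable
        return None
    res = AnovaRM(df, depvar="value", subject="well", within=["interval"]).fit()
    return float(res.anova_table["Pr > F"].iloc[0])


def parameter_trend_summary(
    fits: pd.DataFrame,
    group_col: str,
    value_cols=("kappa1", "kappa2", "theta"),
    corr_pairs=(("rho", "kappa2"),),
):
    """Per-group parameter means +/- sd and Pearson correlations.

    ``fits`` is a tidy table of per-well fits (e.g. rows built with
    :meth:`FitResult.as_row` plus grouping columns).  Requires >= 3 groups;
    each correlation needs >= 3 wells and non-constant values.
    """
    groups = fits[group_col].unique()
    if len(groups) < 3:
        raise InsufficientDataError(
            f"trend summary needs >= 3 groups, got {len(groups)}"
        )
    summary = fits.groupby(group_col)[list(value_cols)].agg(["mean", "std"])
    correlations = {}
    for a, b in corr_pairs:
        sub = fits[[a, b]].dropna()
        if len(sub) < 3:
            raise InsufficientDataError(f"correlation {a}~{b} needs >= 3 wells")
        if np.ptp(sub[a].to_numpy()) == 0 or np.ptp(sub[b].to_numpy()) == 0:
            raise DegenerateDataError(
                f"correlation {a}~{b} undefined: a variable is constant"
            )
        r, p = stats.pearsonr(sub[a], sub[b])
        correlations[(a, b)] = (float(r), float(p))
    return summary, correlations
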