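"""Fitting the killing kinetics to MRI-derived tumour-volume series.

Lesion volumes from longitudinal imaging are converted to cancer-cell
counts by dividing by the volume of a single (spherical) glioma cell of
diameter ~20 um.  The predator-prey system is then integrated piecewise
across CAR T-cell infusions — each infusion adds a configured fraction
(typically 5-10%, the share of the dose assumed to reach the lesion) of the
infused cells to Y instantaneously — and (kappa1, kappa2, theta) are
estimated by RMSE minimisation on the cell counts, with the growth rate rho
pre-computed from early imaging time points and the carrying capacity K
fixed (default 1e9 cells, the tissue-scale order of magnitude).

Rates fitted on cell counts are small numbers (kappa's ~ 1e-13..1e-8
day^-1 cell^-1) but become comparable to the in vitro CI-unit estimates
once multiplied by K, i.e. on the dimensionless B = kappa2*K/rho scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .errors import (
    ConfigError,
    InsufficientDataError,
    IntegrationError,
    InvalidInputError,
    UnderDeterminedError,
)
from .estimators import _carrgo_sensitivity_rhs
from .fitting import FitResult
from .model import CarrgoParams

__all__ = [
    "CELL_DIAMETER_UM",
    "cell_volume_um3",
    "volume_to_cells",
    "cells_to_volume_mm3",
    "LesionSeries",
    "estimate_growth_rate",
    "fit_lesion",
    "fit_lesions_joint",
]

logger = logging.getLogger(__name__)

CELL_DIAMETER_UM = 20.0
UM3_PER_MM3 = 1e9


def cell_volume_um3(diameter_um: float = CELL_DIAMETER_UM) -> float:
    """Volume of one spherical cell, (4 pi / 3) (d/2)^3 in um^3."""
    if diameter_um <= 0:
        raise InvalidInputError(f"cell diameter must be > 0, got {diameter_um}")
    return (4.0 * np.pi / 3.0) * (diameter_um / 2.0) ** 3


def volume_to_cells(volume, diameter_um: float = CELL_DIAMETER_UM, unit: str = "um3"):
    """Cancer-cell count = tumour volume / single-cell volume, rounded.

    ``unit`` is ``"um3"`` or ``"mm3"`` (1 mm^3 = 1e9 um^3).
    """
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise InvalidInputError("volume must be >= 0")
    if unit == "mm3":
        v = v * UM3_PER_MM3
    elif unit != "um3":
        raise InvalidInputError(f"unknown volume unit {unit!r}")
    counts = np.rint(v / cell_volume_um3(diameter_um)).astype(np.int64)
    return int(counts) if counts.ndim == 0 else counts


def cells_to_volume_mm3(cells, diameter_um: float = CELL_DIAMETER_UM):
    """Inverse of :func:`volume_to_cells` (mm^3), up to rounding."""
    return np.asarray(cells, dtype=float) * cell_volume_um3(diameter_um) / UM3_PER_MM3


@dataclass
class LesionSeries:
    """Sparse tumour-volume observations for one lesion, with dosing.

    ``doses`` holds (day, infused_cells, fraction_reaching_lesion) triples;
    fractions outside [0.05, 0.10] are accepted only with
    ``allow_any_fraction`` (the narrow interval reflects how little of an
    intraventricular dose reaches any single lesion).  ``mask_days``
    annotates intervals (e.g. radiotherapy) to exclude from fitting.
    """

    days: np.ndarray
    volumes_mm3: np.ndarray
    doses: list = field(default_factory=list)
    rho: float | None = None
    mask_days: list = field(default_factory=list)
    name: str = ""
    allow_any_fraction: bool = False

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.volumes_mm3 = np.asarray(self.volumes_mm3, dtype=float)
        if self.days.shape != self.volumes_mm3.shape or self.days.ndim != 1:
            raise InvalidInputError("days and volumes must be 1-D of equal length")
        if np.any(np.diff(self.days) <= 0):
            raise InvalidInputError("observation days must be strictly increasing")
        if np.any(self.volumes_mm3 < 0):
            raise InvalidInputError("volumes must be >= 0")
        for day, cells, frac in self.doses:
            if not self.allow_any_fraction and not (0.05 <= frac <= 0.10):
                raise ConfigError(
                    f"dose fraction {frac} outside the assumed 5-10% interval"
                )
            if cells < 0:
                raise ConfigError("infused cell count must be >= 0")

    @property
    def cells(self) -> np.ndarray:
        return volume_to_cells(self.volumes_mm3, unit="mm3")

    def dose_events(self):
        """(day, cells_reaching_lesion) pairs, time-ordered."""
        return sorted((d, c * f) for d, c, f in self.doses)

    def observation_mask(self) -> np.ndarray:
        keep = np.ones(len(self.days), dtype=bool)
        for a, b in self.mask_days:
            keep &= ~((self.days >= a) & (self.days <= b))
        return keep


def estimate_growth_rate(series: LesionSeries, two_point: bool = True) -> float:
    """Net growth rate from early imaging, rho = ln(N2/N1)/(t2-t1).

    Uses the first two pre-treatment observations (exponential early-growth
    approximation: two points cannot constrain K, and young lesions are far
    below carrying capacity).  With ``two_point=False`` a log-linear
    regression over all pre-dose points is used instead.
    """
    first_dose = min((d for d, _ in series.dose_events()), default=np.inf)
    pre = series.days < first_dose
    if pre.sum() < 2:
        raise InsufficientDataError("need >= 2 pre-treatment observations")
    days = series.days[pre]
    cells = series.cells[pre].astype(float)
    if cells[0] <= 0:
        raise InvalidInputError("first observation has zero cells; rate undefined")
    if two_point:
        if cells[1] <= 0:
            raise InvalidInputError("second observation has zero cells; rate undefined")
        return float(np.log(cells[1] / cells[0]) / (days[1] - days[0]))
    if np.any(cells <= 0):
        raise InvalidInputError("zero-cell observation in pre-treatment window")
    slope = np.polyfit(days, np.log(cells), 1)[0]
    return float(slope)


def _solve_piecewise(p, rho, K, x0_cells, t_obs, events, rtol=1e-8, atol=1e-4):
    """Integrate state + sensitivities across dose events.

    Y jumps by the event size at each dose; the dose is parameter-free so
    the sensitivities are continuous across events.  Returns X(t_obs) and
    dX/dp there.
    """
    rhs = _carrgo_sensitivity_rhs(rho, K, *p)
    # guards against wild optimizer candidates: Y blowing up (huge kappa2)
    # or X collapsing into denormals (huge kappa1), both of which stall the
    # integrator; either terminates the solve into the penalty branch
    cap = 1e3 * K
    floor = 1e-12 * K

    def blown_up(_t, z):
        return cap - z[1]

    def extinct(_t, z):
        return z[0] - floor

    blown_up.terminal = True
    extinct.terminal = True
    z = np.concatenate(([x0_cells, 0.0], np.zeros(6)))
    t_now = t_obs[0]
    X_out = np.empty(len(t_obs))
    J_out = np.empty((len(t_obs), 3))
    X_out[0] = z[0]
    J_out[0] = z[2:5]
    obs_idx = 1
    for d, size in events:
        if d <= t_now:
            z[1] += size  # dose exactly at the first observation
    ev = [(d, s) for d, s in events if d > t_now]
    segment_ends = [d for d, _ in ev] + [t_obs[-1]]
    seg_doses = [s for _, s in ev] + [0.0]
    for t_end, dose in zip(segment_ends, seg_doses):
        if t_end > t_now:
            t_eval = [t for t in t_obs if t_now < t <= t_end]
            sol = solve_ivp(
                rhs, (t_now, t_end), z,
                t_eval=sorted(set(t_eval + [t_end])),
                method="LSODA", rtol=rtol, atol=atol, events=(blown_up, extinct),
            )
            if not sol.success or any(ev.size for ev in sol.t_events):
                raise IntegrationError("piecewise integration failed", t_now)
            for k, tk in enumerate(sol.t):
                if obs_idx < len(t_obs) and np.isclose(tk, t_obs[obs_idx]):
                    X_out[obs_idx] = sol.y[0, k]
                    J_out[obs_idx] = sol.y[2:5, k]
                    obs_idx += 1
            z = sol.y[:, -1].copy()
            t_now = t_end
        z[1] += dose
    if obs_idx != len(t_obs):
        raise IntegrationError("observation times not all reached")
    return X_out, J_out


def fit_lesion(
    series: LesionSeries,
    rho: float,
    K: float = 1e9,
    bounds: dict | None = None,
    n_starts: int = 8,
    seed: int | None = 0,
    rtol: float = 1e-8,
) -> FitResult:
    """Estimate (kappa1, kappa2, theta) for one lesion.

    ``rho`` comes from :func:`estimate_growth_rate`; ``K`` is fixed.  The
    initial condition is the first observed cell count with Y = 0 (the
    series must begin before the first infusion).  RMSE on cell counts is
    minimised; intervals in ``series.mask_days`` are excluded.
    """
    keep = series.observation_mask()
    days = series.days[keep]
    cells = series.cells[keep].astype(float)
    events = series.dose_events()
    if len(days) < 4:
        raise UnderDeterminedError("lesion fit needs >= 4 usable observations")
    if events and min(d for d, _ in events) < days[0]:
        raise ConfigError("dose precedes the first observation")
    scale = rho / K
    b = {
        "kappa1": (0.0, 1e3 * scale),
        "kappa2": (-1e3 * scale, 1e3 * scale),
        "theta": (0.0, 10.0),
    }
    if bounds:
        b.update(bounds)
    lo = [b[k][0] for k in ("kappa1", "kappa2", "theta")]
    hi = [b[k][1] for k in ("kappa1", "kappa2", "theta")]
    atol_cells = max(cells.max() * 1e-10, 1e-6)

    def run(start):
        cachebox = {}

        def evaluate(p):
            key = tuple(p)
            if key not in cachebox:
                cachebox.clear()
                penalty = (np.full(len(days), cells.max() * 10),
                           np.zeros((len(days), 3)))
                if not np.all(np.isfinite(p)):
                    return penalty
                try:
                    Xm, J = _solve_piecewise(
                        p, rho, K, cells[0], days, events, rtol=rtol, atol=atol_cells
                    )
                    if not (np.all(np.isfinite(Xm)) and np.all(np.isfinite(J))):
                        raise IntegrationError("non-finite solution")
                    cachebox[key] = (Xm - cells, J)
                except IntegrationError:
                    cachebox[key] = penalty
            return cachebox[key]

        return least_squares(
            lambda p: evaluate(p)[0],
            x0=start,
            jac=lambda p: evaluate(p)[1],
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=100,
        )

    rng = np.random.default_rng(seed)
    starts = [[50 * scale, scale, 1e-5]]
    for _ in range(max(0, n_starts - 1)):
        k1 = 10 ** rng.uniform(np.log10(scale * 1e-1), np.log10(hi[0]))
        k2 = 10 ** rng.uniform(np.log10(scale * 1e-2), np.log10(hi[1]))
        k2 *= rng.choice([-1.0, 1.0])
        th = 10 ** rng.uniform(-7, 0)
        starts.append([k1, k2, th])
    # residual floor: once a start explains the data to count-rounding
    # precision, further starts cannot improve on it
    floor_cost = 0.5 * len(days) * (1e-6 * cells.max()) ** 2
    best = None
    for s in starts:
        res = run(s)
        if best is None or res.cost < best.cost:
            best, best_start = res, s
        if best.cost < floor_cost:
            break
    p = best.x
    Xm, _ = _solve_piecewise(p, rho, K, cells[0], days, events, rtol=rtol,
                             atol=atol_cells)
    rmse = float(np.sqrt(np.mean((Xm - cells) ** 2)))
    from .fitting import goodness_of_fit

    try:
        r2 = goodness_of_fit(Xm, cells)
    except Exception:
        r2 = np.nan
    params = CarrgoParams(
        rho=rho, K=K, kappa1=float(p[0]), kappa2=float(p[1]), theta=float(p[2]),
        unit_label="cells",
    )
    return FitResult(
        params=params,
        fitted=("kappa1", "kappa2", "theta"),
        rmse=rmse,
        r2=r2,
        n_points=len(days),
        converged=bool(best.success),
        bounds_used=b,
        start_point=dict(zip(("kappa1", "kappa2", "theta"), best_start)),
        well_id=series.name,
    )


def fit_lesions_joint(
    series_list: list[LesionSeries],
    rhos: list[float],
    K: float = 1e9,
    bounds: dict | None = None,
    n_starts: int = 8,
    seed: int | None = 0,
    rtol: float = 1e-8,
) -> FitResult:
    """Joint fit of several lesions sharing one (kappa1, kappa2, theta).

    Each lesion keeps its own rho, initial condition and dose schedule;
    residuals are concatenated.  Used when responding lesions in one
    patient are assumed to share killing kinetics.
    """
    if len(series_list) != len(rhos) or len(series_list) < 2:
        raise InvalidInputError("need >= 2 series with matching rhos")
    prepared = []
    for s, r in zip(series_list, rhos):
        keep = s.observation_mask()
        days = s.days[keep]
        cells = s.cells[keep].astype(float)
        if len(days) < 4:
            raise UnderDeterminedError(f"lesion {s.name}: needs >= 4 observations")
        prepared.append((days, cells, s.dose_events(), r))
    scale = max(rhos) / K
    b = {
        "kappa1": (0.0, 1e3 * scale),
        "kappa2": (-1e3 * scale, 1e3 * scale),
        "theta": (0.0, 10.0),
    }
    if bounds:
        b.update(bounds)
    lo = [b[k][0] for k in ("kappa1", "kappa2", "theta")]
    hi = [b[k][1] for k in ("kappa1", "kappa2", "theta")]

    def residuals_jac(p):
        res, jac = [], []
        if not np.all(np.isfinite(p)):
            n_all = sum(len(d) for d, *_ in prepared)
            big = max(c.max() for _, c, *_ in prepared) * 10
            return np.full(n_all, big), np.zeros((n_all, 3))
        for days, cells, events, r in prepared:
            atol_cells = max(cells.max() * 1e-10, 1e-6)
            try:
                Xm, J = _solve_piecewise(p, r, K, cells[0], days, events,
                                         rtol=rtol, atol=atol_cells)
                res.append(Xm - cells)
                jac.append(J)
            except IntegrationError:
                res.append(np.full(len(days), cells.max() * 10))
                jac.append(np.zeros((len(days), 3)))
        return np.concatenate(res), np.vstack(jac)

    cachebox = {}

    def evaluate(p):
        key = tuple(p)
        if key not in cachebox:
            cachebox.clear()
            cachebox[key] = residuals_jac(p)
        return cachebox[key]

    rng = np.random.default_rng(seed)
    starts = [[50 * scale, scale, 1e-5]]
    for _ in range(max(0, n_starts - 1)):
        k1 = 10 ** rng.uniform(np.log10(scale * 1e-1), np.log10(hi[0]))
        k2 = 10 ** rng.uniform(np.log10(scale * 1e-2), np.log10(hi[1]))
        k2 *= rng.choice([-1.0, 1.0])
        th = 10 ** rng.uniform(-7, 0)
        starts.append([k1, k2, th])
    n_all = sum(len(d) for d, *_ in prepared)
    floor_cost = 0.5 * n_all * (
        1e-6 * max(c.max() for _, c, *_ in prepared)
    ) ** 2
    best = None
    for s in starts:
        res = least_squares(
            lambda p: evaluate(p)[0], x0=s, jac=lambda p: evaluate(p)[1],
            bounds=(lo, hi), method="trf", x_scale="jac",
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=100,
        )
        if best is None or res.cost < best.cost:
            best, best_start = res, s
        if best.cost < floor_cost:
            break
    p = best.x
    all_res, _ = residuals_jac(p)
    rmse = float(np.sqrt(np.mean(all_res**2)))
    params = CarrgoParams(
        rho=float(np.mean(rhos)), K=K, kappa1=float(p[0]), kappa2=float(p[1]),
        theta=float(p[2]), unit_label="cells",
    )
    return FitResult(
        params=params,
        fitted=("kappa1", "kappa2", "theta"),
        rmse=rmse,
        r2=np.nan,
        n_points=sum(len(d) for d, *_ in prepared),
        converged=bool(best.success),
        bounds_used=b,
        start_point=dict(zip(("kappa1", "kappa2", "theta"), best_start)),
        well_id="+".join(s.name for s in series_list),
    )
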