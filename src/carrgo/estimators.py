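"""Scikit-learn style estimators for the growth and killing-kinetics fits.

Two regressors cover the two stages of the assay analysis:

* :class:`LogisticGrowthRegressor` -- fits (rho, K) of logistic growth to an
  untreated well, with the initial density fixed at the first observed value
  (a two-parameter fit).
* :class:`CarrgoRegressor` -- fits (kappa1, kappa2, theta) of the
  predator-prey system to a treated well, with (rho, K) fixed from the
  paired untreated fit and the CAR T-cell inoculum known from the E:T ratio.

Both minimise the root-mean-square error via bounded least squares
(``scipy.optimize.least_squares``).  The CARRGO fit integrates the forward
sensitivity equations alongside the state, so the optimizer sees an exact
Jacobian; this matters because theta is a numerically flat direction on the
few-day horizon of the assay.

The estimators follow the sklearn contract (``get_params``/``set_params``,
fitted attributes with trailing underscores, ``fit``/``predict``) and
compose with sklearn tooling; ``X`` is the 1-D (or column) array of
observation times in days and ``y`` the cell-index values.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    IntegrationError,
    InvalidInputError,
)
from .model import logistic_solution

__all__ = ["LogisticGrowthRegressor", "CarrgoRegressor"]

_PENALTY = 1e6


def _as_time_vector(X):
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise InvalidInputError("time input must be 1-D (or a single column)")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    return t


def _r2(predicted, observed):
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        return np.nan
    return float(np.corrcoef(predicted, observed)[0, 1] ** 2)


class LogisticGrowthRegressor(RegressorMixin, BaseEstimator):
    """Fit logistic growth X(t) = K X0 e^{rho t} / (K + X0(e^{rho t}-1)).

    Parameters
    ----------
    x0 : float, optional
        Initial density.  Default: the first observed value (not fitted).
    rho_init, K_init : float, optional
        Starting guesses; derived from the data when omitted.
    bounds : dict, optional
        ``{"rho": (lo, hi), "K": (lo, hi)}`` overrides.

    Attributes
    ----------
    rho_, K_ : float
        Fitted net growth rate (day^-1) and carrying capacity.
    rmse_, r2_ : float
        Root-mean-square error and squared Pearson correlation of the fit.
    converged_ : bool
    """

    def __init__(self, x0=None, rho_init=None, K_init=None, bounds=None, max_nfev=400):
        self.x0 = x0
        self.rho_init = rho_init
        self.K_init = K_init
        self.bounds = bounds
        self.max_nfev = max_nfev

    def fit(self, X, y):
        t = _as_time_vector(X)
        y = np.asarray(y, dtype=float)
        if len(t) != len(y):
            raise InvalidInputError("X and y must have equal length")
        if len(t) < 4:
            raise InsufficientDataError("logistic fit needs >= 4 points")
        if np.ptp(y) == 0:
            raise DegenerateDataError("constant series carries no growth signal")
        x0 = float(y[0]) if self.x0 is None else float(self.x0)
        if x0 <= 0:
            raise DegenerateDataError("initial density must be positive")
        t_rel = t - t[0]
        ymax = float(np.max(y))
        bounds = {"rho": (1e-4, 50.0), "K": (ymax * (1 + 1e-6), 1e4 * ymax)}
        if self.bounds:
            bounds.update(self.bounds)
        K0 = self.K_init if self.K_init is not None else 1.3 * ymax
        if self.rho_init is not None:
            r0 = self.rho_init
        else:
            # crude exponential-phase slope as a starting point
            with np.errstate(divide="ignore"):
                r0 = (np.log(max(y[-1], 1e-12)) - np.log(x0)) / max(t_rel[-1], 1e-9)
            r0 = float(np.clip(r0 * 1.5, bounds["rho"][0] * 2, bounds["rho"][1] / 2))
        K0 = float(np.clip(K0, *bounds["K"]))

        def residuals(p):
            rho, K = p
            return logistic_solution(rho, K, x0, t_rel) - y

        def jac(p):
            rho, K = p
            E = np.exp(-rho * t_rel)
            D = x0 + (K - x0) * E
            dL_drho = x0 * K * (K - x0) * t_rel * E / D**2
            dL_dK = x0 / D - x0 * K * E / D**2
            return np.column_stack([dL_drho, dL_dK])

        lo = [bounds["rho"][0], bounds["K"][0]]
        hi = [bounds["rho"][1], bounds["K"][1]]
        res = least_squares(
            residuals,
            x0=[r0, K0],
            jac=jac,
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=self.max_nfev,
        )
        self.rho_, self.K_ = map(float, res.x)
        self.x0_ = x0
        pred = logistic_solution(self.rho_, self.K_, x0, t_rel)
        self.rmse_ = float(np.sqrt(np.mean((pred - y) ** 2)))
        self.r2_ = _r2(pred, y)
        self.n_points_ = len(t)
        self.t0_ = float(t[0])
        self.converged_ = bool(res.success)
        self.bounds_used_ = bounds
        self.start_point_ = {"rho": r0, "K": K0}
        self.result_ = res
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        return logistic_solution(self.rho_, self.K_, self.x0_, t - self.t0_)


def _carrgo_sensitivity_rhs(rho, K, k1, k2, th):
    """RHS of the state + forward-sensitivity system (8 equations).

    State layout: [X, Y, SX1, SX2, SX3, SY1, SY2, SY3] where SXj = dX/dp_j,
    SYj = dY/dp_j for p = (kappa1, kappa2, theta).
    """

    def rhs(_t, z):
        X, Y = z[0], z[1]
        SX = z[2:5]
        SY = z[5:8]
        a11 = rho * (1.0 - 2.0 * X / K) - k1 * Y
        a12 = -k1 * X
        a21 = k2 * Y
        a22 = k2 * X - th
        XY = X * Y
        dX = rho * X * (1.0 - X / K) - k1 * XY
        dY = k2 * XY - th * Y
        dSX = a11 * SX + a12 * SY + np.array([-XY, 0.0, 0.0])
        dSY = a21 * SX + a22 * SY + np.array([0.0, XY, -Y])
        return np.concatenate(([dX, dY], dSX, dSY))

    return rhs


class CarrgoRegressor(RegressorMixin, BaseEstimator):
    """Fit the killing kinetics (kappa1, kappa2, theta) of a treated well.

    The cancer growth parameters ``rho`` and ``K`` come from the paired
    untreated fit and stay fixed.  The initial cancer density is the first
    observed value of the fit window; the CAR T-cell density at the window
    start is bridged from the known inoculum ``y0_dose`` added at
    ``t_dose`` using the exponential predator solution
    ``Y(t0) = y0_dose * exp((kappa2 * x_bridge - theta) * (t0 - t_dose))``
    with ``x_bridge`` the observed mean cancer density over the short gap
    (the gap exists because the treatment-time spike is excluded from the
    window).

    Parameters
    ----------
    rho, K : float
        Fixed growth parameters (day^-1; density units of the data).
    y0_dose : float
        CAR T-cell inoculum in the data's density units.
    t_dose : float, optional
        Dose time in days.  When omitted the inoculum is applied at the
        first observation time (no bridge).
    x_bridge : float, optional
        Mean observed cancer density over [t_dose, t0]; defaults to the
        first observation.
    bounds : dict, optional
        Per-parameter (lo, hi) overrides.  Defaults: kappa1 in
        [0, 1e3 rho/K], kappa2 in [-1e3 rho/K, 1e3 rho/K], theta in [0, 10].
    start : dict, optional
        Starting point overrides.
    n_starts, seed
        Optional internal multi-start (log-uniform draws within bounds,
        sign-symmetric for kappa2); the best run by RMSE wins.

    Attributes
    ----------
    kappa1_, kappa2_, theta_ : float
    rmse_, r2_, converged_, bound_pinned_, n_points_
    """

    def __init__(
        self,
        rho=1.0,
        K=10.0,
        y0_dose=0.1,
        t_dose=None,
        x_bridge=None,
        bounds=None,
        start=None,
        n_starts=1,
        seed=None,
        rtol=1e-8,
        atol=1e-10,
        max_nfev=400,
    ):
        self.rho = rho
        self.K = K
        self.y0_dose = y0_dose
        self.t_dose = t_dose
        self.x_bridge = x_bridge
        self.bounds = bounds
        self.start = start
        self.n_starts = n_starts
        self.seed = seed
        self.rtol = rtol
        self.atol = atol
        self.max_nfev = max_nfev

    # -- model machinery ---------------------------------------------------

    def _initial_state(self, p, t0, x0):
        k1, k2, th = p
        if self.t_dose is None:
            y_t0 = self.y0_dose
            dSY = np.zeros(3)
        else:
            dt = t0 - self.t_dose
            if dt < 0:
                raise InvalidInputError("t_dose must not be after the first observation")
            xb = x0 if self.x_bridge is None else self.x_bridge
            y_t0 = self.y0_dose * np.exp((k2 * xb - th) * dt)
            dSY = y_t0 * np.array([0.0, xb * dt, -dt])
        return np.concatenate(([x0, y_t0], np.zeros(3), dSY))

    def _solve(self, p, t, x0):
        z0 = self._initial_state(p, t[0], x0)
        rhs = _carrgo_sensitivity_rhs(self.rho, self.K, *p)
        # terminal guards: wild multi-start candidates can blow Y up (huge
        # kappa2) or crush X into denormals (huge kappa1), stalling the
        # integrator; either terminates the solve into the penalty branch
        cap = max(1e6, 1e3 * self.K)
        floor = 1e-12 * self.K

        def blown_up(_t, z):
            return cap - z[1]

        def extinct(_t, z):
            return z[0] - floor

        blown_up.terminal = True
        extinct.terminal = True
        sol = solve_ivp(
            rhs,
            (t[0], t[-1]),
            z0,
            t_eval=t,
            method="LSODA",
            rtol=self.rtol,
            atol=self.atol,
            events=(blown_up, extinct),
        )
        if not sol.success or sol.y.shape[1] != len(t):
            raise IntegrationError("CARRGO sensitivity integration failed")
        return sol.y[0], sol.y[2:5].T  # X(t), dX/dp (n, 3)

    def _fit_single(self, t, y, x0, start_vec, bounds_lo, bounds_hi):
        cache = {}

        def evaluate(p):
            key = tuple(p)
            if key not in cache:
                cache.clear()
                # never hand a non-finite candidate to the integrator (a
                # penalty step's zero Jacobian can produce NaN trial points)
                if not np.all(np.isfinite(p)):
                    return np.full(len(t), _PENALTY), np.zeros((len(t), 3)), False
                try:
                    Xm, J = self._solve(p, t, x0)
                    if not (np.all(np.isfinite(Xm)) and np.all(np.isfinite(J))):
                        raise IntegrationError("non-finite solution")
                    cache[key] = (Xm - y, J, True)
                except IntegrationError:
                    cache[key] = (np.full(len(t), _PENALTY), np.zeros((len(t), 3)), False)
            return cache[key]

        def fun(p):
            return evaluate(p)[0]

        def jac(p):
            return evaluate(p)[1]

        res = least_squares(
            fun,
            x0=start_vec,
            jac=jac,
            bounds=(bounds_lo, bounds_hi),
            method="trf",
            x_scale="jac",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=self.max_nfev,
        )
        return res

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        t = _as_time_vector(X)
        y = np.asarray(y, dtype=float)
        if len(t) != len(y):
            raise InvalidInputError("X and y must have equal length")
        if len(t) < 4:
            raise InsufficientDataError("CARRGO fit needs >= 4 points")
        x0 = float(y[0])
        if x0 <= 0:
            raise DegenerateDataError("initial cancer density must be positive")
        scale = self.rho / self.K
        bounds = {
            "kappa1": (0.0, 1e3 * scale),
            "kappa2": (-1e3 * scale, 1e3 * scale),
            "theta": (0.0, 10.0),
        }
        if self.bounds:
            bounds.update(self.bounds)
        start = {"kappa1": 10.0 * scale, "kappa2": scale, "theta": 1e-3}
        if self.start:
            start.update(start_clip(self.start, bounds))
        lo = [bounds[k][0] for k in ("kappa1", "kappa2", "theta")]
        hi = [bounds[k][1] for k in ("kappa1", "kappa2", "theta")]
        starts = [[start["kappa1"], start["kappa2"], start["theta"]]]
        if self.n_starts > 1:
            rng = np.random.default_rng(self.seed)
            for _ in range(self.n_starts - 1):
                k1 = 10 ** rng.uniform(np.log10(scale * 1e-2), np.log10(hi[0]))
                mag2 = 10 ** rng.uniform(np.log10(scale * 1e-2), np.log10(hi[1]))
                k2 = mag2 * rng.choice([-1.0, 1.0])
                th = 10 ** rng.uniform(-6, 1)
                starts.append([k1, k2, min(th, hi[2])])
        best = None
        for s in starts:
            res = self._fit_single(t, y, x0, s, lo, hi)
            if best is None or res.cost < best.cost:
                best = res
                best_start = s
        p = best.x
        self.kappa1_, self.kappa2_, self.theta_ = map(float, p)
        Xm, _ = self._solve(p, t, x0)
        self.rmse_ = float(np.sqrt(np.mean((Xm - y) ** 2)))
        self.r2_ = _r2(Xm, y)
        self.n_points_ = len(t)
        self.x0_ = x0
        self.t_ = t
        # a parameter sitting on a non-trivial bound signals a constrained,
        # not an interior, optimum
        pinned = []
        for val, (blo, bhi), name in zip(p, zip(lo, hi), ("kappa1", "kappa2", "theta")):
            span = bhi - blo
            if (val - blo) < 1e-9 * span and blo not in (0.0,):
                pinned.append(name)
            if (bhi - val) < 1e-9 * span:
                pinned.append(name)
        self.bound_pinned_ = bool(pinned)
        self.pinned_params_ = tuple(pinned)
        self.converged_ = bool(best.success) and not self.bound_pinned_
        self.bounds_used_ = bounds
        self.start_point_ = dict(zip(("kappa1", "kappa2", "theta"), best_start))
        self.result_ = best
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        tt = t if t[0] == self.t_[0] else np.concatenate(([self.t_[0]], t))
        Xm, _ = self._solve([self.kappa1_, self.kappa2_, self.theta_], tt, self.x0_)
        return Xm if len(tt) == len(t) else Xm[1:]


def start_clip(start: dict, bounds: dict) -> dict:
    """Clip a user start point into the feasible box."""
    out = {}
    for k, v in start.items():
        lo, hi = bounds[k]
        out[k] = float(np.clip(v, lo, hi))
    return out
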