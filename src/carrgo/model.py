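"""Predator-prey dynamics of CAR T-cell mediated cancer-cell killing.

The model couples a logistically growing cancer-cell population ``X`` (prey)
with a CAR T-cell population ``Y`` (predator)::

    dX/dt = rho * X * (1 - X/K) - kappa1 * X * Y
    dY/dt = kappa2 * X * Y - theta * Y

``rho`` is the net cancer growth rate (day^-1), ``K`` the carrying capacity,
``kappa1`` the killing rate, ``kappa2`` the net CAR T-cell
proliferation/exhaustion rate upon contact with a cancer cell (its sign
distinguishes stimulation from exhaustion), and ``theta`` the CAR T-cell
death rate.  Densities are carried in cell-index (CI) units by default, with
an optional affine CI-to-cell calibration applied at I/O time; all rates are
per day.

Rescaling ``tau = rho t``, ``x = X/K``, ``y = (kappa1/rho) Y`` removes the
units and leaves the two dimensionless groups ``A = theta/rho`` and
``B = kappa2 K / rho`` that organise the phase plane (see
:mod:`carrgo.phase`)::

    dx/dtau = x (1 - x) - x y
    dy/dtau = B x y - A y
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import (
    DegenerateScalingError,
    IntegrationError,
    InvalidInputError,
    UndefinedRatioError,
)

__all__ = [
    "CarrgoParams",
    "State",
    "DimensionlessParams",
    "Trajectory",
    "carrgo_rhs",
    "scaled_rhs",
    "simulate",
    "simulate_scaled",
    "logistic_solution",
    "nondimensionalize",
    "redimensionalize",
    "scale_trajectory",
    "endpoint_ratio",
]

logger = logging.getLogger(__name__)

#: Default solver tolerances.  Trajectories hug the invariant axes X=0 and
#: Y=0 where the system is mildly stiff, hence a stiff-capable method and
#: tight tolerances by default.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


def _require_finite(name, *values):
    for v in values:
        if not np.all(np.isfinite(v)):
            raise InvalidInputError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class CarrgoParams:
    """The five kinetic constants of the model.

    Parameters
    ----------
    rho : float
        Cancer net growth rate, day^-1.  Non-negative.
    K : float
        Carrying capacity, in ``unit_label`` units.  Positive.
    kappa1 : float
        CAR T-cell killing rate, day^-1 per ``unit_label`` unit.  Non-negative.
    kappa2 : float
        Net CAR T-cell proliferation (positive) or exhaustion (negative)
        rate upon cancer-cell contact, day^-1 per unit.  Any sign.
    theta : float
        CAR T-cell death rate, day^-1.  Non-negative.
    unit_label : str
        Density unit tag, ``"CI"`` (cell index) or ``"cells"``; applies to
        every density-scaled parameter in the instance.
    """

    rho: float
    K: float
    kappa1: float
    kappa2: float
    theta: float
    unit_label: str = "CI"

    def __post_init__(self):
        _require_finite(
            "CarrgoParams", self.rho, self.K, self.kappa1, self.kappa2, self.theta
        )
        if self.rho < 0:
            raise InvalidInputError(f"rho must be >= 0, got {self.rho}")
        if self.K <= 0:
            raise InvalidInputError(f"K must be > 0, got {self.K}")
        if self.kappa1 < 0:
            raise InvalidInputError(f"kappa1 must be >= 0, got {self.kappa1}")
        if self.theta < 0:
            raise InvalidInputError(f"theta must be >= 0, got {self.theta}")
        if self.unit_label not in ("CI", "cells"):
            raise InvalidInputError(
                f"unit_label must be 'CI' or 'cells', got {self.unit_label!r}"
            )

    def replace(self, **kwargs) -> "CarrgoParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class State:
    """Instantaneous densities (X = cancer cells, Y = CAR T-cells)."""

    X: float
    Y: float

    def __post_init__(self):
        _require_finite("State", self.X, self.Y)
        if self.X < 0 or self.Y < 0:
            raise InvalidInputError(f"densities must be >= 0, got ({self.X}, {self.Y})")


@dataclass(frozen=True)
class DimensionlessParams:
    """The two dimensionless groups A = theta/rho and B = kappa2*K/rho.

    Biologically A >= 0 (theta, rho >= 0); negative A is accepted for
    phase-plane exploration outside the physical domain.
    """

    A: float
    B: float

    def __post_init__(self):
        _require_finite("DimensionlessParams", self.A, self.B)


@dataclass
class Trajectory:
    """A simulated solution on a time grid.

    ``t`` is in days for dimensional runs, or the dimensionless time ``tau``
    when ``scaled`` is set; ``X`` and ``Y`` are aligned with ``t``.
    """

    t: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    scaled: bool = False

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if not (self.t.shape == self.X.shape == self.Y.shape):
            raise InvalidInputError("t, X, Y must have identical shapes")
        if self.t.ndim != 1 or len(self.t) < 2:
            raise InvalidInputError("t must be a 1-D grid with >= 2 points")
        if np.any(np.diff(self.t) <= 0):
            raise InvalidInputError("t must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Tidy export (columns t_days, X, Y, scaled_flag)."""
        return pd.DataFrame(
            {
                "t_days": self.t,
                "X": self.X,
                "Y": self.Y,
                "scaled_flag": np.full(len(self.t), self.scaled),
            }
        )


def carrgo_rhs(state, params: CarrgoParams):
    """Right-hand side (dX/dt, dY/dt) of the dimensional system.

    ``state`` may be a :class:`State` or any (X, Y) pair.
    """
    if isinstance(state, State):
        X, Y = state.X, state.Y
    else:
        X, Y = state
    _require_finite("state", X, Y)
    dX = params.rho * X * (1.0 - X / params.K) - params.kappa1 * X * Y
    dY = params.kappa2 * X * Y - params.theta * Y
    return dX, dY


def scaled_rhs(state, dp: DimensionlessParams):
    """Right-hand side (dx/dtau, dy/dtau) of the scaled system."""
    x, y = (state.X, state.Y) if isinstance(state, State) else state
    _require_finite("state", x, y)
    dx = x * (1.0 - x) - x * y
    dy = dp.B * x * y - dp.A * y
    return dx, dy


def _integrate(rhs, y0, t_grid, rtol, atol, method):
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise InvalidInputError("t_grid must be 1-D and strictly increasing")
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or sol.y.shape[1] != len(t_grid):
        last = float(sol.t[-1]) if sol.t.size else None
        raise IntegrationError(
            f"ODE integration failed: {sol.message}", last_valid_time=last
        )
    X, Y = sol.y
    # The axes X=0 and Y=0 are invariant manifolds of the exact system, so any
    # negative excursion is solver error; clamp and log when beyond atol.
    for name, arr in (("X", X), ("Y", Y)):
        worst = arr.min()
        if worst < -atol:
            logger.warning(
                "clamping negative %s excursion (min %.3e) to 0", name, worst
            )
        np.clip(arr, 0.0, None, out=arr)
    return t_grid, X, Y


def simulate(
    params: CarrgoParams,
    X0: float,
    Y0: float,
    t_grid,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the dimensional system from (X0, Y0) over ``t_grid`` (days)."""
    _require_finite("initial condition", X0, Y0)
    if X0 < 0 or Y0 < 0:
        raise InvalidInputError("X0 and Y0 must be >= 0")

    def rhs(_t, z):
        X, Y = z
        return [
            params.rho * X * (1.0 - X / params.K) - params.kappa1 * X * Y,
            params.kappa2 * X * Y - params.theta * Y,
        ]

    t, X, Y = _integrate(rhs, [X0, Y0], t_grid, rtol, atol, method)
    return Trajectory(t=t, X=X, Y=Y, scaled=False)


def simulate_scaled(
    dp: DimensionlessParams,
    x0: float,
    y0: float,
    tau_grid,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the scaled system from (x0, y0) over ``tau_grid``."""
    _require_finite("initial condition", x0, y0)
    if x0 < 0 or y0 < 0:
        raise InvalidInputError("x0 and y0 must be >= 0")

    def rhs(_t, z):
        x, y = z
        return [x * (1.0 - x) - x * y, dp.B * x * y - dp.A * y]

    t, X, Y = _integrate(rhs, [x0, y0], tau_grid, rtol, atol, method)
    return Trajectory(t=t, X=X, Y=Y, scaled=True)


def logistic_solution(rho: float, K: float, X0: float, t):
    """Closed-form logistic growth K*X0*e^{rho t} / (K + X0*(e^{rho t} - 1)).

    This is the exact solution of the cancer-cell equation with Y = 0.
    Vectorised over ``t``.
    """
    _require_finite("logistic inputs", rho, K, X0)
    if K <= 0:
        raise InvalidInputError(f"K must be > 0, got {K}")
    if X0 < 0:
        raise InvalidInputError(f"X0 must be >= 0, got {X0}")
    t = np.asarray(t, dtype=float)
    # Computed on the stable form X0*K / (X0 + (K - X0)*exp(-rho t)) to avoid
    # overflow of e^{rho t} at large t.
    out = X0 * K / (X0 + (K - X0) * np.exp(-rho * t))
    return out if out.ndim else float(out)


def nondimensionalize(params: CarrgoParams) -> DimensionlessParams:
    """Map kinetic constants to the dimensionless groups (A, B).

    Uses the scaling tau = rho*t, x = X/K, y = (kappa1/rho)*Y, which gives
    A = theta/rho and B = kappa2*K/rho.  Requires rho > 0.
    """
    if params.rho <= 0:
        raise DegenerateScalingError("nondimensionalization requires rho > 0")
    return DimensionlessParams(
        A=params.theta / params.rho, B=params.kappa2 * params.K / params.rho
    )


def redimensionalize(
    dp: DimensionlessParams, rho: float, K: float, kappa1: float
) -> CarrgoParams:
    """Inverse of :func:`nondimensionalize` given the scale-setting constants."""
    if rho <= 0:
        raise DegenerateScalingError("redimensionalization requires rho > 0")
    return CarrgoParams(
        rho=rho, K=K, kappa1=kappa1, kappa2=dp.B * rho / K, theta=dp.A * rho
    )


def scale_trajectory(traj: Trajectory, params: CarrgoParams) -> Trajectory:
    """Apply the scaling maps to a dimensional trajectory."""
    if traj.scaled:
        raise InvalidInputError("trajectory is already scaled")
    if params.rho <= 0:
        raise DegenerateScalingError("scaling requires rho > 0")
    return Trajectory(
        t=traj.t * params.rho,
        X=traj.X / params.K,
        Y=traj.Y * params.kappa1 / params.rho,
        scaled=True,
    )


def endpoint_ratio(traj: Trajectory, tol: float = 1e-9) -> float:
    """Cancer-cell to T-cell ratio X/Y at the final time point.

    Mirrors the endpoint comparison against flow-cytometry counts; undefined
    (raises) when Y has collapsed below ``tol``.
    """
    y_end = traj.Y[-1]
    if y_end <= tol:
        raise UndefinedRatioError(
            f"Y(t_end) = {y_end:.3e} <= tol = {tol:.1e}; CC/TC ratio undefined"
        )
    return float(traj.X[-1] / y_end)
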