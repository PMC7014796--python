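"""Phase-plane analysis of the scaled predator-prey system.

The scaled system

    dx/dtau = x (1 - x) - x y
    dy/dtau = B x y - A y

has equilibria P1 = (0, 0), P2 = (1, 0) and, when admissible (0 < A <= B),
the coexistence point P3 = (A/B, 1 - A/B).  When A ~ 0 the whole y-axis
x = 0 is a line of (non-isolated) equilibria; a point (0, y) on it attracts
nearby trajectories when y > 1, the scaled form of the killing-pressure
condition Y > rho/kappa1.

Three treatment regimes follow from the signs of A and B:

* case 1 (success): A ~ 0, B > 0 -- cancer eliminated, residual T cells;
* case 2 (failure): A ~ 0, B < 0 -- T cells exhaust, cancer reaches K;
* case 3 (coexistence): A > 0, B > 0, A <= B -- damped oscillation into P3,
  read clinically as pseudo-progression / pseudo-response.

Parameter regions the three cases do not cover are labelled "other".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidPointError
from .model import CarrgoParams, DimensionlessParams, carrgo_rhs, simulate_scaled

__all__ = [
    "FixedPoint",
    "FixedPointReport",
    "fixed_points",
    "jacobian_scaled",
    "classify_stability",
    "classify_case",
    "analyze",
    "transient_outcome",
    "phase_portrait_frame",
]

#: Threshold below which A is treated as zero for case assignment (fitted
#: theta values are tiny relative to rho but rarely exactly zero).
A_TOL = 1e-6

#: Tolerance on eigenvalue real parts; smaller magnitudes are non-hyperbolic.
EIG_TOL = 1e-10


@dataclass
class FixedPoint:
    """One equilibrium with its stability diagnosis."""

    label: str  # P1, P2, P3 or axis_line
    x: float
    y: float
    stability: str | None = None  # stable / unstable / saddle / non-hyperbolic / non-isolated
    eigenvalues: tuple | None = None
    note: str = ""

    @property
    def attracting(self) -> bool:
        return self.stability == "stable"


@dataclass
class FixedPointReport:
    """Equilibria of the scaled system plus the regime (case) label."""

    A: float
    B: float
    points: list = field(default_factory=list)
    case_label: str = "other"
    note: str = ""

    def __getitem__(self, label: str) -> FixedPoint:
        for p in self.points:
            if p.label == label:
                return p
        raise KeyError(label)

    @property
    def labels(self):
        return [p.label for p in self.points]


def fixed_points(dp: DimensionlessParams, a_tol: float = A_TOL) -> FixedPointReport:
    """Locate the equilibria for the given (A, B); stability left unset.

    P3 is included only when it lies in the (closed) first quadrant,
    i.e. 0 < A <= B.  With B = 0 and A > 0 the coexistence point is
    undefined and omitted with a note.  With A below ``a_tol`` the y-axis is
    reported as a non-isolated equilibrium line.
    """
    report = FixedPointReport(A=dp.A, B=dp.B)
    report.points.append(FixedPoint("P1", 0.0, 0.0))
    report.points.append(FixedPoint("P2", 1.0, 0.0))
    if abs(dp.A) < a_tol:
        report.points.append(
            FixedPoint(
                "axis_line",
                0.0,
                float("nan"),
                stability="non-isolated",
                note="x = 0 is a line of equilibria; (0, y) attracts when y > 1",
            )
        )
    elif dp.B == 0:
        report.note = "P3 undefined (B = 0 with A > 0); omitted"
    elif 0 < dp.A <= dp.B:
        x3 = dp.A / dp.B
        report.points.append(FixedPoint("P3", x3, 1.0 - x3))
    report.case_label = classify_case(dp, a_tol)
    return report


def jacobian_scaled(x: float, y: float, dp: DimensionlessParams) -> np.ndarray:
    """Analytic Jacobian of the scaled system at (x, y)."""
    return np.array(
        [[1.0 - 2.0 * x - y, -x], [dp.B * y, dp.B * x - dp.A]], dtype=float
    )


def classify_stability(
    point, dp: DimensionlessParams, *, eq_tol: float = 1e-8, eig_tol: float = EIG_TOL
):
    """Stability label and eigenvalues for one equilibrium.

    ``point`` is a :class:`FixedPoint` or an (x, y) pair.  The point must
    satisfy the equilibrium equations within ``eq_tol``.  Labels follow the
    signs of the eigenvalue real parts: all negative -> ``stable``, all
    positive -> ``unstable``, mixed -> ``saddle``; any real part within
    ``eig_tol`` of zero -> ``non-hyperbolic``.  The non-isolated axis line
    (A ~ 0) is labelled ``non-isolated`` with the y > 1 attraction condition.
    """
    if isinstance(point, FixedPoint):
        if point.label == "axis_line" or point.stability == "non-isolated":
            point.stability = "non-isolated"
            point.note = point.note or "(0, y) attracts when y > 1"
            return point.stability, None
        x, y = point.x, point.y
    else:
        x, y = point
    dx = x * (1.0 - x) - x * y
    dy = dp.B * x * y - dp.A * y
    if abs(dx) > eq_tol or abs(dy) > eq_tol:
        raise InvalidPointError(
            f"({x}, {y}) is not an equilibrium: residual ({dx:.2e}, {dy:.2e})"
        )
    eig = np.linalg.eigvals(jacobian_scaled(x, y, dp))
    re = eig.real
    if np.any(np.abs(re) <= eig_tol):
        label = "non-hyperbolic"
    elif np.all(re < 0):
        label = "stable"
    elif np.all(re > 0):
        label = "unstable"
    else:
        label = "saddle"
    if isinstance(point, FixedPoint):
        point.stability = label
        point.eigenvalues = tuple(eig)
    return label, tuple(eig)


def classify_case(dp: DimensionlessParams, a_tol: float = A_TOL) -> str:
    """Assign the treatment regime from the signs of (A, B)."""
    if abs(dp.A) < a_tol:
        if dp.B > 0:
            return "case1_success"
        if dp.B < 0:
            return "case2_failure"
        return "other"
    if dp.A > 0 and dp.B > 0 and dp.A <= dp.B:
        return "case3_coexistence"
    return "other"


def analyze(dp: DimensionlessParams, a_tol: float = A_TOL) -> FixedPointReport:
    """Full report: equilibria with stability labels and the case label."""
    report = fixed_points(dp, a_tol)
    for p in report.points:
        classify_stability(p, dp)
    return report


def transient_outcome(
    X0: float, Y0: float, params: CarrgoParams, *, rel_tol: float = 1e-9
) -> str:
    """Early-response label from the initial killing-pressure inequality.

    The sign of ``Y0 - (rho/kappa1) * (1 - X0/K)`` is (algebraically) the
    sign of -dX/dt at t = 0, so it decides whether the cancer population
    first grows or first shrinks; combined with the long-run regime this
    yields:

    * ``transient_progression`` -- initial growth before eventual response
      (cases 1/3), the model's reading of pseudo-progression;
    * ``transient_regression`` -- initial shrinkage before eventual failure
      (case 2);
    * ``monotone_response`` / ``monotone_failure`` -- initial trend already
      matches the long-run outcome;
    * ``boundary`` -- initial condition on the dX/dt = 0 line.

    With kappa1 = 0 the threshold is undefined and the label is monotone,
    decided by the sign of B (response for B > 0).
    """
    if X0 <= 0:
        raise InvalidInputError("transient_outcome requires X0 > 0")
    from .model import nondimensionalize

    dp = nondimensionalize(params)
    case = classify_case(dp)
    failing = case == "case2_failure" or (case == "other" and dp.B < 0)
    if params.kappa1 == 0:
        return "monotone_failure" if dp.B < 0 else "monotone_response"
    threshold = (params.rho / params.kappa1) * (1.0 - X0 / params.K)
    scale = max(abs(threshold), abs(Y0), 1.0)
    if abs(Y0 - threshold) <= rel_tol * scale:
        return "boundary"
    if Y0 < threshold:  # dX/dt > 0: cancer grows first
        return "monotone_failure" if failing else "transient_progression"
    return "transient_regression" if failing else "monotone_response"


def stability_by_simulation(
    point,
    dp: DimensionlessParams,
    radius: float = 1e-2,
    tau_max: float = 400.0,
    n_starts: int = 4,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> bool:
    """Attractor test by long-horizon simulation (independent of the Jacobian).

    Perturbs the equilibrium by ``radius`` in ``n_starts`` directions,
    integrates to ``tau_max`` and reports True when every trajectory ends
    within ``radius`` of the point.  Starts are clipped into the closed
    first quadrant only when the equilibrium itself lies on an axis
    boundary of it, preserving off-axis escape directions.
    """
    from scipy.integrate import solve_ivp

    x_eq, y_eq = (point.x, point.y) if isinstance(point, FixedPoint) else point
    escape = 0.5

    def rhs(_t, z):
        x, y = z
        return [x * (1.0 - x) - x * y, dp.B * x * y - dp.A * y]

    def escaped(_t, z):
        return np.hypot(z[0] - x_eq, z[1] - y_eq) - escape

    escaped.terminal = True
    angles = np.linspace(0.0, 2.0 * np.pi, n_starts, endpoint=False) + 0.3
    for a in angles:
        z0 = [max(x_eq + radius * np.cos(a), 0.0), max(y_eq + radius * np.sin(a), 0.0)]
        sol = solve_ivp(
            rhs, (0.0, tau_max), z0, method="LSODA", rtol=rtol, atol=atol,
            events=escaped, dense_output=False,
        )
        if sol.t_events[0].size or not sol.success:
            return False  # left the neighbourhood (or blew up): not attracting
        if np.hypot(sol.y[0, -1] - x_eq, sol.y[1, -1] - y_eq) > radius:
            return False
    return True


def phase_portrait_frame(
    dp: DimensionlessParams,
    starts=None,
    tau_max: float = 60.0,
    n_times: int = 400,
) -> pd.DataFrame:
    """Sampled trajectories and equilibria for phase-portrait export.

    Returns a tidy frame (kind, trajectory_id, tau, x, y) suitable for CSV
    export or plotting.
    """
    if starts is None:
        starts = [(x0, y0) for x0 in (0.2, 0.5, 0.9) for y0 in (0.1, 0.5, 1.2)]
    tau = np.linspace(0.0, tau_max, n_times)
    rows = []
    for i, (x0, y0) in enumerate(starts):
        traj = simulate_scaled(dp, x0, y0, tau)
        rows.append(
            pd.DataFrame(
                {
                    "kind": "trajectory",
                    "trajectory_id": i,
                    "tau": traj.t,
                    "x": traj.X,
                    "y": traj.Y,
                }
            )
        )
    rep = analyze(dp)
    eq = pd.DataFrame(
        {
            "kind": "equilibrium",
            "trajectory_id": -1,
            "tau": np.nan,
            "x": [p.x for p in rep.points],
            "y": [p.y for p in rep.points],
        }
    )
    eq["label"] = [p.label for p in rep.points]
    eq["stability"] = [p.stability for p in rep.points]
    out = pd.concat(rows + [eq], ignore_index=True)
    out.attrs["case_label"] = rep.case_label
    return out
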