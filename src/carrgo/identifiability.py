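"""Local, numerical practical-identifiability diagnostics.

Only the cancer-cell trajectory X(t) is observed (the impedance readout
does not separate CAR T-cells), so whether (kappa1, kappa2, theta) can be
resolved from a well is a property of the sensitivity matrix
S[i, j] = dX(t_i)/dp_j.  The diagnostics here are local: central finite
differences of the simulated trajectory around a nominal parameter point,
rank and conditioning of the (scaled) sensitivity matrix, and the smallest
number of observation times at which the matrix reaches full rank.
Together with multi-start dispersion this tests the practical claim —
"if the optimisation converges, it converges to unique values" — without a
symbolic structural-identifiability derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .model import CarrgoParams, simulate

__all__ = [
    "IdentifiabilityReport",
    "finite_difference_sensitivity",
    "sensitivity_matrix",
    "identifiability_from_sensitivity",
    "assess_identifiability",
]

FREE_PARAMS_DEFAULT = ("kappa1", "kappa2", "theta")

#: Singular values below RANK_RTOL * sigma_max count as numerically zero.
RANK_RTOL = 1e-8


@dataclass
class IdentifiabilityReport:
    sensitivity_rank: int
    condition_number: float
    min_points_needed: int
    per_parameter_flags: dict
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))
    free_params: tuple = FREE_PARAMS_DEFAULT


def finite_difference_sensitivity(predict, p0, rel_step: float = 1e-6):
    """Central-difference Jacobian of ``predict(p) -> vector`` at ``p0``.

    The step for parameter j is ``rel_step * (|p0_j| + rel_step_floor)``
    with an absolute floor of 1 so that parameters sitting at zero still
    get a finite probe.  Generic helper, reused for toy models in tests.
    """
    p0 = np.asarray(p0, dtype=float)
    cols = []
    for j in range(len(p0)):
        h = rel_step * (abs(p0[j]) + 1.0)
        up, dn = p0.copy(), p0.copy()
        up[j] += h
        dn[j] -= h
        cols.append((np.asarray(predict(up)) - np.asarray(predict(dn))) / (2 * h))
    return np.column_stack(cols)


def sensitivity_matrix(
    params: CarrgoParams,
    X0: float,
    Y0: float,
    t_points,
    free_params=FREE_PARAMS_DEFAULT,
    rel_step: float = 1e-6,
    rtol: float = 1e-12,
    atol: float = 1e-14,
) -> np.ndarray:
    """S[i, j] = dX(t_i)/dp_j by central differences on the trajectory.

    ``t_points`` (days) need not be distinct or sorted — duplicated
    observation times duplicate rows.  The underlying integrations run at
    tighter-than-default tolerance so solver noise stays well below the
    difference quotient.
    """
    t_points = np.asarray(t_points, dtype=float)
    if t_points.ndim != 1 or len(t_points) == 0:
        raise InvalidInputError("t_points must be a non-empty 1-D array")
    t0 = min(0.0, t_points.min())
    grid = np.unique(np.concatenate([[t0], t_points]))
    if len(grid) < 2:
        grid = np.array([t0, t0 + 1e-6])

    def predict(pvec):
        kw = {name: val for name, val in zip(free_params, pvec)}
        p = params.replace(**kw)
        traj = simulate(p, X0, Y0, grid, rtol=rtol, atol=atol)
        lookup = dict(zip(traj.t, traj.X))
        return np.array([lookup[t] for t in t_points])

    p0 = np.array([getattr(params, name) for name in free_params])
    return finite_difference_sensitivity(predict, p0, rel_step)


def identifiability_from_sensitivity(
    S: np.ndarray,
    param_values=None,
    free_params=FREE_PARAMS_DEFAULT,
    rank_rtol: float = RANK_RTOL,
    weak_condition: float = 1e6,
) -> IdentifiabilityReport:
    """Rank/conditioning diagnosis of a sensitivity matrix.

    Columns are first scaled by the parameter magnitudes (floored at 1e-6)
    so entries are comparable semi-relative sensitivities.  A parameter is
    flagged ``non_identifiable`` when it loads (>0.5) on a null-space
    direction, ``weakly_identifiable`` when the matrix is full-rank but
    ill-conditioned and the parameter loads on the weakest direction, and
    ``identifiable`` otherwise.
    """
    S = np.asarray(S, dtype=float)
    n_par = S.shape[1]
    if param_values is not None:
        scales = np.maximum(np.abs(np.asarray(param_values, float)), 1e-6)
        S = S * scales[None, :]
    if not np.any(S):
        return IdentifiabilityReport(
            sensitivity_rank=0,
            condition_number=np.inf,
            min_points_needed=-1,
            per_parameter_flags={n: "non_identifiable" for n in free_params},
            singular_values=np.zeros(n_par),
            free_params=tuple(free_params),
        )
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    rank = int(np.sum(sv > rank_rtol * sv[0]))
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    flags = {}
    for j, name in enumerate(free_params):
        null_load = np.sqrt(np.sum(Vt[rank:, j] ** 2)) if rank < n_par else 0.0
        weak_load = abs(Vt[-1, j])
        if rank < n_par and null_load > 0.5:
            flags[name] = "non_identifiable"
        elif rank == n_par and cond > weak_condition and weak_load > 0.5:
            flags[name] = "weakly_identifiable"
        else:
            flags[name] = "identifiable"
    return IdentifiabilityReport(
        sensitivity_rank=rank,
        condition_number=cond,
        min_points_needed=-1,
        per_parameter_flags=flags,
        singular_values=sv,
        free_params=tuple(free_params),
    )


def assess_identifiability(
    params: CarrgoParams,
    X0: float,
    Y0: float,
    t_points,
    free_params=FREE_PARAMS_DEFAULT,
    rel_step: float = 1e-6,
    rank_rtol: float = RANK_RTOL,
) -> IdentifiabilityReport:
    """Full local identifiability report at a (fitted) parameter point.

    ``min_points_needed`` is found by adding the observation times one at a
    time (in the order given) until the sensitivity matrix reaches full
    rank; -1 means full rank is never reached on the offered grid.
    """
    t_points = np.asarray(t_points, dtype=float)
    S = sensitivity_matrix(params, X0, Y0, t_points, free_params, rel_step)
    p0 = [getattr(params, n) for n in free_params]
    report = identifiability_from_sensitivity(
        S, param_values=p0, free_params=free_params, rank_rtol=rank_rtol
    )
    n_par = len(free_params)
    min_pts = -1
    for k in range(1, len(t_points) + 1):
        sub = identifiability_from_sensitivity(
            S[:k], param_values=p0, free_params=free_params, rank_rtol=rank_rtol
        )
        if sub.sensitivity_rank == n_par:
            min_pts = k
            break
    report.min_points_needed = min_pts
    return report
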