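"""Synthetic killing-assay plates and lesion series with known ground truth.

The generator emulates the statistical structure of a 96-well impedance
cytotoxicity experiment: an attachment-phase ramp over the first 24 h,
logistic growth of untreated wells, predator-prey dynamics of treated wells
from the moment CAR T-cells are added (~24 h after seeding, at E:T ratios
1:5 / 1:10 / 1:20 against the seeded count), a one-sample plate-handling
spike at the treatment time, and independent multiplicative + additive
measurement noise on the cell index.  Cell counts map to CI through an
affine calibration.

The default plate mirrors the study conditions the analysis is built for:
three cell lines differing in growth rate (0.72, 1.07 and 2.1 day^-1) and
response regime (the fastest line's CAR T-cells exhaust, kappa2 < 0), with
killing rate decreasing and kappa2 increasing with CAR T-cell dose, and a
CAR T-cell death rate below 1e-3 day^-1.  Every well draws its noise from
a named substream of one plate seed, so adding wells never perturbs
existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .invivo import cells_to_volume_mm3
from .model import CarrgoParams, Trajectory, logistic_solution, simulate
from .rtca import WellMeta, WellSeries

__all__ = [
    "CellLineTruth",
    "PlateConfig",
    "default_cell_lines",
    "default_plate_config",
    "generate_plate",
    "generate_invivo_series",
    "SyntheticLesion",
]

HOURS_PER_DAY = 24.0

#: kappa multipliers per CAR product relative to the BBz truth; mock T-cells
#: barely kill and are hypoactivated (net-negative kappa2).
PRODUCT_KAPPA1_FACTOR = {"BBz": 1.0, "28z": 0.9, "mock": 0.05}
PRODUCT_KAPPA2_MOCK = -0.3


@dataclass(frozen=True)
class CellLineTruth:
    """Generating kinetics for one cell line (CI units).

    ``kappa1_by_et`` / ``kappa2_by_et`` encode the dose dependence of the
    killing and proliferation/exhaustion rates (keys are E:T fractions).
    """

    name: str
    rho: float
    K: float
    seeding_count: float
    theta: float
    kappa1_by_et: dict
    kappa2_by_et: dict

    def kinetics(self, et: float, car_product: str = "BBz") -> CarrgoParams:
        k1 = self.kappa1_by_et[et] * PRODUCT_KAPPA1_FACTOR[car_product]
        if car_product == "mock":
            k2 = PRODUCT_KAPPA2_MOCK
        else:
            k2 = self.kappa2_by_et[et]
            if car_product == "28z":
                k2 = k2 * 0.85 if k2 > 0 else k2 * 1.15
        return CarrgoParams(
            rho=self.rho, K=self.K, kappa1=k1, kappa2=k2, theta=self.theta,
            unit_label="CI",
        )


def default_cell_lines() -> list[CellLineTruth]:
    """Three lines spanning slow/intermediate/fast growth and both regimes.

    Growth rates follow the values estimated for the modelled lines
    (0.72, 1.07, 2.1 day^-1); the fastest, low-antigen-history line drives
    its CAR T-cells to net exhaustion (kappa2 < 0, treatment failure) while
    the glioma lines support net CAR T-cell expansion (treatment success).
    kappa1 falls and kappa2 rises with dose, the observed dose trends.
    """
    return [
        CellLineTruth(
            name="PBT138H", rho=0.72, K=10.0, seeding_count=12_500, theta=5e-4,
            kappa1_by_et={0.2: 1.5, 0.1: 2.0, 0.05: 2.5},
            kappa2_by_et={0.2: 1.2, 0.1: 0.9, 0.05: 0.6},
        ),
        CellLineTruth(
            name="PBT030", rho=1.07, K=12.0, seeding_count=12_500, theta=5e-4,
            kappa1_by_et={0.2: 1.2, 0.1: 1.6, 0.05: 2.0},
            kappa2_by_et={0.2: 0.8, 0.1: 0.6, 0.05: 0.4},
        ),
        CellLineTruth(
            name="HT1080H", rho=2.1, K=15.0, seeding_count=2_000, theta=5e-4,
            kappa1_by_et={0.2: 90.0, 0.1: 110.0, 0.05: 130.0},
            kappa2_by_et={0.2: -0.3, 0.1: -0.5, 0.05: -0.7},
        ),
    ]


@dataclass
class PlateConfig:
    """Layout and noise model of a synthetic plate."""

    cell_lines: list = field(default_factory=default_cell_lines)
    et_ratios: tuple = (0.2, 0.1, 0.05)  # 1:5, 1:10, 1:20
    car_products: tuple = ("BBz",)
    replicates_untreated: int = 3
    replicates_treated: int = 3
    sampling_interval_h: float = 0.25
    duration_h: float = 96.0
    treat_time_h: float = 24.0
    attachment_ramp_h: float = 24.0
    spike_amplitude: float = 0.10  # fraction of current CI, one sample
    noise_mult_sd: float = 0.02
    noise_add_sd: float = 0.01
    calibration_slope: float = 8e-5  # CI per cell
    calibration_intercept: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sampling_interval_h <= 0:
            raise ConfigError("sampling_interval_h must be > 0")
        if self.noise_mult_sd < 0 or self.noise_add_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if min(self.replicates_untreated, self.replicates_treated) < 1:
            raise ConfigError("replicates must be >= 1")


def default_plate_config(seed: int = 0, **overrides) -> PlateConfig:
    """The study-condition plate (three lines, triplicates, BBz arm)."""
    return PlateConfig(seed=seed, **overrides)


def _well_rng(seed: int, well_id: str) -> np.random.Generator:
    # named substream: one plate seed + a stable per-well hash
    return np.random.default_rng([seed, zlib.crc32(well_id.encode())])


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _et_tag(et: float) -> str:
    return f"1-{int(round(1 / et))}"


def generate_plate(cfg: PlateConfig):
    """Simulate a plate; returns (wells, truth) with the generating truth.

    Untreated wells follow the attachment ramp into logistic growth;
    treated wells switch to the predator-prey system at ``treat_time`` with
    Y0 = seeding_count * E:T (in CI-equivalents via the calibration slope).
    The handling spike is applied plate-wide at the treatment sample
    whenever the plate contains treated wells.  Identical config and seed
    give bit-identical output.
    """
    dt = cfg.sampling_interval_h
    t_h = np.arange(0.0, cfg.duration_h + dt / 2, dt)
    t_days = t_h / HOURS_PER_DAY
    has_treatment = bool(cfg.et_ratios) and bool(cfg.car_products)
    spike_idx = int(np.argmin(np.abs(t_h - cfg.treat_time_h))) if has_treatment else None
    ramp = np.where(
        t_h < cfg.attachment_ramp_h, _smoothstep(t_h / cfg.attachment_ramp_h), 1.0
    )
    wells, truth_rows = [], []

    def finish(well_id, ci_true, meta, truth):
        ci = ci_true.copy()
        if spike_idx is not None:
            ci[spike_idx] *= 1.0 + cfg.spike_amplitude
        rng = _well_rng(cfg.seed, well_id)
        # both deviate arrays are always drawn so the noise realisation per
        # well is invariant to switching either noise term on or off
        z_mult = rng.standard_normal(ci.shape)
        z_add = rng.standard_normal(ci.shape)
        ci = ci * (1.0 + cfg.noise_mult_sd * z_mult) + cfg.noise_add_sd * z_add
        np.clip(ci, 0.0, None, out=ci)
        wells.append(WellSeries(t=t_h.copy(), ci=ci, meta=meta))
        truth_rows.append(truth)

    for line in cfg.cell_lines:
        x0_ci = cfg.calibration_slope * line.seeding_count + cfg.calibration_intercept
        untreated_ci = ramp * logistic_solution(line.rho, line.K, x0_ci, t_days)
        for r in range(1, cfg.replicates_untreated + 1):
            wid = f"{line.name}_untr_r{r}"
            meta = WellMeta(
                cell_line=line.name, seeding_count=line.seeding_count,
                car_product="none", treat_time_h=cfg.treat_time_h,
                replicate_id=r, well_id=wid,
            )
            finish(wid, untreated_ci, meta, {
                "well_id": wid, "cell_line": line.name, "car_product": "none",
                "et_ratio": np.nan, "replicate_id": r, "rho": line.rho,
                "K": line.K, "kappa1": np.nan, "kappa2": np.nan, "theta": np.nan,
                "Y0_ci": np.nan, "seeding_count": line.seeding_count,
            })
        if not has_treatment:
            continue
        post = t_h >= cfg.treat_time_h
        x_treat = float(
            logistic_solution(line.rho, line.K, x0_ci, cfg.treat_time_h / HOURS_PER_DAY)
        )
        for product in cfg.car_products:
            for et in cfg.et_ratios:
                params = line.kinetics(et, product)
                y0_ci = cfg.calibration_slope * line.seeding_count * et
                traj = simulate(params, x_treat, y0_ci, t_days[post])
                ci_true = untreated_ci.copy()
                ci_true[post] = traj.X
                for r in range(1, cfg.replicates_treated + 1):
                    wid = f"{line.name}_{product}_{_et_tag(et)}_r{r}"
                    meta = WellMeta(
                        cell_line=line.name, seeding_count=line.seeding_count,
                        car_product=product, et_ratio=et,
                        treat_time_h=cfg.treat_time_h, replicate_id=r, well_id=wid,
                    )
                    finish(wid, ci_true, meta, {
                        "well_id": wid, "cell_line": line.name,
                        "car_product": product, "et_ratio": et, "replicate_id": r,
                        "rho": params.rho, "K": params.K, "kappa1": params.kappa1,
                        "kappa2": params.kappa2, "theta": params.theta,
                        "Y0_ci": y0_ci, "seeding_count": line.seeding_count,
                    })
    return wells, pd.DataFrame(truth_rows)


@dataclass
class SyntheticLesion:
    """Ground-truth lesion series: sparse observations + dense segments.

    ``segments`` holds one dense :class:`~carrgo.model.Trajectory` per
    inter-dose interval; X is continuous across a dose while Y jumps by the
    dose size.
    """

    days: np.ndarray
    volumes_mm3: np.ndarray
    cells: np.ndarray
    segments: list
    doses: list


def generate_invivo_series(
    params: CarrgoParams,
    X0: float,
    doses: list,
    obs_days,
    dense_per_segment: int = 200,
) -> SyntheticLesion:
    """Simulate a lesion under a dosing schedule and sample sparse volumes.

    ``doses`` holds (day, cells_reaching_lesion) pairs, applied as
    instantaneous additions to Y; integration is piecewise between events
    (X continuous, Y jumps).  Volumes come from the spherical-cell rule.
    """
    obs_days = np.asarray(obs_days, dtype=float)
    if np.any(np.diff(obs_days) <= 0):
        raise ConfigError("obs_days must be strictly increasing")
    events = sorted(doses)
    if events and events[0][0] < obs_days[0]:
        raise ConfigError("dose precedes the start of observation")
    t0, t1 = obs_days[0], obs_days[-1]
    seg_bounds = [t0] + [d for d, _ in events if t0 < d < t1] + [t1]
    X, Y = float(X0), 0.0
    for d, size in events:
        if d <= t0:
            Y += size
    segments = []
    obs_X = {float(t0): X}
    t_now = t0
    for t_end in seg_bounds[1:]:
        grid = np.unique(np.concatenate([
            np.linspace(t_now, t_end, dense_per_segment),
            obs_days[(obs_days >= t_now) & (obs_days <= t_end)],
        ]))
        traj = simulate(params, X, Y, grid)
        segments.append(traj)
        for tk, xk in zip(traj.t, traj.X):
            if np.any(np.isclose(tk, obs_days)):
                obs_X[float(tk)] = float(xk)
        X, Y = float(traj.X[-1]), float(traj.Y[-1])
        for d, size in events:
            if np.isclose(d, t_end):
                Y += size
        t_now = t_end
    cells = np.array([obs_X[min(obs_X, key=lambda k: abs(k - d))] for d in obs_days])
    return SyntheticLesion(
        days=obs_days,
        volumes_mm3=cells_to_volume_mm3(cells),
        cells=cells,
        segments=segments,
        doses=events,
    )
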