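"""Reading, writing and preprocessing real-time cell-analysis (RTCA) plates.

An RTCA instrument reports a dimensionless electrical-impedance readout, the
cell index (CI), per well at ~15-min resolution.  CI is approximately linear
in adherent cell number, so model parameters can be carried in CI units and
converted with an affine calibration when cell counts are needed.

Preprocessing mirrors the killing-assay protocol: the first ~24 h are an
attachment phase (excluded), CAR T-cells are added at ``treat_time`` (a
plate-handling spike contaminates that sample), and above ~80% of the
maximum CI the CI-to-cell-number linearity breaks down, so the fit window
runs from just after treatment up to the 80%-of-maximum crossing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import (
    CalibrationError,
    InvalidIntervalError,
    MetadataError,
    PlateFormatError,
    PreprocessingError,
)

__all__ = [
    "WellMeta",
    "WellSeries",
    "FitWindow",
    "load_plate",
    "write_plate",
    "select_fit_window",
    "ci_to_cells",
    "cells_to_ci",
    "fit_calibration",
    "downsample",
]

logger = logging.getLogger(__name__)

CAR_PRODUCTS = ("BBz", "28z", "mock", "none")


def _normalize_product(p) -> str:
    if p is None:
        return "none"
    p = str(p).replace("ζ", "z")  # accept the Greek-zeta spelling
    if p not in CAR_PRODUCTS:
        raise MetadataError(f"unknown car_product {p!r}; expected one of {CAR_PRODUCTS}")
    return p


@dataclass(frozen=True)
class WellMeta:
    """Experimental annotation of one well."""

    cell_line: str
    seeding_count: float
    car_product: str = "none"
    et_ratio: float | None = None  # effectors per target, e.g. 1/5 = 0.2
    treat_time_h: float = 24.0
    replicate_id: int = 1
    well_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "car_product", _normalize_product(self.car_product))
        treated = self.car_product != "none"
        if treated and (self.et_ratio is None or self.et_ratio <= 0):
            raise MetadataError(
                f"well {self.well_id or '?'}: treated wells need a positive et_ratio"
            )
        if not treated and self.et_ratio is not None:
            raise MetadataError(
                f"well {self.well_id or '?'}: untreated wells must not carry an et_ratio"
            )

    @property
    def treated(self) -> bool:
        return self.car_product != "none"


@dataclass
class WellSeries:
    """One well's (time, cell-index) series plus metadata.

    Times are hours since seeding; CI values are dimensionless and finite.
    """

    t: np.ndarray
    ci: np.ndarray
    meta: WellMeta

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.ci = np.asarray(self.ci, dtype=float)
        if self.t.shape != self.ci.shape or self.t.ndim != 1:
            raise PlateFormatError("t and ci must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise PlateFormatError(
                f"well {self.meta.well_id or '?'}: time must be strictly increasing"
            )
        if not np.all(np.isfinite(self.ci)):
            raise PlateFormatError(f"well {self.meta.well_id or '?'}: non-finite CI")

    def __len__(self):
        return len(self.t)

    def sliced(self, start: int, end: int) -> "WellSeries":
        return WellSeries(t=self.t[start:end], ci=self.ci[start:end], meta=self.meta)

    def to_frame(self, window: "FitWindow | None" = None) -> pd.DataFrame:
        """Tidy per-well export (t_hours, ci, in_window flag)."""
        flag = np.zeros(len(self), dtype=bool)
        if window is not None:
            flag[window.start : window.end] = True
        return pd.DataFrame({"t_hours": self.t, "ci": self.ci, "in_window": flag})


@dataclass(frozen=True)
class FitWindow:
    """Half-open index range [start, end) of a WellSeries used for fitting."""

    start: int
    end: int
    reasons: tuple = ()

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise PreprocessingError(f"invalid window [{self.start}, {self.end})")


def _load_metadata_map(metadata_map):
    if isinstance(metadata_map, (str, Path)):
        with open(metadata_map) as fh:
            metadata_map = yaml.safe_load(fh)
    if "wells" in metadata_map:
        plate_defaults = {
            k: v for k, v in metadata_map.items() if k not in ("wells",)
        }
        wells = metadata_map["wells"]
    else:
        plate_defaults, wells = {}, metadata_map
    return plate_defaults, wells


def load_plate(path, metadata_map, time_col: str = "time_h") -> list[WellSeries]:
    """Read a wide plate CSV (one time column, one column per well).

    ``metadata_map`` is a mapping well-name -> metadata dict, or a YAML file
    with optional plate-level defaults (``treat_time_h``, ...) and a
    ``wells`` section.  Columns without metadata are logged and skipped;
    wells named in the map but absent from the CSV raise
    :class:`MetadataError`.
    """
    plate_defaults, well_map = _load_metadata_map(metadata_map)
    df = pd.read_csv(path)
    if time_col not in df.columns:
        raise PlateFormatError(f"plate CSV lacks time column {time_col!r}")
    t = df[time_col].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise PlateFormatError("time column is not strictly increasing")
    missing = set(well_map) - (set(df.columns) - {time_col})
    if missing:
        raise MetadataError(f"metadata names wells absent from the CSV: {sorted(missing)}")
    out = []
    treat_default = float(plate_defaults.get("treat_time_h", 24.0))
    for col in df.columns:
        if col == time_col:
            continue
        if col not in well_map:
            logger.info("skipping unmapped plate column %r", col)
            continue
        m = dict(well_map[col])
        m.setdefault("treat_time_h", treat_default)
        m.setdefault("well_id", col)
        meta = WellMeta(**m)
        out.append(WellSeries(t=t.copy(), ci=df[col].to_numpy(dtype=float), meta=meta))
    return out


def write_plate(wells: list[WellSeries], csv_path, meta_path=None, time_col="time_h"):
    """Write wells back to the wide-CSV + YAML dialect that load_plate reads.

    All wells must share one time grid.
    """
    t0 = wells[0].t
    data = {time_col: t0}
    meta = {"wells": {}}
    for w in wells:
        if len(w.t) != len(t0) or not np.allclose(w.t, t0):
            raise PlateFormatError("write_plate requires a shared time grid")
        data[w.meta.well_id] = w.ci
        m = {
            "cell_line": w.meta.cell_line,
            "seeding_count": float(w.meta.seeding_count),
            "car_product": w.meta.car_product,
            "treat_time_h": float(w.meta.treat_time_h),
            "replicate_id": int(w.meta.replicate_id),
        }
        if w.meta.et_ratio is not None:
            m["et_ratio"] = float(w.meta.et_ratio)
        meta["wells"][w.meta.well_id] = m
    pd.DataFrame(data).to_csv(csv_path, index=False)
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


def select_fit_window(
    ws: WellSeries,
    confluency_frac: float = 0.8,
    spike_halfwidth_h: float = 1.0,
    ci_max: float | None = None,
) -> FitWindow:
    """Select the post-treatment, below-confluency fit window.

    The window starts at the first sample with
    ``t >= treat_time + spike_halfwidth`` (excluding both the attachment
    phase and the plate-handling spike at the treatment time) and ends
    before the first sample whose CI exceeds ``confluency_frac`` times the
    well's maximum CI (where CI stops tracking cell number).  ``ci_max``
    overrides the per-well maximum, e.g. to re-window a series that was
    already trimmed.
    """
    t_start = ws.meta.treat_time_h + spike_halfwidth_h
    idx = np.nonzero(ws.t >= t_start)[0]
    if idx.size == 0:
        raise PreprocessingError(
            f"well {ws.meta.well_id or '?'}: no samples at or after "
            f"treat_time + spike_halfwidth = {t_start} h (post_treatment rule)"
        )
    start = int(idx[0])
    tail = ws.ci[start:]
    cmax = float(np.max(tail)) if ci_max is None else float(ci_max)
    thresh = confluency_frac * cmax
    over = np.nonzero(tail > thresh)[0]
    end = start + int(over[0]) if over.size else len(ws)
    if end <= start:
        raise PreprocessingError(
            f"well {ws.meta.well_id or '?'}: confluency cutoff at "
            f"{confluency_frac:.0%} of max CI leaves no samples (confluency_cutoff rule)"
        )
    return FitWindow(start=start, end=end, reasons=("post_treatment", "confluency_cutoff"))


def cells_to_ci(cells, slope: float, intercept: float = 0.0):
    """Affine calibration CI = slope * cells + intercept (slope > 0)."""
    if slope <= 0:
        raise CalibrationError(f"calibration slope must be > 0, got {slope}")
    return slope * np.asarray(cells, dtype=float) + intercept


def ci_to_cells(ci, slope: float, intercept: float = 0.0):
    """Inverse calibration cells = (CI - intercept) / slope."""
    if slope <= 0:
        raise CalibrationError(f"calibration slope must be > 0, got {slope}")
    return (np.asarray(ci, dtype=float) - intercept) / slope


def fit_calibration(ci_values, cell_counts):
    """Least-squares slope/intercept of CI against cell count.

    Returns (slope, intercept, r_squared); the linearity of this relation
    (r^2 > 0.9 in practice) is what justifies working in CI units.
    """
    res = stats.linregress(np.asarray(cell_counts, float), np.asarray(ci_values, float))
    if res.slope <= 0:
        raise CalibrationError(f"fitted calibration slope {res.slope} is not positive")
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def downsample(ws: WellSeries, interval_h: float) -> WellSeries:
    """Thin a series to a regular grid of ``interval_h``-spaced samples.

    Keeps, for each multiple of ``interval_h`` inside the recorded span, the
    sample nearest in time; multiples are absolute (anchored at t = 0, the
    seeding time) so that windowing and down-sampling commute on aligned
    grids.  The first and last samples are always retained.  ``interval_h``
    below the native spacing is rejected.
    """
    native = float(np.median(np.diff(ws.t)))
    if interval_h < native * (1 - 1e-9):
        raise InvalidIntervalError(
            f"interval {interval_h} h is below the native spacing {native} h"
        )
    if abs(interval_h - native) <= 1e-9 * max(interval_h, native):
        return replace(ws, t=ws.t.copy(), ci=ws.ci.copy())
    k0 = int(np.ceil(ws.t[0] / interval_h - 1e-9))
    k1 = int(np.floor(ws.t[-1] / interval_h + 1e-9))
    grid = np.arange(k0, k1 + 1) * interval_h
    # searchsorted gives the right neighbour; swap to the closer of the two
    take = []
    for g, i in zip(grid, np.searchsorted(ws.t, grid)):
        i = min(i, len(ws.t) - 1)
        if i > 0 and abs(ws.t[i - 1] - g) <= abs(ws.t[i] - g):
            i -= 1
        take.append(i)
    take += [0, len(ws.t) - 1]
    idx = np.unique(take)
    return WellSeries(t=ws.t[idx], ci=ws.ci[idx], meta=ws.meta)
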