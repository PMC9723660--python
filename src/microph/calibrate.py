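"""Linear excitation-ratio ↔ pH calibration for the ratiometric biosensor.

The sensor's excitation ratio R = I475/I395 responds linearly to external pH
with a negative slope over roughly pH 4.6–7.6 (unbuffered medium) or 5.0–7.4
(buffered). The curve is fitted by ordinary least squares on the per-level
mean ratios — one point per pH level, each level weighted equally — inverted
to convert per-cell ratios to pH, and used to propagate ratio precision into
pH precision via sd_pH = sd_R / |slope|.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CellObservation, QCFlag

__all__ = [
    "Medium",
    "CalibrationPoint",
    "CalibrationCurve",
    "fit_calibration",
    "ratio_to_ph",
    "propagate_sd",
    "apply_calibration",
    "synthetic_calibration_points",
    "read_calibration_csv",
    "write_curve_json",
    "read_curve_json",
]

#: grace margin (pH units) beyond the fitted range before flagging
RANGE_MARGIN = 0.2


class Medium(str, Enum):
    BUFFERED = "buffered"
    UNBUFFERED = "unbuffered"


@dataclass(frozen=True)
class CalibrationPoint:
    """All per-cell ratios measured at one known pH level."""

    ph_true: float
    ratios: tuple[float, ...]
    medium: Medium = Medium.UNBUFFERED

    def __post_init__(self) -> None:
        if not (3.0 <= self.ph_true <= 9.0):
            raise ValueError("ph_true outside the plausible [3, 9] range")
        if len(self.ratios) < 1 or any(r <= 0 for r in self.ratios):
            raise ValueError("need at least one positive ratio per level")

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios))

    @property
    def sd_ratio(self) -> float:
        return float(np.std(self.ratios, ddof=1)) if len(self.ratios) > 1 else 0.0


@dataclass
class CalibrationCurve:
    """Fitted line R = slope·pH + intercept with its validity range."""

    slope: float
    intercept: float
    r_squared: float
    ph_range: tuple[float, float]
    sd_by_level: dict[float, float] = field(default_factory=dict)
    medium: Medium = Medium.UNBUFFERED

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("calibration slope must be negative")
        if self.ph_range[0] >= self.ph_range[1]:
            raise ValueError("ph_range must be (min, max) with min < max")

    def ratio(self, ph: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(ph, dtype=float) + self.intercept


def fit_calibration(points: list[CalibrationPoint]) -> CalibrationCurve:
    """OLS of per-level mean ratio on pH (levels weighted equally).

    Raises if fewer than two distinct pH levels are given or if the fitted
    slope is non-negative (a non-responsive sensor).
    """
    levels = sorted({p.ph_true for p in points})
    if len(levels) < 2:
        raise ValueError("need at least two distinct pH levels to calibrate")
    media = {p.medium for p in points}
    if len(media) > 1:
        raise ValueError("fit one curve per medium; mixed media supplied")
    by_level: dict[float, list[CalibrationPoint]] = {}
    for p in points:
        by_level.setdefault(p.ph_true, []).append(p)
    ph = np.array(levels)
    mean_r = np.array(
        [np.mean([r for p in by_level[lv] for r in p.ratios]) for lv in levels]
    )
    fit = stats.linregress(ph, mean_r)
    if fit.slope >= 0:
        raise ValueError(f"non-responsive sensor: fitted slope {fit.slope:.4f} >= 0")
    sd_by_level = {
        lv: float(np.std([r for p in by_level[lv] for r in p.ratios], ddof=1))
        if sum(len(p.ratios) for p in by_level[lv]) > 1
        else 0.0
        for lv in levels
    }
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        ph_range=(float(ph.min()), float(ph.max())),
        sd_by_level=sd_by_level,
        medium=media.pop(),
    )


def ratio_to_ph(curve: CalibrationCurve, ratio: float) -> tuple[float, QCFlag]:
    """Invert the curve: pH = (R − intercept)/slope, range-checked.

    Values more than 0.2 pH units outside the fitted range are flagged
    ``out_of_calibration_range`` (reported, but excluded from mapping by
    default) rather than clamped: extrapolating the sensor past its
    calibrated response is not defensible.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    ph = (ratio - curve.intercept) / curve.slope
    lo, hi = curve.ph_range
    flag = (
        QCFlag.OK
        if (lo - RANGE_MARGIN) <= ph <= (hi + RANGE_MARGIN)
        else QCFlag.OUT_OF_CALIBRATION_RANGE
    )
    return float(ph), flag


def propagate_sd(curve: CalibrationCurve, sd_ratio: float) -> float:
    """First-order precision propagation: sd_pH = sd_R / |slope|."""
    if sd_ratio < 0:
        raise ValueError("sd_ratio must be >= 0")
    return sd_ratio / abs(curve.slope)


def apply_calibration(
    observations: list[CellObservation], curve: CalibrationCurve
) -> list[CellObservation]:
    """Fill ``ph`` on every ok-flagged observation in place; returns the list.

    Observations that invert outside the calibrated range are re-flagged
    ``out_of_calibration_range`` (their pH is still recorded).
    """
    for obs in observations:
        if obs.qc_flag is not QCFlag.OK:
            continue
        ph, flag = ratio_to_ph(curve, obs.ratio)
        obs.ph = ph
        obs.qc_flag = flag
    return observations


def synthetic_calibration_points(
    slope: float = -0.475,
    intercept: float = 3.965,
    ph_levels: tuple[float, ...] = (4.6, 5.0, 5.4, 5.8, 6.2, 6.6, 7.0, 7.4, 7.6),
    n_cells: int = 300,
    sd_lo: float = 0.01,
    sd_hi: float = 0.10,
    medium: Medium = Medium.UNBUFFERED,
    seed: int = 0,
) -> list[CalibrationPoint]:
    """Emulate a single-cell calibration experiment on a known line.

    Per-cell ratios at each level are the true line value plus Gaussian noise
    whose sd interpolates linearly from ``sd_lo`` at the highest pH to
    ``sd_hi`` at the lowest, mirroring the observed trend of ratio scatter
    growing toward acidic pH. ~300 cells per level matches a realistic
    per-level census.
    """
    rng = np.random.default_rng(seed)
    lo, hi = min(ph_levels), max(ph_levels)
    points = []
    for ph in ph_levels:
        frac = (hi - ph) / (hi - lo) if hi > lo else 0.0
        sd = sd_lo + frac * (sd_hi - sd_lo)
        true_r = slope * ph + intercept
        ratios = true_r + rng.normal(0.0, sd, size=n_cells)
        ratios = np.clip(ratios, 1e-6, None)
        points.append(CalibrationPoint(ph, tuple(float(r) for r in ratios), medium))
    return points


def read_calibration_csv(path: str | Path) -> list[CalibrationPoint]:
    """Read a long-format table: ph_true,medium,cell_id,ratio."""
    df = pd.read_csv(path)
    required = {"ph_true", "medium", "ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"calibration CSV must have columns {sorted(required)}")
    points = []
    for (ph, medium), grp in df.groupby(["ph_true", "medium"], sort=True):
        points.append(
            CalibrationPoint(float(ph), tuple(grp["ratio"].astype(float)), Medium(medium))
        )
    return points


def write_curve_json(curve: CalibrationCurve, path: str | Path) -> None:
    payload = {
        "slope": curve.slope,
        "intercept": curve.intercept,
        "r_squared": curve.r_squared,
        "ph_range": list(curve.ph_range),
        "sd_by_level": {f"{k:g}": v for k, v in curve.sd_by_level.items()},
        "medium": curve.medium.value,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_curve_json(path: str | Path) -> CalibrationCurve:
    with open(path) as fh:
        payload = json.load(fh)
    return CalibrationCurve(
        slope=payload["slope"],
        intercept=payload["intercept"],
        r_squared=payload["r_squared"],
        ph_range=tuple(payload["ph_range"]),
        sd_by_level={float(k): v for k, v in payload["sd_by_level"].items()},
        medium=Medium(payload["medium"]),
    )
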