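"""Calibration-curve fitting, back-calculation and linearity acceptance.

The regression is performed on the internal-standard response ratio
(analyte peak area / IS peak area) against nominal concentration, the
standard practice for isotope-dilution LC-MS/MS assays.  Unweighted least
squares is the default; 1/x and 1/x² weighting are available because a
1000-fold calibration range concentrates leverage at the top of the curve.

Linearity acceptance combines four rules:

* at least 75% of calibration points — and never fewer than 6 — back-
  calculate within ±15% of nominal,
* every relative residual |y − ŷ|/ŷ is at most 20%,
* the standard deviation of the relative residuals,
  sqrt(Σ(Y_i − Ȳ)²/(n − 2)) on the fraction scale, is at most 0.1,
* r² ≥ 0.99.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pkbioval.config import Thresholds

__all__ = [
    "CalibrationStandard",
    "CalibrationCurve",
    "LinearityReport",
    "fit_calibration",
    "back_calculate",
    "evaluate_linearity",
    "standards_from_frame",
]

WEIGHTINGS = ("none", "1/x", "1/x2")


@dataclass
class CalibrationStandard:
    """One calibration standard: nominal concentration and peak areas."""

    nominal_conc: float  # ng/mL
    analyte_area: float
    is_area: float

    @property
    def response(self) -> float:
        """Analyte/IS area ratio."""
        if self.is_area <= 0:
            raise ValueError("response undefined for non-positive IS area")
        return self.analyte_area / self.is_area


@dataclass
class CalibrationCurve:
    """Fitted calibration line with residual diagnostics."""

    slope: float                 # response per ng/mL
    intercept: float             # response
    r: float
    r_squared: float
    weighting: str
    nominal: np.ndarray = field(repr=False)
    responses: np.ndarray = field(repr=False)
    back_calculated: np.ndarray = field(repr=False)
    relative_residuals: np.ndarray = field(repr=False)  # fractions |y-ŷ|/ŷ
    sd_relative_residuals: float = float("nan")

    def predict(self, conc) -> np.ndarray:
        return self.slope * np.asarray(conc, dtype=float) + self.intercept


def standards_from_frame(df: pd.DataFrame) -> list[CalibrationStandard]:
    """Build standards from a calibration table, dropping blank/zero records."""
    sub = df[df["sample_type"] == "standard"] if "sample_type" in df else df
    return [
        CalibrationStandard(
            nominal_conc=float(row.level_ng_ml),
            analyte_area=float(row.analyte_area),
            is_area=float(row.is_area),
        )
        for row in sub.itertuples()
    ]


def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(x)
    if weighting == "1/x":
        return 1.0 / x
    if weighting == "1/x2":
        return 1.0 / x**2
    raise ValueError(f"unknown weighting {weighting!r}; choose from {WEIGHTINGS}")


def fit_calibration(
    standards: Iterable[CalibrationStandard],
    weighting: str = "none",
) -> CalibrationCurve:
    """Weighted least-squares line of response ratio vs nominal concentration.

    Blank/zero records (non-positive nominal concentration) are excluded.
    Requires at least 6 distinct concentration levels.
    """
    standards = [s for s in standards if s.nominal_conc > 0]
    n_levels = len({s.nominal_conc for s in standards})
    if n_levels < 6:
        raise ValueError(
            f"calibration requires at least 6 distinct non-blank levels, got {n_levels}"
        )
    x = np.array([s.nominal_conc for s in standards], dtype=float)
    y = np.array([s.response for s in standards], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in nominal concentrations: singular fit")

    w = _weights(x, weighting)
    xb = np.average(x, weights=w)
    yb = np.average(y, weights=w)
    sxx = np.sum(w * (x - xb) ** 2)
    slope = float(np.sum(w * (x - xb) * (y - yb)) / sxx)
    intercept = float(yb - slope * xb)

    fitted = slope * x + intercept
    ss_res = np.sum(w * (y - fitted) ** 2)
    ss_tot = np.sum(w * (y - yb) ** 2)
    r_squared = float(1.0 - ss_res / ss_tot)
    r = math.copysign(math.sqrt(max(r_squared, 0.0)), slope)

    back = (y - intercept) / slope
    rel_res = np.abs(y - fitted) / fitted
    n = len(x)
    sd_rel = float(np.sqrt(np.sum((rel_res - rel_res.mean()) ** 2) / (n - 2)))

    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r=float(r),
        r_squared=r_squared,
        weighting=weighting,
        nominal=x,
        responses=y,
        back_calculated=back,
        relative_residuals=rel_res,
        sd_relative_residuals=sd_rel,
    )


def back_calculate(curve: CalibrationCurve, response) -> np.ndarray | float:
    """Invert the fitted line: concentration = (response − intercept)/slope."""
    if curve.slope == 0:
        raise ZeroDivisionError("slope is zero: calibration line has no inverse")
    out = (np.asarray(response, dtype=float) - curve.intercept) / curve.slope
    return float(out) if out.ndim == 0 else out


@dataclass
class LinearityReport:
    """Per-criterion values and booleans for the linearity acceptance rules."""

    point_deviations_pct: np.ndarray     # signed % deviation per standard
    n_points_within: int
    n_points: int
    points_ok: bool
    max_relative_residual_pct: float
    relative_residuals_ok: bool
    sd_relative_residuals: float
    sd_relative_residuals_ok: bool
    r_squared: float
    r_squared_ok: bool
    passed: bool

    def to_dict(self) -> dict:
        return {
            "point_deviations_pct": [float(v) for v in self.point_deviations_pct],
            "n_points_within": self.n_points_within,
            "n_points": self.n_points,
            "points_ok": self.points_ok,
            "max_relative_residual_pct": self.max_relative_residual_pct,
            "relative_residuals_ok": self.relative_residuals_ok,
            "sd_relative_residuals": self.sd_relative_residuals,
            "sd_relative_residuals_ok": self.sd_relative_residuals_ok,
            "r_squared": self.r_squared,
            "r_squared_ok": self.r_squared_ok,
            "passed": self.passed,
        }


def evaluate_linearity(
    curve: CalibrationCurve,
    thresholds: Thresholds | None = None,
) -> LinearityReport:
    """Apply all four linearity acceptance rules to a fitted curve."""
    thr = thresholds or Thresholds()
    dev_pct = 100.0 * (curve.back_calculated - curve.nominal) / curve.nominal
    within = np.abs(dev_pct) <= thr.point_deviation_pct
    n = len(dev_pct)
    n_within = int(within.sum())
    points_ok = n_within >= max(6, math.ceil(0.75 * n))

    max_rel = float(100.0 * np.max(curve.relative_residuals))
    rel_ok = max_rel <= thr.relative_residual_pct
    sd_ok = curve.sd_relative_residuals <= thr.sd_relative_residuals
    r2_ok = curve.r_squared >= thr.r_squared

    return LinearityReport(
        point_deviations_pct=dev_pct,
        n_points_within=n_within,
        n_points=n,
        points_ok=points_ok,
        max_relative_residual_pct=max_rel,
        relative_residuals_ok=rel_ok,
        sd_relative_residuals=curve.sd_relative_residuals,
        sd_relative_residuals_ok=bool(sd_ok),
        r_squared=curve.r_squared,
        r_squared_ok=bool(r2_ok),
        passed=bool(points_ok and rel_ok and sd_ok and r2_ok),
    )
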