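"""Dose-proportionality regressions of exposure against dose.

Two small models describe how exposure scales across a handful of dose
groups:

* power model ``y = a·x^b`` for AUC(0→t) vs dose, fitted as ordinary least
  squares of ln y on ln x (the classical dose-proportionality power model;
  b = 1 means exact proportionality);
* logarithmic model ``y = m·ln(x) + c`` for C_max vs dose, fitted by OLS
  with ln-dose as the regressor.

With only three dose groups these are descriptive fits; r² is reported on
the fitted scale and no inference is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = ["DoseResponseFit", "fit_power", "fit_logarithmic"]


@dataclass
class DoseResponseFit:
    """A fitted dose--exposure regression.

    For the power model ``coefficient`` is the multiplier a and
    ``exponent_or_intercept`` the exponent b of ``y = a·x^b``; for the
    logarithmic model they are the slope m and intercept c of
    ``y = m·ln(x) + c``.
    """

    model: str                    # "power" | "logarithmic"
    coefficient: float
    exponent_or_intercept: float
    r_squared: float
    scale_of_r2: str              # "log-log" | "raw"
    r_squared_raw: float | None = None  # secondary raw-scale r² (power model)

    def to_dict(self) -> dict:
        return asdict(self)

    def predict(self, doses) -> np.ndarray:
        x = np.asarray(doses, dtype=float)
        if self.model == "power":
            return self.coefficient * x ** self.exponent_or_intercept
        return self.coefficient * np.log(x) + self.exponent_or_intercept


def _check_xy(doses, values, require_positive_y: bool) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(doses, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) != len(y):
        raise ValueError("doses and values must have equal length")
    if len(x) < 3:
        raise ValueError("at least 3 (dose, value) pairs are required")
    if np.any(x <= 0):
        raise ValueError("doses must be strictly positive")
    if require_positive_y and np.any(y <= 0):
        raise ValueError("values must be strictly positive for the power model")
    return x, y


def fit_power(doses, values) -> DoseResponseFit:
    """Power regression ``y = a·x^b`` via OLS on the log--log scale."""
    x, y = _check_xy(doses, values, require_positive_y=True)
    res = stats.linregress(np.log(x), np.log(y))
    coefficient = math.exp(res.intercept)
    exponent = float(res.slope)
    fitted_raw = coefficient * x**exponent
    ss_res = float(np.sum((y - fitted_raw) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return DoseResponseFit(
        model="power",
        coefficient=float(coefficient),
        exponent_or_intercept=exponent,
        r_squared=float(res.rvalue**2),
        scale_of_r2="log-log",
        r_squared_raw=1.0 - ss_res / ss_tot,
    )


def fit_logarithmic(doses, values) -> DoseResponseFit:
    """Logarithmic regression ``y = m·ln(x) + c`` by OLS."""
    x, y = _check_xy(doses, values, require_positive_y=False)
    res = stats.linregress(np.log(x), y)
    return DoseResponseFit(
        model="logarithmic",
        coefficient=float(res.slope),
        exponent_or_intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        scale_of_r2="raw",
    )
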