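"""Noncompartmental analysis (NCA) of plasma concentration--time profiles.

Implements the linear trapezoidal AUC(0→t) and AUMC(0→t), mean residence
time, terminal (elimination-phase) log-linear regression with automatic
window selection, and the derived parameters C_max, t_max, C_last, t_last,
Cl_B/F and Vd_area/F.

Concentrations in ng/mL are treated as µg/L throughout, so AUC carries
µg·h/L and clearance lands in L/h once the dose is expressed in µg.

BLQ (below the limit of quantitation) policy: leading BLQ samples before
the first quantifiable one (typically the pre-dose sample) are kept as
zeros; embedded or trailing BLQ samples are excluded from the trapezoid
and from the terminal fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcentrationTimeProfile",
    "TerminalFit",
    "NcaResult",
    "auc_linear_trapezoid",
    "aumc_linear_trapezoid",
    "mrt",
    "terminal_slope",
    "nca_summary",
    "profiles_from_frame",
    "profiles_to_frame",
    "group_summary",
]


@dataclass
class ConcentrationTimeProfile:
    """One subject's concentration--time series with dosing metadata."""

    subject_id: str
    group: str
    dose_mg_per_kg: float
    body_weight_kg: float
    times: np.ndarray
    concentrations: np.ndarray
    blq_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.blq_flags is None:
            self.blq_flags = np.zeros(self.times.shape, dtype=bool)
        else:
            self.blq_flags = np.asarray(self.blq_flags, dtype=bool)
        if not (len(self.times) == len(self.concentrations) == len(self.blq_flags)):
            raise ValueError("times, concentrations and blq_flags must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("negative concentrations are not allowed")

    def usable_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Apply the BLQ policy and return the (time, concentration) points
        that enter AUC/AUMC and the terminal fit."""
        blq = self.blq_flags
        keep = ~blq
        if keep.any():
            first_quant = int(np.argmax(keep))
            t = []
            c = []
            for i in range(len(self.times)):
                if i < first_quant and blq[i]:
                    t.append(self.times[i])
                    c.append(0.0)  # leading BLQ -> zero
                elif not blq[i]:
                    t.append(self.times[i])
                    c.append(self.concentrations[i])
            return np.asarray(t), np.asarray(c)
        return np.empty(0), np.empty(0)


@dataclass
class TerminalFit:
    """Log-linear elimination-phase regression over a selected window."""

    k_el: float
    intercept_ln: float  # intercept of ln C vs t
    n_points: int
    r_squared: float
    adj_r_squared: float
    window_times: tuple[float, ...]

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.k_el


@dataclass
class NcaResult:
    """All noncompartmental parameters for one subject."""

    subject_id: str
    group: str
    dose_mg_per_kg: float
    body_weight_kg: float
    auc_0_t: float          # µg·h/L
    aumc_0_t: float         # µg·h²/L
    mrt_0_t: float          # h
    k_el: float             # 1/h
    t_half_el: float        # h
    cl_over_f: float        # L/h
    vd_area_over_f: float   # L
    c_max: float            # ng/mL
    t_max: float            # h
    c_last: float           # ng/mL
    t_last: float           # h
    n_terminal_points: int
    terminal_r_squared: float

    def as_dict(self) -> dict:
        return asdict(self)


def auc_linear_trapezoid(profile: ConcentrationTimeProfile) -> float:
    """AUC(0→t_last) by the linear trapezoidal rule (µg·h/L)."""
    t, c = profile.usable_points()
    if len(t) < 2:
        raise ValueError("at least 2 quantifiable points are required for AUC")
    return float(np.trapezoid(c, t))


def aumc_linear_trapezoid(profile: ConcentrationTimeProfile) -> float:
    """AUMC(0→t_last): linear trapezoid applied to t·C(t) (µg·h²/L)."""
    t, c = profile.usable_points()
    if len(t) < 2:
        raise ValueError("at least 2 quantifiable points are required for AUMC")
    return float(np.trapezoid(t * c, t))


def mrt(auc: float, aumc: float) -> float:
    """Mean residence time AUMC/AUC (h)."""
    if auc == 0:
        raise ValueError("AUC must be positive to compute MRT")
    return aumc / auc


def _loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln C on t -> (slope, intercept, r_squared)."""
    res = stats.linregress(t, np.log(c))
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def terminal_slope(
    profile: ConcentrationTimeProfile,
    n_points: int | None = None,
) -> TerminalFit:
    """Elimination rate constant from the terminal log-linear phase.

    Candidate windows are the suffixes (ending at the last quantifiable
    point) of the post-peak points, each with >= 3 points.  The window with
    the largest adjusted r² wins; ties go to the wider window.  Passing
    ``n_points`` fixes the window size instead.
    """
    t, c = profile.usable_points()
    if len(t) == 0:
        raise ValueError("no quantifiable points")
    i_max = int(np.argmax(c))
    t_peak = t[i_max]
    mask = (t > t_peak) & (c > 0)
    if np.any((t > t_peak) & (c <= 0)):
        warnings.warn("non-positive concentrations after t_max excluded from terminal fit")
    tt, cc = t[mask], c[mask]
    if len(tt) < 3:
        raise ValueError("at least 3 quantifiable post-peak points are required")

    if n_points is not None:
        if n_points < 3 or n_points > len(tt):
            raise ValueError(f"n_points must be in [3, {len(tt)}]")
        starts = [len(tt) - n_points]
    else:
        starts = range(len(tt) - 2)

    best: TerminalFit | None = None
    for s in starts:
        wt, wc = tt[s:], cc[s:]
        n = len(wt)
        slope, intercept, r2 = _loglinear(wt, wc)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        cand = TerminalFit(
            k_el=-slope,
            intercept_ln=intercept,
            n_points=n,
            r_squared=r2,
            adj_r_squared=adj,
            window_times=tuple(wt),
        )
        if (
            best is None
            or cand.adj_r_squared > best.adj_r_squared + 1e-12
            or (abs(cand.adj_r_squared - best.adj_r_squared) <= 1e-12
                and cand.n_points > best.n_points)
        ):
            best = cand
    assert best is not None
    return best


def nca_summary(
    profile: ConcentrationTimeProfile,
    n_terminal_points: int | None = None,
) -> NcaResult:
    """Complete noncompartmental parameter set for one profile.

    The total dose is ``dose_mg_per_kg × body_weight_kg × 1000`` µg, so
    Cl_B/F = dose/AUC is in L/h and Vd_area/F = Cl/k_el in L.
    """
    t, c = profile.usable_points()
    if len(t) < 2:
        raise ValueError("profile has too few quantifiable points")
    auc = auc_linear_trapezoid(profile)
    aumc = aumc_linear_trapezoid(profile)
    term = terminal_slope(profile, n_points=n_terminal_points)
    i_max = int(np.argmax(c))  # first occurrence on ties
    quant = c > 0
    i_last = int(np.nonzero(quant)[0][-1]) if quant.any() else len(c) - 1
    dose_ug = profile.dose_mg_per_kg * profile.body_weight_kg * 1000.0
    cl = dose_ug / auc
    return NcaResult(
        subject_id=profile.subject_id,
        group=profile.group,
        dose_mg_per_kg=profile.dose_mg_per_kg,
        body_weight_kg=profile.body_weight_kg,
        auc_0_t=auc,
        aumc_0_t=aumc,
        mrt_0_t=mrt(auc, aumc),
        k_el=term.k_el,
        t_half_el=term.t_half,
        cl_over_f=cl,
        vd_area_over_f=cl / term.k_el,
        c_max=float(c[i_max]),
        t_max=float(t[i_max]),
        c_last=float(c[i_last]),
        t_last=float(t[i_last]),
        n_terminal_points=term.n_points,
        terminal_r_squared=term.r_squared,
    )


# ---------------------------------------------------------------------------
# tabular I/O helpers (profiles.csv schema)

PROFILE_COLUMNS = [
    "group", "subject_id", "dose_mg_per_kg", "body_weight_kg",
    "time_h", "conc_ng_ml", "blq_flag",
]


def profiles_to_frame(profiles: Sequence[ConcentrationTimeProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for t, c, b in zip(p.times, p.concentrations, p.blq_flags):
            rows.append((p.group, p.subject_id, p.dose_mg_per_kg,
                         p.body_weight_kg, t, c, bool(b)))
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def profiles_from_frame(df: pd.DataFrame) -> list[ConcentrationTimeProfile]:
    out = []
    for (group, subject), sub in df.groupby(["group", "subject_id"], sort=True):
        sub = sub.sort_values("time_h")
        out.append(ConcentrationTimeProfile(
            subject_id=str(subject),
            group=str(group),
            dose_mg_per_kg=float(sub["dose_mg_per_kg"].iloc[0]),
            body_weight_kg=float(sub["body_weight_kg"].iloc[0]),
            times=sub["time_h"].to_numpy(),
            concentrations=sub["conc_ng_ml"].to_numpy(),
            blq_flags=sub["blq_flag"].to_numpy(dtype=bool),
        ))
    return out


def group_summary(results: Sequence[NcaResult] | pd.DataFrame) -> pd.DataFrame:
    """Mean ± sample SD of each parameter per dose group."""
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame([r.as_dict() for r in results])
    numeric = results.drop(columns=["subject_id"]).groupby("group", sort=True)
    agg = numeric.agg(["mean", lambda s: s.std(ddof=1)])
    agg.columns = [f"{col}_{'sd' if fn == '<lambda_0>' else fn}" for col, fn in agg.columns]
    return agg.reset_index()
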