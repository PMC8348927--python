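"""Validation statistics for the LC-MS/MS assay.

Each acceptance statistic is an elementary function of replicate peak areas
or back-calculated concentrations:

* precision: CV% = 100·SD/mean of replicate concentrations (sample SD, n−1),
* accuracy: mean of 100·|C_t − C_n|/C_n against the nominal concentration,
* LOD: 3 × SD of the LLOQ replicate concentrations (with an S/N ≥ 3 gate),
* matrix effect: 100 − 100·mean(post-extraction)/mean(neat); positive values
  are ionisation suppression,
* recovery: 100·mean(pre-extraction)/mean(post-extraction),
* carry-over: blank area after a high-QC injection as % of the LLOQ analyte
  area (and of the IS area for the internal standard),
* stability: signed % change of stored vs freshly prepared samples,
* selectivity: no endogenous blank-matrix peak with S/N ≥ 10.

Ratio statistics (matrix effect, recovery, carry-over, stability) divide
arm means rather than averaging per-replicate ratios; the two conventions
agree to first order and the mean-of-arms form is the direct reading of
the acceptance formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from pkbioval.config import Thresholds

__all__ = [
    "precision",
    "accuracy",
    "lod_from_lloq",
    "matrix_effect",
    "recovery",
    "carry_over",
    "stability",
    "selectivity_check",
    "precision_accuracy_table",
    "matrix_effect_table",
    "recovery_table",
    "stability_table",
    "CarryOverResult",
    "StabilityResult",
    "LodResult",
]


def _arr(values) -> np.ndarray:
    return np.asarray(values, dtype=float)


def precision(replicates) -> float:
    """Relative standard deviation (CV%) of replicate concentrations."""
    x = _arr(replicates)
    if len(x) < 2:
        raise ValueError("precision requires at least 2 replicates")
    m = x.mean()
    if m == 0:
        raise ZeroDivisionError("CV undefined: mean concentration is zero")
    return float(100.0 * x.std(ddof=1) / m)


def accuracy(measured, nominal: float) -> float:
    """Mean absolute deviation from nominal, in percent."""
    x = _arr(measured)
    if len(x) < 1:
        raise ValueError("accuracy requires at least 1 replicate")
    if nominal == 0:
        raise ZeroDivisionError("accuracy undefined for zero nominal concentration")
    return float(np.mean(100.0 * np.abs(x - nominal) / nominal))


@dataclass
class LodResult:
    lod: float                # ng/mL, 3 × SD of LLOQ back-calculations
    sd: float                 # ng/mL
    mean_sn: float | None     # mean S/N of the LLOQ replicates, if supplied
    sn_gate_ok: bool | None   # S/N ≥ 3 gate


def lod_from_lloq(lloq_back_calcs, signal_to_noise=None) -> LodResult:
    """Limit of detection as 3 × sample SD of LLOQ replicate concentrations."""
    x = _arr(lloq_back_calcs)
    if len(x) < 2:
        raise ValueError("LOD requires at least 2 LLOQ replicates")
    sd = float(x.std(ddof=1))
    mean_sn = None
    gate = None
    if signal_to_noise is not None:
        mean_sn = float(_arr(signal_to_noise).mean())
        gate = mean_sn >= 3.0
    return LodResult(lod=3.0 * sd, sd=sd, mean_sn=mean_sn, sn_gate_ok=gate)


def matrix_effect(post_extraction, neat) -> float:
    """Ionisation suppression/enhancement in percent.

    ``100 − 100·mean(X_i)/mean(X)`` where X_i are analyte areas spiked into
    extracted matrix and X the areas in neat solvent (the 100% reference).
    Positive = suppression, negative = enhancement.
    """
    xi = _arr(post_extraction)
    x = _arr(neat)
    if x.mean() == 0:
        raise ZeroDivisionError("matrix effect undefined: mean neat area is zero")
    return float(100.0 - 100.0 * xi.mean() / x.mean())


def recovery(pre_extraction, post_extraction) -> float:
    """Total extraction recovery in percent: 100·mean(X_z)/mean(X_i)."""
    xz = _arr(pre_extraction)
    xi = _arr(post_extraction)
    if xi.mean() == 0:
        raise ZeroDivisionError("recovery undefined: mean post-extraction area is zero")
    return float(100.0 * xz.mean() / xi.mean())


@dataclass
class CarryOverResult:
    analyte_pct: float        # blank analyte area as % of the LLOQ area
    is_pct: float | None      # blank IS area as % of the IS reference area
    analyte_ok: bool
    is_ok: bool | None
    passed: bool

    def to_dict(self) -> dict:
        return asdict(self)


def carry_over(
    blank_areas,
    lloq_mean_area: float,
    is_blank_areas=None,
    is_reference_area: float | None = None,
    thresholds: Thresholds | None = None,
) -> CarryOverResult:
    """Carry-over of analyte (vs LLOQ area) and internal standard (vs its own
    reference area) in blanks injected after high-concentration samples."""
    thr = thresholds or Thresholds()
    if lloq_mean_area == 0:
        raise ZeroDivisionError("carry-over undefined: LLOQ mean area is zero")
    analyte_pct = float(100.0 * _arr(blank_areas).mean() / lloq_mean_area)
    analyte_ok = analyte_pct <= thr.carryover_analyte_pct
    is_pct = None
    is_ok = None
    if is_blank_areas is not None and is_reference_area:
        is_pct = float(100.0 * _arr(is_blank_areas).mean() / is_reference_area)
        is_ok = is_pct <= thr.carryover_is_pct
    passed = bool(analyte_ok and (is_ok is not False))
    return CarryOverResult(
        analyte_pct=analyte_pct, is_pct=is_pct,
        analyte_ok=bool(analyte_ok), is_ok=is_ok, passed=passed,
    )


@dataclass
class StabilityResult:
    change_pct: float  # signed: negative = decrease of the stored samples
    passed: bool

    def to_dict(self) -> dict:
        return asdict(self)


def stability(stored, fresh, thresholds: Thresholds | None = None) -> StabilityResult:
    """Signed percent change of stored (S_t) vs fresh (S_0) samples:
    ``100·mean(S_t)/mean(S_0) − 100``; acceptable within ±15%."""
    thr = thresholds or Thresholds()
    s0 = _arr(fresh)
    if s0.mean() == 0:
        raise ZeroDivisionError("stability undefined: mean fresh area is zero")
    change = float(100.0 * _arr(stored).mean() / s0.mean() - 100.0)
    return StabilityResult(change_pct=change, passed=bool(abs(change) <= thr.stability_pct))


def selectivity_check(
    blanks: pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Per-matrix maximum blank S/N with a flag at the S/N ≥ 10 limit.

    Expects columns ``matrix`` and ``signal_to_noise``.
    """
    thr = thresholds or Thresholds()
    out = (
        blanks.groupby("matrix", sort=True)["signal_to_noise"]
        .max()
        .rename("max_sn")
        .reset_index()
    )
    out["flagged"] = out["max_sn"] >= thr.selectivity_sn
    return out


# ---------------------------------------------------------------------------
# tabular wrappers over the tidy tables produced by pkbioval.simulate


def precision_accuracy_table(df: pd.DataFrame) -> pd.DataFrame:
    """Intra-day (per level, day) and inter-day (per level, pooled) precision
    and accuracy from a replicate table with columns level, nominal_conc,
    day, replicate, measured_conc."""
    rows = []
    for (level, day), sub in df.groupby(["level", "day"], sort=True):
        nominal = float(sub["nominal_conc"].iloc[0])
        rows.append({
            "level": level, "scope": "intra_day", "day": day,
            "precision_pct": precision(sub["measured_conc"]),
            "accuracy_pct": accuracy(sub["measured_conc"], nominal),
            "n": len(sub),
        })
    for level, sub in df.groupby("level", sort=True):
        nominal = float(sub["nominal_conc"].iloc[0])
        rows.append({
            "level": level, "scope": "inter_day", "day": None,
            "precision_pct": precision(sub["measured_conc"]),
            "accuracy_pct": accuracy(sub["measured_conc"], nominal),
            "n": len(sub),
        })
    return pd.DataFrame(rows)


def _two_arm_table(
    df: pd.DataFrame,
    stat,
    numerator_arm: str,
    denominator_arm: str,
    value_name: str,
) -> pd.DataFrame:
    rows = []
    keys = [k for k in ("matrix", "level") if k in df.columns]
    for key, sub in df.groupby(keys, sort=True):
        num = sub.loc[sub["arm"] == numerator_arm, "area"]
        den = sub.loc[sub["arm"] == denominator_arm, "area"]
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec[value_name] = stat(num, den)
        rows.append(rec)
    return pd.DataFrame(rows)


def matrix_effect_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per (matrix, level) matrix effect from a two-arm area table."""
    return _two_arm_table(df, matrix_effect, "post_extraction", "neat", "matrix_effect_pct")


def recovery_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per (matrix, level) total recovery from a two-arm area table."""
    return _two_arm_table(df, recovery, "pre_extraction", "post_extraction", "recovery_pct")


def stability_table(df: pd.DataFrame, thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Signed stability change per (condition, period, level)."""
    rows = []
    for (condition, period, level), sub in df.groupby(
        ["condition", "period_h", "level"], sort=True
    ):
        stored = sub.loc[sub["arm"] == "stored", "area"]
        fresh = sub.loc[sub["arm"] == "fresh", "area"]
        res = stability(stored, fresh, thresholds)
        rows.append({
            "condition": condition, "period_h": period, "level": level,
            "change_pct": res.change_pct, "passed": res.passed,
        })
    return pd.DataFrame(rows)
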