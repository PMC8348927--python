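"""Seeded synthetic-data generator for every input the pipeline consumes.

Emulates the pilot study design: three groups of pigs dosed orally at
20/40/80 mg/kg and sampled hourly over 0--11 h, an 11-point calibration
run with blank and zero samples, and the validation sample sets (precision/
accuracy replicates, matrix-effect and recovery arms, carry-over pairs,
stability pairs, selectivity blanks).

Noise model: multiplicative lognormal with a prescribed coefficient of
variation.  Chromatographic peak areas and plasma concentrations are
positive with roughly proportional scatter, which the lognormal captures
while a plain additive Gaussian would not.  The lognormal is parameterised
to have mean exactly 1, so injected truths are unbiased targets for the
downstream estimators.

Every function takes all of its randomness from the ``SimulationConfig``
seed; a fixed config yields byte-identical output tables.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pkbioval import bateman
from pkbioval.config import (
    QC_LEVELS,
    STABILITY_CONDITIONS,
    SimulationConfig,
)
from pkbioval.nca import ConcentrationTimeProfile

__all__ = [
    "simulate_profiles",
    "simulate_calibration_run",
    "simulate_validation_sets",
]

# distinct offsets decouple the RNG streams of the three generators, so the
# calibration draw count cannot perturb the profile draws for the same seed
_PROFILE_STREAM = 0
_CALIBRATION_STREAM = 1
_VALIDATION_STREAM = 2


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def _truncated_relative_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """1 + eps with eps ~ Normal(0, cv), redrawn while the factor is <= 0."""
    if cv == 0:
        return np.ones(size)
    eps = rng.normal(0.0, cv, size=size)
    bad = eps <= -1.0
    while bad.any():  # vanishingly rare for cv << 1, but areas must stay positive
        eps[bad] = rng.normal(0.0, cv, size=int(bad.sum()))
        bad = eps <= -1.0
    return 1.0 + eps


# ---------------------------------------------------------------------------
# concentration–time profiles


def simulate_profiles(config: SimulationConfig) -> list[ConcentrationTimeProfile]:
    """Simulate one Bateman concentration--time profile per subject.

    Group g uses rates ``(k_ab, k_el)`` and a noise-free peak concentration
    ``cmax_scale`` from ``config.pk_params_per_group[g]``.  Concentrations
    are perturbed by mean-1 multiplicative lognormal noise with CV
    ``config.residual_cv``; the pre-dose sample at t = 0 stays exactly 0.
    Samples below ``lloq_ng_ml`` are flagged BLQ but keep their value.
    """
    rng = _rng(config, _PROFILE_STREAM)
    times = np.asarray(config.sampling_times_h, dtype=float)
    profiles: list[ConcentrationTimeProfile] = []
    for g, (dose, (k_ab, k_el, cmax_scale)) in enumerate(
        zip(config.doses, config.pk_params_per_group), start=1
    ):
        if abs(k_ab - k_el) < bateman.DEGENERATE_TOL:
            warnings.warn(
                f"group {g}: k_ab == k_el, using the degenerate t*exp(-k*t) limit form"
            )
        amplitude = bateman.amplitude_for_cmax(cmax_scale, k_ab, k_el)
        for s in range(1, config.n_subjects_per_group + 1):
            weight = rng.normal(config.body_weight_mean_kg, config.body_weight_sd_kg)
            weight = float(max(weight, 1.0))
            clean = bateman.bateman(times, amplitude, k_ab, k_el, t_lag=config.t_lag_h)
            noise = _lognormal_factors(rng, config.residual_cv, times.shape)
            conc = np.where(times > config.t_lag_h, clean * noise, 0.0)
            conc[times == 0] = 0.0
            blq = conc < config.lloq_ng_ml
            profiles.append(ConcentrationTimeProfile(
                subject_id=f"pig_{g}_{s}",
                group=f"group{g}_{dose:g}mgkg",
                dose_mg_per_kg=float(dose),
                body_weight_kg=round(weight, 2),
                times=times.copy(),
                concentrations=conc,
                blq_flags=blq,
            ))
    return profiles


# ---------------------------------------------------------------------------
# calibration runs


def simulate_calibration_run(
    config: SimulationConfig,
    n_runs: int = 1,
    cv: float = 0.03,
    is_cv: float = 0.02,
) -> pd.DataFrame:
    """Simulate calibration runs as a tidy table.

    Each run covers every level in ``config.calibration_levels_ng_ml`` with
    analyte area = ``area_per_conc × nominal × (1 + eps)``, eps truncated
    Normal(0, cv), plus one blank record (no analytes) and one zero record
    (internal standard only).

    Columns: run_id, level_ng_ml, analyte_area, is_area, sample_type.
    """
    rng = _rng(config, _CALIBRATION_STREAM)
    rows = []
    levels = np.asarray(config.calibration_levels_ng_ml, dtype=float)
    for run in range(1, n_runs + 1):
        rows.append((run, 0.0, 0.0, 0.0, "blank"))
        is_zero = config.is_area_mean * _truncated_relative_noise(rng, is_cv, ())
        rows.append((run, 0.0, 0.0, float(is_zero), "zero"))
        analyte = config.area_per_conc * levels * _truncated_relative_noise(rng, cv, levels.shape)
        is_areas = config.is_area_mean * _truncated_relative_noise(rng, is_cv, levels.shape)
        for lvl, a, i in zip(levels, analyte, is_areas):
            rows.append((run, float(lvl), float(a), float(i), "standard"))
    return pd.DataFrame(
        rows, columns=["run_id", "level_ng_ml", "analyte_area", "is_area", "sample_type"]
    )


# ---------------------------------------------------------------------------
# validation sample sets


def simulate_validation_sets(
    config: SimulationConfig,
    *,
    cv: float = 0.03,
    matrix_suppression: float | Mapping[str, float] = 0.076,
    recovery: float = 0.8775,
    carryover_fraction: float = 0.047,
    is_carryover_fraction: float = 0.0,
    stability_change: float | Mapping[tuple[str, float], float] = -0.05,
    matrices: Sequence[str] = ("pig",),
    n_replicates: int = 6,
    n_days: int = 3,
    selectivity_sn_range: tuple[float, float] = (0.0, 8.0),
) -> dict[str, pd.DataFrame]:
    """Generate the full validation bundle with injectable ground truths.

    The injected effects are exact multiplicative truths — e.g. a
    ``matrix_suppression`` of 0.08 shrinks every post-extraction area to
    92% of the matching neat mean — so every downstream estimator can be
    checked against a known answer.  ``matrix_suppression`` may be a
    mapping from matrix name to per-matrix truth.

    Returns a dict of tidy tables keyed by
    ``precision_accuracy | matrix_effect | recovery | carry_over |
    stability | selectivity``.
    """
    rng = _rng(config, _VALIDATION_STREAM)
    reps = range(1, n_replicates + 1)

    # precision / accuracy: n_days × n_replicates at LLOQ + 4 QC levels
    pa_rows = []
    for level, nominal in QC_LEVELS.items():
        level_cv = config.qc_cv.get(level, cv)
        for day in range(1, n_days + 1):
            measured = nominal * _truncated_relative_noise(rng, level_cv, n_replicates)
            for rep, m in zip(reps, measured):
                pa_rows.append(("precision_accuracy", level, nominal, day, rep, float(m)))
    precision_accuracy = pd.DataFrame(
        pa_rows, columns=["test", "level", "nominal_conc", "day", "replicate", "measured_conc"]
    )

    qc_only = [lvl for lvl in QC_LEVELS if lvl != "LLOQ"]

    # matrix effect: neat vs post-extraction arms, per matrix and QC level
    me_rows = []
    for matrix in matrices:
        supp = (
            matrix_suppression[matrix]
            if isinstance(matrix_suppression, Mapping)
            else matrix_suppression
        )
        for level in qc_only:
            neat_mean = config.area_per_conc * QC_LEVELS[level]
            neat = neat_mean * _truncated_relative_noise(rng, cv, n_replicates)
            post = neat_mean * (1.0 - supp) * _truncated_relative_noise(rng, cv, n_replicates)
            for rep, a in zip(reps, neat):
                me_rows.append(("matrix_effect", matrix, level, rep, "neat", float(a)))
            for rep, a in zip(reps, post):
                me_rows.append(("matrix_effect", matrix, level, rep, "post_extraction", float(a)))
    matrix_effect = pd.DataFrame(
        me_rows, columns=["test", "matrix", "level", "replicate", "arm", "area"]
    )

    # recovery: post-extraction (100% reference) vs pre-extraction arms
    rec_rows = []
    for matrix in matrices:
        for level in qc_only:
            base = config.area_per_conc * QC_LEVELS[level]
            post = base * _truncated_relative_noise(rng, cv, n_replicates)
            pre = base * recovery * _truncated_relative_noise(rng, cv, n_replicates)
            for rep, a in zip(reps, post):
                rec_rows.append(("recovery", matrix, level, rep, "post_extraction", float(a)))
            for rep, a in zip(reps, pre):
                rec_rows.append(("recovery", matrix, level, rep, "pre_extraction", float(a)))
    recovery_tbl = pd.DataFrame(
        rec_rows, columns=["test", "matrix", "level", "replicate", "arm", "area"]
    )

    # carry-over: HQC injections, trailing blanks, and LLOQ reference areas
    lloq_area = config.area_per_conc * config.lloq_ng_ml
    hqc_area = config.area_per_conc * QC_LEVELS["HQC"]
    co_rows = []
    hqc = hqc_area * _truncated_relative_noise(rng, cv, n_replicates)
    blanks = carryover_fraction * lloq_area * _truncated_relative_noise(rng, cv, n_replicates)
    lloqs = lloq_area * _truncated_relative_noise(rng, cv, n_replicates)
    is_blanks = is_carryover_fraction * config.is_area_mean * np.ones(n_replicates)
    for rep in reps:
        i = rep - 1
        co_rows.append(("carry_over", "hqc", rep, float(hqc[i]), config.is_area_mean))
        co_rows.append(("carry_over", "blank", rep, float(blanks[i]), float(is_blanks[i])))
        co_rows.append(("carry_over", "lloq", rep, float(lloqs[i]), config.is_area_mean))
    carry_over = pd.DataFrame(
        co_rows, columns=["test", "sample", "replicate", "analyte_area", "is_area"]
    )

    # stability: fresh vs stored arms per condition, period and QC level
    st_rows = []
    for condition, periods in STABILITY_CONDITIONS:
        for period in periods:
            change = (
                stability_change.get((condition, period), 0.0)
                if isinstance(stability_change, Mapping)
                else stability_change
            )
            for level in qc_only:
                base = config.area_per_conc * QC_LEVELS[level]
                fresh = base * _truncated_relative_noise(rng, cv, n_replicates)
                stored = base * (1.0 + change) * _truncated_relative_noise(rng, cv, n_replicates)
                for rep, a in zip(reps, fresh):
                    st_rows.append(("stability", condition, period, level, rep, "fresh", float(a)))
                for rep, a in zip(reps, stored):
                    st_rows.append(("stability", condition, period, level, rep, "stored", float(a)))
    stability = pd.DataFrame(
        st_rows,
        columns=["test", "condition", "period_h", "level", "replicate", "arm", "area"],
    )

    # selectivity: blank-matrix injections with small endogenous S/N values
    sel_rows = []
    lo, hi = selectivity_sn_range
    for matrix in matrices:
        sn = rng.uniform(lo, hi, size=n_replicates)
        for rep, s in zip(reps, sn):
            sel_rows.append(("selectivity", matrix, rep, float(s)))
    selectivity = pd.DataFrame(
        sel_rows, columns=["test", "matrix", "replicate", "signal_to_noise"]
    )

    return {
        "precision_accuracy": precision_accuracy,
        "matrix_effect": matrix_effect,
        "recovery": recovery_tbl,
        "carry_over": carry_over,
        "stability": stability,
        "selectivity": selectivity,
    }
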