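"""Configuration objects for simulation and for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: QC level labels in increasing concentration order, with their nominal
#: concentrations (ng/mL): LLOQ 10, low 50, intermediate 500, medium 5000,
#: high 10,000.
QC_LEVELS: dict[str, float] = {
    "LLOQ": 10.0,
    "LQC": 50.0,
    "IQC": 500.0,
    "MQC": 5000.0,
    "HQC": 10000.0,
}

#: default per-level coefficient of variation of back-calculated QC
#: concentrations; larger near the quantitation limit, a few percent at the
#: top of the range, consistent with routine LC-MS/MS performance
DEFAULT_QC_CV: dict[str, float] = {
    "LLOQ": 0.12,
    "LQC": 0.07,
    "IQC": 0.045,
    "MQC": 0.03,
    "HQC": 0.03,
}

#: stability study arms: (condition label, storage periods in hours)
STABILITY_CONDITIONS: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("stock_2C", (120.0,)),
    ("working_standard_2C", (72.0, 120.0)),
    ("autosampler_4C", (24.0, 48.0)),
    ("freeze_thaw", (24.0, 48.0, 96.0, 1680.0)),
    ("processing_temperature_21C", (3.0,)),
)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic-data generator.

    The defaults encode the pilot study design: three groups of three pigs
    (body weight 58.3 ± 4.09 kg) dosed orally at 20/40/80 mg/kg and sampled
    hourly from 0 to 11 h, an 11-point calibration from 10 to 10,000 ng/mL,
    and QC levels at 10/50/500/5000/10,000 ng/mL.

    ``pk_params_per_group`` holds one ``(k_ab, k_el, cmax_scale)`` triple per
    dose group; ``cmax_scale`` is the noise-free peak concentration (ng/mL)
    of the simulated Bateman curve, so group peak heights can be pinned
    directly to plausible values.
    """

    seed: int = 0
    n_subjects_per_group: int = 3
    doses: tuple[float, ...] = (20.0, 40.0, 80.0)
    body_weight_mean_kg: float = 58.3
    body_weight_sd_kg: float = 4.09
    sampling_times_h: tuple[float, ...] = tuple(float(t) for t in range(12))
    pk_params_per_group: tuple[tuple[float, float, float], ...] = (
        (0.27, 0.49, 406.73),
        (0.81, 0.62, 2079.87),
        (1.96, 0.81, 4272.27),
    )
    residual_cv: float = 0.10
    calibration_levels_ng_ml: tuple[float, ...] = (
        10.0, 25.0, 50.0, 100.0, 250.0, 500.0,
        1000.0, 2500.0, 5000.0, 7500.0, 10000.0,
    )
    qc_levels_ng_ml: tuple[float, ...] = (10.0, 50.0, 500.0, 5000.0, 10000.0)
    qc_cv: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_QC_CV))
    area_per_conc: float = 13.374
    is_area_mean: float = 24601.28
    lloq_ng_ml: float = 10.0
    t_lag_h: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be strictly positive")
        if len(self.doses) != len(self.pk_params_per_group):
            raise ValueError("one (k_ab, k_el, cmax_scale) triple is required per dose")
        for k_ab, k_el, scale in self.pk_params_per_group:
            if k_ab <= 0 or k_el <= 0 or scale <= 0:
                raise ValueError("rate constants and concentration scales must be > 0")
        if not 0 <= self.residual_cv < 1:
            raise ValueError("residual_cv must lie in [0, 1)")
        times = tuple(self.sampling_times_h)
        if times[0] != 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sampling times must start at 0 and be strictly increasing")
        if any(c <= 0 for c in self.calibration_levels_ng_ml):
            raise ValueError("calibration levels must be positive")
        if self.area_per_conc <= 0:
            raise ValueError("area_per_conc must be positive")
        if self.body_weight_mean_kg <= 0 or self.body_weight_sd_kg < 0:
            raise ValueError("invalid body-weight parameters")
        if self.lloq_ng_ml <= 0:
            raise ValueError("lloq_ng_ml must be positive")


@dataclass
class Thresholds:
    """Acceptance thresholds applied throughout the validation reports.

    Defaults are the standard bioanalytical acceptance criteria: ±15% for
    precision, accuracy, matrix effect and stability; ≤20% relative
    residuals with at least 75% (and no fewer than 6) calibration points
    within ±15%; r² ≥ 0.99; carry-over ≤20% of the LLOQ analyte area and
    ≤5% of the internal-standard area.
    """

    precision_pct: float = 15.0
    accuracy_pct: float = 15.0
    point_deviation_pct: float = 15.0
    relative_residual_pct: float = 20.0
    sd_relative_residuals: float = 0.1
    r_squared: float = 0.99
    matrix_effect_pct: float = 15.0
    recovery_rsd_pct: float = 15.0
    carryover_analyte_pct: float = 20.0
    carryover_is_pct: float = 5.0
    stability_pct: float = 15.0
    selectivity_sn: float = 10.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    profiles_csv: str | None = None  # use existing data instead of simulating
    calibration_csv: str | None = None
    # calibration weighting (none | 1/x | 1/x2): the pipeline defaults to
    # 1/x2 because the 10-10,000 ng/mL range spans three decades and an
    # unweighted fit sacrifices the bottom standards to the top ones
    weighting: str = "1/x2"
    report_decimals: int = 2
    lambda_z_points: int | None = None  # fix the terminal window size

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**_tupleize(raw.pop("simulation", {})))
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(simulation=sim, thresholds=thr, **raw)


def _tupleize(block: dict) -> dict:
    """YAML lists -> tuples where SimulationConfig expects tuples."""
    out = dict(block)
    for key in ("doses", "sampling_times_h", "calibration_levels_ng_ml", "qc_levels_ng_ml"):
        if key in out:
            out[key] = tuple(out[key])
    if "pk_params_per_group" in out:
        out["pk_params_per_group"] = tuple(tuple(t) for t in out["pk_params_per_group"])
    return out
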