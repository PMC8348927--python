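"""End-to-end pipeline: simulate → calibrate → validate → NCA → absorption
fit → dose proportionality, with machine-readable reports.

Every stage logs its threshold decisions to stderr and contributes to a
single report dictionary; artifacts are written as CSV/JSON with stable
formatting so that a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from pkbioval import calibration as cal
from pkbioval import compartmental, doseprop, nca, simulate, validation
from pkbioval.config import PipelineConfig

__all__ = ["run_pipeline", "render_table5", "PipelineError"]

log = logging.getLogger("pkbioval")

#: parameter rows of the group PK summary, in report order, with units
TABLE5_ROWS: tuple[tuple[str, str], ...] = (
    ("auc_0_t", "µg·h/L"),
    ("aumc_0_t", "µg·h²/L"),
    ("c_max", "ng/mL"),
    ("t_max", "h"),
    ("c_last", "ng/mL"),
    ("t_last", "h"),
    ("k_el", "1/h"),
    ("t_half_el", "h"),
    ("mrt_0_t", "h"),
    ("cl_over_f", "L/h"),
    ("vd_area_over_f", "L"),
    ("k_ab", "1/h"),
    ("t_half_ab", "h"),
    ("mat", "h"),
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", stage, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", stage, dt, exc)
            return False

    return _Timer()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write all artifacts under ``outdir``.

    Returns the full report dictionary (also written as ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.simulation.seed}

    # --- data: simulate or load -------------------------------------------
    with _timed("data"):
        if config.profiles_csv is not None:
            ppath = Path(config.profiles_csv)
            if not ppath.exists():
                raise PipelineError("data", f"profiles path does not exist: {ppath}")
            profiles_df = pd.read_csv(ppath)
            profiles = nca.profiles_from_frame(profiles_df)
        else:
            profiles = simulate.simulate_profiles(config.simulation)
            profiles_df = nca.profiles_to_frame(profiles)
        if config.calibration_csv is not None:
            cpath = Path(config.calibration_csv)
            if not cpath.exists():
                raise PipelineError("data", f"calibration path does not exist: {cpath}")
            calib_df = pd.read_csv(cpath)
        else:
            calib_df = simulate.simulate_calibration_run(config.simulation, n_runs=4)
        vsets = simulate.simulate_validation_sets(config.simulation)
        profiles_df.to_csv(outdir / "profiles.csv", index=False)
        calib_df.to_csv(outdir / "calibration.csv", index=False)
        for name, frame in vsets.items():
            frame.to_csv(outdir / f"validation_{name}.csv", index=False)

    # --- calibration ------------------------------------------------------
    with _timed("calibration"):
        lin_reports = {}
        for run_id, sub in calib_df.groupby("run_id"):
            curve = cal.fit_calibration(
                cal.standards_from_frame(sub), weighting=config.weighting
            )
            rep = cal.evaluate_linearity(curve, config.thresholds)
            log.info(
                "calibration run %s: r^2=%.5f passed=%s", run_id, rep.r_squared, rep.passed
            )
            lin_reports[str(run_id)] = {
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r": curve.r,
                "weighting": curve.weighting,
                **rep.to_dict(),
            }
        report["linearity"] = lin_reports
        _write_json(outdir / "linearity_report.json", lin_reports)

    # --- validation statistics -------------------------------------------
    with _timed("validation"):
        thr = config.thresholds
        pa = validation.precision_accuracy_table(vsets["precision_accuracy"])
        pa["precision_ok"] = pa["precision_pct"] <= thr.precision_pct
        pa["accuracy_ok"] = pa["accuracy_pct"] <= thr.accuracy_pct

        lloq = vsets["precision_accuracy"].query("level == 'LLOQ'")
        lod = validation.lod_from_lloq(lloq["measured_conc"])

        me = validation.matrix_effect_table(vsets["matrix_effect"])
        me["ok"] = me["matrix_effect_pct"].abs() <= thr.matrix_effect_pct
        rec = validation.recovery_table(vsets["recovery"])

        co_df = vsets["carry_over"]
        co = validation.carry_over(
            blank_areas=co_df.query("sample == 'blank'")["analyte_area"],
            lloq_mean_area=float(co_df.query("sample == 'lloq'")["analyte_area"].mean()),
            is_blank_areas=co_df.query("sample == 'blank'")["is_area"],
            is_reference_area=config.simulation.is_area_mean,
            thresholds=thr,
        )
        stab = validation.stability_table(vsets["stability"], thr)
        sel = validation.selectivity_check(vsets["selectivity"], thr)

        report["validation"] = {
            "precision_accuracy": pa.to_dict(orient="records"),
            "lod_ng_ml": lod.lod,
            "lloq_sd_ng_ml": lod.sd,
            "matrix_effect": me.to_dict(orient="records"),
            "matrix_effect_pooled_pct": float(me["matrix_effect_pct"].mean()),
            "recovery": rec.to_dict(orient="records"),
            "recovery_pooled_pct": float(rec["recovery_pct"].mean()),
            "carry_over": co.to_dict(),
            "stability": stab.to_dict(orient="records"),
            "selectivity": sel.to_dict(orient="records"),
        }
        _write_json(outdir / "validation_report.json", report["validation"])

    # --- noncompartmental analysis ---------------------------------------
    with _timed("nca"):
        try:
            results = [
                nca.nca_summary(p, n_terminal_points=config.lambda_z_points)
                for p in profiles
            ]
        except ValueError as err:
            raise PipelineError("nca", str(err)) from err
        nca_df = pd.DataFrame([r.as_dict() for r in results])
        nca_df.to_csv(outdir / "nca_results.csv", index=False)

    # --- one-compartment absorption analysis ------------------------------
    with _timed("compartmental"):
        fits = []
        for p in profiles:
            try:
                fits.append(compartmental.fit_one_compartment(p))
            except (ValueError, RuntimeError) as err:
                raise PipelineError("compartmental", f"{p.subject_id}: {err}") from err
        comp_df = pd.DataFrame([f.as_dict() for f in fits])
        comp_df.to_csv(outdir / "compartmental_results.csv", index=False)

    # --- group summary -----------------------------------------------------
    with _timed("summary"):
        merged = nca_df.merge(
            comp_df[["subject_id", "k_ab", "t_half_ab", "mat"]], on="subject_id"
        )
        merged.to_csv(outdir / "subject_results.csv", index=False)
        summary = nca.group_summary(
            merged.drop(columns=["n_terminal_points", "terminal_r_squared"])
        )
        summary.to_csv(outdir / "group_summary.csv", index=False)
        report["group_summary"] = summary.to_dict(orient="records")
        table = render_table5(summary, decimals=config.report_decimals)
        (outdir / "pk_summary_table.txt").write_text(table)

    # --- dose proportionality ---------------------------------------------
    with _timed("dose_proportionality"):
        doses = summary["dose_mg_per_kg_mean"].to_numpy()
        power = doseprop.fit_power(doses, summary["auc_0_t_mean"].to_numpy())
        logfit = doseprop.fit_logarithmic(doses, summary["c_max_mean"].to_numpy())
        report["dose_proportionality"] = {
            "auc_power": power.to_dict(),
            "cmax_logarithmic": logfit.to_dict(),
        }
        _write_json(outdir / "dose_proportionality.json", report["dose_proportionality"])
        log.info(
            "dose proportionality: AUC ~ %.4f * dose^%.4f (r^2=%.5f)",
            power.coefficient, power.exponent_or_intercept, power.r_squared,
        )

    _write_json(outdir / "report.json", report)
    return report


def render_table5(summary: pd.DataFrame, decimals: int = 2) -> str:
    """Render the group PK summary as a mean ± SD text table.

    One row per parameter, one column per dose group; round-half-even
    display at ``decimals`` places (full precision stays in the CSV/JSON
    artifacts).
    """
    groups = list(summary["group"])
    header = ["Parameter (unit)"] + [
        f"{g} ({d:g} mg/kg)"
        for g, d in zip(groups, summary["dose_mg_per_kg_mean"])
    ]
    lines = ["\t".join(header)]
    for param, unit in TABLE5_ROWS:
        cells = [f"{param} ({unit})"]
        for _, row in summary.iterrows():
            mean = row.get(f"{param}_mean", np.nan)
            sd = row.get(f"{param}_sd", np.nan)
            if pd.isna(sd):
                cells.append(f"{mean:.{decimals}f}")
            else:
                cells.append(f"{mean:.{decimals}f} ± {sd:.{decimals}f}")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
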