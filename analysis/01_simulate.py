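"""Generate the synthetic study dataset.

Emulates the pilot design — three groups of three pigs dosed orally at
20/40/80 mg/kg, sampled hourly 0--11 h — plus the full bench-validation
sample sets (4 calibration runs, 3x6 precision/accuracy replicates per
level, matrix-effect/recovery/carry-over/stability arms).  Everything is
seeded and lands under results/data/.
"""

from pathlib import Path

from pkbioval import nca, simulate
from pkbioval.config import SimulationConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)

    profiles = simulate.simulate_profiles(cfg)
    frame = nca.profiles_to_frame(profiles)
    frame.to_csv(OUT / "profiles.csv", index=False)
    n_blq = int(frame["blq_flag"].sum())
    print(f"profiles: {len(profiles)} subjects x {len(cfg.sampling_times_h)} samples, "
          f"{n_blq} below the 10 ng/mL LLOQ")

    calib = simulate.simulate_calibration_run(cfg, n_runs=4)
    calib.to_csv(OUT / "calibration.csv", index=False)
    print(f"calibration: 4 runs x {len(cfg.calibration_levels_ng_ml)} levels "
          f"(plus blank and zero records)")

    for name, table in simulate.simulate_validation_sets(cfg).items():
        table.to_csv(OUT / f"validation_{name}.csv", index=False)
        print(f"validation {name}: {len(table)} rows")


if __name__ == "__main__":
    main()
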