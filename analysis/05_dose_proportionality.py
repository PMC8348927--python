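"""Dose-proportionality regressions.

Fits the power model (AUC vs dose, log--log OLS) and the logarithmic model
(C_max vs dose) twice: once on the synthetic study's group means and once
on the published group means of the original pilot study (a desk check that
the printed dose-proportionality equations follow from the printed group
means).  Writes results/pk/dose_proportionality.json.
"""

import json
from pathlib import Path

import pandas as pd

from pkbioval import doseprop
from pkbioval.datasets import reference_pig_pk_means

OUT = Path(__file__).resolve().parent.parent / "results" / "pk"


def fit_pair(doses, auc, cmax) -> dict:
    power = doseprop.fit_power(doses, auc)
    logfit = doseprop.fit_logarithmic(doses, cmax)
    return {"auc_power": power.to_dict(), "cmax_logarithmic": logfit.to_dict()}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = pd.read_csv(OUT / "group_summary.csv")
    synthetic = fit_pair(
        summary["dose_mg_per_kg_mean"], summary["auc_0_t_mean"], summary["c_max_mean"]
    )
    ref = reference_pig_pk_means()
    published = fit_pair(ref["dose_mg_per_kg"], ref["auc_0_t"], ref["c_max"])

    report = {"synthetic_study": synthetic, "published_group_means": published}
    (OUT / "dose_proportionality.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )

    for name, block in report.items():
        p = block["auc_power"]
        l = block["cmax_logarithmic"]
        print(f"{name}: AUC = {p['coefficient']:.4f} · dose^{p['exponent_or_intercept']:.4f} "
              f"(r² = {p['r_squared']:.5f}); "
              f"C_max = {l['coefficient']:.4f}·ln(dose) {l['exponent_or_intercept']:+.4f} "
              f"(r² = {l['r_squared']:.3f})")


if __name__ == "__main__":
    main()
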