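"""Published reference values used as inputs to desk-check computations.

These are group-level summary values from a published pilot oral-dosing
study of 4-acetamidobenzoic acid in pigs (three groups of three animals at
20/40/80 mg/kg, sampled hourly over 0--11 h) and its accompanying LC-MS/MS
validation report.  Only printed summary numbers are available — the
underlying animal-level data were never deposited — so these tables serve
as *inputs* to arithmetic cross-checks (parameter identities, the
dose-proportionality regressions on group means), not as data the package
claims to reproduce at the subject level.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_pig_pk_means", "REFERENCE_VALIDATION"]


def reference_pig_pk_means() -> pd.DataFrame:
    """Group-mean noncompartmental and absorption parameters per dose.

    Columns: dose (mg/kg), auc_0_t (µg·h/L), aumc_0_t (µg·h²/L),
    c_max (ng/mL), k_el and k_ab (1/h), t_half_el and t_half_ab (h),
    mrt_0_t (h), cl_over_f (L/h), vd_area_over_f (L), mat (h).
    """
    return pd.DataFrame({
        "dose_mg_per_kg": [20.0, 40.0, 80.0],
        "auc_0_t": [878.74, 3402.52, 12868.1],
        "aumc_0_t": [5935.97, 19015.92, 88002.9],
        "c_max": [406.73, 2079.87, 4272.27],
        "t_max": [6.0, 5.0, 6.0],
        "c_last": [12.32, 10.21, 68.11],
        "t_last": [11.0, 11.0, 11.0],
        "k_el": [0.49, 0.62, 0.81],
        "t_half_el": [1.42, 1.12, 0.85],
        "mrt_0_t": [6.76, 5.59, 6.84],
        "cl_over_f": [682.8, 352.68, 186.51],
        "vd_area_over_f": [1399.78, 568.33, 229.56],
        "k_ab": [0.27, 0.81, 1.96],
        "t_half_ab": [2.57, 0.86, 0.36],
        "mat": [3.70, 1.23, 0.51],
    })


#: printed summary numbers from the validation report of the same assay:
#: the LLOQ replicate SD (ng/mL) behind the LOD, the mean LLOQ analyte peak
#: area, and the mean blank analyte area observed after high-QC injections
REFERENCE_VALIDATION: dict[str, float] = {
    "lloq_nominal_ng_ml": 10.0,
    "lloq_sd_ng_ml": 1.09,
    "lloq_mean_area": 133.74,
    "carryover_blank_mean_area": 6.27,
    "hqc_mean_area": 193810.4,
    "is_mean_area": 24601.28,
}
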