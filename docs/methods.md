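# Methods

## Scope and data model

`pkbioval` covers the computational side of validating an LC-MS/MS plasma
assay for 4-acetamidobenzoic acid and analysing a pilot oral-dosing study
in pigs. Inputs begin at integrated peak areas and back-calculated
concentrations; peak integration, S/N estimation from chromatograms and
instrument-file parsing are out of scope. Because the original
animal-level data were never deposited, the package pairs every estimator
with a seeded generator that emulates the study design, and ships the
published group-mean parameters (`pkbioval.datasets`) as inputs for
arithmetic desk checks only.

## Synthetic-data generator

**Study design emulated.** Three dose groups (20/40/80 mg/kg) of three
subjects with body weight ~ Normal(58.3, 4.09²) kg, sampled at
0, 1, …, 11 h; an 11-point calibration from 10 to 10,000 ng/mL with blank
and zero records; QC levels at 10 (LLOQ), 50, 500, 5000 and 10,000 ng/mL;
validation arms of six replicates (three days for precision/accuracy).

**Concentration model.** Each profile follows the one-compartment
first-order absorption (Bateman) curve. Per-group defaults take the
published mean rates — (k_ab, k_el) = (0.27, 0.49), (0.81, 0.62),
(1.96, 0.81) h⁻¹ — and a `cmax_scale` equal to the published mean C_max
per group. The amplitude is normalised so the noise-free peak equals
`cmax_scale`; this keeps the curve positive for any rate ordering
(the raw pre-exponential changes sign under flip-flop) and pins simulated
peak heights to realistic magnitudes without claiming to reproduce the
real profiles.

**Noise model.** Multiplicative lognormal with mean exactly 1 and CV
`residual_cv` (default 0.10) on concentrations; truncated relative
Gaussian noise on peak areas (default 3% CV for areas, per-QC-level CVs
from ~3% at HQC to 12% at the LLOQ for measured concentrations, matching
the precision range a validated LC-MS/MS method typically shows).
Chromatographic responses are positive and roughly proportional in their
scatter, which the multiplicative model captures and an additive Gaussian
would not. The mean-1 parameterisation makes injected truths unbiased
targets, so noise-free runs recover every injected effect exactly — the
basis of the exact-recovery test battery.

**What it does not emulate.** Between-animal variance components beyond
body weight (the published per-group SDs reflect real biological
variation with an unknown structure), within-run drift and autocorrelated
instrument noise, species-specific endogenous backgrounds, and delayed
drinking-water absorption (a `t_lag_h` parameter exists but defaults to
0). Passing tests therefore demonstrate estimator correctness under a
clean, known noise model — not performance on real plasma data.

A consequence worth stating: because group peak concentrations are pinned
to the published C_max means (which rise roughly logarithmically in
dose), the synthetic study's AUC–dose power exponent is below 1, unlike
the supra-proportional exposure of the real study. The
dose-proportionality desk check therefore runs on the published group
means, where the printed power and logarithmic equations are reproduced.

**Determinism.** All randomness flows from `numpy.random.default_rng`
seeded by `(seed, stream)` pairs, one stream per generator, so the three
generators are mutually independent and every output table is
byte-identical under a fixed config.

## Calibration and linearity

The regression variable is the analyte/IS peak-area ratio (standard
isotope-dilution practice). Weighted least squares with weights 1, 1/x or
1/x² is computed in closed form; r² = 1 − SS_res/SS_tot on the fitted
(weighted) scale, with r = sign(slope)·√r². `fit_calibration` defaults to
unweighted OLS; the pipeline config defaults to 1/x² because on the
simulated 1000-fold range the unweighted fit back-calculates the bottom
standards 70–180% off nominal — the classic argument for relative
weighting in bioanalysis — while 1/x² passes all four linearity rules.

Linearity rules as implemented: (i) at least 75% of points, and never
fewer than 6, back-calculate within ±15% of nominal; (ii) every relative
residual |y − ŷ|/ŷ ≤ 20%; (iii) SD of relative residuals,
√(Σ(Yᵢ − Ȳ)²/(n − 2)) on the *fraction* scale, ≤ 0.1 (on the percent
scale the 0.1 limit would be unsatisfiable); (iv) r² ≥ 0.99. Blank and
zero records never enter the fit. Quadratic models and automatic outlier
re-fitting are deliberately not offered.

## Validation statistics

All SDs use the n − 1 denominator. Ratio statistics (matrix effect,
recovery, carry-over, stability) are ratios of arm means rather than
means of per-replicate ratios — the direct reading of the acceptance
formulas, which are written with one symbol per arm; at the simulated
noise levels the two conventions differ well below the acceptance
resolution. Precision groups by (level, day) intra-day and pools all
days inter-day. Accuracy applies the same ±15% gate at the LLOQ as at the
QC levels. All gates are inclusive (a statistic exactly at its threshold
passes), so boundary behaviour is well defined and tested.

## Noncompartmental analysis

Concentrations in ng/mL are read as µg/L, so trapezoidal AUC(0→t) lands
in µg·h/L and Cl_B/F = dose_total/AUC in L/h with
dose_total = dose(mg/kg) × weight(kg) × 1000 µg. BLQ policy: leading BLQ
samples (pre-absorption) are kept as zeros; embedded and trailing BLQ
samples are excluded from the trapezoid and the terminal fit — the
conservative standard choice.

The terminal slope is fitted by OLS on ln C vs t over a window selected
automatically: among all suffixes of the strictly-post-peak quantifiable
points with ≥3 points, the one with the largest adjusted r² wins, ties
going to the wider window; `n_points`/`--lambda-z-points` fixes the
window instead. C_max/t_max take the first occurrence on ties; no
extrapolation of AUC to infinity is attempted (the study reports AUC(0→t)
only). Group summaries are arithmetic mean ± sample SD of per-subject
parameters; ratio identities (MRT = AUMC/AUC, Vd = Cl/k_el, t½ = ln2/k)
hold exactly per subject and only approximately on group means — which is
exactly how the published summary table behaves.

## One-compartment absorption

The feathering construction extrapolates the terminal line over the
absorption phase and log-fits the residuals; it is exact on noise-free
Bateman data but needs several pre-peak samples, so at the hourly design
with t_max ≈ 0.8–1.4 h it typically falls back to the heuristic
k_ab = 3·k_el initial value (with a warning). The default estimator is
nonlinear least squares on the full Bateman curve initialised by
feathering; `method="residuals"` returns the classical feathering answer
itself. Non-convergence is flagged, never silent.

Loss: unweighted SSQ by default; `weighting="1/yhat2"` gives relative
weighting, the loss matched to the multiplicative noise model, and is the
recommended (and Monte-Carlo-verified) choice for noisy profiles spanning
two orders of magnitude — at the hourly 0–11 h design with 10% CV it
brings the median relative error of k_ab from ≈16% down to ≈12–13%
(n = 200 simulated subjects).

Flip-flop: the Bateman curve is invariant under exchanging k_ab and k_el
(with the amplitude sign), so the labels are conventions. Fits are
relabelled to k_ab > k_el by default (`enforce_kab_gt_kel=False` keeps
the initialiser's labelling). Note the published 20 mg/kg group has
k_ab < k_el; simulated data from those rates will be reported with the
labels exchanged unless the guard is disabled. When |k_ab − k_el| falls
below 10⁻⁶ the degenerate limit model A·t·e^(−kt) is refitted. MAT and
t₁/₂,ab are pure functions 1/k_ab and ln2/k_ab, asserted on every fit.

## Dose proportionality

The power model is fitted as OLS of ln y on ln x — the linearising fit,
which reproduces the published coefficient/exponent from the published
group means; a raw-scale r² is reported as a secondary diagnostic since
the original fitting scale is not knowable. The logarithmic C_max model
is OLS with regressor ln(dose). With only three dose groups both are
descriptive; no p-values are produced.

## Reporting and pipeline

Thresholds live in one `Thresholds` object (defaults: 15% precision/
accuracy/matrix effect/stability, 20% relative residual, r² 0.99, 20%/5%
carry-over, S/N 10 selectivity). Reports carry raw values alongside every
boolean so each decision is recomputable; display rounding is
round-half-even at 2 decimals while machine outputs keep full precision.
Logging (stage timing, threshold decisions, fallback warnings) goes to
stderr only, keeping artifacts byte-reproducible under a fixed seed.

## Problem sizes

The shipped analysis uses the study's own scale (3×3 subjects, 12
samples, 4 calibration runs, 6-replicate validation arms). Monte-Carlo
checks use 200 simulated subjects for rate recovery and feathering
accuracy, 500 runs for the calibration r² gate and 1000 subjects for the
noise-CV calibration — sizes at which the binomial/median acceptance
margins are comfortably resolved.
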