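"""One-compartment first-order absorption analysis.

Estimates the absorption rate constant k_ab — and the derived mean
absorption time MAT = 1/k_ab and absorption half-life t_1/2kab = ln2/k_ab —
by fitting the Bateman curve

    C(t) = A (exp(-k_el (t - t_lag)) - exp(-k_ab (t - t_lag)))

to an oral concentration--time profile.  Two routes are available:

* ``method="residuals"``: the classical feathering construction.  The
  terminal log-linear line (from :func:`pkbioval.nca.terminal_slope`) is
  extrapolated back over the absorption phase; the residuals between the
  extrapolated line and the observed pre-peak concentrations decay as
  ``exp(-k_ab t)``, so a log-linear fit of the residuals gives k_ab.
* ``method="nls"`` (default): full nonlinear least squares on the Bateman
  curve, initialised by the feathering estimate.

Because the Bateman curve is symmetric under exchanging the two rate
constants (flip-flop kinetics), fitted rates are by default relabelled so
that k_ab > k_el; pass ``enforce_kab_gt_kel=False`` to keep the labelling
of the initialiser.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, stats

from pkbioval import bateman
from pkbioval.nca import ConcentrationTimeProfile, TerminalFit, terminal_slope

__all__ = [
    "OneCompartmentFit",
    "method_of_residuals",
    "fit_one_compartment",
    "absorption_half_life",
    "mean_absorption_time",
]

_FALLBACK_KAB_FACTOR = 3.0  # heuristic initial k_ab when feathering is impossible


@dataclass
class OneCompartmentFit:
    """Fitted Bateman parameters with derived absorption quantities."""

    subject_id: str
    k_ab: float          # 1/h
    k_el: float          # 1/h
    amplitude: float     # ng/mL; pre-exponential A
    t_lag: float         # h
    t_half_ab: float     # h, ln2/k_ab
    mat: float           # h, 1/k_ab
    rss: float           # residual sum of squares (ng/mL)^2
    converged: bool
    method: str
    degenerate: bool = False  # k_ab == k_el limit model used

    def as_dict(self) -> dict:
        return asdict(self)

    def predict(self, t) -> np.ndarray:
        return bateman.bateman(t, self.amplitude, self.k_ab, self.k_el, self.t_lag)


def absorption_half_life(k_ab: float) -> float:
    """t_1/2kab = ln2 / k_ab (h)."""
    return math.log(2.0) / k_ab


def mean_absorption_time(k_ab: float) -> float:
    """MAT = 1/k_ab (h) for first-order absorption."""
    return 1.0 / k_ab


def _derived(k_ab: float) -> tuple[float, float]:
    return absorption_half_life(k_ab), mean_absorption_time(k_ab)


def method_of_residuals(
    profile: ConcentrationTimeProfile,
    terminal: TerminalFit | None = None,
) -> tuple[float, float]:
    """Feathering (method of residuals) initial estimate of (k_ab, amplitude).

    Falls back to ``k_ab = 3·k_el`` with a warning when fewer than two
    positive residuals are available (e.g. no pre-peak samples).
    """
    if terminal is None:
        terminal = terminal_slope(profile)
    t, c = profile.usable_points()
    i_max = int(np.argmax(c))
    t_peak = t[i_max]
    amplitude = math.exp(terminal.intercept_ln)

    pre = (t < t_peak) & (c > 0)
    extrapolated = amplitude * np.exp(-terminal.k_el * t[pre])
    residuals = extrapolated - c[pre]
    tr = t[pre][residuals > 0]
    rr = residuals[residuals > 0]
    if len(rr) < 2:
        warnings.warn(
            "method of residuals: fewer than 2 positive pre-peak residuals; "
            f"falling back to k_ab = {_FALLBACK_KAB_FACTOR:g} x k_el"
        )
        return _FALLBACK_KAB_FACTOR * terminal.k_el, amplitude
    res = stats.linregress(tr, np.log(rr))
    k_ab = -float(res.slope)
    if k_ab <= 0:
        warnings.warn("method of residuals produced a non-positive k_ab; using fallback")
        return _FALLBACK_KAB_FACTOR * terminal.k_el, amplitude
    return k_ab, amplitude


def fit_one_compartment(
    profile: ConcentrationTimeProfile,
    method: str = "nls",
    weighting: str | None = None,
    fit_tlag: bool = False,
    enforce_kab_gt_kel: bool = True,
) -> OneCompartmentFit:
    """Fit the Bateman curve to one profile.

    Parameters
    ----------
    method:
        ``"nls"`` for nonlinear least squares (default) or ``"residuals"``
        for the pure feathering estimate.
    weighting:
        ``None`` for unweighted least squares or ``"1/yhat2"`` for relative
        weighting (useful over a wide concentration range).
    fit_tlag:
        Also estimate an absorption lag time (default: fixed at 0).
    enforce_kab_gt_kel:
        Relabel the fitted rates so the faster one is reported as k_ab.
    """
    t, c = profile.usable_points()
    n_quant = int(np.sum(c > 0))
    min_points = 5 if fit_tlag else 4
    if n_quant < min_points:
        raise ValueError(f"at least {min_points} quantifiable points are required")

    terminal = terminal_slope(profile)
    k_el0 = terminal.k_el
    k_ab0, amp0 = method_of_residuals(profile, terminal)

    if method == "residuals":
        k_ab, k_el, amp = k_ab0, k_el0, amp0
        if enforce_kab_gt_kel and k_ab < k_el:
            k_ab, k_el, amp = k_el, k_ab, -amp
        t_half_ab, mat = _derived(k_ab)
        pred = bateman.bateman(t, amp, k_ab, k_el)
        return OneCompartmentFit(
            subject_id=profile.subject_id,
            k_ab=k_ab, k_el=k_el, amplitude=amp, t_lag=0.0,
            t_half_ab=t_half_ab, mat=mat,
            rss=float(np.sum((c - pred) ** 2)),
            converged=True, method="residuals",
        )
    if method != "nls":
        raise ValueError(f"unknown method {method!r}; choose 'nls' or 'residuals'")

    # canonical initialisation: faster rate labelled k_ab, positive amplitude
    if k_ab0 < k_el0:
        k_ab0, k_el0 = k_el0, k_ab0

    if fit_tlag:
        def model(tt, amp, ka, ke, tlag):
            return bateman.bateman(tt, amp, ka, ke, tlag)
        p0 = [amp0, k_ab0, k_el0, 0.0]
        bounds = ([-np.inf, 1e-6, 1e-6, 0.0], [np.inf, np.inf, np.inf, float(t[-1])])
    else:
        def model(tt, amp, ka, ke):
            return bateman.bateman(tt, amp, ka, ke)
        p0 = [amp0, k_ab0, k_el0]
        bounds = ([-np.inf, 1e-6, 1e-6], [np.inf, np.inf, np.inf])

    sigma = None
    if weighting == "1/yhat2":
        pred0 = np.maximum(model(t, *p0), 1e-12)
        sigma = pred0  # curve_fit minimises sum(((y - f)/sigma)^2)
    elif weighting is not None:
        raise ValueError(f"unknown weighting {weighting!r}")

    converged = True
    try:
        popt, _ = optimize.curve_fit(
            model, t, c, p0=p0, bounds=bounds, sigma=sigma, maxfev=20000
        )
    except RuntimeError as err:
        warnings.warn(f"Bateman fit did not converge: {err}")
        converged = False
        popt = np.asarray(p0, dtype=float)

    amp, k_ab, k_el = float(popt[0]), float(popt[1]), float(popt[2])
    t_lag = float(popt[3]) if fit_tlag else 0.0

    degenerate = abs(k_ab - k_el) < 1e-6
    if degenerate:
        # refit the k_ab == k_el limit model A·t·exp(-k·t)
        def limit_model(tt, amp_, k_):
            ts = np.maximum(tt - t_lag, 0.0)
            return amp_ * ts * np.exp(-k_ * ts)
        k0 = 0.5 * (k_ab + k_el)
        popt, _ = optimize.curve_fit(
            limit_model, t, c, p0=[amp * k0 * math.e, k0],
            bounds=([-np.inf, 1e-6], [np.inf, np.inf]), maxfev=20000,
        )
        amp, k_ab = float(popt[0]), float(popt[1])
        k_el = k_ab
        warnings.warn("k_ab == k_el within tolerance: degenerate limit model used")

    if enforce_kab_gt_kel and k_ab < k_el:
        k_ab, k_el, amp = k_el, k_ab, -amp  # flip-flop relabelling, same curve

    pred = (
        bateman.bateman(t, amp, k_ab, k_el, t_lag)
        if not degenerate
        else amp * np.maximum(t - t_lag, 0.0) * np.exp(-k_ab * np.maximum(t - t_lag, 0.0))
    )
    t_half_ab, mat = _derived(k_ab)
    return OneCompartmentFit(
        subject_id=profile.subject_id,
        k_ab=k_ab, k_el=k_el, amplitude=amp, t_lag=t_lag,
        t_half_ab=t_half_ab, mat=mat,
        rss=float(np.sum((c - pred) ** 2)),
        converged=converged, method="nls", degenerate=degenerate,
    )
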