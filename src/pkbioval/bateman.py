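"""One-compartment first-order absorption (Bateman) curve and its integrals.

The oral one-compartment model with first-order absorption rate ``k_ab`` and
first-order elimination rate ``k_el`` gives the plasma concentration

    C(t) = A * (exp(-k_el * t) - exp(-k_ab * t))

where the pre-exponential amplitude is A = F*D*k_ab / (V*(k_ab - k_el)).
The curve is invariant under exchanging the two rate constants together with
the sign of A ("flip-flop" kinetics), so the labelling of the rates is a
convention, not a property of the curve.

When the two rates coincide the difference of exponentials degenerates and
the limit form ``A * t * exp(-k * t)`` applies.
"""

from __future__ import annotations

import numpy as np

#: below this rate separation the two-exponential form is numerically
#: degenerate and the limit form is used instead
DEGENERATE_TOL = 1e-9


def bateman(t, amplitude: float, k_ab: float, k_el: float, t_lag: float = 0.0):
    """Evaluate the Bateman curve at times ``t`` (hours).

    Negative shifted times (before ``t_lag``) evaluate to 0.  Handles the
    ``k_ab == k_el`` degeneracy with the ``A*t*exp(-k*t)`` limit form.
    """
    t = np.asarray(t, dtype=float)
    ts = np.maximum(t - t_lag, 0.0)
    if abs(k_ab - k_el) < DEGENERATE_TOL:
        k = 0.5 * (k_ab + k_el)
        return amplitude * ts * np.exp(-k * ts)
    return amplitude * (np.exp(-k_el * ts) - np.exp(-k_ab * ts))


def t_max(k_ab: float, k_el: float) -> float:
    """Time of the curve maximum: ln(k_ab/k_el)/(k_ab - k_el), or 1/k at the
    equal-rates degeneracy."""
    if abs(k_ab - k_el) < DEGENERATE_TOL:
        return 1.0 / (0.5 * (k_ab + k_el))
    return float(np.log(k_ab / k_el) / (k_ab - k_el))


def peak_concentration(amplitude: float, k_ab: float, k_el: float) -> float:
    """Concentration at the analytic :func:`t_max`."""
    return float(bateman(t_max(k_ab, k_el), amplitude, k_ab, k_el))


def amplitude_for_cmax(cmax: float, k_ab: float, k_el: float) -> float:
    """Amplitude that yields a given peak concentration.

    Positive for any rate ordering, which makes it the convenient
    parameterisation for simulation: the flip-flop sign bookkeeping of the
    raw pre-exponential A is absorbed into the normalisation.
    """
    unit_peak = peak_concentration(1.0, k_ab, k_el)
    return cmax / unit_peak


def auc_0_T(amplitude: float, k_ab: float, k_el: float, T: float) -> float:
    """Closed-form integral of the curve over [0, T]."""
    if abs(k_ab - k_el) < DEGENERATE_TOL:
        k = 0.5 * (k_ab + k_el)
        return amplitude * (1.0 - (1.0 + k * T) * np.exp(-k * T)) / k**2
    term_el = (1.0 - np.exp(-k_el * T)) / k_el
    term_ab = (1.0 - np.exp(-k_ab * T)) / k_ab
    return amplitude * (term_el - term_ab)


def aumc_0_T(amplitude: float, k_ab: float, k_el: float, T: float) -> float:
    """Closed-form first-moment integral (t*C) over [0, T]."""
    if abs(k_ab - k_el) < DEGENERATE_TOL:
        k = 0.5 * (k_ab + k_el)
        # ∫ t^2 e^{-kt} dt over [0, T]
        e = np.exp(-k * T)
        return amplitude * (2.0 - (k * T * (k * T + 2.0) + 2.0) * e) / k**3

    def first_moment(k: float) -> float:
        # ∫_0^T t e^{-kt} dt
        return (1.0 - (1.0 + k * T) * np.exp(-k * T)) / k**2

    return amplitude * (first_moment(k_el) - first_moment(k_ab))
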