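"""Closed-form one-compartment toxicokinetics of BaP and urinary 3-OHBaP.

The body is a single compartment B; each exposure route feeds an absorption
site that empties into the body with a route-specific first-order rate ka,
and the body eliminates with rate k_b.  The urinary 3-OHBaP excretion rate is
a route-specific fraction alpha of the elimination flux, alpha * k_b * B.

For a bolus D on the absorption site, the body burden is the Bateman
function

    B(t) = D ka / (ka - k_b) (exp(-k_b t) - exp(-ka t)),

with the limit D ka t exp(-ka t) at ka = k_b.  Rectangular deposit-rate
windows are handled by exact convolution of the impulse response, so the
whole model is closed-form; superposition across windows and routes is
additive.

Scenario levels map onto deposit rates as in the PBPK engine: inhalation
ng/m3 x alveolar ventilation; dermal fmol/mL x 1 L vehicle spread uniformly
over the contact window; oral nmol bolus spread over its window.  Amounts
are nmol, time hours.
"""

from __future__ import annotations

import numpy as np

from .exposure import (DEFAULT_VENTILATION_ML_H, ExposureScenario,
                       air_ngm3_to_fmolml)
from .params import TKParams, default_tk_params

__all__ = [
    "bolus_body_burden",
    "window_body_burden",
    "body_burden",
    "urinary_rate",
    "urinary_cumulative",
    "body_bolus_cumulative_urine",
    "deposit_rate_windows",
]

_FMOL_TO_NMOL = 1e-6
_DERMAL_VEHICLE_ML = 1000.0  # "diluted in about one liter"
_EQUAL_RATE_TOL = 1e-9


def bolus_body_burden(t, dose: float, ka: float, k_b: float):
    """Body burden B(t) (nmol) after a bolus ``dose`` on the absorption site."""
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tp = np.maximum(t, 0.0)
    if abs(ka - k_b) < _EQUAL_RATE_TOL * max(ka, k_b):
        out = dose * ka * tp * np.exp(-ka * tp)
    else:
        out = (dose * ka / (ka - k_b)
               * (np.exp(-k_b * tp) - np.exp(-ka * tp)))
    out = np.where(t >= 0, out, 0.0)
    return float(out[0]) if scalar else out


def _cum_impulse(t, ka: float, k_b: float):
    """H(t) = integral_0^t of the unit impulse response; H(inf) = 1/k_b."""
    t = np.asarray(t, dtype=float)
    tp = np.maximum(t, 0.0)
    if abs(ka - k_b) < _EQUAL_RATE_TOL * max(ka, k_b):
        # int ka s e^{-ka s} ds = (1 - (1 + ka t) e^{-ka t}) / ka
        return (1.0 - (1.0 + ka * tp) * np.exp(-ka * tp)) / ka
    c = ka / (ka - k_b)
    return c * (-np.expm1(-k_b * tp) / k_b + np.expm1(-ka * tp) / ka)


def _cum2_impulse(t, ka: float, k_b: float):
    """H2(t) = integral_0^t H(s) ds (for cumulative urine under window input)."""
    t = np.asarray(t, dtype=float)
    tp = np.maximum(t, 0.0)
    if abs(ka - k_b) < _EQUAL_RATE_TOL * max(ka, k_b):
        return (tp / ka
                - (2.0 - (2.0 + ka * tp) * np.exp(-ka * tp)) / ka**2)
    c = ka / (ka - k_b)
    return c * ((tp + np.expm1(-k_b * tp) / k_b) / k_b
                - (tp + np.expm1(-ka * tp) / ka) / ka)


def window_body_burden(t, rate: float, t0: float, t1: float,
                       ka: float, k_b: float):
    """B(t) for a constant deposit rate (nmol/h) on the site over [t0, t1]."""
    if not t1 > t0:
        raise ValueError("window requires t1 > t0")
    t = np.asarray(t, dtype=float)
    return rate * (_cum_impulse(t - t0, ka, k_b) - _cum_impulse(t - t1, ka, k_b))


def _window_cumulative(t, rate: float, t0: float, t1: float,
                       ka: float, k_b: float):
    """integral_0^t B(s) ds for the rectangular window input."""
    t = np.asarray(t, dtype=float)
    return rate * (_cum2_impulse(t - t0, ka, k_b) - _cum2_impulse(t - t1, ka, k_b))


def deposit_rate_windows(scenario: ExposureScenario,
                         ventilation_ml_h: float = DEFAULT_VENTILATION_ML_H
                         ) -> list[tuple[str, float, float, float]]:
    """Map scenario windows to (route, t0, t1, deposit rate nmol/h)."""
    out = []
    for w in scenario.windows:
        if w.route == "inhalation":
            rate = (air_ngm3_to_fmolml(w.level) * ventilation_ml_h
                    * _FMOL_TO_NMOL)
        elif w.route == "dermal":
            dose = w.level * _DERMAL_VEHICLE_ML * _FMOL_TO_NMOL
            rate = dose / w.duration
        else:  # oral bolus spread over its window
            rate = w.level / w.duration
        out.append((w.route, float(w.start), float(w.end), rate))
    return out


def body_burden(t, scenario: ExposureScenario,
                tk: TKParams | None = None) -> dict[str, np.ndarray]:
    """Per-route body burden B_route(t) (nmol) by superposition of windows."""
    tk = tk or default_tk_params()
    t = np.asarray(t, dtype=float)
    burdens: dict[str, np.ndarray] = {}
    for route, t0, t1, rate in deposit_rate_windows(scenario):
        if rate == 0.0:
            continue
        contrib = window_body_burden(t, rate, t0, t1, tk.ka(route), tk.k_b)
        burdens[route] = burdens.get(route, np.zeros_like(t)) + contrib
    return burdens


def urinary_rate(t, scenario: ExposureScenario,
                 tk: TKParams | None = None) -> np.ndarray:
    """Urinary 3-OHBaP excretion rate (nmol/h): sum over routes of alpha k_b B."""
    tk = tk or default_tk_params()
    t = np.asarray(t, dtype=float)
    total = np.zeros_like(t)
    for route, burden in body_burden(t, scenario, tk).items():
        total += tk.alpha(route) * tk.k_b * burden
    return total


def urinary_cumulative(t, scenario: ExposureScenario,
                       tk: TKParams | None = None) -> np.ndarray:
    """Cumulative urinary 3-OHBaP (nmol); tends to sum alpha_route x dose."""
    tk = tk or default_tk_params()
    t = np.asarray(t, dtype=float)
    total = np.zeros_like(t)
    for route, t0, t1, rate in deposit_rate_windows(scenario):
        if rate == 0.0:
            continue
        total += (tk.alpha(route) * tk.k_b
                  * _window_cumulative(t, rate, t0, t1, tk.ka(route), tk.k_b))
    return total


def body_bolus_cumulative_urine(t, dose: float, route: str,
                                tk: TKParams | None = None):
    """Cumulative urine after a bolus placed directly in the body compartment.

    With absorption already complete, B(t) = D exp(-k_b t) and the cumulative
    urinary 3-OHBaP is alpha_route * D * (1 - exp(-k_b t)), reaching the
    urinary-fraction limit alpha * D as t -> infinity.
    """
    tk = tk or default_tk_params()
    t = np.asarray(t, dtype=float)
    out = -tk.alpha(route) * dose * np.expm1(-tk.k_b * np.maximum(t, 0.0))
    return out if out.ndim else float(out)
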