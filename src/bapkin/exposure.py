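"""Multi-day, multi-route exposure scenarios and air-concentration conversion.

A scenario is an ordered set of rectangular exposure windows on a common time
axis whose origin is 00:00 of the first exposure day.  Windows written with a
clock end time earlier than the start ("20:00-13:00") span midnight and are
stored as single windows whose end offset exceeds 24 h.

Levels are route-specific: ng/m3 air concentration for inhalation, fmol/mL
vehicle concentration for dermal contact, nmol bolus for oral intake.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .params import MW_BAP

__all__ = [
    "ROUTES",
    "DEFAULT_VENTILATION_ML_H",
    "DEFAULT_SKIN_AREA_CM2",
    "ExposureWindow",
    "ExposureScenario",
    "air_ngm3_to_fmolml",
    "inhalation_intake_rate",
    "dermal_flux",
    "worker_fixture",
    "worker_ids",
    "load_scenario",
    "save_scenario",
]

ROUTES = ("inhalation", "dermal", "oral")

ROUTE_UNITS = {"inhalation": "ng/m3", "dermal": "fmol/mL", "oral": "nmol"}

DEFAULT_VENTILATION_ML_H = 478_800.0  # 7.98 L/min worker ventilation
DEFAULT_SKIN_AREA_CM2 = 18_000.0      # whole-body exposed area


@dataclass(frozen=True)
class ExposureWindow:
    """One rectangular exposure window.

    start/end are hours from the scenario origin, end > start.  ``level`` is
    in the route-specific unit (see ROUTE_UNITS).
    """

    route: str
    start: float
    end: float
    level: float

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}, got {self.route!r}")
        if not self.end > self.start:
            raise ValueError(f"window end ({self.end}) must exceed start ({self.start})")
        if self.level < 0:
            raise ValueError(f"level must be >= 0, got {self.level}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def unit(self) -> str:
        return ROUTE_UNITS[self.route]


@dataclass(frozen=True)
class ExposureScenario:
    """Ordered collection of exposure windows over a finite horizon (hours)."""

    windows: tuple[ExposureWindow, ...]
    horizon: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(self.windows))
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        for w in self.windows:
            if w.start < 0 or w.end > self.horizon + 1e-9:
                raise ValueError(
                    f"window [{w.start}, {w.end}] lies outside [0, {self.horizon}]")

    def by_route(self, route: str) -> tuple[ExposureWindow, ...]:
        return tuple(w for w in self.windows if w.route == route)

    def breakpoints(self) -> np.ndarray:
        """Sorted unique window edges plus 0 and the horizon."""
        pts = {0.0, float(self.horizon)}
        for w in self.windows:
            pts.add(float(w.start))
            pts.add(float(w.end))
        return np.array(sorted(pts))

    def level_at(self, t: float, route: str) -> float:
        """Summed level of all windows of ``route`` active at time t (start-inclusive)."""
        return sum(w.level for w in self.by_route(route) if w.start <= t < w.end)

    def scaled(self, factor: float) -> "ExposureScenario":
        """Scenario with every window level multiplied by ``factor`` (> 0)."""
        if factor < 0:
            raise ValueError("factor must be >= 0")
        return replace(
            self,
            windows=tuple(replace(w, level=w.level * factor) for w in self.windows),
        )

    def with_levels(self, levels: Iterable[float]) -> "ExposureScenario":
        """Scenario with window levels replaced (same order as .windows)."""
        levels = list(levels)
        if len(levels) != len(self.windows):
            raise ValueError("one level per window required")
        return replace(
            self,
            windows=tuple(replace(w, level=lv)
                          for w, lv in zip(self.windows, levels)),
        )

    def nominal_intake(self) -> float:
        """Sum of window rate x duration in native units (diagnostic)."""
        return sum(w.level * w.duration for w in self.windows)


# ---------------------------------------------------------------------------
# unit conversions and intake rates
# ---------------------------------------------------------------------------

def air_ngm3_to_fmolml(conc_ngm3: float) -> float:
    """Convert an air concentration from ng/m3 to fmol/mL.

    ng/m3 divided by the molar mass (g/mol) gives nmol/m3, and 1 nmol/m3 is
    dimensionally identical to 1 fmol/mL.  (Published figures additionally
    multiply by 1e3 for display on a shared axis; that display scale is not a
    physical conversion and is not applied here.)
    """
    if conc_ngm3 < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_ngm3}")
    return conc_ngm3 / MW_BAP


def inhalation_intake_rate(conc_air_fmolml: float,
                           ventilation_ml_h: float = DEFAULT_VENTILATION_ML_H) -> float:
    """Inhaled amount per hour (fmol/h) while an exposure window is active."""
    if ventilation_ml_h <= 0:
        raise ValueError("ventilation must be > 0")
    return conc_air_fmolml * ventilation_ml_h


def dermal_flux(conc_vehicle_fmolml: float,
                k_p_cm_h: float,
                area_cm2: float = DEFAULT_SKIN_AREA_CM2) -> float:
    """Percutaneous flux (fmol/h) from a vehicle film of given concentration.

    flux = k_P x area x C_vehicle, with fmol/cm3 == fmol/mL.
    """
    if conc_vehicle_fmolml < 0 or k_p_cm_h < 0 or area_cm2 < 0:
        raise ValueError("inputs must be >= 0")
    return k_p_cm_h * area_cm2 * conc_vehicle_fmolml


# ---------------------------------------------------------------------------
# scenario file IO
# ---------------------------------------------------------------------------

def _scenario_to_dict(s: ExposureScenario) -> dict:
    return {
        "label": s.label,
        "horizon_h": float(s.horizon),
        "windows": [
            {"route": w.route, "start_h": float(w.start), "end_h": float(w.end),
             "level": float(w.level), "unit": w.unit}
            for w in s.windows
        ],
    }


def _scenario_from_dict(d: dict) -> ExposureScenario:
    windows = []
    for i, w in enumerate(d.get("windows", [])):
        expected = ROUTE_UNITS.get(w.get("route", ""), None)
        if "unit" in w and w["unit"] != expected:
            raise ValueError(
                f"window {i}: unit {w['unit']!r} does not match route "
                f"{w.get('route')!r} (expected {expected!r})")
        windows.append(ExposureWindow(route=w["route"], start=w["start_h"],
                                      end=w["end_h"], level=w["level"]))
    return ExposureScenario(windows=tuple(windows), horizon=d["horizon_h"],
                            label=d.get("label", ""))


def save_scenario(scenario: ExposureScenario, path: str | Path) -> None:
    path = Path(path)
    doc = _scenario_to_dict(scenario)
    text = (json.dumps(doc, indent=2) if path.suffix == ".json"
            else yaml.safe_dump(doc, sort_keys=False))
    path.write_text(text)


def load_scenario(path: str | Path) -> ExposureScenario:
    path = Path(path)
    raw = path.read_text()
    doc = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    return _scenario_from_dict(doc)


def intake_rate_frame(scenario: ExposureScenario, dt: float = 0.5) -> pd.DataFrame:
    """Tidy frame of window level per route on a regular grid (for plotting/export)."""
    t = np.arange(0.0, scenario.horizon + dt / 2, dt)
    rows = {"time_h": t}
    for route in ROUTES:
        rows[route] = [scenario.level_at(ti, route) for ti in t]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# worker fixtures: the published measured and best-fit exposure scenarios
# ---------------------------------------------------------------------------

class WorkerScenarios(NamedTuple):
    measured: ExposureScenario   # measured-air inhalation windows
    simulated: ExposureScenario  # best-fit inhalation + dermal windows


def _w(route: str, day: int, start_clock: float, end_clock: float,
       level: float) -> ExposureWindow:
    """Window from day number (1-based) and clock hours; end <= start spans midnight."""
    start = 24.0 * (day - 1) + start_clock
    end = 24.0 * (day - 1) + (end_clock if end_clock > start_clock
                              else end_clock + 24.0)
    return ExposureWindow(route=route, start=start, end=end, level=level)


# (measured inhalation, simulated inhalation, simulated dermal) per worker.
# Tuples: (day, start_clock, end_clock, level).
_FIXTURES: dict[int, dict] = {
    # artificial shooting target factory (2 exposure days, shift ~12/13:00-21:00)
    1: {"inh": [(1, 12, 21, 233.0), (2, 12, 21, 302.0)],
        "sim_inh": [(1, 12, 21, 2749.4), (2, 12, 21, 3322.0)],
        "derm": [(1, 12, 24, 19.8), (2, 13, 1, 26.1)]},
    2: {"inh": [(1, 12, 21, 208.0), (2, 12, 21, 285.0)],
        "sim_inh": [(1, 12, 21, 1040.0), (2, 12, 21, 1425.0)],
        "derm": [(1, 12, 12, 7.5), (2, 8, 20, 10.8)]},
    3: {"inh": [(1, 13, 21, 537.0), (2, 13, 21, 991.0)],
        "sim_inh": [(1, 13, 21, 13962.0), (2, 13, 21, 21802.0)],
        "derm": [(1, 13, 10, 47.1), (2, 20, 13, 123.6)]},
    4: {"inh": [(1, 13, 21, 422.0), (2, 13, 21, 583.0)],
        "sim_inh": [(1, 13, 21, 6330.0), (2, 13, 21, 8745.0)],
        "derm": [(1, 13, 10, 36.2), (2, 20, 13, 39.5)]},
    5: {"inh": [(1, 13, 21, 519.0), (2, 13, 21, 684.0)],
        "sim_inh": [(1, 13, 21, 7785.0), (2, 13, 21, 8208.0)],
        "derm": [(1, 13, 10, 36.2), (2, 20, 16, 56.8)]},
    # carbon disk brake production plant (2 exposure days, shift 8:00-16:00)
    6: {"inh": [(1, 8, 16, 8.0)],
        "sim_inh": [(1, 8, 16, 240.0), (2, 8, 16, 240.0)],
        "derm": [(1, 8, 16, 2.0), (2, 8, 16, 4.6)]},
    7: {"inh": [(1, 8, 16, 9300.0), (2, 8, 16, 560.0)],
        "sim_inh": [(1, 8, 16, 4650.0), (2, 8, 16, 5600.0)],
        "derm": [(1, 8, 8, 32.6), (2, 8, 10, 106.3)]},
    8: {"inh": [(1, 8, 16, 5650.0), (2, 8, 16, 270.0)],
        "sim_inh": [(1, 8, 16, 6215.0), (2, 8, 16, 4050.0)],
        "derm": [(1, 8, 24, 43.5), (2, 8, 16, 21.9)]},
    9: {"inh": [(1, 8, 16, 1500.0), (2, 8, 16, 65.0)],
        "sim_inh": [(1, 8, 16, 7500.0), (2, 8, 16, 6500.0)],
        "derm": [(1, 8, 8, 41.0), (2, 8, 9, 123.4)]},
    10: {"inh": [(1, 8, 16, 775.0), (2, 8, 16, 63.0)],
         "sim_inh": [(1, 8, 16, 2712.5), (2, 8, 16, 5670.0)],
         "derm": [(1, 8, 8, 16.6), (2, 8, 9, 351.6)]},
    # silicon production plant, furnace repair (4 exposure days, shift 6:00-14:00).
    # Air was measured on days 1 and 4; days 2-3 default to the day-1 value.
    11: {"inh": [(1, 6, 14, 3619.0), (2, 6, 14, 3619.0), (3, 6, 14, 3619.0),
                 (4, 6, 14, 18.5)],
         "sim_inh": [(1, 6, 14, 6514.2), (2, 6, 14, 1881.8), (3, 6, 14, 1737.1),
                     (4, 6, 14, 3619.0)],
         "derm": [(1, 6, 21, 33.3), (2, 6, 17, 23.6), (3, 6, 14, 15.1),
                  (4, 6, 22, 22.6)]},
    12: {"inh": [(1, 6, 14, 2668.1), (2, 6, 14, 2668.1), (3, 6, 14, 2668.1),
                 (4, 6, 14, 77.0)],
         "sim_inh": [(1, 6, 14, 8537.9), (2, 6, 14, 800.4), (3, 6, 14, 3201.7),
                     (4, 6, 14, 4002.1)],
         "derm": [(1, 6, 18, 49.9), (2, 6, 5, 10.0), (3, 6, 5, 9.1),
                  (4, 6, 2, 10.8)]},
    13: {"inh": [(1, 6, 14, 2121.5), (2, 6, 14, 2121.5), (3, 6, 14, 2121.5),
                 (4, 6, 14, 28.0)],
         "sim_inh": [(1, 6, 14, 2121.5), (2, 6, 14, 2651.9), (3, 6, 14, 424.3),
                     (4, 6, 14, 28.0)],
         "derm": [(1, 6, 14, 21.5), (2, 6, 14, 29.0), (3, 6, 14, 7.8),
                  (4, 6, 14, 0.3)]},
    14: {"inh": [(1, 6, 14, 3996.7), (2, 6, 14, 3996.7), (3, 6, 14, 3996.7),
                 (4, 6, 14, 51.0)],
         "sim_inh": [(1, 6, 14, 45962.0), (2, 6, 14, 399.7), (3, 6, 14, 3996.7),
                     (4, 6, 14, 2805.0)],
         "derm": [(1, 6, 14, 498.6), (2, 6, 14, 0.0), (3, 6, 18, 52.0),
                  (4, 6, 6, 13.3)]},
}


def worker_ids() -> tuple[int, ...]:
    return tuple(sorted(_FIXTURES))


def worker_fixture(worker_id: int) -> WorkerScenarios:
    """Published exposure scenarios for one of the 14 monitored workers.

    Returns the measured-air inhalation scenario and the best-fit simulated
    scenario (inhalation + dermal windows).  The horizon extends 72 h past the
    last window to cover the post-exposure collection period.
    """
    if worker_id not in _FIXTURES:
        raise KeyError(f"unknown worker id {worker_id}; valid ids: {worker_ids()}")
    fx = _FIXTURES[worker_id]
    # dermal windows with level 0 are placeholders in the published tables
    measured = [_w("inhalation", *t) for t in fx["inh"]]
    simulated = ([_w("inhalation", *t) for t in fx["sim_inh"]]
                 + [_w("dermal", *t) for t in fx["derm"] if t[3] > 0])
    last = max(w.end for w in measured + simulated)
    horizon = 24.0 * np.ceil((last + 72.0) / 24.0)
    return WorkerScenarios(
        measured=ExposureScenario(tuple(measured), horizon,
                                  label=f"worker{worker_id}-measured"),
        simulated=ExposureScenario(tuple(simulated), horizon,
                                   label=f"worker{worker_id}-simulated"),
    )
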