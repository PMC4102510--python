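"""Void-level, creatinine-corrected urinary 3-OHBaP series.

A void is one urine collection with its interval, volume and creatinine
content.  Model output (a cumulative-urine curve U(t) in nmol) is turned into
a void-level concentration by differencing U over each collection interval
and dividing by the moles of creatinine co-excreted in that void:

    conc = (U(t_end) - U(t_start)) / n_creatinine   [nmol / mol creatinine]

plus an optional additive background level.  When a void carries no
creatinine measurement, a default excretion of 1.2 g/day is partitioned
proportionally to interval duration (a physiological convention).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .params import MW_CREATININE

__all__ = [
    "DEFAULT_CREATININE_G_PER_DAY",
    "UrineVoid",
    "VoidSeries",
    "void_concentrations",
    "read_void_csv",
    "write_void_csv",
]

DEFAULT_CREATININE_G_PER_DAY = 1.2

_CSV_COLUMNS = ["subject", "t_start_h", "t_end_h", "volume_mL",
                "creatinine_mmol", "conc_nmol_per_mol_creat"]


@dataclass(frozen=True)
class UrineVoid:
    """One micturition: interval (h), volume (mL), creatinine, optional measurement."""

    t_start: float
    t_end: float
    volume_ml: float
    creatinine_mmol: float | None = None
    concentration: float | None = None  # measured 3-OHBaP, nmol/mol creatinine

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(f"t_end ({self.t_end}) must exceed t_start ({self.t_start})")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be > 0")
        if self.creatinine_mmol is not None and self.creatinine_mmol <= 0:
            raise ValueError("creatinine_mmol must be > 0 when given")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def creatinine_mol(self) -> float:
        """Moles of creatinine in the void; defaults from 1.2 g/day if unmeasured."""
        if self.creatinine_mmol is not None:
            return self.creatinine_mmol * 1e-3
        grams = DEFAULT_CREATININE_G_PER_DAY * self.duration / 24.0
        return grams / MW_CREATININE


@dataclass(frozen=True)
class VoidSeries:
    """Chronologically ordered, non-overlapping urine voids for one subject."""

    subject: str
    voids: tuple[UrineVoid, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "voids", tuple(self.voids))
        for prev, cur in zip(self.voids, self.voids[1:]):
            if cur.t_start < prev.t_end - 1e-9:
                raise ValueError(
                    f"voids overlap or are out of order near t={cur.t_start}")

    def __len__(self) -> int:
        return len(self.voids)

    def intervals(self) -> np.ndarray:
        return np.array([[v.t_start, v.t_end] for v in self.voids])

    def concentrations(self) -> np.ndarray:
        return np.array([np.nan if v.concentration is None else v.concentration
                         for v in self.voids])

    def with_concentrations(self, conc: Sequence[float]) -> "VoidSeries":
        if len(conc) != len(self.voids):
            raise ValueError("one concentration per void required")
        return VoidSeries(self.subject,
                          tuple(replace(v, concentration=float(c))
                                for v, c in zip(self.voids, conc)))


def void_concentrations(model_output, series: VoidSeries,
                        background: float = 0.0) -> np.ndarray:
    """Per-void 3-OHBaP concentrations (nmol/mol creatinine) from model output.

    ``model_output`` is either a PBPK :class:`~bapkin.pbpk.Trajectory` or any
    callable mapping time (h) to cumulative urinary 3-OHBaP (nmol).
    ``background`` is added to every void.
    """
    if callable(getattr(model_output, "urine_cumulative", None)):
        horizon = float(model_output.times[-1])
        u: Callable = model_output.urine_cumulative
    elif callable(model_output):
        horizon = np.inf
        u = model_output
    else:
        raise TypeError("model_output must be a Trajectory or a callable U(t)")

    out = np.empty(len(series))
    for i, v in enumerate(series.voids):
        if v.t_start < -1e-9 or v.t_end > horizon + 1e-9:
            raise ValueError(
                f"void [{v.t_start}, {v.t_end}] outside simulated horizon "
                f"[0, {horizon}]")
        excreted = float(np.asarray(u(v.t_end)) - np.asarray(u(v.t_start)))
        out[i] = excreted / v.creatinine_mol() + background
    return out


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

def write_void_csv(series: VoidSeries, path: str | Path) -> None:
    rows = []
    for v in series.voids:
        rows.append({
            "subject": series.subject,
            "t_start_h": v.t_start,
            "t_end_h": v.t_end,
            "volume_mL": v.volume_ml,
            "creatinine_mmol": (np.nan if v.creatinine_mmol is None
                                else v.creatinine_mmol),
            "conc_nmol_per_mol_creat": (np.nan if v.concentration is None
                                        else v.concentration),
        })
    # %.17g keeps every double exactly through the text round-trip
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False,
                                                    float_format="%.17g")


def read_void_csv(path: str | Path) -> VoidSeries:
    """Read a void series; schema violations are reported with row numbers."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    voids = []
    subject = ""
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after header
        try:
            subject = str(row["subject"])
            voids.append(UrineVoid(
                t_start=float(row["t_start_h"]),
                t_end=float(row["t_end_h"]),
                volume_ml=float(row["volume_mL"]),
                creatinine_mmol=(None if pd.isna(row["creatinine_mmol"])
                                 else float(row["creatinine_mmol"])),
                concentration=(None if pd.isna(row["conc_nmol_per_mol_creat"])
                               else float(row["conc_nmol_per_mol_creat"])),
            ))
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: row {rowno}: {err}") from err
    try:
        return VoidSeries(subject=subject, voids=tuple(voids))
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err
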