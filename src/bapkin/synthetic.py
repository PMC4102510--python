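"""Synthetic worker urinary datasets with known ground truth.

The generator simulates a chosen kinetic model (PBPK or one-compartment) for
an exposure scenario, aggregates the cumulative urinary 3-OHBaP over a void
schedule, and applies mean-one multiplicative lognormal measurement noise and
an additive background, returning the observed series together with the
generating truth.  The default void schedule emulates the published
collection designs: all micturitions in separate bottles at waking hours
(boundaries at 06:00, 10:00, 14:00, 18:00 and 22:00 each day, the overnight
interval collected at 06:00).

Noise is mean-one by construction, so the expected observation equals the
noiseless void concentration.  Every dataset is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import one_compartment as tkmod
from .exposure import ExposureScenario
from .params import (PBPKParameterSet, TKParams, default_human_pbpk_params,
                     default_tk_params)
from .pbpk import PBPKModel
from .urine import UrineVoid, VoidSeries, void_concentrations

__all__ = [
    "SyntheticSpec",
    "default_void_schedule",
    "generate_worker_dataset",
]

_WAKING_BOUNDARIES = (6.0, 10.0, 14.0, 18.0, 22.0)


def default_void_schedule(horizon: float,
                          rng: np.random.Generator | None = None,
                          volume_range: tuple[float, float] = (100.0, 400.0)
                          ) -> tuple[UrineVoid, ...]:
    """Voids tiling [0, horizon] with boundaries at waking clock hours.

    Urine volumes are drawn uniformly from ``volume_range`` (mL); creatinine
    is left unmeasured so the 1.2 g/day convention applies downstream.
    """
    rng = rng or np.random.default_rng()
    boundaries = [0.0]
    day = 0
    while True:
        for clock in _WAKING_BOUNDARIES:
            t = 24.0 * day + clock
            if t >= horizon:
                break
            if t > boundaries[-1]:
                boundaries.append(t)
        else:
            day += 1
            continue
        break
    if horizon > boundaries[-1] + 1e-9:
        boundaries.append(float(horizon))
    return tuple(
        UrineVoid(t_start=a, t_end=b,
                  volume_ml=float(rng.uniform(*volume_range)))
        for a, b in zip(boundaries, boundaries[1:])
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic worker dataset.

    ``cv`` is the coefficient of variation of the mean-one lognormal
    measurement noise (default 15%, covering assay plus physiological
    variability); ``background`` is the additive urinary level in nmol/mol
    creatinine (0 by default; ~0.5 emulates exposed workers at week onset).
    """

    scenario: ExposureScenario
    model: str = "pbpk"  # "pbpk" | "tk"
    params: PBPKParameterSet = field(default_factory=default_human_pbpk_params)
    tk: TKParams = field(default_factory=default_tk_params)
    cv: float = 0.15
    background: float = 0.0
    seed: int = 0
    subject: str = "synthetic"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.model not in ("pbpk", "tk"):
            raise ValueError("model must be 'pbpk' or 'tk'")


def generate_worker_dataset(spec: SyntheticSpec,
                            voids: tuple[UrineVoid, ...] | None = None
                            ) -> tuple[VoidSeries, dict]:
    """Simulate, aggregate voids, apply noise and background.

    Returns the observed series (concentrations filled in) and a ground-truth
    record with the generating scenario levels, model and seed.
    """
    rng = np.random.default_rng(spec.seed)
    if voids is None:
        voids = default_void_schedule(spec.scenario.horizon, rng)
    for v in voids:
        if v.t_start < 0 or v.t_end > spec.scenario.horizon + 1e-9:
            raise ValueError(
                f"void [{v.t_start}, {v.t_end}] outside the scenario horizon")
    series = VoidSeries(subject=spec.subject, voids=tuple(voids))

    if spec.model == "pbpk":
        traj = PBPKModel(spec.params).simulate(spec.scenario, dt=0.5)
        clean = void_concentrations(traj, series, background=spec.background)
    else:
        clean = void_concentrations(
            lambda t: tkmod.urinary_cumulative(t, spec.scenario, spec.tk),
            series, background=spec.background)

    if spec.cv > 0:
        sigma = np.sqrt(np.log1p(spec.cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma,
                              size=len(series))
    else:
        noise = np.ones(len(series))
    observed = series.with_concentrations(clean * noise)

    truth = {
        "model": spec.model,
        "seed": spec.seed,
        "cv": spec.cv,
        "background": spec.background,
        "scenario_label": spec.scenario.label,
        "window_levels": [w.level for w in spec.scenario.windows],
        "window_routes": [w.route for w in spec.scenario.windows],
        "clean_concentrations": clean.tolist(),
    }
    return observed, truth
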