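"""Coupled BaP + 3-OHBaP physiologically-based pharmacokinetic engine.

Model structure
---------------
Both chemicals share a single well-mixed blood compartment and organ
compartments for lung, adipose tissue, skin, kidney, liver and rest-of-body.
Tissues with a permeability-area coefficient (BaP: lung; 3-OHBaP: lung,
adipose, kidney) are diffusion-limited,

    dA_i/dt = PA_i (C_bl - C_i / P_i),

the others are perfusion-limited with the organ blood flow Q_i in place of
PA_i.  Pulmonary uptake of BaP is Q_alv (C_inh - C_bl / P_B): gross alveolar
intake minus exhaled back-loss through the blood:air partition.  Dermal input
is k_P * area * P_DV * C_vehicle into skin tissue during contact windows.

BaP is metabolized in the liver with a first-order clearance V_max/K_M acting
on the venous-equilibrated liver concentration C_liv/P_LV; the fraction
f_3OHBaP of that flux forms 3-OHBaP in the liver, the remainder leaves as
other metabolites.  BaP undergoes biliary transfer K_B to the gut lumen and
fecal excretion K_F.  3-OHBaP undergoes fast biliary transfer K_b, fecal
excretion K_f, entero-hepatic reabsorption K_gil, hepatic further metabolism
(its own V_max/K_M), renal transfer K_kb from kidney tissue to the bladder
and bladder emptying K_bu into cumulative urine.

Because every transfer is first-order and inputs are piecewise-constant, the
state equation is x' = A x + b(t) with constant A and segment-wise constant
b.  ``simulate`` therefore propagates the exact solution with the matrix
exponential of the augmented system segment by segment; accuracy is set by
machine precision, not a step-size tolerance.  ``derivatives`` exposes the
raw vector field for adaptive ODE cross-checks.

Amounts are nmol; time is hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .exposure import ExposureScenario, air_ngm3_to_fmolml
from .params import PBPKParameterSet, default_human_pbpk_params

__all__ = [
    "STATE_NAMES",
    "PBPKModel",
    "Trajectory",
    "derivatives",
    "simulate",
    "mass_balance_report",
]

# state vector layout -------------------------------------------------------
P_BL, P_LU, P_AT, P_SK, P_KI, P_LI, P_RB, P_GI, P_FEC = range(9)
(M_BL, M_LU, M_AT, M_SK, M_KI, M_LI, M_RB, M_GI, M_BLAD, M_UR, M_FEC) = range(9, 20)
ABS_INH, ABS_DER, ABS_ORAL, MET_P, OTH_M, EXHALED = range(20, 26)
N_STATES = 26

STATE_NAMES = (
    "bap_blood", "bap_lung", "bap_adipose", "bap_skin", "bap_kidney",
    "bap_liver", "bap_rest", "bap_gi_lumen", "bap_feces",
    "ohbap_blood", "ohbap_lung", "ohbap_adipose", "ohbap_skin", "ohbap_kidney",
    "ohbap_liver", "ohbap_rest", "ohbap_gi_lumen", "ohbap_bladder",
    "ohbap_urine", "ohbap_feces",
    "absorbed_inhalation", "absorbed_dermal", "absorbed_oral",
    "bap_metabolized", "ohbap_other_metabolites", "bap_exhaled",
)

_FMOL_TO_NMOL = 1e-6


def _exchange(a: np.ndarray, i_tissue: int, i_blood: int,
              coeff: float, v_tissue: float, v_blood: float, partition: float) -> None:
    """Add a reversible blood<->tissue exchange with transfer coefficient (mL/h)."""
    a[i_tissue, i_blood] += coeff / v_blood
    a[i_tissue, i_tissue] -= coeff / (v_tissue * partition)
    a[i_blood, i_blood] -= coeff / v_blood
    a[i_blood, i_tissue] += coeff / (v_tissue * partition)


def build_matrix(params: PBPKParameterSet) -> np.ndarray:
    """Constant system matrix A (1/h) of the coupled linear vector field."""
    ph = params.physiology
    bap, met = params.bap, params.ohbap
    a = np.zeros((N_STATES, N_STATES))

    # ---- BaP ----
    _exchange(a, P_LU, P_BL, bap.pa_lung, ph.v_lung, ph.v_blood, bap.p_lung)
    _exchange(a, P_AT, P_BL, ph.q_adipose, ph.v_adipose, ph.v_blood, bap.p_adipose)
    _exchange(a, P_SK, P_BL, ph.q_skin, ph.v_skin, ph.v_blood, bap.p_skin)
    _exchange(a, P_KI, P_BL, ph.q_kidney, ph.v_kidney, ph.v_blood, bap.p_kidney)
    _exchange(a, P_LI, P_BL, ph.q_liver, ph.v_liver, ph.v_blood, bap.p_liver)
    _exchange(a, P_RB, P_BL, ph.q_rest, ph.v_rest, ph.v_blood, bap.p_rest)
    # exhaled back-loss through the alveolar interface
    k_exh = ph.alveolar_ventilation / (bap.p_blood_air * ph.v_blood)
    a[P_BL, P_BL] -= k_exh
    a[EXHALED, P_BL] += k_exh
    # hepatic metabolism on venous-equilibrated liver concentration
    k_met = bap.clearance / (ph.v_liver * bap.p_liver)
    a[P_LI, P_LI] -= k_met
    a[MET_P, P_LI] += k_met
    a[M_LI, P_LI] += bap.f_metabolite * k_met  # 3-OHBaP formation in liver
    # biliary transfer and fecal excretion
    a[P_LI, P_LI] -= bap.k_bile
    a[P_GI, P_LI] += bap.k_bile
    a[P_GI, P_GI] -= bap.k_feces + bap.k_oral
    a[P_FEC, P_GI] += bap.k_feces
    a[P_LI, P_GI] += bap.k_oral  # oral absorption (default 0)

    # ---- 3-OHBaP ----
    _exchange(a, M_LU, M_BL, met.pa_lung, ph.v_lung, ph.v_blood, met.p_lung)
    _exchange(a, M_AT, M_BL, met.pa_adipose, ph.v_adipose, ph.v_blood, met.p_adipose)
    _exchange(a, M_SK, M_BL, ph.q_skin, ph.v_skin, ph.v_blood, met.p_skin)
    _exchange(a, M_KI, M_BL, met.pa_kidney, ph.v_kidney, ph.v_blood, met.p_kidney)
    _exchange(a, M_LI, M_BL, ph.q_liver, ph.v_liver, ph.v_blood, met.p_liver)
    _exchange(a, M_RB, M_BL, ph.q_rest, ph.v_rest, ph.v_blood, met.p_rest)
    # hepatic loss to further metabolites
    k_met_m = met.clearance / (ph.v_liver * met.p_liver)
    a[M_LI, M_LI] -= k_met_m
    a[OTH_M, M_LI] += k_met_m
    # biliary transfer, fecal excretion, entero-hepatic reabsorption
    a[M_LI, M_LI] -= met.k_bile
    a[M_GI, M_LI] += met.k_bile
    a[M_GI, M_GI] -= met.k_feces + met.k_gut_reabsorption
    a[M_FEC, M_GI] += met.k_feces
    a[M_LI, M_GI] += met.k_gut_reabsorption
    # renal path: kidney tissue -> bladder -> urine
    a[M_KI, M_KI] -= met.k_kidney_bladder
    a[M_BLAD, M_KI] += met.k_kidney_bladder
    a[M_BLAD, M_BLAD] -= met.k_bladder_urine
    a[M_UR, M_BLAD] += met.k_bladder_urine
    return a


def input_vector(params: PBPKParameterSet,
                 inh_ngm3: float, dermal_fmolml: float,
                 oral_nmol_h: float) -> np.ndarray:
    """Constant input vector b (nmol/h) for one exposure segment."""
    ph = params.physiology
    bap = params.bap
    b = np.zeros(N_STATES)
    if inh_ngm3:
        rate = (air_ngm3_to_fmolml(inh_ngm3) * ph.alveolar_ventilation
                * _FMOL_TO_NMOL)
        b[P_BL] += rate
        b[ABS_INH] += rate
    if dermal_fmolml:
        rate = (bap.k_p * ph.skin_area_cm2 * bap.p_vehicle * dermal_fmolml
                * _FMOL_TO_NMOL)
        b[P_SK] += rate
        b[ABS_DER] += rate
    if oral_nmol_h:
        b[P_GI] += oral_nmol_h
        b[ABS_ORAL] += oral_nmol_h
    return b


class PBPKModel:
    """Parameterized model instance with its precomputed system matrix."""

    def __init__(self, params: PBPKParameterSet | None = None) -> None:
        self.params = params or default_human_pbpk_params()
        self.A = build_matrix(self.params)

    def _segment_input(self, scenario: ExposureScenario, t0: float, t1: float
                       ) -> np.ndarray:
        tm = 0.5 * (t0 + t1)
        inh = scenario.level_at(tm, "inhalation")
        derm = scenario.level_at(tm, "dermal")
        oral_rate = sum(w.level / w.duration for w in scenario.by_route("oral")
                        if w.start <= tm < w.end)
        return input_vector(self.params, inh, derm, oral_rate)

    def derivatives(self, t: float, state: np.ndarray,
                    scenario: ExposureScenario) -> np.ndarray:
        """Raw vector field dx/dt at time t (for external ODE integration)."""
        state = np.asarray(state, dtype=float)
        if state.shape != (N_STATES,):
            raise ValueError(f"state must have shape ({N_STATES},)")
        if not np.all(np.isfinite(state)):
            raise FloatingPointError("non-finite state passed to derivatives")
        if np.min(state) < -1e-6:
            raise FloatingPointError(
                f"negative state amount {np.min(state):.3e} nmol: integrator failure")
        b = self._segment_input(scenario, t, t)
        return self.A @ state + b

    def simulate(self, scenario: ExposureScenario,
                 grid: np.ndarray | None = None, dt: float = 0.1,
                 initial_state: np.ndarray | None = None) -> "Trajectory":
        """Exact piecewise propagation of the linear system over the scenario.

        ``grid`` defaults to a regular grid of step ``dt`` over [0, horizon];
        window edges are always inserted so segment inputs are exact.
        """
        if grid is None:
            grid = np.arange(0.0, scenario.horizon + dt / 2, dt)
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing with >= 2 points")
        if grid[0] < 0 or grid[-1] > scenario.horizon + 1e-9:
            raise ValueError("grid must lie within [0, horizon]")

        times = np.union1d(np.round(grid, 12),
                           np.round(scenario.breakpoints(), 12))
        times = times[(times >= grid[0] - 1e-12) & (times <= grid[-1] + 1e-12)]
        n = len(times)
        states = np.zeros((n, N_STATES))
        if initial_state is not None:
            states[0] = np.asarray(initial_state, dtype=float)

        # cache the augmented transition per distinct step length
        cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        aug = np.zeros((2 * N_STATES, 2 * N_STATES))
        aug[:N_STATES, :N_STATES] = self.A
        aug[:N_STATES, N_STATES:] = np.eye(N_STATES)

        x = states[0].copy()
        for k in range(n - 1):
            h = times[k + 1] - times[k]
            key = round(float(h), 12)
            if key not in cache:
                e = expm(aug * h)
                cache[key] = (e[:N_STATES, :N_STATES], e[:N_STATES, N_STATES:])
            phi, s = cache[key]
            b = self._segment_input(scenario, times[k], times[k + 1])
            x = phi @ x + s @ b
            states[k + 1] = x

        undershoot = float(np.min(states))
        if undershoot < -1e-9:
            raise FloatingPointError(
                f"negative amounts beyond tolerance: min={undershoot:.3e} nmol")
        return Trajectory(times=times, states=states, params=self.params,
                          scenario=scenario)


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course: per-compartment amounts (nmol) on a time grid (h)."""

    times: np.ndarray
    states: np.ndarray
    params: PBPKParameterSet
    scenario: ExposureScenario

    def series(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def urine_cumulative(self, t: float | np.ndarray | None = None) -> np.ndarray:
        """Cumulative urinary 3-OHBaP (nmol), optionally interpolated at t."""
        u = self.states[:, M_UR]
        if t is None:
            return u
        return np.interp(np.asarray(t, dtype=float), self.times, u)

    def urinary_rate(self, t: float | np.ndarray | None = None) -> np.ndarray:
        """Urinary 3-OHBaP excretion rate K_bu * A_bladder (nmol/h)."""
        rate = self.params.ohbap.k_bladder_urine * self.states[:, M_BLAD]
        if t is None:
            return rate
        return np.interp(np.asarray(t, dtype=float), self.times, rate)

    def absorbed(self) -> np.ndarray:
        return self.states[:, [ABS_INH, ABS_DER, ABS_ORAL]].sum(axis=1)

    def mass_balance(self) -> np.ndarray:
        """Per-point |absorbed - accounted| / max(absorbed, eps)."""
        s = self.states
        f = self.params.bap.f_metabolite
        accounted = (
            s[:, P_BL:P_FEC + 1].sum(axis=1)       # all BaP pools incl. GI, feces
            + s[:, EXHALED]
            + (1.0 - f) * s[:, MET_P]              # other BaP metabolites
            + s[:, M_BL:M_FEC + 1].sum(axis=1)     # all 3-OHBaP pools incl. urine
            + s[:, OTH_M]
        )
        absorbed = self.absorbed()
        return np.abs(absorbed - accounted) / np.maximum(absorbed, 1e-300)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: time_h, compartment, amount_nmol."""
        n = len(self.times)
        return pd.DataFrame({
            "time_h": np.repeat(self.times, N_STATES),
            "compartment": np.tile(STATE_NAMES, n),
            "amount_nmol": self.states.reshape(-1),
        })


def derivatives(t: float, state: np.ndarray, params: PBPKParameterSet,
                scenario: ExposureScenario) -> np.ndarray:
    """Vector field of the coupled system (module-level convenience)."""
    return PBPKModel(params).derivatives(t, state, scenario)


def simulate(params: PBPKParameterSet, scenario: ExposureScenario,
             grid: np.ndarray | None = None, dt: float = 0.1) -> Trajectory:
    """Simulate the scenario with the exact linear propagator."""
    return PBPKModel(params).simulate(scenario, grid=grid, dt=dt)


def mass_balance_report(trajectory: Trajectory) -> float:
    """Maximum relative mass-balance discrepancy along the trajectory."""
    return float(trajectory.mass_balance().max())
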