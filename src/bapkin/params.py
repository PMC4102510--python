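"""Model parameters, species physiology and rat-to-human scaling rules.

The human parameter defaults are the published values for the coupled
benzo(a)pyrene (BaP) / 3-hydroxybenzo(a)pyrene (3-OHBaP) PBPK model and the
companion one-compartment toxicokinetic (TK) model.  Rat values are optional
user inputs: when absent, the human defaults are loaded directly rather than
derived through the interspecies scaling rules.

Units follow the source conventions throughout: volumes mL, flows and
clearances mL/h, first-order rates 1/h, skin permeability cm/h, partition
coefficients dimensionless.  Amounts elsewhere in the package are nmol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = [
    "MW_BAP",
    "MW_3OHBAP",
    "MW_CREATININE",
    "SpeciesPhysiology",
    "ChemicalPBPKParams",
    "PBPKParameterSet",
    "TKParams",
    "ScalingConstants",
    "SensitivityRanges",
    "human_physiology",
    "rat_physiology",
    "default_human_pbpk_params",
    "default_tk_params",
    "default_scaling_constants",
    "default_sensitivity_ranges",
    "morimoto_skin_factor",
    "scale_rate_by_gfr",
    "scale_rate_by_bileflow",
    "scale_metabolic_clearance",
    "scale_skin_permeability",
    "load_params",
    "save_params",
]

# Molar masses (g/mol), standard chemistry.
MW_BAP = 252.31
MW_3OHBAP = 268.31
MW_CREATININE = 113.12


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesPhysiology:
    """Organ volumes, blood flows and exchange surfaces for one species.

    Volumes in mL, flows in mL/h, skin area in cm², glomerular filtration in
    mL/min, bile flow in mL/day.
    """

    species: str
    v_blood: float
    v_lung: float
    v_adipose: float
    v_skin: float
    v_kidney: float
    v_liver: float
    v_rest: float
    cardiac_output: float
    q_adipose: float
    q_skin: float
    q_kidney: float
    q_liver: float
    q_rest: float
    alveolar_ventilation: float
    skin_area_cm2: float
    gfr_ml_min: float
    bile_flow_ml_day: float

    def __post_init__(self) -> None:
        if self.species not in ("rat", "human"):
            raise ValueError(f"species must be 'rat' or 'human', got {self.species!r}")
        for f in fields(self):
            if f.name == "species":
                continue
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")
        organ_flow = (
            self.q_adipose + self.q_skin + self.q_kidney + self.q_liver + self.q_rest
        )
        if organ_flow > self.cardiac_output * (1 + 1e-9):
            raise ValueError(
                f"organ blood flows ({organ_flow:g} mL/h) exceed cardiac output "
                f"({self.cardiac_output:g} mL/h)"
            )


def human_physiology() -> SpeciesPhysiology:
    """Reference 70-kg human physiology.

    Volumes and flow fractions are standard reference-man values; the
    alveolar ventilation of 7.98 L/min is the worker value used for
    occupational exposure simulation.
    """
    qc = 336_000.0  # 5.6 L/min cardiac output
    return SpeciesPhysiology(
        species="human",
        v_blood=5200.0,
        v_lung=532.0,
        v_adipose=14_900.0,
        v_skin=2600.0,
        v_kidney=310.0,
        v_liver=1820.0,
        v_rest=44_638.0,
        cardiac_output=qc,
        q_adipose=0.050 * qc,
        q_skin=0.058 * qc,
        q_kidney=0.175 * qc,
        q_liver=0.250 * qc,  # total splanchnic (arterial + portal)
        q_rest=qc - (0.050 + 0.058 + 0.175 + 0.250) * qc,
        alveolar_ventilation=478_800.0,  # 7.98 L/min
        skin_area_cm2=18_000.0,  # whole-body exposed area assumption
        gfr_ml_min=125.0,
        bile_flow_ml_day=350.0,
    )


def rat_physiology() -> SpeciesPhysiology:
    """Reference 0.25-kg rat physiology (optional input for scaling demos)."""
    qc = 4980.0  # 83 mL/min
    return SpeciesPhysiology(
        species="rat",
        v_blood=16.0,
        v_lung=1.5,
        v_adipose=17.5,
        v_skin=40.0,
        v_kidney=2.0,
        v_liver=10.0,
        v_rest=163.0,
        cardiac_output=qc,
        q_adipose=0.070 * qc,
        q_skin=0.058 * qc,
        q_kidney=0.141 * qc,
        q_liver=0.183 * qc,
        q_rest=qc - (0.070 + 0.058 + 0.141 + 0.183) * qc,
        alveolar_ventilation=5100.0,
        skin_area_cm2=40.0,
        gfr_ml_min=1.31,
        bile_flow_ml_day=22.5,
    )


# ---------------------------------------------------------------------------
# chemical-specific PBPK parameters
# ---------------------------------------------------------------------------

# fields that must be present (not None) per chemical
_REQUIRED = {
    "bap": {
        "p_lung", "p_adipose", "p_skin", "p_kidney", "p_liver", "p_rest",
        "pa_lung", "clearance", "f_metabolite", "k_bile", "k_feces",
        "k_p", "p_vehicle", "p_blood_air",
    },
    "3ohbap": {
        "p_lung", "p_adipose", "p_skin", "p_kidney", "p_liver", "p_rest",
        "pa_lung", "pa_adipose", "pa_kidney", "clearance", "k_bile",
        "k_kidney_bladder", "k_bladder_urine", "k_feces", "k_gut_reabsorption",
    },
}

_OPTIONAL = {"bap": {"k_oral"}, "3ohbap": set()}


@dataclass(frozen=True)
class ChemicalPBPKParams:
    """PBPK parameters for one chemical (BaP or 3-OHBaP).

    ``None`` marks a parameter that does not exist for that chemical (for
    example tissue permeabilities other than lung exist only for 3-OHBaP, the
    absorption constants only for BaP).
    """

    chemical: str  # "bap" | "3ohbap"
    # tissue:blood partition coefficients (dimensionless)
    p_lung: float
    p_adipose: float
    p_skin: float
    p_kidney: float
    p_liver: float
    p_rest: float
    # permeability-area coefficients (mL/h); None => perfusion-limited
    pa_lung: float | None = None
    pa_adipose: float | None = None
    pa_kidney: float | None = None
    # metabolic clearance V_max/K_M (mL/h) and metabolite yield
    clearance: float | None = None
    f_metabolite: float | None = None  # fraction of BaP metabolism yielding 3-OHBaP
    # elimination rate constants (1/h)
    k_bile: float | None = None
    k_kidney_bladder: float | None = None
    k_bladder_urine: float | None = None
    k_feces: float | None = None
    k_gut_reabsorption: float | None = None
    # absorption constants (BaP only)
    k_p: float | None = None          # skin permeability, cm/h
    p_vehicle: float | None = None    # vehicle:skin partition, dimensionless
    p_blood_air: float | None = None  # blood:air partition, dimensionless
    # oral absorption from GI lumen, 1/h (not in the published set; default 0)
    k_oral: float = 0.0

    def __post_init__(self) -> None:
        if self.chemical not in _REQUIRED:
            raise ValueError(f"chemical must be 'bap' or '3ohbap', got {self.chemical!r}")
        required = _REQUIRED[self.chemical]
        for f in fields(self):
            if f.name in ("chemical", "k_oral"):
                continue
            v = getattr(self, f.name)
            if f.name in required:
                if v is None or v <= 0:
                    raise ValueError(
                        f"{self.chemical}: {f.name} must be present and strictly "
                        f"positive, got {v!r}"
                    )
            elif v is not None:
                raise ValueError(
                    f"{self.chemical}: {f.name} is not part of this chemical's "
                    f"parameter set (got {v!r})"
                )
        if self.k_oral < 0:
            raise ValueError("k_oral must be >= 0")
        if self.f_metabolite is not None and not (0.0 < self.f_metabolite < 1.0):
            raise ValueError(f"f_metabolite must lie in (0, 1), got {self.f_metabolite}")


@dataclass(frozen=True)
class PBPKParameterSet:
    """Complete parameterization of the coupled BaP + 3-OHBaP PBPK model."""

    bap: ChemicalPBPKParams
    ohbap: ChemicalPBPKParams
    physiology: SpeciesPhysiology = field(default_factory=human_physiology)

    def __post_init__(self) -> None:
        if self.bap.chemical != "bap" or self.ohbap.chemical != "3ohbap":
            raise ValueError("PBPKParameterSet requires (bap, 3ohbap) in that order")


def default_human_pbpk_params() -> PBPKParameterSet:
    """Published human parameter values for the coupled PBPK model."""
    bap = ChemicalPBPKParams(
        chemical="bap",
        p_lung=2670.00,
        p_adipose=65.90,
        p_skin=1.87,
        p_kidney=2.08,
        p_liver=12.90,
        p_rest=10.00,
        pa_lung=80.70,
        clearance=951.69e3,
        f_metabolite=0.185,
        k_bile=0.338,
        k_feces=0.334,
        k_p=0.00132,
        p_vehicle=1.0,
        p_blood_air=2.04,
    )
    ohbap = ChemicalPBPKParams(
        chemical="3ohbap",
        p_lung=2.92,
        p_adipose=1.42,
        p_skin=0.80,
        p_kidney=40.40,
        p_liver=1.83,
        p_rest=1.00,
        pa_lung=0.20,
        pa_adipose=0.711,
        pa_kidney=12.90,
        clearance=37.13e3,
        k_bile=663.80,
        k_kidney_bladder=60.40,
        k_bladder_urine=0.102,
        k_feces=0.173,
        k_gut_reabsorption=0.00693,
    )
    return PBPKParameterSet(bap=bap, ohbap=ohbap)


# ---------------------------------------------------------------------------
# one-compartment toxicokinetic parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TKParams:
    """One-compartment model: route absorption rates, elimination, urinary yields.

    ``ka_oral`` has no published value; it defaults to ``ka_inh`` and should be
    considered unsupported.  ``alpha_oral`` is unconfigured (None) by default.
    """

    ka_inh: float = 48.35e-3   # 1/h
    ka_der: float = 61.81e-3   # 1/h
    k_b: float = 198.26e-3     # 1/h, elimination from body
    alpha_inh: float = 3.99e-2
    alpha_der: float = 1.64e-2
    ka_oral: float | None = None
    alpha_oral: float | None = None

    def __post_init__(self) -> None:
        for name in ("ka_inh", "ka_der", "k_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("alpha_inh", "alpha_der"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.ka_oral is None:
            object.__setattr__(self, "ka_oral", self.ka_inh)
        if self.alpha_oral is not None and not (0.0 < self.alpha_oral < 1.0):
            raise ValueError("alpha_oral must lie in (0, 1) when set")

    def ka(self, route: str) -> float:
        return {"inhalation": self.ka_inh, "dermal": self.ka_der,
                "oral": self.ka_oral}[route]

    def alpha(self, route: str) -> float:
        a = {"inhalation": self.alpha_inh, "dermal": self.alpha_der,
             "oral": self.alpha_oral}[route]
        if a is None:
            raise ValueError("alpha_oral is not configured")
        return a


def default_tk_params() -> TKParams:
    return TKParams()


# ---------------------------------------------------------------------------
# interspecies scaling
# ---------------------------------------------------------------------------

def morimoto_skin_factor() -> float:
    """Human/rat skin permeability scaling factor f_S (dimensionless).

    Relates permeability coefficients in human and hairless-rat skin through
    the octanol-water partition coefficient (here 10^0.79... ~ 6.19 enters as
    printed):

        f_S = (1.17e-7 * 6.19**0.751 + 2.73e-8)
              / (14.78e-7 * 6.19**0.589 + 8.33e-8)
    """
    num = 1.17e-7 * 6.19**0.751 + 2.73e-8
    den = 14.78e-7 * 6.19**0.589 + 8.33e-8
    return num / den


@dataclass(frozen=True)
class ScalingConstants:
    """Rat-to-human extrapolation constants.

    ``c_rat_human`` is the fitted ratio between human and rat metabolism
    rates.  ``adipose_ratio_rat`` is (V_AT/Q_AT) for the rat (h) and
    ``adipose_turnover_human`` is (Q_AT/V_AT) for the human (1/h); their
    product enters the TK elimination-rate extrapolation.
    """

    c_rat_human: float = 1020.03
    gfr_ratio: float = 125.0 / 1.31
    bile_ratio: float = 350.0 / 22.5
    f_s: float = field(default_factory=morimoto_skin_factor)
    adipose_ratio_rat: float = 17.5 / 348.6        # (V_AT/Q_AT)_rat, h
    adipose_turnover_human: float = 16_800.0 / 14_900.0  # (Q_AT/V_AT)_human, 1/h

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")
        if not self.f_s < 1.0:
            raise ValueError("f_s must be < 1")


def default_scaling_constants() -> ScalingConstants:
    return ScalingConstants()


def _check_nonneg(x: float, what: str) -> None:
    if x < 0:
        raise ValueError(f"{what} must be >= 0, got {x}")


def scale_rate_by_gfr(rat_rate: float) -> float:
    """Scale a renal-filtration-linked rate by the human/rat GFR ratio (125/1.31)."""
    _check_nonneg(rat_rate, "rat_rate")
    return rat_rate * (125.0 / 1.31)


def scale_rate_by_bileflow(rat_rate: float) -> float:
    """Scale a biliary-excretion-linked rate by the human/rat bile flow ratio (350/22.5)."""
    _check_nonneg(rat_rate, "rat_rate")
    return rat_rate * (350.0 / 22.5)


def scale_metabolic_clearance(rat_vmax_km: float, c: float) -> float:
    """Scale a rat metabolic clearance (mL/h) by the fitted constant C_rat-human."""
    if rat_vmax_km <= 0 or c <= 0:
        raise ValueError("rat_vmax_km and c must be strictly positive")
    return c * rat_vmax_km


def scale_skin_permeability(rat_k_p: float, f_s: float | None = None) -> float:
    """Scale a rat skin permeability coefficient (cm/h) by the Morimoto factor."""
    _check_nonneg(rat_k_p, "rat_k_p")
    return rat_k_p * (morimoto_skin_factor() if f_s is None else f_s)


def scale_tk_elimination(rat_k_b: float,
                         constants: ScalingConstants | None = None) -> float:
    """Rat-to-human extrapolation of the TK whole-body elimination rate k_b.

    k_b,human = (V_AT/Q_AT)_rat * (Q_AT/V_AT)_human * (125/1.31)
                * C_rat-human * k_b,rat
    """
    _check_nonneg(rat_k_b, "rat_k_b")
    c = constants or ScalingConstants()
    return (c.adipose_ratio_rat * c.adipose_turnover_human * c.gfr_ratio
            * c.c_rat_human * rat_k_b)


# ---------------------------------------------------------------------------
# Monte Carlo sensitivity ranges
# ---------------------------------------------------------------------------

# symmetric relative ranges used in the published Monte Carlo stability runs
_DEFAULT_RANGES = {
    ("bap", "p_lung"): 0.396,
    ("bap", "p_adipose"): 0.396,
    ("bap", "p_skin"): 0.396,
    ("bap", "p_kidney"): 0.396,
    ("bap", "p_liver"): 0.396,
    ("bap", "p_rest"): 0.296,
    ("bap", "pa_lung"): 0.396,
    ("bap", "clearance"): 0.38,
    ("bap", "f_metabolite"): 0.040,
    ("bap", "k_bile"): 0.396,
    ("bap", "k_feces"): 0.396,
    ("bap", "k_p"): 0.396,
    ("bap", "p_vehicle"): 0.396,
    ("bap", "p_blood_air"): 0.396,
    ("3ohbap", "p_lung"): 0.396,
    ("3ohbap", "p_adipose"): 0.396,
    ("3ohbap", "p_skin"): 0.396,
    ("3ohbap", "p_kidney"): 0.396,
    ("3ohbap", "p_liver"): 0.396,
    ("3ohbap", "p_rest"): 0.396,
    ("3ohbap", "pa_lung"): 0.396,
    ("3ohbap", "pa_adipose"): 0.396,
    ("3ohbap", "pa_kidney"): 0.396,
    ("3ohbap", "clearance"): 0.048,
    ("3ohbap", "k_bile"): 0.396,
    ("3ohbap", "k_kidney_bladder"): 0.046,
    ("3ohbap", "k_bladder_urine"): 0.12,
    ("3ohbap", "k_feces"): 0.396,
    ("3ohbap", "k_gut_reabsorption"): 0.396,
}


@dataclass(frozen=True)
class SensitivityRanges:
    """Per-parameter symmetric relative perturbation ranges, fractions in [0, 1)."""

    ranges: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES))

    def __post_init__(self) -> None:
        for key, r in self.ranges.items():
            if not (0.0 <= r < 1.0):
                raise ValueError(f"range for {key} must lie in [0, 1), got {r}")

    def get(self, chemical: str, name: str) -> float:
        return self.ranges.get((chemical, name), 0.0)

    def scaled(self, factor: float) -> "SensitivityRanges":
        return SensitivityRanges({k: v * factor for k, v in self.ranges.items()})

    def subset(self, keys) -> "SensitivityRanges":
        keys = set(keys)
        return SensitivityRanges({k: v for k, v in self.ranges.items() if k in keys})


def default_sensitivity_ranges() -> SensitivityRanges:
    return SensitivityRanges()


# ---------------------------------------------------------------------------
# parameter file IO (symbol names as printed)
# ---------------------------------------------------------------------------

# Table-symbol <-> field maps per chemical
_SYMBOLS_BAP = {
    "P_LUA": "p_lung", "P_ATV": "p_adipose", "P_SV": "p_skin", "P_KV": "p_kidney",
    "P_LV": "p_liver", "P_RV": "p_rest", "PA_LU": "pa_lung",
    "Vmax_KM": "clearance", "f_3OHBaP": "f_metabolite",
    "K_B": "k_bile", "K_F": "k_feces",
    "k_P": "k_p", "P_DV": "p_vehicle", "P_B": "p_blood_air",
    "k_oral": "k_oral",
}
_SYMBOLS_OHBAP = {
    "P_lua": "p_lung", "P_atv": "p_adipose", "P_sv": "p_skin", "P_kv": "p_kidney",
    "P_lv": "p_liver", "P_rv": "p_rest", "PA_lu": "pa_lung",
    "PA_at": "pa_adipose", "PA_k": "pa_kidney",
    "Vmax_KM": "clearance", "K_b": "k_bile",
    "K_kb": "k_kidney_bladder", "K_kbr": "k_kidney_bladder",  # synonyms
    "K_bu": "k_bladder_urine", "K_f": "k_feces", "K_gil": "k_gut_reabsorption",
}


def _chem_to_dict(p: ChemicalPBPKParams) -> dict:
    table = _SYMBOLS_BAP if p.chemical == "bap" else _SYMBOLS_OHBAP
    out = {}
    for sym, attr in table.items():
        if sym == "K_kbr":  # write canonical name only
            continue
        v = getattr(p, attr)
        if v is not None:
            out[sym] = float(v)
    return out


def _chem_from_dict(chemical: str, d: dict) -> ChemicalPBPKParams:
    table = _SYMBOLS_BAP if chemical == "bap" else _SYMBOLS_OHBAP
    kwargs: dict = {"chemical": chemical}
    for sym, value in d.items():
        if sym not in table:
            raise ValueError(f"unknown parameter symbol {sym!r} for {chemical}")
        kwargs[table[sym]] = float(value)
    return ChemicalPBPKParams(**kwargs)


def save_params(params: PBPKParameterSet, path: str | Path) -> None:
    """Write a parameter set as YAML or JSON (by extension), symbols as printed."""
    doc = {
        "species": params.physiology.species,
        "BaP": _chem_to_dict(params.bap),
        "3-OHBaP": _chem_to_dict(params.ohbap),
    }
    path = Path(path)
    text = (json.dumps(doc, indent=2) if path.suffix == ".json"
            else yaml.safe_dump(doc, sort_keys=False))
    path.write_text(text)


def load_params(path: str | Path,
                physiology: SpeciesPhysiology | None = None) -> PBPKParameterSet:
    """Read a parameter file; validates per-chemical symbol presence patterns."""
    path = Path(path)
    raw = path.read_text()
    doc = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    if not isinstance(doc, dict) or "BaP" not in doc or "3-OHBaP" not in doc:
        raise ValueError(f"{path}: expected mapping with 'BaP' and '3-OHBaP' sections")
    species = doc.get("species", "human")
    if physiology is None:
        physiology = human_physiology() if species == "human" else rat_physiology()
    return PBPKParameterSet(
        bap=_chem_from_dict("bap", doc["BaP"]),
        ohbap=_chem_from_dict("3ohbap", doc["3-OHBaP"]),
        physiology=physiology,
    )
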