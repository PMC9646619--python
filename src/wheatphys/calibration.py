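"""Calibration defaults for the synthetic glasshouse experiment.

One place for every number the generator uses: per-cultivar photosynthetic
parameter sets, treatment effect multipliers, and trait baselines.  Each
multiplier encodes one measured effect from the glasshouse study the
generator emulates (the comment states which); multipliers of exactly 1.0
mark effects reported only as significance statements without a magnitude
(unquantified) or absent effects.  Trait baselines in ``SCOUT_BASELINES``
are NOT study-reported values — the study reports relative effects, not
absolute per-plant magnitudes — they are plausible free defaults for a
well-watered glasshouse wheat plant and are documented as such.

Users can zero any effect by setting its multiplier to 1.0, or run the
fully null generator via ``null_multipliers()``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .constants import KineticConstants
from .fvcb import FvCBParameters, TempScaling

__all__ = ["CultivarCalibration", "CULTIVARS", "EFFECTS", "SCOUT_BASELINES",
           "CULTIVAR_RATIOS", "null_multipliers", "cultivar_params",
           "gm_at_temperature"]


@dataclass(frozen=True)
class CultivarCalibration:
    """Fitted temperature-response parameter set for one cultivar."""

    name: str
    Vcmax25: float   # umol m-2 s-1
    Jmax25: float    # umol m-2 s-1
    Rd25: float      # umol m-2 s-1
    gm25: float      # mol m-2 s-1 bar-1
    EaV: float       # kJ mol-1, Arrhenius Vcmax
    EaJ: float       # kJ mol-1, peaked Jmax
    deltaS_J: float  # J mol-1 K-1
    Hd_J: float      # kJ mol-1 (fixed)
    EaR: float       # kJ mol-1, Arrhenius Rd
    Q10: float       # respiration temperature coefficient
    Asat_Topt: float  # degC, parabola optimum of light-saturated A
    Asat_Aopt: float  # umol m-2 s-1, A at that optimum
    Asat_b: float     # umol m-2 s-1 degC-2, parabola curvature
    gm_Topt: float    # degC, vertex of the quadratic gm(T)
    gm_curv: float    # mol m-2 s-1 bar-1 degC-2, downward curvature of gm(T)


#: Per-cultivar parameter sets (temperature-response campaign, ambient CO2).
CULTIVARS: dict[str, CultivarCalibration] = {
    "Scout": CultivarCalibration(
        name="Scout", Vcmax25=192.7, Jmax25=187.9, Rd25=1.25, gm25=0.31,
        EaV=43.3, EaJ=37.7, deltaS_J=648.3, Hd_J=200.0, EaR=30.9, Q10=1.51,
        Asat_Topt=23.4, Asat_Aopt=24.6, Asat_b=0.05,
        gm_Topt=27.9, gm_curv=5e-4),
    "Yitpi": CultivarCalibration(
        name="Yitpi", Vcmax25=198.4, Jmax25=186.1, Rd25=1.25, gm25=0.25,
        EaV=46.4, EaJ=41.1, deltaS_J=647.0, Hd_J=200.0, EaR=33.2, Q10=1.56,
        Asat_Topt=23.4, Asat_Aopt=22.0, Asat_b=0.05,
        gm_Topt=32.5, gm_curv=5e-4),
}
# Asat_b (parabola curvature) and gm_curv are not reported; they are free
# defaults at a magnitude that keeps the response realistic over 15-35 degC.


def cultivar_params(name: str,
                    kinetics: KineticConstants | None = None) -> FvCBParameters:
    """FvCB parameter object (with temperature scaling) for one cultivar."""
    c = CULTIVARS[name]
    return FvCBParameters(
        Vcmax25=c.Vcmax25, Jmax25=c.Jmax25, Rd25=c.Rd25, gm25=c.gm25,
        kinetics=kinetics or KineticConstants(),
        scal_V=TempScaling(Ea=c.EaV),
        scal_J=TempScaling(Ea=c.EaJ, Hd=c.Hd_J, deltaS=c.deltaS_J, peaked=True),
        scal_R=TempScaling(Ea=c.EaR))


def gm_at_temperature(name: str, tleaf_c: float) -> float:
    """Quadratic mesophyll conductance profile pinned to gm25 at 25 degC.

    gm(T) = gm_vertex - curv*(T - Topt)^2 with the vertex height chosen so
    that gm(25) equals the cultivar's gm at 25 degC exactly.
    """
    c = CULTIVARS[name]
    vertex = c.gm25 + c.gm_curv * (25.0 - c.gm_Topt) ** 2
    return vertex - c.gm_curv * (tleaf_c - c.gm_Topt) ** 2


#: Treatment effect multipliers.  Keys ending in a cultivar name are
#: cultivar-specific; "unquantified" effects default to 1.0.
EFFECTS: dict[str, float] = {
    # eCO2-grown plants, A measured at growth CO2: +21% stimulation.
    "agrowth_eco2": 1.21,
    # eCO2-grown plants, A measured at the common 400 umol mol-1 reference:
    # -12% downregulation (strongest at mid-season).
    "acommon_eco2": 0.88,
    # stomatal conductance under eCO2: -10%.
    "gs_eco2": 0.90,
    # photosynthetic capacity downregulation under eCO2: Vcmax -14% (Scout),
    # -15% (Yitpi); no effect on Jmax.
    "vcmax_eco2_Scout": 0.86,
    "vcmax_eco2_Yitpi": 0.85,
    "jmax_eco2": 1.00,
    # biomass stimulation by eCO2 at anthesis (control plants): +9% Scout,
    # +29% Yitpi.
    "biomass_eco2_Scout": 1.09,
    "biomass_eco2_Yitpi": 1.29,
    # grain-number (and hence yield) stimulation by eCO2 in control plants
    # at final harvest: +64% Scout, +50% Yitpi.
    "grain_number_eco2_Scout": 1.64,
    "grain_number_eco2_Yitpi": 1.50,
    # grain N (protein via x5.7) under eCO2: -18% in Yitpi only.
    "grain_N_eco2_Scout": 1.00,
    "grain_N_eco2_Yitpi": 0.82,
    # heat stress alone was not detrimental to biomass or yield (unquantified
    # direction; neutral default).
    "biomass_hs": 1.00,
    "grain_hs": 1.00,
    # HS x eCO2 interaction: the eCO2 biomass/yield gain is absent in
    # heat-stressed plants (interaction cancels the eCO2 multiplier).
    "hs_cancels_eco2_yield_gain": 1.0,  # 1.0 = interaction active; 0.0 = off
}


def null_multipliers() -> dict[str, float]:
    """All-effects-off multiplier set for null-calibration simulations."""
    return {k: (0.0 if k == "hs_cancels_eco2_yield_gain" else 1.0)
            for k in EFFECTS}


#: Absolute Scout baselines per time point (free, non-study values at
#: plausible glasshouse magnitudes).  Grain traits exist only at final
#: harvest; leaf area / number only while canopies were measured.
SCOUT_BASELINES: dict[str, dict[str, float]] = {
    "total_dry_mass": {"T0": 0.05, "T1": 2.0, "T2": 12.0, "T3": 28.0, "T4": 35.0},  # g
    "tillers":        {"T1": 2.0, "T2": 6.0, "T3": 10.0, "T4": 10.0},
    "leaf_area":      {"T1": 80.0, "T2": 250.0, "T3": 300.0},                       # cm2
    "leaf_number":    {"T1": 8.0, "T2": 25.0, "T3": 50.0},
    "height":         {"T2": 70.0, "T3": 80.0, "T4": 80.0},                         # cm
    "grain_mass":     {"T4": 10.0},                                                 # g
    "grain_number":   {"T4": 250.0},
    "grain_size":     {"T4": 40.0},                                                 # mg
    "grain_N":        {"T4": 2.0},                                                  # %
    "fvfm":           {"T1": 0.82, "T2": 0.82, "T3": 0.82, "T4": 0.80},
    "leaf_N_pct":     {"T2": 2.0, "T3": 2.0},                                       # %
    "LMA":            {"T1": 40.0, "T2": 40.0, "T3": 40.0},                         # g m-2
    "plant_N_pct":    {"T1": 1.5, "T2": 1.5, "T3": 1.5, "T4": 1.5},                 # %
}

#: Yitpi-to-Scout trait ratios per time point (measured contrasts at
#: ambient CO2: Yitpi tillering/biomass advantage, Scout earlier height
#: and bigger grains, Yitpi's higher grain N).
CULTIVAR_RATIOS: dict[str, dict[str, float]] = {
    "total_dry_mass": {"T3": 1.42, "T4": 1.84},
    "tillers":        {"T3": 2.30, "T4": 1.88},
    "leaf_area":      {"T3": 3.54},
    "leaf_number":    {"T3": 2.28},
    "height":         {"T2": 1.0 / 1.74},
    "grain_number":   {"T4": 1.54},
    "grain_size":     {"T4": 0.76},
    "grain_N":        {"T4": 1.26},
}


def cultivar_ratio(trait: str, timepoint: str) -> float:
    return CULTIVAR_RATIOS.get(trait, {}).get(timepoint, 1.0)


def effects_copy() -> dict[str, float]:
    return copy.deepcopy(EFFECTS)
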