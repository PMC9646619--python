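"""Seeded generator for the factorial eCO2 x heat-stress glasshouse experiment.

Emulates 2 cultivars x 2 growth CO2 levels (450/650 umol mol-1) x 4
heat-stress regimes x 5 time points x n plants per cell, producing:

* single-point gas-exchange records (growth-CO2 and common-400
  measurements at 25 and 35 degC leaf temperature),
* A-Ci curves at the 8-step CO2 ladder at anthesis,
* concurrent isotope observations round-trippable by the gm estimator,
* a per-plant trait table (biomass, tillers, leaf area, grain traits,
  grain N, Fv/Fm), and
* a temperature-response campaign (parameter values at 15-35 degC).

Calibrated treatment effects enter as multiplicative factors on an
FvCB-computed cultivar baseline (see :mod:`wheatphys.calibration`), so a
zero-noise run reproduces every configured effect exactly and downstream
estimators can be validated against the configuration.  Noise is
mean-preserving multiplicative lognormal.  All randomness derives from
one master seed through per-stage streams keyed by stable labels, so
adding a stage never shifts another stage's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import calibration as cal
from .constants import DiscriminationConstants, KineticConstants
from .fvcb import (FvCBParameters, LeafEnvironment, arrhenius_scale,
                   net_assimilation, parabola_asat, q10_respiration)
from .isotope import LeafState, predict_delta_obs

__all__ = ["ExperimentConfig", "generate_design", "generate_gas_exchange",
           "generate_aci_curves", "generate_isotope_obs", "generate_traits",
           "generate_temperature_campaign", "derived_leaf_indices",
           "stage_rng"]

#: The 8-step CO2 ladder of the response-curve protocol (umol mol-1).
ACI_CO2_STEPS = (50.0, 100.0, 230.0, 330.0, 420.0, 650.0, 1200.0, 1800.0)

#: Leaf temperatures of the thermal campaign (degC).
CAMPAIGN_TEMPERATURES = (15.0, 20.0, 25.0, 30.0, 35.0)

#: Common measurement reference CO2 (umol mol-1).
COMMON_CO2 = 400.0

#: Operating intercellular-to-ambient CO2 ratio and its spread.
CI_CA_RATIO = 0.70
CI_CA_SD = 0.02

#: Fixed chamber CO2 drawdown used to encode isotope observations.
ISOTOPE_DRAWDOWN = 20.0
DELTA_REF_AIR = -8.0  # permil, delta-13C of chamber supply air

#: Measurement (instrument) noise CV as a fraction of the plant-level CV,
#: so a zero-noise config is exactly deterministic.
MEASUREMENT_CV_RATIO = 0.2

_REDRAW_LIMIT = 100


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream for one generator stage, keyed by a label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


@dataclass(frozen=True)
class ExperimentConfig:
    """Design, calibration and noise settings of one synthetic experiment."""

    seed: int
    cultivars: tuple[str, ...] = ("Scout", "Yitpi")
    co2_levels: tuple[float, float] = (450.0, 650.0)   # ambient, elevated
    hs_regimes: tuple[str, ...] = ("Control", "HS1", "HS2", "HS1+2")
    hs_daytime: dict = field(default_factory=lambda: {"HS1": 38.1, "HS2": 33.5})
    timepoints: tuple[str, ...] = ("T0", "T1", "T2", "T3", "T4")
    n_per_cell: int = 10
    noise_cv_traits: float = 0.10
    noise_cv_gas: float = 0.05
    multipliers: dict = field(default_factory=cal.effects_copy)
    #: None -> the calibrated Yitpi/Scout trait ratios; {} -> no cultivar
    #: contrast (the fully null generator).
    cultivar_ratios: dict | None = None
    kinetics: KineticConstants = field(default_factory=KineticConstants)
    isotope_consts: DiscriminationConstants = field(
        default_factory=DiscriminationConstants)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_per_cell < 2:
            raise ValueError("need at least 2 plants per cell")
        for k, v in self.multipliers.items():
            if k != "hs_cancels_eco2_yield_gain" and v <= 0:
                raise ValueError(f"multiplier {k} must be positive")

    @property
    def ambient_co2(self) -> float:
        return self.co2_levels[0]

    @property
    def elevated_co2(self) -> float:
        return self.co2_levels[1]

    def mult(self, key: str, cultivar: str | None = None) -> float:
        if cultivar is not None and f"{key}_{cultivar}" in self.multipliers:
            return self.multipliers[f"{key}_{cultivar}"]
        return self.multipliers[key]


def generate_design(config: ExperimentConfig) -> pd.DataFrame:
    """Full factorial design table minus the unharvested HS1-only x T4 cells.

    Row counts are deterministic from the config; the seed only permutes
    plant identifiers.
    """
    rows = []
    for tp in config.timepoints:
        for cv in config.cultivars:
            for co2 in config.co2_levels:
                for hs in config.hs_regimes:
                    if tp == "T4" and hs == "HS1":
                        continue  # HS1-only plants were not carried to maturity
                    for rep in range(config.n_per_cell):
                        rows.append((cv, co2, hs, tp, rep))
    df = pd.DataFrame(rows, columns=["cultivar", "co2", "hs", "timepoint", "rep"])
    rng = stage_rng(config.seed, "design-ids")
    ids = rng.permutation(len(df)) + 1
    df.insert(0, "plant_id", [f"P{int(i):05d}" for i in ids])
    return df


def _redraw_bounded(rng, draw, ok, size) -> np.ndarray:
    """Draw with rejection until ``ok`` holds everywhere (bounded retries)."""
    x = draw(size)
    for _ in range(_REDRAW_LIMIT):
        bad = ~ok(x)
        if not bad.any():
            return x
        x[bad] = draw(int(bad.sum()))
    raise RuntimeError(f"redraw limit ({_REDRAW_LIMIT}) exceeded")


def _baseline_A(config: ExperimentConfig, cultivar: str, tleaf: float,
                ci: float) -> tuple[float, float]:
    """Deterministic FvCB (net A, gross potential) for one cultivar/state."""
    params = cal.cultivar_params(cultivar, config.kinetics)
    env = LeafEnvironment(Tleaf=tleaf, PPFD=1500.0, Ci=ci)
    a, _ = net_assimilation(params, env, temp_correct=True)
    rd = arrhenius_scale(params.Rd25, params.scal_R.Ea, tleaf)
    return a, a + rd


def generate_gas_exchange(design: pd.DataFrame,
                          config: ExperimentConfig) -> pd.DataFrame:
    """Single-point gas-exchange records for every plant at T1, T2 and T3.

    Each plant is measured at its growth CO2 and at the common 400
    umol mol-1 reference, at 25 and 35 degC.  The deterministic layer is
    the cultivar's FvCB baseline at the common reference state scaled by
    the calibrated eCO2 multipliers (stimulation at growth CO2,
    downregulation at common CO2); plant-to-plant variation (CV
    ``noise_cv_gas``) multiplies the plant's whole response, and a small
    measurement noise (CV 1%) sits on top.  Draws violating Ci < Ca or
    net A above the gross FvCB potential are rejected and redrawn.
    """
    base = design[design["timepoint"].isin(["T1", "T2", "T3"])].copy()
    rng_plant = stage_rng(config.seed, "gas-plant")
    base["plant_factor"] = _lognormal_factor(rng_plant, config.noise_cv_gas,
                                             len(base))

    grid = pd.DataFrame(
        [(m, t) for m in ("growth", "common") for t in (25.0, 35.0)],
        columns=["meas_type", "Tleaf"])
    df = base.merge(grid, how="cross")

    eco2 = df["co2"] == config.elevated_co2
    df["Ca_meas"] = np.where(
        (df["meas_type"] == "growth") & eco2, config.elevated_co2, COMMON_CO2)

    # Deterministic cultivar baseline at the common reference state.
    a_base, pot = {}, {}
    for cvname in config.cultivars:
        for t in (25.0, 35.0):
            a_base[(cvname, t)], _ = _baseline_A(
                config, cvname, t, CI_CA_RATIO * COMMON_CO2)
    df["A_det"] = [a_base[(c, t)] for c, t in zip(df["cultivar"], df["Tleaf"])]

    m_growth = config.multipliers["agrowth_eco2"]
    m_common = config.multipliers["acommon_eco2"]
    df.loc[eco2 & (df["meas_type"] == "growth"), "A_det"] *= m_growth
    df.loc[eco2 & (df["meas_type"] == "common"), "A_det"] *= m_common

    # Gross potential at the actual measurement state (bounds the draws).
    for key in set(zip(df["cultivar"], df["Tleaf"], df["Ca_meas"])):
        cvname, t, ca = key
        _, p = _baseline_A(config, cvname, t, CI_CA_RATIO * ca)
        pot[key] = p
    potential = np.array([
        pot[k] * f for k, f in zip(
            zip(df["cultivar"], df["Tleaf"], df["Ca_meas"]),
            df["plant_factor"])])

    rng_meas = stage_rng(config.seed, "gas-measurement")
    meas_cv = MEASUREMENT_CV_RATIO * config.noise_cv_gas
    det = (df["A_det"] * df["plant_factor"]).to_numpy()
    # reject and redraw measurement noise that pushes net A above the
    # gross FvCB potential of the plant's own state (bounded retries)
    a = det * _lognormal_factor(rng_meas, meas_cv, len(df))
    bad = a > potential
    tries = 0
    while bad.any():
        a[bad] = det[bad] * _lognormal_factor(rng_meas, meas_cv,
                                              int(bad.sum()))
        bad = a > potential
        tries += 1
        if tries > _REDRAW_LIMIT:
            raise RuntimeError("gas-exchange redraw limit exceeded")
    df["A"] = a

    rng_ci = stage_rng(config.seed, "gas-ci")
    ratio = _redraw_bounded(
        rng_ci,
        lambda n: rng_ci.normal(CI_CA_RATIO, CI_CA_SD, n),
        lambda r: (r > 0.3) & (r < 0.95),
        len(df))
    df["Ci"] = ratio * df["Ca_meas"]

    gs_base = 0.45
    gs_mult = np.where(eco2, config.multipliers["gs_eco2"], 1.0)
    rng_gs = stage_rng(config.seed, "gas-gs")
    df["gs"] = gs_base * gs_mult * df["plant_factor"] * _lognormal_factor(
        rng_gs, meas_cv, len(df))
    df["E"] = df["gs"] * 0.015  # mol m-2 s-1 at ~1.5 kPa leaf-air VPD
    df["Rd"] = [
        q10_respiration(cal.CULTIVARS[c].Rd25, cal.CULTIVARS[c].Q10, t)
        for c, t in zip(df["cultivar"], df["Tleaf"])]
    df["PPFD"] = 1500.0
    return df.drop(columns=["A_det"])


def generate_aci_curves(design: pd.DataFrame,
                        config: ExperimentConfig) -> pd.DataFrame:
    """A-Ci curves (8-step CO2 ladder, 25 degC, PPFD 1500) per plant at T3.

    Each plant carries its cultivar's capacities scaled by the calibrated
    eCO2 downregulation of Vcmax (Jmax unchanged) and by the plant's
    variability factor; noise (CV ``noise_cv_gas``) applies to the
    assimilation readings.  Long format: one row per curve point.
    """
    at_t3 = design[(design["timepoint"] == "T3")
                   & (design["hs"] != "HS1")].reset_index(drop=True)
    rng_plant = stage_rng(config.seed, "aci-plant")
    rng_noise = stage_rng(config.seed, "aci-noise")
    plant_factor = _lognormal_factor(rng_plant, config.noise_cv_gas, len(at_t3))

    ci = np.asarray(ACI_CO2_STEPS)
    frames = []
    for i, row in at_t3.iterrows():
        c = cal.CULTIVARS[row["cultivar"]]
        eco2 = row["co2"] == config.elevated_co2
        vmult = config.mult("vcmax_eco2", row["cultivar"]) if eco2 else 1.0
        jmult = config.multipliers["jmax_eco2"] if eco2 else 1.0
        f = plant_factor[i]
        params = replace(cal.cultivar_params(row["cultivar"], config.kinetics),
                         Vcmax25=c.Vcmax25 * vmult * f,
                         Jmax25=c.Jmax25 * jmult * f)
        env = LeafEnvironment(Tleaf=25.0, PPFD=1500.0, Ci=ci)
        a, _ = net_assimilation(params, env, temp_correct=True)
        a = a * _lognormal_factor(rng_noise, config.noise_cv_gas, ci.size)
        frames.append(pd.DataFrame({
            "plant_id": row["plant_id"], "cultivar": row["cultivar"],
            "co2": row["co2"], "hs": row["hs"], "Ci": ci, "A": a,
            "Tleaf": 25.0, "PPFD": 1500.0, "Rd": c.Rd25, "gm": c.gm25}))
    return pd.concat(frames, ignore_index=True)


def _delta_sam_for(delta_o: float, eps: float, delta_ref: float) -> float:
    """Sample-air delta-13C that encodes a target observed discrimination."""
    return delta_ref + delta_o * (1000.0 + delta_ref) / (
        1000.0 * eps + delta_o * (eps - 1.0))


def generate_isotope_obs(design: pd.DataFrame,
                         config: ExperimentConfig) -> pd.DataFrame:
    """Concurrent gas-exchange + isotope observations at five leaf temperatures.

    Ambient-CO2 plants only (matching the measurement campaign): for each
    cultivar x temperature x replicate, the plant's true gm follows the
    cultivar's quadratic gm(T) profile times a lognormal plant factor; the
    observed discrimination is forward-predicted and encoded into
    reference/sample CO2 and delta-13C pairs, so the whole table is
    round-trippable by :mod:`wheatphys.isotope`.
    """
    cells = design[(design["timepoint"] == "T1")
                   & (design["co2"] == config.ambient_co2)
                   & (design["hs"] == "Control")]
    rng = stage_rng(config.seed, "isotope-gm")
    k = config.kinetics
    consts = config.isotope_consts
    rows = []
    for _, plant in cells.iterrows():
        cvname = plant["cultivar"]
        factors = _lognormal_factor(rng, config.noise_cv_gas,
                                    len(CAMPAIGN_TEMPERATURES))
        for t, f in zip(CAMPAIGN_TEMPERATURES, factors):
            gm_true = cal.gm_at_temperature(cvname, t) * f
            a, _ = _baseline_A(config, cvname, t, CI_CA_RATIO * COMMON_CO2)
            gstar = arrhenius_scale(k.GammaStar25, k.EaGammaStar, t)
            ca = COMMON_CO2
            ci = CI_CA_RATIO * ca
            state = LeafState(A=a, Rd=cal.CULTIVARS[cvname].Rd25, E=0.003,
                              Ca=ca, Ci=ci, GammaStar=gstar,
                              gt_ac=a / (ca - ci))
            delta_o = predict_delta_obs(state, consts, gm_true)
            csam = ca
            cref = ca + ISOTOPE_DRAWDOWN
            eps = cref / (cref - csam)
            dsam = _delta_sam_for(delta_o, eps, DELTA_REF_AIR)
            rows.append({
                "plant_id": plant["plant_id"], "cultivar": cvname, "Tleaf": t,
                "Cref": cref, "Csam": csam, "delta_ref": DELTA_REF_AIR,
                "delta_sam": dsam, "A": a, "Rd": state.Rd, "E": state.E,
                "Ca": ca, "Ci": ci, "GammaStar": gstar, "gt_ac": state.gt_ac,
                "gm_true": gm_true})
    return pd.DataFrame(rows)


#: Traits that the eCO2 grain multipliers act on at final harvest.
_GRAIN_YIELD_TRAITS = ("grain_number", "grain_mass")


def _eco2_trait_multiplier(config: ExperimentConfig, trait: str,
                           cultivar: str, timepoint: str) -> float:
    if trait == "total_dry_mass" and timepoint in ("T3", "T4"):
        return config.mult("biomass_eco2", cultivar)
    if trait in _GRAIN_YIELD_TRAITS and timepoint == "T4":
        return config.mult("grain_number_eco2", cultivar)
    if trait == "grain_N" and timepoint == "T4":
        return config.mult("grain_N_eco2", cultivar)
    return 1.0


def generate_traits(design: pd.DataFrame,
                    config: ExperimentConfig) -> pd.DataFrame:
    """Per-plant trait table from the multiplicative lognormal model.

    trait = Scout baseline(time point) x cultivar ratio x eCO2 multiplier
    x HS multiplier x interaction x exp(noise).  The HS x eCO2 interaction
    removes the eCO2 biomass/yield gain in heat-stressed plants at final
    harvest.  Traits undefined at a time point (grain before maturity,
    leaf area after canopy closure) are NaN.  Fv/Fm is bounded at 0.87.
    """
    df = design.copy()
    rng = stage_rng(config.seed, "traits")
    eco2 = (df["co2"] == config.elevated_co2).to_numpy()
    hs_on = (df["hs"] != "Control").to_numpy()
    interact = config.multipliers["hs_cancels_eco2_yield_gain"]

    ratios = (cal.CULTIVAR_RATIOS if config.cultivar_ratios is None
              else config.cultivar_ratios)
    for trait, baselines in cal.SCOUT_BASELINES.items():
        base = df["timepoint"].map(baselines).to_numpy(dtype=float)
        ratio = np.array([
            ratios.get(trait, {}).get(tp, 1.0) if c == "Yitpi" else 1.0
            for c, tp in zip(df["cultivar"], df["timepoint"])])
        emult = np.array([
            _eco2_trait_multiplier(config, trait, c, tp) if e else 1.0
            for c, tp, e in zip(df["cultivar"], df["timepoint"], eco2)])
        hmult = np.ones(len(df))
        if trait == "total_dry_mass":
            hmult[:] = config.multipliers["biomass_hs"]
        elif trait in _GRAIN_YIELD_TRAITS:
            hmult[:] = config.multipliers["grain_hs"]
        hmult = np.where(hs_on, hmult, 1.0)
        # HS cancels the eCO2 yield/biomass gain at final harvest.
        if trait in _GRAIN_YIELD_TRAITS + ("total_dry_mass",):
            at_t4 = (df["timepoint"] == "T4").to_numpy()
            cancel = hs_on & eco2 & at_t4
            emult = np.where(cancel, emult ** (1.0 - interact), emult)
        noise = _lognormal_factor(rng, config.noise_cv_traits, len(df))
        val = base * ratio * emult * hmult * noise
        if trait == "fvfm":
            val = np.minimum(val, 0.87)
        df[trait] = val
    return df


def generate_temperature_campaign(config: ExperimentConfig,
                                  n_rep: int = 5,
                                  noise_cv: float = 0.0) -> pd.DataFrame:
    """Parameter-by-temperature series for the thermal-response campaign.

    For each cultivar, emits Vcmax (Arrhenius), Jmax (peaked Arrhenius),
    Rd (Arrhenius), Asat (parabola) and gm (quadratic profile) at the five
    campaign temperatures, ``n_rep`` replicates each, with optional
    multiplicative noise.  Long format (parameter, cultivar, Tleaf, value)
    — the input layout of the temperature-response fitters.
    """
    rng = stage_rng(config.seed, "temperature-campaign")
    rows = []
    for cvname in config.cultivars:
        c = cal.CULTIVARS[cvname]
        for t in CAMPAIGN_TEMPERATURES:
            params = cal.cultivar_params(cvname, config.kinetics)
            values = {
                "Vcmax": arrhenius_scale(c.Vcmax25, c.EaV, t),
                "Jmax": params.scal_J.scale(c.Jmax25, t),
                "Rd": arrhenius_scale(c.Rd25, c.EaR, t),
                "Asat": parabola_asat(c.Asat_Aopt, c.Asat_Topt, c.Asat_b, t),
                "gm": cal.gm_at_temperature(cvname, t),
            }
            for name, v in values.items():
                noise = _lognormal_factor(rng, noise_cv, n_rep)
                for r in range(n_rep):
                    rows.append({"parameter": name, "cultivar": cvname,
                                 "Tleaf": t, "rep": r, "value": v * noise[r]})
    return pd.DataFrame(rows)


def derived_leaf_indices(records: pd.DataFrame) -> pd.DataFrame:
    """Derived leaf/plant indices appended as columns where inputs exist.

    iWUE = A/gs; Narea = N(mmol g-1) x LMA(g m-2); PNUE = A/Narea;
    protein = N(%) x 5.7; NUtE = grain yield / total plant N.  Undefined
    denominators (gs = 0, Narea = 0, N = 0) yield NaN, never an exception.
    """
    df = records.copy()
    n_molar_mass = 14.007  # g mol-1

    def safe_div(num, den):
        den = np.asarray(den, dtype=float)
        return np.where(den != 0, np.asarray(num, dtype=float)
                        / np.where(den == 0, np.nan, den), np.nan)

    if {"A", "gs"} <= set(df.columns):
        df["iWUE"] = safe_div(df["A"], df["gs"])
    if {"leaf_N_pct", "LMA"} <= set(df.columns):
        n_mmol_g = df["leaf_N_pct"] / 100.0 / n_molar_mass * 1000.0
        df["Narea"] = n_mmol_g * df["LMA"]  # mmol m-2
        if "A" in df.columns:
            df["PNUE"] = safe_div(df["A"], df["Narea"])
    if "grain_N" in df.columns:
        df["grain_protein"] = df["grain_N"] * 5.7
    if {"grain_mass", "total_dry_mass", "plant_N_pct"} <= set(df.columns):
        total_n = df["total_dry_mass"] * df["plant_N_pct"] / 100.0
        df["NUtE"] = safe_div(df["grain_mass"], total_n)
    return df
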