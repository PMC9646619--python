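"""Mesophyll conductance from 13CO2/12CO2 discrimination with ternary correction.

Observed discrimination is computed from reference/sample CO2 concentration
and delta-13C of a gas-mixing line; mesophyll conductance gm follows from
the gap between the observed discrimination and the value predicted at
infinite gm, corrected for respiratory and photorespiratory fractionation
and for the ternary interaction of CO2 and water-vapour fluxes:

    gm = [((1+t)/(1-t)) * (b - ai - e*Rd/(A+Rd)) * A/Ca]
         / (Delta_i - Delta_o - Delta_e - Delta_f)

with t = (1 + a')*E / (2*gt_ac) the ternary correction factor,
Delta_i = (1/(1-t)) * [a' + ((1+t)*b - a') * Ci/Ca],
Delta_e = ((1+t)/(1-t)) * e*Rd/((A+Rd)*Ca) * (Ci - GammaStar) and
Delta_f = ((1+t)/(1-t)) * f * GammaStar/Ca.

Permil quantities are carried in permil and converted to fractional form
only inside (1 + a') terms.  A forward predictor (the exact algebraic
inverse) is provided for simulation and round-trip testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DiscriminationConstants

__all__ = [
    "DrawdownError",
    "InvalidStateError",
    "EstimationFailureError",
    "IsotopeObservation",
    "LeafState",
    "DiscriminationComponents",
    "observed_discrimination",
    "ternary_t",
    "predicted_components",
    "gm_from_discrimination",
    "predict_delta_obs",
    "estimate_gm_table",
]

#: Relative CO2 drawdown below which epsilon explodes and a warning is raised.
MIN_RELATIVE_DRAWDOWN = 1e-3


class DrawdownError(ZeroDivisionError):
    """Reference and sample CO2 are equal: epsilon is undefined.

    The estimator needs a measurable CO2 draw-down (Cref != Csam) across
    the leaf chamber.
    """


class InvalidStateError(ValueError):
    """A leaf state violates a physical requirement (e.g. t >= 1)."""


class EstimationFailureError(RuntimeError):
    """gm estimation failed; message carries the component breakdown."""


@dataclass(frozen=True)
class IsotopeObservation:
    """Paired reference/sample CO2 and delta-13C from the gas-mixing line."""

    Cref: float       # umol mol-1, air entering the chamber
    Csam: float       # umol mol-1, air exiting the chamber
    delta_ref: float  # permil
    delta_sam: float  # permil

    def __post_init__(self) -> None:
        if self.Cref <= 0 or self.Csam <= 0:
            raise InvalidStateError("CO2 concentrations must be positive")


@dataclass(frozen=True)
class LeafState:
    """Concurrent gas-exchange state entering the gm estimator."""

    A: float          # umol m-2 s-1
    Rd: float         # umol m-2 s-1
    E: float          # mol m-2 s-1
    Ca: float         # umol mol-1
    Ci: float         # umol mol-1
    GammaStar: float  # umol mol-1
    gt_ac: float      # mol m-2 s-1, total CO2 conductance (boundary + stomata)

    def __post_init__(self) -> None:
        if not self.Ca > self.Ci > 0:
            raise InvalidStateError("require Ca > Ci > 0")
        if self.A + self.Rd <= 0:
            raise InvalidStateError("A + Rd must be positive for a lit leaf")
        if self.gt_ac <= 0:
            raise InvalidStateError("gt_ac must be positive")


@dataclass(frozen=True)
class DiscriminationComponents:
    """Ternary factor and discrimination components (permil)."""

    t: float
    Delta_i: float
    Delta_e: float
    Delta_f: float


def observed_discrimination(obs: IsotopeObservation):
    """Observed photosynthetic 13C discrimination from the gas-mixing line.

    epsilon = Cref / (Cref - Csam);
    Delta_o = 1000*eps*(d_sam - d_ref) / (1000 + d_sam - eps*(d_sam - d_ref)).

    Returns (epsilon, Delta_o in permil).  Raises :class:`DrawdownError`
    when Cref == Csam and warns on a degenerate (<0.1%) drawdown.
    """
    dd = obs.Cref - obs.Csam
    if dd == 0:
        raise DrawdownError(
            "Cref equals Csam: a measurable CO2 draw-down across the chamber "
            "is required to define epsilon"
        )
    if abs(dd) / obs.Cref < MIN_RELATIVE_DRAWDOWN:
        warnings.warn(
            f"CO2 drawdown {dd:.4g} umol mol-1 is below "
            f"{MIN_RELATIVE_DRAWDOWN:.0%} of Cref; epsilon={obs.Cref / dd:.3g} "
            "is poorly conditioned",
            stacklevel=2,
        )
    eps = obs.Cref / dd
    dshift = obs.delta_sam - obs.delta_ref
    delta_o = 1000.0 * eps * dshift / (1000.0 + obs.delta_sam - eps * dshift)
    return eps, delta_o


def ternary_t(state: LeafState, consts: DiscriminationConstants) -> float:
    """Ternary correction factor t = (1 + a') * E / (2 * gt_ac).

    a' enters in fractional form (permil / 1000).  t = 0 at zero
    transpiration and must stay below 1 for a physical state.
    """
    t = (1.0 + consts.a_prime / 1000.0) * state.E / (2.0 * state.gt_ac)
    if t >= 1.0:
        raise InvalidStateError(f"ternary factor t={t:.3g} >= 1 is unphysical")
    if t < 0:
        raise InvalidStateError("negative ternary factor")
    return t


def predicted_components(state: LeafState, consts: DiscriminationConstants,
                         t: float | None = None) -> DiscriminationComponents:
    """Predicted discrimination components Delta_i, Delta_e, Delta_f (permil)."""
    if t is None:
        t = ternary_t(state, consts)
    if t >= 1.0:
        raise InvalidStateError("ternary factor t >= 1")
    ratio = (1.0 + t) / (1.0 - t)
    delta_i = (consts.a_prime + ((1.0 + t) * consts.b - consts.a_prime)
               * state.Ci / state.Ca) / (1.0 - t)
    delta_e = ratio * (consts.e * state.Rd / ((state.A + state.Rd) * state.Ca)
                       * (state.Ci - state.GammaStar))
    delta_f = ratio * consts.f * state.GammaStar / state.Ca
    return DiscriminationComponents(t=t, Delta_i=delta_i, Delta_e=delta_e,
                                    Delta_f=delta_f)


def _drawdown_coefficient(state: LeafState, consts: DiscriminationConstants,
                          t: float) -> float:
    """((1+t)/(1-t)) * (b - ai - e*Rd/(A+Rd)) * A/Ca — permil per (mol m-2 s-1 bar-1)."""
    ratio = (1.0 + t) / (1.0 - t)
    eff_b = consts.b - consts.ai - consts.e * state.Rd / (state.A + state.Rd)
    return ratio * eff_b * state.A / state.Ca


def gm_from_discrimination(state: LeafState, consts: DiscriminationConstants,
                           delta_o: float) -> float:
    """Mesophyll conductance (mol m-2 s-1 bar-1) from observed discrimination.

    Requires the observed discrimination to lie below the infinite-gm
    prediction net of the respiratory and photorespiratory components.
    """
    comp = predicted_components(state, consts)
    gap = comp.Delta_i - delta_o - comp.Delta_e - comp.Delta_f
    if gap <= 0:
        raise EstimationFailureError(
            "observed discrimination is not below the infinite-gm prediction: "
            f"Delta_i={comp.Delta_i:.4g}, Delta_o={delta_o:.4g}, "
            f"Delta_e={comp.Delta_e:.4g}, Delta_f={comp.Delta_f:.4g}, "
            f"t={comp.t:.4g}"
        )
    return _drawdown_coefficient(state, consts, comp.t) / gap


def predict_delta_obs(state: LeafState, consts: DiscriminationConstants,
                      gm: float) -> float:
    """Forward-predict observed discrimination for a known gm (exact inverse).

    Delta_o = Delta_i - Delta_e - Delta_f - coeff / gm, the algebraic
    rearrangement of the gm estimator; composing with
    :func:`gm_from_discrimination` is the identity.
    """
    if gm <= 0:
        raise InvalidStateError("gm must be positive")
    comp = predicted_components(state, consts)
    drawdown = 0.0 if math.isinf(gm) else _drawdown_coefficient(
        state, consts, comp.t) / gm
    return comp.Delta_i - comp.Delta_e - comp.Delta_f - drawdown


def estimate_gm_table(df: pd.DataFrame,
                      consts: DiscriminationConstants | None = None,
                      gamma_star: float = 42.75,
                      gt_from_drawdown: bool = True) -> pd.DataFrame:
    """Per-row gm estimation for an isotope log table.

    Expects columns Cref, Csam, delta_ref, delta_sam, A, Rd, E, Ca, Ci and
    optionally GammaStar and gt_ac.  When gt_ac is absent it is inferred
    from the gas-exchange drawdown as A/(Ca - Ci).  Returns the component
    breakdown (epsilon, t, Delta_o, Delta_i, Delta_e, Delta_f) and gm per
    observation; rows where estimation fails carry NaN gm and the error
    message in an ``error`` column.
    """
    consts = consts or DiscriminationConstants()
    out = []
    for _, row in df.iterrows():
        rec: dict = {}
        try:
            obs = IsotopeObservation(row["Cref"], row["Csam"],
                                     row["delta_ref"], row["delta_sam"])
            eps, delta_o = observed_discrimination(obs)
            gt = row.get("gt_ac")
            if gt is None or (isinstance(gt, float) and math.isnan(gt)):
                if not gt_from_drawdown:
                    raise InvalidStateError("gt_ac missing")
                gt = row["A"] / (row["Ca"] - row["Ci"])
            state = LeafState(A=row["A"], Rd=row.get("Rd", 0.0), E=row["E"],
                              Ca=row["Ca"], Ci=row["Ci"],
                              GammaStar=row.get("GammaStar", gamma_star),
                              gt_ac=gt)
            comp = predicted_components(state, consts)
            gm = gm_from_discrimination(state, consts, delta_o)
            rec.update(epsilon=eps, t=comp.t, Delta_o=delta_o,
                       Delta_i=comp.Delta_i, Delta_e=comp.Delta_e,
                       Delta_f=comp.Delta_f, gm=gm, error="")
        except (InvalidStateError, EstimationFailureError, DrawdownError,
                KeyError) as exc:
            rec.update(gm=float("nan"), error=str(exc))
        out.append(rec)
    res = pd.DataFrame(out, index=df.index)
    return pd.concat([df, res], axis=1)
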