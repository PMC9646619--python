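"""Forward Farquhar-von Caemmerer-Berry (FvCB) leaf photosynthesis model.

Net assimilation is the minimum of the Rubisco-limited and the
RuBP-regeneration-limited rate minus day respiration, with a finite
mesophyll conductance coupling chloroplastic CO2 (Cc) to intercellular
CO2 (Ci) through Cc = Ci - A/gm.  Temperature scaling uses the standard
Arrhenius function for Vcmax, Rd and the Rubisco kinetic constants, a
peaked (Harley-type) Arrhenius function for Jmax, and optionally a Q10
form for respiration.

Units: rates in umol m-2 s-1, conductances in mol m-2 s-1 bar-1,
CO2 mole fractions in umol mol-1 (== ubar at 1 bar), energies in
kJ mol-1 except the entropy term deltaS in J mol-1 K-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KELVIN0, R_GAS, T_REF_K, KineticConstants

__all__ = [
    "InvalidParameterError",
    "NumericalGuardError",
    "TempScaling",
    "LeafEnvironment",
    "FvCBParameters",
    "arrhenius_scale",
    "peaked_arrhenius_scale",
    "topt_peaked",
    "q10_respiration",
    "electron_transport",
    "net_assimilation",
    "parabola_asat",
]


class InvalidParameterError(ValueError):
    """A model parameter violates its physical domain."""


class NumericalGuardError(RuntimeError):
    """A solver found no physical root; carries diagnostic context."""


def _to_kelvin(tleaf_c):
    return np.asarray(tleaf_c, dtype=float) + KELVIN0


def arrhenius_scale(k25, Ea, tleaf_c):
    """Scale a rate from 25 degC to ``tleaf_c`` with the Arrhenius function.

    k(T) = k25 * exp[Ea * (Tk - 298) / (R * 298 * Tk)] with Ea in kJ mol-1.
    Strictly increasing in temperature for Ea > 0 and exactly k25 at 25 degC.
    """
    if np.any(np.asarray(k25) <= 0):
        raise InvalidParameterError("k25 must be strictly positive")
    tk = _to_kelvin(tleaf_c)
    out = k25 * np.exp(Ea * 1e3 * (tk - T_REF_K) / (R_GAS * T_REF_K * tk))
    return out if out.ndim else float(out)


def peaked_arrhenius_scale(k25, Ea, Hd, deltaS, tleaf_c):
    """Peaked Arrhenius temperature response (deactivation above the optimum).

    k(T) = Arrhenius(k25, Ea, T) * [1 + exp((298*dS - Hd)/(298*R))]
                                  / [1 + exp((Tk*dS - Hd)/(Tk*R))]

    Ea, Hd in kJ mol-1; deltaS in J mol-1 K-1.  Equals k25 at 25 degC and
    has a unique interior maximum when 0 < Ea < Hd.
    """
    if not 0 < Ea < Hd:
        raise InvalidParameterError("require 0 < Ea < Hd (otherwise no optimum)")
    if deltaS <= 0:
        raise InvalidParameterError("deltaS must be positive")
    tk = _to_kelvin(tleaf_c)
    rise = arrhenius_scale(k25, Ea, tleaf_c)
    num = 1.0 + np.exp((T_REF_K * deltaS - Hd * 1e3) / (T_REF_K * R_GAS))
    den = 1.0 + np.exp((tk * deltaS - Hd * 1e3) / (tk * R_GAS))
    out = np.asarray(rise) * num / den
    return out if out.ndim else float(out)


def topt_peaked(Ea, Hd, deltaS):
    """Closed-form temperature optimum (degC) of the peaked Arrhenius function.

    Topt[K] = Hd / (deltaS - R * ln(Ea / (Hd - Ea))), Ea and Hd in kJ mol-1,
    deltaS in J mol-1 K-1.
    """
    if not 0 < Ea < Hd:
        raise InvalidParameterError("require 0 < Ea < Hd")
    denom = deltaS - R_GAS * math.log(Ea / (Hd - Ea))
    if denom <= 0:
        raise InvalidParameterError("optimum undefined: denominator <= 0")
    return Hd * 1e3 / denom - KELVIN0


def q10_respiration(Rd25, Q10, tleaf_c):
    """Dark respiration at ``tleaf_c`` from the Q10 model Rd25 * Q10**((T-25)/10)."""
    if np.any(np.asarray(Rd25) <= 0) or Q10 <= 0:
        raise InvalidParameterError("Rd25 and Q10 must be positive")
    t = np.asarray(tleaf_c, dtype=float)
    out = Rd25 * Q10 ** ((t - 25.0) / 10.0)
    return out if out.ndim else float(out)


def electron_transport(ppfd, Jmax, theta, alpha):
    """Potential electron transport rate J from a non-rectangular hyperbola.

    J is the smaller root of theta*J^2 - (alpha*Q + Jmax)*J + alpha*Q*Jmax = 0;
    J -> Jmax as PPFD -> inf and J = 0 at PPFD = 0.
    """
    if Jmax <= 0:
        raise InvalidParameterError("Jmax must be positive")
    if not 0 < theta <= 1:
        raise InvalidParameterError("theta must be in (0, 1]")
    if not 0 < alpha < 0.5:
        raise InvalidParameterError("alpha must be in (0, 0.5)")
    q = np.asarray(ppfd, dtype=float)
    if np.any(q < 0):
        raise InvalidParameterError("PPFD must be non-negative")
    aq = alpha * q
    disc = (aq + Jmax) ** 2 - 4.0 * theta * aq * Jmax
    if np.any(disc < 0):
        raise NumericalGuardError("negative discriminant in light response")
    out = (aq + Jmax - np.sqrt(disc)) / (2.0 * theta)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TempScaling:
    """Arrhenius / peaked-Arrhenius scaling constants for one rate."""

    Ea: float                 # kJ mol-1
    Hd: float = 200.0         # kJ mol-1 (deactivation; used when peaked)
    deltaS: float = 650.0     # J mol-1 K-1 (entropy; used when peaked)
    peaked: bool = False

    def __post_init__(self) -> None:
        if self.peaked and not 0 < self.Ea < self.Hd:
            raise InvalidParameterError("peaked scaling requires 0 < Ea < Hd")

    def scale(self, k25, tleaf_c):
        if self.peaked:
            return peaked_arrhenius_scale(k25, self.Ea, self.Hd, self.deltaS, tleaf_c)
        return arrhenius_scale(k25, self.Ea, tleaf_c)


@dataclass(frozen=True)
class LeafEnvironment:
    """Instantaneous leaf-level drivers of the forward model."""

    Tleaf: float              # degC
    PPFD: float               # umol m-2 s-1
    Ci: float                 # umol mol-1
    Ca: float | None = None   # umol mol-1, optional

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.PPFD) < 0):
            raise InvalidParameterError("PPFD must be non-negative")
        if np.any(np.asarray(self.Ci) < 0):
            raise InvalidParameterError("Ci must be non-negative")
        if not -10.0 <= self.Tleaf <= 55.0:
            raise InvalidParameterError("Tleaf outside plausible leaf range")


@dataclass(frozen=True)
class FvCBParameters:
    """FvCB capacity parameters at 25 degC plus their temperature scaling.

    ``gm25 = inf`` switches the model to the infinite-mesophyll-conductance
    form (Cc = Ci exactly).  Defaults for theta and alpha are the common
    light-response constants of A-Ci fitting tools.
    """

    Vcmax25: float
    Jmax25: float
    Rd25: float = 1.25
    gm25: float = math.inf
    theta: float = 0.85
    alpha: float = 0.24
    kinetics: KineticConstants = field(default_factory=KineticConstants)
    scal_V: TempScaling = field(default_factory=lambda: TempScaling(Ea=43.3))
    scal_J: TempScaling = field(
        default_factory=lambda: TempScaling(Ea=37.7, Hd=200.0, deltaS=648.3, peaked=True)
    )
    scal_R: TempScaling = field(default_factory=lambda: TempScaling(Ea=30.9))

    def __post_init__(self) -> None:
        if self.Vcmax25 <= 0 or self.Jmax25 <= 0 or self.Rd25 <= 0:
            raise InvalidParameterError("Vcmax25, Jmax25, Rd25 must be positive")
        if self.gm25 <= 0:
            raise InvalidParameterError("gm25 must be positive (or infinite)")
        if not 0 < self.theta <= 1:
            raise InvalidParameterError("theta must be in (0, 1]")
        if not 0 < self.alpha < 0.5:
            raise InvalidParameterError("alpha must be in (0, 0.5)")

    def at_leaf_temperature(self, tleaf_c, temp_correct: bool = True):
        """Return (Vcmax, Jmax, Rd, Kc, Ko, GammaStar) at ``tleaf_c``.

        With ``temp_correct=False`` the capacity parameters and Rd are taken
        as already expressed at the leaf temperature (no 25 degC
        normalisation), while the kinetic constants are always scaled.
        """
        k = self.kinetics
        kc = arrhenius_scale(k.Kc25, k.EaKc, tleaf_c)
        ko = arrhenius_scale(k.Ko25, k.EaKo, tleaf_c)
        gstar = arrhenius_scale(k.GammaStar25, k.EaGammaStar, tleaf_c)
        if temp_correct:
            vcmax = self.scal_V.scale(self.Vcmax25, tleaf_c)
            jmax = self.scal_J.scale(self.Jmax25, tleaf_c)
            rd = self.scal_R.scale(self.Rd25, tleaf_c)
        else:
            vcmax, jmax, rd = self.Vcmax25, self.Jmax25, self.Rd25
        return vcmax, jmax, rd, kc, ko, gstar


def _limited_rate(a1, a2, ci, gamma_star, rd, gm):
    """Net A for one limitation: gross rate a1*(Cc - G*)/(Cc + a2), Cc = Ci - A/gm.

    Returns the physical (smaller) root of the coupling quadratic
    A^2 - A*[gm*(Ci+a2) + a1 - Rd] + gm*[a1*(Ci-G*) - Rd*(Ci+a2)] = 0.
    """
    ci = np.asarray(ci, dtype=float)
    if math.isinf(gm):
        return a1 * (ci - gamma_star) / (ci + a2) - rd
    b = gm * (ci + a2) + a1 - rd
    c = gm * (a1 * (ci - gamma_star) - rd * (ci + a2))
    disc = b * b - 4.0 * c
    if np.any(disc < 0):
        raise NumericalGuardError(
            f"no physical root (disc<0): a1={a1:.4g}, a2={a2:.4g}, gm={gm:.4g}, "
            f"Ci range [{np.min(ci):.4g}, {np.max(ci):.4g}]"
        )
    # smaller root in the cancellation-safe form (b can dwarf the root)
    return 2.0 * c / (b + np.sqrt(disc))


def net_assimilation(params: FvCBParameters, env: LeafEnvironment,
                     temp_correct: bool = True):
    """Net CO2 assimilation and the active limitation at one leaf state.

    A = min(Ac, Aj) - Rd with Ac = Vcmax*(Cc-G*)/(Cc + Kc*(1+O/Ko)) and
    Aj = J*(Cc-G*)/(4*Cc + 8*G*), Cc = Ci - A/gm solved per limitation.
    Ties report "Rubisco".  Scalar Ci gives scalars; array Ci broadcasts.

    Returns (A, limitation) with limitation in {"Rubisco", "RuBP"}.
    """
    vcmax, jmax, rd, kc, ko, gstar = params.at_leaf_temperature(
        env.Tleaf, temp_correct=temp_correct
    )
    j = electron_transport(env.PPFD, jmax, params.theta, params.alpha)
    km = kc * (1.0 + params.kinetics.O / ko)
    ac = _limited_rate(vcmax, km, env.Ci, gstar, rd, params.gm25)
    aj = _limited_rate(j / 4.0, 2.0 * gstar, env.Ci, gstar, rd, params.gm25)
    a = np.minimum(ac, aj)
    lim = np.where(ac <= aj, "Rubisco", "RuBP")
    if np.ndim(a) == 0:
        return float(a), str(lim)
    return a, lim


def parabola_asat(Aopt, Topt, b_curv, tleaf_c):
    """Light-saturated assimilation from the parabola Aopt - b*(T - Topt)^2."""
    if b_curv <= 0:
        raise InvalidParameterError("curvature b must be positive")
    t = np.asarray(tleaf_c, dtype=float)
    out = Aopt - b_curv * (t - Topt) ** 2
    return out if out.ndim else float(out)
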