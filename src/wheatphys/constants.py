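"""Physical constants and default parameter sets.

All temperature-response arithmetic uses the Kelvin offset 273 so that
25 degC maps exactly onto the 298 K reference of the Arrhenius forms.
Partial pressures assume 1 bar total pressure, so mole fractions in
umol mol-1 are numerically equal to ubar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Universal gas constant (J mol-1 K-1).
R_GAS = 8.314

#: Kelvin offset used throughout (25 degC <-> 298 K).
KELVIN0 = 273.0

#: Reference temperature (K) for all k25-style parameters.
T_REF_K = 298.0


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetic constants and their Arrhenius activation energies.

    Defaults are the widely used tobacco in-vivo set (the de-facto default
    of A-Ci fitting tools): Kc25 = 404.9 ubar, Ko25 = 278.4 mbar,
    GammaStar25 = 42.75 ubar, with activation energies 79.43, 36.38 and
    37.83 kJ mol-1, at an oxygen partial pressure of 210 mbar.
    """

    Kc25: float = 404.9        # ubar
    Ko25: float = 278.4        # mbar
    GammaStar25: float = 42.75  # ubar
    O: float = 210.0           # mbar
    EaKc: float = 79.43        # kJ mol-1
    EaKo: float = 36.38        # kJ mol-1
    EaGammaStar: float = 37.83  # kJ mol-1

    def __post_init__(self) -> None:
        for name in ("Kc25", "Ko25", "GammaStar25", "O"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.GammaStar25 >= self.Kc25:
            raise ValueError("GammaStar25 must be below Kc25")


@dataclass(frozen=True)
class DiscriminationConstants:
    """Fractionation constants for 13C photosynthetic discrimination (permil).

    e = 0 encodes the assumption of null fractionation by mitochondrial
    respiration in the light.  ai = 1.8 permil combines dissolution (1.1)
    and aqueous diffusion (0.7).  When boundary-layer conductance is not
    measured, a_prime defaults to the free-air diffusion value a = 4.4
    (large boundary-layer conductance limit).
    """

    a: float = 4.4        # diffusion through air
    ab: float = 2.9       # diffusion through the boundary layer
    a_prime: float = 4.4  # combined boundary layer + stomata
    ai: float = 1.8       # dissolution + liquid-phase diffusion
    b: float = 27.3       # net RuBP + PEP carboxylation
    f: float = 11.6       # photorespiration
    e: float = 0.0        # mitochondrial respiration in the light

    def __post_init__(self) -> None:
        if not (self.b > self.a > 0):
            raise ValueError("require b > a > 0")
        if self.f <= 0:
            raise ValueError("f must be positive")
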