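"""Temperature-response fitting for photosynthetic parameters.

Fits, by nonlinear (or closed-form) least squares against leaf
temperature: the Arrhenius model (Vcmax, Rd), the Q10 model (Rd), the
peaked Arrhenius model with fixed deactivation energy (Jmax), a parabola
in its (Aopt, Topt) parameterisation (Asat), and a plain quadratic whose
vertex is reported as the optimum (gm, gs, Ci, Jmax/Vcmax ratio).
Replicates at a temperature are fitted as individual points.  Standard
errors come from the Jacobian at the optimum (asymptotic, Gauss-Newton).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .fvcb import (arrhenius_scale, peaked_arrhenius_scale, q10_respiration,
                   parabola_asat, topt_peaked)

__all__ = ["TempSeries", "TempResponseFit", "fit_arrhenius", "fit_q10",
           "fit_peaked", "fit_parabola", "fit_quadratic", "build_table1"]

#: Measured leaf temperatures of the thermal-response protocol (degC).
STANDARD_TEMPERATURES = (15.0, 20.0, 25.0, 30.0, 35.0)

#: Fixed deactivation energy for the peaked Jmax fit (kJ mol-1).
HD_FIXED = 200.0

#: Peaked-fit start and entropy bounds guarding against Ea/deltaS exchange.
PEAKED_EA_START = 40.0      # kJ mol-1
PEAKED_DS_START = 640.0     # J mol-1 K-1
PEAKED_DS_BOUNDS = (500.0, 800.0)


@dataclass(frozen=True)
class TempSeries:
    """Observations of one parameter across leaf temperatures."""

    parameter: str
    Tleaf: np.ndarray
    value: np.ndarray
    cultivar: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.Tleaf, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "Tleaf", t)
        object.__setattr__(self, "value", v)
        if t.shape != v.shape:
            raise ValueError("Tleaf and value must have equal length")

    def require_temperatures(self, n: int) -> None:
        if np.unique(self.Tleaf).size < n:
            raise ValueError(
                f"{self.parameter}: need >= {n} distinct temperatures, "
                f"got {np.unique(self.Tleaf).size}")


@dataclass(frozen=True)
class TempResponseFit:
    """One fitted temperature-response model."""

    model: str                       # arrhenius | q10 | peaked | parabola | quadratic
    parameter: str
    cultivar: str
    coefficients: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    rss: float = 0.0


def _se_from_pcov(names, pcov):
    d = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return dict(zip(names, (float(x) for x in d)))


def fit_arrhenius(series: TempSeries) -> TempResponseFit:
    """Least-squares Arrhenius fit -> (k25, Ea in kJ mol-1)."""
    series.require_temperatures(4)
    k0 = float(np.interp(25.0, np.sort(series.Tleaf),
                         series.value[np.argsort(series.Tleaf)]))
    popt, pcov = curve_fit(
        lambda t, k25, ea: arrhenius_scale(k25, ea, t),
        series.Tleaf, series.value, p0=[max(k0, 1e-6), 40.0], maxfev=10000)
    resid = series.value - arrhenius_scale(popt[0], popt[1], series.Tleaf)
    return TempResponseFit(
        model="arrhenius", parameter=series.parameter, cultivar=series.cultivar,
        coefficients={"k25": float(popt[0]), "Ea": float(popt[1])},
        se=_se_from_pcov(["k25", "Ea"], pcov), rss=float(resid @ resid))


def fit_q10(series: TempSeries) -> TempResponseFit:
    """Q10 fit of respiration in log space -> (Rd25, Q10).

    ln Rd = ln Rd25 + ((T - 25)/10) * ln Q10 is linear, so the fit is the
    exact closed-form regression; for a two-point series at 25 and 35 degC
    this reduces to Q10 = Rd(35)/Rd(25).
    """
    if np.any(series.value <= 0):
        raise ValueError("Q10 fit requires strictly positive values")
    series.require_temperatures(2)
    x = (series.Tleaf - 25.0) / 10.0
    y = np.log(series.value)
    X = np.column_stack([np.ones_like(x), x])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    rd25, q10 = float(np.exp(beta[0])), float(np.exp(beta[1]))
    resid = series.value - q10_respiration(rd25, q10, series.Tleaf)
    dof = max(x.size - 2, 1)
    sigma2 = float(y @ y - beta @ (X.T @ y)) / dof if x.size > 2 else 0.0
    try:
        cov = np.linalg.inv(X.T @ X) * max(sigma2, 0.0)
        se_log = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        se = {"Rd25": rd25 * se_log[0], "Q10": q10 * se_log[1]}  # delta method
    except np.linalg.LinAlgError:
        se = {"Rd25": float("nan"), "Q10": float("nan")}
    return TempResponseFit(
        model="q10", parameter=series.parameter, cultivar=series.cultivar,
        coefficients={"Rd25": rd25, "Q10": q10}, se=se,
        rss=float(resid @ resid))


def fit_peaked(series: TempSeries, Hd: float = HD_FIXED) -> TempResponseFit:
    """Peaked Arrhenius fit with fixed Hd -> (k25, Ea, deltaS, Topt, value at Topt).

    deltaS is bounded to [500, 800] J mol-1 K-1 to prevent parameter
    exchange with Ea; Topt comes from the closed form and the value there
    by evaluation.  A series rising monotonically to its warm end gets a
    boundary-optimum warning.
    """
    series.require_temperatures(5)
    k0 = float(np.interp(25.0, np.sort(series.Tleaf),
                         series.value[np.argsort(series.Tleaf)]))
    popt, pcov = curve_fit(
        lambda t, k25, ea, ds: peaked_arrhenius_scale(k25, ea, Hd, ds, t),
        series.Tleaf, series.value,
        p0=[max(k0, 1e-6), PEAKED_EA_START, PEAKED_DS_START],
        bounds=([1e-6, 1.0, PEAKED_DS_BOUNDS[0]],
                [np.inf, Hd - 1e-6, PEAKED_DS_BOUNDS[1]]),
        maxfev=20000)
    k25, ea, ds = (float(v) for v in popt)
    topt = topt_peaked(ea, Hd, ds)
    if topt >= float(np.max(series.Tleaf)):
        warnings.warn(
            f"{series.parameter}: fitted optimum {topt:.1f} degC at/beyond the "
            "warmest measured temperature (monotone series?)", stacklevel=2)
    v_opt = peaked_arrhenius_scale(k25, ea, Hd, ds, topt)
    resid = series.value - peaked_arrhenius_scale(k25, ea, Hd, ds, series.Tleaf)
    return TempResponseFit(
        model="peaked", parameter=series.parameter, cultivar=series.cultivar,
        coefficients={"k25": k25, "Ea": ea, "deltaS": ds, "Hd": Hd,
                      "Topt": topt, "value_at_Topt": float(v_opt)},
        se=_se_from_pcov(["k25", "Ea", "deltaS"], pcov),
        rss=float(resid @ resid))


def fit_parabola(series: TempSeries) -> TempResponseFit:
    """Parabola fit Asat = Aopt - b*(T - Topt)^2 via exact quadratic regression.

    The model is an exact re-parameterisation of y = A + B*T + C*T^2 with
    C = -b, Topt = -B/(2C), Aopt = A - B^2/(4C), so the closed-form
    polynomial least squares is the global optimum.
    """
    series.require_temperatures(3)
    quad = fit_quadratic(series)
    A, B, C = (quad.coefficients[k] for k in ("A", "B", "C"))
    if C >= 0:
        warnings.warn(
            f"{series.parameter}: fitted parabola opens upward (b <= 0); "
            "no interior optimum", stacklevel=2)
        topt = float("nan") if C == 0 else -B / (2.0 * C)
        return TempResponseFit(model="parabola", parameter=series.parameter,
                               cultivar=series.cultivar,
                               coefficients={"Aopt": float("nan"), "Topt": topt,
                                             "b_curv": -C},
                               rss=quad.rss)
    topt = -B / (2.0 * C)
    aopt = A - B * B / (4.0 * C)
    return TempResponseFit(
        model="parabola", parameter=series.parameter, cultivar=series.cultivar,
        coefficients={"Aopt": float(aopt), "Topt": float(topt),
                      "b_curv": float(-C)},
        se={}, rss=quad.rss)


def fit_quadratic(series: TempSeries) -> TempResponseFit:
    """Exact quadratic least squares y = A + B*T + C*T^2 with vertex report.

    The vertex -B/(2C) is the reported optimum for gm/gs/Ci-style series;
    C = 0 leaves the vertex undefined (flagged as NaN).
    """
    series.require_temperatures(3)
    t = series.Tleaf
    X = np.column_stack([np.ones_like(t), t, t * t])
    beta, *_ = np.linalg.lstsq(X, series.value, rcond=None)
    A, B, C = (float(b) for b in beta)
    resid = series.value - X @ beta
    rss = float(resid @ resid)
    if abs(C) < 1e-12:
        vertex = float("nan")
        warnings.warn(f"{series.parameter}: quadratic term ~0, vertex undefined",
                      stacklevel=2)
    else:
        vertex = -B / (2.0 * C)
    dof = max(t.size - 3, 1)
    try:
        cov = np.linalg.inv(X.T @ X) * rss / dof
        se = _se_from_pcov(["A", "B", "C"], cov)
    except np.linalg.LinAlgError:
        se = {}
    return TempResponseFit(
        model="quadratic", parameter=series.parameter, cultivar=series.cultivar,
        coefficients={"A": A, "B": B, "C": C, "vertex": vertex}, se=se, rss=rss)


#: (row label, source fit parameter, coefficient) layout of the summary table.
_TABLE1_ROWS = [
    ("Asat Topt (degC)", "Asat", "Topt"),
    ("Aopt (umol m-2 s-1)", "Asat", "Aopt"),
    ("gm Topt (degC)", "gm", "vertex"),
    ("gm at 25 degC (mol m-2 s-1 bar-1)", "gm", "at25"),
    ("Vcmax at 25 degC (umol m-2 s-1)", "Vcmax", "k25"),
    ("EaV (kJ mol-1)", "Vcmax", "Ea"),
    ("Jmax at 25 degC (umol m-2 s-1)", "Jmax", "k25"),
    ("Jmax Topt (degC)", "Jmax", "Topt"),
    ("Jmax at Topt (umol m-2 s-1)", "Jmax", "value_at_Topt"),
    ("EaJ (kJ mol-1)", "Jmax", "Ea"),
    ("deltaS_J (J mol-1 K-1)", "Jmax", "deltaS"),
    ("Hd (kJ mol-1)", "Jmax", "Hd"),
    ("Rd at 25 degC (umol m-2 s-1)", "Rd", "k25"),
    ("EaR (kJ mol-1)", "Rd", "Ea"),
    ("Q10", "Rd_q10", "Q10"),
]


def build_table1(fits: dict[str, TempResponseFit], cultivar: str = "") -> pd.DataFrame:
    """Assemble the per-cultivar temperature-response summary table.

    ``fits`` maps parameter keys {Asat, gm, Vcmax, Jmax, Rd, Rd_q10} to
    their fitted models (parabola, quadratic, arrhenius, peaked, arrhenius,
    q10 respectively).  Missing fits yield rows marked unavailable; the
    special ``at25`` coefficient evaluates the quadratic at 25 degC.
    """
    rows = []
    for label, key, coef in _TABLE1_ROWS:
        fit = fits.get(key)
        if fit is None:
            rows.append({"row": label, "cultivar": cultivar,
                         "value": float("nan"), "se": float("nan"),
                         "available": False})
            continue
        if coef == "at25":
            c = fit.coefficients
            val = c["A"] + c["B"] * 25.0 + c["C"] * 625.0
            se = float("nan")
        else:
            val = fit.coefficients.get(coef, float("nan"))
            se = fit.se.get(coef, float("nan"))
        rows.append({"row": label, "cultivar": cultivar, "value": val,
                     "se": se, "available": not np.isnan(val)})
    return pd.DataFrame(rows)
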