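"""Estimate Vcmax and Jmax from A-Ci (or A-Cc) response curves.

The estimator is a joint two-parameter nonlinear least squares on the
min(Ac, Aj) - Rd surface of the FvCB model, with measured mesophyll
conductance and day respiration held fixed — no segmented per-limitation
fitting and no TPU limitation.  With temperature correction off, the
fitted capacities are expressed at the curve's leaf temperature rather
than normalised to 25 degC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .constants import KineticConstants
from .fvcb import FvCBParameters, InvalidParameterError, LeafEnvironment, net_assimilation

__all__ = ["AciCurve", "AciFitResult", "FitFailureError", "fit_aci",
           "assign_limitation", "fit_from_cc"]

#: Default optimizer start per the joint estimator convention.
VCMAX_START = 100.0
JMAX_RATIO_START = 1.7
#: Convergence tolerance on the cost change and iteration cap.
FTOL = 1e-8
MAX_ITER = 500
#: Restart scalings applied to the start values on non-convergence.
RESTART_SCALES = (1.0, 0.5, 2.0)


class FitFailureError(RuntimeError):
    """The curve fit failed to converge after bounded restarts."""


@dataclass(frozen=True)
class AciCurve:
    """One CO2-response curve: ordered (Ci, A) points plus fixed conditions."""

    Ci: np.ndarray            # umol mol-1
    A: np.ndarray             # umol m-2 s-1
    Tleaf: float = 25.0       # degC
    PPFD: float = 1500.0      # umol m-2 s-1
    Rd_measured: float = 1.25  # umol m-2 s-1
    gm_measured: float = math.inf  # mol m-2 s-1 bar-1; inf = ignore mesophyll

    def __post_init__(self) -> None:
        ci = np.asarray(self.Ci, dtype=float)
        a = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "Ci", ci)
        object.__setattr__(self, "A", a)
        if ci.shape != a.shape:
            raise ValueError("Ci and A must have equal length")
        if ci.size < 5:
            raise ValueError("an A-Ci curve needs at least 5 points")
        if np.any(ci <= 0):
            raise ValueError("Ci must be strictly positive")

    @property
    def spans_both_regimes(self) -> bool:
        """True when the curve has points below 300 and above 600 umol mol-1."""
        return bool(np.any(self.Ci < 300) and np.any(self.Ci > 600))


@dataclass(frozen=True)
class AciFitResult:
    """Fitted capacities with per-point diagnostics.

    Vcmax and Jmax are at the curve's leaf temperature when the fit ran
    with ``temp_correct=False`` (the default), otherwise at 25 degC.
    """

    Vcmax: float
    Jmax: float
    limitation: np.ndarray         # per-point {"Rubisco", "RuBP"}
    rss: float
    converged: bool
    se_Vcmax: float
    se_Jmax: float
    temp_correct: bool
    fit_axis: str = "Ci"           # "Ci" or "Cc"
    n_restarts: int = 0


def _make_params(vcmax: float, jmax: float, curve: AciCurve,
                 kinetics: KineticConstants, gm: float) -> FvCBParameters:
    return FvCBParameters(Vcmax25=vcmax, Jmax25=jmax, Rd25=curve.Rd_measured,
                          gm25=gm, kinetics=kinetics)


def _predict(vcmax, jmax, curve, kinetics, gm, temp_correct):
    params = _make_params(vcmax, jmax, curve, kinetics, gm)
    env = LeafEnvironment(Tleaf=curve.Tleaf, PPFD=curve.PPFD, Ci=curve.Ci)
    a, _ = net_assimilation(params, env, temp_correct=temp_correct)
    return a


def fit_aci(curve: AciCurve, kinetics: KineticConstants | None = None,
            temp_correct: bool = False) -> AciFitResult:
    """Joint least-squares fit of (Vcmax, Jmax) to an A-Ci curve.

    Minimises the residual sum of squares between measured A and the FvCB
    prediction over all points, with the curve's measured Rd and gm fixed.
    Deterministic given the fixed start (Vcmax0 = 100, Jmax0 = 170) with
    bounded restarts from x0.5 and x2 on non-convergence.

    Warns when the curve lacks low- or high-Ci coverage (Jmax or Vcmax
    weakly identified) or when one limitation never activates.
    """
    kinetics = kinetics or KineticConstants()
    if not curve.spans_both_regimes:
        warnings.warn(
            "Ci span misses <300 or >600 umol mol-1; Vcmax/Jmax may be "
            "weakly identified", stacklevel=2)

    gm = curve.gm_measured

    def residuals(x):
        try:
            return _predict(x[0], x[1], curve, kinetics, gm, temp_correct) - curve.A
        except InvalidParameterError:
            return np.full_like(curve.A, 1e6)

    best = None
    n_restarts = 0
    for i, s in enumerate(RESTART_SCALES):
        x0 = np.array([VCMAX_START * s, VCMAX_START * JMAX_RATIO_START * s])
        sol = least_squares(residuals, x0, bounds=([1e-3, 1e-3], [2e3, 2e3]),
                            ftol=FTOL, xtol=1e-10, gtol=1e-10,
                            max_nfev=MAX_ITER * 3)
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
            n_restarts = i
        if sol.success and sol.cost < 1e-10 * max(1.0, float(np.sum(curve.A**2))):
            break
    if best is None or not best.success:
        raise FitFailureError(
            f"A-Ci fit did not converge after {len(RESTART_SCALES)} starts; "
            f"status={getattr(best, 'status', None)}")

    vcmax, jmax = best.x
    rss = float(2.0 * best.cost)
    # Asymptotic standard errors from the Jacobian at the optimum.
    dof = max(curve.Ci.size - 2, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])

    params = _make_params(vcmax, jmax, curve, kinetics, gm)
    lim = assign_limitation(curve, params, temp_correct=temp_correct)
    if len(set(lim.tolist())) < 2:
        warnings.warn("all points share one limitation; fit is weakly posed",
                      stacklevel=2)
    return AciFitResult(Vcmax=float(vcmax), Jmax=float(jmax), limitation=lim,
                        rss=rss, converged=bool(best.success),
                        se_Vcmax=float(se[0]), se_Jmax=float(se[1]),
                        temp_correct=temp_correct, n_restarts=n_restarts)


def assign_limitation(curve: AciCurve, params: FvCBParameters,
                      temp_correct: bool = False) -> np.ndarray:
    """Label each curve point by its active FvCB limitation (min rule)."""
    env = LeafEnvironment(Tleaf=curve.Tleaf, PPFD=curve.PPFD, Ci=curve.Ci)
    _, lim = net_assimilation(params, env, temp_correct=temp_correct)
    return np.asarray(lim)


def fit_from_cc(curve: AciCurve, kinetics: KineticConstants | None = None,
                temp_correct: bool = False) -> AciFitResult:
    """Fit on the chloroplastic-CO2 axis: Cc = Ci - A/gm, then gm -> inf.

    With finite measured gm the Cc-axis fit and the Ci-axis fit are two
    routes to the same capacities and agree closely on well-behaved data.
    """
    gm = curve.gm_measured
    if math.isinf(gm):
        cc = curve.Ci.copy()
    else:
        cc = curve.Ci - curve.A / gm
    if np.any(cc <= 0):
        raise ValueError(
            "invalid Ci -> Cc transformation: A > gm*Ci at some point")
    cc_curve = replace(curve, Ci=cc, gm_measured=math.inf)
    res = fit_aci(cc_curve, kinetics=kinetics, temp_correct=temp_correct)
    return replace(res, fit_axis="Cc")
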