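"""Temperature-response fitters: self-consistency, oracles, summary table."""

import numpy as np
import pytest

from wheatphys.fvcb import (arrhenius_scale, parabola_asat,
                            peaked_arrhenius_scale, q10_respiration)
from wheatphys.tempresp import (TempSeries, build_table1, fit_arrhenius,
                                fit_parabola, fit_peaked, fit_q10,
                                fit_quadratic)

#: The five measured leaf temperatures of the thermal protocol.
FIVE_TEMPS = np.array([15.0, 20.0, 25.0, 30.0, 35.0])


def series(name, values, temps=FIVE_TEMPS, cultivar="Scout"):
    return TempSeries(parameter=name, Tleaf=np.asarray(temps, float),
                      value=np.asarray(values, float), cultivar=cultivar)


class TestArrheniusFit:
    @pytest.mark.parametrize("k25,ea", [(1.25, 30.9), (192.7, 43.3)])
    def test_exact_recovery(self, k25, ea):
        fit = fit_arrhenius(series("Rd", arrhenius_scale(k25, ea, FIVE_TEMPS)))
        assert fit.coefficients["k25"] == pytest.approx(k25, rel=1e-6)
        assert fit.coefficients["Ea"] == pytest.approx(ea, rel=1e-6)

    def test_constant_series(self):
        fit = fit_arrhenius(series("x", np.full(5, 3.7)))
        assert fit.coefficients["Ea"] == pytest.approx(0.0, abs=1e-6)
        assert fit.coefficients["k25"] == pytest.approx(3.7, rel=1e-8)


class TestQ10Fit:
    def test_exact_recovery_of_q10_series(self):
        fit = fit_q10(series("Rd", q10_respiration(1.25, 1.51, FIVE_TEMPS)))
        assert fit.coefficients["Rd25"] == pytest.approx(1.25, rel=1e-9)
        assert fit.coefficients["Q10"] == pytest.approx(1.51, rel=1e-9)

    def test_arrhenius_generated_respiration_gives_reported_q10(self):
        """The Arrhenius and Q10 respiration models are mutually consistent:
        fitting Q10 to Arrhenius-generated Rd lands on the reported value."""
        fit = fit_q10(series("Rd", arrhenius_scale(1.25, 30.9, FIVE_TEMPS)))
        assert fit.coefficients["Q10"] == pytest.approx(1.51, abs=0.03)

    def test_two_point_ratio(self):
        fit = fit_q10(series("Rd", [1.0, 1.6], temps=[25.0, 35.0]))
        assert fit.coefficients["Q10"] == pytest.approx(1.6, rel=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fit_q10(series("Rd", [1.0, -0.5, 1.0, 2.0, 3.0]))


class TestPeakedFit:
    @pytest.mark.parametrize("k25,ea,ds,lo,hi", [
        (187.9, 37.7, 648.3, 29.3, 30.4),
        (186.1, 41.1, 647.0, 30.2, 31.2)])
    def test_noiseless_recovery(self, k25, ea, ds, lo, hi):
        vals = peaked_arrhenius_scale(k25, ea, 200.0, ds, FIVE_TEMPS)
        fit = fit_peaked(series("Jmax", vals))
        assert fit.coefficients["k25"] == pytest.approx(k25, rel=1e-4)
        assert fit.coefficients["Ea"] == pytest.approx(ea, rel=1e-4)
        assert fit.coefficients["deltaS"] == pytest.approx(ds, rel=1e-4)
        assert lo <= fit.coefficients["Topt"] <= hi

    def test_value_at_topt_dominates_inputs(self):
        vals = peaked_arrhenius_scale(187.9, 37.7, 200.0, 648.3, FIVE_TEMPS)
        fit = fit_peaked(series("Jmax", vals))
        assert fit.coefficients["value_at_Topt"] >= vals.max() - 1e-9

    def test_monotone_series_warns(self):
        vals = arrhenius_scale(100.0, 60.0, FIVE_TEMPS)  # no deactivation
        with pytest.warns(UserWarning, match="optimum"):
            fit_peaked(series("Jmax", vals))


class TestParabolaFit:
    @pytest.mark.parametrize("aopt,topt", [(24.6, 23.4), (22.0, 23.4)])
    def test_exact_recovery(self, aopt, topt):
        vals = parabola_asat(aopt, topt, 0.05, FIVE_TEMPS)
        fit = fit_parabola(series("Asat", vals))
        assert fit.coefficients["Aopt"] == pytest.approx(aopt, rel=1e-9)
        assert fit.coefficients["Topt"] == pytest.approx(topt, rel=1e-9)
        assert fit.coefficients["b_curv"] == pytest.approx(0.05, rel=1e-9)

    def test_vertex_equals_quadratic_regression(self):
        """Parabola fit is the closed-form quadratic regression, re-parameterised."""
        rng = np.random.default_rng(5)
        vals = parabola_asat(24.6, 23.4, 0.05, FIVE_TEMPS) \
            * (1.0 + rng.normal(0.0, 0.03, 5))
        s = series("Asat", vals)
        pfit = fit_parabola(s)
        qfit = fit_quadratic(s)
        A, B, C = (qfit.coefficients[k] for k in "ABC")
        assert pfit.coefficients["Topt"] == pytest.approx(-B / (2 * C), rel=1e-9)
        assert pfit.coefficients["Aopt"] \
            == pytest.approx(A - B * B / (4 * C), rel=1e-9)

    def test_upward_opening_warns(self):
        with pytest.warns(UserWarning, match="upward"):
            fit_parabola(series("Asat", [5.0, 3.0, 2.0, 3.0, 5.0]))


class TestQuadraticFit:
    def test_gm_vertex_recovery(self):
        vals = 0.314 - 5e-4 * (FIVE_TEMPS - 27.9) ** 2
        fit = fit_quadratic(series("gm", vals))
        assert fit.coefficients["vertex"] == pytest.approx(27.9, rel=1e-9)

    def test_linear_data_flags_vertex(self):
        with pytest.warns(UserWarning, match="vertex"):
            fit = fit_quadratic(series("Ci", 2.0 + 0.5 * FIVE_TEMPS))
        assert np.isnan(fit.coefficients["vertex"])

    def test_three_points_interpolate(self):
        fit = fit_quadratic(series("x", [1.0, 4.0, 2.0],
                                   temps=[10.0, 20.0, 30.0]))
        assert fit.rss == pytest.approx(0.0, abs=1e-18)


class TestNoiseProperties:
    def test_ea_bias_and_interval_coverage(self):
        """3% noise, 500 replicates: Ea bias < 2% and ~95% CI coverage in
        [90%, 99%]."""
        from scipy.stats import t as t_dist
        rng = np.random.default_rng(99)
        truth = 43.3
        clean = arrhenius_scale(192.7, truth, FIVE_TEMPS)
        sigma = np.sqrt(np.log1p(0.03**2))
        tcrit = t_dist.ppf(0.975, FIVE_TEMPS.size - 2)
        eas, hits = [], 0
        for _ in range(500):
            noisy = clean * np.exp(rng.normal(-sigma**2 / 2, sigma, 5))
            fit = fit_arrhenius(series("Vcmax", noisy))
            ea = fit.coefficients["Ea"]
            se = fit.se["Ea"]
            eas.append(ea)
            if abs(ea - truth) <= tcrit * se:
                hits += 1
        assert abs(np.mean(eas) - truth) / truth < 0.02
        assert 0.90 <= hits / 500 <= 0.99


class TestSummaryTable:
    @pytest.fixture
    def full_fits(self):
        return {
            "Vcmax": fit_arrhenius(series(
                "Vcmax", arrhenius_scale(192.7, 43.3, FIVE_TEMPS))),
            "Jmax": fit_peaked(series(
                "Jmax", peaked_arrhenius_scale(187.9, 37.7, 200.0, 648.3,
                                               FIVE_TEMPS))),
            "Rd": fit_arrhenius(series(
                "Rd", arrhenius_scale(1.25, 30.9, FIVE_TEMPS))),
            "Rd_q10": fit_q10(series(
                "Rd", arrhenius_scale(1.25, 30.9, FIVE_TEMPS))),
            "Asat": fit_parabola(series(
                "Asat", parabola_asat(24.6, 23.4, 0.05, FIVE_TEMPS))),
            "gm": fit_quadratic(series(
                "gm", 0.314 - 5e-4 * (FIVE_TEMPS - 27.9) ** 2)),
        }

    def test_full_run_populates_all_rows(self, full_fits):
        table = build_table1(full_fits, cultivar="Scout")
        assert len(table) == 15
        assert table["available"].all()

    def test_hd_row_is_fixed_200(self, full_fits):
        table = build_table1(full_fits, cultivar="Scout")
        hd = table.loc[table["row"].str.startswith("Hd"), "value"].iloc[0]
        assert hd == 200.0

    def test_missing_fit_leaves_other_rows(self, full_fits):
        del full_fits["gm"]
        table = build_table1(full_fits, cultivar="Scout")
        gm_rows = table[table["row"].str.startswith("gm")]
        assert not gm_rows["available"].any()
        assert table[~table["row"].str.startswith("gm")]["available"].all()
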