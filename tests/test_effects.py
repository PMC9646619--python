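"""Percent-change estimates, factorial ANOVA and Tukey letter displays."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import studentized_range

from wheatphys.effects import (factorial_anova, percent_change,
                               significance_stars, tukey_letters)
from wheatphys.synthetic import ExperimentConfig, generate_design, generate_traits
from wheatphys.calibration import null_multipliers


class TestPercentChange:
    def test_identical_groups(self):
        est = percent_change([5.0, 5.0, 5.0], [5.0, 5.0, 5.0], B=200, seed=1)
        assert est.percent == pytest.approx(0.0)
        assert est.ci_low <= 0.0 <= est.ci_high

    def test_deterministic_arithmetic(self):
        est = percent_change([12.0, 12.0], [10.0, 10.0], B=100, seed=1)
        assert est.percent == pytest.approx(20.0)

    def test_large_sample_trait_contrast(self):
        """Yitpi-vs-Scout biomass at anthesis lands on the configured +42%."""
        cfg = ExperimentConfig(seed=5, n_per_cell=1000)
        d = generate_design(cfg)
        tr = generate_traits(d, cfg)
        t3 = tr[(tr["timepoint"] == "T3") & (tr["hs"] == "Control")
                & (tr["co2"] == 450.0)]
        est = percent_change(
            t3[t3["cultivar"] == "Yitpi"]["total_dry_mass"],
            t3[t3["cultivar"] == "Scout"]["total_dry_mass"], B=500, seed=5)
        assert est.percent == pytest.approx(42.0, abs=2.0)
        assert est.ci_low < 42.0 < est.ci_high

    def test_guards(self):
        with pytest.raises(ValueError, match="at least 2"):
            percent_change([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="positive"):
            percent_change([1.0, 2.0], [-1.0, -2.0])

    def test_bootstrap_coverage(self):
        """Nominal 95% percentile CI covers the true percent change in
        [92%, 98%] of seeded replicates (n=10 per group, CV 10%)."""
        rng = np.random.default_rng(123)
        sigma = np.sqrt(np.log1p(0.01))
        true_pct = 20.0
        hits = 0
        n_rep = 400
        for i in range(n_rep):
            ref = 10.0 * np.exp(rng.normal(-sigma**2 / 2, sigma, 10))
            treat = 12.0 * np.exp(rng.normal(-sigma**2 / 2, sigma, 10))
            est = percent_change(treat, ref, B=999, seed=i)
            if est.ci_low <= true_pct <= est.ci_high:
                hits += 1
        assert 0.92 <= hits / n_rep <= 0.98


class TestFactorialAnova:
    @staticmethod
    def _null_table(seed, n=4):
        cfg = ExperimentConfig(seed=seed, n_per_cell=n, cultivar_ratios={},
                               multipliers=null_multipliers())
        d = generate_design(cfg)
        tr = generate_traits(d, cfg)
        return tr[tr["timepoint"] == "T4"]

    def test_detects_pure_co2_effect(self):
        cfg = ExperimentConfig(seed=3, n_per_cell=10)
        tr = generate_traits(generate_design(cfg), cfg)
        tab = factorial_anova(tr[tr["timepoint"] == "T4"], "grain_number")
        assert tab.loc["C(co2)", "PR(>F)"] < 1e-6

    def test_balanced_order_invariance(self):
        t4 = self._null_table(seed=8)
        a = factorial_anova(t4, "total_dry_mass",
                            factors=("cultivar", "co2", "hs"))
        b = factorial_anova(t4, "total_dry_mass",
                            factors=("hs", "co2", "cultivar"))
        for term_a, term_b in [("C(cultivar)", "C(cultivar)"),
                               ("C(co2)", "C(co2)"), ("C(hs)", "C(hs)")]:
            assert a.loc[term_a, "sum_sq"] \
                == pytest.approx(b.loc[term_b, "sum_sq"], rel=1e-9)

    def test_empty_cell_is_named(self):
        t4 = self._null_table(seed=9)
        broken = t4[~((t4["cultivar"] == "Scout") & (t4["co2"] == 650.0)
                      & (t4["hs"] == "HS2"))]
        with pytest.raises(ValueError, match="empty design cell"):
            factorial_anova(broken, "total_dry_mass")

    def test_null_type_one_error_rate(self):
        """Under the null generator the CO2 term rejects at ~alpha=0.05."""
        rejections = 0
        n_sim = 300
        for s in range(n_sim):
            t4 = self._null_table(seed=10_000 + s, n=3)
            tab = factorial_anova(t4, "total_dry_mass")
            if tab.loc["C(co2)", "PR(>F)"] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_interaction_power(self):
        """The HS-cancels-eCO2-gain pattern drives the CO2 x HS term with
        high power at the experiment's cell size; the three-way component
        (the small Scout/Yitpi difference in the cancelled gain) needs a
        larger cohort to surface."""
        hits2, hits3 = 0, 0
        n_sim = 20
        for s in range(n_sim):
            cfg = ExperimentConfig(seed=20_000 + s, n_per_cell=10)
            tr = generate_traits(generate_design(cfg), cfg)
            tab = factorial_anova(tr[tr["timepoint"] == "T4"], "grain_number")
            if tab.loc["C(co2):C(hs)", "PR(>F)"] < 0.05:
                hits2 += 1
        for s in range(n_sim):
            cfg = ExperimentConfig(seed=30_000 + s, n_per_cell=150)
            tr = generate_traits(generate_design(cfg), cfg)
            tab = factorial_anova(tr[tr["timepoint"] == "T4"], "grain_number")
            if tab.loc["C(cultivar):C(co2):C(hs)", "PR(>F)"] < 0.05:
                hits3 += 1
        assert hits2 / n_sim > 0.8
        assert hits3 / n_sim > 0.8


class TestStars:
    @pytest.mark.parametrize("p,stars", [
        (0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.2, "")])
    def test_mapping(self, p, stars):
        assert significance_stars(p) == stars


class TestTukeyLetters:
    def test_equal_means_share_letter(self):
        letters = tukey_letters({"a": 5.0, "b": 5.0, "c": 5.0},
                                mse=1.0, df_resid=20, n_per_cell=5)
        assert len(set(letters.values())) == 1

    def test_separated_means_distinct(self):
        letters = tukey_letters({"lo": 0.0, "hi": 100.0},
                                mse=0.01, df_resid=20, n_per_cell=5)
        assert letters["lo"] != letters["hi"]

    def test_letters_match_pairwise_oracle(self):
        """Shared letters exactly when the studentized-range test accepts."""
        means = {"w": 10.0, "x": 10.8, "y": 13.0, "z": 20.0}
        mse, df, n = 1.2, 16, 5
        letters = tukey_letters(means, mse, df, n)
        qcrit = studentized_range.ppf(0.95, len(means), df)
        hsd = qcrit * np.sqrt(mse / n)
        for a in means:
            for b in means:
                if a >= b:
                    continue
                nonsig = abs(means[a] - means[b]) <= hsd
                shared = bool(set(letters[a]) & set(letters[b]))
                assert shared == nonsig, (a, b, letters)

    def test_df_guard(self):
        with pytest.raises(ValueError):
            tukey_letters({"a": 1.0, "b": 2.0}, 1.0, 0, 5)
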