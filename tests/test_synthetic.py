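"""Synthetic-experiment generator: design, determinism, calibrated effects."""

import numpy as np
import pandas as pd
import pytest

from wheatphys import calibration as cal
from wheatphys.synthetic import (ExperimentConfig, derived_leaf_indices,
                                 generate_aci_curves, generate_design,
                                 generate_gas_exchange, generate_isotope_obs,
                                 generate_temperature_campaign,
                                 generate_traits)


class TestDesign:
    def test_cell_counts(self):
        cfg = ExperimentConfig(seed=1, n_per_cell=10)
        d = generate_design(cfg)
        assert (d["timepoint"] == "T3").sum() == 2 * 2 * 4 * 10
        # HS1-only plants were not carried to final harvest
        t4 = d[d["timepoint"] == "T4"]
        assert set(t4["hs"]) == {"Control", "HS2", "HS1+2"}
        assert len(t4) == 2 * 2 * 3 * 10

    def test_seed_permutes_ids_not_counts(self):
        d1 = generate_design(ExperimentConfig(seed=1, n_per_cell=5))
        d2 = generate_design(ExperimentConfig(seed=2, n_per_cell=5))
        assert len(d1) == len(d2)
        assert sorted(d1["plant_id"]) == sorted(d2["plant_id"])
        assert not (d1["plant_id"] == d2["plant_id"]).all()
        pd.testing.assert_frame_equal(d1.drop(columns="plant_id"),
                                      d2.drop(columns="plant_id"))

    def test_mandatory_seed_and_minimum_n(self):
        with pytest.raises(ValueError):
            ExperimentConfig(seed=1, n_per_cell=1)
        with pytest.raises((ValueError, TypeError)):
            ExperimentConfig(seed=None)


class TestDeterminism:
    def test_same_seed_byte_identical(self, small_config):
        runs = []
        for _ in range(2):
            d = generate_design(small_config)
            runs.append((generate_gas_exchange(d, small_config),
                         generate_traits(d, small_config),
                         generate_isotope_obs(d, small_config)))
        for a, b in zip(*runs):
            pd.testing.assert_frame_equal(a, b)

    def test_stage_streams_independent(self, small_config):
        """Trait draws do not depend on whether gas exchange ran first."""
        d = generate_design(small_config)
        t_alone = generate_traits(d, small_config)
        generate_gas_exchange(d, small_config)
        t_after = generate_traits(d, small_config)
        pd.testing.assert_frame_equal(t_alone, t_after)


class TestZeroNoiseExactness:
    def test_gas_exchange_multipliers_exact(self, noiseless_config):
        d = generate_design(noiseless_config)
        gx = generate_gas_exchange(d, noiseless_config)
        g = gx[(gx["Tleaf"] == 25.0) & (gx["hs"] == "Control")
               & (gx["timepoint"] == "T2")]
        for meas, expected in [("growth", 1.21), ("common", 0.88)]:
            m = g[g["meas_type"] == meas].groupby("co2")["A"].mean()
            assert m[650.0] / m[450.0] == pytest.approx(expected, rel=1e-12)

    def test_trait_multipliers_exact(self, noiseless_config):
        d = generate_design(noiseless_config)
        tr = generate_traits(d, noiseless_config)
        t3 = tr[(tr["timepoint"] == "T3") & (tr["hs"] == "Control")
                & (tr["co2"] == 450.0)]
        ratio = (t3[t3["cultivar"] == "Yitpi"]["total_dry_mass"].mean()
                 / t3[t3["cultivar"] == "Scout"]["total_dry_mass"].mean())
        assert ratio == pytest.approx(1.42, rel=1e-12)
        t4s = tr[(tr["timepoint"] == "T4") & (tr["hs"] == "Control")
                 & (tr["cultivar"] == "Scout")]
        gn = t4s.groupby("co2")["grain_number"].mean()
        assert gn[650.0] / gn[450.0] == pytest.approx(1.64, rel=1e-12)

    def test_hs_cancels_eco2_yield_gain(self, noiseless_config):
        d = generate_design(noiseless_config)
        tr = generate_traits(d, noiseless_config)
        hs = tr[(tr["timepoint"] == "T4") & (tr["hs"] == "HS1+2")
                & (tr["cultivar"] == "Scout")]
        gn = hs.groupby("co2")["grain_number"].mean()
        assert gn[650.0] / gn[450.0] == pytest.approx(1.0, rel=1e-12)

    def test_isotope_round_trip_exact(self, noiseless_config):
        d = generate_design(noiseless_config)
        iso = generate_isotope_obs(d, noiseless_config)
        s25 = iso[(iso["cultivar"] == "Scout") & (iso["Tleaf"] == 25.0)]
        np.testing.assert_allclose(s25["gm_true"], 0.31, rtol=1e-12)
        from wheatphys.isotope import estimate_gm_table
        est = estimate_gm_table(iso)
        np.testing.assert_allclose(est["gm"], est["gm_true"], rtol=1e-9)

    def test_noiseless_aci_recovers_cultivar_capacities(self, noiseless_config):
        from wheatphys.aci import AciCurve, fit_aci
        d = generate_design(noiseless_config)
        curves = generate_aci_curves(d, noiseless_config)
        one = curves[(curves["cultivar"] == "Scout") & (curves["co2"] == 450.0)
                     & (curves["hs"] == "Control")]
        pid = one["plant_id"].iloc[0]
        grp = one[one["plant_id"] == pid]
        fit = fit_aci(AciCurve(Ci=grp["Ci"].to_numpy(), A=grp["A"].to_numpy(),
                               Rd_measured=1.25, gm_measured=0.31))
        assert fit.Vcmax == pytest.approx(192.7, rel=0.005)
        assert fit.Jmax == pytest.approx(187.9, rel=0.005)

    def test_eco2_aci_carries_vcmax_downregulation(self, noiseless_config):
        from wheatphys.aci import AciCurve, fit_aci
        d = generate_design(noiseless_config)
        curves = generate_aci_curves(d, noiseless_config)
        one = curves[(curves["cultivar"] == "Scout") & (curves["co2"] == 650.0)
                     & (curves["hs"] == "Control")]
        grp = one[one["plant_id"] == one["plant_id"].iloc[0]]
        fit = fit_aci(AciCurve(Ci=grp["Ci"].to_numpy(), A=grp["A"].to_numpy(),
                               Rd_measured=1.25, gm_measured=0.31))
        assert fit.Vcmax == pytest.approx(192.7 * 0.86, rel=0.005)
        assert fit.Jmax == pytest.approx(187.9, rel=0.005)


class TestPhysicalInvariants:
    def test_ci_below_ca_and_positive_traits(self, small_config):
        d = generate_design(small_config)
        gx = generate_gas_exchange(d, small_config)
        assert (gx["Ci"] < gx["Ca_meas"]).all()
        assert (gx["A"] > 0).all()
        tr = generate_traits(d, small_config)
        for trait in ("total_dry_mass", "tillers", "grain_number"):
            assert (tr[trait].dropna() > 0).all()

    def test_fvfm_bounded(self, small_config):
        tr = generate_traits(generate_design(small_config), small_config)
        v = tr["fvfm"].dropna()
        assert ((v > 0) & (v <= 0.87)).all()

    def test_grain_traits_absent_before_maturity(self, small_config):
        tr = generate_traits(generate_design(small_config), small_config)
        early = tr[tr["timepoint"] != "T4"]
        assert early["grain_mass"].isna().all()
        assert tr[tr["timepoint"] == "T4"]["grain_mass"].notna().all()


class TestCampaignAndIndices:
    def test_campaign_matches_models_when_noiseless(self, small_config):
        camp = generate_temperature_campaign(small_config, n_rep=2,
                                             noise_cv=0.0)
        g = camp[(camp["parameter"] == "gm") & (camp["cultivar"] == "Scout")
                 & (camp["Tleaf"] == 25.0)]
        assert g["value"].iloc[0] == pytest.approx(0.31)
        v = camp[(camp["parameter"] == "Vcmax") & (camp["cultivar"] == "Scout")
                 & (camp["Tleaf"] == 25.0)]
        assert v["value"].iloc[0] == pytest.approx(192.7)

    def test_derived_indices(self):
        df = pd.DataFrame({
            "A": [20.0, 10.0], "gs": [0.4, 0.0],
            "leaf_N_pct": [2.0, 2.0], "LMA": [40.0, 40.0],
            "grain_N": [2.0, 3.0],
            "grain_mass": [10.0, 12.0], "total_dry_mass": [30.0, 30.0],
            "plant_N_pct": [1.5, 1.5]})
        out = derived_leaf_indices(df)
        assert out["iWUE"].iloc[0] == pytest.approx(50.0)
        assert np.isnan(out["iWUE"].iloc[1])  # gs = 0 flagged, no exception
        assert out["grain_protein"].iloc[0] == pytest.approx(11.4)
        assert out["NUtE"].iloc[0] == pytest.approx(10.0 / 0.45)
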