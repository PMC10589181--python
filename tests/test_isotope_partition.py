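"""Mixing equation, four-pool accounting, recovery diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from litterfate.isotope_partition import (ReferenceSignature, c_recovery,
                                          f_c4, mass_recovery,
                                          partition_pools, relative_change,
                                          summarize_treatments,
                                          relative_change_summary)
from litterfate.pipeline import treatment_metadata


class TestFC4:
    @pytest.mark.parametrize("sample,ref,litter,expected", [
        (-26.2, -26.2, -14.2, 0.0),     # sample equals the reference
        (-14.2, -26.2, -14.2, 1.0),     # sample equals the litter
        (-20.2, -26.2, -14.2, 0.5),     # midpoint
        (-23.2, -26.2, -14.2, 0.25),    # quarter of the span
    ])
    def test_known_mixtures(self, sample, ref, litter, expected):
        assert f_c4(sample, ref, litter) == pytest.approx(expected)

    def test_zero_denominator_names_inputs(self):
        with pytest.raises(ZeroDivisionError, match="-26.2"):
            f_c4(-20.0, -26.2, -26.2)

    def test_clipping(self):
        assert f_c4(-28.0, -26.2, -14.2) == 0.0
        assert f_c4(-28.0, -26.2, -14.2, clip=False) < 0

    @given(st.floats(-35, -5), st.floats(-35, -5))
    def test_strictly_increasing_in_sample(self, d1, d2):
        """f_c4 is monotone in the sample delta when litter > reference."""
        ref, litter = -26.2, -14.2
        f1 = f_c4(d1, ref, litter, clip=False)
        f2 = f_c4(d2, ref, litter, clip=False)
        assert (f1 < f2) == (d1 < d2) or d1 == d2


class TestPartitionPools:
    def test_roundtrip_recovers_true_pools(self, noisefree_dataset):
        """Noise-free observations invert to the simulator's true pools
        to < 1e-9 relative, for every treatment and occasion."""
        ds = noisefree_dataset
        ref = ReferenceSignature.from_observations(
            ds.observations, delta_litter=ds.design.delta_litter)
        part = partition_pools(ds.observations, ref)
        kg = ds.design.soil_mass_g / 1000.0
        merged = part.merge(ds.true_states, on=["treatment", "replicate",
                                                "month"])
        for obs_col, true_col in [("poc_new", "poc_new_g"),
                                  ("poc_old", "poc_old_g"),
                                  ("maoc_new", "maoc_new_g"),
                                  ("maoc_old", "maoc_old_g")]:
            got = merged[obs_col].to_numpy()
            want = merged[true_col].to_numpy() / kg
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)

    def test_control_has_no_new_pools(self, noisefree_dataset):
        ds = noisefree_dataset
        ref = ReferenceSignature.from_observations(
            ds.observations, delta_litter=ds.design.delta_litter)
        part = partition_pools(ds.observations, ref)
        con = part[part["treatment"] == "CON"]
        assert np.allclose(con["poc_new"], 0, atol=1e-12)
        assert np.allclose(con["maoc_new"], 0, atol=1e-12)

    def test_fraction_at_litter_delta_is_all_new(self, noisefree_dataset):
        ds = noisefree_dataset
        obs = ds.observations.copy()
        target = (obs["treatment"] == "CN50") & (obs["month"] == 24.0)
        obs.loc[target, "fine_d13c"] = ds.design.delta_litter
        ref = ReferenceSignature.from_observations(
            obs, delta_litter=ds.design.delta_litter)
        part = partition_pools(obs, ref)
        sel = part[(part["treatment"] == "CN50") & (part["month"] == 24.0)]
        assert np.allclose(sel["maoc_old"], 0, atol=1e-12)
        maoc_total = sel["maoc_new"] + sel["maoc_old"]
        assert np.allclose(sel["maoc_new"], maoc_total)

    def test_pool_additivity_is_exact(self, noisy_dataset):
        ds = noisy_dataset
        ref = ReferenceSignature.from_observations(
            ds.observations, delta_litter=ds.design.delta_litter)
        part = partition_pools(ds.observations, ref)
        pc = part.attrs  # clip bookkeeping exists
        assert "n_clipped" in pc and "clip_rate" in pc
        obs = ds.observations
        share = obs["coarse_mass_g"] / (obs["coarse_mass_g"]
                                        + obs["fine_mass_g"])
        # new + old sums to the constant-proportion fraction totals exactly
        t0_share = share[obs["month"] == 0].groupby(obs["treatment"]).mean()
        pc_used = obs["treatment"].map(t0_share)
        np.testing.assert_allclose(
            part["poc_new"] + part["poc_old"],
            obs["coarse_c_gkg"] * pc_used, rtol=1e-12)

    def test_mean_f_c4_unbiased_under_delta_noise(self):
        """The mixing equation is linear in delta, so additive delta noise
        leaves the estimated litter-derived fraction unbiased."""
        rng = np.random.default_rng(7)
        ref, litter, truth = -26.2, -14.2, 0.37
        delta_true = ref + truth * (litter - ref)
        n = 2000
        estimates = [f_c4(delta_true + 0.2 * rng.standard_normal(),
                          ref, litter, clip=False) for _ in range(n)]
        se = np.std(estimates, ddof=1) / np.sqrt(n)
        assert abs(np.mean(estimates) - truth) < 2 * se

    def test_implausible_delta_warns(self, noisy_dataset):
        ds = noisy_dataset
        obs = ds.observations.copy()
        obs.loc[obs.index[0], "bulk_d13c"] = -50.0
        ref = ReferenceSignature.from_observations(
            obs, delta_litter=ds.design.delta_litter)
        with pytest.warns(UserWarning, match="plausibility"):
            partition_pools(obs, ref)


class TestRecoveries:
    def test_c_recovery_exact_sum(self):
        part = {"poc_new": 2.0, "poc_old": 2.0, "maoc_new": 3.0,
                "maoc_old": 3.0, "bulk_total": 10.0}
        assert c_recovery(part) == pytest.approx(100.0)

    def test_c_recovery_arithmetic(self):
        part = {"poc_new": 2.0, "poc_old": 2.0, "maoc_new": 3.0,
                "maoc_old": 3.0, "bulk_total": 9.8}
        assert c_recovery(part) == pytest.approx(102.04, abs=0.005)

    def test_c_recovery_noisefree_is_100(self, noisefree_dataset):
        ds = noisefree_dataset
        ref = ReferenceSignature.from_observations(
            ds.observations, delta_litter=ds.design.delta_litter)
        part = partition_pools(ds.observations, ref)
        np.testing.assert_allclose(part["c_recovery_pct"], 100.0, rtol=1e-9)

    def test_c_recovery_zero_bulk_rejected(self):
        with pytest.raises(ValueError):
            c_recovery({"poc_new": 1, "poc_old": 1, "maoc_new": 1,
                        "maoc_old": 1, "bulk_total": 0.0})

    @pytest.mark.parametrize("coarse,fine,input_mass,expected", [
        (3.0, 2.0, 5.0, 100.0),
        (2.95, 1.96, 5.0, 98.2),
    ])
    def test_mass_recovery_arithmetic(self, coarse, fine, input_mass, expected):
        got = mass_recovery({"coarse_mass_g": coarse, "fine_mass_g": fine,
                             "input_mass_g": input_mass})
        assert got == pytest.approx(expected)

    def test_mass_recovery_zero_input_rejected(self):
        with pytest.raises(ValueError):
            mass_recovery({"coarse_mass_g": 1, "fine_mass_g": 1,
                           "input_mass_g": 0.0})


class TestRelativeChange:
    def test_no_change_is_zero(self):
        assert relative_change(5.0, 5.0, "control_t0_fraction") == 0.0

    def test_maoc_new_share_of_added_litter(self):
        assert relative_change(0.93, 10.0, "added_litter_C") == pytest.approx(9.3)

    def test_bulk_loss_arithmetic(self):
        baseline = 11.2 + 10.0
        got = relative_change(6.44, baseline, "control_t0_bulk")
        assert got == pytest.approx(100 * (6.44 - baseline) / baseline)

    def test_unknown_basis_rejected(self):
        with pytest.raises(ValueError, match="basis"):
            relative_change(1.0, 1.0, "whatever")

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_change(1.0, 0.0, "control_t0_bulk")


class TestSummaries:
    def test_average_is_mean_of_treatment_means(self):
        df = pd.DataFrame({
            "treatment": ["A"] * 2 + ["B"] * 2,
            "x": [1.0, 3.0, 10.0, 14.0],
        })
        out = summarize_treatments(df, ["x"])
        avg = out[out["treatment"] == "Average"].iloc[0]
        assert avg["x_mean"] == pytest.approx((2.0 + 12.0) / 2)

    def test_single_treatment_average_equals_its_mean(self):
        df = pd.DataFrame({"treatment": ["A"] * 3, "x": [1.0, 2.0, 3.0]})
        out = summarize_treatments(df, ["x"])
        assert (out[out["treatment"] == "Average"]["x_mean"].iloc[0]
                == pytest.approx(2.0))

    def test_replicate_order_invariance(self, noisy_dataset):
        ds = noisy_dataset
        ref = ReferenceSignature.from_observations(
            ds.observations, delta_litter=ds.design.delta_litter)
        meta = treatment_metadata(ds.design)
        litter_c = meta.loc[~meta["is_control"], "litter_c_gkg"]
        part = partition_pools(ds.observations, ref)
        a = relative_change_summary(part, month=24.0, added_litter_c_gkg=litter_c)
        shuffled = part.sample(frac=1.0, random_state=3)
        b = relative_change_summary(shuffled, month=24.0, added_litter_c_gkg=litter_c)
        pd.testing.assert_frame_equal(
            a.sort_values("treatment").reset_index(drop=True),
            b.sort_values("treatment").reset_index(drop=True))
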