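"""Deterministic and probabilistic sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

import fpecea
from fpecea.sensitivity import (
    ceac,
    draw_beta,
    draw_gamma,
    draw_lognormal_rr,
    one_way,
    run_psa,
    scenario,
)


class TestOneWay:
    def test_degenerate_range_has_zero_spread(self, base):
        ps = base.copy()
        mask = ps.clinical["parameter"] == "p_refracture_nh"
        for col in ("low", "high"):
            ps.clinical.loc[mask, col] = ps.clinical.loc[mask, "value"]
        ps.validate()
        res = one_way(ps, "p_refracture_nh", sex="women")
        assert res.spread == pytest.approx(0.0, abs=1e-9)

    def test_unknown_parameter_raises(self, base):
        with pytest.raises(KeyError):
            one_way(base, "p_no_such_thing")

    def test_bounds_move_the_icer_in_opposite_directions(self, base, cea_results):
        res = one_way(base, "rr", sex="women")
        icer = cea_results["women"].icer_value
        assert res.low_result.icer_value < icer < res.high_result.icer_value


class TestScenario:
    def test_collapsed_ranges_reproduce_base_case(self, base, cea_results):
        ps = base.copy()
        for frame in (ps.clinical, ps.costs):
            frame["low"] = frame["value"]
            frame["high"] = frame["value"]
        ps.intervention["low"] = ps.intervention["value"]
        ps.intervention["high"] = ps.intervention["value"]
        ps = ps.with_effect(rr_low=ps.effect.rr, rr_high=ps.effect.rr)
        res = scenario(ps, "best", sex="women")
        assert res.d_cost == pytest.approx(cea_results["women"].d_cost)
        assert res.fractures_averted == pytest.approx(
            cea_results["women"].fractures_averted)

    def test_worst_case_is_worse_than_base(self, base, cea_results):
        worst = scenario(base, "worst", sex="women")
        assert (worst.status in ("dominated", "undefined")
                or worst.icer_value > cea_results["women"].icer_value)

    def test_invalid_kind_rejected(self, base):
        with pytest.raises(ValueError):
            scenario(base, "middling")


class TestDistributions:
    """Method-of-moments fits hit the target mean (checked over 1e5 draws)."""

    def test_beta_mean(self):
        rng = np.random.default_rng(0)
        x = draw_beta(rng, 0.117, 0.0936, 0.1404, 100_000)
        assert x.mean() == pytest.approx(0.117, rel=0.01)
        assert ((x > 0) & (x < 1)).all()

    def test_gamma_mean(self):
        rng = np.random.default_rng(0)
        x = draw_gamma(rng, 8516.0, 0.4 * 8516.0, 100_000)
        assert x.mean() == pytest.approx(8516.0, rel=0.01)
        assert x.std() == pytest.approx(0.4 * 8516.0, rel=0.02)

    def test_lognormal_rr_quantiles_match_ci(self, base):
        rng = np.random.default_rng(0)
        x = draw_lognormal_rr(rng, base.effect, 200_000)
        assert np.median(x) == pytest.approx(0.73, rel=0.01)
        assert np.quantile(x, 0.025) == pytest.approx(0.56, rel=0.02)
        assert np.quantile(x, 0.975) == pytest.approx(0.95, rel=0.02)

    def test_degenerate_sd_returns_point(self):
        rng = np.random.default_rng(0)
        assert (draw_gamma(rng, 100.0, 0.0, 5) == 100.0).all()
        assert (draw_beta(rng, 0.2, 0.2, 0.2, 5) == 0.2).all()

    def test_unfittable_beta_falls_back_with_warning(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning):
            x = draw_beta(rng, 0.5, -3.0, 4.0, 1000)
        assert ((x >= 0.4) & (x <= 0.6)).all()


class TestPSA:
    def test_seed_reproducibility_bit_for_bit(self, base):
        a = run_psa(base, 64, seed=123, sex="women")
        b = run_psa(base, 64, seed=123, sex="women")
        pd.testing.assert_frame_equal(a.samples, b.samples)
        c = run_psa(base, 64, seed=124, sex="women")
        assert not a.samples["d_cost"].equals(c.samples["d_cost"])

    def test_zero_scale_reproduces_base_case(self, base, cea_results):
        psa = run_psa(base, 1, seed=5, sex="women", scale=0.0)
        row = psa.samples.iloc[0]
        assert row["d_cost"] == pytest.approx(cea_results["women"].d_cost, rel=1e-9)
        assert row["averted"] == pytest.approx(
            cea_results["women"].fractures_averted, rel=1e-9)

    def test_probability_at_zero_wtp_is_cost_saving_fraction(self, base):
        psa = run_psa(base, 500, seed=7, sex="men")
        frac = (psa.samples["d_cost"] < 0).mean()
        assert psa.prob_cost_effective(0.0) == frac

    def test_samples_respect_distribution_support(self, base):
        psa = run_psa(base, 500, seed=11, sex="women")
        assert (psa.samples["rr"] > 0).all()
        assert (psa.samples[["cost_fpe", "cost_ref"]] > 0).all().all()


class TestCEAC:
    def test_all_dominant_samples_give_probability_one(self, base):
        psa = run_psa(base, 8, seed=3, sex="women")
        psa.samples["d_cost"] = -1.0
        psa.samples["averted"] = 0.001
        curve = ceac(psa, np.array([0.0, 1e5, 5e5]))
        assert (curve["prob_cost_effective"] == 1.0).all()

    def test_curve_start_equals_cost_saving_fraction(self, base):
        psa = run_psa(base, 400, seed=9, sex="women")
        curve = ceac(psa, np.array([0.0, 2e5]))
        assert curve["prob_cost_effective"].iloc[0] == (
            psa.samples["d_cost"] < 0).mean()

    def test_probabilities_in_unit_interval(self, base):
        psa = run_psa(base, 300, seed=13, sex="men")
        curve = ceac(psa)
        assert curve["prob_cost_effective"].between(0, 1).all()
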