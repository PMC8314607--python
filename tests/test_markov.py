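"""Transition matrices and the cohort trace."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fpecea
from fpecea.markov import TransitionError, build_matrix, rr_effective, run_cohort
from fpecea.synthetic import generate_parameter_set

from conftest import assert_row_stochastic


def _zero_intervention(params):
    ps = params.copy()
    for col in ("value", "low", "high", "sd"):
        ps.intervention[col] = 0.0
    return ps


def _everyone_dies(params):
    """Certain death every cycle; the WELL row keeps room for fractures."""
    ps = params.copy()
    post = ps.clinical["parameter"].str.startswith("p_mort") \
        & (ps.clinical["parameter"] != "p_mort_well")
    ps.clinical.loc[post, ["value", "low", "high"]] = 1.0
    for idx, row in ps.clinical[ps.clinical["parameter"] == "p_mort_well"].iterrows():
        ff = ps.clinical[
            (ps.clinical["parameter"] == "p_first_fracture")
            & (ps.clinical["sex"] == row["sex"])
            & (ps.clinical["age_lower"] == row["age_lower"])
        ]["value"].iloc[0]
        ps.clinical.loc[idx, ["value", "low", "high"]] = 1.0 - ff
    ps.validate()
    return ps


class TestRrEffective:
    def test_no_residual_effect_leaves_risk_unchanged(self, base):
        eff = base.effect
        assert rr_effective(eff, 0.0) == 1.0

    def test_full_effect_full_participation_gives_raw_rr(self, base):
        eff = fpecea.InterventionEffect(participation_rate=1.0)
        assert rr_effective(eff, 1.0) == pytest.approx(0.73)

    def test_half_participation_dilutes_linearly(self):
        eff = fpecea.InterventionEffect(participation_rate=0.5)
        assert rr_effective(eff, 1.0) == pytest.approx(1 - 0.5 * 0.27)

    def test_rejects_multiplier_outside_unit_interval(self, base):
        with pytest.raises(ValueError):
            rr_effective(base.effect, 1.5)


class TestBuildMatrix:
    def test_death_row_is_absorbing(self, base):
        M = build_matrix(base, 80, 10, "no-fpe", sex="men")
        assert M[-1].tolist() == [0, 0, 0, 0, 0, 1]

    def test_well_row_composes_additively(self, base):
        M = build_matrix(base, 75, 0, "no-fpe", sex="women")
        W, H, D = 0, 1, 5
        assert M[W, H] == pytest.approx(0.003)
        assert M[W, D] == pytest.approx(0.009)
        assert M[W, W] == pytest.approx(0.988)

    def test_intervention_arm_scales_first_fracture_by_rr(self, base):
        ps = base.with_effect(participation_rate=1.0)
        M = build_matrix(ps, 75, 0, "fpe", effect_multiplier=1.0, sex="women")
        assert M[0, 1] == pytest.approx(0.003 * 0.73)

    def test_rows_are_stochastic_everywhere(self, base):
        for sex in ("women", "men"):
            for cycle, age in ((0, 75), (10, 80), (30, 90), (49, 99.5)):
                for arm in ("fpe", "no-fpe"):
                    assert_row_stochastic(build_matrix(base, age, cycle, arm, sex=sex))

    def test_excess_probability_mass_raises(self, base):
        ps = base.copy()
        mask = ps.clinical["parameter"].isin(["p_nh_admission", "p_refracture_acute"])
        ps.clinical.loc[mask, ["value", "low", "high"]] = 0.6
        with pytest.raises(TransitionError):
            build_matrix(ps, 75, 0, "no-fpe", sex="women")


class TestCohortTrace:
    def test_occupancy_conservation_and_monotone_death(self, traces):
        for trace in traces.values():
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            dead = trace.occupancy[:, -1]
            assert np.all(np.diff(dead) >= -1e-15)
            for series in (trace.cost_ltc_by_cycle, trace.cost_treatment_by_cycle,
                           trace.first_fractures_by_cycle, trace.refractures_by_cycle):
                assert np.all(series >= 0)

    def test_horizon_is_fifty_cycles_from_age_75(self, traces):
        trace = traces[("women", "no-fpe")]
        assert trace.occupancy.shape == (51, 6)
        assert trace.ages[0] == 75
        assert trace.ages[-1] == pytest.approx(99.5)

    def test_base_case_totals_match_published_table(self, traces):
        """Expected fractures and admissions per woman/man without the program."""
        women = traces[("women", "no-fpe")]
        assert women.cum_hip_fractures == pytest.approx(0.1916, rel=0.05)
        assert women.cum_refractures == pytest.approx(0.0401, rel=0.25)
        men = traces[("men", "no-fpe")]
        assert men.cum_hip_fractures == pytest.approx(0.0729, rel=0.12)
        for trace in (women, men):
            assert 0 < trace.cum_nh_admissions < trace.cum_hip_fractures

    def test_all_dead_after_first_cycle_stops_fractures(self, base):
        ps = _everyone_dies(base)
        trace = run_cohort(ps, "no-fpe", sex="women")
        assert trace.occupancy[2:, -1] == pytest.approx(1.0)
        assert trace.first_fractures_by_cycle[1:].sum() == 0.0

    def test_zero_mortality_keeps_everyone_alive(self, base):
        ps = base.copy()
        mask = ps.clinical["parameter"].str.startswith("p_mort")
        ps.clinical.loc[mask, ["value", "low", "high"]] = 0.0
        ps.validate()
        trace = run_cohort(ps, "fpe", sex="men")
        assert trace.occupancy[:, -1].max() == 0.0

    def test_no_admissions_means_empty_nursing_home(self, base):
        ps = base.copy()
        mask = ps.clinical["parameter"] == "p_nh_admission"
        ps.clinical.loc[mask, ["value", "low", "high"]] = 0.0
        ps.validate()
        trace = run_cohort(ps, "no-fpe", sex="women")
        NH, RE = 3, 4
        assert trace.occupancy[:, NH].max() == 0.0
        assert trace.occupancy[:, RE].max() == 0.0
        assert trace.cum_nh_admissions == 0.0

    def test_null_effect_and_free_program_make_arms_identical(self, base):
        ps = _zero_intervention(base).with_effect(rr=1.0, rr_low=1.0, rr_high=1.0)
        fpe = run_cohort(ps, "fpe", sex="women")
        ref = run_cohort(ps, "no-fpe", sex="women")
        np.testing.assert_array_equal(fpe.occupancy, ref.occupancy)
        assert fpe.cum_cost == ref.cum_cost
        assert fpe.cum_hip_fractures == ref.cum_hip_fractures

    def test_intervention_cost_only_in_program_years_of_fpe_arm(self, traces):
        fpe = traces[("women", "fpe")]
        ref = traces[("women", "no-fpe")]
        assert ref.cost_intervention == 0.0
        assert fpe.cost_intervention_by_cycle[:8].min() > 0
        assert fpe.cost_intervention_by_cycle[8:].max() == 0.0

    def test_trace_export_is_tidy(self, traces):
        frame = traces[("men", "fpe")].to_frame()
        assert {"cycle", "age", "WELL", "DEAD", "cost_ltc",
                "first_fractures"} <= set(frame.columns)
        assert len(frame) == 51


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_random_parameter_sets_keep_invariants(seed):
    """Row-stochastic matrices and conserved occupancy for perturbed inputs."""
    ps = generate_parameter_set(seed)
    arm = "fpe" if seed % 2 else "no-fpe"
    sex = "women" if seed % 3 else "men"
    trace = run_cohort(ps, arm, sex=sex)
    np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(np.diff(trace.occupancy[:, -1]) >= -1e-15)
    assert trace.cum_cost >= 0
    M = build_matrix(ps, 85, 20, arm, sex=sex)
    assert_row_stochastic(M)
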