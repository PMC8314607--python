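"""Parameter loading, validation and lookup."""

import numpy as np
import pandas as pd
import pytest

import fpecea
from fpecea.parameters import ParameterValidationError, lookup, write_parameters

BANDS5 = [75, 80, 85, 90, 95]

# Published clinical inputs, cell for cell (per 6-month cycle, women/men by
# five age bands 75-79 ... 95+).
TABLE1 = {
    "p_first_fracture": {
        "women": [0.003, 0.006, 0.010, 0.015, 0.019],
        "men": [0.002, 0.003, 0.005, 0.009, 0.012],
    },
    "p_first_fracture_late": {
        "women": [0.004, 0.009, 0.014, 0.020, 0.025],
        "men": [0.002, 0.004, 0.007, 0.012, 0.016],
    },
    "p_refracture_acute": {
        "women": [0.018, 0.034, 0.055, 0.075, 0.094],
        "men": [0.009, 0.017, 0.027, 0.043, 0.058],
    },
    "p_refracture_late": {
        "women": [0.019, 0.023, 0.027, 0.029, 0.025],
        "men": [0.013, 0.018, 0.021, 0.025, 0.023],
    },
    "p_refracture_nh": {
        "women": [0.064, 0.079, 0.084, 0.091, 0.069],
        "men": [0.030, 0.043, 0.039, 0.047, 0.015],
    },
    "p_nh_admission": {
        "women": [0.067, 0.117, 0.147, 0.180, 0.201],
        "men": [0.066, 0.096, 0.106, 0.117, 0.186],
    },
    "p_mort_well": {
        "women": [0.009, 0.016, 0.029, 0.063, 0.063],
        "men": [0.018, 0.030, 0.047, 0.074, 0.074],
    },
    "p_mort_acute_fracture": {
        "women": [0.038, 0.056, 0.073, 0.129, 0.129],
        "men": [0.082, 0.109, 0.130, 0.188, 0.188],
    },
    "p_mort_post_fracture": {
        "women": [0.018, 0.023, 0.042, 0.076, 0.076],
        "men": [0.032, 0.045, 0.069, 0.101, 0.101],
    },
    "p_mort_nh": {
        "women": [0.134, 0.134, 0.161, 0.161, 0.217],
        "men": [0.224, 0.223, 0.266, 0.265, 0.332],
    },
    "p_mort_nh_refracture": {
        "women": [0.252, 0.251, 0.298, 0.297, 0.389],
        "men": [0.435, 0.433, 0.501, 0.500, 0.597],
    },
}

TABLE2_FLAT = {"hospital_care": 7280, "revision": 961,
               "rehabilitation": 2209, "outpatient_care": 1114,
               "ltc_nursing_home": 8516}
TABLE2_LTC = {
    "ltc_well": {"women": [394, 831, 1601, 2550], "men": [348, 651, 1221, 2000]},
    "ltc_post_fracture": {"women": [990, 2264, 3274, 4519],
                          "men": [918, 2000, 2748, 3764]},
}
INTERVENTION = {"women": [139, 93, 49, 5, 0], "men": [139, 94, 49, 5, 0]}


def test_bundled_tables_match_published_inputs(base):
    """Every clinical and cost cell equals the published point estimate."""
    for name, by_sex in TABLE1.items():
        for sex, values in by_sex.items():
            got = base.clinical_values(name, sex)["value"].tolist()
            assert got == pytest.approx(values), (name, sex)
    for name, value in TABLE2_FLAT.items():
        assert base.cost_values(name, "women")["value"].iloc[0] == value
    for name, by_sex in TABLE2_LTC.items():
        for sex, values in by_sex.items():
            assert base.cost_values(name, sex)["value"].tolist() == values
    for sex, values in INTERVENTION.items():
        assert base.intervention_schedule(sex).tolist() == values
    assert base.treatment_cost_total() == 7280 + 961 + 2209 + 1114


def test_lookup_maps_age_to_band(base):
    assert lookup(base, 83, "p_nh_admission", "women")[0] == 0.117
    assert lookup(base, 99, "p_refracture_nh", "men")[0] == 0.015
    # open-ended bands: 95+ pre-fracture mortality equals the 90-94 value
    assert (lookup(base, 97, "p_mort_well", "women")
            == lookup(base, 92, "p_mort_well", "women"))
    assert lookup(base, 75, "p_first_fracture", "women")[0] == 0.003
    assert lookup(base, 80, "ltc_well", "men")[0] == 651


@pytest.mark.parametrize("age", [74, 101, -3])
def test_lookup_rejects_out_of_range_age(base, age):
    with pytest.raises(ValueError):
        lookup(base, age, "p_first_fracture", "women")


def test_range_autofill_is_twenty_percent_clipped(base):
    """Cells without published CIs get [0.8p, 1.2p] intersected with [0,1]."""
    clin = base.clinical
    np.testing.assert_allclose(clin["low"], np.clip(0.8 * clin["value"], 0, 1))
    np.testing.assert_allclose(clin["high"], np.clip(1.2 * clin["value"], 0, 1))
    costs = base.costs
    np.testing.assert_allclose(costs["sd"], 0.4 * costs["value"])
    assert (base.intervention["sd"] == 0.5 * base.intervention["value"]).all()


def test_roundtrip_write_load(base, tmp_path):
    write_parameters(base, tmp_path)
    again = fpecea.load_parameters(tmp_path)
    pd.testing.assert_frame_equal(base.clinical, again.clinical)
    pd.testing.assert_frame_equal(base.costs, again.costs)
    pd.testing.assert_frame_equal(base.intervention, again.intervention)
    assert again.effect == base.effect
    assert again.settings == base.settings
    assert again.param_hash() == base.param_hash()


def test_out_of_range_probability_is_rejected(base):
    ps = base.copy()
    mask = (ps.clinical["parameter"] == "p_mort_well") & (ps.clinical["sex"] == "women")
    ps.clinical.loc[mask.idxmax(), "value"] = 1.3
    with pytest.raises(ParameterValidationError) as err:
        ps.validate()
    assert "p_mort_well" in str(err.value)
    assert "women" in str(err.value)


def test_missing_cells_are_rejected(base):
    ps = base.copy()
    drop = (ps.clinical["parameter"] == "p_nh_admission") & (ps.clinical["sex"] == "men")
    clinical = ps.clinical[~drop]
    with pytest.raises(ParameterValidationError) as err:
        fpecea.ParameterSet(clinical=clinical, costs=ps.costs,
                            intervention=ps.intervention,
                            effect=ps.effect, settings=ps.settings)
    assert "p_nh_admission" in str(err.value)


def test_effect_decay_reaches_zero():
    eff = fpecea.InterventionEffect()
    mult = [eff.decay_multiplier(y) for y in range(6)]
    assert mult[0] == 1.0
    assert mult[1] == pytest.approx(0.72)
    assert all(a >= b for a, b in zip(mult, mult[1:]))
    assert mult[4] == mult[5] == 0.0
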