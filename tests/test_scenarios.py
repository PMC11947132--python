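"""Synthetic two-trial generator: reproducibility, moments, truth by construction."""
import numpy as np
import pandas as pd
import pydantic
import pytest
from scipy import stats

import anchormaic as am
from anchormaic.exceptions import MAICError, SimulationError


def _single_endpoint_scenario(**overrides):
    kwargs = dict(
        effects={"off_change": -1.1},
        baseline_slope={"off_change": 0.0},
        noise_sd={"off_change": 0.0},
        event_probs={},
    )
    kwargs.update(overrides)
    return am.TrialScenario(**kwargs)


def test_identical_seed_gives_bit_identical_tables():
    scn = am.xindi_like(seed=42)
    a = am.simulate_trial(scn)
    b = am.simulate_trial(scn)
    assert a.to_csv(index=False) == b.to_csv(index=False)
    c = am.simulate_trial(scn, seed=43)
    assert a.to_csv(index=False) != c.to_csv(index=False)


def test_off_baseline_respects_inclusion_threshold(ipd, comparator_ipd):
    assert (ipd["off_baseline"] >= 1.5).all()
    assert (comparator_ipd["off_baseline"] >= 1.0).all()


def test_noise_free_limit_recovers_configured_effect():
    scn = _single_endpoint_scenario()
    t = am.simulate_trial(scn, seed=3)
    diff = (
        t.loc[t.arm == "active", "off_change"].mean()
        - t.loc[t.arm == "anchor", "off_change"].mean()
    )
    assert diff == pytest.approx(-1.1, abs=1e-12)


def test_covariate_moments_match_configuration_at_large_n():
    scn = am.xindi_like(n_active=5000, n_anchor=5000, seed=11)
    t = am.simulate_trial(scn)
    n = len(t)
    assert t["age"].mean() == pytest.approx(61.6, abs=3 * 9.3 / np.sqrt(n))
    assert t["bmi"].mean() == pytest.approx(23.9, abs=3 * 3.0 / np.sqrt(n))
    assert t["male"].mean() == pytest.approx(
        0.58, abs=3 * np.sqrt(0.58 * 0.42 / n)
    )
    # OFF time is left-truncated at the inclusion threshold, so the oracle is
    # the truncated-normal mean, not the parent mean.
    a = (1.5 - 5.7) / 3.0
    trunc_mean = stats.truncnorm.mean(a, np.inf, loc=5.7, scale=3.0)
    trunc_sd = stats.truncnorm.std(a, np.inf, loc=5.7, scale=3.0)
    assert t["off_baseline"].mean() == pytest.approx(
        trunc_mean, abs=3 * trunc_sd / np.sqrt(n)
    )


def test_safety_flags_follow_arm_probabilities():
    scn = am.xindi_like(n_active=4000, n_anchor=4000, seed=5)
    t = am.simulate_trial(scn)
    p_active = t.loc[t.arm == "active", "ae"].mean()
    p_anchor = t.loc[t.arm == "anchor", "ae"].mean()
    assert p_active == pytest.approx(0.52, abs=3 * np.sqrt(0.25 / 4000))
    assert p_anchor == pytest.approx(0.42, abs=3 * np.sqrt(0.25 / 4000))


def test_invalid_scenarios_are_rejected():
    with pytest.raises(pydantic.ValidationError):
        am.TrialScenario(n_active=0)
    with pytest.raises(pydantic.ValidationError):
        am.TrialScenario(age_sd=-1.0)
    with pytest.raises(pydantic.ValidationError):
        am.TrialScenario(event_probs={"ae": (0.0, 0.5)})
    with pytest.raises(pydantic.ValidationError):
        am.TrialScenario(modifier_coeffs={"off_change": {"height": 1.0}})


def test_impossible_truncation_raises():
    scn = _single_endpoint_scenario(
        n_active=5, n_anchor=5, off_mean=2.0, off_sd=0.5, off_min_inclusion=30.0
    )
    with pytest.raises(SimulationError):
        am.simulate_trial(scn)


def test_aggregate_all_male_gives_proportion_one():
    t = am.simulate_trial(am.xindi_like(n_active=30, n_anchor=30, male_prop=1.0, seed=2))
    agd = am.aggregate_trial(t)
    assert agd.target("male").value == 1.0
    assert agd.target("male").kind == "binary"


def test_aggregate_null_contrast_when_arms_identical():
    # mirrored arms: same covariates and same endpoint values in both arms
    half = pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(6)],
            "center": [0] * 6,
            "age": [60, 62, 64, 58, 61, 63],
            "male": [1, 0, 1, 0, 1, 0],
            "bmi": [22.0, 23.0, 24.0, 25.0, 23.5, 22.5],
            "off_baseline": [4.0, 5.0, 6.0, 7.0, 5.5, 4.5],
            "off_change": [-1.0, -0.5, -2.0, 0.0, -1.5, -0.3],
        }
    )
    t = pd.concat(
        [half.assign(arm="active"), half.assign(arm="anchor")], ignore_index=True
    )
    agd = am.aggregate_trial(t, endpoints=["off_change"], safety_endpoints=[])
    assert agd.contrast("off_change").estimate == pytest.approx(0.0, abs=1e-10)


def test_aggregate_errors():
    t = am.simulate_trial(am.xindi_like(n_active=20, n_anchor=20, seed=1))
    with pytest.raises(MAICError):
        am.aggregate_trial(t[t.arm == "active"])
    t2 = t.copy()
    t2["bmi"] = 23.0
    with pytest.raises(MAICError, match="zero variance"):
        am.aggregate_trial(t2)


def test_aggregate_recovers_study1_configuration(comparator_ipd, agd):
    n = len(comparator_ipd)
    assert agd.n_total == n
    assert agd.target("male").value == pytest.approx(0.66, abs=3 * np.sqrt(0.25 / n))
    assert agd.target("bmi").value == pytest.approx(23.1, abs=3 * 3.2 / np.sqrt(n))
    a = (1.0 - 6.1) / 2.6
    trunc_mean = stats.truncnorm.mean(a, np.inf, loc=6.1, scale=2.6)
    assert agd.target("off_baseline").value == pytest.approx(
        trunc_mean, abs=3 * 2.6 / np.sqrt(n)
    )


def test_paired_scenarios_identical_except_seed():
    a, b = am.make_paired_scenarios(seed=9)
    da, db = a.model_dump(), b.model_dump()
    assert da.pop("seed") == 9 and db.pop("seed") == 10
    assert da == db


def test_paired_scenarios_reproduce_direction_of_imbalance(paired_scenarios):
    ipd_scn, comp_scn = paired_scenarios
    assert comp_scn.male_prop > ipd_scn.male_prop
    assert comp_scn.bmi_mean < ipd_scn.bmi_mean
    assert comp_scn.off_mean > ipd_scn.off_mean
    assert (comp_scn.n_active, comp_scn.n_anchor) == (163, 158)


def test_effect_modification_biases_naive_but_not_maic():
    """With covariate-by-treatment interactions and covariate shift, the
    unweighted Bucher estimate drifts from the construction truth of zero
    while the MAIC estimate does not."""
    from anchormaic.simulationstudy import modifier_bias

    out = modifier_bias(n_reps=50, seed=7)
    assert abs(out["naive_bias"]) > 0.18
    assert abs(out["maic_bias"]) < 0.15
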