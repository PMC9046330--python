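"""Configuration loading, validation and serialisation."""

import pytest

import fallscea as fc
from fallscea import ConfigError, ValidationError


class TestDefaultConfig:
    def test_published_means_loaded(self, params):
        assert params.p_fall_year1 == 0.36
        assert params.p_fall_recurrent == 0.65
        assert params.rr_fall_exercise == 0.76
        assert params.p_fracture_annual == 0.12
        assert params.rr_fracture_exercise == 0.44
        assert params.c_fx_major == 20724
        assert params.c_intervention == 767
        assert params.u_baseline == 0.79
        assert params.u_recurrent_control == 0.72
        assert params.u_recurrent_exercise == 0.74
        assert params.p_death_fall_by_age == {
            "60_64": 0.023,
            "65_69": 0.043,
            "70_74": 0.065,
        }

    def test_settings(self, params):
        assert params.start_age == 68
        assert params.horizon_years == 3
        assert params.cycle_months == 3
        assert params.discount_annual == 0.05
        assert params.wtp == 50000
        assert params.n_cycles == 12
        assert params.cycle_fraction == 0.25

    def test_every_uncertain_parameter_has_an_estimate(self, params):
        # all value fields plus the three fall-death bands carry CIs
        expected = set(fc.parameters.VALUE_FIELDS) | {
            f"p_death_fall_{b}" for b in fc.parameters.FALL_DEATH_BANDS
        }
        assert set(params.estimates) == expected

    def test_intervention_cost_components_sum_to_total(self, params):
        comps = params.intervention_cost_components
        assert comps is not None
        assert fc.intervention_cost_total(comps) == params.c_intervention

    def test_background_mortality_covers_model_ages(self, params):
        assert min(params.background_mortality) <= 60
        assert max(params.background_mortality) >= 75
        assert all(0 < q < 0.1 for q in params.background_mortality.values())
        # clamped outside the table
        assert params.background_mortality_at(59) == params.background_mortality[60]
        assert params.background_mortality_at(80) == params.background_mortality[75]

    def test_fall_death_band_lookup(self, params):
        assert params.fall_death_at(64.9) == 0.023
        assert params.fall_death_at(65.0) == 0.043
        assert params.fall_death_at(70.25) == 0.065  # cohort age at cycle 9
        assert params.fall_death_at(90.0) == 0.065  # clamped to the last band


class TestValidation:
    def test_split_must_sum_to_one(self, params):
        with pytest.raises(ValidationError, match="p_fx_major"):
            params.replace(p_fx_major=0.62, p_fx_minor=0.30)

    def test_probability_bounds(self, params):
        with pytest.raises(ValidationError, match="p_fall_year1"):
            params.replace(p_fall_year1=1.2)

    def test_negative_cost_rejected(self, params):
        with pytest.raises(ValidationError, match="c_fx_major"):
            params.replace(c_fx_major=-1.0)

    def test_nonpositive_rr_rejected(self, params):
        with pytest.raises(ValidationError, match="rr_fall_exercise"):
            params.replace(rr_fall_exercise=0.0)

    def test_horizon_must_divide_into_cycles(self, params):
        with pytest.raises(ValidationError):
            params.replace(horizon_years=3, cycle_months=5)

    def test_zero_horizon_rejected(self, params):
        with pytest.raises(ValidationError):
            params.replace(horizon_years=0)

    def test_unknown_override_named(self, params):
        with pytest.raises(ValidationError, match="not_a_parameter"):
            params.replace(not_a_parameter=1.0)


class TestConfigErrors:
    def test_unknown_top_level_key(self):
        with pytest.raises(ConfigError, match="typo_section"):
            fc.load_parameters({"typo_section": {}})

    def test_unknown_parameter_name(self):
        with pytest.raises(ConfigError, match="p_fall_yr1"):
            fc.load_parameters({"parameters": {"p_fall_yr1": 0.3}})

    def test_incomplete_parameter_section(self):
        with pytest.raises(ConfigError, match="incomplete"):
            fc.load_parameters({"parameters": {"p_fall_year1": 0.36}})

    def test_estimate_missing_ci(self):
        with pytest.raises(ConfigError, match="missing"):
            fc.load_parameters(
                {"parameters": {"p_fall_year1": {"mean": 0.36, "family": "beta"}}}
            )

    def test_component_total_mismatch(self, tmp_path, params):
        path = tmp_path / "bad.yaml"
        fc.dump_parameters(params, path)
        import yaml

        doc = yaml.safe_load(path.read_text())
        doc["intervention_cost_components"] = {"a": 1, "b": 2}
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        with pytest.raises(ConfigError, match="components"):
            fc.load_parameters(path)


class TestScenarioOverride:
    def test_high_cost_delivery_scenario_loads(self, params):
        scenario = fc.ScenarioOverride("SA4a", {"c_intervention": 3304})
        overridden = scenario.apply(params)
        assert overridden.c_intervention == 3304
        assert overridden.p_fall_year1 == params.p_fall_year1

    def test_band_override_via_flat_key(self, params):
        overridden = params.replace(p_death_fall_65_69=0.05)
        assert overridden.p_death_fall_by_age["65_69"] == 0.05
        assert overridden.p_death_fall_by_age["60_64"] == 0.023

    def test_invalid_override_value_rejected(self, params):
        with pytest.raises(ValidationError):
            fc.ScenarioOverride("bad", {"u_baseline": 1.5}).apply(params)


def test_dump_load_round_trip(tmp_path, params):
    """load -> serialise -> load is the identity on the parameter set."""
    path = tmp_path / "roundtrip.yaml"
    fc.dump_parameters(params, path)
    again = fc.load_parameters(path)
    assert again == params
    assert again.estimates == params.estimates
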