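"""Parameter inventory, treated-rate arithmetic, lookup and config I/O."""

import math

import pytest

from pdcea import parameters as pm

# Every scalar of the published input inventory, keyed by registry id
# (age-banded entries) or checked directly below (stage dicts, settings).
PRINTED_INVENTORY = {
    "incidence.pd.50-59": 0.000211,
    "incidence.pd.60-69": 0.000995,
    "incidence.pd.70-79": 0.003005,
    "incidence.pd.80+": 0.003699,
    "incidence.dm.40-49": 0.00964,
    "incidence.dm.50-59": 0.00964,
    "incidence.dm.60-69": 0.01906,
    "incidence.dm.70-79": 0.01906,
    "incidence.dm.80+": 0.01637,
    "incidence.pd_given_dm.50-59": 0.000464,
    "incidence.pd_given_dm.60-69": 0.001542,
    "incidence.pd_given_dm.70-79": 0.004658,
    "incidence.pd_given_dm.80+": 0.005733,
    "mortality.dm.40-49": 0.01510,
    "mortality.dm.50-59": 0.02195,
    "mortality.dm.60-69": 0.03931,
    "mortality.dm.70-74": 0.05288,
    "mortality.dm.75+": 0.08150,
    "mortality.other.40-49": 0.00266,
    "mortality.other.50-59": 0.00507,
    "mortality.other.60-69": 0.01028,
    "mortality.other.70-79": 0.02677,
    "mortality.other.80+": 0.05722,
    "effects.dm_mortality_factor": 0.88,
    "effects.dm_utility_increment": 0.08,
    "costs.pd_medical.hy2": 69074.2,
    "costs.pd_medical.hy3": 71969.3,
    "costs.pd_medical.hy4": 133558.1,
    "costs.pddm_medical.hy2": 90217.1,
    "costs.pddm_medical.hy3": 77079.1,
    "costs.pd_productivity_loss.hy1": 17261.2,
    "costs.pd_productivity_loss.hy2": 52185.1,
    "costs.pd_productivity_loss.hy3": 95538.9,
    "costs.pd_productivity_loss.hy4": 54593.7,
    "costs.dm_medical.40-49": 43903.6,
    "costs.dm_medical.50-59": 58903.6,
    "costs.dm_medical.60-69": 73903.6,
    "costs.dm_medical.70-79": 88903.6,
    "costs.dm_medical.80+": 103903.6,
    "utilities.pd.hy1": 0.708,
    "utilities.pd.hy2": 0.678,
    "utilities.pd.hy3": 0.622,
    "utilities.pd.hy4": 0.499,
    "utilities.dm_decrement": 0.04,
    "utilities.dm_annual_decline": 0.003,
    "utilities.normal.40-64": 0.92,
    "utilities.normal.65+": 0.84,
    "economics.discount_rate": 0.03,
}


@pytest.mark.parametrize("pid,expected", sorted(PRINTED_INVENTORY.items()))
def test_published_inventory_values(defaults, pid, expected):
    assert pm.get_parameter(defaults, pid) == expected


def test_published_inventory_remainder(defaults):
    ps = defaults
    assert pm.get_parameter(ps, "incidence.pd.40-49") == 0.0
    assert pm.get_parameter(ps, "incidence.pd_given_dm.40-49") == 0.0
    assert ps.mortality.pd_stage == {"hy1": 0.01, "hy2": 0.048,
                                     "hy3": 0.080, "hy4": 0.199}
    assert ps.rates_pd.as_tuple() == (0.3237, 0.068, 0.3192)
    assert ps.rates_pddm.as_tuple() == (0.4369, 0.1462, 0.3192)
    assert (ps.effects.m1, ps.effects.m2, ps.effects.m3) == (0.947, 0.239, 0.206)
    assert ps.costs.pd_medical["hy1"] == 21821.9
    assert ps.costs.pddm_medical["hy1"] == 21821.9
    assert ps.costs.pddm_medical["hy4"] == 148740.9
    assert ps.costs.home_care == {"hy1": 0.0, "hy2": 0.0,
                                  "hy3": 22220.0, "hy4": 22220.0}
    assert ps.costs.dm_productivity_loss.to_dict() == {
        "40-49": 635049.0, "50-59": 605055.6, "60-69": 481893.0, "70+": 0.0}
    assert ps.costs.exenatide_annual == 33926.8
    assert ps.economics.dm_prevalence_at_entry == 0.0605
    assert ps.economics.wtp_gdp == 839558.0
    assert ps.economics.cohort_size == 1000
    assert ps.economics.entry_age == 40
    assert ps.economics.horizon_cycles == 50


def test_defaults_pass_validation(defaults):
    assert pm.validate(defaults) == []


def test_sa_ranges_bracket_base_values(defaults):
    for pid, rng in defaults.ranges.items():
        base = pm.get_parameter(defaults, pid)
        assert rng.low <= base <= rng.high, pid


class TestTreatedRates:
    """Treated rates are the product of base rates and effect multipliers."""

    def test_pd_row(self, defaults):
        treated = pm.derive_treated_rates(defaults.rates_pd, defaults.effects)
        assert pm.displayed_rates(treated) == (0.3065, 0.0163, 0.0658)

    def test_pddm_row(self, defaults):
        treated = pm.derive_treated_rates(defaults.rates_pddm, defaults.effects)
        assert pm.displayed_rates(treated) == (0.4137, 0.0349, 0.0658)

    def test_identity_multipliers_leave_rates_unchanged(self, defaults):
        eff = pm.ExenatideEffectSet(1.0, 1.0, 1.0, 1.0, 0.0)
        treated = pm.derive_treated_rates(defaults.rates_pd, eff)
        assert treated.as_tuple() == defaults.rates_pd.as_tuple()

    def test_unrounded_internally(self, defaults):
        treated = defaults.rates_pd_treated()
        assert treated.lam1 == pytest.approx(0.3237 * 0.947, abs=1e-12)
        assert treated.lam1 != 0.3065

    def test_printed_pddm_lambda3_switch(self, defaults):
        # the published table prints 0.0210 for this cell although its
        # own annotation (0.3192*0.206) gives 0.0658; both supported
        assert defaults.rates_pddm_treated().lam3 == pytest.approx(
            0.3192 * 0.206)
        defaults.options.use_printed_pddm_lambda3 = True
        assert defaults.rates_pddm_treated().lam3 == 0.0210


def test_exenatide_dm_mortality_derivation(defaults):
    """conventional DM mortality x 0.88 reproduces the printed treated
    column to the 5 printed decimals."""
    printed = {"40-49": 0.01329, "50-59": 0.01932, "60-69": 0.03459,
               "70-74": 0.04653, "75+": 0.07172}
    for band in defaults.mortality.dm.bands:
        derived = defaults.dm_mortality_exenatide(band.lower)
        assert round(derived, 5) == printed[band.key]


class TestLookup:
    def test_printed_examples(self, defaults):
        assert pm.lookup(defaults.mortality.dm, 45) == 0.01510
        assert pm.lookup(defaults.incidence.pd, 40) == 0.0
        assert pm.lookup(defaults.mortality.other, 80) == 0.05722

    def test_boundaries_inclusive_lower(self, defaults):
        assert pm.lookup(defaults.mortality.other, 50) == 0.00507
        assert pm.lookup(defaults.mortality.other, 49.9) == 0.00266
        assert pm.lookup(defaults.mortality.dm, 75) == 0.08150

    def test_total_over_model_ages(self, defaults):
        tables = [defaults.incidence.pd, defaults.incidence.dm,
                  defaults.incidence.pd_given_dm, defaults.mortality.dm,
                  defaults.mortality.other, defaults.costs.dm_medical,
                  defaults.costs.dm_productivity_loss,
                  defaults.utilities.normal]
        for table in tables:
            for age in range(40, 120):
                assert math.isfinite(pm.lookup(table, age))

    def test_age_below_first_band(self, defaults):
        with pytest.raises(KeyError):
            pm.lookup(defaults.mortality.dm, 39)


class TestValidate:
    def test_violation_names_field(self, defaults):
        defaults.mortality.pd_stage["hy2"] = -0.1
        problems = pm.validate(defaults)
        assert any("mortality.pd_stage.hy2" in p for p in problems)

    def test_range_excluding_base_flagged(self, defaults):
        defaults.ranges["utilities.pd.hy1"] = pm.ParameterRange(0.9, 0.95)
        problems = pm.validate(defaults)
        assert any("ranges.utilities.pd.hy1" in p for p in problems)

    def test_non_monotone_pd_utilities_flagged(self, defaults):
        defaults.utilities.pd["hy3"] = 0.7  # above stage 2
        assert any("utilities.pd" in p for p in pm.validate(defaults))


class TestConfigIO:
    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_round_trip(self, defaults, tmp_path, suffix):
        path = tmp_path / f"params{suffix}"
        pm.save_parameters(defaults, path)
        loaded = pm.load_parameters(path)
        assert pm.to_dict(loaded) == pm.to_dict(defaults)
        # save(load(p)) is value-identical to load(p)
        path2 = tmp_path / f"again{suffix}"
        pm.save_parameters(loaded, path2)
        assert pm.to_dict(pm.load_parameters(path2)) == pm.to_dict(loaded)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            pm.load_parameters(tmp_path / "nope.yaml")

    def test_unknown_key_is_error_naming_key(self, defaults, tmp_path):
        data = pm.to_dict(defaults)
        data["utilities"]["typo_key"] = 1.0
        path = tmp_path / "bad.json"
        path.write_text(__import__("json").dumps(data))
        with pytest.raises(pm.ConfigError, match="typo_key"):
            pm.load_parameters(path)

    def test_out_of_bounds_utility_rejected(self, defaults, tmp_path):
        data = pm.to_dict(defaults)
        data["utilities"]["pd"]["hy1"] = 1.3
        path = tmp_path / "bad.json"
        path.write_text(__import__("json").dumps(data))
        with pytest.raises(pm.ConfigError, match="utilities.pd"):
            pm.load_parameters(path)

    def test_non_numeric_value_rejected(self, defaults, tmp_path):
        data = pm.to_dict(defaults)
        data["mortality"]["dm"]["40-49"] = "high"
        path = tmp_path / "bad.json"
        path.write_text(__import__("json").dumps(data))
        with pytest.raises(pm.ConfigError, match="mortality.dm"):
            pm.load_parameters(path)

    def test_discount_override(self, defaults, tmp_path):
        data = pm.to_dict(defaults)
        data["economics"]["discount_rate"] = 0.0
        path = tmp_path / "zero.json"
        path.write_text(__import__("json").dumps(data))
        assert pm.load_parameters(path).economics.discount_rate == 0.0
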