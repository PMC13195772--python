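"""ICD-10 mapping, attributable counts, proportions, age standardization."""

import numpy as np
import pandas as pd
import pytest

from aafengine.attribution import (
    age_standardize,
    attributable_deaths,
    build_code_index,
    build_death_table,
    expand_code_patterns,
    map_icd10,
    proportion_of_total,
    rate_table,
)
from aafengine.constants import who_standard_weights


class TestCodeMapping:
    def test_prefix_match_with_fourth_character(self, registry):
        index = build_code_index(registry)
        assert map_icd10("K70.3", index) == "liver_cirrhosis"
        assert map_icd10("K703", index) == "liver_cirrhosis"

    def test_unmatched_code_is_unmapped(self, registry):
        assert map_icd10("C34", build_code_index(registry)) is None

    @pytest.mark.parametrize("code", ["I20", "I25", "I20.0", "I25.9"])
    def test_range_boundaries_resolve(self, registry, code):
        assert map_icd10(code, build_code_index(registry)) == \
            "ischemic_heart_disease"

    def test_range_outside_boundary_unmapped(self, registry):
        index = build_code_index(registry)
        assert map_icd10("I26", index) is None
        assert map_icd10("I19", index) is None

    def test_malformed_code_warned_and_unmapped(self, registry, caplog):
        with caplog.at_level("WARNING"):
            assert map_icd10("7X2", build_code_index(registry)) is None
        assert "malformed" in caplog.text

    def test_empty_code_raises(self, registry):
        with pytest.raises(ValueError, match="empty"):
            map_icd10("  ", build_code_index(registry))

    def test_range_expansion(self):
        assert expand_code_patterns(["I20-I22"]) == ["I20", "I21", "I22"]
        assert expand_code_patterns(["K70", "X45"]) == ["K70", "X45"]

    @pytest.mark.parametrize("pattern", ["I25-I20", "I20-K25", "banana"])
    def test_bad_patterns_raise(self, pattern):
        with pytest.raises(ValueError):
            expand_code_patterns([pattern])


def _records(rows):
    return pd.DataFrame(rows, columns=["year", "sex", "age", "icd10"])


class TestDeathTable:
    def test_counts_conservation(self, registry):
        records = _records([
            (2020, "male", 50, "K70.3"), (2020, "male", 60, "C34"),
            (2020, "female", 40, "I21"), (2020, "male", 30, "F10.2"),
            (2020, "male", 70, "ZZZ"),
        ])
        table = build_death_table(records, registry)
        mapped = int(table.counts["deaths"].sum())
        unmapped = int(table.unmapped["unmapped"].sum())
        assert mapped + unmapped == int(table.totals["deaths"].sum()) == 5

    def test_under_15_excluded_by_default(self, registry):
        records = _records([(2020, "male", 10, "K70"),
                            (2020, "male", 50, "K70")])
        table = build_death_table(records, registry)
        assert int(table.totals["deaths"].sum()) == 1
        with_kids = build_death_table(records, registry,
                                      include_under_min_in_totals=True)
        assert int(with_kids.totals["deaths"].sum()) == 2
        # attribution never includes under-15 deaths either way
        assert int(with_kids.counts["deaths"].sum()) == 1


def _aaf_frame(cells):
    return pd.DataFrame(cells,
                        columns=["year", "sex", "age_group", "cause", "aaf"])


class TestAttributableDeaths:
    def test_aaf_times_count(self, registry):
        counts = pd.DataFrame([
            (2020, "male", "45-59", "liver_cirrhosis", 300)],
            columns=["year", "sex", "age_group", "cause", "deaths"])
        aafs = _aaf_frame([(2020, "male", "45-59", "liver_cirrhosis", 1 / 3)])
        out = attributable_deaths(counts, aafs, registry)
        assert out["attributable"].iloc[0] == pytest.approx(100.0)

    def test_fully_attributable_contributes_full_count(self, registry):
        counts = pd.DataFrame([
            (2020, "male", "45-59", "alcohol_use_disorders", 42)],
            columns=["year", "sex", "age_group", "cause", "deaths"])
        out = attributable_deaths(counts, _aaf_frame([]), registry)
        assert out["attributable"].iloc[0] == 42.0

    def test_zero_aaf_gives_zero(self, registry):
        counts = pd.DataFrame([
            (2020, "male", "45-59", "liver_cirrhosis", 300)],
            columns=["year", "sex", "age_group", "cause", "deaths"])
        aafs = _aaf_frame([(2020, "male", "45-59", "liver_cirrhosis", 0.0)])
        assert attributable_deaths(counts, aafs,
                                   registry)["attributable"].iloc[0] == 0.0

    def test_missing_aaf_raises_with_cell(self, registry):
        counts = pd.DataFrame([
            (2020, "male", "45-59", "liver_cirrhosis", 300)],
            columns=["year", "sex", "age_group", "cause", "deaths"])
        with pytest.raises(ValueError, match="liver_cirrhosis"):
            attributable_deaths(counts, _aaf_frame([]), registry)

    def test_linearity_in_counts(self, registry):
        counts = pd.DataFrame([
            (2020, "male", "45-59", "liver_cirrhosis", 150),
            (2020, "female", "60+", "alcohol_use_disorders", 7)],
            columns=["year", "sex", "age_group", "cause", "deaths"])
        aafs = _aaf_frame([(2020, "male", "45-59", "liver_cirrhosis", 0.41)])
        single = attributable_deaths(counts, aafs, registry)
        doubled = counts.assign(deaths=counts["deaths"] * 2)
        double = attributable_deaths(doubled, aafs, registry)
        np.testing.assert_allclose(double["attributable"],
                                   2 * single["attributable"])

    def test_negative_aaf_retained(self, registry):
        counts = pd.DataFrame([
            (2020, "male", "45-59", "ischemic_heart_disease", 100)],
            columns=["year", "sex", "age_group", "cause", "deaths"])
        aafs = _aaf_frame([
            (2020, "male", "45-59", "ischemic_heart_disease", -0.05)])
        out = attributable_deaths(counts, aafs, registry)
        assert out["attributable"].iloc[0] == pytest.approx(-5.0)


class TestProportions:
    def test_hand_arithmetic(self):
        att = pd.DataFrame({"year": [2020], "sex": ["male"],
                            "attributable": [146.0]})
        tot = pd.DataFrame({"year": [2020], "sex": ["male"],
                            "deaths": [1000]})
        out = proportion_of_total(att, tot)
        assert out["percent"].iloc[0] == pytest.approx(14.6)

    def test_zero_attributable_is_zero_percent(self):
        att = pd.DataFrame({"year": [2020], "sex": ["male"],
                            "attributable": [0.0]})
        tot = pd.DataFrame({"year": [2020], "sex": ["male"], "deaths": [50]})
        assert proportion_of_total(att, tot)["percent"].iloc[0] == 0.0

    def test_zero_total_reported_missing(self):
        att = pd.DataFrame({"year": [2020], "sex": ["male"],
                            "attributable": [0.0]})
        tot = pd.DataFrame({"year": [2020], "sex": ["male"], "deaths": [0]})
        assert np.isnan(proportion_of_total(att, tot)["percent"].iloc[0])

    def test_overall_is_deaths_weighted_mean_of_sexes(self):
        att = pd.DataFrame({"year": [2020, 2020], "sex": ["male", "female"],
                            "attributable": [120.0, 30.0]})
        tot = pd.DataFrame({"year": [2020, 2020], "sex": ["male", "female"],
                            "deaths": [800, 700]})
        by_sex = proportion_of_total(att, tot, by=("year", "sex"))
        overall = proportion_of_total(att, tot, by=("year",))
        weighted = (by_sex["percent"] * by_sex["deaths"]).sum() / \
            by_sex["deaths"].sum()
        assert overall["percent"].iloc[0] == pytest.approx(weighted,
                                                           abs=1e-9)


class TestAgeStandardization:
    GROUPS = ("15-29", "30-44", "45-59", "60+")

    def test_equal_rates_invariant_to_weights(self):
        pops = {g: p for g, p in zip(self.GROUPS, (1e5, 2e5, 1.5e5, 1e5))}
        deaths = {g: pops[g] * 20 / 1e5 for g in self.GROUPS}  # rate 20
        for weights in (who_standard_weights(),
                        {g: 0.25 for g in self.GROUPS}):
            assert age_standardize(deaths, pops, weights) == pytest.approx(
                20.0, abs=1e-12)

    def test_two_group_hand_case(self):
        groups = ("a", "b")
        weights = {"a": 0.25, "b": 0.75}
        pops = {"a": 1e5, "b": 1e5}
        deaths = {"a": 10.0, "b": 30.0}
        assert age_standardize(deaths, pops, weights, groups) == \
            pytest.approx(25.0)

    def test_self_standard_equals_crude(self):
        pops = {g: p for g, p in zip(self.GROUPS, (3e5, 2e5, 2.5e5, 1.5e5))}
        deaths = {g: d for g, d in zip(self.GROUPS, (30, 80, 200, 400))}
        total_pop = sum(pops.values())
        weights = {g: pops[g] / total_pop for g in self.GROUPS}
        crude = sum(deaths.values()) / total_pop * 1e5
        assert age_standardize(deaths, pops, weights) == pytest.approx(
            crude, abs=1e-9)

    def test_missing_population_raises(self):
        with pytest.raises(ValueError, match="60"):
            age_standardize({"15-29": 5.0}, {"15-29": 1e5})

    def test_who_weights_sum_to_one(self):
        assert sum(who_standard_weights().values()) == pytest.approx(
            1.0, abs=1e-12)


class TestRateTable:
    def test_crude_rate_identity_across_strata(self, registry):
        att = pd.DataFrame({
            "year": [2020] * 4, "sex": ["male"] * 2 + ["female"] * 2,
            "age_group": ["30-44", "60+"] * 2,
            "cause": ["liver_cirrhosis"] * 4,
            "attributable": [40.0, 160.0, 10.0, 90.0],
        })
        tot = att.rename(columns={"attributable": "deaths"}).drop(
            columns="cause").assign(deaths=[400, 1600, 200, 1100])
        pop = pd.DataFrame({
            "year": [2020] * 8,
            "sex": ["male"] * 4 + ["female"] * 4,
            "age_group": list(TestAgeStandardization.GROUPS) * 2,
            "population": [2e5, 2e5, 2e5, 1e5, 2e5, 2e5, 2e5, 1e5],
        })
        rates = rate_table(att, tot, pop)
        overall = rates[rates["sex"] == "all"].iloc[0]
        assert overall["crude_rate"] == pytest.approx(
            300.0 / 1.4e6 * 1e5, abs=1e-9)
        # population-share-weighted stratum rates reproduce the crude rate
        shares = pop.groupby("sex")["population"].sum() / \
            pop["population"].sum()
        by_sex = rates[rates["sex"] != "all"].set_index("sex")["crude_rate"]
        agg = (by_sex * shares).sum()
        assert overall["crude_rate"] == pytest.approx(agg, abs=1e-9)
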