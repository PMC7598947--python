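import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hdss import (
    asfr_and_tfr,
    child_mortality_proxies,
    crude_birth_rate,
    crude_death_rate,
    dependency_ratios,
    from_dataframe,
    general_fertility_rate,
    grr_nrr,
    mean_age_of_fertility,
    pyramid_tabulation,
    summary_report,
)
from hdss.indicators import child_mortality_conventional
from conftest import make_census_df

# Observed census marginals of the surveyed districts (counts, not rates)
WOMEN_BY_BAND = [1757, 1314, 1160, 751, 748, 532, 366]
BIRTHS_BY_BAND = [44, 167, 166, 97, 72, 24, 3]


class TestComponentRates:
    @pytest.mark.parametrize(
        "births,pop,expected",
        [(573, 25144, 22.8), (0, 1000, 0.0), (704, 25144, 28.0)],
    )
    def test_crude_birth_rate(self, births, pop, expected):
        assert round(crude_birth_rate(births, pop), 1) == expected

    @pytest.mark.parametrize(
        "deaths,pop,expected",
        [(132, 25144, 5.2), (0, 1000, 0.0), (58, 25144, 2.3)],
    )
    def test_crude_death_rate(self, deaths, pop, expected):
        assert round(crude_death_rate(deaths, pop), 1) == expected

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            crude_birth_rate(10, 0)
        with pytest.raises(ValueError):
            crude_death_rate(10, 0)

    def test_gfr_per_1000_women(self):
        assert round(general_fertility_rate(573, 6628), 1) == 86.5

    @pytest.mark.parametrize(
        "cells,expected",
        [((7, 3, 10, 573), (12.2, 5.2, 17.5)),
         ((0, 0, 0, 573), (0.0, 0.0, 0.0)),
         ((28, 19, 47, 573), (48.9, 33.2, 82.0))],
    )
    def test_child_mortality_proxies(self, cells, expected):
        got = child_mortality_proxies(*cells)
        assert tuple(round(v, 1) for v in got) == expected

    def test_conventional_child_rate_uses_child_exposure(self):
        # 3 deaths among 1,576 children aged 1-4: ~1.9 per 1000 children
        assert round(child_mortality_conventional(3, 1576), 1) == 1.9


class TestFertilitySchedule:
    def test_tfr_from_band_counts(self):
        asfr, tfr = asfr_and_tfr(WOMEN_BY_BAND, BIRTHS_BY_BAND)
        assert round(tfr, 1) == 2.9

    def test_uniform_schedule_closed_form(self):
        asfr, tfr = asfr_and_tfr([10] * 7, [1] * 7)
        assert tfr == pytest.approx(3.5)

    def test_all_zero_births(self):
        _, tfr = asfr_and_tfr([10] * 7, [0] * 7)
        assert tfr == 0.0

    def test_births_in_empty_band_rejected(self):
        with pytest.raises(ValueError):
            asfr_and_tfr([10, 0, 10, 10, 10, 10, 10], [1, 1, 1, 1, 1, 1, 1])

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(min_value=1, max_value=5000), min_size=7, max_size=7),
        st.lists(st.integers(min_value=0, max_value=500), min_size=7, max_size=7),
    )
    def test_tfr_identity(self, women, births):
        """TFR = 5 x sum(ASFR) holds exactly for any counts."""
        asfr, tfr = asfr_and_tfr(women, births)
        assert tfr == pytest.approx(5.0 * asfr.sum(), rel=1e-12)

    def test_mean_age_of_fertility_near_observed(self):
        asfr, _ = asfr_and_tfr(WOMEN_BY_BAND, BIRTHS_BY_BAND)
        assert mean_age_of_fertility(asfr) == pytest.approx(30.06, abs=0.5)


class TestReproductionRates:
    def test_nrr_from_observed_inputs(self):
        # GRR 1.33 daughters/woman discounted by survivorship 0.964
        grr, nrr = grr_nrr([1.33 / 5], 0.964)
        assert round(nrr, 2) == 1.28

    def test_survivorship_one_makes_nrr_equal_grr(self):
        grr, nrr = grr_nrr([0.05] * 7, 1.0)
        assert nrr == grr

    def test_proportional_female_split_reconstruction(self):
        """Splitting all births by the observed infant sex ratio (268 girls of
        573) reproduces the gross rate to ~0.01 of the reported 1.33."""
        asfr, _ = asfr_and_tfr(WOMEN_BY_BAND, BIRTHS_BY_BAND)
        grr, _ = grr_nrr(asfr * 268 / 573, 1.0)
        assert grr == pytest.approx(1.34, abs=0.005)

    def test_invalid_survivorship_rejected(self):
        with pytest.raises(ValueError):
            grr_nrr([0.05] * 7, 1.2)


class TestDependency:
    def test_observed_counts(self):
        total, young, old = dependency_ratios(9335, 15145, 664)
        assert (round(total, 1), round(young, 1), round(old, 1)) == (66.0, 61.6, 4.4)

    def test_no_dependents(self):
        assert dependency_ratios(0, 100, 0) == (0.0, 0.0, 0.0)

    @settings(max_examples=40, deadline=None)
    @given(
        st.integers(min_value=0, max_value=10**6),
        st.integers(min_value=1, max_value=10**6),
        st.integers(min_value=0, max_value=10**6),
    )
    def test_young_plus_old_equals_total(self, y, w, o):
        total, young, old = dependency_ratios(y, w, o)
        assert total == pytest.approx(young + old, rel=1e-12)


class TestSummaryReport:
    def test_regrouping_households_leaves_crude_rates_unchanged(self, clean_bundle):
        b = clean_bundle
        regrouped = b.census.persons.copy()
        regrouped["household_id"] = np.arange(len(regrouped)) // 2
        ds2 = from_dataframe(regrouped)
        r1 = summary_report(b.census, b.births, b.deaths_iddir)
        r2 = summary_report(ds2, b.births, b.deaths_iddir)
        assert r1.cbr == r2.cbr
        assert r1.cdr == r2.cdr
        assert r1.tfr == r2.tfr

    def test_recovers_generator_truth(self, clean_bundle):
        """With no reporting errors every indicator tracks its configured truth."""
        b = clean_bundle
        r = summary_report(b.census, b.births, b.deaths_iddir)
        assert r.tfr == pytest.approx(b.truth["true_tfr"], abs=0.45)
        assert r.cdr == pytest.approx(b.truth["true_cdr_per_1000"], rel=1e-9)
        assert r.cbr == pytest.approx(1000 * b.truth["n_births"] / b.truth["n_persons"])
        assert r.persons_per_household == pytest.approx(
            b.truth["n_persons"] / b.truth["n_households"]
        )
        assert 95 <= r.sex_ratio_total <= 115  # SRB 105 with sampling noise
        assert r.nrr <= r.grr <= r.tfr

    def test_single_person_dataset_degenerate_but_defined(self):
        ds = from_dataframe(make_census_df([(0, 0, 30, "male")]))
        births = pd.DataFrame(columns=["mother_person_id", "plurality", "outcome",
                                       "place", "infant_sex"])
        deaths = pd.DataFrame(columns=["deceased_name_key", "household_id", "sex",
                                       "age_at_death", "date_of_death", "place",
                                       "cause", "source"])
        r = summary_report(ds, births, deaths)
        assert r.cbr == 0.0 and r.cdr == 0.0
        assert r.n_persons == 1

    def test_rounded_view_precision(self, clean_bundle):
        b = clean_bundle
        d = summary_report(b.census, b.births, b.deaths_iddir).rounded()
        assert d["sex_ratio_total"] == int(d["sex_ratio_total"])
        assert d["cbr"] == round(d["cbr"], 1)


def test_pyramid_tabulation_shape(bundle):
    df = pyramid_tabulation(bundle.census)
    assert list(df.columns) == ["band", "lower", "male", "female", "total"]
    assert df["total"].sum() == len(bundle.census.known_age())
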