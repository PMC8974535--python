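"""Country table reading, validation, median imputation and regional medians."""

import statistics
import textwrap

import numpy as np
import pytest

from growthgains import (
    CountryDataError,
    impute_missing,
    read_country_table,
    regional_medians,
    wage_increase_per_haz,
)
from growthgains.country import GROWTH_PERIODS, ImputationRecord
from growthgains.synthetic import generate_profiles

from conftest import make_profile


def _write(tmp_path, text, name="countries.csv"):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


class TestReadCountryTable:
    def test_effective_lfpr_is_product_of_lfpr_and_adult_share(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            iso3,name,who_region,income_group,gni_pc,lfpr_15plus,pop_share_0_14
            IND,India,South-East Asia,lower-middle,1000,0.6,0.333
            """,
        )
        (p,) = read_country_table(path)
        assert p.effective_lfpr == pytest.approx(0.6 * (1 - 0.333))  # 0.4002

    def test_percent_columns_are_stored_as_fractions(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            iso3,who_region,income_group,gni_pc,lfpr_15plus_pct,pop_share_0_14,return_per_school_year_pct
            BGD,South-East Asia,lower-middle,2000,60,0.3,5.2
            """,
        )
        (p,) = read_country_table(path)
        assert p.lfpr_15plus == pytest.approx(0.60)
        assert p.return_per_school_year == pytest.approx(0.052)

    def test_missing_cell_stays_absent_for_later_imputation(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            iso3,who_region,income_group,gni_pc,return_per_school_year
            NPL,South-East Asia,low,800,
            """,
        )
        (p,) = read_country_table(path)
        assert p.return_per_school_year is None
        assert "return_per_school_year" in p.missing_fields()

    def test_duplicate_iso3_is_a_hard_error(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            iso3,who_region,income_group,gni_pc
            IND,South-East Asia,lower-middle,1000
            IND,South-East Asia,lower-middle,1100
            """,
        )
        with pytest.raises(CountryDataError, match="IND"):
            read_country_table(path)

    def test_out_of_range_fraction_names_row_and_column(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            iso3,who_region,income_group,gni_pc,lfpr_15plus
            PAK,Eastern-Mediterranean,lower-middle,1500,1.6
            """,
        )
        with pytest.raises(CountryDataError, match="lfpr_15plus.*PAK"):
            read_country_table(path)

    def test_high_income_countries_are_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            iso3,who_region,income_group,gni_pc
            CHE,European,high,90000
            """,
        )
        with pytest.raises(CountryDataError, match="high-income"):
            read_country_table(path)

    def test_declaring_both_units_for_one_column_is_an_error(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            iso3,who_region,income_group,lfpr_15plus,lfpr_15plus_pct
            IND,South-East Asia,lower-middle,0.6,60
            """,
        )
        with pytest.raises(CountryDataError, match="declare one unit"):
            read_country_table(path)


class TestImputation:
    def test_region_median_fills_missing_return(self):
        donors = [
            make_profile(f"A{i:02d}", return_per_school_year=r)
            for i, r in enumerate([0.02, 0.04, 0.06])
        ]
        target = make_profile("ZMB", return_per_school_year=None)
        out = impute_missing(donors + [target])
        assert out[-1].return_per_school_year == pytest.approx(0.04)
        assert out[-1].imputed == {"return_per_school_year"}

    def test_no_missing_fields_is_identity(self):
        profiles = [make_profile(f"A{i:02d}") for i in range(4)]
        out = impute_missing(profiles)
        assert out == profiles
        assert all(not p.imputed for p in out)

    def test_region_without_donors_falls_back_to_global_median(self):
        # all growth-rate donors live in a different region than the target
        donors = [
            make_profile(
                f"B{i:02d}",
                who_region="Africa",
                growth_rates={p: r for p in GROWTH_PERIODS},
            )
            for i, r in enumerate([0.01, 0.02, 0.03, 0.07])
        ]
        target = make_profile("NPL", who_region="European", growth_rates={})
        audit: list[ImputationRecord] = []
        out = impute_missing(donors + [target], audit=audit)
        oracle = sorted([0.01, 0.02, 0.03, 0.07])
        expected = (oracle[1] + oracle[2]) / 2  # even pool: midpoint convention
        assert out[-1].growth_rates[2020] == pytest.approx(expected)
        assert all(r.donor_pool == "global" for r in audit)

    def test_income_group_median_fills_gni_and_lfpr(self):
        donors = [
            make_profile(f"C{i:02d}", gni_pc=g, lfpr_15plus=l)
            for i, (g, l) in enumerate([(500, 0.5), (900, 0.6), (2000, 0.8)])
        ]
        target = make_profile("TCD", gni_pc=None, lfpr_15plus=None)
        out = impute_missing(donors + [target])
        assert out[-1].gni_pc == pytest.approx(900)
        assert out[-1].lfpr_15plus == pytest.approx(0.6)
        assert out[-1].imputed == {"gni_pc", "lfpr_15plus"}

    def test_field_missing_everywhere_is_a_hard_error(self):
        profiles = [make_profile(f"D{i:02d}", gni_pc=None) for i in range(3)]
        with pytest.raises(CountryDataError, match="gni_pc"):
            impute_missing(profiles)

    def test_imputation_is_idempotent_and_never_alters_present_values(self):
        profiles = generate_profiles(60, seed=7, missing_fraction=0.3)
        once = impute_missing(profiles)
        twice = impute_missing(once)
        assert once == twice
        for before, after in zip(profiles, once):
            for f in ("gni_pc", "lfpr_15plus", "pop_share_0_14", "return_per_school_year"):
                if getattr(before, f) is not None:
                    assert getattr(after, f) == getattr(before, f)
            for period, rate in before.growth_rates.items():
                assert after.growth_rates[period] == rate


class TestWagePerHaz:
    @pytest.mark.parametrize(
        "ret,expected",
        [(0.10, 0.047), (0.0, 0.0), (0.0519, 0.0244)],
        ids=["ten-percent-return", "zero-return", "median-lmic-return"],
    )
    def test_wage_gain_is_schooling_coefficient_times_return(self, ret, expected):
        p = make_profile(return_per_school_year=ret)
        assert wage_increase_per_haz(p) == pytest.approx(expected, abs=5e-5)

    def test_missing_return_raises(self):
        with pytest.raises(CountryDataError):
            wage_increase_per_haz(make_profile(return_per_school_year=None))


@pytest.mark.filterwarnings("ignore:region .* has no countries")
class TestRegionalMedians:
    def test_median_and_count_per_region(self):
        # per-HAZ values 1%, 2%, 9% <=> returns v/0.47
        profiles = [
            make_profile(f"E{i:02d}", who_region="Africa", return_per_school_year=v / 0.47)
            for i, v in enumerate([0.01, 0.02, 0.09])
        ]
        table = regional_medians(profiles)
        assert table.loc["Africa", "median_wage_gain_per_haz"] == pytest.approx(0.02)
        assert table.loc["Africa", "n_countries"] == 3

    def test_single_country_region_returns_its_value(self):
        profiles = [
            make_profile("F00", who_region="Americas", return_per_school_year=0.08),
            make_profile("F01", who_region="Africa", return_per_school_year=0.02),
        ]
        table = regional_medians(profiles)
        assert table.loc["Americas", "median_wage_gain_per_haz"] == pytest.approx(0.47 * 0.08)

    def test_overall_median_matches_sort_based_oracle_for_156_countries(self):
        profiles = generate_profiles(156, seed=11, missing_fraction=0.0)
        table = regional_medians(profiles)
        values = sorted(0.47 * p.return_per_school_year for p in profiles)
        oracle = (values[77] + values[78]) / 2  # even count: central midpoint
        assert table.loc["Overall", "median_wage_gain_per_haz"] == pytest.approx(oracle)
        assert table.loc["Overall", "n_countries"] == 156

    def test_shared_value_appears_in_every_row(self):
        profiles = generate_profiles(30, seed=3, missing_fraction=0.0)
        shared = [p.model_copy(update={"return_per_school_year": 0.05}) for p in profiles]
        table = regional_medians(shared)
        assert np.allclose(table["median_wage_gain_per_haz"], 0.47 * 0.05)

    def test_empty_region_is_omitted_with_warning(self):
        profiles = [make_profile("G00", who_region="Africa")]
        with pytest.warns(UserWarning, match="no countries"):
            table = regional_medians(profiles)
        assert set(table.index) == {"Africa", "Overall"}
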