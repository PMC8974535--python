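"""Published South Asia SDG-scenario reference tables.

Transcriptions of the published country results for the scenario in which
Bangladesh, Bhutan, India, Nepal and Pakistan reach SDG stunting target 2.2
by 2025 (40% reduction from 2012 levels, approached linearly 2020-2025):
per-cohort schooling gains, present-value earnings by discount rate and by
country, per-stunted-child present values, and the regional medians of the
wage gain per HAZ unit. Cell values are kept exactly as printed (hence
rounded); the separately printed margin totals/averages are stored alongside
for cross-checking, since the source computed its margins from unrounded
values.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "COHORTS",
    "wage_gain_by_region",
    "schooling_cells",
    "pv_by_rate_cells",
    "pv_by_country_5pct_cells",
    "pv_per_child_5pct_cells",
    "printed_margins",
    "sdg_prevalence_2025_pct",
    "south_asia_reference_tables",
]

COHORTS = (2020, 2021, 2022, 2023, 2024, 2025)
_COUNTRIES = ("Bangladesh", "Bhutan", "India", "Nepal", "Pakistan")


def _frame(rows: dict[str, list[float]], columns=COHORTS) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(columns), dtype=float)


def wage_gain_by_region() -> pd.DataFrame:
    """Median percent wage gain per unit HAZ increase, by WHO region."""
    data = {
        "Africa": (2.4, 47),
        "Americas": (4.5, 30),
        "Eastern-Mediterranean": (2.4, 20),
        "European": (2.1, 29),
        "South-East Asia": (2.7, 11),
        "Western-Pacific": (3.5, 19),
        "Overall": (2.4, 156),
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=["median_wage_gain_per_haz_pct", "n_countries"]
    ).rename_axis("region")


def schooling_cells() -> pd.DataFrame:
    """Schooling gained per cohort (thousand school years), printed cells."""
    return _frame(
        {
            "Bangladesh": [7.1, 14, 21, 28, 35, 35],
            "Bhutan": [0.2, 0.3, 0.5, 0.7, 0.9, 0.8],
            "India": [359, 721, 1092, 1470, 1865, 1860],
            "Nepal": [4, 8, 13, 17, 21, 20],
            "Pakistan": [46, 94, 143, 194, 247, 247],
        }
    ).rename_axis("country")


def pv_by_rate_cells() -> pd.DataFrame:
    """South Asia PV earnings per cohort (USD millions) by discount rate."""
    return _frame(
        {
            "3%": [5750, 11879, 18489, 25561, 33286, 34062],
            "5%": [2879, 5956, 9282, 12850, 16755, 17166],
            "10%": [677, 1404, 2195, 3048, 3986, 4094],
        }
    ).rename_axis("discount_rate")


def pv_by_country_5pct_cells() -> pd.DataFrame:
    """PV earnings per cohort and country at 5% (USD millions), printed cells."""
    return _frame(
        {
            "Bangladesh": [32, 67, 103, 140, 180, 184],
            "Bhutan": [1, 3, 4, 6, 7, 7],
            "India": [2640, 5457, 8501, 11760, 15329, 15702],
            "Nepal": [10, 20, 31, 43, 55, 56],
            "Pakistan": [195, 409, 643, 901, 1183, 1217],
        }
    ).rename_axis("country")


def pv_per_child_5pct_cells() -> pd.DataFrame:
    """PV earnings per stunted child at 5% (USD), printed cells."""
    return _frame(
        {
            "Bangladesh": [38, 78, 121, 168, 217, 223],
            "Bhutan": [287, 601, 943, 1321, 1740, 1782],
            "India": [267, 555, 868, 1209, 1582, 1625],
            "Nepal": [51, 106, 167, 234, 307, 318],
            "Pakistan": [104, 217, 341, 476, 625, 643],
        }
    ).rename_axis("country")


def printed_margins() -> dict[str, dict]:
    """Margin totals/averages exactly as printed in the source tables."""
    return {
        "schooling": {
            "row_totals": {
                "Bangladesh": 140,
                "Bhutan": 3.4,
                "India": 7367,
                "Nepal": 83,
                "Pakistan": 971,
            },
            "col_totals": dict(zip(COHORTS, [416, 837, 1269, 1709, 2169, 2163])),
            "grand_total": 8563,
        },
        "pv_by_rate": {
            "row_totals": {"3%": 129028, "5%": 64888, "10%": 15404},
        },
        "pv_by_country_5pct": {
            "row_totals": {
                "Bangladesh": 706,
                "Bhutan": 28,
                "India": 59390,
                "Nepal": 215,
                "Pakistan": 4549,
            },
            "col_totals": dict(zip(COHORTS, [2879, 5956, 9282, 12850, 16755, 17166])),
            "grand_total": 64888,
        },
        "pv_per_child_5pct": {
            "row_averages": {
                "Bangladesh": 141,
                "Bhutan": 1113,
                "India": 1018,
                "Nepal": 197,
                "Pakistan": 401,
            },
        },
    }


def sdg_prevalence_2025_pct() -> dict[str, float]:
    """Published 12-23-month stunting prevalence (%) in 2025 at the SDG target."""
    return {
        "Bangladesh": 27.2,
        "Bhutan": 21.5,
        "India": 27.1,
        "Nepal": 25.6,
        "Pakistan": 23.5,
    }


def south_asia_reference_tables() -> dict[str, pd.DataFrame]:
    """All reference tables keyed by short name."""
    return {
        "wage_gain_by_region": wage_gain_by_region(),
        "schooling": schooling_cells(),
        "pv_by_rate": pv_by_rate_cells(),
        "pv_by_country_5pct": pv_by_country_5pct_cells(),
        "pv_per_child_5pct": pv_per_child_5pct_cells(),
    }
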