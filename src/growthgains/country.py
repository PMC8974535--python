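"""Country-level economic and demographic parameters.

Each country is described by a :class:`CountryProfile`: its WHO region and
World Bank income group, GNI per capita (Atlas USD), the labor share of
income, the labor-force participation rate of the 15+ population together
with the 0-14 population share used to re-base it to the whole population,
the Mincerian return to schooling, annual GNI-per-capita growth rates per
five-year period 2020-2080, and live births per calendar year.

Missing values are imputed with donor-pool medians: returns to schooling and
growth rates use the WHO-region median, GNI per capita and the labor-force
inputs use the income-group median, with a global-median fallback when a
pool has no donors. High-income countries are out of scope and rejected at
read time.
"""

from __future__ import annotations

import enum
import statistics
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "WhoRegion",
    "IncomeGroup",
    "CountryProfile",
    "CountryDataError",
    "GROWTH_PERIODS",
    "read_country_table",
    "read_growth_rates",
    "read_births",
    "load_country_inputs",
    "impute_missing",
    "imputation_audit",
    "wage_increase_per_haz",
    "regional_medians",
]

#: Five-year SSP period starts covering 2020-2084.
GROWTH_PERIODS: tuple[int, ...] = tuple(range(2020, 2081, 5))

#: Default coefficient: years of schooling gained per unit HAZ increase
#: among stunted children (pooled LMIC cohort-study estimate).
SCHOOLING_PER_HAZ: float = 0.47


class WhoRegion(str, enum.Enum):
    AFRICA = "Africa"
    AMERICAS = "Americas"
    EASTERN_MEDITERRANEAN = "Eastern-Mediterranean"
    EUROPEAN = "European"
    SOUTH_EAST_ASIA = "South-East Asia"
    WESTERN_PACIFIC = "Western-Pacific"


class IncomeGroup(str, enum.Enum):
    LOW = "low"
    LOWER_MIDDLE = "lower-middle"
    UPPER_MIDDLE = "upper-middle"


class CountryDataError(ValueError):
    """Raised for invalid or inconsistent country input data."""


class CountryProfile(BaseModel):
    """Economic and demographic parameter set for one LMIC.

    Fields that may be absent before imputation are ``Optional``; the
    ``imputed`` set records which fields (and which growth periods, as
    ``growth_rates.<period>``) were filled by donor-pool medians.
    """

    model_config = ConfigDict(validate_assignment=True)

    iso3: str = Field(min_length=3, max_length=3)
    name: str = ""
    who_region: WhoRegion
    income_group: IncomeGroup
    gni_pc: Optional[float] = None  # USD/person/year, Atlas method
    labor_share: float = 0.5  # fraction of national income paid as wages
    lfpr_15plus: Optional[float] = None  # fraction of 15+ population
    pop_share_0_14: Optional[float] = None  # fraction of total population
    return_per_school_year: Optional[float] = None  # fraction wage gain/year
    growth_rates: dict[int, float] = Field(default_factory=dict)
    births: dict[int, float] = Field(default_factory=dict)
    imputed: set[str] = Field(default_factory=set)

    @field_validator("iso3")
    @classmethod
    def _upper(cls, v: str) -> str:
        return v.upper()

    @field_validator("gni_pc")
    @classmethod
    def _gni_positive(cls, v):
        if v is not None and v <= 0:
            raise ValueError("gni_pc must be positive")
        return v

    @field_validator("labor_share")
    @classmethod
    def _labor_share_range(cls, v):
        if not 0 < v <= 1:
            raise ValueError("labor_share must be in (0, 1]")
        return v

    @field_validator("lfpr_15plus")
    @classmethod
    def _lfpr_range(cls, v):
        if v is not None and not 0 < v <= 1:
            raise ValueError("lfpr_15plus must be in (0, 1]")
        return v

    @field_validator("pop_share_0_14")
    @classmethod
    def _pop_share_range(cls, v):
        if v is not None and not 0 <= v < 1:
            raise ValueError("pop_share_0_14 must be in [0, 1)")
        return v

    @field_validator("return_per_school_year")
    @classmethod
    def _return_nonneg(cls, v):
        if v is not None and v < 0:
            raise ValueError("return_per_school_year must be >= 0")
        return v

    @field_validator("growth_rates")
    @classmethod
    def _periods_valid(cls, v: dict[int, float]):
        for period in v:
            if period % 5 or not 2020 <= period <= 2080:
                raise ValueError(
                    f"growth-rate period start {period} must be a multiple of 5 in [2020, 2080]"
                )
        return v

    @field_validator("births")
    @classmethod
    def _births_nonneg(cls, v: dict[int, float]):
        for year, n in v.items():
            if n < 0:
                raise ValueError(f"births for {year} must be >= 0")
        return v

    @property
    def effective_lfpr(self) -> float:
        """LFPR re-based from the 15+ population to the total population."""
        if self.lfpr_15plus is None or self.pop_share_0_14 is None:
            raise CountryDataError(
                f"{self.iso3}: lfpr_15plus / pop_share_0_14 missing; impute first"
            )
        return self.lfpr_15plus * (1.0 - self.pop_share_0_14)

    def missing_fields(self) -> set[str]:
        """Names of imputable fields currently absent, growth periods included."""
        out = {
            f
            for f in ("gni_pc", "lfpr_15plus", "pop_share_0_14", "return_per_school_year")
            if getattr(self, f) is None
        }
        out.update(
            f"growth_rates.{p}" for p in GROWTH_PERIODS if p not in self.growth_rates
        )
        return out


# ---------------------------------------------------------------------------
# CSV reading
# ---------------------------------------------------------------------------

# Columns holding fractions; each may appear as `<name>` (fraction in [0,1])
# or `<name>_pct` (percent in [0,100]) — the suffix is the mandatory
# per-column unit declaration. Growth rates may be negative.
_FRACTION_COLUMNS = (
    "labor_share",
    "lfpr_15plus",
    "pop_share_0_14",
    "return_per_school_year",
)


def _resolve_units(df: pd.DataFrame, base: str, allow_negative: bool = False) -> pd.Series:
    """Return `base` as a fraction Series, honoring the `_pct` declaration."""
    pct = f"{base}_pct"
    if base in df.columns and pct in df.columns:
        raise CountryDataError(f"both '{base}' and '{pct}' present; declare one unit")
    if pct in df.columns:
        col = pd.to_numeric(df[pct], errors="coerce")
        _check_range(col, pct, -100.0 if allow_negative else 0.0, 100.0, df)
        return col / 100.0
    if base in df.columns:
        col = pd.to_numeric(df[base], errors="coerce")
        _check_range(col, base, -1.0 if allow_negative else 0.0, 1.0, df)
        return col
    return pd.Series([None] * len(df), index=df.index, dtype="float64")


def _check_range(col: pd.Series, name: str, lo: float, hi: float, df: pd.DataFrame) -> None:
    bad = col.dropna()
    bad = bad[(bad < lo) | (bad > hi)]
    if len(bad):
        row = bad.index[0]
        label = df["iso3"].iloc[row] if "iso3" in df.columns else row
        raise CountryDataError(
            f"column '{name}', row {label!r}: value {bad.iloc[0]} outside [{lo}, {hi}]"
        )


def read_country_table(path: str | Path) -> list[CountryProfile]:
    """Read ``countries.csv`` (static per-country fields) into profiles.

    Missing cells stay absent (None), to be filled later by
    :func:`impute_missing`. Duplicate iso3 codes, out-of-range values and
    high-income countries are hard errors.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    if "iso3" not in df.columns:
        raise CountryDataError(f"{path}: missing required column 'iso3'")
    df["iso3"] = df["iso3"].astype(str).str.upper()
    dupes = df["iso3"][df["iso3"].duplicated()]
    if len(dupes):
        raise CountryDataError(f"duplicate iso3 code(s): {sorted(set(dupes))}")

    gni = pd.to_numeric(df.get("gni_pc"), errors="coerce") if "gni_pc" in df.columns else None
    if gni is not None:
        neg = gni.dropna()
        neg = neg[neg <= 0]
        if len(neg):
            raise CountryDataError(
                f"column 'gni_pc', row {df['iso3'].iloc[neg.index[0]]!r}: must be positive"
            )

    fracs = {c: _resolve_units(df, c) for c in _FRACTION_COLUMNS}

    profiles = []
    for i, row in df.iterrows():
        group = str(row["income_group"]).strip().lower()
        if group.startswith("high"):
            raise CountryDataError(
                f"{row['iso3']}: high-income countries are out of scope (LMICs only)"
            )
        kwargs = dict(
            iso3=row["iso3"],
            name=str(row.get("name", "") or ""),
            who_region=str(row["who_region"]).strip(),
            income_group=group,
        )
        if gni is not None and pd.notna(gni.iloc[i]):
            kwargs["gni_pc"] = float(gni.iloc[i])
        for c in _FRACTION_COLUMNS:
            v = fracs[c].iloc[i]
            if pd.notna(v):
                kwargs[c] = float(v)
        profiles.append(CountryProfile(**kwargs))
    return profiles


def read_growth_rates(path: str | Path) -> dict[str, dict[int, float]]:
    """Read long-form ``growth_rates.csv`` (iso3, period_start, rate[,_pct])."""
    df = pd.read_csv(path, skipinitialspace=True)
    rate = _resolve_units(df, "rate", allow_negative=True)
    out: dict[str, dict[int, float]] = {}
    for i, row in df.iterrows():
        if pd.isna(rate.iloc[i]):
            continue
        out.setdefault(str(row["iso3"]).upper(), {})[int(row["period_start"])] = float(
            rate.iloc[i]
        )
    return out


def read_births(path: str | Path) -> dict[str, dict[int, float]]:
    """Read long-form ``births.csv`` (iso3, year, births)."""
    df = pd.read_csv(path, skipinitialspace=True)
    out: dict[str, dict[int, float]] = {}
    for _, row in df.iterrows():
        n = float(row["births"])
        if n < 0:
            raise CountryDataError(f"{row['iso3']}: negative births in year {row['year']}")
        out.setdefault(str(row["iso3"]).upper(), {})[int(row["year"])] = n
    return out


def load_country_inputs(
    countries_csv: str | Path,
    growth_rates_csv: str | Path,
    births_csv: str | Path,
) -> list[CountryProfile]:
    """Read and join the three input CSVs into complete (pre-imputation) profiles."""
    profiles = read_country_table(countries_csv)
    growth = read_growth_rates(growth_rates_csv)
    births = read_births(births_csv)
    for p in profiles:
        p.growth_rates = growth.get(p.iso3, {})
        p.births = births.get(p.iso3, {})
    return profiles


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

# field -> donor-pool grouping attribute
_IMPUTATION_POOLS = {
    "return_per_school_year": "who_region",
    "gni_pc": "income_group",
    "lfpr_15plus": "income_group",
    "pop_share_0_14": "income_group",
}


@dataclass(frozen=True)
class ImputationRecord:
    iso3: str
    field: str
    donor_pool: str
    value: float


def _median_or_none(values: list[float]) -> Optional[float]:
    # even-sized pools take the midpoint of the two central values
    return statistics.median(values) if values else None


def _median_table(
    profiles: Iterable[CountryProfile], getter, pool_attr: str
) -> tuple[dict, Optional[float]]:
    """Per-pool and global donor medians for one field."""
    pools: dict = {}
    everyone: list[float] = []
    for p in profiles:
        v = getter(p)
        if v is not None:
            pools.setdefault(getattr(p, pool_attr), []).append(v)
            everyone.append(v)
    return {k: statistics.median(vs) for k, vs in pools.items()}, _median_or_none(everyone)


def impute_missing(
    profiles: list[CountryProfile],
    audit: Optional[list[ImputationRecord]] = None,
) -> list[CountryProfile]:
    """Fill missing fields with donor-pool medians; returns new profiles.

    Returns-to-schooling and growth rates take the WHO-region median of
    countries reporting a value; GNI per capita and the labor-force inputs
    take the income-group median. A pool with no donors falls back to the
    global median. A field missing for every country is a hard error. Pass
    ``audit`` to collect one :class:`ImputationRecord` per filled cell.
    """
    # donor medians are computed once, over the ORIGINAL profiles only
    field_medians = {
        f: _median_table(profiles, lambda x, f=f: getattr(x, f), pool_attr)
        for f, pool_attr in _IMPUTATION_POOLS.items()
    }
    growth_medians = {
        t: _median_table(profiles, lambda x, t=t: x.growth_rates.get(t), "who_region")
        for t in GROWTH_PERIODS
    }

    def lookup(table, glob, pool_key, what):
        if pool_key in table:
            attr = "who_region" if isinstance(pool_key, WhoRegion) else "income_group"
            return table[pool_key], f"{attr}={pool_key.value}"
        if glob is None:
            raise CountryDataError(f"{what} missing for all countries")
        return glob, "global"

    out = []
    for p in profiles:
        q = p.model_copy(deep=True)
        for field, pool_attr in _IMPUTATION_POOLS.items():
            if getattr(q, field) is None:
                table, glob = field_medians[field]
                value, pool = lookup(table, glob, getattr(p, pool_attr), f"field '{field}'")
                setattr(q, field, value)
                q.imputed = q.imputed | {field}
                if audit is not None:
                    audit.append(ImputationRecord(p.iso3, field, pool, value))
        for period in GROWTH_PERIODS:
            if period not in q.growth_rates:
                table, glob = growth_medians[period]
                value, pool = lookup(
                    table, glob, p.who_region, f"growth rate for period {period}"
                )
                q.growth_rates[period] = value
                q.imputed = q.imputed | {f"growth_rates.{period}"}
                if audit is not None:
                    audit.append(
                        ImputationRecord(p.iso3, f"growth_rates.{period}", pool, value)
                    )
        out.append(q)
    return out


def imputation_audit(records: list[ImputationRecord]) -> pd.DataFrame:
    """Audit log as a DataFrame (iso3, field, donor_pool, value)."""
    return pd.DataFrame(
        [(r.iso3, r.field, r.donor_pool, r.value) for r in records],
        columns=["iso3", "field", "donor_pool", "value"],
    )


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def wage_increase_per_haz(
    profile: CountryProfile, schooling_coefficient: float = SCHOOLING_PER_HAZ
) -> float:
    """Fractional wage gain per unit HAZ increase among stunted children.

    Composes the schooling gain per HAZ unit (0.47 years by default) with the
    country's Mincerian return per school year.
    """
    if profile.return_per_school_year is None:
        raise CountryDataError(f"{profile.iso3}: return_per_school_year missing; impute first")
    return schooling_coefficient * profile.return_per_school_year


def regional_medians(
    profiles: list[CountryProfile], schooling_coefficient: float = SCHOOLING_PER_HAZ
) -> pd.DataFrame:
    """Median wage gain per HAZ unit by WHO region, plus an Overall row.

    Returns a DataFrame indexed by region name with columns
    ``median_wage_gain_per_haz`` (fraction) and ``n_countries``.
    """
    values = {
        p.iso3: (p.who_region, wage_increase_per_haz(p, schooling_coefficient))
        for p in profiles
    }
    rows = {}
    for region in WhoRegion:
        pool = sorted(v for r, v in values.values() if r == region)
        if not pool:
            warnings.warn(f"region {region.value} has no countries; omitted")
            continue
        rows[region.value] = (statistics.median(pool), len(pool))
    allpool = sorted(v for _, v in values.values())
    rows["Overall"] = (statistics.median(allpool), len(allpool))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["median_wage_gain_per_haz", "n_countries"]
    ).rename_axis("region")
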