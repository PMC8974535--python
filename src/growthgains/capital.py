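"""Human-capital conversion: HAZ gains to schooling and discounted earnings.

The chain per birth cohort is

    delta-HAZ -> schooling years (x 0.47/HAZ unit among stunted children)
              -> wage uplift     (x Mincerian return per school year)
              -> lifetime gain   (summed over 44 working years, ages 16..59,
                                  wages grown by five-year GNI-pc growth
                                  rates and discounted at 3/5/10%)

The base wage is wage per worker, GNI per capita x labor share (0.5)
divided by the whole-population labor-force participation rate (the 15+
rate re-based with the 0-14 population share). Labor share and LFPR are
held constant over the projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .config import RunConfig
from .country import CountryDataError, CountryProfile, GROWTH_PERIODS
from .scenario import CohortScenario

__all__ = [
    "WorkLife",
    "DiscountSpec",
    "WageTrajectory",
    "CohortImpact",
    "schooling_gain_per_child",
    "base_wage",
    "growth_rate_for_year",
    "wage_trajectory",
    "pv_earnings_per_child",
    "cohort_impacts",
]


@dataclass(frozen=True)
class WorkLife:
    """Working-age window [entry_age, exit_age): 44 years, 16..59, by default."""

    entry_age: int = 16
    exit_age: int = 60

    def __post_init__(self):
        if self.exit_age <= self.entry_age:
            raise ValueError("exit_age must exceed entry_age")

    @property
    def working_years(self) -> int:
        return self.exit_age - self.entry_age


@dataclass(frozen=True)
class DiscountSpec:
    """Discount rates and the year cash flows are discounted back to."""

    rates: tuple[float, ...] = (0.03, 0.05, 0.10)
    reference: str = "cohort_birth_year"  # or "fixed_base_year"
    fixed_base: Optional[int] = None

    def __post_init__(self):
        if any(r < 0 for r in self.rates):
            raise ValueError("discount rates must be >= 0")
        if self.reference not in ("cohort_birth_year", "fixed_base_year"):
            raise ValueError("unknown discount reference")
        if (self.reference == "fixed_base_year") != (self.fixed_base is not None):
            raise ValueError("fixed_base required iff reference is fixed_base_year")

    def reference_year(self, birth_year: int) -> int:
        return birth_year if self.reference == "cohort_birth_year" else self.fixed_base


@dataclass(frozen=True)
class WageTrajectory:
    """Annual wage per worker from a base year to the projection horizon."""

    base_year: int
    base_wage: float
    wages: Mapping[int, float]

    def __post_init__(self):
        if self.wages.get(self.base_year) != self.base_wage:
            raise ValueError("wages[base_year] must equal base_wage")
        if any(w <= 0 for w in self.wages.values()):
            raise ValueError("wages must be positive")


@dataclass(frozen=True)
class CohortImpact:
    """Schooling and present-value earnings gains for one birth cohort."""

    iso3: str
    birth_year: int
    n_births: float
    n_stunted: float
    delta_haz: float
    schooling_per_child: float  # years
    schooling_total: float  # years
    pv_per_child: Mapping[float, float]  # discount rate -> USD
    pv_total: Mapping[float, float]  # discount rate -> USD


def schooling_gain_per_child(delta_haz: float, coefficient: float = 0.47) -> float:
    """Additional schooling years per stunted child for a given HAZ gain."""
    if delta_haz < 0:
        raise ValueError("delta_haz must be >= 0")
    return coefficient * delta_haz


def base_wage(profile: CountryProfile) -> float:
    """Annual wage per worker: GNI pc x labor share / whole-population LFPR."""
    if profile.gni_pc is None:
        raise CountryDataError(f"{profile.iso3}: gni_pc missing; impute first")
    eff = profile.effective_lfpr
    if eff <= 0:
        raise CountryDataError(f"{profile.iso3}: effective LFPR is zero")
    return profile.gni_pc * profile.labor_share / eff


def growth_rate_for_year(profile: CountryProfile, year: int) -> float:
    """Annual GNI-pc growth rate applying in `year`.

    The rate of the five-year period [p, p+5) containing the year; years
    before 2020 use the first period, years beyond 2084 hold the final
    period's rate constant.
    """
    period = min(max((year // 5) * 5, GROWTH_PERIODS[0]), GROWTH_PERIODS[-1])
    try:
        return profile.growth_rates[period]
    except KeyError:
        raise CountryDataError(
            f"{profile.iso3}: growth rate for period {period} missing; impute first"
        ) from None


def wage_trajectory(
    base: float, profile: CountryProfile, base_year: int, horizon: int
) -> WageTrajectory:
    """Compound the base wage annually out to `horizon` (inclusive).

    The ratio wage(t+1)/wage(t) is 1 + the growth rate applying in year t.
    """
    if horizon < base_year:
        raise ValueError("horizon before base year")
    wages = {base_year: base}
    w = base
    for t in range(base_year, horizon):
        w *= 1.0 + growth_rate_for_year(profile, t)
        wages[t + 1] = w
    return WageTrajectory(base_year, base, wages)


def _uplift_fraction(
    return_per_school_year: float, schooling_gain: float, mode: str
) -> float:
    if mode == "linear":
        return return_per_school_year * schooling_gain
    if mode == "compound":
        return (1.0 + return_per_school_year) ** schooling_gain - 1.0
    raise ValueError(f"unknown uplift mode {mode!r}")


def pv_earnings_per_child(
    traj: WageTrajectory,
    profile: CountryProfile,
    schooling_gain: float,
    birth_year: int,
    worklife: WorkLife = WorkLife(),
    spec: DiscountSpec = DiscountSpec(),
    uplift_mode: str = "linear",
) -> dict[float, float]:
    """Present value of the extra lifetime earnings of one stunted child.

    The child earns wage(t) x return x schooling_gain extra in each working
    year t (ages entry..exit-1); each flow is discounted back to the
    reference year (the cohort's own birth year by default).
    """
    if profile.return_per_school_year is None:
        raise CountryDataError(f"{profile.iso3}: return_per_school_year missing")
    uplift = _uplift_fraction(profile.return_per_school_year, schooling_gain, uplift_mode)
    t0 = spec.reference_year(birth_year)
    years = range(birth_year + worklife.entry_age, birth_year + worklife.exit_age)
    missing = [t for t in years if t not in traj.wages]
    if missing:
        raise ValueError(f"wage trajectory does not cover year(s) {missing[:3]}...")
    out = {}
    for d in spec.rates:
        out[d] = sum(traj.wages[t] * uplift * (1.0 + d) ** (-(t - t0)) for t in years)
    return out


def cohort_impacts(
    scenarios: Sequence[CohortScenario],
    profile: CountryProfile,
    config: RunConfig = RunConfig(),
) -> list[CohortImpact]:
    """Assemble per-cohort schooling and earnings impacts for one country.

    Builds the wage trajectory once (from the base-year wage to the last
    cohort's final working year) and applies the schooling and
    present-value conversions cohort by cohort.
    """
    if not scenarios:
        return []
    worklife = WorkLife(config.entry_age, config.exit_age)
    if config.fixed_reference_year is None:
        spec = DiscountSpec(config.discount_rates, "cohort_birth_year")
    else:
        spec = DiscountSpec(config.discount_rates, "fixed_base_year", config.fixed_reference_year)
    horizon = max(s.birth_year for s in scenarios) + worklife.exit_age - 1
    traj = wage_trajectory(base_wage(profile), profile, config.wage_base_year, horizon)
    out = []
    for s in scenarios:
        schooling = schooling_gain_per_child(s.delta_haz, config.schooling_coefficient)
        pv = pv_earnings_per_child(
            traj, profile, schooling, s.birth_year, worklife, spec, config.uplift_mode
        )
        out.append(
            CohortImpact(
                iso3=profile.iso3,
                birth_year=s.birth_year,
                n_births=s.n_births,
                n_stunted=s.n_stunted,
                delta_haz=s.delta_haz,
                schooling_per_child=schooling,
                schooling_total=schooling * s.n_stunted,
                pv_per_child=pv,
                pv_total={d: v * s.n_stunted for d, v in pv.items()},
            )
        )
    return out
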