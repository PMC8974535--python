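"""Stunting trajectories and the HAZ gain among stunted children.

Stunting status for 12-23-month-olds is carried as a four-category HAZ
distribution (> -1, -1 to -2, -2 to -3, < -3); stunting prevalence is the
mass of the two lowest categories (HAZ < -2). A counterfactual scenario
(e.g. reaching SDG target 2.2, a 40% prevalence reduction from 2012 levels
by 2025, approached linearly from 2020) shifts that distribution upward;
the average HAZ gain among the children who were stunted at baseline is
extracted with a rank-preserving match: the baseline stunted mass p is
compared with the lowest-p mass of the counterfactual distribution, each
category represented by a fixed HAZ value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "StuntingDistribution",
    "HazCategoryModel",
    "ScenarioTrajectory",
    "CohortScenario",
    "ScenarioError",
    "sdg_target_prevalence",
    "linear_trajectory",
    "delta_haz_stunted",
    "stunted_count",
    "build_cohort_scenarios",
    "read_stunting_table",
]

_SHARE_TOL = 1e-9

#: Category order, best to worst: HAZ > -1, -1..-2, -2..-3, < -3.
CATEGORY_LABELS = (">-1", "-1 to -2", "-2 to -3", "<-3")


class ScenarioError(ValueError):
    """Raised for invalid stunting-scenario inputs."""


@dataclass(frozen=True)
class StuntingDistribution:
    """Four-category HAZ shares for 12-23-month-olds in one year."""

    year: int
    shares: tuple[float, float, float, float]

    def __post_init__(self):
        if len(self.shares) != 4:
            raise ScenarioError("exactly four category shares required")
        if any(s < 0 for s in self.shares):
            raise ScenarioError(f"negative share in {self.shares}")
        if abs(sum(self.shares) - 1.0) > _SHARE_TOL:
            raise ScenarioError(f"shares sum to {sum(self.shares)}, not 1")

    @property
    def prevalence(self) -> float:
        """Stunting prevalence: mass with HAZ < -2 (categories 3 and 4)."""
        return self.shares[2] + self.shares[3]


@dataclass(frozen=True)
class HazCategoryModel:
    """Representative HAZ value per category (interval midpoints by default).

    The open tails use conservative representatives (0.0 and -3.5); both
    stunted categories must sit below the -2 stunting cut-off and values
    must decrease strictly across categories.
    """

    representatives: tuple[float, float, float, float] = (0.0, -1.5, -2.5, -3.5)

    def __post_init__(self):
        r = self.representatives
        if len(r) != 4:
            raise ScenarioError("exactly four representative values required")
        if any(a >= b for a, b in zip(r[1:], r[:-1])):
            raise ScenarioError("representatives must strictly decrease across categories")
        if r[2] >= -2 or r[3] >= -2:
            raise ScenarioError("stunted-category representatives must lie below -2")


YearEntry = Union[StuntingDistribution, float]


@dataclass(frozen=True)
class ScenarioTrajectory:
    """Paired baseline/counterfactual stunting paths over contiguous years.

    Entries are either full four-category distributions or bare prevalences
    (prevalence-only mode, in which the per-cohort HAZ gain must be supplied
    externally). An improvement-only contract is enforced: counterfactual
    prevalence never exceeds baseline.
    """

    entries: Mapping[int, tuple[YearEntry, YearEntry]]

    def __post_init__(self):
        years = self.years
        if not years:
            raise ScenarioError("trajectory has no years")
        if years != tuple(range(years[0], years[-1] + 1)):
            raise ScenarioError(f"years not contiguous: {years}")
        for y, (base, cf) in self.entries.items():
            bp, cp = _prevalence(base), _prevalence(cf)
            for label, v in (("baseline", bp), ("counterfactual", cp)):
                if not 0 <= v <= 1:
                    raise ScenarioError(f"{label} prevalence {v} in {y} outside [0, 1]")
            if cp > bp + _SHARE_TOL:
                raise ScenarioError(
                    f"counterfactual prevalence {cp:.4f} exceeds baseline {bp:.4f} in {y};"
                    " only improvements are modelled"
                )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.entries))

    def baseline_prevalence(self, year: int) -> float:
        return _prevalence(self.entries[year][0])

    def counterfactual_prevalence(self, year: int) -> float:
        return _prevalence(self.entries[year][1])


def _prevalence(entry: YearEntry) -> float:
    return entry.prevalence if isinstance(entry, StuntingDistribution) else float(entry)


# ---------------------------------------------------------------------------
# Scenario construction
# ---------------------------------------------------------------------------


def sdg_target_prevalence(prev_2012: float) -> float:
    """SDG target 2.2: stunting prevalence reduced by 40% from its 2012 level."""
    if not 0 <= prev_2012 <= 1:
        raise ScenarioError(f"prevalence {prev_2012} outside [0, 1]")
    return 0.6 * prev_2012


def linear_trajectory(
    prev_start: float, prev_end: float, year_start: int, year_end: int
) -> dict[int, float]:
    """Linear prevalence path from (year_start, prev_start) to (year_end, prev_end).

    Both endpoints are included; interior years lie exactly on the chord.
    """
    for v in (prev_start, prev_end):
        if not 0 <= v <= 1:
            raise ScenarioError(f"prevalence {v} outside [0, 1]")
    if year_end <= year_start:
        raise ScenarioError("year_end must exceed year_start")
    years = np.arange(year_start, year_end + 1)
    values = np.linspace(prev_start, prev_end, len(years))
    return {int(y): float(v) for y, v in zip(years, values)}


# ---------------------------------------------------------------------------
# HAZ gain extraction
# ---------------------------------------------------------------------------


def delta_haz_stunted(
    baseline: StuntingDistribution,
    counterfactual: StuntingDistribution,
    model: HazCategoryModel = HazCategoryModel(),
) -> float:
    """Average HAZ gain among baseline-stunted children (rank-preserving).

    Children keep their rank in the HAZ distribution across scenarios: the
    baseline stunted population is the lowest-p mass of the baseline
    distribution (p = baseline prevalence, exactly the two lowest
    categories), and its counterfactual counterpart is the lowest-p mass of
    the counterfactual distribution, splitting a category pro-rata when p
    falls inside it. Each mass is averaged over the representative HAZ
    values; the difference (counterfactual minus baseline) is returned. The
    result is nonnegative whenever the counterfactual distribution
    first-order stochastically dominates the baseline.
    """
    p = baseline.prevalence
    if p <= 0:
        raise ScenarioError("baseline stunting prevalence is zero; no stunted children")
    r = model.representatives
    base_mean = (baseline.shares[2] * r[2] + baseline.shares[3] * r[3]) / p
    cf_mean = _lowest_mass_mean(counterfactual.shares, r, p)
    return cf_mean - base_mean


def _lowest_mass_mean(
    shares: tuple[float, ...], reps: tuple[float, ...], mass: float
) -> float:
    """Representative-HAZ mean over the lowest `mass` of a category distribution."""
    remaining = mass
    acc = 0.0
    for i in (3, 2, 1, 0):  # worst to best
        take = min(remaining, shares[i])
        acc += take * reps[i]
        remaining -= take
        if remaining <= 1e-15:
            break
    return acc / mass


def stunted_count(births: float, prevalence: float) -> float:
    """Stunted children in a cohort; real-valued, rounded only at report time."""
    if births < 0:
        raise ScenarioError("births must be >= 0")
    if not 0 <= prevalence <= 1:
        raise ScenarioError(f"prevalence {prevalence} outside [0, 1]")
    return births * prevalence


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortScenario:
    """One birth cohort's stunting outcome under the scenario pair."""

    birth_year: int
    n_births: float
    n_stunted: float
    delta_haz: float


def build_cohort_scenarios(
    trajectory: ScenarioTrajectory,
    births: Mapping[int, float],
    model: HazCategoryModel = HazCategoryModel(),
    cohort_lag: int = 0,
    delta_haz_override: Optional[Mapping[int, float]] = None,
) -> list[CohortScenario]:
    """Per-cohort stunted counts and HAZ gains from a scenario trajectory.

    The cohort born in year b is evaluated at trajectory year b +
    ``cohort_lag`` (lag 0 pairs the 2020-2025 cohorts one-to-one with the
    2020-2025 prevalence path; lag 1 reads the year the cohort is actually
    12-23 months old). The stunted count uses the *baseline* prevalence —
    the population whose growth improves. ``delta_haz_override`` supplies
    the per-cohort HAZ gain directly (required in prevalence-only mode).
    """
    years = trajectory.years
    cohort_years = [b for b in years if b + cohort_lag in trajectory.entries]
    if not cohort_years:
        raise ScenarioError("trajectory does not cover any cohort's evaluation year")
    out = []
    for b in cohort_years:
        eval_year = b + cohort_lag
        if b not in births:
            raise ScenarioError(f"births missing for cohort year {b}")
        base, cf = trajectory.entries[eval_year]
        prev = _prevalence(base)
        n_stunted = stunted_count(births[b], prev)
        if delta_haz_override is not None and b in delta_haz_override:
            dhaz = float(delta_haz_override[b])
        elif isinstance(base, StuntingDistribution) and isinstance(cf, StuntingDistribution):
            dhaz = 0.0 if prev == 0 else delta_haz_stunted(base, cf, model)
        else:
            raise ScenarioError(
                f"cohort {b}: prevalence-only trajectory needs delta_haz_override"
            )
        if dhaz < 0:
            raise ScenarioError(f"cohort {b}: negative HAZ gain {dhaz}")
        out.append(CohortScenario(b, float(births[b]), n_stunted, dhaz))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SHARE_COLUMNS = ("share_gt_m1", "share_m1_m2", "share_m2_m3", "share_lt_m3")


def read_stunting_table(path: str | Path) -> dict[str, ScenarioTrajectory]:
    """Read long-form ``stunting.csv`` into per-country trajectories.

    Columns: iso3, year, scenario (baseline|counterfactual) and either a
    ``prevalence`` column or the four share columns
    share_gt_m1..share_lt_m3 (fractions, best to worst category).
    """
    df = pd.read_csv(path, skipinitialspace=True)
    has_shares = all(c in df.columns for c in _SHARE_COLUMNS)
    if not has_shares and "prevalence" not in df.columns:
        raise ScenarioError(
            f"{path}: need either a 'prevalence' column or {_SHARE_COLUMNS}"
        )
    out: dict[str, ScenarioTrajectory] = {}
    for iso3, g in df.groupby(df["iso3"].astype(str).str.upper()):
        entries: dict[int, list[Optional[YearEntry]]] = {}
        for _, row in g.iterrows():
            year = int(row["year"])
            scen = str(row["scenario"]).strip().lower()
            if scen not in ("baseline", "counterfactual"):
                raise ScenarioError(f"{iso3} {year}: unknown scenario {row['scenario']!r}")
            if has_shares and all(pd.notna(row[c]) for c in _SHARE_COLUMNS):
                entry: YearEntry = StuntingDistribution(
                    year, tuple(float(row[c]) for c in _SHARE_COLUMNS)
                )
            else:
                entry = float(row["prevalence"])
            entries.setdefault(year, [None, None])[0 if scen == "baseline" else 1] = entry
        pairs = {}
        for year, (base, cf) in entries.items():
            if base is None or cf is None:
                raise ScenarioError(f"{iso3} {year}: baseline/counterfactual pair incomplete")
            pairs[year] = (base, cf)
        out[iso3] = ScenarioTrajectory(pairs)
    return out
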