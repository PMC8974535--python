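"""End-to-end projection: country inputs -> cohort impacts -> report tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .capital import CohortImpact, cohort_impacts
from .config import RunConfig
from .country import CountryProfile, ImputationRecord, impute_missing, imputation_audit
from .reporting import (
    ReportTable,
    earnings_by_country_table,
    earnings_by_rate_table,
    per_child_table,
    schooling_table,
)
from .scenario import HazCategoryModel, ScenarioTrajectory, build_cohort_scenarios

__all__ = ["ProjectionResult", "run_projection"]


@dataclass(frozen=True)
class ProjectionResult:
    """Everything a projection run produced, with table and summary views."""

    impacts: tuple[CohortImpact, ...]
    config: RunConfig
    audit: pd.DataFrame  # imputation log (iso3, field, donor_pool, value)

    def schooling_table(self) -> ReportTable:
        return schooling_table(self.impacts)

    def earnings_by_rate_table(self) -> ReportTable:
        return earnings_by_rate_table(self.impacts, self.config.discount_rates)

    def earnings_by_country_table(self, rate: float = 0.05) -> ReportTable:
        return earnings_by_country_table(self.impacts, rate)

    def per_child_table(self, rate: float = 0.05) -> ReportTable:
        return per_child_table(self.impacts, rate)

    def impacts_frame(self) -> pd.DataFrame:
        """Flat per-cohort record table (one row per country-cohort)."""
        rows = []
        for imp in self.impacts:
            row = {
                "iso3": imp.iso3,
                "birth_year": imp.birth_year,
                "n_births": imp.n_births,
                "n_stunted": imp.n_stunted,
                "delta_haz": imp.delta_haz,
                "schooling_per_child": imp.schooling_per_child,
                "schooling_total": imp.schooling_total,
            }
            for d in sorted(imp.pv_per_child):
                row[f"pv_per_child_{d:g}"] = imp.pv_per_child[d]
                row[f"pv_total_{d:g}"] = imp.pv_total[d]
            rows.append(row)
        return pd.DataFrame(rows).sort_values(["iso3", "birth_year"]).reset_index(drop=True)

    def summary(self) -> str:
        """Plain-text run summary with the headline totals."""
        schooling = sum(i.schooling_total for i in self.impacts)
        lines = [
            "Linear-growth human-capital projection",
            f"  countries: {len({i.iso3 for i in self.impacts})}"
            f"   cohorts: {len({i.birth_year for i in self.impacts})}",
            f"  total additional schooling: {schooling / 1e3:,.1f} thousand years",
        ]
        for d in self.config.discount_rates:
            pv = sum(i.pv_total[d] for i in self.impacts)
            lines.append(
                f"  PV additional lifetime earnings @ {d:.0%}: US$ {pv / 1e6:,.0f} million"
            )
        n_imp = len(self.audit)
        lines.append(f"  imputed cells: {n_imp}")
        return "\n".join(lines)


def run_projection(
    profiles: Sequence[CountryProfile],
    trajectories: Mapping[str, ScenarioTrajectory],
    config: Optional[RunConfig] = None,
    imputed: bool = False,
) -> ProjectionResult:
    """Run the full pipeline for every country with a trajectory.

    Profiles are imputed first (unless ``imputed=True`` signals they already
    were); each country's trajectory is turned into per-cohort stunted
    counts and HAZ gains, then into schooling and discounted-earnings
    impacts.
    """
    config = config or RunConfig()
    records: list[ImputationRecord] = []
    pool = list(profiles) if imputed else impute_missing(list(profiles), audit=records)
    model = HazCategoryModel(config.haz_representatives)
    impacts: list[CohortImpact] = []
    for p in pool:
        if p.iso3 not in trajectories:
            continue
        scen = build_cohort_scenarios(
            trajectories[p.iso3],
            p.births,
            model,
            cohort_lag=config.cohort_lag,
            delta_haz_override=config.delta_haz_override.get(p.iso3),
        )
        impacts.extend(cohort_impacts(scen, p, config))
    return ProjectionResult(tuple(impacts), config, imputation_audit(records))
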