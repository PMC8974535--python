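"""Report tables: per-cohort schooling and earnings aggregates.

Four shapes are produced from a set of :class:`CohortImpact` records:
schooling per birth cohort (thousand school years), present-value earnings
per cohort by discount rate and by country (USD millions), and per-stunted-
child present values (USD, with a cohort Average column). Totals are always
computed from unrounded cells; rounding happens only when a table is
rendered.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .capital import CohortImpact

__all__ = [
    "ReportTable",
    "with_totals",
    "with_average",
    "schooling_table",
    "earnings_by_rate_table",
    "earnings_by_country_table",
    "per_child_table",
    "render",
]

TOTAL = "Total"
AVERAGE = "Average"


@dataclass(frozen=True)
class ReportTable:
    """A titled numeric table with explicit units.

    ``frame`` rows are countries or discount rates; columns are birth
    cohorts plus a Total (or Average) margin.
    """

    title: str
    units: str  # "thousand school years" | "USD millions" | "USD"
    frame: pd.DataFrame

    def cell(self, row, col) -> float:
        return float(self.frame.loc[row, col])


def with_totals(
    cells: pd.DataFrame, total_col: bool = True, total_row: bool = True
) -> pd.DataFrame:
    """Append margin sums to a cells-only table (pre-rounding)."""
    out = cells.copy()
    if total_col:
        out[TOTAL] = out.sum(axis=1)
    if total_row:
        out.loc[TOTAL] = out.sum(axis=0)
    return out


def with_average(cells: pd.DataFrame) -> pd.DataFrame:
    """Append the unweighted mean of the cohort cells as an Average column."""
    out = cells.copy()
    out[AVERAGE] = cells.mean(axis=1)
    return out


def _impact_frame(impacts: Sequence[CohortImpact], value) -> pd.DataFrame:
    """Countries x cohort-years frame of `value(impact)`; errors if ragged."""
    if not impacts:
        raise ValueError("no impacts supplied")
    records = {}
    for imp in impacts:
        records.setdefault(imp.iso3, {})[imp.birth_year] = value(imp)
    cohorts = sorted({y for r in records.values() for y in r})
    for iso3, r in records.items():
        if sorted(r) != cohorts:
            raise ValueError(f"{iso3}: cohort coverage {sorted(r)} ragged vs {cohorts}")
    frame = pd.DataFrame.from_dict(records, orient="index", dtype=float)[cohorts]
    return frame.sort_index().rename_axis("country")


def schooling_table(impacts: Sequence[CohortImpact]) -> ReportTable:
    """Additional schooling per birth cohort, thousand school years."""
    cells = _impact_frame(impacts, lambda i: i.schooling_total / 1e3)
    return ReportTable(
        "Additional years of schooling gained per birth cohort",
        "thousand school years",
        with_totals(cells),
    )


def earnings_by_rate_table(
    impacts: Sequence[CohortImpact], rates: Iterable[float] = (0.03, 0.05, 0.10)
) -> ReportTable:
    """Region-aggregated PV earnings per cohort, one row per discount rate."""
    rows = {}
    for d in rates:
        cells = _impact_frame(impacts, lambda i, d=d: i.pv_total[d] / 1e6)
        rows[f"{d:.0%}"] = cells.sum(axis=0)
    frame = pd.DataFrame(rows).T.rename_axis("discount_rate")
    frame[TOTAL] = frame.sum(axis=1)
    return ReportTable(
        "Present value of additional lifetime earnings per birth cohort by discount rate",
        "USD millions",
        frame,
    )


def earnings_by_country_table(
    impacts: Sequence[CohortImpact], rate: float = 0.05
) -> ReportTable:
    """PV earnings per cohort and country at one discount rate."""
    cells = _impact_frame(impacts, lambda i: i.pv_total[rate] / 1e6)
    return ReportTable(
        f"Present value of additional lifetime earnings per birth cohort at {rate:.0%}",
        "USD millions",
        with_totals(cells),
    )


def per_child_table(impacts: Sequence[CohortImpact], rate: float = 0.05) -> ReportTable:
    """PV earnings per stunted child, with the unweighted cohort Average."""
    cells = _impact_frame(impacts, lambda i: i.pv_per_child[rate])
    return ReportTable(
        f"Present value of additional lifetime earnings per stunted child at {rate:.0%}",
        "USD",
        with_average(cells),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_DECIMALS = {"thousand school years": 1, "USD millions": 0, "USD": 0}


def rounded(table: ReportTable) -> pd.DataFrame:
    """Cells rounded to display precision (schooling to 0.1 thousand years,
    money to whole millions, per-child values to whole dollars)."""
    return table.frame.round(_DECIMALS.get(table.units, 2))


def render(table: ReportTable, fmt: str = "csv") -> str:
    """Render a table as csv, json or markdown text."""
    if fmt == "csv":
        buf = io.StringIO()
        # 17 significant digits: float64 values survive the round-trip exactly
        table.frame.to_csv(buf, float_format="%.17g")
        return buf.getvalue()
    if fmt == "json":
        payload = {
            "title": table.title,
            "units": table.units,
            "columns": [str(c) for c in table.frame.columns],
            "rows": {
                str(idx): [float(v) for v in row]
                for idx, row in table.frame.iterrows()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"
    if fmt == "markdown":
        disp = rounded(table)
        header = [str(disp.index.name or "")] + [str(c) for c in disp.columns]
        lines = [
            "| " + " | ".join(header) + " |",
            "| " + " | ".join("---" for _ in header) + " |",
        ]
        dec = _DECIMALS.get(table.units, 2)
        for idx, row in disp.iterrows():
            cells = [f"{v:.{dec}f}" for v in row]
            lines.append("| " + " | ".join([str(idx)] + cells) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def read_table_csv(path, title: str = "", units: str = "") -> ReportTable:
    """Round-trip companion to ``render(..., 'csv')``; cell values bit-exact."""
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    frame.columns = [int(c) if str(c).isdigit() else c for c in frame.columns]
    return ReportTable(title, units, frame)
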