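"""Optional chart helpers (matplotlib imported lazily)."""

from __future__ import annotations

from typing import Mapping

from .reporting import ReportTable
from .scenario import ScenarioTrajectory

__all__ = ["plot_prevalence_paths", "plot_per_child_bars"]


def plot_prevalence_paths(trajectories: Mapping[str, ScenarioTrajectory], ax=None):
    """Line chart of baseline vs counterfactual stunting prevalence per country."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for iso3, traj in trajectories.items():
        years = traj.years
        ax.plot(years, [100 * traj.counterfactual_prevalence(y) for y in years], label=iso3)
        ax.plot(years, [100 * traj.baseline_prevalence(y) for y in years],
                linestyle="--", alpha=0.4, color=ax.lines[-1].get_color())
    ax.set_xlabel("year")
    ax.set_ylabel("stunting prevalence, 12-23 months (%)")
    ax.legend(fontsize="small")
    return ax


def plot_per_child_bars(table: ReportTable, ax=None):
    """Bar chart of the per-stunted-child PV averages by country."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    averages = table.frame["Average"]
    ax.bar([str(i) for i in averages.index], averages.values)
    ax.set_ylabel(f"PV gain per stunted child ({table.units})")
    return ax
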