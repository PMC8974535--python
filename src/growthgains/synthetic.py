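"""Synthetic country panels and stunting scenarios for offline testing.

Generates plausible LMIC inputs end to end: country profiles (log-uniform
GNI per capita, uniform labor-force and demographic shares, mean-reverting
growth-rate paths, round-robin regions and income groups, a configurable
fraction of cells blanked to exercise imputation), SDG-ramp stunting
trajectories with four-category HAZ shares from a discretized normal, and a
complete on-disk input bundle for the CLI. Everything is deterministic
given a single integer seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import RunConfig
from .country import GROWTH_PERIODS, CountryProfile, IncomeGroup, WhoRegion
from .scenario import ScenarioTrajectory, StuntingDistribution, linear_trajectory, sdg_target_prevalence

__all__ = [
    "DEFAULT_SEED",
    "generate_profiles",
    "generate_trajectories",
    "shares_from_prevalence",
    "write_demo_bundle",
]

DEFAULT_SEED = 20220402

_IMPUTABLE = ("gni_pc", "lfpr_15plus", "pop_share_0_14", "return_per_school_year")


def _iso3(i: int) -> str:
    # synthetic, collision-free codes: XAA, XAB, ... XZZ, YAA, ...
    a, b = divmod(i, 26)
    c, d = divmod(a, 26)
    return chr(ord("X") + c) + chr(ord("A") + d) + chr(ord("A") + b)


def generate_profiles(
    n: int,
    seed: int = DEFAULT_SEED,
    missing_fraction: float = 0.1,
    start_year: int = 2020,
    n_cohorts: int = 6,
) -> list[CountryProfile]:
    """Draw `n` synthetic LMIC profiles, deterministic under `seed`.

    GNI per capita is log-uniform on [500, 12000] USD; the 15+ LFPR uniform
    on [0.4, 0.85]; the 0-14 population share uniform on [0.2, 0.45];
    returns to schooling uniform on [1%, 15%] per year; each five-year
    growth rate follows a mean-reverting walk clipped to [-2%, 8%]. Births
    are log-uniform on [5e4, 5e6] per cohort year. `missing_fraction` of
    the imputable cells are blanked (growth-rate paths dropped whole).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    regions = list(WhoRegion)
    incomes = list(IncomeGroup)
    profiles = []
    for i in range(n):
        gni = float(np.exp(rng.uniform(np.log(500.0), np.log(12_000.0))))
        lfpr = float(rng.uniform(0.4, 0.85))
        pop_share = float(rng.uniform(0.2, 0.45))
        ret = float(rng.uniform(0.01, 0.15))
        # mean-reverting walk around 2.5%/yr, clipped to [-2%, 8%]
        g = float(rng.uniform(0.0, 0.05))
        rates = {}
        for period in GROWTH_PERIODS:
            g = 0.7 * g + 0.3 * 0.025 + float(rng.normal(0.0, 0.01))
            g = float(np.clip(g, -0.02, 0.08))
            rates[period] = g
        births_level = float(np.exp(rng.uniform(np.log(5e4), np.log(5e6))))
        births = {
            start_year + k: births_level * float(rng.uniform(0.97, 1.03))
            for k in range(n_cohorts)
        }
        kwargs = dict(
            iso3=_iso3(i),
            name=f"Synthetica-{i:03d}",
            who_region=regions[i % len(regions)],
            income_group=incomes[i % len(incomes)],
            gni_pc=gni,
            lfpr_15plus=lfpr,
            pop_share_0_14=pop_share,
            return_per_school_year=ret,
            growth_rates=rates,
            births=births,
        )
        for f in _IMPUTABLE:
            if rng.random() < missing_fraction:
                kwargs[f] = None
        if rng.random() < missing_fraction:
            kwargs["growth_rates"] = {}
        profiles.append(CountryProfile(**kwargs))
    return profiles


def shares_from_prevalence(prevalence: float, year: int, sd: float = 1.1) -> StuntingDistribution:
    """Four-category shares from a normal HAZ distribution with P(HAZ < -2) = prevalence.

    The normal's mean is placed so the stunted mass (categories 3+4) equals
    the requested prevalence exactly; the four categories partition the real
    line so shares sum to one by construction.
    """
    prevalence = float(np.clip(prevalence, 1e-6, 1 - 1e-6))
    mu = -2.0 - sd * norm.ppf(prevalence)
    cuts = np.array([-1.0, -2.0, -3.0])
    cdf = norm.cdf((cuts - mu) / sd)  # P(HAZ < -1), P(< -2), P(< -3)
    shares = (1.0 - cdf[0], cdf[0] - cdf[1], cdf[1] - cdf[2], cdf[2])
    return StuntingDistribution(year, tuple(float(s) for s in shares))


def generate_trajectories(
    profiles: list[CountryProfile],
    seed: int = DEFAULT_SEED,
    start_year: int = 2020,
    end_year: int = 2025,
) -> dict[str, ScenarioTrajectory]:
    """SDG-ramp scenario per country: flat-to-gently-declining baseline,
    counterfactual ramping linearly to 60% of the (synthetic) 2012 level."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    out = {}
    for p in profiles:
        # beta draw centred in the 0.2-0.45 band
        base0 = 0.2 + 0.25 * float(rng.beta(2.0, 2.0))
        decline = float(rng.uniform(0.0, 0.01))  # absolute points per year
        prev_2012 = base0 / float(rng.uniform(0.85, 1.0))  # 2012 level >= 2020 level
        target = sdg_target_prevalence(min(prev_2012, 1.0))
        ramp = linear_trajectory(base0, target, start_year, end_year)
        entries = {}
        for y in range(start_year, end_year + 1):
            base_prev = max(base0 - decline * (y - start_year), 0.0)
            cf_prev = min(ramp[y], base_prev)
            entries[y] = (
                shares_from_prevalence(base_prev, y),
                shares_from_prevalence(cf_prev, y),
            )
        out[p.iso3] = ScenarioTrajectory(entries)
    return out


# ---------------------------------------------------------------------------
# On-disk demo bundle
# ---------------------------------------------------------------------------


def write_demo_bundle(
    directory: str | Path,
    n: int = 12,
    seed: int = DEFAULT_SEED,
    missing_fraction: float = 0.1,
) -> Path:
    """Write a complete synthetic input bundle (CSV + config) to `directory`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    profiles = generate_profiles(n, seed, missing_fraction)
    trajectories = generate_trajectories(profiles, seed)

    countries = pd.DataFrame(
        [
            {
                "iso3": p.iso3,
                "name": p.name,
                "who_region": p.who_region.value,
                "income_group": p.income_group.value,
                "gni_pc": p.gni_pc,
                "labor_share": p.labor_share,
                "lfpr_15plus": p.lfpr_15plus,
                "pop_share_0_14": p.pop_share_0_14,
                "return_per_school_year": p.return_per_school_year,
            }
            for p in profiles
        ]
    )
    countries.to_csv(directory / "countries.csv", index=False)

    growth = pd.DataFrame(
        [
            {"iso3": p.iso3, "period_start": period, "rate": rate}
            for p in profiles
            for period, rate in sorted(p.growth_rates.items())
        ]
    )
    growth.to_csv(directory / "growth_rates.csv", index=False)

    births = pd.DataFrame(
        [
            {"iso3": p.iso3, "year": year, "births": n_births}
            for p in profiles
            for year, n_births in sorted(p.births.items())
        ]
    )
    births.to_csv(directory / "births.csv", index=False)

    rows = []
    for iso3, traj in trajectories.items():
        for year in traj.years:
            for scen, dist in zip(("baseline", "counterfactual"), traj.entries[year]):
                rows.append(
                    {
                        "iso3": iso3,
                        "year": year,
                        "scenario": scen,
                        "prevalence": dist.prevalence,
                        "share_gt_m1": dist.shares[0],
                        "share_m1_m2": dist.shares[1],
                        "share_m2_m3": dist.shares[2],
                        "share_lt_m3": dist.shares[3],
                    }
                )
    pd.DataFrame(rows).to_csv(directory / "stunting.csv", index=False)

    RunConfig().to_file(directory / "config.yaml")
    return directory
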