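"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from growthgains import CountryProfile, HazCategoryModel, StuntingDistribution
from growthgains.country import GROWTH_PERIODS


def make_profile(iso3="TST", **overrides) -> CountryProfile:
    """A fully specified single-country profile with simple round numbers."""
    kwargs = dict(
        iso3=iso3,
        name="Testland",
        who_region="South-East Asia",
        income_group="lower-middle",
        gni_pc=1000.0,
        labor_share=0.5,
        lfpr_15plus=0.625,
        pop_share_0_14=0.2,
        return_per_school_year=0.10,
        growth_rates={p: 0.0 for p in GROWTH_PERIODS},
        births={y: 1_000_000.0 for y in range(2020, 2026)},
    )
    kwargs.update(overrides)
    return CountryProfile(**kwargs)


@pytest.fixture
def profile() -> CountryProfile:
    return make_profile()


def brute_force_delta_haz(
    baseline: StuntingDistribution,
    counterfactual: StuntingDistribution,
    model: HazCategoryModel = HazCategoryModel(),
    n_children: int = 1_000_000,
) -> float:
    """Independent rank-preserving simulation oracle for the HAZ gain.

    n pseudo-children are ranked worst-to-best; each is assigned the
    representative HAZ of the category its rank quantile falls into, in
    both scenarios; the gain is averaged over the baseline-stunted fraction.
    """
    reps_worst_first = np.array(model.representatives[::-1])  # <-3 first
    q = (np.arange(n_children) + 0.5) / n_children
    cum_base = np.cumsum(baseline.shares[::-1])
    cum_cf = np.cumsum(counterfactual.shares[::-1])
    haz_base = reps_worst_first[np.searchsorted(cum_base, q, side="left")]
    haz_cf = reps_worst_first[np.searchsorted(cum_cf, q, side="left")]
    stunted = q < baseline.prevalence
    return float(np.mean(haz_cf[stunted] - haz_base[stunted]))


def random_distribution_pair(rng: np.random.Generator, year: int = 2020):
    """A random (baseline, counterfactual) pair where the counterfactual
    first-order dominates the baseline (improvement only)."""
    base = rng.dirichlet(np.ones(4)) + 0.01  # keep every category inhabited
    base /= base.sum()
    # move a random part of each stunted category's mass up one category
    shift3 = base[3] * rng.uniform(0.0, 0.9)  # out of <-3
    shift2 = base[2] * rng.uniform(0.0, 0.9)  # out of -2..-3
    cf = base.copy()
    cf[3] -= shift3
    cf[2] += shift3 - shift2
    cf[1] += shift2
    return (
        StuntingDistribution(year, tuple(base)),
        StuntingDistribution(year, tuple(cf)),
    )
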