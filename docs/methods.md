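# Methods

## Model

The projection is a deterministic accounting chain per country and birth
cohort, linking a stunting counterfactual to human-capital outcomes:

```
stunting scenario ──► ΔHAZ among stunted children
                  ──► schooling gain   s = c · ΔHAZ          (c = 0.47 yr/HAZ)
                  ──► wage uplift      u = r · s             (linear, default)
                  ──► lifetime gain    PV(d) = Σₐ w(b+a) · u · (1+d)^−(b+a−T₀)
```

summed over working ages a = 16…59 (44 payments; the half-open window
[entry_age, exit_age) with defaults 16 and 60). Cohort totals multiply the
per-child figures by the stunted count, births × *baseline* prevalence:
the 0.47 coefficient applies to children who are stunted, so the
denominator is the population whose growth improves, not the smaller
counterfactual stunted population.

Assumptions inherited from the underlying accounting: the labor share of
income (default 0.5) and the labor-force participation rate are constant
over the projection; growth rates are nominal-USD GNI-per-capita growth
applied directly to wages with no separate inflation adjustment; the extra
earnings accrue once per child, with no labor-supply, unemployment,
schooling-cost or tax modelling; improvements are homogeneous within a
cohort (no within-country heterogeneity).

## Stunting representation and ΔHAZ extraction

Stunting among 12–23-month-olds is a four-category HAZ distribution with
cut points −1, −2, −3; prevalence is the mass below −2. How the average
HAZ gain among stunted children is recovered from category shifts is a
genuinely open design point; this package uses a **rank-preserving
lowest-mass match**: children keep their rank across scenarios, the
baseline stunted population is the lowest-p mass (exactly the two bottom
categories), its counterfactual counterpart is the lowest-p mass of the
counterfactual distribution (categories split pro-rata at the boundary),
and each mass is averaged over fixed representative HAZ values per
category. Defaults (0.0, −1.5, −2.5, −3.5) are interval midpoints with
conservative open-tail values; they are configurable, and the result is
invariant to a common shift of all four representatives. For workflows
where the upstream model supplies the HAZ gain directly, a
prevalence-only mode accepts ΔHAZ per cohort via `delta_haz_override`.

The SDG scenario sets the 2025 target to 0.6 × the 2012 prevalence and
interpolates linearly from the 2020 baseline; counterfactual prevalence
above baseline is rejected rather than clamped (improvements only).
Cohorts born 2020–2025 read the trajectory at their birth year
(`cohort_lag = 0`), pairing six cohorts with six scenario years; a strict
age-timing reading (evaluate at b+1, when the cohort is 12–23 months old)
is available as `cohort_lag = 1`. The 12–23-month band is the one age
group modelled.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| schooling_coefficient | 0.47 | school years per HAZ unit | pooled LMIC cohort estimate; linear in ΔHAZ |
| return_per_school_year | per country | fraction/year | Mincerian return; region-median imputed |
| labor_share | 0.5 | fraction | per-country overridable |
| discount_rates | 3%, 5%, 10% | per year | PV strictly decreasing in the rate |
| discount_reference | birth_year | — | per-cohort referencing makes later cohorts' PVs rise with a growing scenario effect; `fixed:<year>` rescales by (1+d)^−(b−T₀) |
| entry_age / exit_age | 16 / 60 | years | 44 working years, ages 16..59 |
| uplift_mode | linear | — | w·r·s; `compound` uses (1+r)^s − 1 (equal to first order) |
| wage_base_year | 2020 | year | GNI vintage seeding w₀ is configurable since the base-year choice is a data-vintage question |
| haz_representatives | 0, −1.5, −2.5, −3.5 | HAZ | strictly decreasing; bottom two below −2 |

Growth rates are one annual rate per five-year period 2020–2080 (any
cross-model averaging happens upstream at data preparation); the rate for
year t is the rate of the period containing t, wage(t+1)/wage(t) = 1 +
rate(t), and the 2080 period's rate extends beyond 2084 so the 2025
cohort's working life (through 2085) is covered.

## Imputation

Median imputation over donor pools of reporting countries: WHO-region
medians for returns to schooling and growth rates; income-group medians
for GNI per capita and the labor-force inputs. The 0–14 population share
is imputed with the income-group pool as well, since it exists only to
re-base the participation rate and shares that field's provenance. A pool
with no donors falls back to the global median; a field with no donors
anywhere is a hard error. Even-sized pools take the midpoint of the two
central values. Imputation is idempotent, never alters a reported value,
and logs every filled cell (country, field, donor pool, value) to an
audit table. High-income countries are rejected at read time: the donor
pools are defined over LMICs only.

Units in the input CSVs are declared per column: `<col>` holds fractions,
`<col>_pct` percent; values are validated against the declared range and
stored internally as fractions.

## Numerical choices

- Totals and averages are computed from unrounded cells; rounding happens
  only at render time (schooling to 0.1 thousand years, money to whole
  millions, per-child values to whole dollars).
- Category shares must sum to 1 within 1e-9; the pro-rata split terminates
  on a residual below 1e-15.
- CSV rendering uses 17-significant-digit floats and round-trip parsing,
  so rendered tables re-read bit-exactly and repeated runs on identical
  inputs are byte-identical.
- Zero baseline prevalence is an error in ΔHAZ extraction (no stunted
  children to improve) but yields a zero-impact cohort when it arises
  inside a trajectory.

## Synthetic data

The generator emulates an LMIC panel: GNI per capita log-uniform on
[500, 12 000] USD, 15+ LFPR uniform on [0.40, 0.85], 0–14 population share
uniform on [0.20, 0.45], returns to schooling uniform on [1%, 15%],
growth rates a mean-reverting walk clipped to [−2%, 8%], births log-uniform
on [5·10⁴, 5·10⁶] per cohort, regions and income groups round-robin, and a
configurable fraction of imputable cells blanked. Trajectories draw a
baseline prevalence in the 0.2–0.45 band (beta-shaped, flat to gently
declining) and ramp the counterfactual linearly to 60% of a synthetic 2012
level; four-category shares come from a discretized normal (σ = 1.1)
whose mean is placed so the below-−2 mass equals the prevalence exactly.
One integer seed (documented default 20220402) drives all generation.

What the synthetic panel does **not** emulate: real covariance between
income, returns and stunting levels; within-country heterogeneity;
non-linear or stalling prevalence paths; demographic feedback on cohort
sizes. Green tests on synthetic data therefore certify the accounting and
its invariants, not the realism of any particular country estimate — real
projections stand on the user's input files.

## Known limitations

- The published per-country results cannot be recomputed from first
  principles (the underlying stunting-model outputs and country input
  vintages are not public); the packaged reference tables cover printed
  output cells only, and reproduction checks are aggregation checks.
- Re-aggregating printed (already rounded) cells reproduces the printed
  margins to about one unit in the last digit; one printed grand total
  differs by two units because the source rounded cells and margins
  independently.
- Mortality/morbidity monetization and intervention costing are out of
  scope; so is fetching any live data.
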