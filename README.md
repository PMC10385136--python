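# fopnl — front-of-pack nutrition-labeling uptake analysis

`fopnl` is a Python toolkit for measuring the market uptake of a voluntary
front-of-pack endorsement logo — specifically the Thailand Healthier Choice
Logo (THCL) — across serial cross-sections of newly launched packaged food
and beverage products. It is aimed at nutrition-policy researchers who work
with product-launch databases (e.g. Mintel GNPD extracts) and need a tested,
reproducible path from raw label records to stratified uptake statistics and
trend projections. Because such databases are proprietary, the package ships
a synthetic launch-market generator with ground-truth annotations so every
stage is testable end to end.

## What it computes

For each product record (one barcode; distinct package sizes are distinct
products) the pipeline:

1. **standardizes** the back-of-pack nutrition panel to per-100 g/mL with
   energy in kJ (kcal × 4.184), resolving "less than" declarations to their
   closest whole number and %RDA mineral declarations to mg;
2. **categorizes** it through a 45-minor → 35-subgroup → 18-reporting-group
   crosswalk, applies scope exclusions (drinking water, vinegar, infant and
   medical foods, supplements, …) and the subgroup's criteria *eligibility
   window* — launches are only counted from the year their subgroup's
   criteria were first published;
3. **imputes** undeclared fiber (subgroup mean of declared non-zero values
   in homogeneous subgroups; nearest-energy matched product otherwise) and
   allocates fruit/vegetable/nut/legume (FVNL) content from ingredient
   predominance rank through a four-band decision tree
   (<25 / ≥25 / ≥67 / 100 % concentrated; ≤40 / >40 / >80 / 100 % non-concentrated);
4. **scores healthfulness** with the Health Star Rating (HSR) points
   algorithm: baseline points for energy, saturated fat, total sugar and
   sodium, minus modifying points for FVNL (V), protein (P, cap rule) and
   fiber (F); the final score `baseline − (V+P+F)` maps through a
   per-category matrix to 0.5–5.0 stars in half-star steps;
5. **classifies eligibility** with a config-driven criteria registry
   (conjunctive per-subgroup thresholds, e.g. total sugar ≤ 6.0 g/100 mL for
   sugar-sweetened beverages, sodium ≤ 1000 mg per 50 g serving for instant
   noodles) and tags display consistency;
6. **measures uptake** per total and per eligible products,

   uptake_total = n_labeled / n_total,  uptake_eligible = n_labeled / n_eligible,

   fits the closed-form least-squares trend `y = a + bX` with
   `b = (nΣty − ΣtΣy)/(nΣt² − (Σt)²)`, `a = (Σy − bΣt)/n` (X = 1, 2, … from
   the first study year), projects it forward with [0, 1] clamping, and
   builds category / HSR / manufacturer-stratified reports with Pearson
   chi-square comparisons.

## Worked example

```python
from fopnl import (
    default_study_scenario, generate_products, annotate_products,
    uptake_series, fit_linear_trend, project_uptake,
)

batch = generate_products(default_study_scenario(), seed=1)
annotated = annotate_products(batch.products)
counted = annotated[annotated["status"] == "assigned_in_window"]

print(len(counted))                                  # 7767
print(f"{counted['eligible'].mean():.1%}")           # 26.4%
print(f"{counted['thcl_displayed'].mean():.1%}")     # 10.8%

series = uptake_series(annotated)
fit = fit_linear_trend(series.years, series.proportions("eligible"))
print(f"{fit.slope:.3f}")                            # 0.103
proj = project_uptake(fit, 2027)
print(proj.tail(1).to_string(index=False))
#  year  predicted  predicted_clamped
#  2027   1.230609                1.0
```

Of 7767 counted synthetic launches, 26.4% are eligible for the logo and
10.8% display it; uptake among eligible products rises by about 10.3
percentage points per year, so a linear continuation would exceed full
uptake (clamped to 100%) by 2027.

The same stages are scriptable from a shell:

```bash
fopnl simulate --out synth.csv --seed 3
fopnl eligibility --in synth.csv --out elig.csv
fopnl analyze --in elig.csv --out report.csv --project-to 2027
```

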