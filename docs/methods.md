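# Methods

This note records the models, parameter choices and numerical conventions
behind `fopnl`, and what the shipped synthetic scenario does and does not
establish about real launch data.

## Study design being modeled

The package analyzes *serial cross-sections of newly launched products*: one
record per barcode per launch year, never a retention panel. Uptake of the
endorsement logo is therefore a flow measure (share of new launches labeled),
on two denominators: all counted launches, and launches whose standardized
panels satisfy their subgroup's nutrient criteria ("eligible"). A subgroup
only enters the denominators from the year its criteria were first published
(the *eligibility window*, inclusive of the start year): criteria for the
founding groups (non-alcoholic beverages, dairy, snacks) date to 2016, ice
cream to 2017, bakery/bread/breakfast cereal to 2019, and meat/fish
subgroups fall after the 2017–2021 window entirely. With the shipped window
configuration the default scenario counts 7767 of 8353 generated launches,
the remainder being pre-window starchy-group launches.

## Panel standardization

Panels are rescaled linearly from per-serving declarations to per-100 g/mL
(rescaling and kcal→kJ conversion commute; energy factor 4.184 kJ/kcal).
"Less than" declarations (`"<x"`) resolve to the whole number nearest to x
(round-half-up; `"<1.0"`→1, `"<0.4"`→0), with a `ceiling` variant available —
the two differ only between x.0 and x.5, and `nearest` is the less aggressive
generalization of the published example. Calcium and iron declared as %RDA
convert to mg with Thai RDI reference values (calcium 800 mg, iron 15 mg),
kept in config because authoritative per-label values vary by issue date.
Records with no usable as-prepared panel are excluded with reason
`"no usable NIP"`, never silently dropped. Internal label inconsistencies
(saturated fat > total fat, sugar > carbohydrate) are flagged as warnings
but not rejected, since printed labels do contain them.

## Fiber and FVNL reconstruction

Thai panels need not declare fiber or FVNL content, so:

* **Fiber** — products listing a fiber-bearing ingredient (inulin, psyllium,
  pectin, fructooligosaccharides, bran, whole grains, …) but no declared
  value receive either the subgroup mean of declared non-zero fiber
  (subgroups flagged homogeneous: dressings, sauces, wet/instant soups,
  extruded snacks) or the fiber of the same-subgroup product with the
  nearest energy density (heterogeneous subgroups; energy is the most
  universally declared proxy for formulation similarity, and ties break on
  the lexicographically lowest barcode for determinism). Products with
  neither declared fiber nor a fiber source get zero. Declared values are
  never overwritten.
* **FVNL** — a four-band decision tree on ingredient predominance rank.
  "Does not substantially contribute to weight" is operationalized with a
  minor-additive lexicon (salt, flavouring, acidity regulators, …), since no
  quantitative threshold is published. Band representatives default to the
  band's lower bound — conservative for downstream V points — with a
  midpoint option. The concentrated/non-concentrated split follows the
  `concentrate`/`paste`/`dried` markers in the ingredient name. Token
  matching is deliberately simple substring matching; it will mis-flag
  e.g. seed oils named after their source plant, which is acceptable for
  the synthetic templates shipped here but a known limitation on free-text
  real-world ingredient lists.

## HSR scoring

The scoring engine is entirely table-driven (`hsr_tables_v7.yaml`,
version-stamped into every result). Band tables use lower-closed,
upper-open intervals: a value sitting exactly on an edge earns the higher
band's points (the published guide's interval phrasing varies; one
convention is fixed and tested at every boundary). Values beyond the top
edge saturate. Concentrated FVNL folds into a single percentage via the
rehydration-weighted formula `(nc + 2c)/(100 + c) × 100`. Protein points are
suppressed when baseline points reach 13 unless V points reach 5 (the cap
rule); beverages (C1) earn V points only. Star matrices are monotone
non-increasing in the final score and emit only half-star values in
[0.5, 5.0]; oils/spreads and cheese subgroups are never scored. A five-grade
summary (A: 4.5–5.0, B: 3.0–3.5, C, D, E descending in one-star bands) is
provided as a convenience mapping. The tables are a best-effort
transcription of the published calculator guide and the engine's guarantees
are structural (monotonicity, score identity, output range) — no claim of
regulatory equivalence with the official calculator is made, and the scheme
itself remains under periodic review, which table version pinning mitigates
but does not resolve.

## Eligibility criteria registry

Criteria are conjunctive per-subgroup threshold sets over panel nutrients,
evaluated per 100 g/mL or per stated serving (the product's declared serving
is used when present, the criteria's stated size otherwise). Three entries
are anchored to published values — sugar-sweetened beverage total sugar
≤ 6.0 g/100 mL; water-based sauce sodium 5000 (fish sauce) to 6000 (soy
sauce) mg/100 mL, modeled as subtype-specific thresholds so both band
endpoints are representable; instant noodle/porridge sodium ≤ 1000 mg per
50 g serving. The remaining 30 entries are plausible placeholders, each
tagged `anchored: false`; all analytics are registry-agnostic, so replacing
the registry with an authoritative one requires no code change. Shipped
conditions use only nutrients that are mandatory on Thai panels (sugar,
sodium, fats, protein), so eligibility never depends on an imputed quantity;
desirable-nutrient floors (`op: ge`) are supported and exercised by the soy
milk protein floor.

## Uptake statistics

Closed-form least squares implements the normal equations directly; the test
suite holds it to 1e-10 agreement with a generic matrix least-squares oracle.
Years encode as X = 1, 2, … from the first fit year — with a published fit of
0.0301X − 0.0199 this encoding puts the 2027 projection at 31.1%, within the
rounding of the ~32% the corresponding study projection reports, which is
why it is the default (the encoding is explicit in `TrendFit.x_start`).
Slope intervals use the t distribution at n−2 df. Constant series are
reported degenerate (R² undefined) rather than R² = 1 or 0. Sub-period fits
(e.g. pre-pandemic vs 2019–2021) reuse the same machinery on year subsets.
Chi-square is Pearson's without continuity correction, df = k−1, with a
warning annotation when any expected cell falls below 1. Displayed
percentages round half-up to one decimal. Manufacturer reports list firms
with ≥ 5 labeled products individually and fold the rest into a residual
row; firm-level trend fits are omitted as their yearly series are too sparse.

## Synthetic market generator

The generator emulates the *structure* of a commercial launch database, not
any real market. Per reporting group it plans deterministic launch counts
(largest-remainder split across subgroups, even split across active years),
draws panel-level eligibility as Bernoulli with the group's eligible share,
and draws nutrients from right-skewed label-like distributions (log-normal
for energy/sugar/sodium/saturated fat, truncated normal for protein/fiber) —
all parameters invented and labeled as such in `default_study.yaml`.
Nutrients named in a subgroup's criteria are then forced consistent with the
drawn eligibility (eligible rows satisfy every condition; ineligible rows
violate the subgroup's leading condition), which makes the generator/rules
engine loop exactly closed: the engine must reproduce the eligibility
annotation on 100% of products, and the suite asserts that it does.

Display is conditional on eligibility:
`P(display | eligible, year, group) = r_g · (0.08 + 0.105·X)`, with `r_g`
solved per group so the group's pooled eligible uptake matches its scenario
target, and `P(display | ineligible) = 0` by default (an anomaly-rate knob
exercises the display-consistency tags). The scenario's calibration targets
are the aggregate moments of the study period it emulates — 7767 counted
launches with the published per-group totals, 27.0% eligible overall, 39.5%
labeled among eligible (hence 10.7% of total), group-level eligible-uptake
levels from the published category table — so simulated headline statistics
land near those values up to binomial noise (≈0.5 pp on the eligible share
at full n). The generator's ground-truth uptake curve is computed
analytically from the plan (`expected_uptake_curve`), and the
parameter-recovery test requires the fitted slope's 95% CI to cover the
analytic slope in ≥ 90% of 200 replicates.

What passing tests on this generator do **not** show: robustness to
free-text category/ingredient noise, to per-serving-only panels, to display
anomalies at real-world rates, or to criteria registries beyond the shipped
thresholds; the nutrient distributions are stylized, and manufacturer
structure is a Zipf toy (its labeled-manufacturer share is reported but not
calibrated).

## Numerical conventions and edge cases

* Panel comparisons to 1e-9 relative tolerance; trend-oracle agreement to
  1e-10 absolute.
* Degenerate inputs: zero uptake denominators report N/A (never 0/0 = 0);
  empty batches dedup to empty with zero removed; a constant trend series is
  flagged rather than fitted blindly; unmapped category codes surface in an
  `unmapped` partition instead of being guessed.
* Determinism: one master seed drives the generator; identical (config,
  seed) pairs are byte-identical. Donor matching and duplicate resolution
  (first-seen wins) have explicit tie-breaks.
* Problem sizes: the default suite runs one full-size market (8353 launches)
  through the complete pipeline and 200 full-size replicates through the
  counting stages; these sizes make the binomial noise bounds in the
  calibration checks meaningful at the study's own n.

## Known source inconsistencies

The published category table this package's tests cross-check against
contains two cells whose printed percentage contradicts the printed n/N pair
beside it (2/11 shown as 18.1 rather than 18.2; 195/332 shown as 57.8 rather
than 58.7), and the eligible-product total appears once as 2139 against the
table's internally consistent 2097. The package reproduces the arithmetic
(and the 2097-consistent totals) in all cases.
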