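# THCL eligibility criteria registry. One entry per THCL subgroup; conditions
# are conjunctive (all must hold). `basis: per100` thresholds apply to the
# standardized per-100 g/mL panel; `basis: per_serving` thresholds apply to the
# stated serving size in grams (`serving_size_g`), evaluated on the product's
# declared serving when available and on the stated size otherwise.
#
# Entries with `anchored: true` carry thresholds printed in the public scheme
# discussion (sugar-sweetened beverages 6.0 g/100 mL total sugar; water-based
# sauce sodium 5000-6000 mg/100 mL; instant noodle/porridge sodium 1000 mg per
# 50 g serving). All other entries are plausible placeholders so the full
# pipeline is exercisable; every analytic stage is registry-agnostic.
#
# Only nutrients that are mandatory on Thai nutrition panels (sugar, sodium,
# fats, protein) are used as shipped conditions, so eligibility never depends
# on an imputed quantity. Fiber floors are representable (op: ge) but unused.
version: "thcl-criteria-2021.1"

subgroups:
  carbonated_soft_drinks:
    anchored: true
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 6.0, basis: per100}
  functional_drinks:
    anchored: true
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 6.0, basis: per100}
  juice_drinks:
    anchored: true
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 6.0, basis: per100}
  instant_tea:
    anchored: true
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 6.0, basis: per100}
  instant_coffee:
    anchored: true
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 6.0, basis: per100}
  fruit_juice:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 10.0, basis: per100}
  vegetable_juice:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 10.0, basis: per100}
  white_milk:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 5.5, basis: per100}
      - {nutrient: saturated_fat, op: le, threshold: 2.5, basis: per100}
  flavored_milk:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 6.0, basis: per100}
      - {nutrient: saturated_fat, op: le, threshold: 2.5, basis: per100}
  drinking_yogurt:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 7.0, basis: per100}
  spoonable_yogurt:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 10.0, basis: per100}
      - {nutrient: total_fat, op: le, threshold: 3.5, basis: per100}
  soy_milk:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 6.0, basis: per100}
      - {nutrient: protein, op: ge, threshold: 2.0, basis: per100}
  nut_milk:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 6.0, basis: per100}
  cereal_milk:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 6.0, basis: per100}
  malted_drinks:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 6.0, basis: per100}
  ice_cream:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 20.0, basis: per100}
      - {nutrient: total_fat, op: le, threshold: 10.0, basis: per100}
  instant_noodles:
    anchored: true
    conditions:
      - {nutrient: sodium, op: le, threshold: 1000.0, basis: per_serving, serving_size_g: 50}
  instant_porridge:
    anchored: true
    conditions:
      - {nutrient: sodium, op: le, threshold: 1000.0, basis: per_serving, serving_size_g: 50}
  fish_sauce:
    anchored: true
    conditions:
      - {nutrient: sodium, op: le, threshold: 5000.0, basis: per100}
  soy_sauce:
    anchored: true
    conditions:
      - {nutrient: sodium, op: le, threshold: 6000.0, basis: per100}
  seasoning_powder:
    anchored: false
    conditions:
      - {nutrient: sodium, op: le, threshold: 18000.0, basis: per100}
  dressing:
    anchored: false
    conditions:
      - {nutrient: total_fat, op: le, threshold: 30.0, basis: per100}
      - {nutrient: sodium, op: le, threshold: 1100.0, basis: per100}
  bread:
    anchored: false
    conditions:
      - {nutrient: sodium, op: le, threshold: 450.0, basis: per100}
      - {nutrient: total_sugar, op: le, threshold: 10.0, basis: per100}
  cakes_and_pastries:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 22.0, basis: per100}
      - {nutrient: total_fat, op: le, threshold: 18.0, basis: per100}
  cookies_and_biscuits:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 22.0, basis: per100}
      - {nutrient: sodium, op: le, threshold: 500.0, basis: per100}
  breakfast_cereal:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 20.0, basis: per100}
      - {nutrient: sodium, op: le, threshold: 500.0, basis: per100}
  cereal_bars:
    anchored: false
    conditions:
      - {nutrient: total_sugar, op: le, threshold: 25.0, basis: per100}
  ready_meals:
    anchored: false
    conditions:
      - {nutrient: sodium, op: le, threshold: 500.0, basis: per100}
  small_meals:
    anchored: false
    conditions:
      - {nutrient: sodium, op: le, threshold: 500.0, basis: per100}
  potato_chips:
    anchored: false
    conditions:
      - {nutrient: sodium, op: le, threshold: 500.0, basis: per100}
  extruded_snacks:
    anchored: false
    conditions:
      - {nutrient: sodium, op: le, threshold: 500.0, basis: per100}
  nuts_and_seeds:
    anchored: false
    conditions:
      - {nutrient: sodium, op: le, threshold: 100.0, basis: per100}
      - {nutrient: total_sugar, op: le, threshold: 7.0, basis: per100}
  bean_snacks:
    anchored: false
    conditions:
      - {nutrient: sodium, op: le, threshold: 240.0, basis: per100}
      - {nutrient: total_sugar, op: le, threshold: 7.0, basis: per100}
  wet_soups:
    anchored: false
    conditions:
      - {nutrient: sodium, op: le, threshold: 340.0, basis: per100}
  instant_soups:
    anchored: false
    conditions:
      - {nutrient: sodium, op: le, threshold: 400.0, basis: per100}
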