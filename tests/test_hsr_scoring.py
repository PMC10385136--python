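"""HSR points engine: band lookups, cap rule, star conversion, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fopnl.hsr_scoring import (
    HSR_CATEGORIES,
    assign_hsr_category,
    baseline_points,
    combined_fvnl_pct,
    hsr_to_grade,
    modifying_points,
    score_frame,
    score_panel,
    score_to_stars,
)

ZERO_PANEL = {
    "energy": 0.0,
    "saturated_fat": 0.0,
    "total_sugar": 0.0,
    "sodium": 0.0,
    "protein": 0.0,
    "fiber": 0.0,
    "fvnl_nonconc_pct": 0.0,
    "fvnl_conc_pct": 0.0,
}


def _panel(**kw):
    return dict(ZERO_PANEL, **kw)


panel_strategy = st.fixed_dictionaries(
    {
        "energy": st.floats(0, 4000),
        "saturated_fat": st.floats(0, 100),
        "total_sugar": st.floats(0, 100),
        "sodium": st.floats(0, 9000),
        "protein": st.floats(0, 40),
        "fiber": st.floats(0, 25),
        "fvnl_nonconc_pct": st.floats(0, 100),
        "fvnl_conc_pct": st.floats(0, 100),
    }
)


def test_zero_panel_scores_zero_baseline(tables):
    assert baseline_points(ZERO_PANEL, tables) == 0


def test_band_boundaries_closed_on_lower_edge(tables):
    # 335 kJ sits exactly on the first energy edge: the band it opens wins
    assert baseline_points(_panel(energy=334.999), tables) == 0
    assert baseline_points(_panel(energy=335.0), tables) == 1
    assert baseline_points(_panel(sodium=90.0), tables) == 1


def test_values_beyond_top_band_saturate(tables):
    a = baseline_points(_panel(sodium=9000), tables)
    b = baseline_points(_panel(sodium=90000), tables)
    assert a == b == 30


def test_midrange_panel_against_manual_lookup(tables):
    """Frozen against by-hand band lookups in the shipped tables: energy
    1500 kJ -> 4, sat fat 5 g -> 5, sugar 15 g -> 3, sodium 450 mg -> 5."""
    panel = _panel(energy=1500, saturated_fat=5, total_sugar=15, sodium=450)
    assert baseline_points(panel, tables) == 4 + 5 + 3 + 5


def test_sole_ingredient_juice_gets_maximal_v_points(tables):
    v, p, f = modifying_points(_panel(fvnl_nonconc_pct=100.0), tables, category="C1")
    assert v == 8  # top of the shipped FVNL table


def test_combined_fvnl_formula(tables):
    # pure concentrated rehydrates to 100%
    assert combined_fvnl_pct(0.0, 100.0, tables) == pytest.approx(100.0)
    # 40% non-conc + 25% conc: (40 + 50) / 125 * 100 = 72
    assert combined_fvnl_pct(40.0, 25.0, tables) == pytest.approx(72.0)


def test_protein_cap_rule(tables):
    # baseline >= 13 and V < 5: P forced to zero
    high = _panel(energy=3400, saturated_fat=10, sodium=900, protein=10)
    base = baseline_points(high, tables)
    assert base >= tables.cap_baseline_threshold
    v, p, f = modifying_points(high, tables, base, "C2")
    assert v < tables.cap_min_v_points and p == 0
    # enough V points release the cap
    released = dict(high, fvnl_nonconc_pct=85.0)
    v2, p2, _ = modifying_points(released, tables, base, "C2")
    assert v2 >= tables.cap_min_v_points and p2 > 0


def test_beverages_earn_v_points_only(tables):
    bev = _panel(protein=10, fiber=5, fvnl_nonconc_pct=50)
    v, p, f = modifying_points(bev, tables, category="C1")
    assert (v, p, f) == (1, 0, 0)


@pytest.mark.parametrize(
    "score, category, stars",
    [
        (-100, "C2", 5.0),  # below the lowest threshold
        (100, "C2", 0.5),  # above the highest
        (5, "C2", 3.0),  # mid-matrix lookup
        (0, "C1D", 3.5),
    ],
)
def test_score_to_stars_matrix(tables, score, category, stars):
    assert score_to_stars(score, category, tables) == stars


def test_final_score_identity_and_unscored(tables):
    res = score_panel(_panel(energy=800, protein=5, fiber=2), "C2", tables)
    assert res.final_score == res.baseline_points - (res.v_points + res.p_points + res.f_points)
    assert res.table_version == tables.version
    unscored = score_panel(ZERO_PANEL, "unscored", tables)
    assert unscored.stars is None


@pytest.mark.parametrize(
    "subgroup, expected",
    [
        ("carbonated_soft_drinks", "C1"),
        ("flavored_milk", "C1D"),
        ("dressing", "unscored"),
        ("ice_cream", "C2D"),
    ],
)
def test_category_routing_by_subgroup_hint(cmap, tables, subgroup, expected):
    assert assign_hsr_category(subgroup, "per100g", (), cmap, tables) == expected


def test_category_routing_fallback_on_ingredients(cmap, tables):
    assert assign_hsr_category(None, "per100mL", ("milk", "sugar"), cmap, tables) == "C1D"
    assert assign_hsr_category(None, "per100mL", ("water",), cmap, tables) == "C1"
    assert assign_hsr_category(None, "per100g", ("rice",), cmap, tables) == "C2"


@pytest.mark.parametrize("stars, grade", [(5.0, "A"), (4.5, "A"), (3.5, "B"), (3.0, "B"), (2.0, "C"), (0.5, "E")])
def test_five_grade_summary(tables, stars, grade):
    assert hsr_to_grade(stars, tables) == grade


@settings(max_examples=200, derandomize=True)
@given(panel=panel_strategy, category=st.sampled_from(HSR_CATEGORIES))
def test_stars_always_half_star_in_range(tables, panel, category):
    res = score_panel(panel, category, tables)
    assert res.stars in {x / 2 for x in range(1, 11)}
    assert res.final_score == res.baseline_points - (res.v_points + res.p_points + res.f_points)


@settings(max_examples=150, derandomize=True)
@given(panel=panel_strategy, category=st.sampled_from(HSR_CATEGORIES))
def test_monotonicity_under_perturbation(tables, panel, category):
    """Worsening any risk nutrient never raises stars; improving any
    modifier never lowers them (protein checked only when uncapped)."""
    base = score_panel(panel, category, tables)
    for nutrient in ("energy", "saturated_fat", "total_sugar", "sodium"):
        worse = dict(panel)
        worse[nutrient] = worse[nutrient] * 1.5 + 10
        assert score_panel(worse, category, tables).stars <= base.stars
    for nutrient, cap in (("fvnl_nonconc_pct", 100), ("fiber", None)):
        better = dict(panel)
        better[nutrient] = min(cap, better[nutrient] * 1.5 + 5) if cap else better[nutrient] * 1.5 + 2
        assert score_panel(better, category, tables).stars >= base.stars
    if base.baseline_points < tables.cap_baseline_threshold:
        better = dict(panel, protein=panel["protein"] + 5)
        assert score_panel(better, category, tables).stars >= base.stars


def test_determinism(tables):
    panel = _panel(energy=1234, saturated_fat=3.3, total_sugar=22, sodium=480, protein=6, fiber=3)
    assert score_panel(panel, "C2", tables) == score_panel(panel, "C2", tables)


def test_frame_scoring_matches_scalar_path(cmap, tables):
    rng = np.random.default_rng(7)
    n = 60
    frame = pd.DataFrame(
        {
            "thcl_subgroup": rng.choice(["carbonated_soft_drinks", "ice_cream", "bread", "flavored_milk"], n),
            "basis": "per100g",
            "ingredients": [()] * n,
            "energy": rng.uniform(0, 3000, n),
            "saturated_fat": rng.uniform(0, 30, n),
            "total_sugar": rng.uniform(0, 60, n),
            "sodium": rng.uniform(0, 2000, n),
            "protein": rng.uniform(0, 20, n),
            "fiber": rng.uniform(0, 10, n),
            "fvnl_nonconc_pct": rng.uniform(0, 100, n),
            "fvnl_conc_pct": 0.0,
        }
    )
    out = score_frame(frame, tables, cmap)
    for _, row in out.iterrows():
        res = score_panel(row.to_dict(), row["hsr_category"], tables)
        assert row["stars"] == res.stars
        assert row["final_score"] == res.final_score
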