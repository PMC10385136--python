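"""Health Star Rating (HSR) scoring via the baseline/modifying-points
nutrient-profiling algorithm.

Baseline points accrue from the risk nutrients (energy, saturated fat, total
sugars, sodium, per 100 g/mL); modifying points from FVNL content (V),
protein (P, subject to the cap rule) and fiber (F). The final score
``baseline - (V + P + F)`` converts to a star rating of 0.5-5.0 in half-star
steps through a per-category matrix — higher stars mean a healthier product
within its category. Four categories are scored here: non-dairy beverages
(C1), dairy beverages (C1D), non-dairy foods (C2) and dairy foods (C2D);
oils/spreads and cheeses route to ``unscored``.

All point tables, the protein-cap parameters and the star matrices are data
(:mod:`fopnl.assets` ``hsr_tables_v7.yaml``), so table revisions never touch
this logic; results carry the table version.
"""

from __future__ import annotations

import math
from typing import Any, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel

from ._assets import load_asset
from .categorization import CategoryMap, load_category_map

HSR_CATEGORIES = ("C1", "C1D", "C2", "C2D")
UNSCORED = "unscored"

HALF_STARS = tuple(x / 2 for x in range(1, 11))


class HsrResult(BaseModel):
    category: str
    baseline_points: int
    v_points: int
    p_points: int
    f_points: int
    final_score: int
    stars: Optional[float]
    table_version: str


class _StepTable:
    """Stepwise band lookup: value v scores points[#edges <= v].

    Bands are closed on the lower edge and open above; values beyond the top
    edge saturate at the top band's points.
    """

    def __init__(self, edges: Sequence[float], points: Sequence[int], name: str):
        self.edges = np.asarray(edges, dtype=float)
        self.points = np.asarray(points, dtype=int)
        if len(self.points) != len(self.edges) + 1:
            raise ValueError(f"{name}: need one more points entry than edges")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError(f"{name}: edges must be strictly increasing")
        if np.any(np.diff(self.points) < 0):
            raise ValueError(f"{name}: points must be non-decreasing")

    def lookup(self, value):
        idx = np.searchsorted(self.edges, value, side="right")
        return self.points[idx]


class HsrTables:
    def __init__(self, data: Mapping[str, Any]):
        self.version: str = data.get("version", "unversioned")
        self.baseline = {
            k: _StepTable(v["edges"], v["points"], f"baseline.{k}")
            for k, v in data["baseline"].items()
        }
        self.modifying = {
            k: _StepTable(v["edges"], v["points"], f"modifying.{k}")
            for k, v in data["modifying"].items()
        }
        self.concentrated_weight = float(data["fvnl_combination"]["concentrated_weight"])
        self.cap_baseline_threshold = int(data["protein_cap"]["baseline_threshold"])
        self.cap_min_v_points = int(data["protein_cap"]["min_v_points"])
        self.applicability = {
            cat: {k: bool(v) for k, v in flags.items()}
            for cat, flags in data["applicability"].items()
        }
        self.star_matrix: dict[str, list[tuple[float, float]]] = {}
        for cat, rows in data["star_matrix"].items():
            entries = [
                (math.inf if row["max"] is None else float(row["max"]), float(row["stars"]))
                for row in rows
            ]
            maxima = [m for m, _ in entries]
            stars = [s for _, s in entries]
            if sorted(maxima) != maxima:
                raise ValueError(f"star matrix {cat}: score bounds must ascend")
            if sorted(stars, reverse=True) != stars:
                raise ValueError(f"star matrix {cat}: stars must descend with score")
            if any(s not in HALF_STARS for s in stars):
                raise ValueError(f"star matrix {cat}: stars must be half-star values")
            self.star_matrix[cat] = entries
        self.grade_map: dict[str, float] = {
            g: float(v) for g, v in data.get("grade_map", {}).items()
        }
        self.dairy_markers = tuple(t.lower() for t in data.get("dairy_markers", ()))


def load_tables(path: str | None = None) -> HsrTables:
    return HsrTables(load_asset(path, "hsr_tables_v7.yaml"))


def assign_hsr_category(
    subgroup: str | None,
    basis: str,
    ingredients: Sequence[str] = (),
    cmap: CategoryMap | None = None,
    tables: HsrTables | None = None,
) -> str:
    """Route a product to C1/C1D/C2/C2D (or ``unscored``).

    The subgroup's category hint wins when present; otherwise beverages
    (per-100 mL basis) split dairy/non-dairy on a dairy-ingredient marker
    scan, and likewise for foods.
    """
    cmap = cmap or load_category_map()
    tables = tables or load_tables()
    if subgroup is not None and subgroup in cmap.subgroups:
        hint = cmap.info(subgroup).hsr_hint
        if hint in HSR_CATEGORIES or hint == UNSCORED:
            return hint
    dairy = any(any(tok in ing.lower() for tok in tables.dairy_markers) for ing in ingredients)
    if basis == "per100mL":
        return "C1D" if dairy else "C1"
    return "C2D" if dairy else "C2"


def combined_fvnl_pct(
    nonconc_pct: float, conc_pct: float, tables: HsrTables | None = None
):
    """Fold concentrated FVNL into a single percentage via the weighted
    rehydration formula ``(nc + w*c) / (100 + (w-1)*c) * 100``."""
    tables = tables or load_tables()
    w = tables.concentrated_weight
    combined = (nonconc_pct + w * conc_pct) / (100.0 + (w - 1.0) * conc_pct) * 100.0
    return np.minimum(combined, 100.0)


def baseline_points(panel: Mapping[str, float], tables: HsrTables | None = None, category: str = "C2") -> int:
    """Sum of the four risk-nutrient band lookups on a per-100 kJ panel."""
    tables = tables or load_tables()
    return int(
        tables.baseline["energy"].lookup(panel["energy"])
        + tables.baseline["saturated_fat"].lookup(panel["saturated_fat"])
        + tables.baseline["total_sugar"].lookup(panel["total_sugar"])
        + tables.baseline["sodium"].lookup(panel["sodium"])
    )


def modifying_points(
    panel: Mapping[str, float],
    tables: HsrTables | None = None,
    baseline: int | None = None,
    category: str = "C2",
) -> tuple[int, int, int]:
    """(V, P, F) modifying points.

    P points are only awarded when the baseline is below the cap threshold or
    V points reach the cap's minimum; component applicability varies by
    category (beverages earn V points only).
    """
    tables = tables or load_tables()
    if baseline is None:
        baseline = baseline_points(panel, tables, category)
    applies = tables.applicability.get(category, {"v": True, "p": True, "f": True})

    fvnl = combined_fvnl_pct(
        panel.get("fvnl_nonconc_pct") or 0.0, panel.get("fvnl_conc_pct") or 0.0, tables
    )
    v = int(tables.modifying["fvnl"].lookup(fvnl)) if applies["v"] else 0

    p = int(tables.modifying["protein"].lookup(panel.get("protein", 0.0))) if applies["p"] else 0
    if baseline >= tables.cap_baseline_threshold and v < tables.cap_min_v_points:
        p = 0

    fiber = panel.get("fiber")
    fiber = 0.0 if fiber is None or (isinstance(fiber, float) and math.isnan(fiber)) else fiber
    f = int(tables.modifying["fiber"].lookup(fiber)) if applies["f"] else 0
    return v, p, f


def score_to_stars(final_score: int, category: str, tables: HsrTables | None = None) -> float:
    """Convert a final score to the category's half-star rating (monotone
    non-increasing in score)."""
    tables = tables or load_tables()
    for bound, stars in tables.star_matrix[category]:
        if final_score <= bound:
            return stars
    raise AssertionError("star matrix has no catch-all row")  # pragma: no cover


def score_panel(
    panel: Mapping[str, float], category: str, tables: HsrTables | None = None
) -> HsrResult:
    """Full HSR computation for one standardized panel."""
    tables = tables or load_tables()
    if category == UNSCORED or category not in HSR_CATEGORIES:
        return HsrResult(
            category=UNSCORED,
            baseline_points=0,
            v_points=0,
            p_points=0,
            f_points=0,
            final_score=0,
            stars=None,
            table_version=tables.version,
        )
    base = baseline_points(panel, tables, category)
    v, p, f = modifying_points(panel, tables, base, category)
    final = base - (v + p + f)
    return HsrResult(
        category=category,
        baseline_points=base,
        v_points=v,
        p_points=p,
        f_points=f,
        final_score=final,
        stars=score_to_stars(final, category, tables),
        table_version=tables.version,
    )


def hsr_to_grade(stars: float, tables: HsrTables | None = None) -> str:
    """Summarize a star rating on a five-grade letter scale (A: 4.5-5.0,
    B: 3.0-3.5, then C/D/E descending in the same one-star pattern)."""
    tables = tables or load_tables()
    for grade, floor in sorted(tables.grade_map.items(), key=lambda kv: -kv[1]):
        if stars >= floor:
            return grade
    return min(tables.grade_map, key=lambda g: tables.grade_map[g])


def score_frame(
    frame: pd.DataFrame,
    tables: HsrTables | None = None,
    cmap: CategoryMap | None = None,
) -> pd.DataFrame:
    """Vectorized scoring; adds ``hsr_category``, point columns and ``stars``.

    Expects standardized panel columns plus ``thcl_subgroup``, ``basis`` and
    ``ingredients``.
    """
    tables = tables or load_tables()
    cmap = cmap or load_category_map()
    out = frame.copy()

    if "hsr_category" not in out.columns:
        hint_map = {name: info.hsr_hint for name, info in cmap.subgroups.items()}
        cats = out["thcl_subgroup"].map(hint_map)
        fallback = cats.isna()
        if fallback.any():
            cats.loc[fallback] = [
                assign_hsr_category(None, basis, ings, cmap, tables)
                for basis, ings in zip(
                    out.loc[fallback, "basis"], out.loc[fallback, "ingredients"]
                )
            ]
        out["hsr_category"] = cats

    scored = out["hsr_category"].isin(HSR_CATEGORIES)
    base = np.zeros(len(out), dtype=int)
    for nutrient in ("energy", "saturated_fat", "total_sugar", "sodium"):
        base += tables.baseline[nutrient].lookup(
            out[nutrient].to_numpy(dtype=float, na_value=0.0)
        )

    fvnl = combined_fvnl_pct(
        out.get("fvnl_nonconc_pct", pd.Series(0.0, index=out.index))
        .to_numpy(dtype=float, na_value=0.0),
        out.get("fvnl_conc_pct", pd.Series(0.0, index=out.index))
        .to_numpy(dtype=float, na_value=0.0),
        tables,
    )
    v = tables.modifying["fvnl"].lookup(fvnl)
    p = tables.modifying["protein"].lookup(out["protein"].to_numpy(dtype=float, na_value=0.0))
    f = tables.modifying["fiber"].lookup(out["fiber"].to_numpy(dtype=float, na_value=0.0))

    applies = out["hsr_category"].map(lambda c: tables.applicability.get(c, {}))
    v = np.where([a.get("v", False) for a in applies], v, 0)
    p = np.where([a.get("p", False) for a in applies], p, 0)
    f = np.where([a.get("f", False) for a in applies], f, 0)
    p = np.where((base >= tables.cap_baseline_threshold) & (v < tables.cap_min_v_points), 0, p)

    final = base - (v + p + f)
    stars = np.full(len(out), np.nan)
    for cat in HSR_CATEGORIES:
        mask = (out["hsr_category"] == cat).to_numpy()
        if mask.any():
            bounds = np.array([b for b, _ in tables.star_matrix[cat]])
            starvals = np.array([s for _, s in tables.star_matrix[cat]])
            idx = np.searchsorted(bounds, final[mask], side="left")
            stars[mask] = starvals[idx]

    out["baseline_points"] = np.where(scored, base, 0)
    out["v_points"] = np.where(scored, v, 0)
    out["p_points"] = np.where(scored, p, 0)
    out["f_points"] = np.where(scored, f, 0)
    out["final_score"] = np.where(scored, final, 0)
    out["stars"] = np.where(scored, stars, np.nan)
    out["hsr_table_version"] = tables.version
    return out
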