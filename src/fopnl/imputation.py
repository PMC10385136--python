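"""Fiber estimation and FVNL allocation from ordered ingredient lists.

Thai nutrition panels are not required to declare dietary fiber or the
fruit/vegetable/nut/legume (FVNL) content that the nutrient-profiling score
needs, so both are reconstructed here:

* fiber — for products listing a fiber-bearing ingredient but no declared
  value, either the subgroup mean of declared non-zero fiber (homogeneous
  subgroups such as dressings or wet soups) or the fiber of the most similar
  product with a declared value (heterogeneous subgroups; similarity =
  nearest energy density within the subgroup);
* FVNL — a four-band decision tree on the predominance rank of FVNL
  ingredients, allocating concentrated and non-concentrated percentages.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel

from ._assets import load_asset
from .categorization import CategoryMap, load_category_map

CONC_BANDS = ("lt25", "ge25", "ge67", "eq100")
NONCONC_BANDS = ("le40", "gt40", "gt80", "eq100")

#: band -> representative percentage under the two assignment policies
_BAND_VALUES = {
    "lower": {
        "lt25": 0.0, "ge25": 25.0, "ge67": 67.0, "eq100": 100.0,
        "le40": 0.0, "gt40": 40.0, "gt80": 80.0,
    },
    "midpoint": {
        "lt25": 12.5, "ge25": 46.0, "ge67": 83.5, "eq100": 100.0,
        "le40": 20.0, "gt40": 60.0, "gt80": 90.0,
    },
}


@dataclass(frozen=True)
class IngredientFlags:
    name: str
    fiber_source: bool
    fvnl_source: bool
    fvnl_concentrated: bool


class FvnlAllocation(BaseModel):
    conc_band: Literal["lt25", "ge25", "ge67", "eq100"]
    nonconc_band: Literal["le40", "gt40", "gt80", "eq100"]
    assigned_conc_pct: float
    assigned_nonconc_pct: float
    concentrated: bool
    rationale: str

    def as_panel_percents(self) -> tuple[float, float]:
        """(non-concentrated %, concentrated %) for the standardized panel;
        the form not present in the product is zero."""
        if self.concentrated:
            return 0.0, self.assigned_conc_pct
        return self.assigned_nonconc_pct, 0.0


class FiberImputation(BaseModel):
    strategy: Literal["declared", "category_mean", "matched_product", "zero_default"]
    value: float
    donor: Optional[str] = None
    warning: Optional[str] = None


@functools.lru_cache(maxsize=1)
def _default_lexicons() -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    fvnl = load_asset(None, "fvnl_lexicon.yaml")
    fiber = load_asset(None, "fiber_sources.yaml")
    minor = load_asset(None, "minor_additives.yaml")
    return (
        tuple(t.lower() for t in fvnl["fvnl_tokens"]),
        tuple(t.lower() for t in fvnl["concentrated_markers"]),
        tuple(t.lower() for t in fiber["fiber_tokens"]),
        tuple(t.lower() for t in minor["minor_additive_tokens"]),
    )


def detect_fvnl_ingredients(
    ingredients: Sequence[str],
    fvnl_tokens: Iterable[str] | None = None,
    concentrated_markers: Iterable[str] | None = None,
    fiber_tokens: Iterable[str] | None = None,
) -> list[IngredientFlags]:
    """Flag each ingredient as fiber source / FVNL source / concentrated FVNL.

    Matching is deterministic case-insensitive substring matching against the
    shipped lexicons (overridable). An empty ingredient list yields no flags.
    """
    d_fvnl, d_conc, d_fiber, _ = _default_lexicons()
    fvnl_tokens = tuple(fvnl_tokens) if fvnl_tokens is not None else d_fvnl
    concentrated_markers = (
        tuple(concentrated_markers) if concentrated_markers is not None else d_conc
    )
    fiber_tokens = tuple(fiber_tokens) if fiber_tokens is not None else d_fiber

    flags = []
    for name in ingredients:
        low = name.lower()
        is_fvnl = any(tok in low for tok in fvnl_tokens)
        flags.append(
            IngredientFlags(
                name=name,
                fiber_source=any(tok in low for tok in fiber_tokens),
                fvnl_source=is_fvnl,
                fvnl_concentrated=is_fvnl and any(tok in low for tok in concentrated_markers),
            )
        )
    return flags


def allocate_fvnl(
    ingredients: Sequence[str],
    flags: Sequence[IngredientFlags] | None = None,
    minor_additives: Iterable[str] | None = None,
    assign: Literal["lower", "midpoint"] = "lower",
) -> FvnlAllocation:
    """Allocate concentrated / non-concentrated FVNL bands from ingredient rank.

    Rules, most to least specific (exactly one fires):

    1. every weight-contributing ingredient is FVNL -> both bands 100%;
    2. FVNL is the first ingredient and all non-FVNL ingredients are minor
       additives (salt, flavouring, ...) -> concentrated >=67, non-conc >80;
    3. FVNL appears among the first three (concentrated) / first two
       (non-concentrated) ingredients -> >=25 / >40;
    4. otherwise -> <25 / <=40.

    The assigned percentage is the band's lower bound (``assign="lower"``,
    conservative for downstream V points) or midpoint.
    """
    if flags is None:
        flags = detect_fvnl_ingredients(ingredients)
    _, _, _, d_minor = _default_lexicons()
    additives = tuple(t.lower() for t in minor_additives) if minor_additives is not None else d_minor

    fvnl_positions = [i for i, f in enumerate(flags) if f.fvnl_source]
    non_fvnl = [f for f in flags if not f.fvnl_source]
    concentrated = any(f.fvnl_concentrated for f in flags)
    values = _BAND_VALUES[assign]

    if fvnl_positions and not non_fvnl:
        conc_band = nonconc_band = "eq100"
        rationale = "sole_ingredient"
    elif fvnl_positions and fvnl_positions[0] == 0 and all(
        any(tok in f.name.lower() for tok in additives) for f in non_fvnl
    ):
        conc_band, nonconc_band = "ge67", "gt80"
        rationale = "first_ingredient_minor_additives"
    elif fvnl_positions and fvnl_positions[0] <= 2:
        conc_band = "ge25"
        nonconc_band = "gt40" if fvnl_positions[0] <= 1 else "le40"
        rationale = "top_position"
    else:
        conc_band, nonconc_band = "lt25", "le40"
        rationale = "minor_position"

    return FvnlAllocation(
        conc_band=conc_band,
        nonconc_band=nonconc_band,
        assigned_conc_pct=values[conc_band],
        assigned_nonconc_pct=values[nonconc_band],
        concentrated=concentrated,
        rationale=rationale,
    )


def impute_fiber(
    declared_fiber: float | None,
    has_fiber_source: bool,
    donors: pd.DataFrame | None,
    homogeneous: bool,
    target_energy: float | None = None,
) -> FiberImputation:
    """Estimate fiber for one product.

    ``donors`` holds same-subgroup products with columns ``fiber``, ``energy``
    and ``barcode``; zero declared values are never used as donors. Declared
    values pass through untouched; products with no fiber-bearing ingredient
    default to zero.
    """
    if declared_fiber is not None and not (
        isinstance(declared_fiber, float) and math.isnan(declared_fiber)
    ):
        return FiberImputation(strategy="declared", value=float(declared_fiber))
    if not has_fiber_source:
        return FiberImputation(strategy="zero_default", value=0.0)

    if donors is not None:
        donors = donors[donors["fiber"].notna() & (donors["fiber"] > 0)]
    if donors is None or donors.empty:
        return FiberImputation(
            strategy="zero_default", value=0.0, warning="no donors with declared fiber"
        )

    if homogeneous:
        return FiberImputation(strategy="category_mean", value=float(donors["fiber"].mean()))

    if target_energy is None:
        raise ValueError("matched-product imputation needs the target energy density")
    gap = (donors["energy"] - target_energy).abs()
    # nearest energy; ties broken by lexicographically lowest barcode
    best = donors.assign(_gap=gap).sort_values(["_gap", "barcode"]).iloc[0]
    return FiberImputation(
        strategy="matched_product", value=float(best["fiber"]), donor=str(best["barcode"])
    )


def impute_fiber_frame(
    frame: pd.DataFrame, cmap: CategoryMap | None = None
) -> pd.DataFrame:
    """Batch fiber imputation; fills ``fiber`` and sets ``fiber_imputed``.

    Expects ``thcl_subgroup``, ``fiber``, ``energy``, ``barcode`` and
    ``ingredients`` columns. Declared values are never modified.
    """
    cmap = cmap or load_category_map()
    out = frame.copy()
    if "fiber_imputed" not in out.columns:
        out["fiber_imputed"] = False

    missing = out["fiber"].isna()
    if not missing.any():
        return out

    has_source = pd.Series(False, index=out.index)
    idx = out.index[missing]
    has_source.loc[idx] = [
        any(f.fiber_source for f in detect_fvnl_ingredients(ings))
        for ings in out.loc[idx, "ingredients"]
    ]

    # no fiber-bearing ingredient: fiber defaults to zero (not an imputation)
    out.loc[missing & ~has_source, "fiber"] = 0.0

    todo = missing & has_source
    for subgroup, block in out[todo].groupby("thcl_subgroup", dropna=False):
        if pd.isna(subgroup) or subgroup not in cmap.subgroups:
            out.loc[block.index, "fiber"] = 0.0
            continue
        homogeneous = cmap.info(str(subgroup)).fiber_homogeneous
        donors = out[
            (out["thcl_subgroup"] == subgroup) & out["fiber"].notna() & (out["fiber"] > 0) & ~todo
        ][["fiber", "energy", "barcode"]]
        for i in block.index:
            imp = impute_fiber(
                None,
                True,
                donors,
                homogeneous,
                target_energy=float(out.at[i, "energy"]),
            )
            out.at[i, "fiber"] = imp.value
            out.at[i, "fiber_imputed"] = imp.strategy in ("category_mean", "matched_product")
    out["fiber"] = out["fiber"].fillna(0.0)
    return out


def allocate_fvnl_frame(frame: pd.DataFrame, assign: Literal["lower", "midpoint"] = "lower") -> pd.DataFrame:
    """Batch FVNL allocation for rows with undeclared FVNL percentages.

    Ingredient lists repeat heavily across products, so allocations are
    memoized on the ingredient tuple.
    """
    out = frame.copy()
    for col in ("fvnl_nonconc_pct", "fvnl_conc_pct"):
        if col not in out.columns:
            out[col] = np.nan
    if "fvnl_imputed" not in out.columns:
        out["fvnl_imputed"] = False

    cache: dict[tuple[str, ...], tuple[float, float]] = {}

    def _alloc(ings: Sequence[str]) -> tuple[float, float]:
        key = tuple(ings)
        if key not in cache:
            cache[key] = allocate_fvnl(key, assign=assign).as_panel_percents()
        return cache[key]

    todo = out["fvnl_nonconc_pct"].isna() & out["fvnl_conc_pct"].isna()
    if todo.any():
        pairs = [_alloc(ings) for ings in out.loc[todo, "ingredients"]]
        out.loc[todo, "fvnl_nonconc_pct"] = [p[0] for p in pairs]
        out.loc[todo, "fvnl_conc_pct"] = [p[1] for p in pairs]
        out.loc[todo, "fvnl_imputed"] = True
    out[["fvnl_nonconc_pct", "fvnl_conc_pct"]] = out[["fvnl_nonconc_pct", "fvnl_conc_pct"]].fillna(0.0)
    return out
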