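"""Config-driven THCL eligibility rules engine.

A product is *eligible* when its standardized nutrient panel satisfies every
condition of its subgroup's criteria set (conditions are conjunctive, as in
other endorsement-logo schemes). Conditions compare a nutrient against a
threshold either per 100 g/mL or per a stated serving size. Eligibility is a
pure function of (panel, subgroup, criteria version); whether the product
actually displays the logo is a separate observation, and the cross of the
two yields the display-consistency tags used in uptake reporting.
"""

from __future__ import annotations

import math
from typing import Any, Literal, Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from ._assets import load_asset

FLAG_CONSISTENT = "displayed_eligible"
FLAG_ANOMALY = "displayed_ineligible"
FLAG_NON_ADOPTER = "not_displayed_eligible"
FLAG_NEUTRAL = "not_displayed_ineligible"


class Condition(BaseModel):
    nutrient: str
    op: Literal["le", "ge"]
    threshold: float = Field(ge=0)
    basis: Literal["per100", "per_serving"] = "per100"
    serving_size_g: Optional[float] = Field(default=None, gt=0)

    def describe(self) -> str:
        sym = "<=" if self.op == "le" else ">="
        unit = "/100" if self.basis == "per100" else f"/{self.serving_size_g:g} g serving"
        return f"{self.nutrient} {sym} {self.threshold:g}{unit}"

    def evaluate(self, panel: Mapping[str, Any], serving_size: float | None = None) -> bool:
        value = panel.get(self.nutrient)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False
        value = float(value)
        if self.basis == "per_serving":
            serving = serving_size if serving_size else self.serving_size_g
            if serving is None:
                return False
            value = value * serving / 100.0
        return value <= self.threshold if self.op == "le" else value >= self.threshold


class CriteriaSet(BaseModel):
    subgroup: str
    conditions: list[Condition]
    anchored: bool = False


class EligibilityResult(BaseModel):
    eligible: bool
    failed_conditions: list[str]
    criteria_version: str
    no_criteria: bool = False


class CriteriaRegistry:
    def __init__(self, data: Mapping[str, Any]):
        self.version: str = data.get("version", "unversioned")
        self.criteria: dict[str, CriteriaSet] = {
            name: CriteriaSet(
                subgroup=name,
                conditions=[Condition(**c) for c in entry["conditions"]],
                anchored=bool(entry.get("anchored", False)),
            )
            for name, entry in data["subgroups"].items()
        }

    def get(self, subgroup: str) -> CriteriaSet | None:
        return self.criteria.get(subgroup)

    def __contains__(self, subgroup: str) -> bool:  # pragma: no cover - trivial
        return subgroup in self.criteria


def load_criteria(path: str | None = None) -> CriteriaRegistry:
    return CriteriaRegistry(load_asset(path, "thcl_criteria.yaml"))


def check_eligibility(
    panel: Mapping[str, Any],
    subgroup: str,
    registry: CriteriaRegistry | None = None,
    serving_size: float | None = None,
) -> EligibilityResult:
    """Evaluate a subgroup's criteria on a standardized panel.

    Per-serving conditions use the product's declared serving size when
    given, and otherwise the criteria's stated serving size. A subgroup with
    no published criteria yields a flagged not-eligible result, since uptake
    analysis is restricted to subgroups with criteria.
    """
    registry = registry or load_criteria()
    criteria = registry.get(subgroup)
    if criteria is None:
        return EligibilityResult(
            eligible=False,
            failed_conditions=[],
            criteria_version=registry.version,
            no_criteria=True,
        )
    failed = [
        c.describe() for c in criteria.conditions if not c.evaluate(panel, serving_size)
    ]
    return EligibilityResult(
        eligible=not failed, failed_conditions=failed, criteria_version=registry.version
    )


def uptake_flag(displayed: bool, eligible: bool) -> str:
    """Display-consistency tag. ``displayed_ineligible`` is the anomaly case:
    real-world data can contain it (relabeling lag, data entry), synthetic
    data by construction does not unless the anomaly knob is raised."""
    if displayed:
        return FLAG_CONSISTENT if eligible else FLAG_ANOMALY
    return FLAG_NON_ADOPTER if eligible else FLAG_NEUTRAL


def check_frame(
    frame: pd.DataFrame, registry: CriteriaRegistry | None = None
) -> pd.DataFrame:
    """Vectorized eligibility; adds ``eligible``, ``n_failed_conditions`` and
    ``no_criteria`` columns keyed on ``thcl_subgroup``."""
    registry = registry or load_criteria()
    out = frame.copy()
    eligible = np.zeros(len(out), dtype=bool)
    n_failed = np.zeros(len(out), dtype=int)
    no_criteria = np.zeros(len(out), dtype=bool)

    serving = (
        out["serving_size"].to_numpy(dtype=float, na_value=np.nan)
        if "serving_size" in out.columns
        else np.full(len(out), np.nan)
    )

    grouped = out.groupby("thcl_subgroup", dropna=False).indices
    for subgroup, idx in grouped.items():
        if pd.isna(subgroup):
            continue
        criteria = registry.get(str(subgroup))
        if criteria is None:
            no_criteria[idx] = True
            continue
        ok = np.ones(len(idx), dtype=bool)
        fails = np.zeros(len(idx), dtype=int)
        for cond in criteria.conditions:
            values = out[cond.nutrient].to_numpy(dtype=float, na_value=np.nan)[idx]
            if cond.basis == "per_serving":
                stated = cond.serving_size_g if cond.serving_size_g is not None else np.nan
                srv = np.where(np.isnan(serving[idx]), stated, serving[idx])
                values = values * srv / 100.0
            passed = values <= cond.threshold if cond.op == "le" else values >= cond.threshold
            passed &= ~np.isnan(values)
            ok &= passed
            fails += (~passed).astype(int)
        eligible[idx] = ok
        n_failed[idx] = fails

    out["eligible"] = eligible
    out["n_failed_conditions"] = n_failed
    out["no_criteria"] = no_criteria
    out["criteria_version"] = registry.version
    if "thcl_displayed" in out.columns:
        disp = out["thcl_displayed"].astype(bool)
        out["uptake_flag"] = np.select(
            [disp & eligible, disp & ~eligible, ~disp & eligible],
            [FLAG_CONSISTENT, FLAG_ANOMALY, FLAG_NON_ADOPTER],
            default=FLAG_NEUTRAL,
        )
    return out
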